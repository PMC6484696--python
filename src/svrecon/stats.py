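"""Paired-measurement agreement and ordinal score comparison.

Implements the statistical toolbox used to validate 3D reconstructions
against a reference modality: intraclass correlation (two-way random effects,
absolute agreement, single measures — ICC(A,1)) with F-based confidence
intervals, Bland-Altman bias and limits of agreement, Lilliefors-corrected
Kolmogorov-Smirnov normality testing of the paired differences, a Wilcoxon
signed-rank test with exact null enumeration for small samples and a
tie-corrected normal approximation otherwise, and identification/score
summaries for structured anatomical assessments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors


def _paired_columns(pairs) -> Tuple[np.ndarray, np.ndarray]:
    """Extract two paired measurement columns; complete pairs only."""
    if isinstance(pairs, pd.DataFrame):
        num = pairs.select_dtypes("number")
        if num.shape[1] < 2:
            raise ValueError("need two numeric measurement columns")
        a = num.iloc[:, 0].to_numpy(dtype=float)
        b = num.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] < 2:
            raise ValueError("pairs must be (n, 2)")
        a, b = arr[:, 0], arr[:, 1]
    keep = np.isfinite(a) & np.isfinite(b)
    return a[keep], b[keep]


# -- intraclass correlation --------------------------------------------------


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    defined: bool = True


def icc_agreement(pairs, confidence: float = 0.95) -> ICCResult:
    """ICC(A,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA mean squares (subjects x raters) with the
    F-distribution confidence interval of McGraw & Wong. With zero total
    variance the coefficient is undefined and flagged.
    """
    a, b = _paired_columns(pairs)
    n = len(a)
    if n < 3:
        raise ValueError("ICC needs at least 3 complete pairs")
    data = np.stack([a, b], axis=1)  # n subjects x k raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    if np.allclose(data, grand):
        return ICCResult(np.nan, np.nan, np.nan, n, defined=False)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    alpha = 1.0 - confidence
    if abs(1.0 - icc) < 1e-15:
        return ICCResult(float(icc), float(icc), float(icc), n)
    a_coef = k * icc / (n * (1 - icc))
    b_coef = 1 + k * icc * (n - 1) / (n * (1 - icc))
    v = (a_coef * msc + b_coef * mse) ** 2 / (
        (a_coef * msc) ** 2 / (k - 1) + (b_coef * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_low = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f_up * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_up * msr)
    return ICCResult(float(icc), float(lo), float(hi), n)


# -- Bland-Altman ------------------------------------------------------------


@dataclass
class BlandAltmanResult:
    bias: float
    bias_ci: Tuple[float, float]
    loa_low: float
    loa_high: float
    sd: float
    paired_t_p: float
    n: int


def bland_altman(pairs, confidence: float = 0.95) -> BlandAltmanResult:
    """Bias (mean of A - B) with t-interval, and 95% limits of agreement.

    LoA = bias ± 1.96 * sd(differences) exactly, matching the conventional
    reporting of method-agreement studies.
    """
    a, b = _paired_columns(pairs)
    n = len(a)
    if n < 2:
        raise ValueError("Bland-Altman needs at least 2 complete pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(n)
    tcrit = sps.t.ppf(0.5 + confidence / 2, n - 1)
    if sd == 0:
        p = 0.0 if bias != 0 else 1.0
    else:
        tstat = bias / se
        p = float(2 * sps.t.sf(abs(tstat), n - 1))
    return BlandAltmanResult(
        bias=bias,
        bias_ci=(bias - tcrit * se, bias + tcrit * se),
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd=sd,
        paired_t_p=p,
        n=n,
    )


def ks_normality(diffs) -> float:
    """Lilliefors-corrected KS test of normality (mean/sd estimated from data)."""
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) < 4:
        raise ValueError("normality test needs at least 4 values")
    if np.ptp(d) == 0:
        raise ValueError("constant input: normality test undefined")
    _, p = lilliefors(d, dist="norm", pvalmethod="table")
    return float(p)


def paired_t(pairs) -> float:
    a, b = _paired_columns(pairs)
    return float(sps.ttest_rel(a, b).pvalue)


def unpaired_t(x, y) -> float:
    return float(sps.ttest_ind(np.asarray(x, float), np.asarray(y, float)).pvalue)


# -- Wilcoxon signed rank ----------------------------------------------------


@dataclass
class WilcoxonResult:
    p: float
    statistic: float  # W+ (sum of positive mid-ranks)
    n_higher: int
    n_tied: int
    n_lower: int
    method: str


def _signed_rank_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided p over all 2^n sign assignments, by convolution.

    Mid-ranks are doubled to integers so the distribution of 2*W+ can be built
    with a polynomial-multiplication dynamic programme.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(round(2 * w_obs))
    cdf = dist[: w2 + 1].sum()
    sf = dist[w2:].sum()
    return float(min(1.0, 2 * min(cdf, sf)))


def wilcoxon_signed_rank(diffs, exact_max_n: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon convention) but counted in the
    effect summary; ties get mid-ranks. Exact enumeration of the null for up
    to ``exact_max_n`` nonzero pairs, tie-corrected normal approximation with
    continuity correction otherwise.
    """
    d = np.asarray(diffs, dtype=float)
    n_higher = int((d > 0).sum())
    n_lower = int((d < 0).sum())
    n_tied = int((d == 0).sum())
    dz = d[d != 0]
    n = len(dz)
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(dz))
    w_pos = float(ranks[dz > 0].sum())
    if n <= exact_max_n:
        p = _signed_rank_exact_p(ranks, w_pos)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(np.abs(dz), return_counts=True)
        tie_term = np.sum(counts**3 - counts) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        diff = w_pos - mean
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
        method = "normal"
    return WilcoxonResult(p, w_pos, n_higher, n_tied, n_lower, method)


# -- structured anatomical assessment ----------------------------------------


SCORE_COLUMNS = ("identified_2d", "identified_3d", "score_2d", "score_3d")


def make_score_table(
    identified_2d, identified_3d, score_2d, score_3d, category=None
) -> pd.DataFrame:
    """Assemble an ordinal score table; scores must be 1-5 where identified."""
    df = pd.DataFrame(
        {
            "identified_2d": np.asarray(identified_2d, dtype=bool),
            "identified_3d": np.asarray(identified_3d, dtype=bool),
            "score_2d": np.asarray(score_2d, dtype=float),
            "score_3d": np.asarray(score_3d, dtype=float),
        }
    )
    if category is not None:
        df["category"] = category
    for mod in ("2d", "3d"):
        ided = df[f"identified_{mod}"]
        sc = df.loc[ided, f"score_{mod}"]
        if sc.isna().any() or not sc.isin([1, 2, 3, 4, 5]).all():
            raise ValueError(f"identified {mod} items need integer scores in 1..5")
        if df.loc[~ided, f"score_{mod}"].notna().any():
            raise ValueError(f"unidentified {mod} items must not carry scores")
    return df


def score_table_from_counts(
    n_items: int,
    n_identified_2d: int,
    n_identified_3d: int,
    n_higher_3d: int,
    n_tied: int,
    score_2d: int = 2,
    score_3d_higher: int = 4,
    score_3d_only: int = 4,
) -> pd.DataFrame:
    """Deterministic score table realising published summary counts.

    Items identified in 2D are assumed identified in 3D as well (consistent
    with head-to-head counts that exhaust the 2D-identified set); of those,
    the first ``n_higher_3d`` score higher in 3D and the next ``n_tied`` tie.
    """
    if n_higher_3d + n_tied != n_identified_2d:
        raise ValueError("higher + tied must equal the both-identified count")
    if not (n_identified_2d <= n_identified_3d <= n_items):
        raise ValueError("inconsistent identification counts")
    id2 = np.zeros(n_items, dtype=bool)
    id3 = np.zeros(n_items, dtype=bool)
    id2[:n_identified_2d] = True
    id3[:n_identified_3d] = True
    s2 = np.full(n_items, np.nan)
    s3 = np.full(n_items, np.nan)
    s2[:n_identified_2d] = score_2d
    s3[:n_higher_3d] = score_3d_higher
    s3[n_higher_3d : n_identified_2d] = score_2d  # tied
    s3[n_identified_2d : n_identified_3d] = score_3d_only
    return make_score_table(id2, id3, s2, s3)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def identification_summary(table: pd.DataFrame) -> dict:
    """Identification counts/percentages and head-to-head score tally.

    Percentages round half-up to the nearest integer; the head-to-head tally
    (higher / tied / lower for 3D) uses only items identified in both
    modalities.
    """
    if len(table) == 0:
        raise ValueError("empty score table")
    n = len(table)
    out = {"n_items": n}
    for mod in ("2d", "3d"):
        ided = table[f"identified_{mod}"]
        cnt = int(ided.sum())
        sc = table.loc[ided, f"score_{mod}"]
        out[mod] = {
            "identified": cnt,
            "identified_pct": _round_half_up(100.0 * cnt / n),
            "mean_score": float(sc.mean()) if cnt else np.nan,
            "median_score": float(sc.median()) if cnt else np.nan,
        }
    both = table["identified_2d"] & table["identified_3d"]
    d = (table.loc[both, "score_3d"] - table.loc[both, "score_2d"]).to_numpy()
    n_both = int(both.sum())
    out["head_to_head"] = {
        "n_comparable": n_both,
        "higher_3d": int((d > 0).sum()),
        "tied": int((d == 0).sum()),
        "lower_3d": int((d < 0).sum()),
        "higher_3d_pct": _round_half_up(100.0 * (d > 0).sum() / n_both) if n_both else np.nan,
    }
    if "category" in table.columns:
        out["by_category"] = {
            str(cat): {
                "n": int(len(g)),
                "identified_2d": int(g["identified_2d"].sum()),
                "identified_3d": int(g["identified_3d"].sum()),
            }
            for cat, g in table.groupby("category")
        }
    return out


def wilcoxon_scores(table: pd.DataFrame) -> WilcoxonResult:
    """Wilcoxon signed-rank on 3D-vs-2D scores over items identified in both."""
    both = table["identified_2d"] & table["identified_3d"]
    d = (table.loc[both, "score_3d"] - table.loc[both, "score_2d"]).to_numpy()
    if len(d) == 0:
        raise ValueError("no items identified in both modalities")
    return wilcoxon_signed_rank(d)


def summary_block(summary: dict, wilcoxon: Optional[WilcoxonResult] = None) -> str:
    """Printable paragraph mirroring the conventional reporting style."""
    n = summary["n_items"]
    s2, s3, hh = summary["2d"], summary["3d"], summary["head_to_head"]
    lines = [
        f"Structures identified in {s2['identified']} ({s2['identified_pct']}%) of {n} "
        f"instances in 2D data and {s3['identified']} ({s3['identified_pct']}%) of {n} in 3D data.",
        f"Where identified in both (n={hh['n_comparable']}), 3D scored higher in "
        f"{hh['higher_3d']} ({hh['higher_3d_pct']}%), tied in {hh['tied']}, lower in {hh['lower_3d']}.",
    ]
    if wilcoxon is not None:
        p = "<0.0001" if wilcoxon.p < 1e-4 else f"={wilcoxon.p:.4g}"
        lines.append(f"Wilcoxon signed-rank test p{p}.")
    return "\n".join(lines)
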