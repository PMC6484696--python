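"""Agreement statistics against exact and independent oracles."""

import numpy as np
import pandas as pd
import pytest

from svrecon import stats as st


# -- ICC ---------------------------------------------------------------------


@pytest.fixture()
def hand_table():
    # 6 paired vessel measurements (mm), two observers
    return np.array(
        [[5.1, 5.3], [4.2, 4.0], [6.8, 6.9], [3.9, 4.4], [5.5, 5.2], [4.8, 4.9]]
    )


def icc_a1_by_hand(data):
    """Explicit two-way ANOVA decomposition, written independently of the
    implementation: subjects as rows, raters as columns."""
    n, k = data.shape
    grand = data.mean()
    msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((data - data.mean(axis=1, keepdims=True) - data.mean(axis=0) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_icc_matches_hand_anova(hand_table):
    res = st.icc_agreement(hand_table)
    assert res.icc == pytest.approx(icc_a1_by_hand(hand_table), abs=1e-12)
    assert res.ci_low <= res.icc <= res.ci_high


def test_icc_matches_pingouin(hand_table):
    pg = pytest.importorskip("pingouin")
    n = len(hand_table)
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2),
            "rater": np.tile(["A", "B"], n),
            "value": hand_table.ravel(),
        }
    )
    ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="value")
    row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    res = st.icc_agreement(hand_table)
    assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
    # pingouin rounds its intervals to 2 decimals
    assert res.ci_low == pytest.approx(row["CI95"][0], abs=0.011)
    assert res.ci_high == pytest.approx(row["CI95"][1], abs=0.011)


def test_icc_perfect_agreement(hand_table):
    data = np.stack([hand_table[:, 0], hand_table[:, 0]], axis=1)
    assert st.icc_agreement(data).icc == pytest.approx(1.0)


def test_icc_column_swap_invariant(hand_table):
    assert st.icc_agreement(hand_table).icc == pytest.approx(
        st.icc_agreement(hand_table[:, ::-1]).icc, abs=1e-12
    )


def test_icc_shared_affine_invariance_and_differential_shift(hand_table):
    base = st.icc_agreement(hand_table).icc
    rescaled = st.icc_agreement(2.5 * hand_table + 7.0).icc
    assert rescaled == pytest.approx(base, abs=1e-10)
    shifted = hand_table.copy()
    shifted[:, 1] += 2.0  # systematic offset between raters
    assert st.icc_agreement(shifted).icc < base  # absolute agreement is sensitive


def test_icc_zero_variance_flagged():
    res = st.icc_agreement(np.full((5, 2), 4.2))
    assert not res.defined


# -- Bland-Altman ------------------------------------------------------------


def test_bland_altman_identity():
    a = np.array([3.0, 4.0, 5.0, 6.0])
    res = st.bland_altman(np.stack([a, a], axis=1))
    assert res.bias == 0.0
    assert res.loa_low == 0.0 and res.loa_high == 0.0


def test_bland_altman_closed_form():
    b = np.array([0.0, 0.0, 0.0])
    a = b + np.array([-1.0, 0.0, 1.0])
    res = st.bland_altman(np.stack([a, b], axis=1))
    assert res.bias == pytest.approx(0.0)
    assert res.sd == pytest.approx(1.0)
    assert res.loa_low == pytest.approx(-1.96)
    assert res.loa_high == pytest.approx(1.96)


def test_bland_altman_ci_matches_t_interval(rng):
    from scipy import stats as sps

    a = 5 + rng.standard_normal(50)
    b = a + 0.3 + 0.5 * rng.standard_normal(50)
    res = st.bland_altman(np.stack([a, b], axis=1))
    d = a - b
    se = d.std(ddof=1) / np.sqrt(len(d))
    tcrit = sps.t.ppf(0.975, len(d) - 1)
    assert res.bias_ci[0] == pytest.approx(d.mean() - tcrit * se, abs=1e-12)
    assert res.bias_ci[1] == pytest.approx(d.mean() + tcrit * se, abs=1e-12)
    assert res.paired_t_p == pytest.approx(sps.ttest_rel(a, b).pvalue, abs=1e-12)


# -- KS normality ------------------------------------------------------------


def test_ks_normality_calibration_and_power():
    """Normal data is rarely rejected; uniform data almost always is."""
    keep, reject = 0, 0
    n_seeds = 200
    for seed in range(n_seeds):
        r = np.random.default_rng(seed)
        if st.ks_normality(r.standard_normal(500)) > 0.05:
            keep += 1
        if st.ks_normality(r.random(500)) < 0.05:
            reject += 1
    assert keep >= 0.90 * n_seeds
    assert reject >= 0.95 * n_seeds


def test_ks_normality_preconditions():
    with pytest.raises(ValueError):
        st.ks_normality([0.1, 0.2, 0.3])
    with pytest.raises(ValueError):
        st.ks_normality([1.0, 1.0, 1.0, 1.0])


# -- Wilcoxon ----------------------------------------------------------------


def wilcoxon_p_by_full_enumeration(diffs):
    """Two-sided p over all 2^n sign assignments (tiny n only)."""
    from itertools import product

    from scipy.stats import rankdata

    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in product([0, 1], repeat=len(d)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    cdf = (ws <= w_obs + 1e-9).mean()
    sf = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(cdf, sf))


@pytest.mark.parametrize(
    "diffs",
    [
        [1, 2, -1, 3, 2, 1],
        [1, 1, 1, 1, -2, 3],
        [2, -3, 4, -1, 5, -2, 1, 1, -1, 2],
        [0.5, 1.5, -0.5, 2.5, 0.5, -1.5],
    ],
)
def test_wilcoxon_exact_matches_enumeration(diffs):
    res = st.wilcoxon_signed_rank(diffs)
    assert res.method == "exact"
    assert res.p == pytest.approx(wilcoxon_p_by_full_enumeration(diffs), abs=1e-12)


def test_wilcoxon_matches_scipy_without_ties():
    from scipy.stats import wilcoxon as scipy_wilcoxon

    d = [1.0, 2.0, -3.0, 4.0, 5.0, -6.0, 7.0, 8.5, -9.0, 10.0]
    res = st.wilcoxon_signed_rank(d)
    ref = scipy_wilcoxon(d, method="exact")
    assert res.p == pytest.approx(ref.pvalue, abs=1e-12)


def test_wilcoxon_one_sided_extreme():
    d = [1] * 10 + [0] * 5
    res = st.wilcoxon_signed_rank(d)
    assert res.p < 0.01
    assert res.n_higher == 10 and res.n_tied == 5 and res.n_lower == 0


def test_wilcoxon_all_ties_is_an_error():
    with pytest.raises(ValueError):
        st.wilcoxon_signed_rank([0, 0, 0])


def test_wilcoxon_exact_and_normal_agree_at_boundary(rng):
    """Tie-corrected normal approximation tracks the exact path at n=25.

    On continuous (untied) differences the two paths agree to a few
    thousandths; heavy ties coarsen the discrete null lattice and bound any
    normal approximation to ~0.02, so that case gets a looser cap.
    """
    errs_cont = []
    for _ in range(20):
        d = rng.standard_normal(25) + 0.3
        exact = st.wilcoxon_signed_rank(d, exact_max_n=25)
        approx = st.wilcoxon_signed_rank(d, exact_max_n=0)
        assert exact.method == "exact" and approx.method == "normal"
        errs_cont.append(abs(exact.p - approx.p))
        assert errs_cont[-1] < 0.01
    assert np.mean(errs_cont) < 0.005

    for _ in range(20):
        d = rng.integers(-3, 4, size=25)
        d = np.where(d == 0, 1, d)  # tie-heavy, n nonzero kept at 25
        exact = st.wilcoxon_signed_rank(d, exact_max_n=25)
        approx = st.wilcoxon_signed_rank(d, exact_max_n=0)
        assert abs(exact.p - approx.p) < 0.04


# -- identification summaries ------------------------------------------------


def test_identification_summary_reproduces_published_percentages():
    table = st.score_table_from_counts(680, 358, 657, 321, 37)
    out = st.identification_summary(table)
    assert out["2d"]["identified"] == 358 and out["2d"]["identified_pct"] == 53
    assert out["3d"]["identified"] == 657 and out["3d"]["identified_pct"] == 97
    hh = out["head_to_head"]
    assert hh["n_comparable"] == 358
    assert hh["higher_3d"] == 321 and hh["higher_3d_pct"] == 90
    assert hh["tied"] == 37 and hh["lower_3d"] == 0


def test_wilcoxon_scores_on_count_table_is_extreme():
    table = st.score_table_from_counts(680, 358, 657, 321, 37)
    res = st.wilcoxon_scores(table)
    assert res.p < 1e-4
    assert res.n_lower == 0


def test_score_table_validation():
    with pytest.raises(ValueError):
        st.make_score_table([True], [True], [6.0], [3.0])
    with pytest.raises(ValueError):
        st.make_score_table([False], [True], [2.0], [3.0])
    with pytest.raises(ValueError):
        st.identification_summary(st.score_table_from_counts(0, 0, 0, 0, 0))


def test_summary_block_mentions_key_numbers():
    table = st.score_table_from_counts(680, 358, 657, 321, 37)
    text = st.summary_block(st.identification_summary(table), st.wilcoxon_scores(table))
    for token in ("53%", "97%", "90%", "Wilcoxon"):
        assert token in text
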