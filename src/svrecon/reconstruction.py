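"""Super-resolution reconstruction with EM outlier rejection.

The forward model treats every acquired slice pixel ``y_ij`` (slice i, pixel
j) as a PSF-weighted average of the unknown isotropic volume ``x`` under the
slice's rigid transform::

    y_ij ≈ s_i * sum_k m_ijk x_k,      sum_k m_ijk = 1

with per-slice gain ``s_i``. The coefficients ``m_ijk`` are the discretised
slice-profile PSF evaluated at voxel centres and row-normalised
(:func:`build_coefficients`). Reconstruction interleaves:

* slice-to-volume registration against the evolving estimate,
* closed-form per-slice gain estimation,
* EM robust statistics: a Gaussian-inlier / uniform-outlier mixture on pixel
  residuals gives voxel posteriors ``p_ij``; a second two-class mixture on
  per-slice mean posteriors gives slice weights ``w_i`` — data beyond these
  statistically defined limits is excluded,
* gradient steps on the weighted least-squares data term plus an
  edge-preserving first-difference (Huber) penalty whose influence saturates
  for neighbour differences above ``delta`` — the gradient-descent form of
  anisotropic diffusion between data updates.

Only voxels inside the mask are ever written: the masked anatomy is treated
as a single rigid patch and everything outside it is ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

from .geometry import RigidTransform
from .image import Mask, Stack, Volume
from .psf import PointSpreadFunction
from .registration import (
    DEFAULT_SLICE_SCHEDULE,
    REFINE_SLICE_SCHEDULE,
    RegistrationResult,
    register_slice_to_volume,
    register_volume_to_volume,
    select_template,
)


class ReconstructionError(RuntimeError):
    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report or {}


@dataclass
class ReconConfig:
    """Tunable reconstruction parameters (units in docstrings below).

    * ``spacing``: output isotropic voxel size, mm; must lie in [0.50, 0.75].
    * ``n_outer``: outer iterations of {registration, scales, EM, SR steps}.
    * ``n_sr``: super-resolution gradient steps per outer iteration.
    * ``alpha``: gradient step size.
    * ``lambda_reg``: edge-preserving regularisation weight.
    * ``delta_frac``: edge threshold as a fraction of the robust intensity
      range — neighbour differences above it are treated as edges and their
      smoothing influence saturates.
    * ``slice_exclusion_threshold``: slices with EM weight below this are
      excluded from the data term.
    """

    spacing: float = 0.7
    n_outer: int = 4
    n_sr: int = 15
    n_sr_final: int = 40
    alpha: float = 1.0
    lambda_reg: float = 0.05
    delta_frac: float = 0.05
    slice_exclusion_threshold: float = 0.2
    pad_mm: float = 4.0
    mask_dilation_mm: float = 3.0
    warmup_sr: bool = True  # SR-refine the average before the first registration pass
    seed: int = 0
    skip_stack_init: bool = False

    def __post_init__(self):
        if not (0.50 <= self.spacing <= 0.75):
            raise ValueError("output spacing must lie in [0.50, 0.75] mm")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.delta_frac <= 0:
            raise ValueError("delta_frac must be > 0")


@dataclass
class EMState:
    """Voxel posteriors and slice weights — the statistically defined limits."""

    p: np.ndarray  # inlier posterior per (valid) pixel, in [0, 1]
    sigma: float  # inlier residual sd, intensity units
    c: float  # inlier mixing fraction
    slice_weights: np.ndarray  # w_i in [0, 1]
    excluded: np.ndarray  # bool per slice


@dataclass
class CoefficientMap:
    """Sparse row-normalised PSF coefficients for all non-excluded slices."""

    matrix: sparse.csr_matrix  # (n_pixels, n_voxels)
    y: np.ndarray  # acquired pixel values
    valid: np.ndarray  # pixel usable: footprint inside grid and mask
    slice_ids: np.ndarray  # flat slice id per pixel
    slice_keys: List[Tuple[str, int]]  # (stack_id, slice index) per flat id
    grid: Volume

    @property
    def n_slices(self) -> int:
        return len(self.slice_keys)

    def simulate(self, x: np.ndarray) -> np.ndarray:
        """Forward-project the volume into slice pixels (unit gain)."""
        return self.matrix @ np.asarray(x, dtype=float).ravel()

    def rows_for_slice(self, flat_id: int) -> np.ndarray:
        return np.where(self.slice_ids == flat_id)[0]


def build_coefficients(
    stacks: Sequence[Stack],
    grid: Volume,
    psf: Optional[PointSpreadFunction] = None,
    mask: Optional[Mask] = None,
) -> CoefficientMap:
    """Discretise the PSF forward model onto the output grid.

    For every non-excluded slice pixel, the PSF is evaluated at the centres of
    the output voxels inside its (rigidly moved) support box and the weights
    are normalised to sum to one. Pixels whose support leaks outside the grid,
    or whose centre falls outside the mask, are flagged invalid and carry no
    coefficients.
    """
    A = grid.affine[:3, :3]
    shape = np.asarray(grid.shape)
    data_parts: List[np.ndarray] = []
    col_parts: List[np.ndarray] = []
    counts_parts: List[np.ndarray] = []
    y_parts: List[np.ndarray] = []
    valid_parts: List[np.ndarray] = []
    sid_parts: List[np.ndarray] = []
    slice_keys: List[Tuple[str, int]] = []

    for stack in stacks:
        for s in stack.slices:
            if s.excluded:
                continue
            flat_id = len(slice_keys)
            slice_keys.append((stack.id or "stack", s.index_in_stack))
            if psf is None:
                psf_s = PointSpreadFunction.for_geometry(s.geometry)
            else:
                psf_s = psf
            T = s.transform
            F = T.rotation_matrix @ s.geometry.orientation  # slice axes in world, after motion
            Pw = T.apply(s.pixel_world().reshape(-1, 3))
            n_px = len(Pw)
            counts = np.zeros(n_px, dtype=np.int64)
            ok = np.ones(n_px, dtype=bool)
            if mask is not None:
                ok &= mask.sample(Pw) > 0.5
            sel = np.where(ok)[0]

            if len(sel):
                Ps = Pw[sel]
                C = grid.world_to_index(Ps)
                half_mm = psf_s.support_cutoff * psf_s.sigmas
                M_ix = np.linalg.inv(A) @ F
                half_idx = np.abs(M_ix) @ half_mm
                axes = [np.arange(-int(np.ceil(h)), int(np.ceil(h)) + 1) for h in half_idx]
                D = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

                base = np.floor(C + 0.5).astype(np.int64)
                V = base[:, None, :] + D[None, :, :]  # (n_sel, m, 3)
                d_world = (V @ A.T + grid.affine[:3, 3]) - Ps[:, None, :]
                d_slice = d_world @ F
                w = psf_s.weight(d_slice)
                inside = np.all((V >= 0) & (V <= shape - 1), axis=-1)
                w_in = np.where(inside, w, 0.0)
                sum_all = w.sum(axis=1)
                sum_in = w_in.sum(axis=1)
                ok_sel = (sum_in > 0) & (sum_in >= 0.999 * sum_all)
                ok[sel] = ok_sel

                w_norm = np.where(
                    ok_sel[:, None], w_in / np.where(sum_in > 0, sum_in, 1.0)[:, None], 0.0
                )
                keep = w_norm > 0
                counts[sel] = keep.sum(axis=1)
                Vc = np.clip(V, 0, shape - 1)
                flat_vox = np.ravel_multi_index(
                    (Vc[..., 0], Vc[..., 1], Vc[..., 2]), tuple(shape.tolist())
                )
                data_parts.append(w_norm[keep])
                col_parts.append(flat_vox[keep].astype(np.int32))
            else:
                ok[:] = False
            counts_parts.append(counts)
            y_parts.append(s.pixels.ravel() / 1.0)
            valid_parts.append(ok)
            sid_parts.append(np.full(n_px, flat_id, dtype=np.int32))

    if not slice_keys:
        raise ReconstructionError("no usable slices intersect the reconstruction grid")

    counts = np.concatenate(counts_parts)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    matrix = sparse.csr_matrix(
        (np.concatenate(data_parts), np.concatenate(col_parts), indptr),
        shape=(len(counts), int(np.prod(shape))),
    )
    cmap = CoefficientMap(
        matrix=matrix,
        y=np.concatenate(y_parts),
        valid=np.concatenate(valid_parts),
        slice_ids=np.concatenate(sid_parts),
        slice_keys=slice_keys,
        grid=grid,
    )
    if cmap.valid.sum() == 0:
        raise ReconstructionError("coefficient map is empty: no slice intersects grid/mask")
    return cmap


def initialize_volume(cmap: CoefficientMap, mask_grid: np.ndarray) -> np.ndarray:
    """PSF-weighted scattered average of all pixels onto the grid (masked).

    ``M^T y / M^T 1`` with row-normalised coefficients is a partition-of-unity
    weighted average, so a constant input reproduces the constant.
    """
    v = cmap.valid.astype(float)
    num = cmap.matrix.T @ (v * cmap.y)
    den = cmap.matrix.T @ v
    x = np.where(den > 1e-9, num / np.where(den > 0, den, 1.0), 0.0)
    x = x.reshape(cmap.grid.shape)
    x[~mask_grid] = 0.0
    return x


def estimate_slice_scales(cmap: CoefficientMap, x: np.ndarray) -> np.ndarray:
    """Closed-form least-squares gain per slice: min_s sum_j (s*yhat - y)^2."""
    yhat = cmap.simulate(x)
    n = cmap.n_slices
    scales = np.ones(n)
    v = cmap.valid
    num = np.bincount(cmap.slice_ids[v], weights=(yhat * cmap.y)[v], minlength=n)
    den = np.bincount(cmap.slice_ids[v], weights=(yhat * yhat)[v], minlength=n)
    nz = den > 1e-12
    scales[nz] = np.clip(num[nz] / den[nz], 0.2, 5.0)
    if (~nz).any():
        warnings.warn(f"{(~nz).sum()} slice(s) simulate to zero; scale kept at 1")
    return scales


def _two_class_slice_mixture(m: np.ndarray, n_iter: int = 30) -> np.ndarray:
    """Posterior of the 'consistent' class for per-slice mean posteriors.

    1D two-component Gaussian mixture, shared variance. Degenerate fits
    (classes collapsing or a single slice) fall back to the raw means.
    """
    m = np.asarray(m, dtype=float)
    if len(m) < 3 or np.ptp(m) < 1e-3:
        return m.copy()
    mu = np.array([np.percentile(m, 10), np.percentile(m, 90)])
    var = max(np.var(m) / 4.0, 1e-6)
    pi = np.array([0.5, 0.5])
    for _ in range(n_iter):
        d = (m[:, None] - mu[None, :]) ** 2
        logr = np.log(pi[None, :] + 1e-12) - d / (2 * var)
        logr -= logr.max(axis=1, keepdims=True)
        r = np.exp(logr)
        r /= r.sum(axis=1, keepdims=True)
        nk = r.sum(axis=0)
        if np.any(nk < 1e-6):
            return m.copy()
        mu = (r * m[:, None]).sum(axis=0) / nk
        var = max(float((r * d).sum() / len(m)), 1e-6)
        pi = nk / len(m)
    lo_c, up_c = int(np.argmin(mu)), int(np.argmax(mu))
    # the split is only meaningful when the lower class is genuinely worse:
    # a tight all-consistent cluster must not be cut in half
    if mu[up_c] - mu[lo_c] < 0.1 or mu[lo_c] > 0.6:
        return m.copy()
    return r[:, up_c]


def em_robust_update(
    residuals: np.ndarray,
    slice_ids: np.ndarray,
    n_slices: int,
    state: Optional[EMState] = None,
    intensity_range: Optional[float] = None,
    exclusion_threshold: float = 0.2,
    n_iterations: int = 25,
) -> EMState:
    """One EM pass of the Gaussian-inlier / uniform-outlier mixture.

    ``residuals`` are the (valid-pixel) differences between gain-corrected
    acquired pixels and the simulated slices; ``slice_ids`` maps each residual
    to its slice. Voxel posteriors, the inlier sd and mixing fraction are
    re-estimated by weighted maximum likelihood; per-slice mean posteriors are
    pushed through a second two-class mixture to give slice weights, and
    slices below ``exclusion_threshold`` are excluded.
    """
    e = np.asarray(residuals, dtype=float)
    if intensity_range is None:
        intensity_range = max(float(np.ptp(e)), 1e-12)
    # support of the uniform outlier component: the observed residual range,
    # floored so that a (near-)perfect fit cannot make the density explode
    obs_range = max(float(np.ptp(e)), 0.01 * intensity_range, 1e-12)
    sigma_floor = 1e-6 * intensity_range
    sigma = state.sigma if state is not None else max(float(e.std()), sigma_floor)
    c = state.c if state is not None else 0.9
    u_density = 1.0 / obs_range

    p = np.ones_like(e)
    for _ in range(n_iterations):
        sigma = max(sigma, sigma_floor)
        g = np.exp(-0.5 * (e / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        num = c * g
        p = num / (num + (1.0 - c) * u_density)
        psum = p.sum()
        if psum < 1e-12:
            break
        sigma = max(float(np.sqrt((p * e * e).sum() / psum)), sigma_floor)
        c = float(np.clip(p.mean(), 1e-3, 1.0 - 1e-3))

    counts = np.bincount(slice_ids, minlength=n_slices).astype(float)
    sums = np.bincount(slice_ids, weights=p, minlength=n_slices)
    m = np.where(counts > 0, sums / np.maximum(counts, 1.0), 0.0)
    w = np.ones(n_slices)
    present = counts > 0
    w[present] = _two_class_slice_mixture(m[present])
    w[~present] = 0.0
    excluded = w < exclusion_threshold
    return EMState(p=p, sigma=sigma, c=c, slice_weights=w, excluded=excluded)


def edge_preserving_gradient(x: np.ndarray, delta: float) -> np.ndarray:
    """Gradient of the Huber first-difference penalty over 6-neighbourhoods.

    The influence function psi(d) = clip(d, -delta, delta) saturates across
    edges, so flat regions are smoothed while step edges are preserved —
    the variational counterpart of anisotropic diffusion filtering.
    """
    g = np.zeros_like(x, dtype=float)
    for axis in range(3):
        d = np.diff(x, axis=axis)
        psi = np.clip(d, -delta, delta)
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[axis] = slice(1, None)
        sl_lo[axis] = slice(None, -1)
        g[tuple(sl_hi)] += psi  # x_k - x_{k-1}
        g[tuple(sl_lo)] -= psi  # x_k - x_{k+1} enters with opposite sign
    return g


def superresolution_step(
    x: np.ndarray,
    cmap: CoefficientMap,
    scales: np.ndarray,
    em: EMState,
    mask_grid: np.ndarray,
    alpha: float = 0.1,
    lambda_reg: float = 0.02,
    delta: float = 1.0,
) -> Tuple[np.ndarray, float]:
    """One gradient step on the robust data term plus edge-preserving penalty.

    x_k <- x_k + alpha * sum_ij w_i p_ij m_ijk (y_ij/s_i - yhat_ij)
               - alpha * lambda * dR/dx_k        (inside the mask only)

    Returns the updated volume and the EM-weighted data misfit before the step.
    """
    shape = x.shape
    xf = x.ravel()
    yhat = cmap.matrix @ xf
    s_px = scales[cmap.slice_ids]
    w_px = em.slice_weights[cmap.slice_ids] * (~em.excluded[cmap.slice_ids])
    e = np.where(cmap.valid, cmap.y / s_px - yhat, 0.0)
    p = np.zeros_like(e)
    p[cmap.valid] = em.p if em.p.shape == e[cmap.valid].shape else 1.0
    weight = w_px * p * cmap.valid
    misfit = float((weight * e * e).sum())
    grad = cmap.matrix.T @ (weight * e)
    x_new = xf + alpha * grad
    x_new = x_new.reshape(shape)
    if lambda_reg > 0:
        x_new = x_new - alpha * lambda_reg * edge_preserving_gradient(x.reshape(shape), delta)
    x_new[~mask_grid] = 0.0
    return x_new, misfit


def _smooth_pose_trajectory(stack: Stack, centroid, window: int = 5) -> None:
    """Median-filter the per-parameter pose sequence in acquisition order."""
    from scipy import ndimage as _ndi

    acq = [i for i in stack.acquisition_order if not stack.slices[i].excluded]
    if len(acq) < window:
        return
    P = np.stack([stack.slices[i].transform.params for i in acq])
    P_s = np.stack(
        [_ndi.median_filter(P[:, j], size=window, mode="nearest") for j in range(6)],
        axis=1,
    )
    for k, i in enumerate(acq):
        stack.slices[i].transform = RigidTransform.from_params(P_s[k], center=centroid)


@dataclass
class ReconResult:
    volume: Volume
    transforms_before: Dict[str, List[RigidTransform]]
    transforms_after: Dict[str, List[RigidTransform]]
    report: dict
    em_state: Optional[EMState] = None


def make_output_grid(mask: Mask, spacing: float, pad_mm: float = 3.0) -> Volume:
    lo, hi = mask.bounding_box_world()
    lo = lo - pad_mm
    hi = hi + pad_mm
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    aff = np.diag([spacing, spacing, spacing, 1.0])
    aff[:3, 3] = lo
    return Volume(np.zeros(shape), aff)


def reconstruct(
    stacks: Sequence[Stack],
    mask: Mask,
    config: Optional[ReconConfig] = None,
    psf: Optional[PointSpreadFunction] = None,
    verbose: bool = False,
) -> ReconResult:
    """Full motion-corrected super-resolution pipeline.

    Template selection by motion score, volume-to-volume initialisation of the
    remaining stacks, then ``n_outer`` iterations of {slice-to-volume
    registration of every slice, gain estimation, EM robust statistics,
    ``n_sr`` super-resolution steps}, on an isotropic output grid derived from
    the mask. Deterministic given the inputs. Emits before/after transform
    logs and an exclusion report.
    """
    if config is None:
        config = ReconConfig()
    if not stacks:
        raise ValueError("at least one stack is required")
    work = [st.shallow_copy() for st in stacks]
    centroid = mask.centroid_world()
    for st in work:
        for s in st.slices:
            s.transform = s.transform.with_center(centroid)

    grid = make_output_grid(mask, config.spacing, config.pad_mm)
    grid_world = grid.grid_world().reshape(-1, 3)
    mask_out = mask.sample(grid_world).reshape(grid.shape) >= 0.5
    if not mask_out.any():
        raise ReconstructionError("mask is empty on the output grid")
    # the solver works on a slightly dilated mask so that the anatomy/air edge
    # just outside the region of interest stays representable; voxels outside
    # the *input* mask are zeroed in the output, preserving the masked-patch
    # contract while keeping boundary voxels well conditioned
    from scipy import ndimage as _ndi

    dil_vox = max(int(np.ceil(config.mask_dilation_mm / float(np.min(mask.as_volume().spacing)))), 1)
    mask_dil = Mask(_ndi.binary_dilation(mask.data, iterations=dil_vox), mask.affine)
    mask_grid = mask_dil.sample(grid_world).reshape(grid.shape) >= 0.5

    transforms_before = {
        st.id: [s.transform for s in st.slices] for st in work
    }

    all_px = np.concatenate([s.pixels.ravel() for st in work for s in st.slices])
    intensity_range = float(
        np.percentile(all_px, 99.5) - np.percentile(all_px, 0.5)
    )
    intensity_range = max(intensity_range, 1e-9)
    delta = config.delta_frac * intensity_range

    template_idx = select_template(work)
    if verbose:
        print(f"[reconstruct] template stack: {work[template_idx].id}")

    cmap = build_coefficients(work, grid, psf, mask_dil)
    x = initialize_volume(cmap, mask_grid)

    if not config.skip_stack_init and len(work) > 1:
        # stack-level initialisation: each stack is rigidly registered to the
        # scattered average of all stacks, which shares the mask's frame (the
        # template defines the least-motion content but the average defines
        # the common frame); slices inherit their stack's pose
        fixed = Volume(x, grid.affine)
        moved = False
        for st in work:
            try:
                res = register_volume_to_volume(
                    st.as_volume(), fixed, mask=mask_dil,
                    init=RigidTransform.identity(center=centroid),
                )
                for s in st.slices:
                    s.transform = res.transform
                moved = True
            except ValueError:
                warnings.warn(f"stack {st.id}: no overlap with average; init kept at identity")
        if moved:
            cmap = build_coefficients(work, grid, psf, mask_dil)
            x = initialize_volume(cmap, mask_grid)

    em = EMState(
        p=np.ones(int(cmap.valid.sum())),
        sigma=0.1 * intensity_range,
        c=0.9,
        slice_weights=np.ones(cmap.n_slices),
        excluded=np.zeros(cmap.n_slices, dtype=bool),
    )
    scales = np.ones(cmap.n_slices)
    misfit_history: List[float] = []
    alpha = config.alpha

    def intensity_pass(n_steps=None):
        """Gain estimation, EM robust statistics and SR gradient steps."""
        nonlocal x, scales, em, alpha
        scales = estimate_slice_scales(cmap, x)
        yhat = cmap.simulate(x)
        s_px = scales[cmap.slice_ids]
        e_valid = (cmap.y / s_px - yhat)[cmap.valid]
        em = em_robust_update(
            e_valid,
            cmap.slice_ids[cmap.valid],
            cmap.n_slices,
            state=None,
            intensity_range=intensity_range,
            exclusion_threshold=config.slice_exclusion_threshold,
        )
        grow = 0
        prev = np.inf
        for _ in range(n_steps if n_steps is not None else config.n_sr):
            x, misfit = superresolution_step(
                x, cmap, scales, em, mask_grid,
                alpha=alpha, lambda_reg=config.lambda_reg, delta=delta,
            )
            misfit_history.append(misfit)
            if misfit > prev:
                grow += 1
                if grow >= 2:
                    alpha *= 0.5  # divergence guard
                    grow = 0
            else:
                grow = 0
            prev = misfit

    for outer in range(config.n_outer):
        # refine intensities first so registration always targets an
        # SR-sharpened estimate rather than the doubly-blurred average
        if outer > 0 or config.warmup_sr:
            intensity_pass()
        current = Volume(x, grid.affine)
        first = outer == 0
        stage_cache: dict = {}  # per-orientation blurred volumes, this outer pass
        for st in work:
            sims = {}
            for s in st.slices:
                if s.excluded:
                    continue
                res = register_slice_to_volume(
                    s, current, mask=mask_dil, init=s.transform, psf=psf,
                    schedule=DEFAULT_SLICE_SCHEDULE if first else REFINE_SLICE_SCHEDULE,
                    seed_search=(4.0, 3.0) if first else None,
                    stage_cache=stage_cache,
                )
                if res.exclude_suggested:
                    s.excluded = True
                elif res.converged:
                    s.transform = res.transform
                    sims[s.index_in_stack] = res.similarity
            # rescue pass: motion is continuous in acquisition time, so a
            # slice that registered much worse than its stack's median is
            # retried from the poses of its temporal neighbours (typically a
            # capture failure after a sudden movement)
            if len(sims) >= 5:
                med = float(np.median(list(sims.values())))
                acq = [i for i in st.acquisition_order if i in sims]
                pos = {i: k for k, i in enumerate(acq)}
                for s in st.slices:
                    i = s.index_in_stack
                    if i not in sims or sims[i] >= med - 0.05:
                        continue
                    k = pos[i]
                    inits = []
                    if k > 0:
                        inits.append(st.slices[acq[k - 1]].transform)
                    if k + 1 < len(acq):
                        inits.append(st.slices[acq[k + 1]].transform)
                    best_sim, best_T = sims[i], None
                    for init_T in inits:
                        res = register_slice_to_volume(
                            s, current, mask=mask_dil, init=init_T, psf=psf,
                            schedule=DEFAULT_SLICE_SCHEDULE, seed_search=(4.0, 3.0),
                            stage_cache=stage_cache,
                        )
                        if res.converged and res.similarity > best_sim + 0.01:
                            best_sim, best_T = res.similarity, res.transform
                    if best_T is not None:
                        s.transform = best_T
                        sims[i] = best_sim
            # temporal pose smoothing: the true motion drifts only ~0.1 mm
            # between consecutive acquisitions while independent per-slice
            # registration errors are several times larger, so a short median
            # filter along acquisition time suppresses the noise and keeps
            # genuine jumps (median filters preserve steps)
            _smooth_pose_trajectory(st, centroid)
        cmap = build_coefficients(work, grid, psf, mask_dil)
        if verbose and misfit_history:
            print(
                f"[reconstruct] outer {outer + 1}/{config.n_outer}: "
                f"misfit {misfit_history[-1]:.4g}, sigma {em.sigma:.3g}, "
                f"excluded {int(em.excluded.sum())}/{cmap.n_slices}",
                flush=True,
            )

    # gauge fixing: per-slice registration never constrains the common-mode
    # pose, so the frame drifts slowly over the outer iterations. The input
    # mask outlines the anatomy in the target frame, so the drift is
    # estimated blindly by rigidly registering the reconstructed occupancy
    # (smoothed indicator of supra-threshold tissue) to the smoothed mask
    # indicator; ``x(p) ~ truth(G p)`` then gives corrected poses G∘T and a
    # resampled volume. Applied once, after the final registration pass.
    try:
        thr = 0.5 * float(np.percentile(x[mask_grid], 90))
        sig_vox = 2.0 / config.spacing
        occ = _ndi.gaussian_filter((x > thr).astype(float), sig_vox)
        ref = _ndi.gaussian_filter(mask_out.astype(float), sig_vox)
        gres = register_volume_to_volume(
            Volume(occ, grid.affine), Volume(ref, grid.affine),
            init=RigidTransform.identity(center=centroid), anchor_weight=1e-6,
        )
        G = gres.transform
    except ValueError:
        G = RigidTransform.identity(center=centroid)
    if G.magnitude() > 1e-3:
        for st in work:
            for s in st.slices:
                s.transform = G.compose(s.transform)
        x = Volume(x, grid.affine).sample(G.invert().apply(grid_world)).reshape(grid.shape)
        x[~mask_grid] = 0.0
        cmap = build_coefficients(work, grid, psf, mask_dil)

    # final robust exclusion: per-slice agreement (NCC between acquired and
    # simulated pixels) is a direct readout of residual misregistration;
    # slices falling more than 3 robust standard deviations below the cohort
    # median vary beyond the statistically defined limits and are dropped
    # before the final intensity pass
    from .registration import ncc as _ncc

    yhat_fin = cmap.simulate(x)
    slice_ncc = {}
    for i in range(cmap.n_slices):
        rows = np.where((cmap.slice_ids == i) & cmap.valid)[0]
        if len(rows) >= 40:
            slice_ncc[i] = _ncc(cmap.y[rows], yhat_fin[rows])
    if len(slice_ncc) >= 10:
        vals = np.array(list(slice_ncc.values()))
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        cut = med - 3.0 * 1.4826 * max(mad, 1e-6)
        drop_keys = {cmap.slice_keys[i] for i, v in slice_ncc.items() if v < cut}
        if drop_keys and len(drop_keys) < 0.5 * cmap.n_slices:
            for st in work:
                for s in st.slices:
                    if (st.id or "stack", s.index_in_stack) in drop_keys:
                        s.excluded = True
            cmap = build_coefficients(work, grid, psf, mask_dil)

    # final intensity pass so the output volume reflects the final poses;
    # run longer here because the gauge resample and final exclusions leave
    # the estimate a little stale
    intensity_pass(config.n_sr_final)

    # final bookkeeping: push EM decisions onto the slices for the report
    weights_by_key = dict(zip(cmap.slice_keys, em.slice_weights))
    excl_by_key = dict(zip(cmap.slice_keys, em.excluded))
    scale_by_key = dict(zip(cmap.slice_keys, scales))
    n_total = 0
    n_excluded = 0
    for st in work:
        for s in st.slices:
            n_total += 1
            key = (st.id or "stack", s.index_in_stack)
            if key in weights_by_key:
                s.weight = float(np.clip(weights_by_key[key], 0.0, 1.0))
                s.scale = float(scale_by_key[key])
                if excl_by_key[key]:
                    s.excluded = True
            if s.excluded:
                n_excluded += 1
    if n_excluded == n_total:
        raise ReconstructionError(
            "all slices excluded", report={"n_slices": n_total, "n_excluded": n_excluded}
        )

    transforms_after = {st.id: [s.transform for s in st.slices] for st in work}
    report = {
        "template_stack": work[template_idx].id,
        "output_spacing_mm": config.spacing,
        "output_shape": list(grid.shape),
        "n_slices": n_total,
        "n_excluded": n_excluded,
        "excluded_slices": [
            {"stack_id": st.id, "slice_index": s.index_in_stack}
            for st in work
            for s in st.slices
            if s.excluded
        ],
        "slice_weights": {
            st.id: [float(s.weight) for s in st.slices] for st in work
        },
        "slice_scales": {st.id: [float(s.scale) for s in st.slices] for st in work},
        "em_sigma": float(em.sigma),
        "em_inlier_fraction": float(em.c),
        "misfit_history": misfit_history,
    }
    x_out = np.where(mask_out, x, 0.0)
    volume = Volume(x_out, grid.affine)
    return ReconResult(volume, transforms_before, transforms_after, report, em)
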