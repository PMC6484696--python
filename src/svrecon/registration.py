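"""Intensity-based rigid registration: template scoring, stack initialisation,
and per-slice 2D-to-3D refinement.

All registrations maximise normalised cross-correlation (NCC) — the problem is
mono-modal (acquired slices vs PSF-simulated slices of the same contrast), so
NCC is smooth, parameter-free and invariant to global affine intensity
scaling. Optimisation is derivative-free local search (Powell) over the six
rigid parameters with a coarse-to-fine smoothing schedule; every step is
deterministic, so identical inputs give identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage, optimize

from .geometry import RigidTransform
from .image import Mask, Slice, Stack, Volume
from .psf import PointSpreadFunction


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalised cross-correlation of two equally-shaped arrays (0 if degenerate)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom < 1e-30:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.clip(np.dot(a, b) / denom, -1.0, 1.0))


@dataclass
class RegistrationResult:
    transform: RigidTransform
    similarity: float
    converged: bool
    n_evaluations: int
    exclude_suggested: bool = False


# -- template selection ------------------------------------------------------


def stack_motion_score(stack: Stack) -> float:
    """Motion score in [-1, 1]: mean NCC between spatially adjacent slices.

    Inter-slice motion decorrelates neighbouring (heavily overlapping) slices,
    so higher scores mean less movement artifact.
    """
    usable = [s for s in stack.slices if not s.excluded]
    if len(usable) < 2:
        warnings.warn("stack has fewer than 2 usable slices; motion score undefined (0)")
        return 0.0
    usable.sort(key=lambda s: s.index_in_stack)
    scores = []
    for a, b in zip(usable[:-1], usable[1:]):
        if b.index_in_stack - a.index_in_stack != 1:
            continue
        if a.pixels.shape == b.pixels.shape:
            scores.append(ncc(a.pixels, b.pixels))
    if not scores:
        warnings.warn("no adjacent slice pairs; motion score undefined (0)")
        return 0.0
    return float(np.mean(scores))


def select_template(stacks: Sequence[Stack]) -> int:
    """Index of the stack with the least movement artifact (ties -> lowest index)."""
    if not stacks:
        raise ValueError("no stacks given")
    scores = np.array([stack_motion_score(s) for s in stacks])
    return int(np.argmax(scores))


# -- volume-to-volume --------------------------------------------------------


def _smoothed(data: np.ndarray, sigma_vox: float) -> np.ndarray:
    if sigma_vox <= 0:
        return np.asarray(data, dtype=float)
    return ndimage.gaussian_filter(np.asarray(data, dtype=float), sigma=sigma_vox)


def register_volume_to_volume(
    moving: Volume,
    fixed: Volume,
    mask: Optional[Mask] = None,
    init: Optional[RigidTransform] = None,
    levels: Sequence[float] = (4.0, 2.0, 1.0),
    max_points: int = 30000,
    min_overlap: int = 100,
    anchor_weight: float = 1e-5,
) -> RegistrationResult:
    """Rigid registration of ``moving`` onto ``fixed`` by masked NCC.

    The estimated transform maps moving-volume world points into the fixed
    frame, i.e. ``moving(p) ~ fixed(T(p))`` — the same convention as the slice
    forward model. Multi-resolution: Gaussian smoothing at ``levels`` mm FWHM
    with matching sample striding, Powell at each level.

    ``anchor_weight`` adds a weak quadratic prior about the initialisation
    (per deg^2 / mm^2). Consecutive stacks of one session differ by small
    motions, and the prior rules out the distant self-similar poses of
    roughly symmetric anatomy (e.g. near-180 degree flips) that NCC alone
    cannot always reject on smoothed images.
    """
    center = mask.centroid_world() if mask is not None else fixed.index_to_world(
        (np.asarray(fixed.shape) - 1) / 2.0
    )
    if init is None:
        init = RigidTransform.identity(center=center)
    params = init.with_center(center).params.copy()
    p_init = params.copy()
    n_eval = 0
    spacing_m = float(np.min(moving.spacing))
    similarity = np.nan

    for level in levels:
        sig_vox_f = (level / 2.355) / fixed.spacing
        fixed_s = Volume(_smoothed(fixed.data, np.mean(sig_vox_f)), fixed.affine)
        sig_vox_m = (level / 2.355) / moving.spacing
        moving_s = _smoothed(moving.data, np.mean(sig_vox_m))
        stride = max(1, int(round(level / spacing_m)))
        ii, jj, kk = (np.arange(0, s, stride) for s in moving.shape)
        I, J, K = np.meshgrid(ii, jj, kk, indexing="ij")
        idx = np.stack([I.ravel(), J.ravel(), K.ravel()], axis=-1)
        if len(idx) > max_points:
            sel = np.linspace(0, len(idx) - 1, max_points).astype(int)
            idx = idx[sel]
        pts = moving.index_to_world(idx)
        vals = moving_s[idx[:, 0], idx[:, 1], idx[:, 2]]

        # freeze the comparison set at the current pose (see slice metric)
        T0 = RigidTransform.from_params(params, center=center)
        q0 = T0.apply(pts)
        inside0 = fixed_s.contains(q0)
        if mask is not None:
            inside0 &= mask.sample(q0) > 0.5
        if inside0.sum() < min_overlap:
            raise ValueError("no field-of-view overlap between volumes under init")
        pts_sub = pts[inside0]
        vals_sub = vals[inside0]

        def metric(p):
            nonlocal n_eval
            n_eval += 1
            T = RigidTransform.from_params(p, center=center)
            prior = anchor_weight * float(np.sum((np.asarray(p) - p_init) ** 2))
            return -ncc(vals_sub, fixed_s.sample(T.apply(pts_sub))) + prior
        res = optimize.minimize(
            metric,
            params,
            method="Powell",
            options={"xtol": 0.01, "ftol": 1e-6, "maxiter": 8},
        )
        params = res.x
        similarity = -float(res.fun)

    T = RigidTransform.from_params(params, center=center)
    return RegistrationResult(T, similarity, bool(np.isfinite(similarity)), n_eval)


# -- slice-to-volume ---------------------------------------------------------


DEFAULT_SLICE_SCHEDULE = (
    # (smoothing sigma in voxels, (n in-plane, n through-plane) quadrature,
    #  max pixels, Powell maxiter[, exact])  — without `exact` the in-plane
    # profile is pre-blurred into the volume (fast); the final `exact` stage
    # integrates the full 3D quadrature per evaluation for an unbiased polish
    (3.0, (3, 3), 250, 3),
    (1.5, (3, 3), 300, 3),
    (0.0, (3, 5), 400, 3),
    (0.0, (3, 5), 400, 3),
)

# short schedule for later outer iterations, when the pose is already close
REFINE_SLICE_SCHEDULE = (
    (1.5, (3, 3), 300, 2),
    (0.0, (3, 5), 400, 3),
)


def register_slice_to_volume(
    slice_: Slice,
    volume: Volume,
    mask: Optional[Mask] = None,
    init: Optional[RigidTransform] = None,
    psf: Optional[PointSpreadFunction] = None,
    schedule=DEFAULT_SLICE_SCHEDULE,
    min_pixels: int = 30,
    maxiter: Optional[int] = None,
    anchor_weight: float = 3e-5,
    seed_search: Tuple[float, float] = (4.0, 3.0),
    stage_cache: Optional[dict] = None,
) -> RegistrationResult:
    """Refine one slice's rigid pose against the current volume estimate.

    The metric compares the acquired pixels with a PSF-simulated slice from
    the volume under the candidate transform, restricted to the mask ∩ slice
    support. The in-plane PSF component is applied by pre-blurring the volume
    along the slice's in-plane world axes (valid because candidate rotations
    are a few degrees, far below what would tilt the blur axes noticeably) —
    the in-plane profile measurably shifts the NCC optimum and cannot be
    dropped, but integrating it per evaluation would cost ~30x more. The
    through-plane profile is integrated by truncated-Gaussian quadrature per
    evaluation, since it moves with the candidate pose.

    The coarse-to-fine ``schedule`` starts with heavy smoothing (cheap, wide
    capture range, helped by a deterministic shrinking pattern search ahead
    of Powell) and ends at full resolution. Between stages the comparison
    region and motion prior are re-anchored at the current pose. A slice
    whose footprint misses the mask is flagged for exclusion rather than
    silently failing.

    ``anchor_weight`` is a weak quadratic motion prior about the stage
    anchor (per deg^2 / mm^2): inter-stage pose updates are small, and the
    prior keeps poorly-determined directions (e.g. tilts of a slice through
    near-cylindrical structures) from wandering along flat ridges of the
    similarity metric. ``maxiter``, if given, overrides the per-stage Powell
    iteration counts. ``stage_cache`` (a plain dict) shares the per-stage
    blurred volumes across slices of the same orientation.
    """
    if psf is None:
        psf = PointSpreadFunction.for_geometry(slice_.geometry)
    if init is None:
        init = slice_.transform
    center = mask.centroid_world() if mask is not None else init.center
    params = init.with_center(center).params.copy()

    p0 = slice_.pixel_world().reshape(-1, 3)
    y = slice_.pixels.ravel()
    n_eval = 0
    if stage_cache is None:
        stage_cache = {}
    O = slice_.geometry.orientation
    similarity = np.nan

    for stage, entry in enumerate(schedule):
        level, quad, max_pixels, stage_maxiter = entry[:4]
        exact = bool(entry[4]) if len(entry) > 4 else False
        n_in_plane, n_through = quad
        key = (level, quad, exact, O.tobytes())
        if key not in stage_cache:
            data = _smoothed(volume.data, level)
            if n_in_plane > 1 and not exact:
                # in-plane PSF as a world-axis blur (slice axes are world axes
                # up to the small candidate rotations)
                sig_world = np.abs(O[:, 0]) * psf.sigmas[0] + np.abs(O[:, 1]) * psf.sigmas[1]
                sig_vox = sig_world / volume.spacing
                data = ndimage.gaussian_filter(data, sig_vox, truncate=psf.support_cutoff)
            stage_cache[key] = Volume(data, volume.affine)
        vol_s = stage_cache[key]
        qkey = ("quad", quad, exact, O.tobytes())
        if qkey not in stage_cache:
            if exact:
                off, qw = psf.quadrature(n_in_plane, n_through)
            else:
                off, qw = psf.through_plane_quadrature(n_through)
            stage_cache[qkey] = (off @ O.T, qw)
        world_offsets, qw = stage_cache[qkey]

        # freeze the comparison region at the stage anchor: letting it follow
        # the candidate transform would let the optimiser shrink the region
        # onto flat anatomy and inflate NCC spuriously
        T0 = RigidTransform.from_params(params, center=center)
        centres0 = T0.apply(p0)
        valid = volume.contains(centres0)
        if mask is not None:
            valid &= mask.sample(centres0) > 0.5
        if valid.sum() < min_pixels:
            if stage == 0:
                return RegistrationResult(init, -np.inf, False, n_eval, exclude_suggested=True)
            break
        sel = np.where(valid)[0]
        if len(sel) > max_pixels:
            sel = sel[np.linspace(0, len(sel) - 1, max_pixels).astype(int)]
        p_sub = p0[sel]
        y_sub = y[sel]
        p_all = (p_sub[:, None, :] + world_offsets[None, :, :]).reshape(-1, 3)
        p_anchor = params.copy()
        inv_aff = vol_s.inv_affine
        vol_data = vol_s.data.astype(float, copy=False)

        def metric(p):
            nonlocal n_eval
            n_eval += 1
            T = RigidTransform.from_params(p, center=center)
            # fused world->index map: index = (T(p_all)) under the volume affine
            R = T.rotation_matrix
            B = inv_aff[:3, :3] @ R
            shift = inv_aff[:3, :3] @ (
                T.center + T.translation - R @ T.center
            ) + inv_aff[:3, 3]
            idx = p_all @ B.T + shift
            vals = ndimage.map_coordinates(
                vol_data, idx.T, order=1, cval=0.0, mode="constant"
            ).reshape(len(p_sub), len(qw))
            prior = anchor_weight * float(np.sum((np.asarray(p) - p_anchor) ** 2))
            return -ncc(y_sub, vals @ qw) + prior

        if stage <= 1 and seed_search is not None:
            # deterministic shrinking pattern search widens the capture range
            # beyond Powell's local line searches (e.g. in-plane rotations)
            d_rot, d_tr = seed_search
            steps = np.array([d_rot] * 3 + [d_tr] * 3, dtype=float) / (stage + 1.0)
            best = params.copy()
            f_best = metric(best)
            for _ in range(3):
                improved = False
                for axis in range(6):
                    for sgn in (+1.0, -1.0):
                        c = best.copy()
                        c[axis] += sgn * steps[axis]
                        f = metric(c)
                        if f < f_best:
                            best, f_best = c, f
                            improved = True
                if not improved:
                    steps *= 0.5
            params = best

        res = optimize.minimize(
            metric,
            params,
            method="Powell",
            options={
                "xtol": 0.02,
                "ftol": 1e-5,
                "maxiter": maxiter if maxiter is not None else stage_maxiter,
            },
        )
        params = res.x
        similarity = -float(res.fun)

    T = RigidTransform.from_params(params, center=center)
    converged = bool(np.isfinite(similarity)) and similarity > -1.0
    return RegistrationResult(T, similarity, converged, n_eval)
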