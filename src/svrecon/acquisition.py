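"""Multi-slice 2D acquisition simulator with per-slice rigid motion.

Simulates the validation protocol: multiple stacks of overlapping 2D slices
(default 9 stacks cycling through three orthogonal orientations, 1.25 mm
in-plane, 2.5 mm thick, 1.25 mm overlap) sampled from a ground-truth volume
through the slice-profile PSF, with each slice displaced by its own rigid
transform, scaled by a per-slice gain, and corrupted by additive Gaussian
noise. The per-slice ground-truth transforms are returned (and can be written
to a transform log) so that registration accuracy can be scored afterwards.

Motion model: slices are acquired in interleaved order (even slice positions
first, then odd), and the 6 rigid parameters follow a random walk in
acquisition time — slow drift each slice step plus occasional larger jumps,
mimicking a fetus that is mostly quiescent but repositions abruptly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import RigidTransform
from .image import Slice, SliceGeometry, Stack, Volume, interleaved_order
from .io import read_transform_log, write_transform_log
from .psf import PointSpreadFunction


@dataclass
class MotionModel:
    """Random-walk + jump model of fetal-like rigid motion (per slice step)."""

    drift_sigma_translation: float = 0.1  # mm per slice step, per axis
    drift_sigma_rotation: float = 0.1  # deg per slice step, per axis
    jump_probability: float = 0.04  # per slice step
    jump_sigma_translation: float = 2.0  # mm
    jump_sigma_rotation: float = 2.0  # deg

    def __post_init__(self):
        for name in (
            "drift_sigma_translation",
            "drift_sigma_rotation",
            "jump_probability",
            "jump_sigma_translation",
            "jump_sigma_rotation",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def still(cls) -> "MotionModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class MotionTrace:
    """Per-slice rigid transforms in acquisition (time) order."""

    transforms: List[RigidTransform]
    model: Optional[MotionModel] = None

    def __len__(self):
        return len(self.transforms)

    def by_slice(self, acquisition_order: np.ndarray) -> List[RigidTransform]:
        """Reorder from acquisition time to spatial slice index."""
        order = np.asarray(acquisition_order, dtype=int)
        out: List[RigidTransform] = [None] * len(order)
        for time_idx, slice_idx in enumerate(order):
            out[slice_idx] = self.transforms[time_idx]
        return out


def sample_motion_trace(
    model: MotionModel, n_slices: int, seed, center=(0.0, 0.0, 0.0)
) -> MotionTrace:
    """Draw a deterministic motion trace: cumulative drift plus sparse jumps.

    With all amplitudes zero every transform is the identity. The final
    displacement after ``n`` steps of pure drift has standard deviation
    ``sigma * sqrt(n)`` per axis (plain random walk).
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    rng = np.random.default_rng(seed)
    inc = np.zeros((n_slices, 6))
    inc[:, :3] = model.drift_sigma_rotation * rng.standard_normal((n_slices, 3))
    inc[:, 3:] = model.drift_sigma_translation * rng.standard_normal((n_slices, 3))
    jumps = rng.random(n_slices) < model.jump_probability
    jump_mag = np.zeros((n_slices, 6))
    jump_mag[:, :3] = model.jump_sigma_rotation * rng.standard_normal((n_slices, 3))
    jump_mag[:, 3:] = model.jump_sigma_translation * rng.standard_normal((n_slices, 3))
    inc += jumps[:, None] * jump_mag
    params = np.cumsum(inc, axis=0)
    transforms = [RigidTransform.from_params(p, center=center) for p in params]
    return MotionTrace(transforms, model=model)


def load_motion_trace(path: str) -> Dict[str, MotionTrace]:
    """Load a transform log as replayable traces keyed by stack id.

    Loaded traces are indexed by spatial slice order (the log's own order);
    replaying them through :func:`simulate_stack` with
    ``trace_in_slice_order=True`` applies identical displacements.
    """
    logs = read_transform_log(path)
    return {sid: MotionTrace(transforms) for sid, transforms in logs.items()}


def save_motion_traces(
    traces: Dict[str, Sequence[RigidTransform]], path: str, pivot=None
) -> str:
    entries = []
    for sid in traces:
        for k, t in enumerate(traces[sid]):
            entries.append((sid, k, t))
    return write_transform_log(entries, path, pivot=pivot)


ORIENTATIONS = {
    # columns: in-plane u, in-plane v, through-plane normal
    "axial": np.eye(3),
    "coronal": np.column_stack([[1.0, 0, 0], [0, 0, 1.0], [0, 1.0, 0]]),
    "sagittal": np.column_stack([[0, 1.0, 0], [0, 0, 1.0], [1.0, 0, 0]]),
}


@dataclass
class ProtocolConfig:
    """Acquisition protocol: 9 stacks over three orthogonal planes by default."""

    n_stacks: int = 9
    orientations: tuple = ("axial", "coronal", "sagittal")
    in_plane_spacing: float = 1.25
    thickness: float = 2.5
    overlap: float = 1.25
    noise_sigma: float = 3.0
    scale_jitter: float = 0.02  # sd of log per-slice gain
    motion: MotionModel = field(default_factory=MotionModel)
    margin: float = 2.0  # mm of in-plane/through-plane coverage margin
    seed: int = 0

    def __post_init__(self):
        if self.n_stacks < 1:
            raise ValueError("n_stacks must be >= 1")
        if not self.orientations:
            raise ValueError("at least one orientation required")

    @property
    def slice_step(self) -> float:
        return self.thickness - self.overlap


def coverage_slices(extent_mm: float, slice_step: float, margin: float = 0.0) -> int:
    """Number of slices needed to cover ``extent_mm`` at the given step."""
    return int(np.ceil((extent_mm + 2 * margin) / slice_step)) + 1


def stack_geometry_for_box(
    orientation_name: str, box_lo: np.ndarray, box_hi: np.ndarray, config: ProtocolConfig
) -> Tuple[SliceGeometry, Tuple[int, int], int]:
    """Slice geometry, in-plane shape and slice count covering a world box."""
    O = ORIENTATIONS[orientation_name]
    lo = np.asarray(box_lo, dtype=float) - config.margin
    hi = np.asarray(box_hi, dtype=float) + config.margin
    extent = hi - lo
    eu = abs(float(extent @ O[:, 0]))
    ev = abs(float(extent @ O[:, 1]))
    en = abs(float(extent @ O[:, 2]))
    nu = int(np.ceil(eu / config.in_plane_spacing)) + 1
    nv = int(np.ceil(ev / config.in_plane_spacing)) + 1
    n_slices = int(np.ceil(en / config.slice_step)) + 1
    # all orientation columns point along +x/+y/+z, so the lo corner is pixel (0,0) of slice 0
    origin = lo.copy()
    geom = SliceGeometry(
        in_plane_spacing=(config.in_plane_spacing, config.in_plane_spacing),
        thickness=config.thickness,
        slice_step=config.slice_step,
        orientation=O,
        origin=origin,
    )
    return geom, (nu, nv), n_slices


def simulate_stack(
    truth: Volume,
    geometry: SliceGeometry,
    n_slices: int,
    shape: Tuple[int, int],
    trace: MotionTrace,
    noise_sigma: float = 0.0,
    scale_jitter: float = 0.0,
    seed=0,
    psf: Optional[PointSpreadFunction] = None,
    stack_id: str = "stack",
    quadrature: Tuple[int, int] = (7, 9),
    trace_in_slice_order: bool = False,
) -> Tuple[Stack, List[RigidTransform]]:
    """Sample one motion-corrupted stack from a ground-truth volume.

    Each slice pixel is the PSF-weighted (Gauss-Hermite) integral of the truth
    over the moved slice footprint, multiplied by a per-slice gain and plus
    Gaussian noise. Returns the stack (slice transforms initialised to
    identity — the truth motion is *not* stored on the slices) together with
    the per-spatial-slice ground-truth transforms.
    """
    if psf is None:
        psf = PointSpreadFunction.for_geometry(geometry)
    if len(trace) != n_slices:
        raise ValueError(f"trace length {len(trace)} != n_slices {n_slices}")
    order = interleaved_order(n_slices)
    truth_by_slice = (
        list(trace.transforms) if trace_in_slice_order else trace.by_slice(order)
    )
    offsets, weights = psf.quadrature(*quadrature)
    rng = np.random.default_rng(seed)
    gains = np.exp(scale_jitter * rng.standard_normal(n_slices)) if scale_jitter > 0 else np.ones(n_slices)
    noise = (
        noise_sigma * rng.standard_normal((n_slices,) + tuple(shape))
        if noise_sigma > 0
        else np.zeros((n_slices,) + tuple(shape))
    )

    slices = []
    O = geometry.orientation
    world_offsets = offsets @ O.T  # slice-frame -> world, before motion
    for k in range(n_slices):
        g = geometry.shifted(k)
        pw = g.pixel_world(shape).reshape(-1, 3)
        T = truth_by_slice[k]
        pts = T.apply(pw[:, None, :] + world_offsets[None, :, :])
        vals = truth.sample(pts.reshape(-1, 3)).reshape(len(pw), len(weights))
        pixels = (vals @ weights).reshape(shape)
        inside = truth.contains(T.apply(pw))
        blank = not inside.any()
        pixels = gains[k] * pixels + noise[k]
        slices.append(
            Slice(
                pixels=pixels,
                geometry=g,
                index_in_stack=k,
                transform=RigidTransform.identity(center=T.center),
                excluded=blank,
                stack_id=stack_id,
            )
        )
    stack = Stack(slices, acquisition_order=order, id=stack_id)
    return stack, truth_by_slice


def simulate_protocol(
    truth: Volume, config: ProtocolConfig, box: Optional[Tuple[np.ndarray, np.ndarray]] = None
) -> Tuple[List[Stack], Dict[str, List[RigidTransform]]]:
    """Simulate the full multi-stack protocol; returns stacks and truth traces.

    Stacks cycle through the configured orientations; every stack gets an
    independent motion trace and noise stream derived from ``config.seed``
    (sub-seed k for stack k's motion, 1000+k for its noise).
    """
    if box is None:
        corners = np.array(
            [
                truth.index_to_world(np.array(c) * (np.asarray(truth.shape) - 1))
                for c in np.ndindex(2, 2, 2)
            ]
        )
        box = (corners.min(axis=0), corners.max(axis=0))
    center = 0.5 * (np.asarray(box[0]) + np.asarray(box[1]))
    stacks: List[Stack] = []
    traces: Dict[str, List[RigidTransform]] = {}
    for k in range(config.n_stacks):
        name = config.orientations[k % len(config.orientations)]
        geom, shape, n_slices = stack_geometry_for_box(name, box[0], box[1], config)
        sid = f"stack{k:02d}_{name}"
        trace = sample_motion_trace(
            config.motion,
            n_slices,
            seed=np.random.SeedSequence([int(config.seed), 1, k]),
            center=center,
        )
        stack, truth_by_slice = simulate_stack(
            truth,
            geom,
            n_slices,
            shape,
            trace,
            noise_sigma=config.noise_sigma,
            scale_jitter=config.scale_jitter,
            seed=np.random.SeedSequence([int(config.seed), 2, k]),
            stack_id=sid,
        )
        stacks.append(stack)
        traces[sid] = truth_by_slice
    return stacks, traces
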