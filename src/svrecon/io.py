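"""NIfTI-1 volume/stack I/O and plain-text rigid-transform logs."""

from __future__ import annotations

import json
import os
from typing import Dict, List, Sequence, Tuple

import nibabel as nib
import numpy as np

from .geometry import RigidTransform
from .image import Mask, Slice, SliceGeometry, Stack, Volume


def read_volume(path: str) -> Volume:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D payload, got shape {data.shape}")
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"{path}: non-invertible affine")
    return Volume(data.astype(float), affine)


def write_volume(volume: Volume, path: str) -> str:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, path)
    return path


def read_mask(path: str) -> Mask:
    v = read_volume(path)
    return Mask(v.data > 0.5, v.affine)


def write_mask(mask: Mask, path: str) -> str:
    return write_volume(Volume(mask.data.astype(np.float32), mask.affine), path)


def _sidecar_path(path: str) -> str:
    base = path
    for ext in (".nii.gz", ".nii"):
        if base.endswith(ext):
            base = base[: -len(ext)]
            break
    return base + ".json"


def write_stack(stack: Stack, path: str) -> str:
    """Write a stack as 3D NIfTI (slice axis third) plus a JSON geometry sidecar.

    NIfTI zooms carry the centre-to-centre spacings; the acquired slice
    thickness (which exceeds the slice step when slices overlap) and the
    acquisition order go in the sidecar.
    """
    vol = stack.as_volume()
    write_volume(vol, path)
    g = stack.geometry
    meta = {
        "stack_id": stack.id,
        "thickness_mm": g.thickness,
        "slice_step_mm": g.slice_step,
        "slice_overlap_mm": g.overlap,
        "in_plane_spacing_mm": g.in_plane_spacing.tolist(),
        "acquisition_order": stack.acquisition_order.tolist(),
        "excluded": [bool(s.excluded) for s in stack.slices],
    }
    with open(_sidecar_path(path), "w") as f:
        json.dump(meta, f, indent=1)
    return path


def read_stack(path: str) -> Stack:
    vol = read_volume(path)
    sidecar = _sidecar_path(path)
    meta = {}
    if os.path.exists(sidecar):
        with open(sidecar) as f:
            meta = json.load(f)
    n = vol.shape[2]
    spacing = vol.spacing
    orientation = vol.affine[:3, :3] / spacing[None, :]
    base = SliceGeometry(
        in_plane_spacing=meta.get("in_plane_spacing_mm", spacing[:2]),
        thickness=float(meta.get("thickness_mm", 2 * spacing[2])),
        slice_step=float(meta.get("slice_step_mm", spacing[2])),
        orientation=orientation,
        origin=vol.affine[:3, 3],
    )
    excluded = meta.get("excluded", [False] * n)
    stack_id = meta.get("stack_id", os.path.basename(path).split(".")[0])
    slices = [
        Slice(
            pixels=vol.data[:, :, k],
            geometry=base.shifted(k),
            index_in_stack=k,
            excluded=bool(excluded[k]),
            stack_id=stack_id,
        )
        for k in range(n)
    ]
    order = meta.get("acquisition_order")
    return Stack(slices, acquisition_order=order, id=stack_id)


# -- transform logs ----------------------------------------------------------
#
# One line per slice: stack_id slice_index rx ry rz tx ty tz  (deg, mm).
# The shared rotation pivot is recorded once in a '# pivot_mm:' comment so a
# log fully determines the world mapping of every slice.

LOG_HEADER = "# stack_id slice_index rot_x_deg rot_y_deg rot_z_deg trans_x_mm trans_y_mm trans_z_mm"


def write_transform_log(
    entries: Sequence[Tuple[str, int, RigidTransform]], path: str, pivot=None
) -> str:
    if pivot is None and entries:
        pivot = entries[0][2].center
    pivot = np.zeros(3) if pivot is None else np.asarray(pivot, dtype=float)
    with open(path, "w") as f:
        f.write(LOG_HEADER + "\n")
        f.write("# pivot_mm: {:.6f} {:.6f} {:.6f}\n".format(*pivot))
        for stack_id, slice_index, t in entries:
            r, tr = t.rotation, t.translation
            f.write(
                f"{stack_id} {slice_index} "
                f"{r[0]:.6f} {r[1]:.6f} {r[2]:.6f} "
                f"{tr[0]:.6f} {tr[1]:.6f} {tr[2]:.6f}\n"
            )
    return path


def read_transform_log(path: str) -> Dict[str, List[RigidTransform]]:
    """Load a transform log as ``{stack_id: [transform per slice index]}``."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such transform log: {path}")
    pivot = np.zeros(3)
    raw: Dict[str, Dict[int, RigidTransform]] = {}
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# pivot_mm:"):
                    pivot = np.array([float(x) for x in line.split(":")[1].split()])
                continue
            parts = line.split()
            if len(parts) != 8:
                raise ValueError(
                    f"{path}:{lineno}: expected 8 fields "
                    f"(stack_id slice_index 3 rotations 3 translations), got {len(parts)}"
                )
            try:
                sid = parts[0]
                sl = int(parts[1])
                vals = [float(x) for x in parts[2:]]
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed numeric field ({e})") from None
            raw.setdefault(sid, {})[sl] = RigidTransform(
                rotation=vals[:3], translation=vals[3:], center=pivot
            )
    out: Dict[str, List[RigidTransform]] = {}
    for sid, d in raw.items():
        n = max(d) + 1
        if sorted(d) != list(range(n)):
            missing = sorted(set(range(n)) - set(d))
            raise ValueError(f"{path}: stack {sid} missing slice indices {missing}")
        out[sid] = [d[i] for i in range(n)]
    return out
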