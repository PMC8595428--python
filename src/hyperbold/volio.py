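"""Volumetric I/O and geometry for dual-field-of-view acquisitions.

A single EPI volume in a hyperscanning session covers two heads at once.
This module reads/writes NIfTI-1, splits the joint field of view into one
dataset per subject, and reorients each subject's data into a common
(radiological) convention so that voxel (i, j, k) is spatially analogous
across subjects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import orientations as nbo

__all__ = [
    "RADIOLOGICAL",
    "VolumeSeries",
    "Mask3D",
    "SubjectLayout",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "split_dual_fov",
    "reorient_to_radiological",
]

#: Default canonical axis triplet for cross-subject comparison.  Radiological
#: display flips left/right relative to neurological (RAS) storage; the exact
#: triplet is a convention declared once and honored everywhere downstream.
RADIOLOGICAL: tuple[str, str, str] = ("L", "A", "S")

_VALID_CODES = frozenset("LRAPIS")
_AXIS_OF = {"L": 0, "R": 0, "A": 1, "P": 1, "I": 2, "S": 2}


def _validate_axcodes(orientation: tuple[str, str, str]) -> None:
    codes = tuple(orientation)
    if len(codes) != 3 or any(c not in _VALID_CODES for c in codes):
        raise ValueError(f"invalid orientation label {orientation!r}")
    if len({_AXIS_OF[c] for c in codes}) != 3:
        raise ValueError(f"orientation {orientation!r} repeats a world axis")


def axcodes_to_affine(
    orientation: tuple[str, str, str], voxel_size_mm: tuple[float, float, float]
) -> np.ndarray:
    """Build a voxel->world affine (origin at voxel 0) from axis codes."""
    _validate_axcodes(orientation)
    ornt = nbo.axcodes2ornt(tuple(orientation))
    aff = np.zeros((4, 4))
    aff[3, 3] = 1.0
    for i, (world_axis, flip) in enumerate(ornt):
        aff[int(world_axis), i] = flip * voxel_size_mm[i]
    return aff


@dataclass
class VolumeSeries:
    """One subject's 4-D BOLD run (x, y, z, t) with acquisition geometry."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tr_s: float = 1.5
    orientation: tuple[str, str, str] = RADIOLOGICAL
    subject_id: str = ""
    run_id: str = ""
    phase_encode: tuple[str, str] = ("x", "+")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"expected 3-D or 4-D data, got ndim={self.data.ndim}")
        if self.data.shape[3] < 1:
            raise ValueError("time dimension must have at least 1 volume")
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be 3 positive lengths, got {self.voxel_size_mm}")
        self.orientation = tuple(self.orientation)
        _validate_axcodes(self.orientation)
        if self.phase_encode[0] not in ("x", "y", "z") or self.phase_encode[1] not in ("+", "-"):
            raise ValueError(f"invalid phase_encode {self.phase_encode!r}")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def affine(self) -> np.ndarray:
        return axcodes_to_affine(self.orientation, self.voxel_size_mm)

    def with_data(self, data: np.ndarray, **changes) -> "VolumeSeries":
        """Copy of this series with new data (and optional field changes)."""
        return dataclasses.replace(self, data=data, meta=dict(self.meta), **changes)


@dataclass
class Mask3D:
    """Boolean 3-D region (e.g. a brain mask) on the same grid as a series."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3-D, got ndim={self.data.ndim}")
        if not self.data.any():
            raise ValueError("mask has no true voxels")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be positive")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_grid(self, series: VolumeSeries) -> None:
        if self.data.shape != series.data.shape[:3]:
            raise ValueError(
                f"mask grid {self.data.shape} does not match series grid {series.data.shape[:3]}"
            )


Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass
class SubjectLayout:
    """Positions of the two subjects inside a joint field of view.

    Boxes are 0-based, inclusive-exclusive voxel bounding boxes.  Facing
    angles are rotations about the scanner y-axis in 5-degree increments on
    [0, 180]; the physical platform supports 1-91 cm of separation.
    """

    boxes: tuple[Box, Box]
    facing_angles_deg: tuple[float, float] = (0.0, 180.0)
    separation_cm: float = 11.0
    subject_ids: tuple[str, str] = ("sub-01", "sub-02")

    def __post_init__(self) -> None:
        if len(self.boxes) != 2:
            raise ValueError("layout needs exactly two boxes")
        self.boxes = tuple(tuple((int(lo), int(hi)) for lo, hi in box) for box in self.boxes)
        for box in self.boxes:
            for lo, hi in box:
                if lo < 0 or hi <= lo:
                    raise ValueError(f"degenerate box bound ({lo}, {hi})")
        if _boxes_overlap(self.boxes[0], self.boxes[1]):
            raise ValueError("subject boxes overlap")
        for ang in self.facing_angles_deg:
            if not (0 <= ang <= 180) or ang % 5 != 0:
                raise ValueError(f"facing angle {ang} must be a multiple of 5 in [0, 180]")
        if not (1.0 <= self.separation_cm <= 91.0):
            raise ValueError(f"separation {self.separation_cm} cm outside the platform's 1-91 cm range")


def _boxes_overlap(a: Box, b: Box) -> bool:
    return all(lo_a < hi_b and lo_b < hi_a for (lo_a, hi_a), (lo_b, hi_b) in zip(a, b))


def read_volume(path: str | Path) -> VolumeSeries:
    """Read a NIfTI-1 file into a :class:`VolumeSeries`.

    3-D images (e.g. masks) are promoted to a single-volume series so masks
    and runs can share one reader.  TR is taken from the time-axis zoom; a
    missing/zero TR falls back to 1 s.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise OSError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3 or 4 dimensions, got {data.ndim}")
    zooms = img.header.get_zooms()
    voxel = tuple(float(z) for z in zooms[:3])
    tr = float(zooms[3]) if data.ndim == 4 and len(zooms) > 3 else 0.0
    if tr <= 0:
        tr = 1.0
    orientation = nbo.aff2axcodes(img.affine)
    return VolumeSeries(
        data=np.asarray(data, dtype=np.float64) if np.issubdtype(data.dtype, np.floating) else data,
        voxel_size_mm=voxel,
        tr_s=tr,
        orientation=orientation,
        run_id=path.name.split(".")[0],
    )


def write_volume(series: VolumeSeries, path: str | Path) -> Path:
    """Write a series as NIfTI-1, encoding voxel size, TR and orientation."""
    path = Path(path)
    data = series.data
    if data.shape[3] == 1:
        data = data[..., 0]  # store single-volume series as plain 3-D
    img = nib.Nifti1Image(data, series.affine)
    zooms = series.voxel_size_mm + ((series.tr_s,) if data.ndim == 4 else ())
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> Mask3D:
    series = read_volume(path)
    return Mask3D(data=series.data[..., 0] > 0, voxel_size_mm=series.voxel_size_mm)


def write_mask(mask: Mask3D, path: str | Path) -> Path:
    series = VolumeSeries(
        data=mask.data.astype(np.uint8),
        voxel_size_mm=mask.voxel_size_mm,
        tr_s=1.0,
    )
    return write_volume(series, path)


def _flip_polarity(pe: tuple[str, str]) -> tuple[str, str]:
    return (pe[0], "-" if pe[1] == "+" else "+")


def split_dual_fov(
    series: VolumeSeries, layout: SubjectLayout
) -> tuple[VolumeSeries, VolumeSeries]:
    """Split a joint two-subject acquisition into per-subject datasets.

    Each output carries exactly the voxels of its bounding box, the subject
    identity from the layout order, and the effective phase-encode polarity:
    a subject rotated 180 degrees about the scanner y-axis sees the phase
    gradient reversed, so face-to-face subjects carry opposite polarities
    (and hence mirrored geometric distortion).
    """
    shape = series.data.shape[:3]
    outputs = []
    for subject_id, box, angle in zip(layout.subject_ids, layout.boxes, layout.facing_angles_deg):
        for axis, (lo, hi) in enumerate(box):
            if hi > shape[axis]:
                raise ValueError(
                    f"box {box} exceeds volume extent {shape} on axis {axis}"
                )
        (x0, x1), (y0, y1), (z0, z1) = box
        sub = series.data[x0:x1, y0:y1, z0:z1, :]
        pe = series.phase_encode
        if angle % 360 == 180:  # rotated to face the other subject
            pe = _flip_polarity(pe)
        outputs.append(
            series.with_data(
                sub.copy(),
                subject_id=subject_id,
                phase_encode=pe,
            )
        )
        outputs[-1].meta["fov_box"] = box
    return outputs[0], outputs[1]


def reorient_to_radiological(
    series: VolumeSeries, convention: tuple[str, str, str] = RADIOLOGICAL
) -> VolumeSeries:
    """Permute/flip data axes so the series matches the canonical convention.

    Idempotent: an already-canonical series is returned unchanged (same
    values, fresh object).  Each single-axis flip is an involution.
    """
    _validate_axcodes(tuple(convention))
    src = nbo.axcodes2ornt(tuple(series.orientation))
    dst = nbo.axcodes2ornt(tuple(convention))
    transform = nbo.ornt_transform(src, dst)
    data = nbo.apply_orientation(series.data, transform)
    perm = transform[:, 0].astype(int)
    voxel = tuple(series.voxel_size_mm[i] for i in np.argsort(perm))
    out = series.with_data(np.ascontiguousarray(data), orientation=tuple(convention))
    out.voxel_size_mm = voxel
    return out
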