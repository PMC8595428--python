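"""Inter-brain synchrony: voxel-wise correlation between two subjects.

After per-run voxel-wise normalization and temporal concatenation, the
Pearson correlation between spatially analogous voxels of the two brains is
Fisher-Z transformed and thresholded.  The transform used is the
variance-stabilized z-score

    z = atanh(r) * sqrt(n - 3)

which is approximately standard normal under independence, so a threshold
of 3.1 corresponds to a one-sided Gaussian tail of about 1e-3.  (The plain
atanh(r) scale is available behind a flag; a threshold of 3.1 on that scale
would require r ~ 0.9996 and is not meaningful for BOLD.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import concatenate_runs, normalize_voxelwise
from .volio import Mask3D, VolumeSeries

__all__ = [
    "SynchronyResult",
    "pairwise_voxel_correlation",
    "fisher_z",
    "synchrony_pipeline",
]

_R_CLIP = 1.0 - 1e-12


@dataclass
class SynchronyResult:
    r_map: np.ndarray
    z_map: np.ndarray
    n_timepoints: int
    threshold: float = 3.1
    two_sided: bool = False
    supra_mask: np.ndarray = field(init=False)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore"):
            if self.two_sided:
                self.supra_mask = np.abs(self.z_map) >= self.threshold
            else:
                self.supra_mask = self.z_map >= self.threshold
        self.supra_mask &= np.isfinite(self.z_map)


def pairwise_voxel_correlation(
    concat_a: VolumeSeries, concat_b: VolumeSeries, mask: Mask3D
) -> np.ndarray:
    """Pearson correlation between spatially analogous voxels of two brains.

    Inputs are the per-run-normalized, concatenated series of each subject
    on identical grids.  Out-of-mask and zero-variance voxels are NaN.
    """
    if concat_a.data.shape != concat_b.data.shape:
        raise ValueError("the two series must share grid and time length")
    if concat_a.n_volumes < 4:
        raise ValueError("need at least 4 timepoints")
    mask.check_grid(concat_a)
    n = concat_a.n_volumes
    A = concat_a.data.reshape(-1, n)
    B = concat_b.data.reshape(-1, n)
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (A * B).sum(axis=1) / (na * nb)
    r = r.reshape(concat_a.data.shape[:3])
    r = np.where(mask.data, r, np.nan)
    return r


def fisher_z(
    r: np.ndarray | float, n: int, variance_stabilized: bool = True
) -> np.ndarray | float:
    """Fisher transform of a correlation map.

    With ``variance_stabilized`` (default), returns atanh(r) * sqrt(n - 3),
    an approximate standard-normal deviate under the null; otherwise the
    plain atanh(r).  r is clipped to +/-(1 - 1e-12) so identical series give
    a finite z.
    """
    if n < 4:
        raise ValueError("need n >= 4 timepoints")
    r_arr = np.clip(np.asarray(r, dtype=float), -_R_CLIP, _R_CLIP)
    z = np.arctanh(r_arr)
    if variance_stabilized:
        z = z * np.sqrt(n - 3.0)
    if np.isscalar(r):
        return float(z)
    return z


def synchrony_pipeline(
    runs_a: list[VolumeSeries],
    runs_b: list[VolumeSeries],
    mask: Mask3D,
    threshold: float = 3.1,
    two_sided: bool = False,
    variance_stabilized: bool = True,
) -> SynchronyResult:
    """Normalize per run, concatenate, correlate, Fisher-Z, threshold.

    Per-run normalization removes inter-run differences in voxel mean and
    SD before concatenation; n for the transform is the total concatenated
    timepoint count (no autocorrelation correction — see the methods note
    for the effective-df caveat).  Thresholding is one-sided at +threshold
    by default, two-sided on |z| optionally.
    """
    if len(runs_a) != len(runs_b) or not runs_a:
        raise ValueError("need equal, nonzero run counts for both subjects")
    for ra, rb in zip(runs_a, runs_b):
        if ra.n_volumes != rb.n_volumes:
            raise ValueError("paired runs must have equal lengths")
    concat_a = concatenate_runs([normalize_voxelwise(r) for r in runs_a])
    concat_b = concatenate_runs([normalize_voxelwise(r) for r in runs_b])
    n = concat_a.n_volumes
    r_map = pairwise_voxel_correlation(concat_a, concat_b, mask)
    with np.errstate(invalid="ignore"):
        z_map = np.where(np.isfinite(r_map), fisher_z(np.nan_to_num(r_map), n, variance_stabilized), np.nan)
    return SynchronyResult(
        r_map=r_map,
        z_map=z_map,
        n_timepoints=n,
        threshold=threshold,
        two_sided=two_sided,
        provenance={
            "n_runs": len(runs_a),
            "n_timepoints": n,
            "threshold": threshold,
            "two_sided": two_sided,
            "variance_stabilized": variance_stabilized,
            "order": "normalize_per_run -> concatenate -> correlate -> fisher_z",
        },
    )
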