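"""Quality-control metrics for a dual-subject session.

Temporal SNR maps and cross-subject summaries, receive-channel noise
correlation with intra-/inter-coil partitioning, and head-motion summaries
against the restraint system's specification (140 um translation, 0.6 deg
rotation over a run).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import detrend_poly
from .volio import Mask3D, VolumeSeries

__all__ = [
    "TsnrMap",
    "NoiseCorrelationMatrix",
    "MotionSummary",
    "tsnr_map",
    "tsnr_summary",
    "noise_correlation",
    "motion_summary",
    "symmetric_relative_difference_pct",
]


def symmetric_relative_difference_pct(a: float, b: float) -> float:
    """|a - b| / mean(a, b) x 100 — the difference convention used for
    between-subject and between-coil comparisons (means 46.4 vs 44.5 give
    ~4.2%)."""
    denom = 0.5 * (a + b)
    if denom == 0:
        raise ValueError("cannot form a relative difference around a zero mean")
    return abs(a - b) / denom * 100.0


@dataclass
class TsnrMap:
    """Per-voxel temporal SNR: mean of the raw course over the SD of the
    detrended course."""

    data: np.ndarray
    detrend_order: int
    subject_id: str = ""
    degenerate: np.ndarray | None = None  # zero-SD voxels, tSNR undefined


def tsnr_map(series: VolumeSeries, detrend_order: int = 2) -> TsnrMap:
    """Temporal SNR = mean(original) / SD(detrended) per voxel.

    The mean is taken on the raw time course (so the baseline intensity is
    preserved in the numerator) while the SD is taken after polynomial
    detrending, so slow drift does not inflate the noise estimate.  Voxels
    with zero residual SD are flagged and set to NaN.
    """
    if series.n_volumes < detrend_order + 2:
        raise ValueError(
            f"need at least detrend_order+2={detrend_order + 2} volumes, got {series.n_volumes}"
        )
    mean = series.data.mean(axis=3)
    resid = detrend_poly(series, detrend_order).data
    sd = resid.std(axis=3)
    degenerate = sd <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.where(degenerate, np.nan, mean / np.where(degenerate, 1.0, sd))
    return TsnrMap(
        data=tsnr,
        detrend_order=detrend_order,
        subject_id=series.subject_id,
        degenerate=degenerate,
    )


def tsnr_summary(
    map_a: TsnrMap,
    map_b: TsnrMap,
    mask_a: Mask3D,
    mask_b: Mask3D,
    rois: dict[str, Mask3D] | None = None,
    hist_bin_width: float = 2.0,
    hist_range: tuple[float, float] = (0.0, 120.0),
) -> dict:
    """Whole-brain and per-ROI tSNR means for two subjects plus histograms.

    Returns whole-brain means, their symmetric relative difference in
    percent, an optional per-ROI table (ROIs evaluated on both maps), and
    fixed-bin-width histograms of in-brain tSNR per subject.
    """
    if map_a.data.shape != mask_a.data.shape or map_b.data.shape != mask_b.data.shape:
        raise ValueError("map and mask grids do not match")

    def _mean(m: TsnrMap, mask: Mask3D) -> float:
        vals = m.data[mask.data]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("mask contains no voxels with defined tSNR")
        return float(vals.mean())

    mu_a, mu_b = _mean(map_a, mask_a), _mean(map_b, mask_b)
    edges = np.arange(hist_range[0], hist_range[1] + hist_bin_width, hist_bin_width)
    hists = {}
    for m, mask, tag in ((map_a, mask_a, "a"), (map_b, mask_b, "b")):
        vals = m.data[mask.data]
        counts, _ = np.histogram(vals[np.isfinite(vals)], bins=edges)
        hists[tag] = pd.DataFrame({"bin_left": edges[:-1], "count": counts})

    roi_rows = []
    for name, roi in (rois or {}).items():
        roi_rows.append(
            {
                "roi": name,
                "mean_a": _mean(map_a, roi),
                "mean_b": _mean(map_b, roi),
                "rel_diff_pct": symmetric_relative_difference_pct(
                    _mean(map_a, roi), _mean(map_b, roi)
                ),
            }
        )
    return {
        "mean_a": mu_a,
        "mean_b": mu_b,
        "rel_diff_pct": symmetric_relative_difference_pct(mu_a, mu_b),
        "roi_table": pd.DataFrame(roi_rows),
        "histograms": hists,
    }


@dataclass
class NoiseCorrelationMatrix:
    """Channel-by-channel noise correlation in percent, with coil labels."""

    matrix: pd.DataFrame  # symmetric, diagonal 100
    coil_of: dict[str, int]
    noise_level: pd.Series = field(default_factory=pd.Series)  # per-channel SD

    def summary(self) -> dict:
        """Intra-/inter-coil extrema and per-coil noise levels.

        Reports, per coil and overall: mean and max off-diagonal intra-coil
        correlation; the maximum inter-coil correlation; the mean channel
        noise level per coil and the symmetric relative difference between
        coils.
        """
        chans = list(self.matrix.columns)
        coils = sorted(set(self.coil_of.values()))
        m = self.matrix.to_numpy()
        out: dict = {"per_coil": {}}
        intra_all = []
        for coil in coils:
            idx = [i for i, ch in enumerate(chans) if self.coil_of[ch] == coil]
            block = m[np.ix_(idx, idx)]
            off = block[~np.eye(len(idx), dtype=bool)]
            out["per_coil"][coil] = {
                "intra_mean_pct": float(np.abs(off).mean()) if off.size else 0.0,
                "intra_max_pct": float(np.abs(off).max()) if off.size else 0.0,
                "noise_level": float(
                    self.noise_level.iloc[idx].mean()
                ) if len(self.noise_level) else float("nan"),
            }
            intra_all.append(np.abs(off))
        inter_vals = []
        for i, ci in enumerate(chans):
            for j, cj in enumerate(chans):
                if j > i and self.coil_of[ci] != self.coil_of[cj]:
                    inter_vals.append(abs(m[i, j]))
        out["intra_max_pct"] = float(np.concatenate(intra_all).max()) if intra_all else 0.0
        out["intra_mean_pct"] = (
            float(np.concatenate(intra_all).mean()) if intra_all else 0.0
        )
        out["inter_max_pct"] = float(max(inter_vals)) if inter_vals else 0.0
        if len(coils) == 2 and len(self.noise_level):
            out["noise_level_diff_pct"] = symmetric_relative_difference_pct(
                out["per_coil"][coils[0]]["noise_level"],
                out["per_coil"][coils[1]]["noise_level"],
            )
        return out


def noise_correlation(
    samples: pd.DataFrame | np.ndarray,
    coil_of: dict[str, int] | list[int],
) -> NoiseCorrelationMatrix:
    """Pearson channel-pair correlation of noise-only samples, in percent.

    ``samples`` holds one channel per column (a DataFrame, or an array of
    shape (n_samples, n_channels)).  A noise-only acquisition — no RF
    transmission — makes this the coil-coupling diagnostic: low inter-coil
    values certify that apparent inter-brain synchrony cannot be a receiver
    artifact.
    """
    if isinstance(samples, np.ndarray):
        samples = pd.DataFrame(
            samples, columns=[f"ch{i + 1:02d}" for i in range(samples.shape[1])]
        )
    if samples.shape[1] < 2:
        raise ValueError("need at least 2 channels")
    if samples.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    sds = samples.std(axis=0, ddof=1)
    if (sds <= 0).any():
        dead = list(sds.index[sds <= 0])
        raise ValueError(f"zero-variance channel(s): {dead}")
    if isinstance(coil_of, list):
        coil_of = {ch: c for ch, c in zip(samples.columns, coil_of)}
    if set(coil_of) != set(samples.columns):
        raise ValueError("coil assignment does not cover the sampled channels")
    corr = samples.corr(method="pearson") * 100.0
    return NoiseCorrelationMatrix(matrix=corr, coil_of=dict(coil_of), noise_level=sds)


@dataclass
class MotionSummary:
    max_translation_um: dict[str, float]
    max_rotation_deg: dict[str, float]
    overall_translation_um: float
    overall_rotation_deg: float
    translation_bound_um: float
    rotation_bound_deg: float
    passed: bool


def motion_summary(
    trace: pd.DataFrame | np.ndarray,
    translation_bound_um: float = 140.0,
    rotation_bound_deg: float = 0.6,
) -> MotionSummary:
    """Per-axis and overall maximum absolute displacement vs the bounds.

    The trace has 6 columns (3 translations in mm, 3 rotations in degrees);
    displacements are taken relative to the first row (the reference
    volume).  PASS means every maximum is within its bound — the criterion
    the four-point head fixation is specified to meet (140 um, 0.6 deg over
    a run).
    """
    arr = np.asarray(trace, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError("motion trace must be 2-D with 6 columns")
    if arr.shape[0] < 1:
        raise ValueError("motion trace is empty")
    rel = arr - arr[0]
    trans_um = np.abs(rel[:, :3]).max(axis=0) * 1000.0
    rot_deg = np.abs(rel[:, 3:]).max(axis=0)
    trans_names = ["x", "y", "z"]
    rot_names = ["pitch", "roll", "yaw"]
    passed = bool(
        (trans_um <= translation_bound_um).all() and (rot_deg <= rotation_bound_deg).all()
    )
    return MotionSummary(
        max_translation_um=dict(zip(trans_names, trans_um.tolist())),
        max_rotation_deg=dict(zip(rot_names, rot_deg.tolist())),
        overall_translation_um=float(trans_um.max()),
        overall_rotation_deg=float(rot_deg.max()),
        translation_bound_um=translation_bound_um,
        rotation_bound_deg=rotation_bound_deg,
        passed=passed,
    )
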