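"""Per-subject BOLD time-series conditioning.

Polynomial detrending, temporal band-pass filtering, mask-renormalized
spatial Gaussian smoothing, voxel-wise normalization, nuisance-component
regression, and run concatenation — the stages the synchrony and task
pipelines compose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre
from scipy.ndimage import gaussian_filter

from .volio import Mask3D, VolumeSeries

__all__ = [
    "NuisanceSet",
    "detrend_poly",
    "bandpass",
    "smooth_gaussian",
    "normalize_voxelwise",
    "regress_nuisance",
    "concatenate_runs",
    "FWHM_TO_SIGMA",
]

#: sigma = FWHM / (2 sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class NuisanceSet:
    """Time courses labeled as noise, to be regressed out of a run."""

    components: np.ndarray  # time x components
    source: str = ""

    def __post_init__(self) -> None:
        self.components = np.atleast_2d(np.asarray(self.components, dtype=float))
        if self.components.ndim != 2:
            raise ValueError("components must be a 2-D (time x component) array")
        if self.components.shape[1] > 1:
            for i in range(self.components.shape[1]):
                for j in range(i + 1, self.components.shape[1]):
                    if np.array_equal(self.components[:, i], self.components[:, j]):
                        raise ValueError(f"components {i} and {j} are identical")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def _as_voxels_by_time(series: VolumeSeries) -> np.ndarray:
    return series.data.reshape(-1, series.n_volumes)


def detrend_poly(series: VolumeSeries, order: int = 5) -> VolumeSeries:
    """Subtract the per-voxel least-squares polynomial of given order.

    The fit uses an orthogonal (Legendre) basis on time normalized to
    [-1, 1], which is numerically stable up to the fifth order the task GLM
    requires.  Residuals have zero mean for any order >= 0.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    n = series.n_volumes
    if n <= order + 1:
        raise ValueError(f"need more than order+1={order + 1} volumes, got {n}")
    tn = np.linspace(-1.0, 1.0, n)
    basis = legendre.legvander(tn, order)
    q, _ = np.linalg.qr(basis)
    Y = _as_voxels_by_time(series).T  # time x voxels
    resid = Y - q @ (q.T @ Y)
    out = series.with_data(resid.T.reshape(series.data.shape))
    out.meta["detrend_order"] = order
    return out


def bandpass(
    series: VolumeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    transition: float = 0.2,
) -> VolumeSeries:
    """Zero-phase temporal band-pass via a tapered frequency-domain mask.

    The gain is 1 across [low, high], 0 beyond a raised-cosine transition of
    fractional width ``transition`` around each edge (gain reaches 0 at
    low*(1-transition) and high*(1+transition)), which attenuates one octave
    past either edge by far more than 20 dB while leaving pass-band
    amplitudes intact.  DC is always removed.
    """
    nyquist = 1.0 / (2.0 * series.tr_s)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) invalid for TR {series.tr_s} (Nyquist {nyquist:g})"
        )
    n = series.n_volumes
    freqs = np.fft.rfftfreq(n, d=series.tr_s)
    gain = _tapered_band_gain(freqs, low_hz, high_hz, transition)
    Y = _as_voxels_by_time(series)
    spec = np.fft.rfft(Y, axis=1)
    filtered = np.fft.irfft(spec * gain[np.newaxis, :], n=n, axis=1)
    out = series.with_data(filtered.reshape(series.data.shape))
    out.meta["bandpass_hz"] = (low_hz, high_hz)
    return out


def _tapered_band_gain(
    freqs: np.ndarray, low: float, high: float, transition: float
) -> np.ndarray:
    lo0, lo1 = low * (1.0 - transition), low
    hi0, hi1 = high, high * (1.0 + transition)
    gain = np.zeros_like(freqs)
    gain[(freqs >= lo1) & (freqs <= hi0)] = 1.0
    rise = (freqs > lo0) & (freqs < lo1)
    gain[rise] = 0.5 * (1.0 - np.cos(np.pi * (freqs[rise] - lo0) / (lo1 - lo0)))
    fall = (freqs > hi0) & (freqs < hi1)
    gain[fall] = 0.5 * (1.0 + np.cos(np.pi * (freqs[fall] - hi0) / (hi1 - hi0)))
    gain[freqs == 0.0] = 0.0
    return gain


def smooth_gaussian(
    series: VolumeSeries, fwhm_mm: float, mask: Mask3D | None = None
) -> VolumeSeries:
    """Per-volume 3-D Gaussian smoothing with a mask-renormalized kernel.

    sigma_mm = fwhm / (2 sqrt(2 ln 2)) per axis, converted to voxels by the
    voxel size.  The kernel is renormalized within the mask (smooth(y*m) /
    smooth(m)), so a constant image stays constant in-mask and no signal
    bleeds in from outside.  Out-of-mask voxels are returned untouched.
    fwhm 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return series.with_data(series.data.copy())
    if mask is not None:
        mask.check_grid(series)
        m = mask.data.astype(float)
    else:
        m = np.ones(series.data.shape[:3])
    sigma_vox = tuple(
        fwhm_mm * FWHM_TO_SIGMA / vs for vs in series.voxel_size_mm
    ) + (0.0,)
    num = gaussian_filter(series.data * m[..., np.newaxis], sigma=sigma_vox, mode="constant")
    den = gaussian_filter(m, sigma=sigma_vox[:3], mode="constant")
    out_data = series.data.copy()
    inside = m > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out_data[inside, :] = num[inside, :] / den[inside][:, np.newaxis]
    out = series.with_data(out_data)
    out.meta["fwhm_mm"] = fwhm_mm
    return out


def normalize_voxelwise(series: VolumeSeries) -> VolumeSeries:
    """Scale every voxel's time course to mean 0, SD 1 (population SD).

    Zero-variance voxels cannot be scaled; they are set to all-zero and
    flagged in ``meta['degenerate_voxels']`` so downstream statistics can
    exclude them.  Idempotent on non-degenerate voxels.
    """
    if series.n_volumes < 2:
        raise ValueError("need at least 2 volumes to normalize")
    Y = _as_voxels_by_time(series)
    mean = Y.mean(axis=1, keepdims=True)
    sd = Y.std(axis=1, keepdims=True)  # population SD (divide by n)
    degenerate = sd[:, 0] <= 0
    sd[degenerate, :] = 1.0
    Z = (Y - mean) / sd
    Z[degenerate, :] = 0.0
    out = series.with_data(Z.reshape(series.data.shape))
    out.meta["normalized"] = "mean0_sd1_population"
    out.meta["degenerate_voxels"] = degenerate.reshape(series.data.shape[:3])
    return out


def regress_nuisance(series: VolumeSeries, nuisance: NuisanceSet) -> VolumeSeries:
    """Project out labeled noise components from every voxel's time course.

    Residuals are orthogonal to every component; signal already orthogonal
    to the components is untouched.  Collinear component sets are rejected.
    """
    X = nuisance.components
    n = series.n_volumes
    if X.shape[0] != n:
        raise ValueError(f"components have {X.shape[0]} timepoints, series has {n}")
    if X.shape[1] >= n:
        raise ValueError("need fewer components than timepoints")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"nuisance components are collinear (rank {rank} < {X.shape[1]}); "
            "remove redundant components"
        )
    q, _ = np.linalg.qr(X)
    Y = _as_voxels_by_time(series).T
    resid = Y - q @ (q.T @ Y)
    out = series.with_data(resid.T.reshape(series.data.shape))
    out.meta["nuisance_regressed"] = nuisance.source or f"{X.shape[1]} components"
    return out


def concatenate_runs(runs: list[VolumeSeries]) -> VolumeSeries:
    """Concatenate runs voxel-wise along time, recording run boundaries."""
    if not runs:
        raise ValueError("no runs to concatenate")
    first = runs[0]
    for r in runs[1:]:
        if r.data.shape[:3] != first.data.shape[:3]:
            raise ValueError("runs are on different grids")
        if r.tr_s != first.tr_s:
            raise ValueError("runs have different TR")
        if r.subject_id != first.subject_id:
            raise ValueError(
                f"runs belong to different subjects: {r.subject_id!r} vs {first.subject_id!r}"
            )
    data = np.concatenate([r.data for r in runs], axis=3)
    boundaries = np.cumsum([r.n_volumes for r in runs]).tolist()
    out = first.with_data(data, run_id="+".join(r.run_id for r in runs))
    out.meta["run_boundaries"] = boundaries
    return out
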