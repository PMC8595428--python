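"""Synthetic paired BOLD data with known ground truth.

Generates two-subject runs in which designated, spatially analogous regions
of the two brains share a band-limited latent signal at a target Pearson
correlation rho, on top of a task response, polynomial scanner drift, and
AR(1) noise.  Also simulates multi-channel receiver-noise samples for the
noise-correlation analysis and smooth bounded head-motion traces.

The generative model per in-mask voxel v and volume t is

    y(v, t) = baseline * (1 + drift(t))
              + c(v) * g(t)              # shared latent, unit variance
              + beta(v) * x_task(t)      # HRF-convolved block regressor
              + eps(v, t)                # AR(1), stationary SD sigma

with c(v) = sigma * sqrt(rho / (1 - rho)) inside the coupling region so that
two voxels sharing g over independent noise correlate at exactly rho in
expectation.  g is standardized per run before scaling, which makes
rho-recovery tests sharp; runs draw independent g and independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .taskglm import BlockDesign, block_regressor, convolve_regressor
from .volio import Mask3D, RADIOLOGICAL, VolumeSeries

__all__ = [
    "NoiseSpec",
    "CouplingSpec",
    "GroundTruth",
    "MOTION_COLUMNS",
    "coupling_amplitude",
    "sample_shared_signal",
    "simulate_pair",
    "simulate_noise_channels",
    "simulate_motion_trace",
    "default_channel_covariance",
    "write_motion_trace",
    "read_motion_trace",
]

#: Column order of motion traces: translations in mm, rotations in degrees.
MOTION_COLUMNS = [
    "trans_x_mm", "trans_y_mm", "trans_z_mm",
    "rot_pitch_deg", "rot_roll_deg", "rot_yaw_deg",
]


@dataclass
class NoiseSpec:
    """Voxel noise model: baseline, AR(1) noise, polynomial drift.

    ``drift_coeffs`` are polynomial coefficients (constant first) evaluated
    on time normalized to [-1, 1]; the drift multiplies the baseline, so a
    coefficient of 0.01 is a 1% excursion.
    """

    baseline: float = 100.0
    sigma: float = 2.2
    ar1_phi: float = 0.3
    drift_coeffs: tuple[float, ...] = (0.0, 0.01, 0.005)

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if not (abs(self.ar1_phi) < 1):
            raise ValueError("|ar1_phi| must be < 1 for stationarity")
        self.drift_coeffs = tuple(float(c) for c in self.drift_coeffs)

    def drift(self, n_volumes: int) -> np.ndarray:
        tn = np.linspace(-1.0, 1.0, n_volumes)
        return np.polynomial.polynomial.polyval(tn, self.drift_coeffs)


@dataclass
class CouplingSpec:
    """Shared-signal region and strength for the two brains."""

    roi: Mask3D
    rho: float = 0.3
    band_hz: tuple[float, float] = (0.01, 0.1)

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        low, high = self.band_hz
        if not (0.0 < low < high):
            raise ValueError(f"invalid band {self.band_hz}")


@dataclass
class GroundTruth:
    """Recovery targets for a simulated pair."""

    coupling_maps: tuple[np.ndarray, np.ndarray]
    beta_maps: tuple[np.ndarray, np.ndarray]
    shared_signals: np.ndarray  # (n_runs, n_volumes), unit variance per run
    motion: tuple[pd.DataFrame, pd.DataFrame]
    rho: float = 0.0
    task_regressor: np.ndarray | None = None

    @property
    def shared_signal(self) -> np.ndarray:
        """All runs' latents concatenated in time."""
        return self.shared_signals.reshape(-1)


def coupling_amplitude(rho: float, sigma: float) -> float:
    """Amplitude c with c^2 / (c^2 + sigma^2) = rho.

    Two voxels sharing a unit-variance latent with amplitude c over
    independent noise of SD sigma correlate at exactly rho.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return sigma * np.sqrt(rho / (1.0 - rho))


def sample_shared_signal(
    n_volumes: int,
    tr_s: float,
    band_hz: tuple[float, float] = (0.01, 0.1),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Band-limited Gaussian series, standardized to mean 0 / SD 1.

    White Gaussian noise is masked in the frequency domain to the requested
    band and standardized exactly (population SD), so spectral power is
    concentrated in-band and coupling amplitudes scale as intended.
    """
    if n_volumes < 8:
        raise ValueError("need at least 8 volumes")
    low, high = band_hz
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0.0 < low < high <= nyquist):
        raise ValueError(f"band {band_hz} invalid for TR {tr_s} (Nyquist {nyquist:g} Hz)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n_volumes)
    freqs = np.fft.rfftfreq(n_volumes, d=tr_s)
    spec = np.fft.rfft(white)
    spec[(freqs < low) | (freqs > high)] = 0.0
    if not np.any(spec):
        raise ValueError(f"band {band_hz} contains no resolvable frequency at n={n_volumes}")
    g = np.fft.irfft(spec, n=n_volumes)
    g = g - g.mean()
    return g / g.std()


def _ar1_noise(
    rng: np.random.Generator, n_series: int, n_volumes: int, sigma: float, phi: float
) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sigma``: (n_series, t)."""
    if sigma == 0:
        return np.zeros((n_series, n_volumes))
    innov_sd = sigma * np.sqrt(1.0 - phi**2)
    eps0 = rng.normal(0.0, sigma, size=n_series)
    if n_volumes == 1 or phi == 0.0:
        if phi == 0.0:
            out = rng.normal(0.0, sigma, size=(n_series, n_volumes))
            out[:, 0] = eps0
            return out
        return eps0[:, np.newaxis]
    innov = rng.normal(0.0, innov_sd, size=(n_series, n_volumes - 1))
    rest, _ = lfilter([1.0], [1.0, -phi], innov, axis=-1, zi=(phi * eps0)[:, np.newaxis])
    return np.concatenate([eps0[:, np.newaxis], rest], axis=1)


def simulate_pair(
    masks: tuple[Mask3D, Mask3D] | Mask3D,
    coupling: CouplingSpec | None = None,
    noise: NoiseSpec | None = None,
    task: BlockDesign | None = None,
    beta: float | np.ndarray = 0.0,
    task_condition: str | None = None,
    n_runs: int = 4,
    n_volumes: int = 400,
    tr_s: float = 1.5,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    motion_bounds: tuple[float, float] = (140.0, 0.6),
    subject_ids: tuple[str, str] = ("sub-01", "sub-02"),
    seed: int = 0,
) -> tuple[list[VolumeSeries], list[VolumeSeries], GroundTruth]:
    """Simulate paired two-subject BOLD runs with known ground truth.

    Both subjects live on identical grids in the canonical orientation, so
    voxel (i, j, k) is spatially analogous across them.  Spatially analogous
    voxels inside the coupling region share one latent g(t) per run; g is
    independent across runs, noise is independent everywhere.  Out-of-mask
    voxels carry small independent background noise (never exact zeros).

    ``beta`` may be a scalar (applied inside the coupling region, or the
    whole mask if no coupling is given) or a full 3-D amplitude map.
    ``task_condition`` selects which block label drives the response
    (default: the design's second condition, the "stimulus").

    Defaults mirror the study's resting acquisitions: four 400-volume runs
    at TR 1.5 s, i.e. 10 minutes per run.
    """
    if isinstance(masks, Mask3D):
        masks = (masks, masks)
    mask_a, mask_b = masks
    if mask_a.data.shape != mask_b.data.shape:
        raise ValueError("subject masks must share one grid shape")
    noise = noise or NoiseSpec()
    shape = mask_a.data.shape

    if coupling is not None:
        if coupling.roi.data.shape != shape:
            raise ValueError("coupling ROI grid does not match the subject masks")
        if not (coupling.roi.data <= mask_a.data).all() or not (
            coupling.roi.data <= mask_b.data
        ).all():
            raise ValueError("coupling ROI must lie inside both subject masks")
        if coupling.rho > 0 and noise.sigma == 0:
            raise ValueError("rho > 0 requires sigma > 0 (coupling rides on noise)")
        c_val = coupling_amplitude(coupling.rho, noise.sigma) if coupling.rho > 0 else 0.0
        roi = coupling.roi.data
    else:
        c_val, roi = 0.0, np.zeros(shape, dtype=bool)

    coupling_map = np.where(roi, c_val, 0.0)

    x_task = None
    if task is not None:
        if task.tr_s != tr_s:
            raise ValueError("task design TR must match the acquisition TR")
        if task.n_volumes > n_volumes:
            raise ValueError(
                f"task design spans {task.n_volumes} volumes, run has only {n_volumes}"
            )
        cond = task_condition or task.conditions[min(1, len(task.conditions) - 1)]
        x_task = np.zeros(n_volumes)
        x_task[: task.n_volumes] = convolve_regressor(block_regressor(task, cond), tr_s)

    beta_maps = []
    for mask in (mask_a, mask_b):
        if np.ndim(beta) == 0:
            region = roi if coupling is not None else mask.data
            beta_maps.append(np.where(region, float(beta), 0.0) if x_task is not None else np.zeros(shape))
        else:
            bmap = np.asarray(beta, dtype=float)
            if bmap.shape != shape:
                raise ValueError("beta map shape does not match the grid")
            beta_maps.append(bmap)

    ss = np.random.SeedSequence(seed)
    key_shared, key_a, key_b, key_motion_a, key_motion_b = ss.spawn(5)
    shared_rngs = [np.random.default_rng(s) for s in key_shared.spawn(n_runs)]
    subj_rngs = {
        0: [np.random.default_rng(s) for s in key_a.spawn(n_runs)],
        1: [np.random.default_rng(s) for s in key_b.spawn(n_runs)],
    }

    band = coupling.band_hz if coupling is not None else (0.01, 0.1)
    shared = np.stack(
        [sample_shared_signal(n_volumes, tr_s, band, rng) for rng in shared_rngs]
    )

    drift = noise.drift(n_volumes)
    bg_sd = max(1e-6, 0.01 * noise.sigma)
    runs: dict[int, list[VolumeSeries]] = {0: [], 1: []}
    for si, (mask, subject_id) in enumerate(zip((mask_a, mask_b), subject_ids)):
        in_mask = mask.data
        n_in = int(in_mask.sum())
        for ri in range(n_runs):
            rng = subj_rngs[si][ri]
            vol = np.empty(shape + (n_volumes,))
            vol[~in_mask, :] = rng.normal(0.0, bg_sd, size=((~in_mask).sum(), n_volumes))
            sig = noise.baseline * (1.0 + drift)[np.newaxis, :] + _ar1_noise(
                rng, n_in, n_volumes, noise.sigma, noise.ar1_phi
            )
            sig = sig + coupling_map[in_mask][:, np.newaxis] * shared[ri][np.newaxis, :]
            if x_task is not None:
                sig = sig + beta_maps[si][in_mask][:, np.newaxis] * x_task[np.newaxis, :]
            vol[in_mask, :] = sig
            runs[si].append(
                VolumeSeries(
                    data=vol,
                    voxel_size_mm=voxel_size_mm,
                    tr_s=tr_s,
                    orientation=RADIOLOGICAL,
                    subject_id=subject_id,
                    run_id=f"run-{ri + 1:02d}",
                    phase_encode=("x", "+" if ri % 2 == 0 else "-"),
                )
            )

    motion = tuple(
        simulate_motion_trace(
            n_volumes,
            max_translation_um=motion_bounds[0],
            max_rotation_deg=motion_bounds[1],
            seed=key,
        )
        for key in (key_motion_a, key_motion_b)
    )
    truth = GroundTruth(
        coupling_maps=(coupling_map.copy(), coupling_map.copy()),
        beta_maps=(beta_maps[0], beta_maps[1]),
        shared_signals=shared,
        motion=motion,  # type: ignore[arg-type]
        rho=coupling.rho if coupling is not None else 0.0,
        task_regressor=x_task,
    )
    return runs[0], runs[1], truth


def simulate_noise_channels(
    covariance: np.ndarray,
    n_samples: int,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Zero-mean multivariate-normal receiver-noise samples.

    Emulates a noise-only acquisition (no RF transmission): each column is
    one receive channel, each row one complex-free sample.  The empirical
    channel correlation converges to the target as samples grow.
    """
    cov = np.asarray(covariance, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-8 * max(eigvals.max(), 1.0):
        raise ValueError("covariance is not positive semi-definite")
    rng = np.random.default_rng(seed)
    samples = rng.multivariate_normal(
        np.zeros(cov.shape[0]), cov, size=n_samples, method="svd"
    )
    cols = [f"ch{i + 1:02d}" for i in range(cov.shape[0])]
    return pd.DataFrame(samples, columns=cols)


def default_channel_covariance(
    n_per_coil: int = 5,
    intra_corr: tuple[float, float] = (0.10, 0.11),
    intra_max: tuple[float, float] = (0.28, 0.29),
    inter_corr: float = 0.023,
    inter_background: float = 0.01,
    noise_level_ratio: float = 1.1019,
) -> tuple[np.ndarray, dict[str, int]]:
    """Two-coil channel covariance shaped like an in-vivo noise matrix.

    Each coil contributes ``n_per_coil`` channels with a common intra-coil
    correlation plus one stronger pair per coil (the typical worst coupled
    neighbours), giving intra-coil means near 12%/13% and maxima of
    28%/29%.  Coils are nearly decoupled: inter-coil pairs sit at a small
    background except one designated worst pair at ``inter_corr`` (2.3%).
    The second coil's channel SD is scaled so the symmetric relative
    difference in mean noise level between coils is about 9.7%.  Returns
    the covariance and a channel-name -> coil-index map.
    """
    n = 2 * n_per_coil
    corr = np.full((n, n), inter_background)
    corr[0, n_per_coil] = corr[n_per_coil, 0] = inter_corr  # worst inter-coil pair
    for b, (base, mx) in enumerate(zip(intra_corr, intra_max)):
        s = slice(b * n_per_coil, (b + 1) * n_per_coil)
        corr[s, s] = base
        i0 = b * n_per_coil
        corr[i0, i0 + 1] = corr[i0 + 1, i0] = mx
    np.fill_diagonal(corr, 1.0)
    sd = np.concatenate(
        [np.ones(n_per_coil), np.full(n_per_coil, noise_level_ratio)]
    )
    cov = corr * np.outer(sd, sd)
    coil_of = {f"ch{i + 1:02d}": (0 if i < n_per_coil else 1) for i in range(n)}
    return cov, coil_of


def simulate_motion_trace(
    n_volumes: int,
    max_translation_um: float = 140.0,
    max_rotation_deg: float = 0.6,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Smooth bounded random-walk head motion, referenced to volume 0.

    Columns follow :data:`MOTION_COLUMNS` (translations in mm, rotations in
    degrees).  Every excursion stays strictly inside the given bounds (each
    column is rescaled to a random 60-95% of its bound), so traces simulated
    at the rig's specification always pass a QC check at that specification.
    """
    if max_translation_um < 0 or max_rotation_deg < 0:
        raise ValueError("bounds must be nonnegative")
    rng = np.random.default_rng(seed)
    cols = {}
    bounds_mm = [max_translation_um / 1000.0] * 3 + [max_rotation_deg] * 3
    for name, bound in zip(MOTION_COLUMNS, bounds_mm):
        walk = np.cumsum(rng.standard_normal(n_volumes))
        walk = gaussian_filter1d(walk, sigma=max(2.0, n_volumes / 50.0), mode="nearest")
        walk = walk - walk[0]
        peak = np.abs(walk).max()
        if bound == 0 or peak == 0:
            cols[name] = np.zeros(n_volumes)
        else:
            cols[name] = walk * (bound * rng.uniform(0.6, 0.95) / peak)
    return pd.DataFrame(cols, columns=MOTION_COLUMNS)


def write_motion_trace(trace: pd.DataFrame, path) -> None:
    """Write a 6-column whitespace-delimited trace with a header line."""
    with open(path, "w") as fh:
        fh.write("# " + " ".join(trace.columns) + "\n")
        np.savetxt(fh, trace.to_numpy(), fmt="%.8f")


def read_motion_trace(path) -> pd.DataFrame:
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"motion trace must have 6 columns, got {arr.shape[1]}")
    return pd.DataFrame(arr, columns=MOTION_COLUMNS)
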