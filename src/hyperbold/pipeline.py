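"""Stage orchestration: simulate, preprocess, QC, synchrony, GLM, report.

Each stage reads its declared inputs from the output directory, runs the
corresponding library functions with the config's parameters, and writes
NIfTI-1 / TSV / JSON outputs plus provenance sidecars.  Every numeric
summary lands in a machine-readable file, never only in a log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess, qc, synchrony, taskglm
from .config import PipelineConfig, file_digest, write_provenance
from .synthgen import (
    CouplingSpec,
    NoiseSpec,
    default_channel_covariance,
    read_motion_trace,
    simulate_noise_channels,
    simulate_pair,
    write_motion_trace,
)
from .taskglm import BlockDesign
from .volio import Mask3D, VolumeSeries, read_mask, read_volume, write_mask, write_volume

logger = logging.getLogger("hyperbold")

STAGES = ["preprocess", "tsnr", "noisecorr", "motion", "synchrony", "glm", "report"]


def _box_mask(shape, box, voxel_size) -> Mask3D:
    data = np.zeros(shape, dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = box
    data[x0:x1, y0:y1, z0:z1] = True
    return Mask3D(data=data, voxel_size_mm=voxel_size)


def _stage_seed(master_seed: int, label: str) -> int:
    """Stable per-stage stream below 2**31 derived from the master seed."""
    ss = np.random.SeedSequence([master_seed, abs(hash_label(label))])
    return int(ss.generate_state(1)[0] % (2**31))


def hash_label(label: str) -> int:
    # deterministic across processes (unlike builtin hash)
    h = 0
    for ch in label:
        h = (h * 131 + ord(ch)) % (2**31)
    return h


def _require(paths: list[Path], stage: str) -> None:
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise FileNotFoundError(f"stage {stage!r} is missing inputs: {missing}")


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def cmd_simulate(cfg: PipelineConfig) -> Path:
    """Write the full synthetic dataset: rest pair, task runs, noise, motion."""
    sim = cfg.simulation
    out = Path(cfg.out_dir) / "sim"
    out.mkdir(parents=True, exist_ok=True)
    logger.info("simulate: grid=%s runs=%dx%d TR=%gs seed=%d",
                sim.grid_shape, sim.n_runs, sim.n_volumes, sim.tr_s, cfg.seed)

    mask = _box_mask(sim.grid_shape, sim.mask_box, sim.voxel_size_mm)
    roi = _box_mask(sim.grid_shape, sim.roi_box, sim.voxel_size_mm)
    noise = NoiseSpec(baseline=sim.baseline, sigma=sim.sigma,
                      ar1_phi=sim.ar1_phi, drift_coeffs=sim.drift_coeffs)
    coupling = CouplingSpec(roi=roi, rho=sim.rho, band_hz=sim.band_hz)

    files: list[Path] = []

    def _save_series(series: VolumeSeries, name: str) -> None:
        p = out / f"{name}.nii"
        write_volume(series, p)
        files.append(p)

    runs_a, runs_b, truth = simulate_pair(
        masks=mask,
        coupling=coupling,
        noise=noise,
        n_runs=sim.n_runs,
        n_volumes=sim.n_volumes,
        tr_s=sim.tr_s,
        voxel_size_mm=sim.voxel_size_mm,
        motion_bounds=(sim.motion_translation_um, sim.motion_rotation_deg),
        subject_ids=sim.subject_ids,
        seed=_stage_seed(cfg.seed, "rest"),
    )
    for runs in (runs_a, runs_b):
        for r in runs:
            _save_series(r, f"{r.subject_id}_{r.run_id}")
    for sid, cmap in zip(sim.subject_ids, truth.coupling_maps):
        p = out / f"truth_coupling_{sid}.nii"
        write_volume(VolumeSeries(cmap, sim.voxel_size_mm, 1.0), p)
        files.append(p)
    for sid, trace in zip(sim.subject_ids, truth.motion):
        p = out / f"motion_{sid}.txt"
        write_motion_trace(trace, p)
        files.append(p)
    np.savetxt(out / "shared_signals.tsv", truth.shared_signals.T, delimiter="\t")
    files.append(out / "shared_signals.tsv")

    for name, m in (("mask", mask), ("roi", roi)):
        p = out / f"{name}.nii"
        write_mask(m, p)
        files.append(p)

    if sim.task is not None:
        t = sim.task
        design = BlockDesign.alternating(
            n_blocks=t.n_blocks,
            duration_a_s=t.duration_baseline_s,
            duration_b_s=t.duration_stimulus_s,
            label_a=t.label_baseline,
            label_b=t.label_stimulus,
            tr_s=sim.tr_s,
        )
        for par, beta in (("par1", t.beta_paradigm1), ("par2", t.beta_paradigm2)):
            runs, _, par_truth = simulate_pair(
                masks=mask,
                coupling=CouplingSpec(roi=roi, rho=0.0, band_hz=sim.band_hz),
                noise=noise,
                task=design,
                beta=beta,
                n_runs=t.n_runs_per_paradigm,
                n_volumes=t.n_volumes,
                tr_s=sim.tr_s,
                voxel_size_mm=sim.voxel_size_mm,
                subject_ids=(f"task-{par}", f"task-{par}-unused"),
                seed=_stage_seed(cfg.seed, f"task-{par}"),
            )[0:3]
            for r in runs:
                _save_series(r, f"task_{par}_{r.run_id}")
            p = out / f"motion_task_{par}.txt"
            write_motion_trace(par_truth.motion[0].iloc[: t.n_volumes], p)
            files.append(p)
        design_sidecar = {
            "blocks": design.blocks,
            "tr_s": design.tr_s,
            "n_volumes": design.n_volumes,
            "conditions": design.conditions,
        }
        _json_dump(design_sidecar, out / "task_design.json")
        files.append(out / "task_design.json")

    nc = sim.noise_channels
    cov, coil_of = default_channel_covariance(
        n_per_coil=nc.n_per_coil,
        intra_corr=nc.intra_corr,
        intra_max=nc.intra_max,
        inter_corr=nc.inter_corr,
        inter_background=nc.inter_background,
        noise_level_ratio=nc.noise_level_ratio,
    )
    samples = simulate_noise_channels(cov, nc.n_samples, seed=_stage_seed(cfg.seed, "noise"))
    samples.to_csv(out / "noise_samples.tsv", sep="\t", index=False, float_format="%.8f")
    files.append(out / "noise_samples.tsv")
    _json_dump(coil_of, out / "coil_assignment.json")
    files.append(out / "coil_assignment.json")

    manifest = {str(p.relative_to(out)): file_digest(p) for p in sorted(files)}
    _json_dump(manifest, out / "manifest.json")
    write_provenance(out / "manifest.json", "simulate",
                     cfg.simulation.model_dump(), cfg.seed)
    return out / "manifest.json"


def _rest_run_paths(cfg: PipelineConfig) -> dict[str, list[Path]]:
    sim_dir = Path(cfg.out_dir) / "sim"
    return {
        sid: [sim_dir / f"{sid}_run-{i + 1:02d}.nii" for i in range(cfg.simulation.n_runs)]
        for sid in cfg.simulation.subject_ids
    }


def _stage_preprocess(cfg: PipelineConfig) -> dict:
    """Resting/synchrony conditioning: smooth, detrend, band-pass.

    Polynomial detrending precedes the frequency-domain filter because an
    FFT mask assumes a periodic signal: an unremoved monotone drift leaks
    across the whole spectrum and, being common to both subjects, would
    masquerade as inter-brain synchrony.
    """
    out = Path(cfg.out_dir) / "preprocess"
    out.mkdir(parents=True, exist_ok=True)
    mask_path = Path(cfg.out_dir) / "sim" / "mask.nii"
    paths = _rest_run_paths(cfg)
    _require([mask_path] + [p for ps in paths.values() for p in ps], "preprocess")
    mask = read_mask(mask_path)
    pp = cfg.preprocessing
    written = []
    for sid, run_paths in paths.items():
        for p in run_paths:
            series = read_volume(p)
            series.subject_id = sid
            series = preprocess.smooth_gaussian(series, pp.fwhm_mm, mask)
            series = preprocess.detrend_poly(series, pp.detrend_order)
            series = preprocess.bandpass(series, *pp.band_hz)
            dest = out / (p.stem + "_preproc.nii")
            write_volume(series, dest)
            write_provenance(dest, "preprocess", pp.model_dump(), cfg.seed, inputs=[p])
            written.append(str(dest))
    return {"written": written}


def _stage_tsnr(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir) / "tsnr"
    out.mkdir(parents=True, exist_ok=True)
    sim_dir = Path(cfg.out_dir) / "sim"
    sids = cfg.simulation.subject_ids
    run1 = {sid: sim_dir / f"{sid}_run-01.nii" for sid in sids}
    mask_path = sim_dir / "mask.nii"
    _require(list(run1.values()) + [mask_path], "tsnr")
    mask = read_mask(mask_path)
    maps = {}
    for sid, p in run1.items():
        series = read_volume(p)
        series.subject_id = sid
        tmap = qc.tsnr_map(series, cfg.qc.tsnr_detrend_order)
        maps[sid] = tmap
        dest = out / f"tsnr_{sid}.nii"
        write_volume(VolumeSeries(np.nan_to_num(tmap.data), series.voxel_size_mm, 1.0), dest)
        write_provenance(dest, "tsnr", {"detrend_order": tmap.detrend_order}, cfg.seed, inputs=[p])
    summary = qc.tsnr_summary(maps[sids[0]], maps[sids[1]], mask, mask)
    for tag, hist in summary["histograms"].items():
        hist.to_csv(out / f"tsnr_hist_{tag}.tsv", sep="\t", index=False)
    result = {
        "mean_a": summary["mean_a"],
        "mean_b": summary["mean_b"],
        "rel_diff_pct": summary["rel_diff_pct"],
    }
    _json_dump(result, out / "tsnr_summary.json")
    return result


def _stage_noisecorr(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir) / "noisecorr"
    out.mkdir(parents=True, exist_ok=True)
    sim_dir = Path(cfg.out_dir) / "sim"
    samples_path = sim_dir / "noise_samples.tsv"
    coil_path = sim_dir / "coil_assignment.json"
    _require([samples_path, coil_path], "noisecorr")
    samples = pd.read_csv(samples_path, sep="\t")
    coil_of = json.loads(coil_path.read_text())
    ncm = qc.noise_correlation(samples, coil_of)
    ncm.matrix.to_csv(out / "noise_correlation_pct.tsv", sep="\t", float_format="%.4f")
    summary = ncm.summary()
    _json_dump(summary, out / "noisecorr_summary.json")
    write_provenance(out / "noisecorr_summary.json", "noisecorr", {}, cfg.seed,
                     inputs=[samples_path])
    return summary


def _stage_motion(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir) / "motion"
    out.mkdir(parents=True, exist_ok=True)
    sim_dir = Path(cfg.out_dir) / "sim"
    results = {}
    paths = [sim_dir / f"motion_{sid}.txt" for sid in cfg.simulation.subject_ids]
    _require(paths, "motion")
    for sid, p in zip(cfg.simulation.subject_ids, paths):
        trace = read_motion_trace(p)
        summ = qc.motion_summary(
            trace, cfg.qc.translation_bound_um, cfg.qc.rotation_bound_deg
        )
        results[sid] = {
            "max_translation_um": summ.overall_translation_um,
            "max_rotation_deg": summ.overall_rotation_deg,
            "pass": summ.passed,
        }
    _json_dump(results, out / "motion_summary.json")
    return results


def _stage_synchrony(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir) / "synchrony"
    out.mkdir(parents=True, exist_ok=True)
    pre = Path(cfg.out_dir) / "preprocess"
    sids = cfg.simulation.subject_ids
    paths = {
        sid: [pre / f"{sid}_run-{i + 1:02d}_preproc.nii" for i in range(cfg.simulation.n_runs)]
        for sid in sids
    }
    mask_path = Path(cfg.out_dir) / "sim" / "mask.nii"
    _require([mask_path] + [p for ps in paths.values() for p in ps], "synchrony")
    mask = read_mask(mask_path)

    def _load(sid):
        runs = []
        for p in paths[sid]:
            s = read_volume(p)
            s.subject_id = sid
            runs.append(s)
        return runs

    sc = cfg.synchrony
    result = synchrony.synchrony_pipeline(
        _load(sids[0]), _load(sids[1]), mask,
        threshold=sc.threshold, two_sided=sc.two_sided,
        variance_stabilized=sc.variance_stabilized,
    )
    vs = cfg.simulation.voxel_size_mm
    for name, arr in (("r", result.r_map), ("z", result.z_map),
                      ("supra", result.supra_mask.astype(np.uint8))):
        dest = out / f"synchrony_{name}.nii"
        write_volume(VolumeSeries(np.nan_to_num(np.asarray(arr, float)), vs, 1.0), dest)
    summary = {
        "n_timepoints": result.n_timepoints,
        "threshold": result.threshold,
        "two_sided": result.two_sided,
        "n_supra_voxels": int(result.supra_mask.sum()),
        "median_r_in_mask": float(np.nanmedian(result.r_map)),
        "provenance": result.provenance,
    }
    _json_dump(summary, out / "synchrony.json")
    write_provenance(out / "synchrony.json", "synchrony", sc.model_dump(), cfg.seed)
    return summary


def _stage_glm(cfg: PipelineConfig) -> dict:
    sim = cfg.simulation
    if sim.task is None:
        raise ValueError("config has no task block; nothing for the GLM stage to do")
    t = sim.task
    out = Path(cfg.out_dir) / "glm"
    out.mkdir(parents=True, exist_ok=True)
    sim_dir = Path(cfg.out_dir) / "sim"
    design = BlockDesign.alternating(
        n_blocks=t.n_blocks,
        duration_a_s=t.duration_baseline_s,
        duration_b_s=t.duration_stimulus_s,
        label_a=t.label_baseline,
        label_b=t.label_stimulus,
        tr_s=sim.tr_s,
    )
    g = cfg.glm
    stim_label = f"cond_{t.label_stimulus}"
    base_label = f"cond_{t.label_baseline}"
    effects: dict[str, dict[str, list[np.ndarray]]] = {}
    vs = sim.voxel_size_mm
    for par in ("par1", "par2"):
        run_paths = [
            sim_dir / f"task_{par}_run-{i + 1:02d}.nii" for i in range(t.n_runs_per_paradigm)
        ]
        motion_path = sim_dir / f"motion_task_{par}.txt"
        _require(run_paths + [motion_path], "glm")
        motion = read_motion_trace(motion_path).to_numpy()[: design.n_volumes]
        X = taskglm.build_design(
            design, motion=motion, detrend_order=g.detrend_order,
            drift_high_hz=g.drift_high_hz,
        )
        effects[par] = {stim_label: [], base_label: []}
        for p in run_paths:
            series = read_volume(p)
            series = series.with_data(series.data[..., : design.n_volumes])
            fit = taskglm.fit_glm(series, X)
            effects[par][stim_label].append(fit.coefficients[stim_label])
            effects[par][base_label].append(fit.coefficients[base_label])
    summary: dict = {}
    for par in ("par1", "par2"):
        contrast = taskglm.paired_contrast(
            effects[par][stim_label], effects[par][base_label],
            threshold=g.paired_threshold_t,
        )
        for name, arr in (("effect", contrast.effect_map), ("t", contrast.t_map),
                          ("z", contrast.z_map), ("supra", contrast.supra_mask.astype(np.uint8))):
            write_volume(VolumeSeries(np.nan_to_num(np.asarray(arr, float)), vs, 1.0),
                         out / f"paired_{par}_{name}.nii")
        summary[f"paired_{par}"] = {
            "df": contrast.df,
            "threshold_t": contrast.threshold,
            "n_supra_voxels": int(np.nansum(contrast.supra_mask)),
        }
    unpaired = taskglm.unpaired_contrast(
        effects["par1"][stim_label], effects["par2"][stim_label],
        threshold=g.unpaired_threshold_z,
    )
    for name, arr in (("effect", unpaired.effect_map), ("t", unpaired.t_map),
                      ("z", unpaired.z_map), ("supra", unpaired.supra_mask.astype(np.uint8))):
        write_volume(VolumeSeries(np.nan_to_num(np.asarray(arr, float)), vs, 1.0),
                     out / f"unpaired_{name}.nii")
    summary["unpaired"] = {
        "df": unpaired.df,
        "threshold_z": unpaired.threshold,
        "n_supra_voxels": int(np.nansum(unpaired.supra_mask)),
    }
    _json_dump(summary, out / "glm.json")
    write_provenance(out / "glm.json", "glm", g.model_dump(), cfg.seed)
    return summary


def _stage_report(cfg: PipelineConfig) -> dict:
    base = Path(cfg.out_dir)
    report: dict = {"seed": cfg.seed}
    sources = {
        "tsnr": base / "tsnr" / "tsnr_summary.json",
        "noisecorr": base / "noisecorr" / "noisecorr_summary.json",
        "motion": base / "motion" / "motion_summary.json",
        "synchrony": base / "synchrony" / "synchrony.json",
        "glm": base / "glm" / "glm.json",
    }
    for key, path in sources.items():
        if path.exists():
            report[key] = json.loads(path.read_text())
    _json_dump(report, base / "report.json")
    return report


_STAGE_FUNCS = {
    "preprocess": _stage_preprocess,
    "tsnr": _stage_tsnr,
    "noisecorr": _stage_noisecorr,
    "motion": _stage_motion,
    "synchrony": _stage_synchrony,
    "glm": _stage_glm,
    "report": _stage_report,
}


def cmd_run(cfg: PipelineConfig, stage: str) -> dict:
    """Run one pipeline stage; inputs must already exist on disk."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    logger.info("stage %s: out_dir=%s seed=%d", stage, cfg.out_dir, cfg.seed)
    return _STAGE_FUNCS[stage](cfg)


def run_all(cfg: PipelineConfig) -> dict:
    """simulate + every stage in order; returns the final report."""
    cmd_simulate(cfg)
    result: dict = {}
    for stage in STAGES:
        if stage == "glm" and cfg.simulation.task is None:
            continue
        result = cmd_run(cfg, stage)
    return result
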