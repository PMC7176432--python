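"""Reproducible multi-stage pipelines over the analysis modules.

A :class:`PipelineConfig` selects stages and carries every module
parameter plus one global seed; the seed is expanded deterministically
into per-stage child seeds so stages can be re-run independently.  Each
run writes a :class:`RunManifest` (JSON) recording the config hash, the
child seeds and a checksum for every file produced, so identical
config+seed runs are byte-identical and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from pathlib import Path

import numpy as np

from smtrace import imaging, io, kinetics, simkit, steps
from smtrace._version import __version__
from smtrace.errors import InvalidArgumentError

STAGES = ("simulate", "detect", "trace", "steps", "fret", "mm", "ic50",
          "telegraph")


@dataclasses.dataclass
class PipelineConfig:
    """Stage selection plus all module parameters.

    Defaults mirror the analysis conventions: 800 A.U. normalisation
    scale, leakage beta 0.12, E threshold 0.5, 6 px background kernel,
    3x3 ROIs, k_max 8 and 0.1 s frames.
    """

    stages: tuple = ("simulate", "steps")
    out_dir: str = "smtrace-out"
    seed: int = 0
    # simulate
    n_traces: int = 50
    n_frames: int = 600
    frame_interval: float = 0.1
    unit_intensity: float = 80.0
    noise_sd: float = 20.0
    background_level: float = 0.0
    n_fluors: int = 1
    bleach_rate: float = 0.1
    # imaging
    kernel_px: int = 6
    min_peak: float | None = None
    stack_path: str | None = None
    roi_path: str | None = None
    # steps
    scale: float = 800.0
    k_max: int = 8
    trace_path: str | None = None
    # fret
    beta: float = 0.12
    threshold: float = 0.5
    fret_path: str | None = None
    # kinetics tables
    curves_path: str | None = None
    series_path: str | None = None
    paths_path: str | None = None

    def validate(self):
        for stage in self.stages:
            if stage not in STAGES:
                raise InvalidArgumentError(f"unknown stage: {stage}")
        if not (0 <= self.beta < 1):
            raise InvalidArgumentError("beta must lie in [0, 1)")
        if self.scale <= 0 or self.k_max < 2 or self.kernel_px < 2:
            raise InvalidArgumentError("parameter outside its domain")
        if self.frame_interval <= 0:
            raise InvalidArgumentError("frame_interval must be > 0")

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def child_seeds(seed, n):
    """Deterministic per-stage child seeds (< 2**31) from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _checksum(path):
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig):
    """Execute the selected stages in dependency order; returns the manifest.

    Missing inputs fail before any stage runs; on a stage failure the
    partial outputs are kept and the manifest marks the failure point.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    order = [s for s in STAGES if s in config.stages]
    # fail fast on missing external inputs
    for stage, attr in (("detect", "stack_path"), ("mm", "curves_path"),
                        ("ic50", "series_path"), ("telegraph", "paths_path")):
        path = getattr(config, attr)
        if stage in order and path is not None and not Path(path).exists():
            raise InvalidArgumentError(f"input for stage {stage!r} missing: {path}")
    seeds = dict(zip(STAGES, child_seeds(config.seed, len(STAGES))))
    manifest = {
        "tool": "smtrace",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "child_seeds": seeds,
        "started_utc": _time.strftime("%Y-%m-%dT%H:%M:%SZ", _time.gmtime()),
        "stages": {},
        "status": "ok",
    }
    produced = {}
    try:
        for stage in order:
            outputs = _run_stage(stage, config, seeds[stage], out, produced)
            manifest["stages"][stage] = {
                "outputs": {str(p): _checksum(p) for p in outputs},
            }
    except Exception as exc:
        manifest["status"] = f"failed at {stage}: {exc}"
        _write_manifest(manifest, out)
        raise
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest, out):
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _run_stage(stage, config, seed, out, produced):
    if stage == "simulate":
        traces, truths = [], {}
        for i in range(config.n_traces):
            cfg = simkit.SimConfig(
                n_frames=config.n_frames,
                frame_interval=config.frame_interval,
                unit_intensity=config.unit_intensity,
                noise_sd=config.noise_sd,
                background_level=config.background_level,
                seed=seed + i,
            )
            trace, truth = simkit.simulate_photobleaching_trace(
                config.n_fluors, cfg, bleach_rate=config.bleach_rate
            )
            trace.trace_id = f"sim-{i:04d}"
            traces.append(trace)
            truths[trace.trace_id] = truth
        trace_path = out / "traces.tsv"
        truth_path = out / "ground_truth.tsv"
        manifest_path = out / "ground_truth_params.txt"
        io.write_trace_table(traces, trace_path)
        io.write_ground_truth(truths, truth_path, manifest_path)
        produced["traces"] = traces
        return [trace_path, truth_path, manifest_path]
    if stage == "detect":
        stack = io.read_stack(config.stack_path,
                              frame_interval=config.frame_interval)
        clean = imaging.subtract_background(stack, kernel_px=config.kernel_px)
        rois = imaging.detect_spots(imaging.detection_image(clean),
                                    min_peak=config.min_peak)
        roi_path = out / "rois.tsv"
        io.write_roi_table(rois, roi_path)
        produced["stack"] = clean
        produced["rois"] = rois
        return [roi_path]
    if stage == "trace":
        stack = produced.get("stack")
        rois = produced.get("rois")
        if stack is None:
            stack = imaging.subtract_background(
                io.read_stack(config.stack_path,
                              frame_interval=config.frame_interval),
                kernel_px=config.kernel_px,
            )
        if rois is None:
            rois = io.read_roi_table(config.roi_path)
        traces = [imaging.extract_trace(stack, roi) for roi in rois]
        trace_path = out / "traces.tsv"
        io.write_trace_table(traces, trace_path)
        produced["traces"] = traces
        return [trace_path]
    if stage == "steps":
        traces = produced.get("traces")
        if traces is None:
            traces = io.read_trace_table(config.trace_path)
        summary_rows, path_rows = [], []
        for trace in traces:
            scaled = steps.normalize_trace(trace, scale=config.scale)
            curve = steps.bic_model_selection(scaled, k_max=config.k_max)
            fit = curve.fits[curve.selected]
            n_steps = int(np.sum(np.diff(fit.levels[fit.path]) < 0))
            summary_rows.append((trace.trace_id, fit.n_states, n_steps,
                                 fit.n_states - 1, fit.bic))
            path_rows.extend(
                (trace.trace_id, frame, int(state))
                for frame, state in enumerate(fit.path)
            )
        import pandas as pd
        summary_path = out / "steps_summary.tsv"
        path_path = out / "steps_path.tsv"
        pd.DataFrame(summary_rows, columns=[
            "trace_id", "n_states", "n_steps", "max_probes", "bic",
        ]).to_csv(summary_path, sep="\t", index=False)
        pd.DataFrame(path_rows, columns=["trace_id", "frame", "state"]).to_csv(
            path_path, sep="\t", index=False
        )
        return [summary_path, path_path]
    if stage == "fret":
        from smtrace import fret as fret_mod
        traces = io.read_fret_table(config.fret_path)
        kept, rejected = fret_mod.filter_fret_traces(traces)
        dist = fret_mod.efficiency_distribution(
            kept, beta=config.beta, threshold=config.threshold
        )
        import pandas as pd
        dist_path = out / "fret_distribution.tsv"
        summary_path = out / "fret_summary.txt"
        pd.DataFrame({
            "bin_lo": dist.bin_edges[:-1],
            "bin_hi": dist.bin_edges[1:],
            "frequency": dist.frequency,
        }).to_csv(dist_path, sep="\t", index=False)
        reasons = {}
        for _, reason in rejected:
            reasons[reason] = reasons.get(reason, 0) + 1
        io.write_results({
            "n_kept": len(kept),
            "n_rejected": len(rejected),
            **{f"rejected_{k}": v for k, v in reasons.items()},
            "low_e_fraction": dist.low_e_fraction,
            "config_hash": config.config_hash(),
        }, summary_path)
        return [dist_path, summary_path]
    if stage == "mm":
        import pandas as pd
        table = pd.read_csv(config.curves_path, sep="\t")
        rates, concs = [], []
        for atp, group in table.groupby("atp_um"):
            curve = simkit.ProgressCurve(
                atp_um=float(atp),
                time_s=group["time_s"].to_numpy(dtype=float),
                counts=group["count"].to_numpy(dtype=float),
            )
            k, _ = kinetics.fit_progress_curve(curve)
            rates.append(k)
            concs.append(float(atp))
        fit = kinetics.fit_michaelis_menten(rates, concs)
        path = out / "mm_fit.txt"
        io.write_results({
            "K_M_um": fit.K_M, "k_cat_max_per_s": fit.k_cat_max,
            "stderr_K_M": fit.stderr_K_M,
            "stderr_k_cat_max": fit.stderr_k_cat_max,
            "config_hash": config.config_hash(),
        }, path)
        return [path]
    if stage == "ic50":
        import pandas as pd
        table = pd.read_csv(config.series_path, sep="\t")
        fit = kinetics.fit_dose_response(
            table["activity_pct"].to_numpy(dtype=float),
            table["inhibitor_um"].to_numpy(dtype=float),
        )
        path = out / "ic50_fit.txt"
        io.write_results({
            "IC50_um": fit.IC50, "hill": fit.hill, "top": fit.top,
            "bottom": fit.bottom, "stderr_IC50": fit.stderr_IC50,
            "config_hash": config.config_hash(),
        }, path)
        return [path]
    if stage == "telegraph":
        import pandas as pd
        table = pd.read_csv(config.paths_path, sep="\t")
        paths = [
            group.sort_values("frame")["state"].to_numpy(dtype=int)
            for _, group in table.groupby("trace_id", sort=False)
        ]
        fit = kinetics.estimate_telegraph_rates(paths, config.frame_interval)
        path = out / "telegraph_fit.txt"
        io.write_results({
            "k_gen_per_s": fit.k_gen, "k_rem_per_s": fit.k_rem,
            "n_on_dwells": fit.n_on_dwells, "n_off_dwells": fit.n_off_dwells,
            "config_hash": config.config_hash(),
        }, path)
        return [path]
    raise InvalidArgumentError(f"unknown stage: {stage}")  # pragma: no cover
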