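"""End-to-end orchestration: simulate -> extract -> features -> predict -> report.

One global seed fans out into named per-stage substreams so stages stay
reproducible and individually resumable; each stage writes its outputs under
the run directory and a manifest records seeds, hashes and wall time.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import eeg_blinks, features, fnirs_cardiac, predict, simulate, stats_report
from .features import FEATURE_COLUMNS, assemble_feature_target_tables, episode_summary_features, secondary_task_metrics
from .simulate import SimulationConfig, SubjectSession

__all__ = ["PipelineConfig", "run_pipeline", "extract_subject_features", "cohort_tables"]

STAGES = ("simulate", "extract", "features", "predict", "report")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str | Path = "runs/default"
    seed: int = 0
    signals: tuple[str, ...] = ("fnirs", "eeg")
    cv_repeats: int = 100
    hrv_window_s: float = 30.0
    resume: bool = True
    verbosity: int = 1

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def extract_subject_features(
    session: SubjectSession,
    hrv_window_s: float = 30.0,
    ica_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run both extraction chains and summarise one subject's episodes."""
    hr, hrv = fnirs_cardiac.hr_hrv_from_optical(session.optical, hrv_window_s=hrv_window_s)
    if session.eeg is not None:
        blinks, cleaned = eeg_blinks.blinks_from_eeg(
            session.eeg, session.layout.episodes, seed=ica_seed
        )
        removed = cleaned.removed_fragment_intervals
    else:
        blinks, removed = None, ()
    feat_rows = []
    for ep in session.layout.episodes:
        ef = episode_summary_features(hr, hrv, blinks, ep, session.subject_id, removed)
        feat_rows.append(ef.as_dict())
    targ = session.targets.copy()
    rts, nrrs, err_rates = [], [], []
    for _, row in targ.iterrows():
        ep = session.layout.episode(row["episode_label"])
        rt, nrr = secondary_task_metrics(session.task_log, ep)
        rts.append(rt)
        nrrs.append(nrr)
        err_rates.append(row["errors_10"] / (ep.duration / 60.0))
    targ["reaction_time"] = rts
    targ["non_response_rate"] = nrrs
    targ["error_rate_10"] = err_rates
    return pd.DataFrame(feat_rows), targ


def cohort_tables(
    config: SimulationConfig,
    signals: tuple[str, ...] = ("fnirs", "eeg"),
    hrv_window_s: float = 30.0,
    ica_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-episode feature and target tables for a simulated cohort."""
    all_feats, all_targs = [], []
    for session in simulate.iter_cohort(config, signals):
        f, t = extract_subject_features(session, hrv_window_s, ica_seed)
        all_feats.append(f)
        all_targs.append(t)
    return pd.concat(all_feats, ignore_index=True), pd.concat(all_targs, ignore_index=True)


def ground_truth_feature_tables(
    config: SimulationConfig,
    hrv_window_s: float = 30.0,
    hrv_step_s: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature/target tables computed from generator ground truth.

    Skips signal synthesis and extraction: HR statistics come from the true
    HR trajectory, HRV from its windowed band powers, blink rate from the
    realised blink times.  Used to study the statistical machinery (sign
    recovery, cross-validation behaviour) free of extraction noise.
    """
    feat_rows, targ_rows = [], []
    for session in simulate.iter_cohort(config, signals=()):
        tr = session.truth
        n = tr.true_hr.size
        grid = np.arange(n) / config.fnirs_rate
        hr = fnirs_cardiac.HeartRateSeries(t=grid, hr=tr.true_hr, rate=config.fnirs_rate)
        hrv = fnirs_cardiac.compute_hrv_series(hr, window_s=hrv_window_s, step_s=hrv_step_s)
        for ep in session.layout.episodes:
            blink_count = int(np.sum((tr.true_blink_times >= ep.start) & (tr.true_blink_times < ep.end)))
            row = episode_summary_features(hr, hrv, None, ep, session.subject_id).as_dict()
            row["br_mean"] = 60.0 * blink_count / ep.duration
            feat_rows.append(row)
        targ = session.targets.copy()
        rts, nrrs, errs = [], [], []
        for _, trow in targ.iterrows():
            ep = session.layout.episode(trow["episode_label"])
            rt, nrr = secondary_task_metrics(session.task_log, ep)
            rts.append(rt)
            nrrs.append(nrr)
            errs.append(trow["errors_10"] / (ep.duration / 60.0))
        targ["reaction_time"] = rts
        targ["non_response_rate"] = nrrs
        targ["error_rate_10"] = errs
        targ_rows.append(targ)
    return pd.DataFrame(feat_rows), pd.concat(targ_rows, ignore_index=True)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; resumable from cached stage outputs.

    Returns the manifest (also written to ``manifest.json``): per stage the
    seed, wall time, output files with hashes, and whether it was restored
    from cache.  A stage failure is recorded and re-raised after the manifest
    is flushed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}

    def record(stage: str, t_start: float, files: list[Path], cached: bool) -> None:
        manifest["stages"].append({
            "stage": stage,
            "seed": config.stage_seed(stage),
            "cached": cached,
            "wall_s": round(time.time() - t_start, 3),
            "outputs": {f.name: _hash_file(f) for f in files if f.exists()},
        })

    def flush() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    sim_cfg = simulate.SimulationConfig(
        **{**config.simulation.__dict__, "seed": config.stage_seed("simulate")}
    )

    feat_path = out / "features.csv"
    targ_path = out / "targets.csv"
    try:
        t0 = time.time()
        cached = config.resume and feat_path.exists() and targ_path.exists()
        if cached:
            feats = pd.read_csv(feat_path)
            targs = pd.read_csv(targ_path)
        else:
            feats, targs = cohort_tables(
                sim_cfg, config.signals, config.hrv_window_s,
                ica_seed=config.stage_seed("extract"),
            )
            feats.to_csv(feat_path, index=False, float_format="%.10g")
            targs.to_csv(targ_path, index=False, float_format="%.10g")
        record("simulate", t0, [], cached)
        record("extract", t0, [], cached)
        record("features", t0, [feat_path, targ_path], cached)

        t0 = time.time()
        table_path = out / "prediction_table.csv"
        cached = config.resume and table_path.exists()
        if cached:
            table = pd.read_csv(table_path)
        else:
            f_pool, t_pool = assemble_feature_target_tables(feats, targs)
            result = predict.build_prediction_table(
                f_pool, t_pool,
                predict.CFNetSpec(seed=config.stage_seed("predict")),
                repeats=config.cv_repeats, seed=config.stage_seed("predict"),
            )
            table = result.table
            table.to_csv(table_path, index=False, float_format="%.10g")
        record("predict", t0, [table_path], cached)

        t0 = time.time()
        comparisons = []
        rest = feats[feats["episode_label"] == "Rest"].groupby("subject_id").mean(numeric_only=True)
        task = feats[feats["episode_label"].isin(simulate.TASK_LABELS)].groupby("subject_id").mean(numeric_only=True)
        common = rest.index.intersection(task.index)
        for col in ("hr_mean", "hrv_mean", "br_mean"):
            a = rest.loc[common, col].to_numpy()
            b = task.loc[common, col].to_numpy()
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() >= 5:
                comparisons.append(
                    stats_report.compare_groups(a[ok], b[ok], paired=True,
                                                label_a=f"rest:{col}", label_b=f"task:{col}")
                )
        stats_report.render_report(
            out / "report", prediction_table=table, group_comparisons=comparisons,
            feature_table=feats, boxplot_columns=("hr_mean", "hrv_mean", "br_mean"),
        )
        report_files = sorted((out / "report").glob("*"))
        record("report", t0, report_files, False)
        manifest["status"] = "complete"
    except Exception as exc:  # noqa: BLE001 - manifest must record the failure
        manifest["status"] = f"failed: {type(exc).__name__}: {exc}"
        flush()
        raise
    flush()
    return manifest
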