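"""Per-episode feature summaries, behavioural metrics and pooled tables.

Physiological predictors per subject x episode: mean/std/max/min of HR and
HRV plus the episode blink rate (nine features in all; only the blink mean is
used because blinks are too sparse for within-episode statistics).  Targets
are NASA-TLX scores and dual-task behaviour.  Task episodes (Task1, Task2,
Task1R) are pooled into aligned feature/target tables for prediction;
alternative predictor sources (first rest episode, task-minus-rest deltas)
support the rest-physiology re-analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eeg_blinks import BlinkEvents, blink_rate
from .fnirs_cardiac import HeartRateSeries, HRVSeries
from .simulate import Episode, SessionLayout, SecondaryTaskLog, TASK_LABELS

__all__ = [
    "EpisodeFeatures",
    "FEATURE_COLUMNS",
    "episode_summary_features",
    "secondary_task_metrics",
    "smooth_timecourse",
    "detect_outliers",
    "assemble_feature_target_tables",
]

FEATURE_COLUMNS = (
    "hr_mean", "hr_std", "hr_max", "hr_min",
    "hrv_mean", "hrv_std", "hrv_max", "hrv_min",
    "br_mean",
)


@dataclass
class EpisodeFeatures:
    subject_id: str
    episode_label: str
    hr_mean: float
    hr_std: float
    hr_max: float
    hr_min: float
    hrv_mean: float
    hrv_std: float
    hrv_max: float
    hrv_min: float
    br_mean: float

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "episode_label": self.episode_label,
            **{c: getattr(self, c) for c in FEATURE_COLUMNS},
        }


def _stats(x: np.ndarray) -> tuple[float, float, float, float]:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return (np.nan,) * 4
    return float(x.mean()), float(x.std()), float(x.max()), float(x.min())


def episode_summary_features(
    hr: HeartRateSeries,
    hrv: HRVSeries,
    blinks: BlinkEvents | None,
    episode: Episode,
    subject_id: str = "",
    removed_fragments=(),
) -> EpisodeFeatures:
    """Mean/std/max/min of HR and HRV plus blink rate within one episode.

    Statistics use only samples falling inside the episode; empty coverage
    yields NaN markers for the affected features.
    """
    hr_sel = episode.contains(hr.t)
    hrv_sel = episode.contains(hrv.t)
    hm, hs, hmax, hmin = _stats(hr.hr[hr_sel])
    vm, vs, vmax, vmin = _stats(hrv.hrv[hrv_sel])
    br = blink_rate(blinks, (episode.start, episode.end), removed_fragments)
    return EpisodeFeatures(
        subject_id=subject_id, episode_label=episode.label,
        hr_mean=hm, hr_std=hs, hr_max=hmax, hr_min=hmin,
        hrv_mean=vm, hrv_std=vs, hrv_max=vmax, hrv_min=vmin,
        br_mean=br,
    )


def secondary_task_metrics(
    log: SecondaryTaskLog,
    episode: Episode,
    aggregate: str = "mean",
) -> tuple[float, float]:
    """Reaction time and non-response rate for one episode.

    A stimulus counts as non-responded when no response arrives before the
    next stimulus onset (the last stimulus has no successor and is judged by
    presence of a response alone).  Reaction time aggregates the latencies of
    responded stimuli (mean by default, median selectable).
    """
    onsets = np.asarray(log.stimulus_onsets, dtype=float)
    resp = np.asarray(log.response_times, dtype=float)
    sel = np.flatnonzero((onsets >= episode.start) & (onsets < episode.end))
    if sel.size == 0:
        return float("nan"), float("nan")
    next_onset = np.full(onsets.size, np.inf)
    next_onset[:-1] = onsets[1:]
    responded = np.isfinite(resp[sel]) & (resp[sel] < next_onset[sel])
    latencies = resp[sel][responded] - onsets[sel][responded]
    if latencies.size == 0:
        rt = float("nan")
    elif aggregate == "median":
        rt = float(np.median(latencies))
    else:
        rt = float(np.mean(latencies))
    nrr = 1.0 - responded.sum() / sel.size
    return rt, float(nrr)


def smooth_timecourse(series: np.ndarray, rate: float, window_s: float = 10.0) -> np.ndarray:
    """Centred moving average with a window shrinking at the edges."""
    if window_s <= 0:
        raise ValueError("window must be > 0")
    x = np.asarray(series, dtype=float)
    win = max(int(round(window_s * rate)), 1)
    half = win // 2
    csum = np.cumsum(np.concatenate(([0.0], x)))
    n = x.size
    i0 = np.maximum(np.arange(n) - half, 0)
    i1 = np.minimum(np.arange(n) + half + 1, n)
    return (csum[i1] - csum[i0]) / (i1 - i0)


def detect_outliers(values: np.ndarray, w: float = 2.0) -> np.ndarray:
    """Tukey-style outlier mask with widened fences (default w = 2).

    A point is an outlier when above ``q3 + w*(q3 - q1)`` or below
    ``q1 - w*(q3 - q1)``; quartiles by linear interpolation of order
    statistics.  Fewer than 4 values: all-false with a warning.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    mask = np.zeros(x.shape, dtype=bool)
    if finite.sum() < 4:
        warnings.warn("fewer than 4 values: outlier fences undefined", stacklevel=2)
        return mask
    q1, q3 = np.percentile(x[finite], [25, 75])
    iqr = q3 - q1
    mask[finite] = (x[finite] > q3 + w * iqr) | (x[finite] < q1 - w * iqr)
    return mask


def _first_rest_label_map(layout: SessionLayout) -> str:
    for ep in layout.episodes:
        if ep.label == "Rest":
            return ep.label
    raise ValueError("layout has no rest episode")


def assemble_feature_target_tables(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    pooling: tuple[str, ...] = TASK_LABELS,
    predictor_source: str = "task",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aligned pooled tables, one row per subject x task episode.

    ``predictor_source``:
      * ``"task"``  - features from the task episode itself (default);
      * ``"rest"``  - features from the subject's first rest episode;
      * ``"delta"`` - task features minus first-rest features.

    Rows lacking either side are dropped with a warning; remaining rows are
    key-aligned exactly.
    """
    if predictor_source not in ("task", "rest", "delta"):
        raise ValueError("predictor_source must be task, rest or delta")
    feats = features.copy()
    targs = targets.copy()
    keys = ["subject_id", "episode_label"]
    task_feats = feats[feats["episode_label"].isin(pooling)]
    if predictor_source in ("rest", "delta"):
        rest = feats[feats["episode_label"] == "Rest"]
        # first rest per subject
        rest = rest.groupby("subject_id", as_index=False).first()
        rest_vals = rest.set_index("subject_id")[list(FEATURE_COLUMNS)]
        rows = []
        for _, r in task_feats.iterrows():
            sid = r["subject_id"]
            if sid not in rest_vals.index:
                continue
            base = rest_vals.loc[sid]
            row = {k: r[k] for k in keys}
            for c in FEATURE_COLUMNS:
                row[c] = base[c] if predictor_source == "rest" else r[c] - base[c]
            rows.append(row)
        task_feats = pd.DataFrame(rows)
    task_targs = targs[targs["episode_label"].isin(pooling)]
    merged_keys = task_feats[keys].merge(task_targs[keys], on=keys)
    n_expected = max(len(task_feats), len(task_targs))
    if len(merged_keys) < n_expected:
        missing_f = set(map(tuple, task_targs[keys].values)) - set(map(tuple, task_feats[keys].values))
        missing_t = set(map(tuple, task_feats[keys].values)) - set(map(tuple, task_targs[keys].values))
        warnings.warn(
            f"dropping unmatched rows: missing features for {sorted(missing_f)}, "
            f"missing targets for {sorted(missing_t)}",
            stacklevel=2,
        )
    f_out = task_feats.merge(merged_keys, on=keys).sort_values(keys).reset_index(drop=True)
    t_out = task_targs.merge(merged_keys, on=keys).sort_values(keys).reset_index(drop=True)
    if not (f_out[keys].values == t_out[keys].values).all():
        raise ValueError("feature/target key alignment failed")
    return f_out, t_out
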