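"""Group comparisons, time-course summaries, rest-vs-task shift, reporting.

Group differences use the Wilcoxon signed-rank test for paired samples
(same subjects under two conditions) and the two-sample Kolmogorov-Smirnov
test otherwise; both are distribution-free.  Time courses are smoothed by a
10 s moving window and summarised across subjects as mean +/- sd, with
fixed-length edge segments for task episodes of unequal duration.  The
rest-vs-task shift analysis regresses the task-minus-rest change of a metric
on its resting value, the signature of regression-to-the-mean and of the
floor effect that compresses HRV under load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .features import detect_outliers, smooth_timecourse

__all__ = [
    "GroupComparison",
    "TimecourseSummary",
    "ShiftReport",
    "compare_groups",
    "timecourse_summary",
    "rest_task_shift",
    "boxplot_stats",
    "render_report",
]


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    test: str                      # "signed-rank" | "ks"
    statistic: float
    p: float
    paired: bool
    n_a: int
    n_b: int
    note: str = ""


def compare_groups(
    a: np.ndarray,
    b: np.ndarray,
    paired: bool,
    label_a: str = "A",
    label_b: str = "B",
) -> GroupComparison:
    """Wilcoxon signed-rank (paired) or two-sample KS (unpaired), two-sided.

    Paired inputs must be matched by subject order and equal in length.
    All-zero paired differences are degenerate; they are flagged and reported
    with p = 1.  Groups smaller than 5 carry a low-power note.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    note = ""
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal-length, matched groups")
        d = a - b
        if np.all(d == 0):
            return GroupComparison(label_a, label_b, "signed-rank", 0.0, 1.0, True,
                                   a.size, b.size, note="all differences zero")
        stat, p = stats.wilcoxon(a, b)
        test = "signed-rank"
    else:
        stat, p = stats.ks_2samp(a, b)
        test = "ks"
    if min(a.size, b.size) < 5:
        note = "n < 5: low power"
    return GroupComparison(label_a, label_b, test, float(stat), float(p), paired,
                           a.size, b.size, note=note)


@dataclass
class TimecourseSummary:
    t: np.ndarray                  # grid relative to episode start (s)
    mean: np.ndarray
    sd: np.ndarray
    t_end: np.ndarray | None = None   # grid relative to episode end
    mean_end: np.ndarray | None = None
    sd_end: np.ndarray | None = None
    n_subjects: int = 0


def timecourse_summary(
    series_per_subject: list[tuple[np.ndarray, np.ndarray]],
    episode,
    rate: float,
    smooth_s: float = 10.0,
    edge_s: float | None = 40.0,
) -> TimecourseSummary:
    """Cross-subject mean and sd of episode-aligned, smoothed time courses.

    Each subject contributes a (t, value) series; values are smoothed by a
    centred ``smooth_s`` moving window, then aligned to the episode start.
    When ``edge_s`` is given (task episodes of unequal duration), only the
    first and last ``edge_s`` seconds are aggregated, the trailing segment
    aligned to the episode end.
    """
    if len(series_per_subject) < 2:
        raise ValueError("need at least 2 subjects")
    head_rows, tail_rows = [], []
    n_edge = int(round((edge_s if edge_s else episode.duration) * rate))
    for t, x in series_per_subject:
        sel = episode.contains(t)
        if not np.any(sel):
            continue
        xs = smooth_timecourse(x[sel], rate, smooth_s)
        if xs.size < n_edge:
            continue
        head_rows.append(xs[:n_edge])
        tail_rows.append(xs[-n_edge:])
    if len(head_rows) < 2:
        raise ValueError("insufficient overlapping coverage across subjects")
    head = np.asarray(head_rows)
    grid = np.arange(n_edge) / rate
    out = TimecourseSummary(
        t=grid, mean=head.mean(axis=0), sd=head.std(axis=0), n_subjects=head.shape[0]
    )
    if edge_s is not None:
        tail = np.asarray(tail_rows)
        out.t_end = grid - edge_s
        out.mean_end = tail.mean(axis=0)
        out.sd_end = tail.std(axis=0)
    return out


@dataclass
class ShiftReport:
    metric: str
    rest: np.ndarray
    task: np.ndarray
    r_within_rest: float           # e.g. HR-vs-HRV correlation uses pairs upstream
    delta_slope: float             # slope of (task - rest) on rest
    delta_intercept: float
    delta_r: float
    delta_p: float


def rest_task_shift(rest: np.ndarray, task: np.ndarray, metric: str = "") -> ShiftReport:
    """Regress the task-related change of a metric on its resting value.

    A near-zero slope means the task shifts the metric uniformly (HR-like); a
    slope near -1 with strongly negative r means the metric collapses to a
    floor regardless of its resting value (HRV-like, regression to the mean
    compounded by the lower bound near zero).
    """
    rest = np.asarray(rest, dtype=float)
    task = np.asarray(task, dtype=float)
    if rest.size != task.size:
        raise ValueError("rest and task must be matched by subject")
    ok = np.isfinite(rest) & np.isfinite(task)
    rest, task = rest[ok], task[ok]
    delta = task - rest
    res = stats.linregress(rest, delta)
    return ShiftReport(
        metric=metric, rest=rest, task=task,
        r_within_rest=float(np.corrcoef(rest, task)[0, 1]) if rest.size > 2 else float("nan"),
        delta_slope=float(res.slope), delta_intercept=float(res.intercept),
        delta_r=float(res.rvalue), delta_p=float(res.pvalue),
    )


def boxplot_stats(values: np.ndarray, w: float = 2.0) -> dict:
    """Median, quartiles, whisker ends and outliers under the w-fence rule.

    Whiskers extend to the most extreme points not flagged as outliers by
    ``detect_outliers`` (fences at q1 - w*IQR and q3 + w*IQR).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return {"n": 0}
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    mask = detect_outliers(x, w) if x.size >= 4 else np.zeros(x.size, dtype=bool)
    inliers = x[~mask]
    return {
        "n": int(x.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inliers.min()),
        "whisker_high": float(inliers.max()),
        "outliers": sorted(float(v) for v in x[mask]),
    }


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def render_report(
    out_dir: str | Path,
    prediction_table: pd.DataFrame | None = None,
    group_comparisons: list[GroupComparison] | None = None,
    feature_table: pd.DataFrame | None = None,
    boxplot_columns: tuple[str, ...] = (),
    w: float = 2.0,
) -> dict:
    """Write CSV tables, boxplot summaries and a markdown digest; manifest back.

    Deterministic: regeneration from the same inputs is byte-identical (no
    timestamps).  Missing inputs are listed in the manifest and a partial
    report is produced.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"written": [], "missing": [], "hashes": {}}
    lines = ["# Analysis report", ""]
    if prediction_table is not None:
        path = out / "prediction_table.csv"
        prediction_table.to_csv(path, index=False)
        manifest["written"].append(path.name)
        manifest["hashes"][path.name] = _hash_df(prediction_table)
        lines += ["## Prediction performance", "", "See `prediction_table.csv`.", ""]
    else:
        manifest["missing"].append("prediction_table")
    if group_comparisons:
        rows = [vars(g) for g in group_comparisons]
        gdf = pd.DataFrame(rows)
        path = out / "group_comparisons.csv"
        gdf.to_csv(path, index=False)
        manifest["written"].append(path.name)
        manifest["hashes"][path.name] = _hash_df(gdf)
        lines += ["## Group comparisons", "", "See `group_comparisons.csv`.", ""]
    else:
        manifest["missing"].append("group_comparisons")
    if feature_table is not None and boxplot_columns:
        box_rows = []
        for col in boxplot_columns:
            if col not in feature_table.columns:
                manifest["missing"].append(f"boxplot:{col}")
                continue
            for label, grp in feature_table.groupby("episode_label"):
                st = boxplot_stats(grp[col].to_numpy(), w=w)
                st.update({"column": col, "episode_label": label,
                           "outliers": ";".join(f"{v:g}" for v in st.get("outliers", []))})
                box_rows.append(st)
        if box_rows:
            bdf = pd.DataFrame(box_rows)
            path = out / "boxplot_stats.csv"
            bdf.to_csv(path, index=False)
            manifest["written"].append(path.name)
            manifest["hashes"][path.name] = _hash_df(bdf)
            lines += ["## Boxplot summaries", "", "See `boxplot_stats.csv`.", ""]
    elif feature_table is None:
        manifest["missing"].append("feature_table")
    (out / "report.md").write_text("\n".join(lines))
    manifest["written"].append("report.md")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
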