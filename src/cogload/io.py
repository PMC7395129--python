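"""Delimited-text signal files with JSON sidecars.

One TSV per recording (one column per channel, header row) plus a sidecar
carrying the sample rate, channel metadata, episode layout and seed; target
tables and secondary-task logs as CSV.  Everything round-trips exactly
enough for the extraction chain (float64 via repr precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import (
    EEGRecording,
    Episode,
    OpticalRecording,
    SecondaryTaskLog,
    SessionLayout,
)

__all__ = [
    "write_optical",
    "read_optical",
    "write_eeg",
    "read_eeg",
    "write_layout",
    "read_layout",
    "write_task_log",
    "read_task_log",
]


def _write_matrix(path: Path, samples: np.ndarray, names: list[str], fmt: str = "%.10g") -> None:
    df = pd.DataFrame(samples.T, columns=names)
    df.to_csv(path, sep="\t", index=False, float_format=fmt)


def write_optical(rec: OpticalRecording, path: str | Path, layout: SessionLayout | None = None,
                  seed: int | None = None) -> None:
    path = Path(path)
    names = [f"ch{p}_{int(wl)}nm" for p, wl in zip(rec.channel_pairs, rec.wavelengths)]
    _write_matrix(path, rec.samples, names)
    sidecar = {
        "kind": "fnirs_optical",
        "rate": rec.rate,
        "wavelengths": rec.wavelengths.tolist(),
        "channel_pairs": rec.channel_pairs.tolist(),
        "source_detector_distance_mm": rec.source_detector_distance_mm,
        "dpf": rec.dpf,
        "t0": rec.t0,
        "seed": seed,
        "layout": layout_to_dict(layout) if layout else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_optical(path: str | Path) -> OpticalRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    df = pd.read_csv(path, sep="\t")
    return OpticalRecording(
        samples=df.to_numpy(dtype=float).T,
        rate=float(meta["rate"]),
        wavelengths=np.asarray(meta["wavelengths"], dtype=float),
        channel_pairs=np.asarray(meta["channel_pairs"]),
        source_detector_distance_mm=float(meta["source_detector_distance_mm"]),
        dpf=float(meta["dpf"]),
        t0=float(meta["t0"]),
    )


def write_eeg(rec: EEGRecording, path: str | Path, layout: SessionLayout | None = None,
              seed: int | None = None) -> None:
    path = Path(path)
    # microvolt signals: 5 significant digits keep files tractable
    _write_matrix(path, rec.samples, list(rec.channel_names), fmt="%.5g")
    sidecar = {
        "kind": "eeg",
        "rate": rec.rate,
        "channel_names": list(rec.channel_names),
        "t0": rec.t0,
        "seed": seed,
        "layout": layout_to_dict(layout) if layout else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_eeg(path: str | Path) -> EEGRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    df = pd.read_csv(path, sep="\t")
    return EEGRecording(
        samples=df.to_numpy(dtype=float).T,
        rate=float(meta["rate"]),
        channel_names=tuple(meta["channel_names"]),
        t0=float(meta["t0"]),
    )


def layout_to_dict(layout: SessionLayout) -> list[dict]:
    return [{"label": e.label, "start": e.start, "end": e.end} for e in layout.episodes]


def layout_from_dict(data: list[dict]) -> SessionLayout:
    return SessionLayout(tuple(Episode(d["label"], d["start"], d["end"]) for d in data))


def write_layout(layout: SessionLayout, path: str | Path) -> None:
    Path(path).write_text(json.dumps(layout_to_dict(layout), indent=2))


def read_layout(path: str | Path) -> SessionLayout:
    return layout_from_dict(json.loads(Path(path).read_text()))


def write_task_log(log: SecondaryTaskLog, path: str | Path) -> None:
    pd.DataFrame({
        "stimulus_onset_s": log.stimulus_onsets,
        "stimulus_duration_ms": log.stimulus_durations,
        "response_time_s": log.response_times,
    }).to_csv(path, index=False, float_format="%.10g")


def read_task_log(path: str | Path) -> SecondaryTaskLog:
    df = pd.read_csv(path)
    return SecondaryTaskLog(
        stimulus_onsets=df["stimulus_onset_s"].to_numpy(dtype=float),
        stimulus_durations=df["stimulus_duration_ms"].to_numpy(dtype=float),
        response_times=df["response_time_s"].to_numpy(dtype=float),
    )
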