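#!/usr/bin/env python
"""Generate the demonstration cohort.

Simulates a multi-subject dual-task session cohort (fNIRS + EEG + secondary
task logs + workload targets) with full ground truth.  Signal files are
large, so they go under ``scratch/cohort/``; the target table and layout go
under ``results/``.

Desk-scale choices: 8 subjects, 3-minute task episodes, EEG at 1000 Hz.
Run ``python analysis/01_simulate_cohort.py`` from the repository root.
"""

from pathlib import Path

import pandas as pd

from cogload import io as sig_io
from cogload import simulate

RESULTS = Path("results")
SCRATCH = Path("scratch/cohort")

CONFIG = simulate.SimulationConfig(
    n_subjects=6,
    seed=2026,
    layout=simulate.default_layout(task_s=150.0, rest_s=90.0, baseline_s=90.0),
    eeg_rate=600.0,
)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    sig_io.write_layout(CONFIG.layout, RESULTS / "layout.json")
    targets = []
    for session in simulate.iter_cohort(CONFIG):
        sdir = SCRATCH / session.subject_id
        sdir.mkdir(exist_ok=True)
        sig_io.write_optical(session.optical, sdir / "fnirs.tsv", CONFIG.layout, CONFIG.seed)
        sig_io.write_eeg(session.eeg, sdir / "eeg.tsv", CONFIG.layout, CONFIG.seed)
        sig_io.write_task_log(session.task_log, sdir / "task_log.csv")
        targets.append(session.targets)
        print(f"  wrote {session.subject_id}: "
              f"{session.optical.samples.shape[1]} fNIRS samples, "
              f"{session.eeg.samples.shape[1]} EEG samples, "
              f"{session.task_log.stimulus_onsets.size} beeps, "
              f"{session.truth.true_blink_times.size} blinks")
    table = pd.concat(targets, ignore_index=True)
    table.to_csv(RESULTS / "targets.csv", index=False, float_format="%.6g")
    print(f"cohort of {CONFIG.n_subjects} subjects; targets -> {RESULTS/'targets.csv'}")


if __name__ == "__main__":
    main()
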