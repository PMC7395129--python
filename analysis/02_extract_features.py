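#!/usr/bin/env python
"""Extract physiological features from the simulated cohort.

Runs the two extraction chains on each subject's signal files:

* fNIRS -> Beer-Lambert -> 0.5-2 Hz band-pass -> beat periods -> HR ->
  windowed HF/(HF+LF) HRV;
* EEG -> baseline correction -> fragment/channel cleaning -> 0.16-40 Hz FIR
  -> 200 Hz -> ICA -> blink component -> blink times -> blink rate;

then summarises per episode (mean/std/max/min of HR and HRV, BR mean) and
appends reaction time / non-response rate from the secondary-task log to the
target table.  Outputs ``results/features.csv`` and
``results/targets_with_behaviour.csv``.
"""

from pathlib import Path

import pandas as pd

from cogload import eeg_blinks, fnirs_cardiac
from cogload import io as sig_io
from cogload.features import episode_summary_features, secondary_task_metrics

RESULTS = Path("results")
SCRATCH = Path("scratch/cohort")


def main() -> None:
    layout = sig_io.read_layout(RESULTS / "layout.json")
    targets = pd.read_csv(RESULTS / "targets.csv")
    rows = []
    rts = {}
    for sdir in sorted(p for p in SCRATCH.iterdir() if p.is_dir()):
        sid = sdir.name
        optical = sig_io.read_optical(sdir / "fnirs.tsv")
        hr, hrv = fnirs_cardiac.hr_hrv_from_optical(optical)
        eeg = sig_io.read_eeg(sdir / "eeg.tsv")
        blinks, cleaned = eeg_blinks.blinks_from_eeg(eeg, layout.episodes, seed=0)
        removed = cleaned.removed_fragment_intervals
        log = sig_io.read_task_log(sdir / "task_log.csv")
        for ep in layout.episodes:
            rows.append(episode_summary_features(hr, hrv, blinks, ep, sid, removed).as_dict())
            rts[(sid, ep.label)] = secondary_task_metrics(log, ep)
        print(f"  {sid}: blink component "
              f"{'found' if blinks is not None else 'NOT found'}; "
              f"{len(removed)} fragments excised")
    feats = pd.DataFrame(rows)
    feats.to_csv(RESULTS / "features.csv", index=False, float_format="%.6g")

    targets["reaction_time"] = [rts[(r.subject_id, r.episode_label)][0] for r in targets.itertuples()]
    targets["non_response_rate"] = [rts[(r.subject_id, r.episode_label)][1] for r in targets.itertuples()]
    dur = {ep.label: ep.duration for ep in layout.episodes}
    targets["error_rate_10"] = targets["errors_10"] / (targets["episode_label"].map(dur) / 60.0)
    targets.to_csv(RESULTS / "targets_with_behaviour.csv", index=False, float_format="%.6g")
    print(f"features for {feats.subject_id.nunique()} subjects x "
          f"{feats.episode_label.nunique()} episode types -> {RESULTS/'features.csv'}")


if __name__ == "__main__":
    main()
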