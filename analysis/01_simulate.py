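#!/usr/bin/env python
"""Simulate the study cohort and write one CSV bundle per subject.

Generates three subjects under the graded LBNP ladder (decompensating at
-60, -70 and -80 mmHg), each with finger-, triceps- and clavicle-like PPG
channels plus reference heart rate and ground-truth reserve, and writes the
bundles under scratch/data/. Prints per-subject vitals so the cohort can be
eyeballed before analysis.
"""

import argparse
from pathlib import Path

from ppgreserve import SITE_PROFILES, build_standard_protocol, generate_multisite
from ppgreserve.io import write_recording
from ppgreserve.pipeline import _subject_seed

from common import STUDY


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument(
        "--out", type=Path,
        default=Path(__file__).resolve().parent.parent / "scratch" / "data",
    )
    args = parser.parse_args()

    profiles = [SITE_PROFILES[s] for s in STUDY["sites"]]
    for subj, hdd in enumerate(STUDY["hdd_pressures"]):
        protocol = build_standard_protocol(hdd, completed=True)
        rec = generate_multisite(
            protocol, profiles, seed=_subject_seed(args.seed, subj)
        )
        out = args.out / f"subject_{subj:02d}"
        write_recording(rec, out)
        hr = rec.reference_hr
        print(
            f"subject {subj}: HDD {hdd:+.0f} mmHg, {protocol.stop_time / 60:.0f} min, "
            f"{len(rec.true_beat_times)} beats, HR {hr.min():.0f}-{hr.max():.0f} bpm, "
            f"reserve 100->{rec.crm_gt.values[-1]:.0f}% -> {out}/"
        )


if __name__ == "__main__":
    main()
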