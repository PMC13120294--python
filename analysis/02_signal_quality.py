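#!/usr/bin/env python
"""Signal-quality stage: rolling SNR and template SQI per site and filter.

Answers: does band-pass filtering rescue the wearable sites' beat
morphology, and which filter does it best? Writes the quality table to
results/signal_quality.csv and prints the cross-site contrast.
"""

import argparse

from common import RESULTS, ensure_summary


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    summary = ensure_summary(args.seed)
    table = (
        summary.groupby(["site", "filter"])[["median_snr_db", "median_sqi"]]
        .median()
        .reset_index()
    )
    out = RESULTS / "signal_quality.csv"
    table.to_csv(out, index=False, float_format="%.4g")

    wide = table.pivot(index="site", columns="filter", values="median_sqi")
    print("median SQI by site and filter condition:")
    print(wide.round(3).to_string(), "\n")
    print(
        f"triceps-like: raw SQI {wide.loc['triceps', 'raw']:.2f} -> "
        f"{wide.loc['triceps', 'chebyshev2']:.2f} after Chebyshev II — heavy "
        "baseline wander destroys raw beat morphology; band-passing recovers it."
    )
    print(
        f"clavicle-like: best filtered SQI {wide.loc['clavicle'].max():.2f} — "
        "weak pulsatility under broadband noise; no filter recovers this site."
    )
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
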