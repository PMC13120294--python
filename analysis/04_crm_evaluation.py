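#!/usr/bin/env python
"""Reserve-prediction stage: surrogate CRM accuracy and trend lead time.

Answers: with site-dependent degradation injected into the surrogate
predictions, how much bias/error does the evaluation recover, and how much
early warning does trend detection give before protocol stop? Writes
results/crm_metrics.csv.
"""

import argparse

from common import RESULTS, ensure_summary

CRM_COLS = ["crm_r2", "crm_mde", "crm_mdae", "crm_trend_time_min"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    summary = ensure_summary(args.seed)
    # CRM metrics are per subject-site (independent of the PPG filter column)
    table = (
        summary.drop_duplicates(["subject", "site"])
        .groupby("site")[CRM_COLS]
        .median()
        .reset_index()
    )
    out = RESULTS / "crm_metrics.csv"
    table.to_csv(out, index=False, float_format="%.4g")

    print("surrogate CRM evaluation (median across subjects):")
    print(table.round(2).to_string(index=False), "\n")
    t = table.set_index("site")
    print(
        "all sites underestimate reserve (negative MdE), as injected; note the "
        "recovered bias understates the injected one at the noisiest site "
        "because predictions clip at the 0% floor late in the run. Trend "
        f"detection leads protocol stop by {t.loc['finger', 'crm_trend_time_min']:.1f} "
        "min at the cleanest site."
    )
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
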