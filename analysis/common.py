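"""Shared study definition for the numbered analysis drivers.

All drivers analyse the same simulated cohort: three subjects who
decompensate at -60, -70 and -80 mmHg (bracketing the typical final LBNP
step), each recorded at three sensor-site profiles and processed under four
filter conditions. The summary table is cached per seed so the drivers can
be run in any order without recomputing the study.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from ppgreserve import AnalysisConfig, run_pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"

STUDY = dict(
    n_subjects=3,
    sites=("finger", "triceps", "clavicle"),
    filters=("raw", "butterworth", "chebyshev2", "fir_custom"),
    hdd_pressures=(-60.0, -70.0, -80.0),
)


def study_config(seed: int) -> AnalysisConfig:
    return AnalysisConfig(seed=seed, **STUDY)


def ensure_summary(seed: int) -> pd.DataFrame:
    """Run (or reload) the full study summary for this seed."""
    RESULTS.mkdir(exist_ok=True)
    cache = RESULTS / f"study_summary_seed{seed}.csv"
    if cache.exists():
        return pd.read_csv(cache)
    summary = run_pipeline(study_config(seed))
    summary.to_csv(cache, index=False, float_format="%.10g")
    return summary
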