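import numpy as np
import pandas as pd
import pytest

from hrvscreen.cohort import (
    AutonomicParams,
    CohortSpec,
    default_effect_profiles,
    generate_cohort,
    generate_rr_series,
)
from hrvscreen.features import feature_table
from hrvscreen.preprocess import segment_and_epoch
from hrvscreen.standardize import standardize_table


def cohort_feature_tables(spec: CohortSpec, profiles=None):
    """Generate a cohort and run it through epoching, features and
    standardization in memory (no ECG rendering)."""
    records = generate_cohort(spec, profiles)
    epochs = []
    for rec in records:
        for seg in rec.segments:
            epochs.extend(
                segment_and_epoch(
                    seg.rr,
                    [(seg.condition, 0.0, seg.duration)],
                    participant_id=rec.participant_id,
                )
            )
    feats = feature_table(epochs)
    std = standardize_table(feats)
    groups = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "group": [r.group for r in records],
        }
    )
    return records, feats, std, groups


@pytest.fixture(scope="session")
def small_cohort():
    """A 10 HC / 6 IWD cohort with the default planted effects, used by the
    module-level tests that only need valid tables of realistic shape."""
    return cohort_feature_tables(CohortSpec(n_hc=10, n_iwd=6, seed=11), default_effect_profiles())


@pytest.fixture(scope="session")
def clean_rr_300s():
    """A five-minute low-noise RR series with known LF/HF tones."""
    params = AutonomicParams(
        hr_mean=65, a_lf=0.03, a_hf=0.05, f_lf=0.10, f_resp=0.25, jitter_sd=3.0
    )
    return params, generate_rr_series(params, 300.0, seed=5)
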