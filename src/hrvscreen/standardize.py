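"""Calm-referenced within-participant z-standardization.

For participant s with calm-state feature values F_{s,calm}^{(1..n)}:

    mu_s    = (1/n) sum_i F^{(i)}
    sigma_s = sqrt( (1/(n-1)) sum_i (F^{(i)} - mu_s)^2 )
    F_std   = (F_{s,epoch} - mu_s) / sigma_s

so every standardized value is the deviation from the participant's own calm
baseline in units of the calm state's SD.  At least two calm epochs are
required (the SD uses the n-1 denominator); zero-variance features are
flagged and propagate as missing rather than +-inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BaselineDegenerateError, KeyingError
from .features import FEATURE_NAMES, HRVFeatureVector


@dataclass
class CalmBaseline:
    participant_id: str
    mu: dict[str, float]
    sigma: dict[str, float]
    n: int
    zero_variance: set[str] = field(default_factory=set)


@dataclass
class StandardizedFeatureVector:
    participant_id: str
    condition: str
    epoch_index: int
    values: dict[str, float]


def fit_baseline(
    calm_epochs: list[HRVFeatureVector] | pd.DataFrame,
    participant_id: str = "",
) -> CalmBaseline:
    """Per-feature calm mean (1/n) and SD (1/(n-1)) for one participant.

    Raises BaselineDegenerateError with fewer than two calm epochs; features
    with zero calm variance are flagged (their standardized values will be
    missing downstream).  NaN feature values are excluded pairwise per
    feature; a feature with < 2 finite calm values is also flagged.
    """
    if isinstance(calm_epochs, pd.DataFrame):
        table = calm_epochs[list(FEATURE_NAMES)]
    else:
        table = pd.DataFrame([fv.as_dict() for fv in calm_epochs])
    n = len(table)
    if n < 2:
        raise BaselineDegenerateError(
            f"participant {participant_id!r}: {n} calm epoch(s); the calm SD "
            "(n-1 denominator) needs at least 2"
        )
    mu: dict[str, float] = {}
    sigma: dict[str, float] = {}
    zero_var: set[str] = set()
    for name in FEATURE_NAMES:
        vals = table[name].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            mu[name] = np.nan
            sigma[name] = np.nan
            zero_var.add(name)
            continue
        mu[name] = float(np.mean(vals))
        sigma[name] = float(np.std(vals, ddof=1))
        if sigma[name] == 0.0:
            zero_var.add(name)
    return CalmBaseline(
        participant_id=participant_id, mu=mu, sigma=sigma, n=n, zero_variance=zero_var
    )


def standardize(
    fv: HRVFeatureVector,
    baseline: CalmBaseline,
    participant_id: str = "",
    condition: str = "",
    epoch_index: int = 0,
) -> StandardizedFeatureVector:
    """Apply the calm-referenced z-transform to one feature vector."""
    if participant_id and baseline.participant_id and participant_id != baseline.participant_id:
        raise KeyingError(
            f"feature vector for {participant_id!r} standardized against "
            f"baseline of {baseline.participant_id!r}"
        )
    out: dict[str, float] = {}
    raw = fv.as_dict()
    for name in FEATURE_NAMES:
        if name in baseline.zero_variance or not np.isfinite(raw[name]):
            out[name] = np.nan
        else:
            out[name] = (raw[name] - baseline.mu[name]) / baseline.sigma[name]
    return StandardizedFeatureVector(
        participant_id=participant_id or baseline.participant_id,
        condition=condition,
        epoch_index=epoch_index,
        values=out,
    )


def standardize_table(features: pd.DataFrame) -> pd.DataFrame:
    """Standardize a full feature table against each participant's calm epochs.

    Input: the feature_table schema (participant_id, condition, epoch_index,
    nine features).  Output mirrors it with feature columns suffixed ``_std``;
    calm epochs are standardized too (per participant they have mean 0, SD 1
    by construction).  Zero-variance feature counts are recorded in
    ``df.attrs['zero_variance_counts']``.
    """
    out_rows = []
    zero_counts: dict[str, int] = {name: 0 for name in FEATURE_NAMES}
    for pid, sub in features.groupby("participant_id", sort=True):
        calm = sub[sub["condition"] == "calm"]
        base = fit_baseline(calm, participant_id=str(pid))
        for name in base.zero_variance:
            zero_counts[name] += 1
        for _, row in sub.iterrows():
            vals = {}
            for name in FEATURE_NAMES:
                if name in base.zero_variance or not np.isfinite(row[name]):
                    vals[f"{name}_std"] = np.nan
                else:
                    vals[f"{name}_std"] = (row[name] - base.mu[name]) / base.sigma[name]
            out_rows.append(
                {
                    "participant_id": pid,
                    "condition": row["condition"],
                    "epoch_index": row["epoch_index"],
                    **vals,
                }
            )
    out = pd.DataFrame(out_rows)
    out.attrs["zero_variance_counts"] = zero_counts
    return out
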