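"""Extract the nine HRV features per 1-min epoch and standardize them
against each participant's calm baseline.

The calm segment (192 s -> three epochs) defines a per-participant mean and
SD for every feature; all epochs are then expressed in units of that calm
SD, so a value of +2 means "two calm-state SDs above this person's calm
level".
"""

import pandas as pd

from hrvscreen import CohortSpec, generate_cohort, feature_table, standardize_table
from hrvscreen.preprocess import segment_and_epoch

records = generate_cohort(CohortSpec(n_hc=3, n_iwd=2, seed=3))
epochs = []
for rec in records:
    for seg in rec.segments:
        epochs.extend(
            segment_and_epoch(
                seg.rr, [(seg.condition, 0.0, seg.duration)],
                participant_id=rec.participant_id,
            )
        )

feats = feature_table(epochs)
std = standardize_table(feats)

pd.set_option("display.width", 120)
print("raw features (first participant, one row per epoch):")
cols = ["condition", "epoch_index", "MeanNN", "SDNN", "RMSSD", "LFn", "Resp_rate"]
first = feats[feats.participant_id == records[0].participant_id]
print(first[cols].round(3).to_string(index=False))

print("\nstandardized (same participant; calm rows average to 0 by construction):")
scols = ["condition", "epoch_index", "MeanNN_std", "RMSSD_std", "LFn_std"]
sfirst = std[std.participant_id == records[0].participant_id]
print(sfirst[scols].round(3).to_string(index=False))

calm_mean = sfirst[sfirst.condition == "calm"]["RMSSD_std"].mean()
print(f"\ncalm RMSSD_std mean = {calm_mean:+.2e}  (0 up to floating point)")
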