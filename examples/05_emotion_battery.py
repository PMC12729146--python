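"""Train the emotion-specific screening models and compare conditions.

One classifier per stimulus condition: emotion models use calm-standardized
features, the calm baseline model uses raw calm features.  The protocol is a
participant-grouped stratified 7:3 split, grouped 5-fold CV for
hyperparameter selection, then held-out accuracy / AUC / precision with
participant-bootstrap 95% CIs.
"""

from hrvscreen import RunConfig, cohort_tables
from hrvscreen.models import ModelConfig, battery_table, run_emotion_battery

feats, std, groups = cohort_tables(RunConfig(n_hc=66, n_iwd=30, seed=11))
cfg = ModelConfig(seed=11, search_budget=5, n_bootstrap=400)
reports = run_emotion_battery(std, feats, groups, base_config=cfg)

table = battery_table(reports)
cols = ["condition", "algorithm", "accuracy", "auc", "auc_lo", "auc_hi", "precision"]
print(table[cols].round(3).to_string(index=False))

ertc = table[table.algorithm == "ertc"].set_index("condition")["auc"]
print(
    f"\nsadness AUC {ertc['sadness']:.3f} vs calm baseline {ertc['calm']:.3f}:"
    "\nthe sadness-elicited model should discriminate the groups best, and the"
    "\ncalm-state model should sit near chance - the ordering the screen's"
    "\nsadness-dominant divergence predicts."
)
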