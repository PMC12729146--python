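"""Run the dual-phase screen on a full-size synthetic cohort.

Phase 1 asks, within each group, whether an emotion shifted each HRV feature
away from calm; phase 2 asks, within each emotion, whether the depressed and
control groups responded differently.  A cell is flagged only when the raw
Mann-Whitney p, the BH-FDR-adjusted p, and |Cohen's d| all clear their
thresholds (0.05 / 0.05 / 0.2).
"""

import pandas as pd

from hrvscreen import RunConfig, cohort_tables
from hrvscreen.stats import dual_phase_screen

feats, std, groups = cohort_tables(RunConfig(n_hc=66, n_iwd=30, seed=11))
report = dual_phase_screen(std, groups)

sad2 = report.phase2[report.phase2.emotion == "sadness"]
print("phase 2 (IWD vs HC) under sadness:")
print(
    sad2[["feature", "p_raw", "p_fdr", "cohen_d", "significant"]]
    .round(4)
    .to_string(index=False)
)
print(f"\nflagged cells overall: {report.significant_fraction() * 100:.1f}%")
print(
    "\nThe planted divergence raises the depressed group's sadness RMSSD/CVSD"
    "\n(positive d, flagged) while its frequency-domain response is blunted"
    "\n(positive d on LFn/LFHF: the controls' LFn falls further under sadness)."
)
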