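"""Dual-phase nonparametric screening of standardized HRV features.

Phase 1 (elicitation validity): within each group, each emotion's
standardized feature values are compared against the same group's
standardized calm values (Mann-Whitney U, two-sided).

Phase 2 (group divergence): within each emotion, IWD values are compared
against HC values.

p-values are Benjamini-Hochberg FDR-adjusted within each family of nine
features (one family per phase x emotion x group-contrast cell), and a cell
is flagged significant only when raw p < 0.05, adjusted p < 0.05 and
|Cohen's d| > 0.2 all hold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .cohort import CONDITIONS, GROUPS
from .errors import IncompleteDesignError, UndefinedFeatureError, ValidationError
from .features import FEATURE_NAMES

EMOTIONS = tuple(c for c in CONDITIONS if c != "calm")

ALPHA = 0.05
D_THRESHOLD = 0.2
#: combined-sample-size cutoff below which (tie-free) exact permutation is used
EXACT_N_CUTOFF = 16


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of x (U statistic of the first sample).

    Uses the exact permutation distribution when n_x + n_y <= 16 and the
    pooled sample is tie-free, otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError(
            f"each sample needs >= 2 observations (got {len(x)}, {len(y)})"
        )
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= EXACT_N_CUTOFF and no_ties) else "asymptotic"
    res = sstats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cohens_d(x, y) -> float:
    """Standardized mean difference with the pooled (n-1) SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("Cohen's d needs >= 2 observations per sample")
    nx, ny = len(x), len(y)
    s2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    if s2 == 0:
        raise UndefinedFeatureError("zero pooled SD: Cohen's d undefined")
    return float((np.mean(x) - np.mean(y)) / np.sqrt(s2))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class StatTestResult:
    feature: str
    phase: int
    emotion: str
    contrast: str  # e.g. "HC: sadness vs calm" or "sadness: IWD vs HC"
    u_statistic: float
    p_raw: float
    p_fdr: float
    cohen_d: float
    n_x: int
    n_y: int
    significant: bool = False


@dataclass
class DivergenceReport:
    """Grid of dual-phase test results plus descriptive group statistics."""

    phase1: pd.DataFrame
    phase2: pd.DataFrame
    descriptives: pd.DataFrame
    unit: str = "epoch"
    alpha: float = ALPHA
    d_threshold: float = D_THRESHOLD

    def significant_fraction(self) -> float:
        """Fraction of all testable grid cells flagged significant."""
        both = pd.concat([self.phase1, self.phase2], ignore_index=True)
        both = both[np.isfinite(both["p_raw"])]
        return float(both["significant"].mean()) if len(both) else 0.0

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.phase1.to_csv(out / "phase1_elicitation.csv", index=False, float_format="%.6g")
        self.phase2.to_csv(out / "phase2_group.csv", index=False, float_format="%.6g")
        self.descriptives.to_csv(out / "descriptives.csv", index=False, float_format="%.6g")

    def summary_text(self) -> str:
        """Text grid of mean+-SD per (feature, condition, group) with markers:
        underline-analogue '_' for a significant within-group change (phase 1)
        and bold-analogue '*' for a significant between-group difference
        (phase 2)."""
        p1_sig = {
            (r.feature, r.emotion, r.contrast.split(":")[0]): r.significant
            for r in self.phase1.itertuples()
        }
        p2_sig = {
            (r.feature, r.emotion): r.significant for r in self.phase2.itertuples()
        }
        lines = [f"{'feature':<10}" + "".join(
            f"{c[:4] + ' ' + g:>16}" for c in CONDITIONS for g in GROUPS
        )]
        desc = self.descriptives.set_index(["feature", "condition", "group"])
        for f in FEATURE_NAMES:
            cells = []
            for c in CONDITIONS:
                for g in GROUPS:
                    try:
                        row = desc.loc[(f, c, g)]
                        s = f"{row['mean']:.2f}±{row['sd']:.2f}"
                    except KeyError:
                        s = "--"
                    if p1_sig.get((f, c, g), False):
                        s = "_" + s + "_"
                    if p2_sig.get((f, c), False):
                        s = "*" + s + "*"
                    cells.append(f"{s:>16}")
            lines.append(f"{f:<10}" + "".join(cells))
        return "\n".join(lines)


def _cell_values(
    table: pd.DataFrame, group: str | None, condition: str, feature: str, unit: str
) -> np.ndarray:
    sub = table[table["condition"] == condition]
    if group is not None:
        sub = sub[sub["group"] == group]
    col = f"{feature}_std" if f"{feature}_std" in sub.columns else feature
    if unit == "participant":
        vals = sub.groupby("participant_id")[col].mean().to_numpy()
    else:
        vals = sub[col].to_numpy(dtype=float)
    return vals[np.isfinite(vals)]


def dual_phase_screen(
    std_table: pd.DataFrame,
    groups: pd.DataFrame | dict[str, str],
    alpha: float = ALPHA,
    d_threshold: float = D_THRESHOLD,
    unit: str = "epoch",
) -> DivergenceReport:
    """Run both screening phases on a standardized feature table.

    ``std_table`` follows the standardize_table schema; ``groups`` maps
    participant_id -> group label (dict or two-column DataFrame).  ``unit``
    chooses the test observation: 'epoch' (default; every epoch is one
    observation) or 'participant' (epoch values averaged per participant
    first).

    FDR families are the nine features of each (phase, emotion, contrast)
    cell-set.  Significance requires p_raw < alpha, p_fdr < alpha and
    |d| > d_threshold simultaneously.
    """
    if unit not in ("epoch", "participant"):
        raise ValidationError(f"unit must be 'epoch' or 'participant', got {unit!r}")
    if isinstance(groups, pd.DataFrame):
        gmap = dict(zip(groups["participant_id"], groups["group"]))
    else:
        gmap = dict(groups)
    table = std_table.copy()
    table["group"] = table["participant_id"].map(gmap)
    if table["group"].isna().any():
        missing = sorted(table.loc[table["group"].isna(), "participant_id"].unique())
        raise IncompleteDesignError(f"participants without group label: {missing}")

    # design completeness: >= 2 participants per group, every condition present
    gaps = []
    for g in GROUPS:
        gtab = table[table["group"] == g]
        if gtab["participant_id"].nunique() < 2:
            gaps.append(f"group {g} has {gtab['participant_id'].nunique()} participant(s)")
        for c in CONDITIONS:
            if (gtab["condition"] == c).sum() == 0:
                gaps.append(f"group {g} missing condition {c!r}")
    if gaps:
        raise IncompleteDesignError("incomplete design: " + "; ".join(gaps))

    def run_family(pairs: list[tuple[str, np.ndarray, np.ndarray]], phase: int,
                   emotion: str, contrast: str) -> list[StatTestResult]:
        results = []
        for feature, x, y in pairs:
            if len(x) < 2 or len(y) < 2:
                results.append(StatTestResult(
                    feature, phase, emotion, contrast, np.nan, np.nan, np.nan,
                    np.nan, len(x), len(y)))
                continue
            u, p = mann_whitney_u(x, y)
            try:
                d = cohens_d(x, y)
            except UndefinedFeatureError:
                d = 0.0 if np.array_equal(x, y) else np.nan
            results.append(StatTestResult(
                feature, phase, emotion, contrast, u, p, np.nan, d, len(x), len(y)))
        testable = [r for r in results if np.isfinite(r.p_raw)]
        if testable:
            adj = bh_fdr([r.p_raw for r in testable])
            for r, pf in zip(testable, adj):
                r.p_fdr = float(pf)
                r.significant = bool(
                    r.p_raw < alpha and r.p_fdr < alpha
                    and np.isfinite(r.cohen_d) and abs(r.cohen_d) > d_threshold
                )
        return results

    phase1: list[StatTestResult] = []
    for g in GROUPS:
        calm_vals = {f: _cell_values(table, g, "calm", f, unit) for f in FEATURE_NAMES}
        for e in EMOTIONS:
            pairs = [
                (f, _cell_values(table, g, e, f, unit), calm_vals[f])
                for f in FEATURE_NAMES
            ]
            phase1.extend(run_family(pairs, 1, e, f"{g}: {e} vs calm"))

    phase2: list[StatTestResult] = []
    for c in CONDITIONS:  # calm included as a built-in sanity contrast
        pairs = [
            (f,
             _cell_values(table, "IWD", c, f, unit),
             _cell_values(table, "HC", c, f, unit))
            for f in FEATURE_NAMES
        ]
        phase2.extend(run_family(pairs, 2, c, f"{c}: IWD vs HC"))

    desc_rows = []
    for f in FEATURE_NAMES:
        for c in CONDITIONS:
            for g in GROUPS:
                vals = _cell_values(table, g, c, f, unit)
                desc_rows.append({
                    "feature": f, "condition": c, "group": g,
                    "mean": float(np.mean(vals)) if len(vals) else np.nan,
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                    "n": len(vals),
                })

    def frame(results: list[StatTestResult]) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "feature": r.feature, "phase": r.phase, "emotion": r.emotion,
                "contrast": r.contrast, "U": r.u_statistic, "p_raw": r.p_raw,
                "p_fdr": r.p_fdr, "cohen_d": r.cohen_d, "n_x": r.n_x,
                "n_y": r.n_y, "significant": r.significant,
            }
            for r in results
        ])

    return DivergenceReport(
        phase1=frame(phase1), phase2=frame(phase2),
        descriptives=pd.DataFrame(desc_rows), unit=unit,
        alpha=alpha, d_threshold=d_threshold,
    )
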