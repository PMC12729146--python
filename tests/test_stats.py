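"""Dual-phase screening statistics: Mann-Whitney U against brute-force
enumeration, BH step-up against the hand definition, Cohen's d, and the
screen's design contracts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvscreen.errors import (
    IncompleteDesignError,
    UndefinedFeatureError,
    ValidationError,
)
from hrvscreen.features import FEATURE_NAMES
from hrvscreen.stats import bh_fdr, cohens_d, dual_phase_screen, mann_whitney_u


def brute_force_mwu_p(x, y):
    """Exact two-sided p by enumerating every relabelling of the pooled
    sample (oracle for small tie-free inputs)."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}

    def u_of(idx):
        rank_sum = sum(ranks[pooled[i]] for i in idx)
        return rank_sum - nx * (nx + 1) / 2

    u_obs = u_of(range(nx))
    mean_u = nx * (len(pooled) - nx) / 2
    dev_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        total += 1
        if abs(u_of(idx) - mean_u) >= dev_obs - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_samples_exact_enumeration(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 labelings as extreme

    @pytest.mark.parametrize("nx,ny", [(2, 3), (3, 3), (4, 4), (5, 5), (4, 6)])
    def test_matches_brute_force_enumeration_small_n(self, nx, ny):
        rng = np.random.default_rng(nx * 100 + ny)
        for _ in range(5):
            x = rng.normal(size=nx)
            y = rng.normal(loc=rng.uniform(-1, 1), size=ny)
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(brute_force_mwu_p(x, y), abs=1e-12)

    def test_identical_multisets_via_tie_path(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0] * 2
        _, p = mann_whitney_u(x, list(x))
        assert p >= 0.99

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        y = rng.normal(0.8, size=15)
        u0, p0 = mann_whitney_u(x, y)
        u1, p1 = mann_whitney_u(np.exp(x), np.exp(y))
        assert u0 == u1
        assert p0 == pytest.approx(p1)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([1.0], [2.0, 3.0])


class TestCohensD:
    def test_unit_separation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1, 1, size=20000)
        y = rng.normal(0, 1, size=20000)
        assert cohens_d(x, y) == pytest.approx(1.0, abs=0.05)

    def test_identical_samples_give_zero(self):
        x = [1.0, 2.0, 3.5, 4.0]
        assert cohens_d(x, x) == 0.0

    def test_hand_computation_with_pooled_sd_one(self):
        assert cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.0)

    def test_zero_pooled_sd_undefined(self):
        with pytest.raises(UndefinedFeatureError):
            cohens_d([2.0, 2.0], [2.0, 2.0])


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_arithmetic_by_hand(self):
        out = bh_fdr([0.005, 0.01, 0.03, 0.04])
        assert out == pytest.approx([0.02, 0.02, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.2, 1.2])

    @settings(derandomize=True, max_examples=200)
    @given(
        p=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=30)
    )
    def test_matches_step_up_definition_and_dominates_input(self, p):
        out = bh_fdr(p)
        # independent step-up oracle
        p_arr = np.asarray(p, dtype=float)
        m = len(p_arr)
        order = np.argsort(p_arr, kind="mergesort")
        adj = p_arr[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        assert np.allclose(out, expected, atol=1e-12)
        assert np.all(out >= p_arr - 1e-15)


def _toy_std_table(rng, n_per_group=4, epochs=2, shift=0.0):
    rows = []
    for g, n in (("HC", n_per_group), ("IWD", n_per_group)):
        for i in range(n):
            pid = f"{g}{i}"
            for cond in ("calm", "happiness", "sadness", "fear", "anger"):
                for e in range(epochs + (1 if cond == "calm" else 0)):
                    row = {"participant_id": pid, "condition": cond, "epoch_index": e}
                    for name in FEATURE_NAMES:
                        v = rng.normal()
                        if g == "IWD" and cond == "sadness" and name == "RMSSD":
                            v += shift
                        row[f"{name}_std"] = v
                    rows.append(row)
    groups = pd.DataFrame(
        {
            "participant_id": [f"{g}{i}" for g in ("HC", "IWD") for i in range(n_per_group)],
            "group": ["HC"] * n_per_group + ["IWD"] * n_per_group,
        }
    )
    return pd.DataFrame(rows), groups


class TestDualPhaseScreen:
    def test_grid_shape_covers_all_cells(self):
        std, groups = _toy_std_table(np.random.default_rng(0))
        rep = dual_phase_screen(std, groups)
        assert len(rep.phase1) == 2 * 4 * 9  # group x emotion x feature
        assert len(rep.phase2) == 5 * 9  # condition (incl calm sanity) x feature
        assert len(rep.descriptives) == 9 * 5 * 2

    def test_significance_rule_requires_all_three_criteria(self):
        std, groups = _toy_std_table(np.random.default_rng(1), shift=3.0)
        rep = dual_phase_screen(std, groups)
        for r in pd.concat([rep.phase1, rep.phase2]).itertuples():
            if r.significant:
                assert r.p_raw < 0.05 and r.p_fdr < 0.05 and abs(r.cohen_d) > 0.2
        sad_rmssd = rep.phase2[
            (rep.phase2.emotion == "sadness") & (rep.phase2.feature == "RMSSD")
        ]
        assert sad_rmssd["significant"].item()

    def test_single_participant_group_rejected(self):
        std, groups = _toy_std_table(np.random.default_rng(2))
        solo = std[std["participant_id"] != "IWD1"]
        solo = solo[~solo["participant_id"].str.startswith("IWD")
                    | (solo["participant_id"] == "IWD0")]
        with pytest.raises(IncompleteDesignError):
            dual_phase_screen(solo, groups[groups.participant_id.isin(solo.participant_id)])

    def test_missing_condition_rejected_with_named_gap(self):
        std, groups = _toy_std_table(np.random.default_rng(3))
        gapped = std[
            ~((std["condition"] == "fear") & std["participant_id"].str.startswith("IWD"))
        ]
        with pytest.raises(IncompleteDesignError, match="fear"):
            dual_phase_screen(gapped, groups)

    def test_permutation_equivariance_over_participant_order(self):
        std, groups = _toy_std_table(np.random.default_rng(4))
        rep_a = dual_phase_screen(std, groups)
        shuffled = std.sample(frac=1.0, random_state=9).reset_index(drop=True)
        rep_b = dual_phase_screen(shuffled, groups)
        pd.testing.assert_frame_equal(rep_a.phase1, rep_b.phase1)
        pd.testing.assert_frame_equal(rep_a.phase2, rep_b.phase2)

    def test_participant_aggregation_mode(self):
        std, groups = _toy_std_table(np.random.default_rng(5))
        rep = dual_phase_screen(std, groups, unit="participant")
        # 4 participants per group -> phase-2 sample sizes are participants
        assert (rep.phase2["n_x"] == 4).all()

    def test_calm_sanity_cell_never_significant(self):
        # phase-1 contrasts of calm against itself cannot exist; the built-in
        # sanity cell is the phase-2 calm contrast on self-standardized values
        for seed in range(5):
            std, groups = _toy_std_table(np.random.default_rng(seed))
            rep = dual_phase_screen(std, groups)
            calm = rep.phase2[rep.phase2.emotion == "calm"]
            assert not calm["significant"].any()
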