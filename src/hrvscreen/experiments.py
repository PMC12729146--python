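"""Replicated validation experiments on synthetic cohorts.

These are the package's headline computations: parameter-recovery checks for
the generator/feature chain, detector fidelity benchmarks, null calibration
of the dual-phase screen, and recovery of the planted sadness divergence by
both the screen and the classifier battery.  Each function is fully seeded
and returns plain dictionaries of numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (
    AutonomicParams,
    CohortSpec,
    NoiseConfig,
    default_effect_profiles,
    generate_cohort,
    generate_rr_series,
    null_effect_profiles,
    render_ecg,
)
from .features import compute_features, feature_table
from .models import ModelConfig, run_emotion_battery
from .preprocess import detect_r_peaks, filter_ecg, segment_and_epoch
from .standardize import standardize_table
from .stats import dual_phase_screen


def _child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible sub-seeds below 2**31 derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def _cohort_tables(seed: int, n_hc: int, n_iwd: int, profiles):
    records = generate_cohort(CohortSpec(n_hc=n_hc, n_iwd=n_iwd, seed=seed), profiles)
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
    groups = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "group": [r.group for r in records],
        }
    )
    return feats, std, groups


def respiratory_recovery(
    seed: int = 0,
    n_epochs: int = 100,
    f_resps: tuple[float, ...] = (0.20, 0.25, 0.30),
    tolerance_bpm: float = 1.0,
) -> dict:
    """Fraction of 1-min epochs whose HF-peak respiratory rate lands within
    ``tolerance_bpm`` of the generator's 60 * f_resp ground truth."""
    seeds = _child_seeds(seed, n_epochs)
    hits = 0
    n = 0
    for i, s in enumerate(seeds):
        f = f_resps[i % len(f_resps)]
        params = AutonomicParams(
            hr_mean=70.0, a_lf=0.02, a_hf=0.05, f_resp=f, jitter_sd=8.0
        )
        rr = generate_rr_series(params, 61.0, seed=s)
        for ep in segment_and_epoch(rr, [("calm", 0.0, 61.0)]):
            rate = compute_features(ep).Resp_rate
            n += 1
            if np.isfinite(rate) and abs(rate - 60.0 * f) <= tolerance_bpm:
                hits += 1
    return {"within_tolerance_fraction": hits / n, "n": n}


def _match_stats(detected: np.ndarray, truth: np.ndarray, tol_s: float):
    d = np.abs(detected[:, None] - truth[None, :])
    sens = float((d.min(axis=0) <= tol_s).mean())  # truth matched
    prec = float((d.min(axis=1) <= tol_s).mean())  # detections matched
    return sens, prec


def detector_benchmark(
    seed: int = 0, n_records: int = 5, duration: float = 120.0
) -> dict:
    """R-peak recovery against generator annotations: noise-free at 10 ms
    tolerance, and at 10 dB SNR white noise at 50 ms tolerance."""
    seeds = _child_seeds(seed, n_records)
    clean_rates = []
    noisy_sens, noisy_prec = [], []
    for s in seeds:
        rng = np.random.default_rng(s)
        params = AutonomicParams(
            hr_mean=float(rng.uniform(58, 85)),
            a_lf=0.03,
            a_hf=0.05,
            jitter_sd=float(rng.uniform(8, 25)),
        )
        rr = generate_rr_series(params, duration, seed=rng)
        clean = render_ecg(rr, 500.0)
        det = detect_r_peaks(filter_ecg(clean))
        sens, _ = _match_stats(det.beat_times, clean.r_annotations, 0.010)
        clean_rates.append(sens)

        noise_sd = float(np.sqrt(np.mean(clean.samples**2) / 10.0))  # 10 dB SNR
        noisy = render_ecg(rr, 500.0, NoiseConfig(white_sd=noise_sd), seed=rng)
        det_n = detect_r_peaks(filter_ecg(noisy))
        sens, prec = _match_stats(det_n.beat_times, noisy.r_annotations, 0.050)
        noisy_sens.append(sens)
        noisy_prec.append(prec)
    return {
        "noise_free_match_fraction": float(np.mean(clean_rates)),
        "snr10_sensitivity": float(np.mean(noisy_sens)),
        "snr10_precision": float(np.mean(noisy_prec)),
        "n_records": n_records,
    }


def null_calibration(
    seed: int = 0,
    n_replicates: int = 100,
    n_hc: int = 66,
    n_iwd: int = 30,
    with_models: bool = True,
) -> dict:
    """All-identity effect profiles: the dual-phase screen's significant-cell
    rate should stay near (below) the nominal level, and every emotion
    model's held-out AUC should average near 1/2."""
    seeds = _child_seeds(seed, n_replicates)
    profiles = null_effect_profiles()
    fracs = []
    aucs: list[dict] = []
    for s in seeds:
        feats, std, groups = _cohort_tables(s, n_hc, n_iwd, profiles)
        report = dual_phase_screen(std, groups)
        fracs.append(report.significant_fraction())
        if with_models:
            reports = run_emotion_battery(
                std, feats, groups,
                base_config=ModelConfig(search_budget=1, n_bootstrap=0, seed=s),
                algorithms=("ertc",),
            )
            aucs.append({c: r.auc for (c, _), r in reports.items()})
    out = {
        "significant_cell_rate": float(np.mean(fracs)),
        "n_replicates": n_replicates,
    }
    if with_models:
        auc_df = pd.DataFrame(aucs)
        out["mean_auc_by_condition"] = {
            c: float(auc_df[c].mean()) for c in auc_df.columns
        }
        out["auc_grand_mean"] = float(auc_df.values.mean())
    return out


def planted_recovery(
    seed: int = 0,
    n_replicates: int = 25,
    n_hc: int = 66,
    n_iwd: int = 30,
) -> dict:
    """Default sadness-dominant profiles: rate at which the phase-2 sadness
    RMSSD and CVSD cells are flagged, per-condition ERTC AUC medians, and the
    rate at which the sadness model ranks first."""
    seeds = _child_seeds(seed, n_replicates)
    profiles = default_effect_profiles()
    flags_rmssd, flags_cvsd, flags_joint = [], [], []
    aucs: list[dict] = []
    for s in seeds:
        feats, std, groups = _cohort_tables(s, n_hc, n_iwd, profiles)
        report = dual_phase_screen(std, groups)
        sad = report.phase2[report.phase2.emotion == "sadness"].set_index("feature")
        flags_rmssd.append(bool(sad.loc["RMSSD", "significant"]))
        flags_cvsd.append(bool(sad.loc["CVSD", "significant"]))
        flags_joint.append(flags_rmssd[-1] and flags_cvsd[-1])
        reports = run_emotion_battery(
            std, feats, groups,
            base_config=ModelConfig(search_budget=1, n_bootstrap=0, seed=s),
            algorithms=("ertc",),
        )
        aucs.append({c: r.auc for (c, _), r in reports.items()})
    auc_df = pd.DataFrame(aucs)
    return {
        "sadness_rmssd_flag_rate": float(np.mean(flags_rmssd)),
        "sadness_cvsd_flag_rate": float(np.mean(flags_cvsd)),
        "sadness_joint_flag_rate": float(np.mean(flags_joint)),
        "median_auc_by_condition": {
            c: float(auc_df[c].median()) for c in auc_df.columns
        },
        "sadness_first_rate": float((auc_df.idxmax(axis=1) == "sadness").mean()),
        "n_replicates": n_replicates,
    }
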