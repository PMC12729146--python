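"""The nine per-epoch HRV features.

Time domain: MeanNN, SDNN (sample SD, n-1), RMSSD, and the coefficient-of-
variation forms CVNN = SDNN/MeanNN and CVSD = RMSSD/MeanNN.

Frequency domain: the NN tachogram is resampled to a uniform 4 Hz grid by
cubic interpolation, the power spectral density estimated by Welch
(32-s Hann windows, 50% overlap), and band powers integrated over
LF = 0.04-0.15 Hz and HF = 0.15-0.40 Hz.  Normalized powers use
total = LF + HF (VLF is unresolvable in 1-min epochs), so LFn + HFn = 1 by
construction and LF/HF is their ratio.

The respiratory rate is obtained indirectly from the HF component of HRV:
60 x the HF-band spectral peak frequency (respiratory sinus arrhythmia),
with parabolic refinement of the peak bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .errors import InsufficientDataError, OutOfBandError, UndefinedFeatureError
from .preprocess import Epoch

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
RESAMPLE_HZ = 4.0
WELCH_WINDOW_S = 32.0

FEATURE_NAMES = (
    "MeanNN", "SDNN", "RMSSD", "CVNN", "CVSD", "LFn", "HFn", "LFHF", "Resp_rate",
)


@dataclass
class HRVFeatureVector:
    """The nine features for one epoch (NaN where undefined/flagged)."""

    MeanNN: float
    SDNN: float
    RMSSD: float
    CVNN: float
    CVSD: float
    LFn: float
    HFn: float
    LFHF: float
    Resp_rate: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def time_domain(
    nn_ms: np.ndarray, adjacent: np.ndarray | None = None
) -> tuple[float, float, float, float, float]:
    """(MeanNN, SDNN, RMSSD, CVNN, CVSD) from NN intervals in ms.

    SDNN uses the n-1 denominator.  Successive differences are taken only
    between adjacent interval pairs (``adjacent[i]`` true when interval i-1
    is interval i's true predecessor), so cleaning gaps never fabricates
    differences.
    """
    nn = np.asarray(nn_ms, dtype=float)
    if len(nn) < 2:
        raise InsufficientDataError("SDNN", f"needs >= 2 NN intervals, got {len(nn)}")
    if len(nn) < 3:
        raise InsufficientDataError("RMSSD", f"needs >= 3 NN intervals, got {len(nn)}")
    mean_nn = float(np.mean(nn))
    sdnn = float(np.std(nn, ddof=1))
    if adjacent is None:
        diffs = np.diff(nn)
    else:
        adjacent = np.asarray(adjacent, dtype=bool)
        diffs = (nn - np.roll(nn, 1))[adjacent]
    if len(diffs) < 2:
        raise InsufficientDataError("RMSSD", "fewer than 2 successive differences")
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    return mean_nn, sdnn, rmssd, sdnn / mean_nn, rmssd / mean_nn


def frequency_domain(
    nn_ms: np.ndarray,
    nn_end_times: np.ndarray,
    resample_hz: float = RESAMPLE_HZ,
    welch_window_s: float = WELCH_WINDOW_S,
    min_nn: int = 20,
) -> tuple[float, float, float, float, float, float]:
    """(LFn, HFn, LFHF, lf_power, hf_power, hf_peak_freq).

    Powers are in ms^2 (integrated Welch PSD of the cubic-resampled
    tachogram).  On an all-equal tachogram total power is zero: a warning is
    issued and LFn/HFn are returned as NaN.  HF power exactly zero with LF
    power positive raises UndefinedFeatureError for LF/HF.
    """
    nn = np.asarray(nn_ms, dtype=float)
    t = np.asarray(nn_end_times, dtype=float)
    if len(nn) < min_nn:
        raise InsufficientDataError(
            "frequency_domain", f"needs >= {min_nn} NN intervals, got {len(nn)}"
        )
    if np.ptp(nn) == 0:
        warnings.warn("all-equal tachogram: zero spectral power", stacklevel=2)
        return np.nan, np.nan, np.nan, 0.0, 0.0, np.nan

    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    x = CubicSpline(t, nn)(grid)
    x = x - np.mean(x)
    nperseg = min(int(welch_window_s * resample_hz), len(x))
    freqs, psd = sps.welch(
        x, fs=resample_hz, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant",
    )
    lf_mask = (freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])
    hf_mask = (freqs >= HF_BAND[0]) & (freqs <= HF_BAND[1])
    lf_power = float(np.trapezoid(psd[lf_mask], freqs[lf_mask]))
    hf_power = float(np.trapezoid(psd[hf_mask], freqs[hf_mask]))
    total = lf_power + hf_power
    if total == 0:
        warnings.warn("zero LF+HF power", stacklevel=2)
        return np.nan, np.nan, np.nan, lf_power, hf_power, np.nan
    if hf_power == 0:
        raise UndefinedFeatureError("LF/HF undefined: HF power is zero")

    hf_idx = np.flatnonzero(hf_mask)
    k = hf_idx[int(np.argmax(psd[hf_idx]))]
    hf_peak = _parabolic_peak(freqs, psd, k)
    hf_peak = float(np.clip(hf_peak, HF_BAND[0], HF_BAND[1]))
    return (
        lf_power / total, hf_power / total, lf_power / hf_power,
        lf_power, hf_power, hf_peak,
    )


def _parabolic_peak(freqs: np.ndarray, psd: np.ndarray, k: int) -> float:
    """Quadratic interpolation of a PSD peak over its two neighbours."""
    if k <= 0 or k >= len(psd) - 1:
        return float(freqs[k])
    y0, y1, y2 = psd[k - 1], psd[k], psd[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(freqs[k])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(freqs[k] + delta * (freqs[1] - freqs[0]))


def respiratory_rate(hf_peak_freq: float) -> float:
    """Respiratory rate (breaths/min) from the HF spectral peak: 60 x f."""
    if not np.isfinite(hf_peak_freq) or not HF_BAND[0] <= hf_peak_freq <= HF_BAND[1]:
        raise OutOfBandError(
            f"HF peak {hf_peak_freq} Hz outside the {HF_BAND[0]}-{HF_BAND[1]} Hz band"
        )
    return 60.0 * hf_peak_freq


def compute_features(epoch: Epoch) -> HRVFeatureVector:
    """All nine features for one epoch; frequency features become NaN when
    flagged (zero power), never silently wrong."""
    mean_nn, sdnn, rmssd, cvnn, cvsd = time_domain(epoch.nn_ms, epoch.adjacent)
    lfn, hfn, lfhf, _, _, hf_peak = frequency_domain(epoch.nn_ms, epoch.nn_end_times)
    resp = respiratory_rate(hf_peak) if np.isfinite(hf_peak) else np.nan
    return HRVFeatureVector(
        MeanNN=mean_nn, SDNN=sdnn, RMSSD=rmssd, CVNN=cvnn, CVSD=cvsd,
        LFn=lfn, HFn=hfn, LFHF=lfhf, Resp_rate=resp,
    )


def feature_table(epochs: list[Epoch]) -> pd.DataFrame:
    """One row per epoch: participant_id, condition, epoch_index, the nine
    Table-style feature columns, and an n_nn quality column."""
    rows = []
    for ep in epochs:
        fv = compute_features(ep)
        row = {
            "participant_id": ep.participant_id,
            "condition": ep.condition,
            "epoch_index": ep.epoch_index,
            **fv.as_dict(),
            "n_nn": ep.n_nn,
        }
        rows.append(row)
    return pd.DataFrame(rows)
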