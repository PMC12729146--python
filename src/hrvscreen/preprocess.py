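"""ECG preprocessing: filtering, R-peak detection, segmentation and epoching.

Mirrors a standard single-lead acquisition chain: a 0.5-100 Hz band-pass plus
a 50 Hz notch (both applied zero-phase so R-peak latencies are preserved), a
derivative/square/moving-window-integrate detector with adaptive thresholding
and a 200 ms refractory period, then segmentation by stimulus timestamps and
extraction of non-overlapping 1-min epochs tiled backward from each segment's
end.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .cohort import ECGSignal, RRSeries
from .errors import DetectionError, ParameterError, SegmentError

logger = logging.getLogger(__name__)

#: physiological NN bounds (ms); intervals outside are removed, not interpolated
NN_BOUNDS_MS = (200.0, 3000.0)
#: minimum NN intervals for an epoch to be analyzable
MIN_NN_PER_EPOCH = 20
EPOCH_LEN_S = 60.0


def _raised_cosine_gain(
    freqs: np.ndarray,
    band: tuple[float, float],
    notch_freq: float,
    notch_bandwidth: float,
    low_transition: float,
    high_transition: float,
) -> np.ndarray:
    """Spectral gain: smooth (raised-cosine) band-pass edges at ``band`` plus
    a raised-cosine notch dip centred on ``notch_freq``."""
    gain = np.ones_like(freqs)
    lo, hi = band
    # high-pass edge: 0 below lo - w/2, 1 above lo + w/2
    w = low_transition
    ramp = np.clip((freqs - (lo - w / 2)) / w, 0.0, 1.0)
    gain *= 0.5 - 0.5 * np.cos(np.pi * ramp)
    # low-pass edge
    w = high_transition
    ramp = np.clip(((hi + w / 2) - freqs) / w, 0.0, 1.0)
    gain *= 0.5 - 0.5 * np.cos(np.pi * ramp)
    # notch dip
    delta = np.abs(freqs - notch_freq)
    inside = delta < notch_bandwidth
    gain[inside] *= 0.5 - 0.5 * np.cos(np.pi * delta[inside] / notch_bandwidth)
    return gain


def filter_ecg(
    ecg: ECGSignal,
    band: tuple[float, float] = (0.5, 100.0),
    notch_freq: float = 50.0,
    notch_bandwidth: float = 2.0,
) -> ECGSignal:
    """Band-pass (0.5-100 Hz) with a 50 Hz notch, applied in the frequency
    domain (exactly zero phase, so R-peak latencies are untouched).

    The spectral gain uses raised-cosine transitions (~0.5 Hz wide at the
    high-pass edge, ~10 Hz at the low-pass edge, 2 Hz half-width for the
    notch).  A frequency-domain application is chosen over filtfilt'd IIR
    sections because a truncated mains or drift cycle sits exactly at the
    record boundary, where a recursive filter's edge transient cannot be
    absorbed by reflection padding.

    Raises ParameterError when the sampling rate cannot represent the 100 Hz
    band edge (fs <= 200 Hz).
    """
    fs = ecg.sampling_rate
    if fs <= 2 * band[1]:
        raise ParameterError(
            f"sampling rate {fs} Hz cannot represent the {band[1]} Hz band edge"
        )
    x = ecg.samples - np.mean(ecg.samples)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    gain = _raised_cosine_gain(freqs, band, notch_freq, notch_bandwidth, 0.5, 10.0)
    out = np.fft.irfft(spec * gain, n=len(x))
    return ECGSignal(samples=out, sampling_rate=fs, r_annotations=ecg.r_annotations)


def detect_r_peaks(ecg: ECGSignal, refractory_s: float = 0.2) -> RRSeries:
    """Derivative-square-integrate R detector with adaptive thresholding.

    Pipeline: 5-15 Hz band-pass -> derivative -> squaring -> 150 ms
    moving-window integration -> candidate peaks at >= 200 ms spacing ->
    running signal/noise peak levels with threshold
    npk + 0.25 (spk - npk) -> beat time refined to the local maximum of the
    input (filtered) signal near each accepted candidate.

    Raises DetectionError on flat input or when fewer than two beats emerge.
    """
    fs = ecg.sampling_rate
    x = ecg.samples
    if len(x) < fs:  # under a second of data
        raise DetectionError("signal too short for R detection")
    if np.ptp(x) == 0:
        raise DetectionError("flat signal: no QRS activity detectable")

    sos = sps.butter(2, (5.0, 15.0), btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    sq = deriv**2
    win = max(1, int(round(0.15 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    min_dist = max(1, int(round(refractory_s * fs)))
    cand, _ = sps.find_peaks(mwi, distance=min_dist)
    if len(cand) < 2:
        raise DetectionError(f"only {len(cand)} candidate peaks found")

    # adaptive threshold (running signal / noise peak estimates)
    init = mwi[: int(2 * fs)]
    spk = float(np.max(init))
    npk = float(np.mean(init)) * 0.5
    accepted = []
    for idx in cand:
        h = mwi[idx]
        thr = npk + 0.25 * (spk - npk)
        if h >= thr:
            accepted.append(idx)
            spk = 0.125 * h + 0.875 * spk
        else:
            npk = 0.125 * h + 0.875 * npk
    if len(accepted) < 2:
        raise DetectionError(f"only {len(accepted)} beats passed the adaptive threshold")

    # refine: local max of the filtered ECG around each integrated-energy peak
    half = int(round(0.10 * fs))
    peaks = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(len(x), idx + half + 1)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(peaks)
    # enforce refractory after refinement, keeping the taller peak
    keep: list[int] = []
    for p in peaks:
        if keep and p - keep[-1] < min_dist:
            if x[p] > x[keep[-1]]:
                keep[-1] = int(p)
        else:
            keep.append(int(p))
    if len(keep) < 2:
        raise DetectionError("fewer than two beats after refractory merge")
    return RRSeries(beat_times=np.asarray(keep, dtype=float) / fs)


@dataclass
class Epoch:
    """A 60-s analysis window of NN intervals inside one stimulus segment.

    ``epoch_index`` counts backward from the segment end: index 0 is the final
    window, so the last beat of a segment always lands in epoch 0.  ``adjacent``
    marks NN intervals whose predecessor interval is also present (successive
    differences are only taken across adjacent pairs after cleaning).
    """

    participant_id: str
    condition: str
    epoch_index: int
    nn_ms: np.ndarray
    nn_end_times: np.ndarray
    window: tuple[float, float]
    adjacent: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nn_ms = np.asarray(self.nn_ms, dtype=float)
        self.nn_end_times = np.asarray(self.nn_end_times, dtype=float)
        if self.adjacent is None:
            self.adjacent = np.ones(len(self.nn_ms), dtype=bool)
            if len(self.adjacent):
                self.adjacent[0] = False  # first interval has no predecessor here

    @property
    def n_nn(self) -> int:
        return len(self.nn_ms)


def clean_nn(
    nn_ms: np.ndarray,
    nn_end_times: np.ndarray,
    bounds: tuple[float, float] = NN_BOUNDS_MS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Drop NN intervals outside physiological bounds.

    Returns (nn, end_times, adjacency-of-consecutive-survivors, n_removed).
    Removed intervals break adjacency for successive-difference statistics.
    """
    nn_ms = np.asarray(nn_ms, dtype=float)
    nn_end_times = np.asarray(nn_end_times, dtype=float)
    ok = (nn_ms > bounds[0]) & (nn_ms < bounds[1])
    idx = np.flatnonzero(ok)
    adjacent = np.zeros(len(idx), dtype=bool)
    if len(idx) > 1:
        adjacent[1:] = np.diff(idx) == 1
    return nn_ms[idx], nn_end_times[idx], adjacent, int((~ok).sum())


def segment_and_epoch(
    rr: RRSeries,
    segments: list[tuple[str, float, float]],
    participant_id: str = "",
    epoch_len_s: float = EPOCH_LEN_S,
    min_nn: int = MIN_NN_PER_EPOCH,
    nn_bounds: tuple[float, float] = NN_BOUNDS_MS,
) -> list[Epoch]:
    """Cut the RR series by stimulus segments and tile 1-min epochs backward
    from each segment's end.

    A segment of length L yields floor(L/60) non-overlapping windows
    [end-60, end), [end-120, end-60), ...; an epoch keeps the NN intervals
    whose *terminating* beat lies inside its window; epochs with fewer than
    ``min_nn`` cleaned intervals are dropped with a warning.
    """
    for cond, start, end in segments:
        if start >= end:
            raise SegmentError(f"segment {cond!r}: start {start} >= end {end}")
    ordered = sorted(segments, key=lambda s: s[1])
    for (_, _, e0), (c1, s1, _) in zip(ordered, ordered[1:]):
        if s1 < e0:
            raise SegmentError(f"segments overlap near {c1!r} at t={s1}")

    nn_all = rr.nn_ms
    end_all = rr.nn_end_times
    epochs: list[Epoch] = []
    for cond, start, end in segments:
        n_windows = int(np.floor((end - start) / epoch_len_s))
        if n_windows == 0:
            warnings.warn(
                f"{participant_id or 'recording'}/{cond} segment "
                f"[{start:.0f},{end:.0f}) is shorter than one {epoch_len_s:.0f}-s "
                "epoch; dropped",
                stacklevel=2,
            )
            continue
        for j in range(n_windows - 1, -1, -1):  # chronological emission
            w_end = end - j * epoch_len_s
            w_start = w_end - epoch_len_s
            mask = (end_all >= w_start) & (end_all < w_end)
            nn, ends, adjacent, n_removed = clean_nn(
                nn_all[mask], end_all[mask], nn_bounds
            )
            if n_removed:
                logger.info(
                    "%s/%s epoch %d: removed %d out-of-bounds NN",
                    participant_id, cond, j, n_removed,
                )
            if len(nn) < min_nn:
                warnings.warn(
                    f"{participant_id or 'recording'}/{cond} window "
                    f"[{w_start:.0f},{w_end:.0f}) has {len(nn)} < {min_nn} NN "
                    "intervals; epoch dropped",
                    stacklevel=2,
                )
                continue
            epochs.append(
                Epoch(
                    participant_id=participant_id,
                    condition=cond,
                    epoch_index=j,
                    nn_ms=nn,
                    nn_end_times=ends,
                    window=(w_start, w_end),
                    adjacent=adjacent,
                )
            )
    return epochs


# ---------------------------------------------------------------------------
# readers


def read_ecg_csv(path, sampling_rate: float | None = None) -> ECGSignal:
    """Two-column ECG CSV (time_s, amplitude); the sampling rate is inferred
    from the time column unless given."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = sampling_rate if sampling_rate is not None else 1.0 / float(np.median(np.diff(t)))
    return ECGSignal(samples=df["amplitude"].to_numpy(), sampling_rate=fs)


def read_segment_table(path) -> list[tuple[str, float, float]]:
    """Segment annotation CSV with columns condition,start_s,end_s."""
    df = pd.read_csv(path)
    return [
        (str(r.condition), float(r.start_s), float(r.end_s))
        for r in df.itertuples(index=False)
    ]
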