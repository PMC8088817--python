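"""Four automated interictal HFO detectors (STE, SLL, HIL, MNI) and rate computation.

All detectors share a zero-phase band-pass front end and operate on one channel
at a time over bands f_lo-300 Hz with f_lo in {80, 150, 250}.  Detection rules:

STE  — an event is a maximal run of moving root-mean-square (RMS) values above
       mean + 5 SD of the epoch's RMS series, lasting at least the minimum
       duration, and containing more than 6 rectified-signal peaks above
       mean + 3 SD of the rectified trace.
SLL  — short line length L(t) = windowed sum of |x_i - x_{i-1}|; events are
       maximal runs of L above the 97.5th percentile of its empirical CDF.
HIL  — Hilbert analytic-signal envelope; events are maximal runs above
       mean + 5 SD of the envelope, statistics taken per analysis window.
MNI  — windowed RMS energy.  If enough baseline (oscillation-free background,
       identified by within-band spectral flatness) exists, the threshold is
       the 99.9999th percentile of the baseline energy distribution; otherwise
       each 1-minute segment uses the 95th percentile of its own energy CDF
       with iterative re-detection (detected runs are removed from the CDF
       sample and the threshold recomputed a fixed number of times).

Supra-threshold runs separated by less than ``merge_gap_ms`` are merged before
the duration/peak criteria are applied.  Times are seconds from epoch start,
half-open intervals [t_start, t_end).  Every windowed statistic is left-aligned:
the value at index i summarises samples [i, i+w), and a run [a, b) of window
indices maps to the sample span [a, b - 1 + w).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "DetectorParams",
    "HFOEvent",
    "bandpass_zero_phase",
    "detect_ste",
    "detect_sll",
    "detect_hil",
    "detect_mni",
    "detect",
    "event_rate",
    "DETECTORS",
    "BAND_FLOORS",
]

DETECTORS = ("STE", "SLL", "HIL", "MNI")
BAND_FLOORS = (80, 150, 250)
BAND_TOP = 300.0


@dataclass
class HFOEvent:
    """One detected event on one channel."""

    channel_id: str
    t_start: float
    t_end: float
    detector: str
    band_floor: int
    peak_freq: float = float("nan")
    verification_label: str = "unverified"

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")


@dataclass(frozen=True)
class DetectorParams:
    """All detector thresholds, config-exposed with the study's quoted defaults.

    Window lengths follow the original detector publications; every value can
    be overridden.
    """

    band: tuple[float, float] = (80.0, BAND_TOP)
    # STE
    rms_window_ms: float = 3.0
    rms_threshold_sd: float = 5.0
    min_peaks: int = 6
    peak_threshold_sd: float = 3.0
    min_duration_ms: float = 6.0
    # SLL
    ll_window_ms: float = 12.0
    ecdf_percentile: float = 97.5
    # HIL
    envelope_threshold_sd: float = 5.0
    analysis_window_s: float = 5.0
    # MNI
    baseline_percentile: float = 99.9999
    no_baseline_percentile: float = 95.0
    segment_s: float = 60.0
    mni_rms_window_ms: float = 10.0
    baseline_window_s: float = 0.125
    baseline_flatness: float = 0.45
    min_baseline_fraction: float = 0.05
    mni_iterations: int = 1
    # shared
    merge_gap_ms: float = 10.0
    edge_exclude_ms: float = 50.0

    def __post_init__(self) -> None:
        f_lo, f_hi = self.band
        if not (0 < f_lo < f_hi):
            raise ValueError("band must satisfy 0 < f_lo < f_hi")
        for p in (self.ecdf_percentile, self.baseline_percentile, self.no_baseline_percentile):
            if not (0 < p < 100):
                raise ValueError("percentiles must lie in (0, 100)")


def bandpass_zero_phase(
    x: np.ndarray, f_lo: float, f_hi: float, fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward filtering)."""
    nyq = fs / 2.0
    if not (0 < f_lo < f_hi):
        raise ValueError("need 0 < f_lo < f_hi")
    if f_hi >= nyq:
        # the study band top (300 Hz) sits below 500 Hz Nyquist; allow a
        # slightly lower effective edge when fs is at the 2x margin
        f_hi = 0.98 * nyq
        if f_hi <= f_lo:
            raise ValueError(f"band ({f_lo}, {f_hi}) infeasible at fs={fs}")
    sos = sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


# ---------------------------------------------------------------------------
# shared run machinery


def _window_samples(ms: float, fs: float) -> int:
    return max(1, int(round(ms * fs / 1000.0)))


def _moving_rms(x: np.ndarray, w: int) -> np.ndarray:
    win = np.lib.stride_tricks.sliding_window_view(x**2, w)
    return np.sqrt(win.mean(axis=-1))


def _line_length(x: np.ndarray, w: int) -> np.ndarray:
    """L[i] = sum of |x_j - x_{j-1}| over the w-sample window starting at i."""
    d = np.abs(np.diff(x))
    if w < 2:
        raise ValueError("line-length window must span >= 2 samples")
    win = np.lib.stride_tricks.sliding_window_view(d, w - 1)
    return win.sum(axis=-1)


def _blank_edges(mask: np.ndarray, params: "DetectorParams", fs: float) -> np.ndarray:
    """Zero the supra-threshold mask near the epoch boundaries, where the
    zero-phase filter and analytic transform are unreliable."""
    e = int(round(params.edge_exclude_ms * fs / 1000.0))
    if e > 0:
        mask = mask.copy()
        mask[:e] = False
        mask[-e:] = False
    return mask


def analytic_envelope(xf: np.ndarray, fs: float, pad_s: float = 1.0) -> np.ndarray:
    """Hilbert envelope with reflective padding (suppresses FFT wraparound)."""
    pad = min(int(round(pad_s * fs)), xf.size - 1)
    padded = np.pad(xf, pad, mode="reflect")
    env = np.abs(sps.hilbert(padded))
    return env[pad : pad + xf.size]


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [a, b) index runs of True."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(m.size)
    return list(zip(starts, ends))


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    """Merge runs separated by fewer than ``gap`` samples."""
    if not runs:
        return []
    merged = [runs[0]]
    for a, b in runs[1:]:
        pa, pb = merged[-1]
        if a - pb < gap:
            merged[-1] = (pa, b)
        else:
            merged.append((a, b))
    return merged


def _compressed_peaks(v: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a plateau of equal values counts once
    (reported at its first sample)."""
    starts = np.concatenate(([0], np.flatnonzero(np.diff(v) != 0) + 1))
    vals = v[starts]
    if vals.size < 3:
        return np.array([], dtype=int)
    mid = np.flatnonzero((vals[1:-1] > vals[:-2]) & (vals[1:-1] > vals[2:])) + 1
    return starts[mid]


def _spectral_flatness_inband(seg: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Geometric/arithmetic mean ratio of the periodogram within the passband."""
    freqs, pxx = sps.periodogram(seg, fs=fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    p = pxx[sel]
    p = p[p > 0]
    if p.size == 0:
        return 1.0
    return float(np.exp(np.mean(np.log(p))) / np.mean(p))


def _event_peak_freq(xf: np.ndarray, fs: float, a: int, b: int, band: tuple[float, float]) -> float:
    seg = xf[a:b]
    if seg.size < 8:
        return float("nan")
    freqs, pxx = sps.periodogram(seg, fs=fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        return float("nan")
    return float(freqs[sel][np.argmax(pxx[sel])])


def _events_from_runs(
    runs: list[tuple[int, int]],
    w: int,
    fs: float,
    params: DetectorParams,
    detector: str,
    channel_id: str,
    xf: np.ndarray,
) -> list[HFOEvent]:
    min_dur = _window_samples(params.min_duration_ms, fs)
    out = []
    for a, b in runs:
        s0, s1 = a, b - 1 + w
        if s1 - s0 < min_dur:
            continue
        out.append(
            HFOEvent(
                channel_id=channel_id,
                t_start=s0 / fs,
                t_end=s1 / fs,
                detector=detector,
                band_floor=int(params.band[0]),
                peak_freq=_event_peak_freq(xf, fs, s0, s1, params.band),
            )
        )
    return out


def _prep(x: np.ndarray, fs: float, params: DetectorParams | None) -> tuple[np.ndarray, DetectorParams]:
    params = params or DetectorParams()
    x = np.asarray(x, dtype=float)
    xf = bandpass_zero_phase(x, params.band[0], params.band[1], fs)
    return xf, params


# ---------------------------------------------------------------------------
# detectors


def detect_ste(
    x: np.ndarray, fs: float, params: DetectorParams | None = None, channel_id: str = "ch"
) -> list[HFOEvent]:
    """Short Time Energy detector (moving-RMS threshold + rectified-peak count)."""
    xf, params = _prep(x, fs, params)
    w = _window_samples(params.rms_window_ms, fs)
    if xf.size < w:
        raise ValueError("epoch shorter than the RMS window")
    rms = _moving_rms(xf, w)
    thr = rms.mean() + params.rms_threshold_sd * rms.std()
    supra = _blank_edges(rms > thr, params, fs)
    runs = _merge_runs(_bool_runs(supra), _window_samples(params.merge_gap_ms, fs))
    rect = np.abs(xf)
    peak_thr = rect.mean() + params.peak_threshold_sd * rect.std()
    peaks = _compressed_peaks(rect)
    peaks = peaks[rect[peaks] > peak_thr]
    events = []
    for ev in _events_from_runs(runs, w, fs, params, "STE", channel_id, xf):
        s0, s1 = int(round(ev.t_start * fs)), int(round(ev.t_end * fs))
        n_peaks = int(np.count_nonzero((peaks >= s0) & (peaks < s1)))
        if n_peaks > params.min_peaks:
            events.append(ev)
    return events


def detect_sll(
    x: np.ndarray, fs: float, params: DetectorParams | None = None, channel_id: str = "ch"
) -> list[HFOEvent]:
    """Short Line Length detector (ECDF percentile threshold)."""
    xf, params = _prep(x, fs, params)
    w = _window_samples(params.ll_window_ms, fs)
    if xf.size < w or w < 2:
        raise ValueError("epoch shorter than the line-length window")
    ll = _line_length(xf, w)
    # a (near-)constant signal has identically zero line length: no events
    if ll.max() <= 1e-9 * max(1.0, float(np.abs(x).max())):
        return []
    thr = np.percentile(ll, params.ecdf_percentile)
    supra = _blank_edges(ll > thr, params, fs)
    runs = _merge_runs(_bool_runs(supra), _window_samples(params.merge_gap_ms, fs))
    return _events_from_runs(runs, w, fs, params, "SLL", channel_id, xf)


def detect_hil(
    x: np.ndarray, fs: float, params: DetectorParams | None = None, channel_id: str = "ch"
) -> list[HFOEvent]:
    """Hilbert detector (analytic-signal envelope threshold per analysis window)."""
    xf, params = _prep(x, fs, params)
    env = analytic_envelope(xf, fs)
    n = env.size
    seg = max(1, int(round(params.analysis_window_s * fs)))
    supra = np.zeros(n, dtype=bool)
    for a in range(0, n, seg):
        e = env[a : a + seg]
        thr = e.mean() + params.envelope_threshold_sd * e.std()
        supra[a : a + seg] = e > thr
    supra = _blank_edges(supra, params, fs)
    runs = _merge_runs(_bool_runs(supra), _window_samples(params.merge_gap_ms, fs))
    return _events_from_runs(runs, 1, fs, params, "HIL", channel_id, xf)


def _mni_baseline_mask(xf: np.ndarray, fs: float, params: DetectorParams) -> np.ndarray:
    """Boolean per-sample mask of oscillation-free baseline.

    The epoch is cut into ``baseline_window_s`` windows; a window is baseline
    when its within-band spectral flatness is at least ``baseline_flatness``
    (band-limited noise is flat across the passband, a sustained oscillation
    concentrates power at one frequency).
    """
    w = int(round(params.baseline_window_s * fs))
    mask = np.zeros(xf.size, dtype=bool)
    for a in range(0, xf.size - w + 1, w):
        seg = xf[a : a + w]
        if _spectral_flatness_inband(seg, fs, params.band) >= params.baseline_flatness:
            mask[a : a + w] = True
    return mask


def detect_mni(
    x: np.ndarray, fs: float, params: DetectorParams | None = None, channel_id: str = "ch"
) -> list[HFOEvent]:
    """MNI detector (baseline-percentile or per-minute iterative CDF threshold)."""
    xf, params = _prep(x, fs, params)
    w = _window_samples(params.mni_rms_window_ms, fs)
    if xf.size < w:
        raise ValueError("epoch shorter than the energy window")
    energy = _moving_rms(xf, w)
    gap = _window_samples(params.merge_gap_ms, fs)
    base = _mni_baseline_mask(xf, fs, params)
    # energy index i summarises samples [i, i+w): it belongs to baseline when
    # the whole window does
    base_energy_idx = np.flatnonzero(
        np.lib.stride_tricks.sliding_window_view(base, w).all(axis=-1)
    )
    if base.mean() >= params.min_baseline_fraction and base_energy_idx.size > 0:
        thr = np.percentile(energy[base_energy_idx], params.baseline_percentile)
        runs = _merge_runs(_bool_runs(_blank_edges(energy > thr, params, fs)), gap)
        return _events_from_runs(runs, w, fs, params, "MNI", channel_id, xf)
    # no-baseline branch: per-segment CDF threshold with iterative re-detection
    seg_len = int(round(params.segment_s * fs))
    supra = np.zeros(energy.size, dtype=bool)
    for a in range(0, energy.size, seg_len):
        e = energy[a : a + seg_len]
        active = np.ones(e.size, dtype=bool)
        thr = np.percentile(e, params.no_baseline_percentile)
        for _ in range(params.mni_iterations):
            thr = np.percentile(e[active], params.no_baseline_percentile)
            active &= ~(e > thr)
            if active.sum() < 10:
                break
        supra[a : a + e.size] = e > thr
    runs = _merge_runs(_bool_runs(_blank_edges(supra, params, fs)), gap)
    return _events_from_runs(runs, w, fs, params, "MNI", channel_id, xf)


_DISPATCH = {"STE": detect_ste, "SLL": detect_sll, "HIL": detect_hil, "MNI": detect_mni}


def detect(
    x: np.ndarray,
    fs: float,
    detector: str,
    params: DetectorParams | None = None,
    channel_id: str = "ch",
) -> list[HFOEvent]:
    """Run one named detector ('STE' | 'SLL' | 'HIL' | 'MNI') on one channel."""
    det = detector.upper()
    if det not in _DISPATCH:
        raise ValueError(f"unknown detector {detector!r}")
    return _DISPATCH[det](x, fs, params, channel_id=channel_id)


def event_rate(
    events: list[HFOEvent], epoch_duration_s: float, band_floor: int | None = None
) -> float:
    """Event count scaled to a 5-minute (300 s) denominator."""
    if epoch_duration_s <= 0:
        raise ValueError("epoch_duration_s must be positive")
    n = sum(
        1 for e in events if band_floor is None or e.band_floor == band_floor
    )
    return n * 300.0 / epoch_duration_s


def events_to_frame(events: list[HFOEvent], patient: str = "") -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "patient": patient,
                "channel": e.channel_id,
                "detector": e.detector,
                "band_floor_hz": e.band_floor,
                "t_start_s": e.t_start,
                "t_end_s": e.t_end,
                "peak_freq_hz": e.peak_freq,
                "label": e.verification_label,
            }
            for e in events
        ],
        columns=[
            "patient",
            "channel",
            "detector",
            "band_floor_hz",
            "t_start_s",
            "t_end_s",
            "peak_freq_hz",
            "label",
        ],
    )
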