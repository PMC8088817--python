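"""Independent brute-force oracles for the detector rules.

Each function re-implements a detection rule literally — explicit loops over
samples and windows, no vectorized shortcuts — so the fast implementations in
:mod:`ibp.detectors` can be checked event-for-event on short fixtures.  The
shared signal transforms (zero-phase band-pass, analytic signal) are reused:
the property under test is the detection logic, not the filter.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from ibp.detectors import DetectorParams, analytic_envelope, bandpass_zero_phase


def _win(ms: float, fs: float) -> int:
    return max(1, int(round(ms * fs / 1000.0)))


def _runs_loop(mask) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def _blank_edges_list(mask, params, fs):
    e = int(round(params.edge_exclude_ms * fs / 1000.0))
    out = list(mask)
    for i in range(len(out)):
        if i < e or i >= len(out) - e:
            out[i] = False
    return out


def _merge_loop(runs, gap):
    merged = []
    for a, b in runs:
        if merged and a - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


def _spans(runs, w, fs, min_dur):
    spans = []
    for a, b in runs:
        s0, s1 = a, b - 1 + w
        if s1 - s0 >= min_dur:
            spans.append((s0 / fs, s1 / fs))
    return spans


def _peaks_loop(v: np.ndarray) -> list[int]:
    """Strict local maxima with plateaus counted once at their first sample."""
    starts, vals = [0], [v[0]]
    for i in range(1, len(v)):
        if v[i] != vals[-1]:
            starts.append(i)
            vals.append(v[i])
    out = []
    for j in range(1, len(vals) - 1):
        if vals[j] > vals[j - 1] and vals[j] > vals[j + 1]:
            out.append(starts[j])
    return out


def ste_oracle(x, fs, params: DetectorParams | None = None):
    params = params or DetectorParams()
    xf = bandpass_zero_phase(x, params.band[0], params.band[1], fs)
    w = _win(params.rms_window_ms, fs)
    rms = np.array([np.sqrt(np.sum(xf[i : i + w] ** 2) / w) for i in range(len(xf) - w + 1)])
    thr = np.mean(rms) + params.rms_threshold_sd * np.std(rms)
    runs = _merge_loop(_runs_loop(_blank_edges_list(rms > thr, params, fs)), _win(params.merge_gap_ms, fs))
    rect = np.abs(xf)
    peak_thr = np.mean(rect) + params.peak_threshold_sd * np.std(rect)
    peaks = [p for p in _peaks_loop(rect) if rect[p] > peak_thr]
    spans = []
    for t0, t1 in _spans(runs, w, fs, _win(params.min_duration_ms, fs)):
        s0, s1 = int(round(t0 * fs)), int(round(t1 * fs))
        if sum(1 for p in peaks if s0 <= p < s1) > params.min_peaks:
            spans.append((t0, t1))
    return spans


def sll_oracle(x, fs, params: DetectorParams | None = None):
    params = params or DetectorParams()
    xf = bandpass_zero_phase(x, params.band[0], params.band[1], fs)
    w = _win(params.ll_window_ms, fs)
    ll = np.array(
        [np.sum(np.abs(np.diff(xf[i : i + w]))) for i in range(len(xf) - w + 1)]
    )
    if ll.max() <= 1e-9 * max(1.0, float(np.abs(np.asarray(x)).max())):
        return []
    thr = np.percentile(ll, params.ecdf_percentile)
    runs = _merge_loop(_runs_loop(_blank_edges_list(ll > thr, params, fs)), _win(params.merge_gap_ms, fs))
    return _spans(runs, w, fs, _win(params.min_duration_ms, fs))


def hil_oracle(x, fs, params: DetectorParams | None = None):
    params = params or DetectorParams()
    xf = bandpass_zero_phase(x, params.band[0], params.band[1], fs)
    env = analytic_envelope(xf, fs)  # shared transform; the rule is the loop below
    seg = max(1, int(round(params.analysis_window_s * fs)))
    supra = []
    for a in range(0, len(env), seg):
        e = env[a : a + seg]
        thr = np.mean(e) + params.envelope_threshold_sd * np.std(e)
        supra.extend(bool(v > thr) for v in e)
    runs = _merge_loop(_runs_loop(_blank_edges_list(supra, params, fs)), _win(params.merge_gap_ms, fs))
    return _spans(runs, 1, fs, _win(params.min_duration_ms, fs))


def mni_oracle(x, fs, params: DetectorParams | None = None):
    params = params or DetectorParams()
    xf = bandpass_zero_phase(x, params.band[0], params.band[1], fs)
    w = _win(params.mni_rms_window_ms, fs)
    energy = np.array(
        [np.sqrt(np.sum(xf[i : i + w] ** 2) / w) for i in range(len(xf) - w + 1)]
    )
    # baseline: flat-spectrum windows
    bw = int(round(params.baseline_window_s * fs))
    base = np.zeros(len(xf), dtype=bool)
    for a in range(0, len(xf) - bw + 1, bw):
        seg = xf[a : a + bw]
        freqs, pxx = sps.periodogram(seg, fs=fs)
        sel = (freqs >= params.band[0]) & (freqs <= params.band[1])
        p = pxx[sel]
        p = p[p > 0]
        flat = float(np.exp(np.mean(np.log(p))) / np.mean(p)) if p.size else 1.0
        if flat >= params.baseline_flatness:
            base[a : a + bw] = True
    base_idx = [i for i in range(len(energy)) if base[i : i + w].all()]
    gap = _win(params.merge_gap_ms, fs)
    min_dur = _win(params.min_duration_ms, fs)
    if np.mean(base) >= params.min_baseline_fraction and base_idx:
        thr = np.percentile(energy[base_idx], params.baseline_percentile)
        runs = _merge_loop(_runs_loop(_blank_edges_list(energy > thr, params, fs)), gap)
        return _spans(runs, w, fs, min_dur)
    seg_len = int(round(params.segment_s * fs))
    supra = np.zeros(len(energy), dtype=bool)
    for a in range(0, len(energy), seg_len):
        e = energy[a : a + seg_len]
        active = np.ones(len(e), dtype=bool)
        thr = np.percentile(e, params.no_baseline_percentile)
        for _ in range(params.mni_iterations):
            thr = np.percentile(e[active], params.no_baseline_percentile)
            active &= ~(e > thr)
            if active.sum() < 10:
                break
        supra[a : a + len(e)] = e > thr
    runs = _merge_loop(_runs_loop(_blank_edges_list(supra, params, fs)), gap)
    return _spans(runs, w, fs, min_dur)


ORACLES = {"STE": ste_oracle, "SLL": sll_oracle, "HIL": hil_oracle, "MNI": mni_oracle}
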