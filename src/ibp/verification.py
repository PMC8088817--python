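"""Time-frequency verification of detected events.

Automated detectors flag any supra-threshold energy increase in the analysis
band, including the "false ripple" produced by high-pass filtering a sharply
contoured non-oscillatory transient.  A genuine HFO shows an isolated
blob-like power increase on a wavelet time-frequency map: a local spectral
maximum in the 80-300 Hz range separated from low-frequency power by a clear
trough.  A filtered transient instead shows power decaying monotonically with
frequency — the high-frequency energy is just the tail of a broadband event.

``classify_event`` labels each event as one of
'vHFO_80_150' | 'vHFO_150_250' | 'vHFO_250_300' | 'Spike' | 'Artifact' | 'Others'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .detectors import HFOEvent
from .io import IEEGEpoch

__all__ = [
    "TimeFrequencyMap",
    "tf_map",
    "classify_event",
    "verify_events",
    "verified_rate",
    "VHFO_LABELS",
]

VHFO_LABELS = {"vHFO_80_150": 80, "vHFO_150_250": 150, "vHFO_250_300": 250}
SUB_BANDS = [(80.0, 150.0, "vHFO_80_150"), (150.0, 250.0, "vHFO_150_250"), (250.0, 300.5, "vHFO_250_300")]


@dataclass
class TimeFrequencyMap:
    """Wavelet power around one event, raw and baseline-normalized.

    ``power`` is z-scored per frequency row against the padded flanks (answers
    "is there any event here at this frequency?"); ``raw_power`` keeps the
    absolute spectral shape (answers "is the high-frequency energy an isolated
    blob or the tail of a broadband transient?").
    """

    power: np.ndarray  # frequency x time, z-scored per frequency row
    raw_power: np.ndarray  # frequency x time, unnormalized
    freqs: np.ndarray  # Hz, strictly increasing
    times: np.ndarray  # s, relative to epoch start
    event_mask: np.ndarray  # boolean over times: inside the event window
    edge_padded: bool = False
    method: str = "morlet-cwt"


def _morlet_power(x: np.ndarray, fs: float, freqs: np.ndarray, n_cycles: float = 7.0) -> np.ndarray:
    """Complex-Morlet CWT power via PyWavelets.

    The 'cmorB-C' wavelet has centre frequency C (scale = C*fs/f); the
    bandwidth B is set from the requested number of cycles.
    """
    c = 1.0
    b = (n_cycles / (2 * np.pi)) ** 2 * 2.0
    wavelet = f"cmor{b:.4f}-{c:.1f}"
    scales = c * fs / freqs
    coeffs, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs)
    return np.abs(coeffs) ** 2


def tf_map(
    epoch_or_signal: IEEGEpoch | np.ndarray,
    event: HFOEvent,
    pad_s: float = 0.25,
    fs: float | None = None,
    n_freqs: int = 30,
    f_min: float = 10.0,
    f_max: float = 300.0,
) -> TimeFrequencyMap:
    """Wavelet power map of the unfiltered trace around an event.

    Power is z-scored per frequency row against the padded flanks (the
    ``pad_s`` stretches either side of the event window), so the map reads as
    "SD above local baseline".  Events too close to the epoch edge are padded
    by reflection and flagged.
    """
    if isinstance(epoch_or_signal, IEEGEpoch):
        x = epoch_or_signal.channel(event.channel_id)
        fs = epoch_or_signal.fs
    else:
        x = np.asarray(epoch_or_signal, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare signal")

    freqs = np.geomspace(f_min, f_max, n_freqs)
    pad = int(round(pad_s * fs))
    i0, i1 = int(round(event.t_start * fs)), int(round(event.t_end * fs))
    a, b = i0 - 2 * pad, i1 + 2 * pad
    left = max(0, -a)
    right = max(0, b - x.size)
    seg = x[max(0, a) : min(x.size, b)]
    if left or right:
        seg = np.pad(seg, (left, right), mode="reflect")
    power = _morlet_power(seg, fs, freqs)

    times = (np.arange(a, b)) / fs
    ev_mask = (times >= event.t_start) & (times < event.t_end)
    flank = ~ev_mask
    # drop the outermost pad from the flank statistics (filter edge effects)
    flank[: pad // 2] = False
    flank[-(pad // 2) or None :] = False
    mu = power[:, flank].mean(axis=1, keepdims=True)
    sd = power[:, flank].std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (power - mu) / sd
    return TimeFrequencyMap(
        power=z,
        raw_power=power,
        freqs=freqs,
        times=times,
        event_mask=ev_mask,
        edge_padded=bool(left or right),
    )


def _event_profiles(tfm: TimeFrequencyMap) -> tuple[np.ndarray, np.ndarray]:
    """(z profile, raw profile): means across the event window per frequency."""
    return (
        tfm.power[:, tfm.event_mask].mean(axis=1),
        tfm.raw_power[:, tfm.event_mask].mean(axis=1),
    )


def classify_event(
    tfm: TimeFrequencyMap,
    band_floor: int = 80,
    blob_z: float = 3.0,
    trough_frac: float = 0.5,
    anchor_z: float = 3.0,
) -> str:
    """Label an event from its spectral profiles at event time.

    The z profile decides whether anything stands out of the local background;
    the raw profile decides whether the high-frequency energy is an isolated
    blob (a genuine oscillation adds a local spectral maximum on top of the
    1/f-like background) or just the monotone high-frequency tail of a
    broadband transient — the high-pass-filtering confound.

    vHFO_X  — z-significant high-frequency activity whose raw profile has a
              local maximum inside sub-band X with a trough toward lower
              frequencies dropping below ``trough_frac`` of the peak.
    Spike   — significant energy, but the raw high-frequency profile is a
              monotone tail anchored by strong low-frequency power.
    Artifact— broadband power with no blob and no low-frequency anchor.
    Others  — everything else, including blobs touching the low-frequency
              ridge (resolved conservatively).
    """
    prof_z, prof_raw = _event_profiles(tfm)
    freqs = tfm.freqs
    hi = freqs >= 80.0
    lo = ~hi
    hi_sig = float(prof_z[hi].max())
    low_anchor = float(prof_z[lo].max()) if lo.any() else 0.0

    if hi_sig < blob_z:
        return "Spike" if low_anchor >= anchor_z else "Others"

    # interior local maxima of the raw profile in the >= 80 Hz range that are
    # themselves z-significant (rules out incidental noise bumps)
    cand = [
        i
        for i in np.flatnonzero(hi)
        if 0 < i < prof_raw.size - 1
        and prof_raw[i] > prof_raw[i - 1]
        and prof_raw[i] > prof_raw[i + 1]
        and prof_z[i] >= blob_z
    ]
    if cand:
        p_idx = max(cand, key=lambda i: prof_raw[i])
        # isolation: a valley must separate the blob from the nearest lower
        # frequency carrying at least the blob's own power (a wiggle on the
        # flank of a broadband ridge has no such valley)
        above = [l for l in range(p_idx) if prof_raw[l] >= prof_raw[p_idx]]
        lo_bound = max(above) + 1 if above else 0
        # a genuine oscillation is narrow-band: the valley must appear within
        # one octave below the peak, not somewhere down the broadband slope
        octave = int(np.searchsorted(freqs, freqs[p_idx] / 2.0))
        lo_bound = max(lo_bound, octave)
        trough = (
            float(prof_raw[lo_bound:p_idx].min())
            if p_idx > lo_bound
            else float(prof_raw[p_idx])
        )
        if trough < trough_frac * prof_raw[p_idx]:
            f_peak = freqs[p_idx]
            for f0, f1, lab in SUB_BANDS:
                if f0 <= f_peak < f1:
                    return lab
            return "Others"
        # blob not separable from the broadband ridge: conservative fallthrough
    if low_anchor >= anchor_z:
        return "Spike"
    return "Artifact" if hi_sig >= blob_z else "Others"


def verify_events(
    epoch: IEEGEpoch | np.ndarray,
    events: list[HFOEvent],
    fs: float | None = None,
    pad_s: float = 0.25,
    **classify_kwargs,
) -> list[HFOEvent]:
    """Attach a verification label to every event (in place; returns the list)."""
    for ev in events:
        tfm = tf_map(epoch, ev, pad_s=pad_s, fs=fs)
        ev.verification_label = classify_event(tfm, ev.band_floor, **classify_kwargs)
    return events


def verified_rate(
    events: list[HFOEvent], band_floor: int, epoch_duration_s: float
) -> float:
    """Rate (/5 min) of events verified as vHFO in sub-bands at or above the floor.

    vHFO_>80 counts all three sub-bands, vHFO_>150 the upper two, vHFO_>250
    the top one.  Raises if any event is still unverified.
    """
    if epoch_duration_s <= 0:
        raise ValueError("epoch_duration_s must be positive")
    n = 0
    for ev in events:
        if ev.verification_label == "unverified":
            raise ValueError("verification must run before computing vHFO rates")
        sub_floor = VHFO_LABELS.get(ev.verification_label)
        if sub_floor is not None and sub_floor >= band_floor:
            n += 1
    return n * 300.0 / epoch_duration_s
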