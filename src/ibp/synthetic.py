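"""Synthetic iEEG epochs, electrode layouts and patient cohorts with known ground truth.

Everything here is generative: given a spec and a seed, the output is fully
deterministic, and the returned truth tables are sufficient to recompute every
planted rate and outcome probability exactly.  The generator emulates the study
conditions of a subdural-grid presurgical cohort: 5-minute slow-wave-sleep
epochs sampled at 1000 Hz, pink-noise background, channel-specific rates of
high-frequency oscillations (HFOs), spike-and-wave discharges whose
high-frequency amplitude is coupled to 3-4 Hz phase, sharp non-oscillatory
transients (the classic "false ripple" confound), artifact channels, and a
cohort of ~135 patients whose surgical outcome follows a logistic model with
known coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SignalSpec",
    "PlantedEvent",
    "CohortSpec",
    "Cohort",
    "PatientTruth",
    "make_background",
    "inject_oscillation",
    "inject_sharp_transient",
    "make_coupled_epoch",
    "make_electrode_layout",
    "simulate_cohort",
    "measure_rates",
    "render_patient_epoch",
    "band_noise_sd",
    "COVARIATE_COLUMNS",
    "DEFAULT_TRUE_BETA",
    "DETECTOR_SENSITIVITY",
]


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class SignalSpec:
    """Parameters of one synthetic background channel.

    duration_s : epoch length in seconds (study epochs are 5 min).
    fs         : sampling rate in Hz; must be >= 600 so the 80-300 Hz
                 analysis band is representable.
    noise_sd   : standard deviation of the background in microvolts.
    spectral_exponent : alpha of the 1/f^alpha background power spectrum.
    """

    duration_s: float = 300.0
    fs: float = 1000.0
    noise_sd: float = 20.0
    spectral_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs < 2 * 300:
            raise ValueError("fs must be at least 600 Hz (2 x 300 Hz band top)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass(frozen=True)
class PlantedEvent:
    """One planted ground-truth event.

    kind is 'oscillation' (a genuine HFO: Hann-tapered sinusoid),
    'sharp_transient' (biphasic spike with no oscillatory content; its
    band-passed trace rings — the planted false positive), or
    'spike_wave_complex'.
    """

    kind: str
    t0: float
    f0: float = 120.0
    n_cycles: int = 8
    amplitude: float = 50.0
    width_ms: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("oscillation", "sharp_transient", "spike_wave_complex"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "oscillation":
            if not (80.0 <= self.f0 <= 300.0):
                raise ValueError("oscillation f0 must lie in [80, 300] Hz")
            if self.n_cycles < 4:
                raise ValueError("oscillation needs n_cycles >= 4")

    @property
    def duration_s(self) -> float:
        if self.kind == "oscillation":
            return self.n_cycles / self.f0
        return self.width_ms / 1000.0


COVARIATE_COLUMNS = [
    "age",
    "male",
    "daily_seizures",
    "n_aeds",
    "left_hemisphere",
    "mri_lesion",
    "habitual_sz_captured",
    "soz_fully_resected",
    "extratemporal_resection",
    "resection_size_pct",
]

# Logistic coefficients on the raw covariate coding (male=1, yes=1, age in
# years, resection size in % of hemisphere), plus one coefficient for the true
# resection-completeness (Subtraction) biomarker appended as the 11th column.
DEFAULT_TRUE_BETA = np.array(
    [-0.015, 0.0, -0.4, -0.55, 0.0, 0.25, 0.3, 1.9, -0.35, 0.005, 0.8]
)

# Relative detection sensitivity of each detector, chosen so a non-epileptic
# generative rate of ~5 oscillations / 5 min reproduces the observed contrast
# between inclusive (SLL, HIL) and conservative (STE, MNI) detectors.
DETECTOR_SENSITIVITY = {"STE": 0.18, "SLL": 1.0, "HIL": 1.15, "MNI": 0.14}

# Share of a channel's oscillations whose centre frequency falls in each
# analysis band floor (ripples dominate; fast ripples are rare).
BAND_FRACTION = {80: 1.0, 150: 0.35, 250: 0.10}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generative parameters.

    true_beta has one entry per clinical covariate (10, in the order of
    COVARIATE_COLUMNS) plus a final entry for the true Subtraction biomarker.
    The intercept is solved internally so the cohort-mean success probability
    matches ``target_success_rate``.
    """

    n_patients: int = 135
    channels_per_patient: tuple[int, int] = (64, 152)
    frac_non_epileptic: float = 0.6
    epileptic_rate_multiplier: float = 5.0
    true_beta: np.ndarray = field(default_factory=lambda: DEFAULT_TRUE_BETA.copy())
    target_success_rate: float = 0.704
    baseline_rate_mean: float = 5.0
    baseline_mi_mean: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        beta = np.asarray(self.true_beta, dtype=float)
        if beta.shape != (len(COVARIATE_COLUMNS) + 1,):
            raise ValueError(
                f"true_beta must have {len(COVARIATE_COLUMNS) + 1} entries"
            )
        if not np.all(np.isfinite(beta)):
            raise ValueError("true_beta must be finite")
        if not (0.0 < self.frac_non_epileptic < 1.0):
            raise ValueError("frac_non_epileptic must lie in (0, 1)")


# ---------------------------------------------------------------------------
# signal-level generators


def make_background(spec: SignalSpec) -> np.ndarray:
    """Zero-mean Gaussian 1/f^alpha background, deterministic given the seed.

    Spectral shaping is done in the frequency domain: white Gaussian noise is
    multiplied by f^(-alpha/2) (power then falls as 1/f^alpha) and scaled to
    the requested standard deviation.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    white = rng.standard_normal(n)
    if spec.spectral_exponent == 0:
        x = white
    else:
        spec_w = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
        shaping = np.ones_like(freqs)
        nz = freqs > 0
        shaping[nz] = freqs[nz] ** (-spec.spectral_exponent / 2.0)
        shaping[0] = 0.0  # no DC
        x = np.fft.irfft(spec_w * shaping, n=n)
    x = x - x.mean()
    sd = x.std()
    if sd > 0:
        x = x * (spec.noise_sd / sd)
    return x


def _check_bounds(event: PlantedEvent, n: int, fs: float) -> tuple[int, int]:
    i0 = int(round(event.t0 * fs))
    length = int(round(event.duration_s * fs))
    if i0 < 0 or i0 + length > n:
        raise ValueError(
            f"event at t0={event.t0:.3f}s (duration {event.duration_s:.3f}s) "
            f"extends outside the {n / fs:.1f}s epoch"
        )
    return i0, length


def inject_oscillation(
    x: np.ndarray, event: PlantedEvent, fs: float = 1000.0
) -> np.ndarray:
    """Add a Hann-tapered sinusoidal burst; samples outside the window untouched."""
    if event.kind != "oscillation":
        raise ValueError("inject_oscillation requires an 'oscillation' event")
    i0, length = _check_bounds(event, x.size, fs)
    out = x.copy()
    t = np.arange(length) / fs
    burst = event.amplitude * np.hanning(length) * np.sin(2 * np.pi * event.f0 * t)
    out[i0 : i0 + length] += burst
    return out


def inject_sharp_transient(
    x: np.ndarray, event: PlantedEvent, fs: float = 1000.0
) -> np.ndarray:
    """Add a non-oscillatory biphasic spike (first derivative of a Gaussian).

    Band-pass filtering such a transient at >=80 Hz produces a ripple-like
    deflection with no genuine oscillation — the planted false positive for
    the time-frequency verifier.
    """
    if event.kind != "sharp_transient":
        raise ValueError("inject_sharp_transient requires a 'sharp_transient' event")
    i0, length = _check_bounds(event, x.size, fs)
    out = x.copy()
    length = max(length, 3)
    # sharp apex (discontinuous slope sign change) is what makes the filtered
    # trace ring; smooth bumps would not reproduce the confound
    tt = np.linspace(-1.0, 1.0, length)
    tau = 0.25
    shape = np.sign(tt) * np.exp(-np.abs(tt) / tau)
    shape = shape / np.abs(shape).max()
    out[i0 : i0 + length] += event.amplitude * shape
    return out


def make_coupled_epoch(
    spec: SignalSpec,
    slow_f: float = 3.5,
    mod_depth: float = 0.5,
    carrier_f: float = 200.0,
    carrier_amp: float = 10.0,
    slow_amp: float = 40.0,
) -> np.ndarray:
    """Epoch whose high-frequency amplitude is coupled to slow-wave phase.

    signal = slow_amp*cos(phi) + A0*(1 + m*cos(phi))*cos(2*pi*carrier_f*t) + background
    with phi = 2*pi*slow_f*t.  The analytic mean-vector length of (amplitude,
    phase) is A0*m/2, which is the closed-form expectation of the modulation
    index on this family.  Set spec.noise_sd = 0 to switch the background off.
    """
    if not (3.0 <= slow_f <= 4.0):
        raise ValueError("slow_f must lie in the 3-4 Hz slow-wave band")
    if not (0.0 <= mod_depth <= 1.0):
        raise ValueError("mod_depth must lie in [0, 1]")
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    phi = 2 * np.pi * slow_f * t
    x = slow_amp * np.cos(phi)
    x = x + carrier_amp * (1.0 + mod_depth * np.cos(phi)) * np.cos(
        2 * np.pi * carrier_f * t
    )
    if spec.noise_sd > 0:
        x = x + make_background(spec)
    return x


def band_noise_sd(spec: SignalSpec, f_lo: float = 80.0, f_hi: float = 300.0) -> float:
    """SD of the band-passed background for this spec (for SNR calibration)."""
    from .detectors import bandpass_zero_phase

    bg = make_background(spec)
    return float(bandpass_zero_phase(bg, f_lo, f_hi, spec.fs).std())


# ---------------------------------------------------------------------------
# electrode layouts


def make_electrode_layout(
    n_channels: int,
    seed: int,
    frac_non_epileptic: float = 0.6,
    mri_lesion: bool = True,
    resect_soz_fully: bool = True,
    frac_artifact: float = 0.03,
    resection_frac: float = 0.18,
    radius_mm: float = 70.0,
) -> pd.DataFrame:
    """Sample electrode coordinates on a synthetic hemispheric surface with masks.

    Coordinates are points on a unit-hemisphere patch scaled to ``radius_mm``.
    The epileptic territory is a spatially contiguous cluster: the spiking zone
    is the whole cluster, the SOZ its inner 30% and the lesion (if the patient
    has one on MRI) its inner 20%.  non_epileptic == NOT(soz | lesion | spiking)
    by construction.  Resection is a contiguous cap around the SOZ centroid
    that either covers the SOZ fully or deliberately spares part of it.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels to define a resection")
    rng = np.random.default_rng(seed)
    # points on the z>=0 hemisphere
    pts = rng.standard_normal((n_channels, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts[:, 2] = np.abs(pts[:, 2])
    coords = pts * radius_mm

    n_epi = max(2, int(round((1.0 - frac_non_epileptic) * n_channels)))
    n_epi = min(n_epi, n_channels - 2)  # keep some non-epileptic channels
    centre = coords[rng.integers(n_channels)]
    d = np.linalg.norm(coords - centre, axis=1)
    order = np.argsort(d, kind="stable")
    cluster = order[:n_epi]

    spiking = np.zeros(n_channels, dtype=bool)
    spiking[cluster] = True
    soz = np.zeros(n_channels, dtype=bool)
    soz[cluster[: max(1, int(round(0.3 * n_epi)))]] = True
    lesion = np.zeros(n_channels, dtype=bool)
    if mri_lesion:
        lesion[cluster[: max(1, int(round(0.2 * n_epi)))]] = True

    artifact = rng.random(n_channels) < frac_artifact

    soz_idx = np.flatnonzero(soz)
    soz_centroid = coords[soz_idx].mean(axis=0)
    n_resect = max(soz_idx.size + 1, int(round(resection_frac * n_channels)))
    n_resect = min(n_resect, n_channels - 1)
    d_soz = np.linalg.norm(coords - soz_centroid, axis=1)
    res_order = np.argsort(d_soz, kind="stable")
    resected = np.zeros(n_channels, dtype=bool)
    resected[res_order[:n_resect]] = True
    if resect_soz_fully:
        resected[soz] = True
    else:
        # spare the SOZ channel farthest from the centroid
        spare = soz_idx[np.argmax(d_soz[soz_idx])]
        resected[spare] = False
    # guarantee at least one preserved non-artifact channel
    preserved = ~resected & ~artifact
    if not preserved.any():
        resected[res_order[-1]] = False
        artifact[res_order[-1]] = False

    return pd.DataFrame(
        {
            "channel": [f"CH{i:03d}" for i in range(n_channels)],
            "x_mm": coords[:, 0],
            "y_mm": coords[:, 1],
            "z_mm": coords[:, 2],
            "artifact": artifact,
            "soz": soz,
            "lesion": lesion,
            "spiking": spiking,
            "resected": resected,
            "non_epileptic": ~(soz | lesion | spiking),
        }
    )


# ---------------------------------------------------------------------------
# cohort simulation (rate level, with on-demand signal rendering)


@dataclass
class PatientTruth:
    """Ground truth for one synthetic patient."""

    patient_id: str
    layout: pd.DataFrame
    true_rate: np.ndarray  # oscillations / 5 min per channel (generative)
    true_mi: np.ndarray  # coupling strength (uV) per channel
    covariates: dict
    true_subtraction: float
    success_prob: float = float("nan")
    success: bool = False
    ilae_class: int = 1
    seed: int = 0


@dataclass
class Cohort:
    """A simulated cohort: per-patient truth plus cohort-level tables."""

    spec: CohortSpec
    patients: list[PatientTruth]
    clinical: pd.DataFrame  # covariates + success + ilae_class per patient
    design: pd.DataFrame  # the exact X used to draw outcomes (incl. biomarker)
    true_beta: np.ndarray
    intercept: float
    warnings: list[str] = field(default_factory=list)


def _draw_covariates(rng: np.random.Generator) -> dict:
    age = float(np.clip(4.0 + rng.gamma(2.0, 4.55), 4.0, 44.0))
    n_aeds = int(rng.choice([1, 2, 3, 5], p=[0.296, 0.444, 0.252, 0.008]))
    size = float(np.clip(rng.lognormal(math.log(12.0), 0.8), 0.6, 91.6))
    return {
        "age": age,
        "male": int(rng.random() < 0.504),
        "daily_seizures": int(rng.random() < 0.333),
        "n_aeds": n_aeds,
        "left_hemisphere": int(rng.random() < 0.526),
        "mri_lesion": int(rng.random() < 0.585),
        "habitual_sz_captured": int(rng.random() < 0.867),
        "soz_fully_resected": int(rng.random() < 0.874),
        "extratemporal_resection": int(rng.random() < 0.630),
        "resection_size_pct": size,
    }


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a full cohort with known logistic outcome coefficients.

    Epileptic channels receive generative oscillation rates multiplied by
    ``epileptic_rate_multiplier``.  Each patient's true Subtraction biomarker
    is the resected-minus-preserved mean of the expected STE-detected rate
    (generative rate x STE sensitivity), computed from the truth tables, and
    the success indicator is Bernoulli(logistic(intercept + x . true_beta)).
    """
    rng = np.random.default_rng(spec.seed)
    beta = np.asarray(spec.true_beta, dtype=float)
    lo, hi = spec.channels_per_patient
    patients: list[PatientTruth] = []
    warnings: list[str] = []

    for p in range(spec.n_patients):
        pseed = int(rng.integers(0, 2**31 - 1))
        prng = np.random.default_rng(pseed)
        cov = _draw_covariates(prng)
        n_ch = int(prng.integers(lo, hi + 1))
        layout = make_electrode_layout(
            n_ch,
            seed=int(prng.integers(0, 2**31 - 1)),
            frac_non_epileptic=spec.frac_non_epileptic,
            mri_lesion=bool(cov["mri_lesion"]),
            resect_soz_fully=bool(cov["soz_fully_resected"]),
        )
        rate = prng.gamma(2.0, spec.baseline_rate_mean / 2.0, size=n_ch)
        mi = prng.gamma(2.0, spec.baseline_mi_mean / 2.0, size=n_ch)
        epileptic = ~layout["non_epileptic"].to_numpy()
        rate[epileptic] *= spec.epileptic_rate_multiplier
        mi[epileptic] *= spec.epileptic_rate_multiplier

        ok = ~layout["artifact"].to_numpy()
        res = layout["resected"].to_numpy() & ok
        pres = ~layout["resected"].to_numpy() & ok
        ste = DETECTOR_SENSITIVITY["STE"] * rate
        true_sub = float(ste[res].mean() - ste[pres].mean())

        patients.append(
            PatientTruth(
                patient_id=f"P{p:03d}",
                layout=layout,
                true_rate=rate,
                true_mi=mi,
                covariates=cov,
                true_subtraction=true_sub,
                seed=pseed,
            )
        )

    X = pd.DataFrame([p.covariates for p in patients], dtype=float)
    X["subtraction_biomarker"] = [p.true_subtraction for p in patients]
    lin = X.to_numpy() @ beta
    intercept = float(math.log(spec.target_success_rate / (1 - spec.target_success_rate)) - lin.mean())
    probs = 1.0 / (1.0 + np.exp(-(intercept + lin)))
    draws = rng.random(spec.n_patients)
    for p, prob, u in zip(patients, probs, draws):
        p.success_prob = float(prob)
        p.success = bool(u < prob)
        if p.success:
            p.ilae_class = 1
        else:
            p.ilae_class = int(rng.choice([2, 3, 4, 5], p=[0.05, 0.375, 0.35, 0.225]))

    clinical = X.copy()
    clinical.insert(0, "patient", [p.patient_id for p in patients])
    clinical["success_prob"] = probs
    clinical["success"] = [int(p.success) for p in patients]
    clinical["ilae_class"] = [p.ilae_class for p in patients]

    for col in COVARIATE_COLUMNS:
        if clinical[col].nunique() <= 1:
            warnings.append(f"degenerate design: covariate {col!r} is constant")

    return Cohort(
        spec=spec,
        patients=patients,
        clinical=clinical,
        design=X,
        true_beta=beta,
        intercept=intercept,
        warnings=warnings,
    )


def measure_rates(
    cohort: Cohort, duration_s: float = 300.0, seed: int = 0, mi_noise_sd: float = 0.01
) -> dict[str, pd.DataFrame]:
    """Emulate detector measurement at the rate level (no signal rendering).

    For each patient, detector counts are Poisson with mean
    sensitivity x generative rate x band fraction x duration/300; rates are the
    counts rescaled to /5 min.  Measured MI is the true coupling strength plus
    truncated Gaussian noise.  Returns one channel table per patient keyed by
    patient_id, with columns rate_<det>_<band> and mi_<band>.
    """
    rng = np.random.default_rng(seed)
    scale = duration_s / 300.0
    out: dict[str, pd.DataFrame] = {}
    for p in cohort.patients:
        df = p.layout.copy()
        for det, sens in DETECTOR_SENSITIVITY.items():
            for floor, frac in BAND_FRACTION.items():
                lam = sens * p.true_rate * frac * scale
                counts = rng.poisson(lam)
                df[f"rate_{det}_{floor}"] = counts / scale
        for floor, frac in BAND_FRACTION.items():
            noisy = p.true_mi * frac + rng.normal(0.0, mi_noise_sd, size=len(df))
            df[f"mi_{floor}"] = np.clip(noisy, 0.0, None)
        out[p.patient_id] = df
    return out


def render_patient_epoch(
    patient: PatientTruth,
    duration_s: float = 60.0,
    fs: float = 1000.0,
    noise_sd: float = 20.0,
    snr_sd: float = 15.0,
    spike_rate_per_5min: float = 3.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a multichannel epoch for one patient from its truth tables.

    Oscillation events are planted at each channel's generative rate (Poisson
    counts over the epoch), sharp transients on spiking channels, and
    phase-amplitude-coupled carriers scaled so that the expected modulation
    index equals the channel's true coupling strength.  Artifact channels get
    broadband high-amplitude noise.  Returns (channels x time array, truth
    event table with columns channel/kind/t0_s/f0_hz/n_cycles/amplitude).
    """
    rng = np.random.default_rng(patient.seed + 7)
    n_ch = len(patient.layout)
    n = int(round(duration_s * fs))
    base_spec = SignalSpec(duration_s=duration_s, fs=fs, noise_sd=noise_sd, seed=0)
    bsd = band_noise_sd(base_spec)
    amp = snr_sd * bsd
    samples = np.empty((n_ch, n))
    rows = []
    t = np.arange(n) / fs
    for c in range(n_ch):
        ch_spec = replace(base_spec, seed=int(rng.integers(0, 2**31 - 1)))
        x = make_background(ch_spec)
        if bool(patient.layout["artifact"].iloc[c]):
            x = x + rng.standard_normal(n) * 8 * noise_sd
            samples[c] = x
            continue
        mi_c = patient.true_mi[c]
        if mi_c > 0:
            m = 0.8
            phi = 2 * np.pi * 3.5 * t
            x = x + 30.0 * np.cos(phi)
            x = x + (2 * mi_c / m) * (1 + m * np.cos(phi)) * np.cos(2 * np.pi * 180.0 * t)
        n_osc = rng.poisson(patient.true_rate[c] * duration_s / 300.0)
        for _ in range(n_osc):
            f0 = float(80.0 + 220.0 * rng.beta(1.2, 3.0))
            ncyc = int(rng.integers(6, 13))
            t0 = float(rng.uniform(0.5, duration_s - 0.5 - ncyc / f0))
            ev = PlantedEvent("oscillation", t0=t0, f0=f0, n_cycles=ncyc, amplitude=amp)
            x = inject_oscillation(x, ev, fs)
            rows.append((patient.layout["channel"].iloc[c], "oscillation", t0, f0, ncyc, amp))
        if bool(patient.layout["spiking"].iloc[c]):
            n_sp = rng.poisson(spike_rate_per_5min * duration_s / 300.0)
            for _ in range(n_sp):
                t0 = float(rng.uniform(0.5, duration_s - 0.6))
                ev = PlantedEvent("sharp_transient", t0=t0, amplitude=12 * noise_sd, width_ms=30.0)
                x = inject_sharp_transient(x, ev, fs)
                rows.append((patient.layout["channel"].iloc[c], "sharp_transient", t0, np.nan, 0, 12 * noise_sd))
        samples[c] = x
    truth = pd.DataFrame(
        rows, columns=["channel", "kind", "t0_s", "f0_hz", "n_cycles", "amplitude"]
    )
    return samples, truth
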