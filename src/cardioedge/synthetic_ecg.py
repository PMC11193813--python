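"""Synthetic labeled ECG generation for NSR, AFIB and AFL.

Every beat is a sum-of-Gaussians PQRST template; rhythms differ in their
RR-interval law and atrial activity:

* NSR  — RR ~ Normal(60/mean_hr, rr_cv * mean), full P wave before each QRS.
* AFIB — i.i.d. RR from a truncated lognormal on [300, 1500] ms with high
  coefficient of variation, no P wave, and a low-amplitude fibrillatory
  oscillation near 6 Hz.
* AFL  — continuous sawtooth flutter (F) waves at ``flutter_rate`` per
  minute with a near-constant ventricular response at
  ``flutter_rate / conduction_ratio``.

Additive noise follows the ambulatory-ECG taxonomy: sub-4-Hz baseline
wander, 60-Hz powerline interference, white sensor noise and Poisson-timed
half-sine electrode-motion bursts. Ground truth (beat times, clean signal,
wave offsets) rides along in record metadata so downstream detectors can be
scored against construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from cardioedge.io_formats import AFIB, AFL, NSR, EcgRecord, RhythmAnnotation

#: PQRST template: per-wave (offset ms relative to R, amplitude, width-sigma ms)
DEFAULT_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "P": (-180.0, 0.12, 25.0),
    "Q": (-30.0, -0.12, 10.0),
    "R": (0.0, 1.0, 12.0),
    "S": (30.0, -0.25, 10.0),
    "T": (250.0, 0.30, 60.0),
}


@dataclass
class RhythmSpec:
    """Parameters of one synthetic rhythm.

    ``flutter_rate`` (atrial waves/min) and ``conduction_ratio`` only apply
    to AFL, where the ventricular rate is flutter_rate / conduction_ratio.
    ``fibrillatory_amp`` is the 6-Hz oscillation amplitude for AFIB, in the
    same normalized units as the R amplitude (1.0).
    """

    rhythm: str = NSR
    mean_hr: float = 70.0
    rr_cv: float = 0.05
    p_amplitude: float = 0.12
    flutter_rate: float = 300.0
    conduction_ratio: int = 2
    flutter_amp: float = 0.15
    fibrillatory_amp: float = 0.012
    fibrillatory_freq: float = 6.0
    template: dict = field(default_factory=lambda: dict(DEFAULT_TEMPLATE))
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rhythm not in (NSR, AFIB, AFL):
            raise ValueError(f"unknown rhythm {self.rhythm!r}")
        if not 30.0 <= self.mean_hr <= 250.0:
            raise ValueError("mean_hr must lie in [30, 250] BPM")
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be >= 0")
        if self.conduction_ratio < 1:
            raise ValueError("conduction_ratio must be a positive integer")


@dataclass
class NoiseSpec:
    """Additive noise mixture; all amplitudes in normalized units (R = 1)."""

    baseline_amp: float = 0.0
    baseline_freq: float = 0.3
    powerline_amp: float = 0.0
    powerline_freq: float = 60.0
    white_sigma: float = 0.0
    motion_burst_rate: float = 0.0  # bursts per minute
    motion_amp: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("baseline_amp", "powerline_amp", "white_sigma",
                     "motion_burst_rate", "motion_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.baseline_freq < 4.0:
            raise ValueError("baseline_freq must lie in (0, 4) Hz")


def _sample_rr_s(spec: RhythmSpec, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Draw RR intervals (seconds) until the beat train covers duration_s."""
    mean_rr = 60.0 / spec.mean_hr
    n_guess = int(duration_s / mean_rr * 1.5) + 10
    if spec.rhythm == AFIB:
        # truncated lognormal on [300, 1500] ms: chaotic but physiological
        cv = max(spec.rr_cv, 0.15)
        sigma = np.sqrt(np.log(1.0 + cv**2))
        mu = np.log(mean_rr) - 0.5 * sigma**2
        rr = np.exp(rng.normal(mu, sigma, size=4 * n_guess))
        rr = rr[(rr >= 0.3) & (rr <= 1.5)][:n_guess]
    elif spec.rhythm == AFL:
        mean_rr = 60.0 / (spec.flutter_rate / spec.conduction_ratio)
        rr = rng.normal(mean_rr, spec.rr_cv * mean_rr, size=n_guess)
        rr = np.clip(rr, 0.25, 2.0)
    else:
        rr = rng.normal(mean_rr, spec.rr_cv * mean_rr, size=n_guess)
        rr = np.clip(rr, 0.3, 1.5)
    return rr


def generate_rhythm(
    spec: RhythmSpec,
    duration_s: float = 30.0,
    fs: float = 128.0,
    seed: int | None = None,
    record_id: str = "sim",
    patient_id: str = "sim-patient",
    database_id: str = "synthetic",
) -> EcgRecord:
    """Generate a single-lead labeled record of the requested rhythm.

    Ground-truth beat times (s), RR intervals (ms) and the wave template are
    stored in ``record.metadata``.
    """
    if duration_s < 10:
        raise ValueError("duration_s must be >= 10")
    if fs < 128:
        raise ValueError("fs must be >= 128")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    rr = _sample_rr_s(spec, duration_s, rng)
    # slow autonomic drift: the local mean RR wanders a few percent over
    # minutes, so windows of one record are not carbon copies; a strictly
    # metronomic request (rr_cv = 0) stays exactly periodic
    if spec.rr_cv > 0:
        drift_amp = rng.uniform(0.02, 0.06)
        drift_period = rng.uniform(60.0, 240.0)
        drift_phase = rng.uniform(0, 2 * np.pi)
        t_beat = np.cumsum(rr)
        rr = rr * (
            1.0 + drift_amp * np.sin(2 * np.pi * t_beat / drift_period + drift_phase)
        )
    beat_times = 0.3 + np.cumsum(np.concatenate([[0.0], rr]))
    beat_times = beat_times[beat_times < duration_s - 0.05]

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)

    template = dict(spec.template)
    p_amp = 0.0 if spec.rhythm in (AFIB, AFL) else spec.p_amplitude
    off_p, _, sig_p = template["P"]
    template["P"] = (off_p, p_amp, sig_p)

    # electrode-contact drift: low-amplitude waves (P, T) wax and wane a
    # little over the record while the QRS stays dominant
    amp_mod_amp = rng.uniform(0.05, 0.20)
    amp_mod_period = rng.uniform(90.0, 300.0)
    amp_mod_phase = rng.uniform(0, 2 * np.pi)

    for bt in beat_times:
        wave_scale = 1.0 + amp_mod_amp * np.sin(
            2 * np.pi * bt / amp_mod_period + amp_mod_phase
        )
        for wave, (off_ms, amp, sig_ms) in template.items():
            if amp == 0.0:
                continue
            if wave in ("P", "T"):
                amp = amp * wave_scale
            center = bt + off_ms / 1000.0
            sig = sig_ms / 1000.0
            lo = max(0, int((center - 4 * sig) * fs))
            hi = min(n, int((center + 4 * sig) * fs) + 1)
            if hi > lo:
                x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - center) / sig) ** 2)

    if spec.rhythm == AFIB and spec.fibrillatory_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += spec.fibrillatory_amp * np.sin(
            2 * np.pi * spec.fibrillatory_freq * t + phase
        )
    if spec.rhythm == AFL and spec.flutter_amp > 0:
        phase = rng.uniform(0, 1)
        f_hz = spec.flutter_rate / 60.0
        x += spec.flutter_amp * 0.5 * sps.sawtooth(
            2 * np.pi * (f_hz * t + phase), width=0.3
        )

    rec = EcgRecord(
        signals=x[np.newaxis, :],
        fs=fs,
        lead_names=["I"],
        units=["mV"],
        patient_id=patient_id,
        record_id=record_id,
        database_id=database_id,
        annotations=[RhythmAnnotation(0, spec.rhythm)],
    )
    rec.metadata.update(
        rhythm=spec.rhythm,
        beat_times_s=beat_times,
        # the drawn intervals, not diff(cumsum): exact at rr_cv = 0
        rr_ms=rr[: max(len(beat_times) - 1, 0)] * 1000.0,
        template=template,
        p_amplitude=p_amp,
        clean_signals=x[np.newaxis, :].copy(),
    )
    return rec


def add_noise(record: EcgRecord, noise: NoiseSpec, seed: int | None = None) -> EcgRecord:
    """Return a copy of ``record`` with the noise mixture added to every lead.

    The clean signal is retained in ``metadata['clean_signals']``.
    """
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    n = record.n_samples
    t = np.arange(n) / record.fs
    out = record.signals.copy()
    clean = record.metadata.get("clean_signals", record.signals.copy())

    for lead in range(out.shape[0]):
        if noise.baseline_amp > 0:
            out[lead] += noise.baseline_amp * np.sin(
                2 * np.pi * noise.baseline_freq * t + rng.uniform(0, 2 * np.pi)
            )
        if noise.powerline_amp > 0:
            out[lead] += noise.powerline_amp * np.sin(
                2 * np.pi * noise.powerline_freq * t + rng.uniform(0, 2 * np.pi)
            )
        if noise.white_sigma > 0:
            out[lead] += rng.normal(0, noise.white_sigma, size=n)
        if noise.motion_burst_rate > 0 and noise.motion_amp > 0:
            n_bursts = rng.poisson(noise.motion_burst_rate * record.duration_s / 60.0)
            burst_len = int(0.5 * record.fs)
            burst = np.sin(np.pi * np.arange(burst_len) / burst_len)  # half-sine
            for _ in range(n_bursts):
                start = rng.integers(0, max(1, n - burst_len))
                out[lead, start : start + burst_len] += (
                    noise.motion_amp * rng.choice([-1.0, 1.0]) * burst
                )

    noisy = EcgRecord(
        signals=out,
        fs=record.fs,
        lead_names=list(record.lead_names),
        units=list(record.units),
        patient_id=record.patient_id,
        record_id=record.record_id,
        database_id=record.database_id,
        annotations=list(record.annotations),
    )
    noisy.metadata.update(record.metadata)
    noisy.metadata["clean_signals"] = clean
    return noisy


# ---------------------------------------------------------------------------
# dataset generation

#: per-class physiology ranges a generated patient is drawn from.
CLASS_PHYSIOLOGY = {
    # the NSR variability range spans AFIB's: ambulatory sinus-rhythm windows
    # with marked sinus arrhythmia or frequent ectopy overlap rate-controlled
    # AFIB on every RR statistic, leaving atrial (P-wave) evidence as the
    # reliable discriminator
    NSR: dict(mean_hr=(55.0, 95.0), rr_cv=(0.05, 0.18), p_amplitude=(0.15, 0.25)),
    AFIB: dict(mean_hr=(70.0, 150.0), rr_cv=(0.15, 0.30), fibrillatory_amp=(0.008, 0.018)),
    # variable AV block makes some flutter ventricular responses moderately
    # irregular; perfectly regular AFL would let RR statistics alone carve
    # out the class
    AFL: dict(flutter_rate=(240.0, 340.0), rr_cv=(0.02, 0.06), flutter_amp=(0.12, 0.18)),
}

#: per-record noise ranges emulating ambulatory recording conditions.
NOISE_RANGES = dict(
    baseline_amp=(0.05, 0.20),
    baseline_freq=(0.15, 0.45),
    powerline_amp=(0.0, 0.10),
    white_sigma=(0.01, 0.04),
    motion_amp=(0.10, 0.30),
)
MOTION_BURSTS_PER_MIN = 1.0

#: conduction mixture: 2:1 fast-regular, 3:1/4:1 slower with visible
#: flutter waves in the P window — AFL is a union of distinct presentations
_AFL_CONDUCTION_CHOICES = (2, 3, 3, 4)


def _draw_spec(rhythm: str, rng: np.random.Generator) -> RhythmSpec:
    phys = CLASS_PHYSIOLOGY[rhythm]
    kw: dict = {"rhythm": rhythm}
    for name, (lo, hi) in phys.items():
        kw[name] = float(rng.uniform(lo, hi))
    if rhythm == AFL:
        kw["conduction_ratio"] = int(rng.choice(_AFL_CONDUCTION_CHOICES))
        kw["mean_hr"] = kw["flutter_rate"] / kw["conduction_ratio"]
    return RhythmSpec(**kw)


def _draw_noise(rng: np.random.Generator) -> NoiseSpec:
    kw = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in NOISE_RANGES.items()}
    return NoiseSpec(motion_burst_rate=MOTION_BURSTS_PER_MIN, **kw)


def generate_labeled_dataset(
    n_per_class: int = 300,
    patients_per_class: int = 10,
    specs: Sequence[RhythmSpec] | None = None,
    seed: int = 0,
    fs: float = 128.0,
    window_s: float = 30.0,
    noisy: bool = True,
) -> list[EcgRecord]:
    """Generate one record per synthetic patient, ``n_per_class`` 30-s windows
    per rhythm class in total.

    Each patient gets a distinct ``patient_id`` and physiology drawn from
    :data:`CLASS_PHYSIOLOGY`; each record gets its own noise realization
    drawn from :data:`NOISE_RANGES` (unless ``noisy=False``). Reproducible
    under a fixed seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    rhythms = [s.rhythm for s in specs] if specs else [NSR, AFIB, AFL]

    records: list[EcgRecord] = []
    for ci, rhythm in enumerate(rhythms):
        base = n_per_class // patients_per_class
        extra = n_per_class - base * patients_per_class
        for pi in range(patients_per_class):
            n_windows = base + (1 if pi < extra else 0)
            if n_windows == 0:
                continue
            spec = specs[ci] if specs else _draw_spec(rhythm, rng)
            pid = f"{rhythm.lower()}-p{pi:03d}"
            rec = generate_rhythm(
                spec,
                duration_s=n_windows * window_s,
                fs=fs,
                seed=int(rng.integers(0, 2**31)),
                record_id=f"{pid}-r0",
                patient_id=pid,
            )
            if noisy:
                rec = add_noise(rec, _draw_noise(rng), seed=int(rng.integers(0, 2**31)))
            records.append(rec)
    return records
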