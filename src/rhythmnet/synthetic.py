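"""Synthetic single-lead ECG generator for the four CinC-2017 rhythm classes.

Beats are modelled as sums of Gaussians (one per P/Q/R/S/T wave), placed at
R-peak times drawn from per-class RR-interval distributions:

* ``N`` (normal sinus rhythm): regular RR (low coefficient of variation),
  P wave present.
* ``A`` (atrial fibrillation): irregularly irregular RR (log-normal draws,
  high CV), no P wave, a small continuous fibrillatory oscillation instead.
* ``O`` (other rhythm): sinus rhythm interrupted by premature ectopic beats
  with widened QRS and no P wave.
* ``~`` (noisy): an underlying sinus rhythm buried in noise at or below
  0 dB SNR.

Additive noise covers the contaminants seen in ambulatory recordings:
baseline wander, powerline interference, broadband EMG-like noise and
sporadic impulse artifacts.  Every draw flows from an explicit seed, so
generation is a pure function of (spec, seed).

The class defaults are desk-scale stand-ins chosen to reproduce the
*discriminative structure* of the real recordings (RR statistics, P-wave
presence, noise floor), not their full morphology; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CLASS_LABELS, ECGRecord

__all__ = [
    "BeatTemplate",
    "RhythmSpec",
    "NoiseSpec",
    "SyntheticDatasetSpec",
    "synthesize_record",
    "add_noise",
    "generate_dataset",
    "snr_db",
]

#: Refractory floor for RR intervals (s); draws are truncated here so beats
#: never overlap non-physiologically.
MIN_RR = 0.2


@dataclass(frozen=True)
class BeatTemplate:
    """Sum-of-Gaussians P-QRS-T beat morphology.

    ``waves`` maps wave name -> (amplitude mV, center offset from R in s,
    Gaussian width in s).  The default template is a textbook lead-II-like
    beat with a dominant R wave.
    """

    waves: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "P": (0.15, -0.20, 0.025),
            "Q": (-0.10, -0.035, 0.010),
            "R": (1.00, 0.0, 0.012),
            "S": (-0.25, 0.035, 0.012),
            "T": (0.35, 0.25, 0.060),
        }
    )

    def __post_init__(self) -> None:
        for name, (_, _, width) in self.waves.items():
            if width <= 0:
                raise ValueError(f"wave {name}: width must be > 0")

    def scaled(self, amplitude: float) -> "BeatTemplate":
        return BeatTemplate(
            {k: (a * amplitude, c, w) for k, (a, c, w) in self.waves.items()}
        )

    def render(
        self,
        t: np.ndarray,
        r_time: float,
        include_p: bool = True,
        qrs_width_factor: float = 1.0,
    ) -> np.ndarray:
        """Evaluate the beat on time grid ``t`` with its R peak at ``r_time``."""
        out = np.zeros_like(t)
        for name, (amp, center, width) in self.waves.items():
            if name == "P" and not include_p:
                continue
            if name in ("Q", "R", "S"):
                width = width * qrs_width_factor
            out += amp * np.exp(-0.5 * ((t - r_time - center) / width) ** 2)
        return out


@dataclass(frozen=True)
class RhythmSpec:
    """Statistical description of one rhythm class.

    mean_rr and rr_cv set the RR-interval distribution; class ``A`` uses a
    log-normal (heavy right tail, matching irregularly irregular conduction)
    and the others a Gaussian, both truncated at 0.2 s.
    """

    class_label: str
    mean_rr: float = 0.85
    rr_cv: float = 0.03
    p_wave_present: bool = True
    fib_amplitude: float = 0.0  # mV
    fib_freq: float = 7.0  # Hz, atrial fibrillatory oscillation
    ectopic_prob: float = 0.0
    target_snr_db: float | None = None

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        if self.mean_rr <= 0:
            raise ValueError("mean RR must be > 0")
        if self.rr_cv < 0:
            raise ValueError("RR CV must be >= 0")

    @classmethod
    def for_class(cls, label: str) -> "RhythmSpec":
        """Default per-class specs (the study conditions for synthetic runs)."""
        defaults = {
            "N": cls("N", mean_rr=0.85, rr_cv=0.03, p_wave_present=True),
            "A": cls(
                "A",
                mean_rr=0.70,
                rr_cv=0.20,
                p_wave_present=False,
                fib_amplitude=0.05,
                fib_freq=7.0,
            ),
            "O": cls("O", mean_rr=0.80, rr_cv=0.06, ectopic_prob=0.18),
            "~": cls("~", mean_rr=0.85, rr_cv=0.03, target_snr_db=-3.0),
        }
        if label not in defaults:
            raise ValueError(f"unknown class {label!r}")
        return defaults[label]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive contamination; all amplitudes in mV, rates in events/s."""

    baseline_amp: float = 0.0
    baseline_freq: float = 0.3  # respiration-scale drift
    powerline_amp: float = 0.0
    powerline_freq: float = 50.0
    broadband_sd: float = 0.0
    impulse_rate: float = 0.0
    impulse_amp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("baseline_amp", "powerline_amp", "broadband_sd",
                     "impulse_rate", "impulse_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def quiet(cls) -> "NoiseSpec":
        return cls()

    @classmethod
    def ambulatory(cls) -> "NoiseSpec":
        """A realistic ambulatory mix: visible wander, mains hum, muscle noise."""
        return cls(
            baseline_amp=0.25,
            baseline_freq=0.3,
            powerline_amp=0.05,
            powerline_freq=50.0,
            broadband_sd=0.04,
            impulse_rate=0.1,
            impulse_amp=0.6,
        )

    def is_silent(self) -> bool:
        return (
            self.baseline_amp == 0
            and self.powerline_amp == 0
            and self.broadband_sd == 0
            and (self.impulse_rate == 0 or self.impulse_amp == 0)
        )


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """A labelled dataset: ``records_per_class`` per rhythm class, durations
    drawn uniformly from ``duration_range`` (the 9-61 s span of the challenge
    recordings), all randomness derived from ``master_seed``."""

    records_per_class: int = 10
    duration_range: tuple[float, float] = (9.0, 61.0)
    fs: float = 300.0
    master_seed: int = 0
    noise: NoiseSpec = field(default_factory=NoiseSpec.ambulatory)
    classes: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        if self.records_per_class < 0:
            raise ValueError("records_per_class must be >= 0")
        lo, hi = self.duration_range
        if not (0 < lo <= hi):
            raise ValueError("invalid duration range")


def _draw_rr_intervals(
    rhythm: RhythmSpec, total_duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw enough RR intervals to cover ``total_duration`` seconds."""
    n_guess = int(np.ceil(total_duration / max(rhythm.mean_rr, MIN_RR))) + 10
    out: list[float] = []
    while sum(out) < total_duration:
        if rhythm.class_label == "A" and rhythm.rr_cv > 0:
            sigma2 = np.log1p(rhythm.rr_cv**2)
            mu = np.log(rhythm.mean_rr) - sigma2 / 2.0
            draws = rng.lognormal(mu, np.sqrt(sigma2), size=n_guess)
        else:
            draws = rng.normal(rhythm.mean_rr, rhythm.rr_cv * rhythm.mean_rr, size=n_guess)
        out.extend(np.maximum(draws, MIN_RR))
    return np.asarray(out)


def _render_clean(
    rhythm: RhythmSpec,
    duration: float,
    fs: float,
    rng: np.random.Generator,
    template: BeatTemplate,
) -> np.ndarray:
    n = int(np.floor(duration * fs))
    t = np.arange(n) / fs
    signal = np.zeros(n)
    rr = _draw_rr_intervals(rhythm, duration + 2.0, rng)
    r_times = np.cumsum(rr) - rr[0] + 0.35  # first beat shortly after onset
    for r_time in r_times:
        if r_time > duration + 0.5:
            break
        ectopic = rhythm.ectopic_prob > 0 and rng.random() < rhythm.ectopic_prob
        if ectopic:
            r_time = max(r_time - 0.35 * rhythm.mean_rr, 0.0)
        include_p = rhythm.p_wave_present and not ectopic
        qrs_factor = 1.8 if ectopic else 1.0
        # only evaluate near the beat for speed
        lo = max(int((r_time - 0.6) * fs), 0)
        hi = min(int((r_time + 0.6) * fs), n)
        if hi > lo:
            signal[lo:hi] += template.render(
                t[lo:hi], r_time, include_p=include_p, qrs_width_factor=qrs_factor
            )
    if rhythm.fib_amplitude > 0:
        # coarse fibrillatory baseline: amplitude-jittered oscillation
        phase = rng.uniform(0, 2 * np.pi)
        wobble = 1.0 + 0.3 * np.sin(2 * np.pi * 0.9 * t + rng.uniform(0, 2 * np.pi))
        signal += rhythm.fib_amplitude * wobble * np.sin(
            2 * np.pi * rhythm.fib_freq * t + phase
        )
    return signal


def _render_noise(
    n: int, noise: NoiseSpec, fs: float, rng: np.random.Generator
) -> np.ndarray:
    t = np.arange(n) / fs
    out = np.zeros(n)
    if noise.baseline_amp > 0:
        out += noise.baseline_amp * np.sin(
            2 * np.pi * noise.baseline_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.powerline_amp > 0:
        out += noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.broadband_sd > 0:
        out += rng.normal(0.0, noise.broadband_sd, size=n)
    if noise.impulse_rate > 0 and noise.impulse_amp > 0:
        n_events = rng.poisson(noise.impulse_rate * n / fs)
        if n_events > 0:
            idx = rng.integers(0, n, size=n_events)
            signs = rng.choice([-1.0, 1.0], size=n_events)
            out[idx] += signs * noise.impulse_amp
    return out


def add_noise(
    signal: np.ndarray, noise: NoiseSpec, fs: float, seed: int
) -> np.ndarray:
    """Add the configured contamination to ``signal``; length-preserving and
    deterministic per seed."""
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("signal must be non-empty")
    if fs <= 0:
        raise ValueError("fs must be > 0")
    rng = np.random.default_rng(seed)
    return signal + _render_noise(signal.size, noise, fs, rng)


def snr_db(clean: np.ndarray, noisy: np.ndarray) -> float:
    """10*log10(clean power / residual power) with residual = noisy - clean."""
    clean = np.asarray(clean, dtype=float)
    resid = np.asarray(noisy, dtype=float) - clean
    p_noise = float(np.mean(resid**2))
    if p_noise == 0:
        return float("inf")
    return 10.0 * np.log10(float(np.mean(clean**2)) / p_noise)


def synthesize_record(
    rhythm: RhythmSpec,
    noise: NoiseSpec,
    duration: float,
    fs: float = 300.0,
    seed: int = 0,
    template: BeatTemplate | None = None,
    record_id: str | None = None,
) -> ECGRecord:
    """Generate one labelled record of ``floor(duration * fs)`` samples.

    If ``rhythm.target_snr_db`` is set, the noise waveform is rescaled so the
    realized SNR equals the target; the clean signal, the realized SNR and
    the seed are stored in ``record.meta``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if fs <= 0:
        raise ValueError("fs must be > 0")
    template = template or BeatTemplate()
    rng = np.random.default_rng(seed)
    clean = _render_clean(rhythm, duration, fs, rng, template)
    noise_wave = _render_noise(clean.size, noise, fs, rng)

    if rhythm.target_snr_db is not None:
        p_clean = float(np.mean(clean**2))
        p_noise = float(np.mean(noise_wave**2))
        if p_noise == 0:
            # target SNR requested but the noise spec is silent: inject
            # broadband noise so the target is achievable
            noise_wave = rng.normal(0.0, 1.0, size=clean.size)
            p_noise = float(np.mean(noise_wave**2))
        target_p_noise = p_clean / 10.0 ** (rhythm.target_snr_db / 10.0)
        noise_wave = noise_wave * np.sqrt(target_p_noise / p_noise)

    samples = clean + noise_wave
    meta = {
        "seed": int(seed),
        "clean": clean,
        "snr_db": snr_db(clean, samples),
    }
    rid = record_id or f"S{rhythm.class_label}{seed:08d}"
    return ECGRecord(record_id=rid, fs=fs, samples=samples, label=rhythm.class_label, meta=meta)


def generate_dataset(
    spec: SyntheticDatasetSpec,
) -> tuple[list[ECGRecord], pd.DataFrame]:
    """Generate ``records_per_class`` records per class plus a manifest.

    Record seeds derive deterministically from the master seed via
    ``numpy.random.SeedSequence`` spawning, so the same spec always yields
    bit-identical records.  The manifest has columns
    (record_id, length, label, seed).
    """
    ss = np.random.SeedSequence(spec.master_seed)
    rows = []
    records: list[ECGRecord] = []
    lo, hi = spec.duration_range
    for ci, label in enumerate(spec.classes):
        rhythm = RhythmSpec.for_class(label)
        for i in range(spec.records_per_class):
            child = np.random.SeedSequence(
                entropy=spec.master_seed, spawn_key=(ci, i)
            )
            seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
            dur_rng = np.random.default_rng(seed + 1)
            duration = float(dur_rng.uniform(lo, hi))
            tag = "T" if label == "~" else label
            rec = synthesize_record(
                rhythm,
                spec.noise,
                duration=duration,
                fs=spec.fs,
                seed=seed,
                record_id=f"S{tag}{ci:01d}{i:05d}",
            )
            records.append(rec)
            rows.append((rec.record_id, len(rec), label, seed))
    manifest = pd.DataFrame(rows, columns=["record_id", "length", "label", "seed"])
    return records, manifest
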