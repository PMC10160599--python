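"""Synthetic 12-lead ECG with ground-truth R-peaks.

Beats are sums of Gaussian bumps for the P, Q, R, S and T waves placed along
a sampled RR sequence; rhythm classes differ in RR statistics and per-wave
morphology (AF: i.i.d. irregular RR at rapid rates with no P wave; PVC/PAC:
premature ectopic beats with a compensatory pause; bundle branch blocks:
widened QRS; I-AVB: prolonged PR; STD/STE: ST-segment offset). The same wave
placement is replicated on all 12 leads with fixed per-lead gains; baseline
wander, powerline and white noise are added last. Everything is
deterministic for a fixed seed.

This is a template model, not a dynamical one: it gives exact R-peak ground
truth and controllable morphology, which is what the detector and classifier
tests need; it does not model fibrillatory f-waves, respiration coupling or
realistic vectorcardiographic lead projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CapabilityError
from .records import ECGRecord, LabelTable, LEAD_NAMES, RhythmLabel

#: Fixed per-lead gains applied to the single synthesized waveform.
LEAD_GAINS = np.array(
    [0.6, 1.0, 0.4, -0.5, 0.3, 0.7, -0.4, 0.8, 1.1, 1.2, 1.0, 0.8]
)

#: Half-width of the QRS complex used for the record-edge truth rule, s.
QRS_HALF_S = 0.06

_RHYTHM_HR = {RhythmLabel.AF: 150.0}
_RHYTHM_CV = {RhythmLabel.AF: 0.30}
_DEFAULT_HR = 70.0
_DEFAULT_CV = 0.03
_RR_FLOOR_S = 0.26


@dataclass
class NoiseConfig:
    """Additive noise amplitudes, in millivolts."""

    baseline_wander_mV: float = 0.10
    powerline_mV: float = 0.05
    white_sd_mV: float = 0.02
    baseline_hz: float = 0.33
    powerline_hz: float = 50.0

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0)


@dataclass
class SynthConfig:
    fs: float = 500.0
    duration_s: float = 10.0
    rhythm: RhythmLabel = RhythmLabel.NORMAL
    mean_hr_bpm: float | None = None     # None -> rhythm default (AF 150, else 70)
    rr_cv: float | None = None           # None -> rhythm default (AF 0.30, else 0.03)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0
    ectopic_fraction: float = 0.15       # PVC / PAC only
    snr_db: float | None = None          # if set, overrides white_sd_mV per lead

    def __post_init__(self):
        if isinstance(self.rhythm, str):
            self.rhythm = RhythmLabel.from_code(self.rhythm)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 1.0 <= self.duration_s <= 600.0:
            raise ValueError("duration_s must lie in [1, 600]")
        hr = self.resolved_hr
        if not 20.0 <= hr <= 300.0:
            raise ValueError("mean_hr_bpm must lie in [20, 300]")
        if self.resolved_cv < 0:
            raise ValueError("rr_cv must be >= 0")

    @property
    def resolved_hr(self) -> float:
        if self.mean_hr_bpm is not None:
            return self.mean_hr_bpm
        return _RHYTHM_HR.get(self.rhythm, _DEFAULT_HR)

    @property
    def resolved_cv(self) -> float:
        if self.rr_cv is not None:
            return self.rr_cv
        return _RHYTHM_CV.get(self.rhythm, _DEFAULT_CV)


@dataclass
class SynthRecord:
    record: ECGRecord
    true_rpeaks: np.ndarray          # sample indices, strictly increasing
    beat_labels: list                # per true beat: "normal" | "ectopic"

    def __post_init__(self):
        self.true_rpeaks = np.asarray(self.true_rpeaks, dtype=int)
        if len(self.beat_labels) != len(self.true_rpeaks):
            raise ValueError("beat_labels must align with true_rpeaks")
        if np.any(np.diff(self.true_rpeaks) <= 0):
            raise ValueError("true_rpeaks must be strictly increasing")


_SUPPORTED = set(RhythmLabel)


def _rr_sequence(config: SynthConfig, rng: np.random.Generator):
    """Sample RR intervals (s) covering the record, plus per-beat ectopy."""
    mean_rr = 60.0 / config.resolved_hr
    sd = config.resolved_cv * mean_rr
    n_max = int(np.ceil(config.duration_s / max(mean_rr * 0.4, _RR_FLOOR_S))) + 4
    if config.rhythm is RhythmLabel.AF:
        rr = rng.normal(mean_rr, sd, size=n_max)
    else:
        rr = rng.normal(mean_rr, sd, size=n_max)
    rr = np.maximum(rr, _RR_FLOOR_S)
    ectopic = np.zeros(n_max, dtype=bool)
    if config.rhythm in (RhythmLabel.PVC, RhythmLabel.PAC):
        candidates = rng.random(n_max) < config.ectopic_fraction
        for k in range(1, n_max - 1):
            if candidates[k] and not ectopic[k - 1]:
                ectopic[k] = True
                rr[k - 1] *= 0.65                  # premature arrival at beat k
                pause = 1.5 if config.rhythm is RhythmLabel.PVC else 1.2
                rr[k] *= pause                     # (near-)compensatory pause
    return rr, ectopic


def _beat_waves(config: SynthConfig, rr_local: float, is_ectopic: bool):
    """(offset_s, sigma_s, amplitude_mV) triples for one beat, R at offset 0."""
    r = float(np.clip(rr_local, 0.3, 1.2))
    rhythm = config.rhythm
    p = (-0.21 * r, 0.025, 0.12)
    q = (-0.025, 0.010, -0.12)
    rw = (0.0, 0.012, 1.0)
    s = (0.025, 0.010, -0.20)
    t = (0.30 * r, 0.060, 0.28)
    waves = []
    if rhythm is RhythmLabel.AF:
        p = None                                   # absent P wave
    elif rhythm is RhythmLabel.IAVB:
        p = (-0.32, 0.025, 0.12)                   # PR interval > 300 ms
    elif rhythm in (RhythmLabel.LBBB, RhythmLabel.RBBB):
        q = (-0.045, 0.022, -0.10)
        rw = (0.0, 0.026, 0.9)
        s = (0.045, 0.022, -0.18)
        if rhythm is RhythmLabel.RBBB:
            waves.append((0.075, 0.018, 0.30))     # R' notch
    elif rhythm is RhythmLabel.STD:
        waves.append((0.11, 0.05, -0.15))          # ST depression
    elif rhythm is RhythmLabel.STE:
        waves.append((0.11, 0.05, 0.20))           # ST elevation
    if is_ectopic:
        if rhythm is RhythmLabel.PVC:
            p = None
            q = (-0.055, 0.025, -0.15)
            rw = (0.0, 0.030, 1.1)
            s = (0.055, 0.025, -0.25)
            t = (0.30 * r, 0.060, -0.25)           # discordant T
        else:                                      # PAC: early low P, normal QRS
            p = (-0.16 * r, 0.020, 0.08)
    waves = [w for w in [p, q, rw, s, t] if w is not None] + waves
    return waves


def _render(config: SynthConfig, rng: np.random.Generator):
    fs = config.fs
    n = int(round(config.duration_s * fs))
    rr, ectopic = _rr_sequence(config, rng)
    t0 = 0.35 + 0.1 * rng.random()
    centers_s = t0 + np.concatenate([[0.0], np.cumsum(rr[:-1])])
    waveform = np.zeros(n)
    truth, beat_labels = [], []
    margin = int(round(QRS_HALF_S * fs))
    for k, c_s in enumerate(centers_s):
        c = int(round(c_s * fs))
        if c_s > config.duration_s + 0.4:
            break
        rr_local = rr[k - 1] if k > 0 else rr[0]
        for off, sig, amp in _beat_waves(config, rr_local, bool(ectopic[k])):
            mu = c + off * fs
            half = int(np.ceil(5 * sig * fs))
            lo = max(0, int(mu) - half)
            hi = min(n, int(mu) + half + 1)
            if hi <= lo:
                continue
            idx = np.arange(lo, hi)
            waveform[lo:hi] += amp * np.exp(-0.5 * ((idx - mu) / (sig * fs)) ** 2)
        # partial beats are synthesized above; ground truth keeps only beats
        # whose full QRS complex lies inside the record
        if margin <= c < n - margin:
            truth.append(c)
            beat_labels.append("ectopic" if ectopic[k] else "normal")
    return waveform, np.asarray(truth, dtype=int), beat_labels


def generate_record(config: SynthConfig) -> SynthRecord:
    """Generate one labelled 12-lead record with ground-truth R-peak indices."""
    if config.rhythm not in _SUPPORTED:
        raise CapabilityError(f"rhythm {config.rhythm} not supported by the generator")
    rng = np.random.default_rng(config.seed)
    waveform, truth, beat_labels = _render(config, rng)
    n = waveform.size
    signal = LEAD_GAINS[:, None] * waveform[None, :]
    noise = config.noise
    tt = np.arange(n) / config.fs
    if noise.baseline_wander_mV > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += noise.baseline_wander_mV * np.sin(
            2 * np.pi * noise.baseline_hz * tt + phase
        )
    if noise.powerline_mV > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += noise.powerline_mV * np.sin(
            2 * np.pi * noise.powerline_hz * tt + phase
        )
    if config.snr_db is not None:
        power = np.mean(signal ** 2, axis=1, keepdims=True)
        sd = np.sqrt(power / 10.0 ** (config.snr_db / 10.0))
        signal = signal + sd * rng.normal(size=signal.shape)
    elif noise.white_sd_mV > 0:
        signal = signal + noise.white_sd_mV * rng.normal(size=signal.shape)
    sex = "Male" if rng.random() < 0.5 else "Female"
    age = int(rng.integers(25, 85))
    record = ECGRecord(
        record_id=f"SYN-{config.rhythm.code}-{config.seed % 10**8:08d}",
        signal=signal,
        fs=config.fs,
        sex=sex,
        age=age,
        labels=[config.rhythm],
    )
    return SynthRecord(record=record, true_rpeaks=truth, beat_labels=beat_labels)


def generate_dataset(n_per_class: int, classes, base_config: SynthConfig | None = None,
                     seed: int = 0):
    """Generate ``n_per_class`` records for every class.

    Per-record seeds are spawned deterministically from (seed, class ordinal,
    index), so records are pairwise distinct and any subset is reproducible.
    Returns (list of SynthRecord, LabelTable).
    """
    classes = [RhythmLabel.from_code(c) if isinstance(c, str) else c for c in classes]
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not classes:
        raise ValueError("classes must not be empty")
    base = base_config if base_config is not None else SynthConfig()
    out, table = [], LabelTable()
    for rhythm in classes:
        for index in range(n_per_class):
            sub = np.random.SeedSequence([seed, rhythm.ordinal, index])
            rec_seed = int(sub.generate_state(1)[0] % (2 ** 31))
            config = replace(
                base, rhythm=rhythm, seed=rec_seed,
                mean_hr_bpm=base.mean_hr_bpm, rr_cv=base.rr_cv,
            )
            sr = generate_record(config)
            sr.record.record_id = f"SYN-{rhythm.code}-{index:04d}"
            out.append(sr)
            table[sr.record.record_id] = [rhythm]
    return out, table
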