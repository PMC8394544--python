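"""Synthetic RR/ECG cohort generation.

The generator produces overnight RR tachograms with the statistical structure
the downstream analysis assumes: band-limited oscillations in the classic
VLF/LF/HF ranges, an apnea-cycle component inside 0.028-0.074 Hz whose
amplitude grows with the simulated apnea-hypopnea index (AHI), a respiratory
oscillation that sets the subject-adaptive BWRes band, optional quadratically
phase-coupled triads (f3 = f1 + f2, phi3 = phi1 + phi2), additive noise, and
injected ectopic/artifact beats that exercise every rejection clause.  It is a
test fixture with controllable spectra, not a physiological model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RRSeries, UniformHRV

#: Pediatric severity partition on AHI (events/hour).
SEVERITY_CUTOFFS = (1.0, 5.0, 10.0)
SEVERITY_LABELS = ("none", "mild", "moderate", "severe")

#: OSA-specific apnea-cycle band (Hz); the apnea component must live here.
APNEA_BAND = (0.028, 0.074)

NYQUIST_HRV = 3.41 / 2.0


def severity_from_ahi(ahi: float) -> str:
    """Map AHI (events/hour) to the four-group pediatric severity label.

    none: AHI < 1; mild: 1 <= AHI < 5; moderate: 5 <= AHI < 10; severe: >= 10.
    """
    if ahi < 0:
        raise ValueError("AHI must be non-negative")
    if ahi < 1:
        return "none"
    if ahi < 5:
        return "mild"
    if ahi < 10:
        return "moderate"
    return "severe"


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    ahi: float
    age: float
    seed: int

    def __post_init__(self) -> None:
        if self.ahi < 0:
            raise ValueError("AHI must be non-negative")
        if not 0 <= self.age <= 13:
            raise ValueError("age must be within the pediatric range 0-13 years")

    @property
    def severity(self) -> str:
        return severity_from_ahi(self.ahi)


@dataclass(frozen=True)
class Component:
    """One oscillatory tachogram component.

    amplitude(AHI) = max(0, amplitude + slope * AHI), in seconds.
    """

    label: str
    freq: float
    amplitude: float
    slope: float = 0.0

    def amp_at(self, ahi: float) -> float:
        return max(0.0, self.amplitude + self.slope * ahi)


def default_components(respiratory_freq: float = 0.25) -> tuple[Component, ...]:
    """Cohort-default oscillations.

    Amplitudes are in the few-tens-of-milliseconds range typical of pediatric
    overnight RR modulation.  The apnea-cycle component (0.055 Hz, inside
    0.028-0.074 Hz) starts near zero and grows ~2 ms per AHI unit, so a severe
    subject (AHI 15) carries ~30 ms of apnea-band modulation; the respiratory
    component shrinks mildly with severity, mimicking the redistribution of
    HRV power toward apneic frequencies.
    """
    return (
        Component("vlf", 0.015, 0.020),
        Component("lf", 0.090, 0.030),
        Component("resp", respiratory_freq, 0.030, -0.0005),
        Component("apnea", 0.055, 0.002, 0.0020),
    )


@dataclass(frozen=True)
class SimulationConfig:
    duration: float = 3.6 * 3600.0  # seconds; leaves >= 3 h after 2x15 min trim
    mean_rr: float = 0.70  # s; ~86 bpm, a typical sleeping child
    components: tuple[Component, ...] = field(default_factory=default_components)
    respiratory_freq: float = 0.25
    qpc_pairs: tuple[tuple[float, float, bool], ...] = ()
    noise_sd: float = 0.015  # s, beat-to-beat white noise
    artifact_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.15 <= self.respiratory_freq <= 0.40:
            raise ValueError("respiratory_freq must lie in [0.15, 0.40] Hz")
        for c in self.components:
            if c.freq >= NYQUIST_HRV:
                raise ValueError(
                    f"component {c.label!r} at {c.freq} Hz is at/above Nyquist"
                )
            if c.label == "apnea" and not (
                APNEA_BAND[0] <= c.freq <= APNEA_BAND[1]
            ):
                raise ValueError("apnea component must lie in 0.028-0.074 Hz")
        if not 0 <= self.artifact_rate < 1:
            raise ValueError("artifact_rate must be a fraction in [0, 1)")


def _with_respiration(config: SimulationConfig) -> SimulationConfig:
    """Re-pin the 'resp' component to config.respiratory_freq."""
    comps = tuple(
        replace(c, freq=config.respiratory_freq) if c.label == "resp" else c
        for c in config.components
    )
    return replace(config, components=comps)


def simulate_rr(profile: SubjectProfile, config: SimulationConfig) -> RRSeries:
    """Generate a raw RR series for one subject.

    The tachogram is RR(t) = mean_rr + sum_i a_i(AHI) cos(2 pi f_i t + phi_i)
    (+ QPC triads) + noise, realized at beat times by iterating
    t_{k+1} = t_k + RR(t_k) (integrate-and-fire on the instantaneous rate).
    A fraction ``artifact_rate`` of beats is then replaced by implausible
    values: short beats (0.2 s), long beats (2.0 s) and 0.8 s step jumps in
    equal proportion.  Deterministic given ``profile.seed``.
    """
    config = _with_respiration(config)
    if config.duration - 2 * 15 * 60.0 < 3 * 3600.0:
        raise ValueError(
            "duration too short: trimming 2x15 min must leave >= 3 h"
        )
    rng = np.random.default_rng(profile.seed)
    amps = np.array([c.amp_at(profile.ahi) for c in config.components])
    freqs = np.array([c.freq for c in config.components])
    phases = rng.uniform(-np.pi, np.pi, size=len(config.components))

    qpc_terms = []
    for f1, f2, coupled in config.qpc_pairs:
        p1, p2 = rng.uniform(-np.pi, np.pi, size=2)
        p3 = p1 + p2 if coupled else rng.uniform(-np.pi, np.pi)
        qpc_terms.append((f1, f2, f1 + f2, p1, p2, p3))
    qpc_amp = 0.01  # 10 ms per triad member

    def rr_of(t: float) -> float:
        val = config.mean_rr + float(np.sum(amps * np.cos(2 * np.pi * freqs * t + phases)))
        for f1, f2, f3, p1, p2, p3 in qpc_terms:
            val += qpc_amp * (
                np.cos(2 * np.pi * f1 * t + p1)
                + np.cos(2 * np.pi * f2 * t + p2)
                + np.cos(2 * np.pi * f3 * t + p3)
            )
        return val

    # integrate-and-fire beat placement
    times: list[float] = []
    vals: list[float] = []
    t = 0.0
    while t < config.duration:
        rr = rr_of(t)
        if config.noise_sd > 0:
            rr += rng.normal(0.0, config.noise_sd)
        rr = max(rr, 0.2)  # guard against non-physical negative intervals
        t += rr
        times.append(t)
        vals.append(rr)
    beat_times = np.asarray(times)
    intervals = np.asarray(vals)

    if config.artifact_rate > 0:
        n = intervals.size
        n_art = int(round(config.artifact_rate * n))
        idx = rng.choice(n, size=n_art, replace=False)
        modes = rng.integers(0, 3, size=n_art)
        for i, m in zip(idx, modes):
            if m == 0:
                intervals[i] = 0.2  # implausibly short
            elif m == 1:
                intervals[i] = 2.0  # implausibly long
            else:
                intervals[i] = intervals[i] + 0.8  # step jump > 0.66 s

    return RRSeries(beat_times=beat_times, intervals=intervals)


def simulate_qpc_signal(
    f1: float,
    f2: float,
    coupled: bool,
    n: int,
    fs: float,
    seed: int,
    noise_sd: float = 0.1,
    amplitude: float = 1.0,
) -> UniformHRV:
    """Three-cosine quadratic-phase-coupling fixture.

    x(t) = A [cos(2 pi f1 t + phi1) + cos(2 pi f2 t + phi2)
              + cos(2 pi (f1+f2) t + phi3)] + noise,
    with phi3 = phi1 + phi2 when ``coupled`` and an independent uniform phase
    otherwise.  Phases are random per realization (per seed).
    """
    if f1 + f2 >= fs / 2:
        raise ValueError("f1 + f2 must be below Nyquist")
    rng = np.random.default_rng(seed)
    p1, p2 = rng.uniform(-np.pi, np.pi, size=2)
    p3 = p1 + p2 if coupled else rng.uniform(-np.pi, np.pi)
    t = np.arange(n) / fs
    x = amplitude * (
        np.cos(2 * np.pi * f1 * t + p1)
        + np.cos(2 * np.pi * f2 * t + p2)
        + np.cos(2 * np.pi * (f1 + f2) * t + p3)
    )
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n)
    return UniformHRV(values=x, fs=fs, t0=0.0)


def _qrs_template(fs: float, width: float = 0.03) -> np.ndarray:
    """Narrow Gaussian spike standing in for the QRS complex."""
    half = int(round(4 * width * fs))
    tt = np.arange(-half, half + 1) / fs
    return np.exp(-0.5 * (tt / width) ** 2)


def simulate_ecg(
    rr: RRSeries, fs: float, seed: int, noise_sd: float = 0.02
) -> "ECGRecord":
    """Place a QRS-like template at cumulative beat times on a noisy baseline.

    The template peak coincides with each beat time to within one sample.
    """
    from .preprocess import ECGRecord

    if fs < 100:
        raise ValueError("ECG sampling rate must be >= 100 Hz")
    rng = np.random.default_rng(seed)
    dur = float(rr.beat_times[-1]) + 1.0
    n = int(np.ceil(dur * fs))
    x = np.zeros(n)
    tmpl = _qrs_template(fs)
    half = tmpl.size // 2
    # include the beat opening the first interval so that interval is
    # recoverable; beats whose template would be clipped by the record edge
    # are skipped (a clipped complex is not a detectable QRS)
    all_beats = np.concatenate(([rr.beat_times[0] - rr.intervals[0]], rr.beat_times))
    for bt in all_beats:
        c = int(round(bt * fs))
        lo, hi = c - half, c + half + 1
        if lo < 0 or hi > n:
            continue
        x[lo:hi] += tmpl
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n)
    return ECGRecord(samples=x, fs=fs, start_offset=0.0)


# ---------------------------------------------------------------------------
# cohorts


def sample_ahi(
    rng: np.random.Generator,
    mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> float:
    """Draw one AHI from a severity-group mixture.

    ``mix`` gives (none, mild, moderate, severe) weights; within a group the
    AHI is uniform on the group's interval (severe: 10-30 e/h).
    """
    w = np.asarray(mix, dtype=float)
    if w.min() < 0 or w.sum() <= 0:
        raise ValueError("mixture weights must be non-negative and sum > 0")
    w = w / w.sum()
    g = rng.choice(4, p=w)
    bounds = [(0.0, 1.0), (1.0, 5.0), (5.0, 10.0), (10.0, 30.0)]
    lo, hi = bounds[g]
    return float(rng.uniform(lo, hi))


def generate_cohort(
    n: int,
    seed: int,
    ahi_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    config: SimulationConfig | None = None,
    respiratory_jitter: float = 0.05,
) -> list[tuple[SubjectProfile, SimulationConfig]]:
    """Draw ``n`` subject profiles with per-subject seeds and configurations.

    Subject seeds derive from the cohort seed by counter; respiratory
    frequency varies subject-to-subject (uniform around the config default)
    so the BWRes band is genuinely subject-adaptive.
    """
    base = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        ahi = sample_ahi(rng, ahi_mix)
        age = float(rng.uniform(2.0, 13.0))
        rf = float(
            np.clip(
                base.respiratory_freq
                + rng.uniform(-respiratory_jitter, respiratory_jitter),
                0.16,
                0.39,
            )
        )
        profile = SubjectProfile(
            subject_id=f"S{i:04d}", ahi=ahi, age=age, seed=seed * 100_000 + i
        )
        out.append((profile, replace(base, respiratory_freq=rf)))
    return out


def write_cohort(
    cohort: list[tuple[SubjectProfile, SimulationConfig]],
    out_dir: str | Path,
) -> pd.DataFrame:
    """Simulate and write RR files plus a CSV manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for profile, cfg in cohort:
        rr = simulate_rr(profile, cfg)
        path = out_dir / f"{profile.subject_id}.rr.txt"
        np.savetxt(path, rr.intervals, fmt="%.6f")
        rows.append(
            {
                "subject_id": profile.subject_id,
                "ahi": profile.ahi,
                "age": profile.age,
                "severity": profile.severity,
                "path": str(path),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
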