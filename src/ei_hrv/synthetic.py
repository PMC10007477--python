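"""Synthetic RR series, ECG, cohorts and questionnaire responses.

Every downstream stage of the pipeline is testable against these generators'
known ground truth.  The RR generator modulates the interval sequence
additively with sinusoids — an analytically tractable way to place spectral
power at chosen frequencies in the VLF/LF/HF bands — rather than an
integral-pulse-frequency-modulation model; see the methods note for what
this does and does not emulate.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import feature_names
from .ecg import EcgRecord
from .rr import RrSeries
from .scoring import DOMAINS

MAX_NOISE_RETRIES = 10
SCORE_GRANULARITY = 10
SCORE_MAX = 1200


class DegenerateSpecError(ValueError):
    """Raised when a generator spec cannot produce a valid output."""


@dataclass(frozen=True)
class RrGenSpec:
    """Specification of a synthetic RR series.

    ``modulations`` is a list of (amplitude ms, frequency Hz, phase rad)
    sinusoids added to the mean interval; frequencies must lie in (0, 0.5]
    Hz, i.e. below the beat-to-beat Nyquist limit of a typical tachogram.
    """

    mean_rr: float = 800.0
    modulations: tuple[tuple[float, float, float], ...] = ()
    noise_sd: float = 0.0
    duration: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "modulations", tuple(tuple(m) for m in self.modulations))
        if self.mean_rr <= 0:
            raise DegenerateSpecError("mean_rr must be positive")
        if self.duration <= 0:
            raise DegenerateSpecError("duration must be positive")
        if self.noise_sd < 0:
            raise DegenerateSpecError("noise_sd must be non-negative")
        for amp, freq, _ in self.modulations:
            if not 0 < freq <= 0.5:
                raise DegenerateSpecError(f"modulation frequency {freq} outside (0, 0.5] Hz")
            if amp < 0:
                raise DegenerateSpecError("modulation amplitude must be non-negative")


def generate_rr_series(spec: RrGenSpec) -> RrSeries:
    """Generate beat times as cumulative sums of modulated intervals.

    Interval *i*, generated at the current beat time *t*, is
    ``mean_rr + Σ A·sin(2π f t + φ) + N(0, noise_sd)`` ms.  A draw that
    would make the interval non-positive is redrawn up to 10 times before
    the spec is declared degenerate — no silent clipping.
    """
    rng = np.random.default_rng(spec.seed)
    times = [0.0]
    intervals: list[float] = []
    t = 0.0
    while True:
        base = spec.mean_rr
        for amp, freq, phase in spec.modulations:
            base += amp * np.sin(2 * np.pi * freq * t + phase)
        iv = base + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
        retries = 0
        while iv <= 0 and retries < MAX_NOISE_RETRIES:
            iv = base + rng.normal(0.0, spec.noise_sd)
            retries += 1
        if iv <= 0:
            raise DegenerateSpecError(
                f"non-positive interval at t={t:.2f} s after {MAX_NOISE_RETRIES} retries"
            )
        t_next = t + iv / 1000.0
        if t_next > spec.duration:
            break
        intervals.append(iv)
        times.append(t_next)
        t = t_next
    if len(intervals) < 1:
        raise DegenerateSpecError("duration too short for a single interval")
    return RrSeries(beat_times=np.asarray(times), intervals=np.asarray(intervals))


def synthesize_ecg(
    rr: RrSeries,
    fs: float = 500.0,
    template_width: float = 40.0,
    participant_id: str = "synthetic",
) -> EcgRecord:
    """Place a QRS-like unit-amplitude Gaussian spike at each beat time.

    ``template_width`` (ms) is the nominal full width of the spike (≈6
    standard deviations); the baseline is 0.  Beats closer together than the
    template width would overlap and raise.
    """
    if fs < 100:
        raise ValueError(f"sampling rate {fs} Hz too low; need >= 100 Hz")
    if rr.n_beats < 1:
        raise ValueError("empty RR series")
    if rr.intervals.min() < template_width:
        raise ValueError(
            f"beat spacing {rr.intervals.min():.0f} ms below template width "
            f"{template_width:.0f} ms; spikes would overlap"
        )
    sigma_s = (template_width / 1000.0) / 6.0
    pad = 3 * sigma_s
    duration = rr.beat_times[-1] + pad
    t = np.arange(int(np.ceil(duration * fs)) + 1) / fs
    x = np.zeros_like(t)
    half = int(np.ceil(4 * sigma_s * fs))
    for beat in rr.beat_times:
        center = int(round(beat * fs))
        lo, hi = max(0, center - half), min(t.size, center + half + 1)
        x[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - beat) / sigma_s) ** 2)
    return EcgRecord(samples=x, fs=fs, participant_id=participant_id)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic participant cohort.

    ``effect_map`` maps feature names (HRV index or dynamics-derived name) to
    a standardised mean difference d: high-group values are shifted by
    ``d * sigma`` relative to the low group.  Scores are multiples of 10 in
    [0, 1200], with the low group strictly below ``score_cut``.
    """

    n_low: int = 22
    n_high: int = 26
    score_cut: int = 820
    effect_map: dict = field(default_factory=dict)
    index_sd: float | dict = 1.0
    index_mean: float | dict = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_low + self.n_high < 2:
            raise DegenerateSpecError("cohort needs at least 2 participants")
        if self.n_low < 0 or self.n_high < 0:
            raise DegenerateSpecError("group sizes must be non-negative")
        if not 0 < self.score_cut <= SCORE_MAX:
            raise DegenerateSpecError(f"score_cut must be in (0, {SCORE_MAX}]")
        known = set(feature_names())
        unknown = [k for k in self.effect_map if k not in known]
        if unknown:
            raise DegenerateSpecError(f"unknown feature name(s) in effect_map: {unknown}")

    def sd_of(self, name: str) -> float:
        if isinstance(self.index_sd, dict):
            return float(self.index_sd.get(name, 1.0))
        return float(self.index_sd)

    def mean_of(self, name: str) -> float:
        if isinstance(self.index_mean, dict):
            return float(self.index_mean.get(name, 0.0))
        return float(self.index_mean)


def generate_cohort(
    spec: CohortSpec, features: list[str] | None = None
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Generate (feature table, score vector, ground-truth labels).

    For each feature f the low group is Normal(mu_f, sigma_f) and the high
    group Normal(mu_f + d_f * sigma_f, sigma_f), with d_f from the effect
    map (0 where absent).  Scores are uniform multiples of 10 strictly below
    ``score_cut`` for the low group and at or above it for the high group.
    Labels are 0 (low) / 1 (high).
    """
    rng = np.random.default_rng(spec.seed)
    if features is None:
        features = feature_names()
    n = spec.n_low + spec.n_high
    labels = np.r_[np.zeros(spec.n_low, dtype=int), np.ones(spec.n_high, dtype=int)]

    table = {}
    for f in features:
        mu, sd = spec.mean_of(f), spec.sd_of(f)
        d = float(spec.effect_map.get(f, 0.0))
        vals = rng.normal(mu, sd, size=n)
        vals[labels == 1] += d * sd
        table[f] = vals

    low_choices = np.arange(0, spec.score_cut, SCORE_GRANULARITY)
    high_choices = np.arange(spec.score_cut, SCORE_MAX + 1, SCORE_GRANULARITY)
    scores = np.concatenate(
        [
            rng.choice(low_choices, size=spec.n_low),
            rng.choice(high_choices, size=spec.n_high),
        ]
    ).astype(float)
    return pd.DataFrame(table), scores, labels


def generate_responses(
    n_items: int,
    accuracy: float,
    domain: str,
    seed: int = 0,
    evaluation: str = "self_awareness",
) -> pd.DataFrame:
    """Response table with exactly ``round(n_items * accuracy)`` correct items.

    Correct items match the target domain on arousal half, valence half and
    keyword (and are flagged recognised); incorrect items mismatch on at
    least one field.  Columns follow the response-CSV layout.
    """
    if not 0 <= accuracy <= 1:
        raise ValueError("accuracy must be in [0, 1]")
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    rng = np.random.default_rng(seed)
    n_correct = int(round(n_items * accuracy))

    high_arousal = domain[0] == "H"
    high_valence = domain[2] == "H"

    def likert(high: bool) -> int:
        return int(rng.integers(5, 8)) if high else int(rng.integers(1, 4))

    rows = []
    for i in range(n_items):
        correct = i < n_correct
        if correct:
            rows.append(
                dict(
                    evaluation=evaluation,
                    target_domain=domain,
                    arousal=likert(high_arousal),
                    valence=likert(high_valence),
                    keyword=domain,
                    recognized=True,
                    stimulus_id=i,
                )
            )
        else:
            # mismatch mode: wrong keyword, midpoint rating, or unrecognised
            mode = rng.integers(0, 3)
            rows.append(
                dict(
                    evaluation=evaluation,
                    target_domain=domain,
                    arousal=4 if mode == 1 else likert(high_arousal),
                    valence=likert(high_valence),
                    keyword="neutral" if mode != 1 else domain,
                    recognized=False,
                    stimulus_id=i,
                )
            )
    frame = pd.DataFrame(rows)
    return frame.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(
        drop=True
    )
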