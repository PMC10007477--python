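"""RR-interval series: the substrate of all HRV computation.

An :class:`RrSeries` holds beat times (seconds, strictly increasing) and the
inter-beat (RR) intervals in milliseconds, together with per-interval quality
flags.  Intervals flagged ``rejected`` are excluded from every downstream
statistic; they are never silently dropped from the container so that
absolute timing is preserved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Physiological plausibility bounds for an RR interval, in ms.
DEFAULT_RR_BOUNDS = (300.0, 2000.0)

#: Maximum relative deviation from the local running median before an
#: interval is flagged as an artifact.
DEFAULT_MEDIAN_TOLERANCE = 0.25

#: Fraction of rejected intervals above which an epoch is considered unusable.
DEFAULT_MAX_REJECT_FRACTION = 0.20


class RrValidationError(ValueError):
    """Raised when beat times or intervals violate the container invariants."""


class EpochQualityError(ValueError):
    """Raised when too many intervals in an epoch are flagged as artifacts."""


@dataclass(frozen=True)
class Epoch:
    """A labelled segment of the recording session.

    Parameters
    ----------
    start, end : float
        Segment boundaries in seconds from record start; half-open
        ``[start, end)``.
    kind : str
        One of ``baseline_neutral``, ``stimulus``, ``post_neutral``.
    domain : str
        Emotional-domain label (``HAHV``/``HALV``/``LALV``/``LAHV``) or
        ``none`` for neutral segments.
    """

    start: float
    end: float
    kind: str = "stimulus"
    domain: str = "none"

    KINDS = ("baseline_neutral", "stimulus", "post_neutral")
    DOMAINS = ("HAHV", "HALV", "LALV", "LAHV", "none")

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"epoch end ({self.end}) must exceed start ({self.start})")
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown epoch kind {self.kind!r}; expected one of {self.KINDS}")
        if self.domain not in self.DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}; expected one of {self.DOMAINS}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def __contains__(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass(frozen=True)
class RrSeries:
    """Beat times and inter-beat intervals.

    Attributes
    ----------
    beat_times : ndarray of float
        Beat (R-peak) times in seconds, strictly increasing.
    intervals : ndarray of float
        RR intervals in ms; ``intervals[i] == 1000 * (beat_times[i+1] -
        beat_times[i])``.
    quality : ndarray of bool
        Per-interval flag, ``True`` where the interval is retained.
    """

    beat_times: np.ndarray
    intervals: np.ndarray
    quality: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        beat_times = np.asarray(self.beat_times, dtype=float)
        intervals = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "beat_times", beat_times)
        object.__setattr__(self, "intervals", intervals)
        if beat_times.ndim != 1:
            raise RrValidationError("beat_times must be one-dimensional")
        if beat_times.size < 2:
            raise RrValidationError("an RR series needs at least 2 beats")
        if np.any(np.diff(beat_times) <= 0):
            raise RrValidationError("beat times must be strictly increasing")
        if intervals.shape != (beat_times.size - 1,):
            raise RrValidationError(
                f"expected {beat_times.size - 1} intervals, got {intervals.size}"
            )
        if not np.allclose(intervals, 1000.0 * np.diff(beat_times), rtol=0, atol=1e-6):
            raise RrValidationError("intervals do not match 1000 * diff(beat_times)")
        if self.quality is None:
            quality = np.ones(intervals.size, dtype=bool)
        else:
            quality = np.asarray(self.quality, dtype=bool)
            if quality.shape != intervals.shape:
                raise RrValidationError("quality flags must match intervals in length")
        object.__setattr__(self, "quality", quality)

    # -- convenience views -------------------------------------------------
    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)

    @property
    def duration(self) -> float:
        """Span from first to last beat, in seconds."""
        return float(self.beat_times[-1] - self.beat_times[0])

    @property
    def retained(self) -> np.ndarray:
        """Retained (quality-ok) intervals, ms."""
        return self.intervals[self.quality]

    @property
    def interval_times(self) -> np.ndarray:
        """Time stamp of each interval: the later beat of the pair, seconds."""
        return self.beat_times[1:]

    def __len__(self) -> int:
        return int(self.intervals.size)


#: Nominal epoch durations of the recording protocol, seconds.
PROTOCOL_DURATIONS = {"baseline_neutral": 360.0, "stimulus": 360.0, "post_neutral": 180.0}
PROTOCOL_TOLERANCE_S = 5.0


def validate_protocol(epochs: list[Epoch], tolerance: float = PROTOCOL_TOLERANCE_S) -> None:
    """Check epochs against the session protocol.

    A session is a 6 min neutral baseline, a 6 min emotional stimulus and a
    3 min trailing neutral clip; each epoch's duration must match its kind's
    nominal length within ``tolerance`` seconds.
    """
    for e in epochs:
        nominal = PROTOCOL_DURATIONS[e.kind]
        if abs(e.duration - nominal) > tolerance:
            raise ValueError(
                f"{e.kind} epoch lasts {e.duration:.1f} s; protocol expects "
                f"{nominal:.0f} ± {tolerance:.0f} s"
            )


def rr_from_peaks(beat_times) -> RrSeries:
    """Build an :class:`RrSeries` from beat times in seconds.

    Raises on fewer than 2 beats or non-increasing times.
    """
    t = np.asarray(beat_times, dtype=float)
    if t.size < 2:
        raise RrValidationError("need at least 2 beats to form intervals")
    if np.any(np.diff(t) <= 0):
        raise RrValidationError("beat times must be strictly increasing")
    return RrSeries(beat_times=t, intervals=1000.0 * np.diff(t))


def _local_median_deviation(intervals: np.ndarray, retained: np.ndarray, k: int = 5) -> np.ndarray:
    """Relative deviation of each interval from the median of its ``k``
    nearest retained neighbours (excluding itself)."""
    dev = np.zeros(intervals.size)
    idx_ret = np.flatnonzero(retained)
    for i in range(intervals.size):
        neigh = idx_ret[idx_ret != i]
        if neigh.size == 0:
            continue
        order = np.argsort(np.abs(neigh - i), kind="stable")
        ref = np.median(intervals[neigh[order[:k]]])
        if ref > 0:
            dev[i] = abs(intervals[i] - ref) / ref
    return dev


def clean_rr(
    rr: RrSeries,
    bounds: tuple[float, float] = DEFAULT_RR_BOUNDS,
    median_tolerance: float = DEFAULT_MEDIAN_TOLERANCE,
    max_reject_fraction: float = DEFAULT_MAX_REJECT_FRACTION,
    interpolate: bool = False,
) -> RrSeries:
    """Flag artifactual intervals.

    An interval is rejected when it lies outside ``bounds`` (ms) or deviates
    by more than ``median_tolerance`` from the running median of its 5
    nearest retained neighbours.  Rejected intervals stay in the container
    (flags only); with ``interpolate=True`` their values are replaced by
    cubic interpolation over retained neighbours and re-flagged as retained,
    which shifts subsequent beat times accordingly — off by default.

    Raises
    ------
    EpochQualityError
        If more than ``max_reject_fraction`` of intervals are rejected.
    """
    if len(rr) == 0:
        raise RrValidationError("empty RR series")
    iv = rr.intervals
    ok = rr.quality & (iv >= bounds[0]) & (iv <= bounds[1])
    # local-median pass, iterated to a fixed point so cleaning is idempotent
    for _ in range(iv.size):
        dev = _local_median_deviation(iv, ok)
        new_ok = ok & (dev <= median_tolerance)
        if np.array_equal(new_ok, ok):
            break
        ok = new_ok

    reject_frac = 1.0 - ok.mean()
    if reject_frac > max_reject_fraction:
        raise EpochQualityError(
            f"{reject_frac:.0%} of intervals rejected (limit {max_reject_fraction:.0%})"
        )

    if interpolate and not ok.all():
        from scipy.interpolate import CubicSpline

        good = np.flatnonzero(ok)
        if good.size >= 4:
            spline = CubicSpline(good, iv[good])
            iv = iv.copy()
            bad = np.flatnonzero(~ok)
            iv[bad] = spline(bad)
            times = np.concatenate([[rr.beat_times[0]], rr.beat_times[0] + np.cumsum(iv) / 1000.0])
            return RrSeries(beat_times=times, intervals=iv)
        warnings.warn("too few retained intervals for cubic interpolation; flags only")
    return replace(rr, quality=ok)


def segment_epochs(rr: RrSeries, annotations: list[Epoch]) -> dict[Epoch, RrSeries]:
    """Split an RR series into per-epoch series.

    Each interval is owned by its *later* beat; epochs are half-open
    ``[start, end)``, so a beat exactly on an epoch edge belongs to the later
    epoch.  Per-epoch series preserve absolute beat times.

    Raises
    ------
    ValueError
        If annotations overlap, extend past the record, or an epoch captures
        fewer than 2 beats.
    """
    if not annotations:
        raise ValueError("no annotations supplied")
    ordered = sorted(annotations, key=lambda e: e.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"annotations overlap: {a} and {b}")
    t_end = rr.beat_times[-1]
    for e in ordered:
        if e.end > t_end + 1e-9:
            raise ValueError(f"annotation {e} extends past record end ({t_end:.1f} s)")

    out: dict[Epoch, RrSeries] = {}
    for e in ordered:
        # interval i (later beat at beat_times[i+1]) belongs to e iff that
        # beat is in [start, end); keep the earlier beat to anchor it.
        owner = rr.interval_times
        mask = (owner >= e.start) & (owner < e.end)
        # the final beat of the record can close the last epoch
        if np.isclose(e.end, t_end):
            mask |= np.isclose(owner, t_end)
        idx = np.flatnonzero(mask)
        if idx.size < 1 or idx.size + 1 < 2:
            raise ValueError(f"epoch {e} contains fewer than 2 beats")
        beats = np.concatenate([[rr.beat_times[idx[0]]], rr.beat_times[idx + 1]])
        if np.any(np.diff(idx) != 1):
            # non-contiguous should not happen with monotone times
            raise ValueError("internal error: non-contiguous interval ownership")
        out[e] = RrSeries(
            beat_times=beats,
            intervals=rr.intervals[idx],
            quality=rr.quality[idx],
        )
    return out
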