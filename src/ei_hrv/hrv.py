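"""Heart-rate-variability indices per analysis window.

Twenty-one indices are computed per window or epoch:

* time domain — BPM, SDNN, RMSSD, pNN50, and a peak–valley RSA estimate;
* frequency domain — absolute band powers (VLF, LF, HF), their natural logs,
  relative powers (fractions of the three-band total), the VLF/HF and LF/HF
  ratios, total power over the full analysed band (tPow, duplicated as tHz —
  see :class:`HrvIndexSet`), the dominant spectral peak (dHz, dPow) and the
  coherence ratio dPow / (tPow − dPow).

The spectrum is an averaged tapered periodogram (Welch) of the evenly
resampled tachogram: cubic interpolation at ``resample_rate``, linear detrend
and a Hann taper per segment.  Band powers are trapezoidal integrals of the
density with interpolated band edges, so integrals are additive across
adjacent bands.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline, interp1d

from .rr import RrSeries

logger = logging.getLogger(__name__)

#: Canonical index order; every per-window table uses these column names.
INDEX_NAMES = (
    "BPM", "SDNN", "RMSSD", "pNN50", "RSA",
    "VLF", "LF", "HF", "lnVLF", "lnLF", "lnHF",
    "VLFp", "LFp", "HFp", "VLF_HF", "LF_HF",
    "tPow", "dPow", "tHz", "dHz", "CohRatio",
)

RSA_BAND_HZ = (0.12, 0.40)


class HrvComputationError(ValueError):
    """Raised when an index cannot be computed from the given series."""


@dataclass(frozen=True)
class SpectralConfig:
    """Configuration of the tachogram spectral estimator.

    Defaults: 4 Hz cubic resampling, Hann-tapered 120 s segments with 50 %
    overlap, and the conventional short-term bands VLF 0.0033–0.04, LF
    0.04–0.15, HF 0.15–0.40 Hz.  The dominant-peak power (dPow) integrates
    the density over ``peak_halfwidth`` either side of the highest peak; a
    single-bin "peak power" would make the coherence ratio depend on
    frequency resolution.
    """

    resample_rate: float = 4.0
    segment_length: float = 120.0
    overlap: float = 0.5
    taper: str = "hann"
    vlf_band: tuple[float, float] = (0.0033, 0.04)
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    peak_halfwidth: float = 0.015
    enforce_disjoint: bool = True

    def __post_init__(self) -> None:
        if self.resample_rate <= 0:
            raise ValueError("resample_rate must be positive")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        nyq = self.resample_rate / 2.0
        bands = (self.vlf_band, self.lf_band, self.hf_band)
        for lo, hi in bands:
            if not 0 < lo < hi <= nyq:
                raise ValueError(f"band ({lo}, {hi}) must lie within (0, {nyq}] Hz")
        if self.enforce_disjoint:
            for (a_lo, a_hi), (b_lo, b_hi) in zip(bands, bands[1:]):
                if b_lo < a_hi:
                    raise ValueError("bands must be ascending and non-overlapping")

    @property
    def total_band(self) -> tuple[float, float]:
        return (self.vlf_band[0], self.hf_band[1])

    @classmethod
    def printed_bands(cls, **kwargs) -> "SpectralConfig":
        """Variant with LF 0.004–0.15 and HF 0.015–0.4 Hz.

        These literal band limits overlap VLF and each other; they are kept
        available for comparison only and disable the disjointness check.
        """
        kwargs.setdefault("lf_band", (0.004, 0.15))
        kwargs.setdefault("hf_band", (0.015, 0.40))
        kwargs.setdefault("enforce_disjoint", False)
        return cls(**kwargs)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class HrvIndexSet:
    """One value per HRV index for a single window or epoch.

    ``tHz`` always equals ``tPow``: the source variable table defines both as
    the absolute power over the full 0.0033–0.4 Hz band, so they are carried
    as two fields with identical values rather than silently dropping one.
    """

    BPM: float
    SDNN: float
    RMSSD: float
    pNN50: float
    RSA: float
    VLF: float
    LF: float
    HF: float
    lnVLF: float
    lnLF: float
    lnHF: float
    VLFp: float
    LFp: float
    HFp: float
    VLF_HF: float
    LF_HF: float
    tPow: float
    dPow: float
    tHz: float
    dHz: float
    CohRatio: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}

    def as_series(self) -> pd.Series:
        return pd.Series(self.as_dict())


@dataclass(frozen=True)
class HrvTimeSeries:
    """Per-index value sequences across sliding windows.

    ``frame`` has one row per window (indexed by window-centre time in
    seconds) and one column per index name; failed windows hold NaN.
    """

    frame: pd.DataFrame
    window_length: float
    step: float

    @property
    def window_centers(self) -> np.ndarray:
        return self.frame.index.to_numpy(dtype=float)

    @property
    def n_windows(self) -> int:
        return len(self.frame)

    def series(self, index: str) -> pd.Series:
        return self.frame[index]


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def _successive_pairs(rr: RrSeries) -> np.ndarray:
    """Differences between adjacent retained intervals; pairs spanning a
    rejected interval are excluded."""
    q = rr.quality
    both = q[:-1] & q[1:]
    return np.diff(rr.intervals)[both]


def time_domain_indices(rr: RrSeries | np.ndarray) -> dict[str, float]:
    """BPM, SDNN, RMSSD and pNN50 from retained intervals.

    BPM = 60000 / mean(RR); SDNN is the sample (ddof=1) standard deviation;
    RMSSD the root of the mean squared successive difference; pNN50 the
    percentage of successive differences strictly greater than 50 ms.
    """
    if not isinstance(rr, RrSeries):
        iv = np.asarray(rr, dtype=float)
        times = np.concatenate([[0.0], np.cumsum(iv) / 1000.0])
        rr = RrSeries(beat_times=times, intervals=iv)
    retained = rr.retained
    if retained.size < 3:
        raise HrvComputationError(
            f"need at least 3 retained intervals, got {retained.size}"
        )
    diffs = _successive_pairs(rr)
    if diffs.size == 0:
        raise HrvComputationError("no adjacent retained interval pairs")
    return {
        "BPM": 60000.0 / float(np.mean(retained)),
        "SDNN": float(np.std(retained, ddof=1)),
        "RMSSD": float(np.sqrt(np.mean(diffs**2))),
        "pNN50": 100.0 * float(np.mean(np.abs(diffs) > 50.0)),
    }


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------

def resample_tachogram(
    rr: RrSeries, rate: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Evenly resample the tachogram (RR in ms vs time of the later beat).

    Cubic interpolation over retained intervals; falls back to linear when
    fewer than 4 retained points are available.
    """
    t = rr.interval_times[rr.quality]
    x = rr.retained
    if t.size < 2:
        raise HrvComputationError("too few retained intervals to resample")
    grid = np.arange(t[0], t[-1] + 0.5 / rate, 1.0 / rate)
    grid = grid[grid <= t[-1]]
    if t.size >= 4:
        f = CubicSpline(t, x)
    else:
        f = interp1d(t, x)
    return grid, np.asarray(f(grid), dtype=float)


def power_spectrum(
    rr: RrSeries, cfg: SpectralConfig = SpectralConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged tapered periodogram of the resampled tachogram.

    Returns (frequency grid in Hz, one-sided power density in ms²/Hz).  Each
    segment is linearly detrended and tapered; for stationary input the
    density integrates to the tachogram variance to within ~10 %.

    Raises
    ------
    HrvComputationError
        If the epoch is shorter than one analysis segment.
    """
    if rr.duration < cfg.segment_length:
        raise HrvComputationError(
            f"epoch {rr.duration:.1f} s shorter than segment length "
            f"{cfg.segment_length:.1f} s"
        )
    grid, x = resample_tachogram(rr, cfg.resample_rate)
    nperseg = int(round(cfg.segment_length * cfg.resample_rate))
    nperseg = min(nperseg, x.size)
    freqs, psd = sps.welch(
        x,
        fs=cfg.resample_rate,
        window=cfg.taper,
        nperseg=nperseg,
        noverlap=int(cfg.overlap * nperseg),
        detrend="linear",
        scaling="density",
    )
    return freqs, psd


def _band_integral(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the density over [lo, hi] with interpolated
    band edges, so integrals over adjacent bands are additive."""
    if hi <= lo:
        return 0.0
    lo = max(lo, freqs[0])
    hi = min(hi, freqs[-1])
    if hi <= lo:
        return 0.0
    inner = (freqs > lo) & (freqs < hi)
    f = np.concatenate([[lo], freqs[inner], [hi]])
    p = np.concatenate([
        [np.interp(lo, freqs, psd)],
        psd[inner],
        [np.interp(hi, freqs, psd)],
    ])
    return float(np.trapezoid(p, f))


def band_powers(
    freqs: np.ndarray, psd: np.ndarray, cfg: SpectralConfig = SpectralConfig()
) -> dict[str, float]:
    """Frequency-domain indices from a power spectrum.

    Relative powers are fractions of the three-band sum (VLF+LF+HF), so they
    add to 1 by construction.  The dominant peak is the highest density value
    within the full analysed band; dPow integrates ±``peak_halfwidth`` around
    it (clipped to the band).

    Raises
    ------
    HrvComputationError
        If the spectrum does not cover the full band, a log is requested of a
        non-positive power, or the peak carries all the power (tPow == dPow).
    """
    lo_req, hi_req = cfg.total_band
    if freqs[0] > lo_req or freqs[-1] < hi_req:
        raise HrvComputationError(
            f"spectrum [{freqs[0]:.4f}, {freqs[-1]:.4f}] Hz does not cover "
            f"[{lo_req}, {hi_req}] Hz"
        )

    vlf = _band_integral(freqs, psd, *cfg.vlf_band)
    lf = _band_integral(freqs, psd, *cfg.lf_band)
    hf = _band_integral(freqs, psd, *cfg.hf_band)
    tpow = _band_integral(freqs, psd, lo_req, hi_req)

    three = vlf + lf + hf
    if three <= 0:
        raise HrvComputationError("no power in the analysed bands")
    for name, val in (("VLF", vlf), ("LF", lf), ("HF", hf)):
        if val <= 0:
            raise HrvComputationError(f"{name} power is non-positive; ln undefined")
    if hf <= 0:
        raise HrvComputationError("HF power is zero; ratios undefined")

    band_mask = (freqs >= lo_req) & (freqs <= hi_req)
    f_band, p_band = freqs[band_mask], psd[band_mask]
    i_peak = int(np.argmax(p_band))
    dhz = float(f_band[i_peak])
    dpow = _band_integral(
        freqs, psd, max(lo_req, dhz - cfg.peak_halfwidth), min(hi_req, dhz + cfg.peak_halfwidth)
    )
    if math.isclose(tpow, dpow, rel_tol=1e-12) or dpow >= tpow:
        raise HrvComputationError("peak power equals total power; coherence ratio undefined")

    return {
        "VLF": vlf,
        "LF": lf,
        "HF": hf,
        "lnVLF": math.log(vlf),
        "lnLF": math.log(lf),
        "lnHF": math.log(hf),
        "VLFp": vlf / three,
        "LFp": lf / three,
        "HFp": hf / three,
        "VLF_HF": vlf / hf,
        "LF_HF": lf / hf,
        "tPow": tpow,
        "dPow": dpow,
        "tHz": tpow,
        "dHz": dhz,
        "CohRatio": dpow / (tpow - dpow),
    }


# ---------------------------------------------------------------------------
# respiratory sinus arrhythmia
# ---------------------------------------------------------------------------

def rsa(
    rr: RrSeries,
    band: tuple[float, float] = RSA_BAND_HZ,
    resample_rate: float = 4.0,
) -> float:
    """Peak–valley RSA estimate in ms.

    Band-passes the resampled tachogram to the respiratory band (default
    0.12–0.40 Hz), identifies oscillation cycles from zero crossings, and
    returns the mean peak-to-trough excursion.  A tachogram with negligible
    band power (variance of the band-passed signal below 1e-6 ms²) returns 0
    by convention; a non-negligible signal with no complete cycle raises.
    """
    if rr.duration < 60:
        raise HrvComputationError(f"epoch {rr.duration:.1f} s too short for RSA (need 60 s)")
    _, x = resample_tachogram(rr, resample_rate)
    nyq = resample_rate / 2.0
    sos = sps.butter(3, [band[0] / nyq, band[1] / nyq], btype="band", output="sos")
    y = sps.sosfiltfilt(sos, x)
    if float(np.var(y)) < 1e-6:
        return 0.0
    sign = np.sign(y)
    sign[sign == 0] = 1
    crossings = np.flatnonzero(np.diff(sign) != 0) + 1
    if crossings.size < 3:
        raise HrvComputationError("no complete respiratory cycle in epoch")
    # segments between crossings alternate sign; pair each positive segment
    # with the following negative one (or vice versa) into one cycle
    bounds = np.concatenate([[0], crossings, [y.size]])
    extrema = []
    for a, b in zip(bounds, bounds[1:]):
        seg = y[a:b]
        if seg.size == 0:
            continue
        extrema.append(seg.max() if seg.mean() > 0 else seg.min())
    # interior segments only: the first and last may be truncated cycles
    extrema = extrema[1:-1]
    if len(extrema) < 2:
        raise HrvComputationError("no complete respiratory cycle in epoch")
    excursions = np.abs(np.diff(extrema))
    return float(np.mean(excursions))


# ---------------------------------------------------------------------------
# full set and sliding windows
# ---------------------------------------------------------------------------

def hrv_index_set(rr: RrSeries, cfg: SpectralConfig = SpectralConfig()) -> HrvIndexSet:
    """Compute the full 21-index set for one window or epoch."""
    td = time_domain_indices(rr)
    freqs, psd = power_spectrum(rr, cfg)
    fd = band_powers(freqs, psd, cfg)
    return HrvIndexSet(RSA=rsa(rr), **td, **fd)


def sliding_hrv(
    rr: RrSeries,
    window: float = 180.0,
    step: float = 10.0,
    cfg: SpectralConfig | None = None,
    span: tuple[float, float] | None = None,
) -> HrvTimeSeries:
    """Full index set over sliding windows.

    Windows of ``window`` seconds advance by ``step`` and must lie fully
    inside ``span`` (default: first to last beat).  A window whose indices
    cannot be computed is recorded as a NaN row, not a failure.  For a
    180 s window the default spectral segment length is shortened to fit
    (min(segment_length, window * 2/3)).
    """
    if cfg is None:
        cfg = SpectralConfig()
    if cfg.segment_length > window:
        cfg = SpectralConfig(**{**cfg.as_dict(), "segment_length": window * 2.0 / 3.0})
    t0, t1 = span if span is not None else (rr.beat_times[0], rr.beat_times[-1])
    total = t1 - t0
    if window > total + 1e-9:
        raise HrvComputationError(
            f"window {window:.0f} s exceeds epoch span {total:.1f} s"
        )
    n_windows = int(np.floor((total - window) / step + 1e-9)) + 1

    rows = []
    centers = []
    owner = rr.interval_times
    for k in range(n_windows):
        w_lo = t0 + k * step
        w_hi = w_lo + window
        centers.append(w_lo + window / 2.0)
        mask = (owner >= w_lo - 1e-9) & (owner <= w_hi + 1e-9)
        idx = np.flatnonzero(mask)
        if idx.size < 3:
            rows.append({name: np.nan for name in INDEX_NAMES})
            continue
        beats = np.concatenate([[rr.beat_times[idx[0]]], rr.beat_times[idx + 1]])
        sub = RrSeries(beat_times=beats, intervals=rr.intervals[idx], quality=rr.quality[idx])
        try:
            rows.append(hrv_index_set(sub, cfg).as_dict())
        except HrvComputationError as exc:
            logger.warning("window at %.0f s failed: %s", w_lo, exc)
            rows.append({name: np.nan for name in INDEX_NAMES})
    frame = pd.DataFrame(rows, index=pd.Index(centers, name="window_center_s"))
    return HrvTimeSeries(frame=frame[list(INDEX_NAMES)], window_length=window, step=step)
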