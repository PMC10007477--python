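"""ECG records and R-peak detection.

The detector follows the classic Pan–Tompkins recipe: band-pass 5–15 Hz,
differentiate, square, integrate over a 150 ms moving window, then pick peaks
of the integrated signal with an adaptive signal/noise threshold and a 200 ms
refractory period.  Each detection is finally re-localised to the maximum of
the raw signal in a short window, so reported beat times track the R wave
rather than the integrator lag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .rr import Epoch

logger = logging.getLogger(__name__)

REFRACTORY_S = 0.200
INTEGRATION_WINDOW_S = 0.150
BANDPASS_HZ = (5.0, 15.0)


@dataclass(frozen=True)
class EcgRecord:
    """A single-lead ECG recording.

    Attributes
    ----------
    samples : ndarray
        Voltage samples (mV).
    fs : float
        Sampling rate in Hz.
    participant_id : str
        Free-form identifier.
    annotations : list of Epoch
        Baseline/stimulus segments, non-overlapping and inside the record.
    """

    samples: np.ndarray
    fs: float
    participant_id: str = ""
    annotations: list[Epoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if samples.size == 0:
            raise ValueError("ECG record has no samples")
        dur = self.duration
        ordered = sorted(self.annotations, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError(f"annotations overlap: {a} and {b}")
        for e in ordered:
            if e.start < 0 or e.end > dur + 1e-9:
                raise ValueError(f"annotation {e} outside record duration {dur:.1f} s")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


def _detection_function(x: np.ndarray, fs: float) -> np.ndarray:
    """Band-pass, differentiate, square, moving-window integrate."""
    nyq = fs / 2.0
    sos = sps.butter(3, [BANDPASS_HZ[0] / nyq, BANDPASS_HZ[1] / nyq], btype="band", output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(filtered) * fs
    squared = deriv**2
    win = max(1, int(round(INTEGRATION_WINDOW_S * fs)))
    kernel = np.ones(win) / win
    return np.convolve(squared, kernel, mode="same")


def detect_r_peaks(ecg: EcgRecord) -> np.ndarray:
    """Detect R-peak times in seconds from record start.

    Uses an adaptive threshold: running signal- and noise-level estimates
    (exponential moving averages of accepted and rejected candidate peaks)
    with threshold ``noise + 0.25 * (signal - noise)``, and a 200 ms
    refractory period.  A flat or pure-noise record (no candidate exceeding
    the adaptive threshold) yields an empty array with a logged warning.

    Raises
    ------
    ValueError
        If ``fs < 100`` Hz or the record is shorter than 10 s.
    """
    if ecg.fs < 100:
        raise ValueError(f"sampling rate {ecg.fs} Hz too low; need >= 100 Hz")
    if ecg.duration < 10:
        raise ValueError(f"record too short ({ecg.duration:.1f} s); need >= 10 s")

    x = ecg.samples
    fs = ecg.fs
    det = _detection_function(x, fs)

    if det.max() <= 0 or not np.isfinite(det).all():
        logger.warning("detection function is degenerate; no beats found")
        return np.array([])

    refractory = int(round(REFRACTORY_S * fs))
    # candidate local maxima of the detection function
    cand, _ = sps.find_peaks(det, distance=refractory)
    if cand.size == 0:
        logger.warning("no candidate peaks in detection function")
        return np.array([])

    # robust initial signal/noise levels: the median of the strongest
    # candidate heights (at least ~40 bpm worth of beats) resists filter
    # edge transients that a plain head-of-record maximum would latch onto
    heights = det[cand]
    n_expected = max(3, int(ecg.duration * 40.0 / 60.0))
    top = np.sort(heights)[-n_expected:]
    spk = float(np.median(top))
    npk = float(np.median(det))  # baseline level of the detection function
    if spk <= 0 or spk <= 1.5 * npk:
        logger.warning("no clear signal level in detection function; no beats found")
        return np.array([])

    accepted: list[int] = []
    for i in cand:
        thr = npk + 0.25 * (spk - npk)
        if det[i] > thr:
            if accepted and i - accepted[-1] < refractory:
                continue
            accepted.append(i)
            # clamp the update so a single outlier peak cannot freeze the
            # threshold above genuine beats
            spk = 0.125 * min(det[i], 4.0 * spk) + 0.875 * spk
        else:
            npk = 0.125 * det[i] + 0.875 * npk

    if not accepted:
        logger.warning("no peaks exceeded the adaptive threshold")
        return np.array([])

    # re-localise to the raw-signal maximum near each detection
    half = int(round(0.075 * fs))
    peaks = []
    for i in accepted:
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(peaks)
    # enforce refractory after re-localisation
    kept = [peaks[0]]
    for p in peaks[1:]:
        if p - kept[-1] >= refractory:
            kept.append(p)
    kept = np.asarray(kept)
    # drop detections that re-localised onto baseline (e.g. ringing sidelobes
    # of a filter edge transient): real R waves share a common amplitude scale
    amp = np.abs(x[kept])
    kept = kept[amp >= 0.3 * np.median(amp)]
    return kept.astype(float) / fs
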