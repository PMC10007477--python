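"""Affect-dynamics statistics on per-window HRV index series.

Three statistics summarise how an index evolves across sliding windows:

* **variability** — sample variance (ddof=1): the overall range of states;
* **instability** — mean squared successive difference (MSSD): moment-to-
  moment change.  On an RR-interval sequence this equals RMSSD²;
* **inertia** — lag-1 Pearson autocorrelation: how strongly the current
  state is predicted by the previous one.

Missing values (NaN) are skipped by variability; for instability and inertia
they break the chain — pairs spanning a gap are excluded.

Features are expressed relative to a neutral baseline epoch (difference by
default) before dynamics are computed, which removes between-person
physiological offsets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hrv import INDEX_NAMES, HrvTimeSeries

DYNAMICS_NAMES = ("variability", "instability", "inertia")


class DynamicsError(ValueError):
    """Raised when a dynamics statistic is undefined for the given series."""


def _clean(series) -> np.ndarray:
    return np.asarray(series, dtype=float)


def variability(series) -> float:
    """Sample variance (denominator n−1) of the non-missing values."""
    x = _clean(series)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise DynamicsError(f"variability needs >= 3 values, got {x.size}")
    return float(np.var(x, ddof=1))


def _consecutive_pairs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = np.isfinite(x)
    both = ok[:-1] & ok[1:]
    return x[:-1][both], x[1:][both]


def instability(series) -> float:
    """Mean squared successive difference over consecutive non-missing pairs."""
    x = _clean(series)
    a, b = _consecutive_pairs(x)
    if a.size < 1:
        raise DynamicsError("instability needs at least one consecutive pair")
    return float(np.mean((b - a) ** 2))


def inertia(series) -> float:
    """Lag-1 Pearson autocorrelation over consecutive non-missing pairs."""
    x = _clean(series)
    if np.sum(np.isfinite(x)) < 4:
        raise DynamicsError("inertia needs >= 4 values")
    a, b = _consecutive_pairs(x)
    if a.size < 3:
        raise DynamicsError("inertia needs >= 3 consecutive pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise DynamicsError("inertia undefined for a constant series")
    return float(np.corrcoef(a, b)[0, 1])


def normalize_to_baseline(
    stimulus_value: float, baseline_value: float, mode: str = "difference"
) -> float:
    """Express a stimulus-epoch value relative to its baseline.

    ``difference`` (default) returns stimulus − baseline; ``ratio`` returns
    stimulus / baseline − 1 and raises on a zero baseline.
    """
    if not (np.isfinite(stimulus_value) and np.isfinite(baseline_value)):
        raise DynamicsError("normalisation requires finite inputs")
    if mode == "difference":
        return float(stimulus_value - baseline_value)
    if mode == "ratio":
        if baseline_value == 0:
            raise DynamicsError("ratio normalisation undefined for zero baseline")
        return float(stimulus_value / baseline_value - 1.0)
    raise ValueError(f"unknown normalisation mode {mode!r}")


def _dynamics_or_nan(fn, series) -> float:
    try:
        return fn(series)
    except DynamicsError:
        return float("nan")


def session_features(
    epochs: dict[str, HrvTimeSeries],
    mode: str = "difference",
) -> pd.Series:
    """Features for one emotional-domain session.

    ``epochs`` maps epoch kind (``baseline_neutral``, ``stimulus``,
    optionally ``post_neutral``) to its per-window index series.  For each
    index the HRV feature is the mean of stimulus windows minus the mean of
    baseline windows; the three dynamics are computed on the
    baseline-normalised window series spanning the whole session in time
    order.
    """
    missing = [k for k in ("baseline_neutral", "stimulus") if k not in epochs]
    if missing:
        raise DynamicsError(f"missing epoch(s): {', '.join(missing)}")
    order = [k for k in ("baseline_neutral", "stimulus", "post_neutral") if k in epochs]

    out: dict[str, float] = {}
    for index in INDEX_NAMES:
        base = epochs["baseline_neutral"].frame[index]
        stim = epochs["stimulus"].frame[index]
        base_mean = float(np.nanmean(base))
        out[index] = normalize_to_baseline(float(np.nanmean(stim)), base_mean, mode)
        session = np.concatenate([epochs[k].frame[index].to_numpy() for k in order])
        if mode == "difference":
            normed = session - base_mean
        else:
            if base_mean == 0:
                raise DynamicsError(f"zero baseline mean for {index} in ratio mode")
            normed = session / base_mean - 1.0
        out[f"variability_{index}"] = _dynamics_or_nan(variability, normed)
        out[f"instability_{index}"] = _dynamics_or_nan(instability, normed)
        out[f"inertia_{index}"] = _dynamics_or_nan(inertia, normed)
    return pd.Series(out)


def participant_features(
    sessions: dict[str, dict[str, HrvTimeSeries]],
    mode: str = "difference",
    per_domain: bool = False,
) -> pd.Series | pd.DataFrame:
    """One feature record per participant.

    ``sessions`` maps emotional-domain label to that session's epoch series.
    Features are averaged across the domains into a single record (the
    default); ``per_domain=True`` instead returns a DataFrame with one row
    per domain.
    """
    if not sessions:
        raise DynamicsError("no sessions supplied")
    rows = {dom: session_features(eps, mode) for dom, eps in sessions.items()}
    table = pd.DataFrame(rows).T
    if per_domain:
        return table
    return table.mean(axis=0)


def feature_names() -> list[str]:
    """All feature-table column names: raw indices plus dynamics expansions."""
    names = list(INDEX_NAMES)
    for stat in DYNAMICS_NAMES:
        names += [f"{stat}_{ix}" for ix in INDEX_NAMES]
    return names
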