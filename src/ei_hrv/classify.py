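"""Emotional-intelligence cut-point selection by significance counting.

Participants are ordered by their emotion-recognition score and every
admissible split of the ordered cohort into a low- and a high-scoring group
is evaluated: each HRV/dynamics feature is compared between the two groups
with a two-sided Welch t-test, and the split that yields the largest number
of features significant at the 0.05 level is selected as the EI cut-point
(ties broken toward the most balanced split, then toward the lower cut).

No multiple-testing correction is applied in the sweep by default; a
Benjamini–Hochberg option exists but changes what "significant" means and is
therefore off unless requested.  Because the selected split maximises a
significance count, its count is biased upward relative to any prespecified
split — a selection effect that a synthetic null cohort makes visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

DYNAMICS_PREFIXES = ("variability_", "instability_", "inertia_")


class SweepError(ValueError):
    pass


@dataclass(frozen=True)
class SplitTest:
    """Welch t-test of one feature between the low and high group."""

    feature: str
    t_stat: float
    p_value: float
    low_mean: float
    low_sd: float
    high_mean: float
    high_sd: float
    n_low: int
    n_high: int


def welch_ttest(low_values, high_values, feature: str = "", equal_var: bool = False) -> SplitTest:
    """Two-sided t-test with Satterthwaite degrees of freedom (Welch).

    ``equal_var=True`` gives the pooled-variance Student test instead.  Two
    groups with zero variance and equal means return t = 0, p = 1 by
    convention rather than NaN.
    """
    lo = np.asarray(low_values, dtype=float)
    hi = np.asarray(high_values, dtype=float)
    if lo.size < 2 or hi.size < 2:
        raise SweepError("each group needs at least 2 values")
    if np.var(lo) == 0 and np.var(hi) == 0:
        if lo.mean() == hi.mean():
            t, p = 0.0, 1.0
        else:
            raise SweepError("zero variance in both groups with unequal means")
    else:
        t, p = stats.ttest_ind(lo, hi, equal_var=equal_var)
    return SplitTest(
        feature=feature,
        t_stat=float(t),
        p_value=float(p),
        low_mean=float(lo.mean()),
        low_sd=float(lo.std(ddof=1)),
        high_mean=float(hi.mean()),
        high_sd=float(hi.std(ddof=1)),
        n_low=int(lo.size),
        n_high=int(hi.size),
    )


def _feature_source(name: str) -> str:
    for prefix in DYNAMICS_PREFIXES:
        if name.startswith(prefix):
            return prefix.rstrip("_")
    return "HRV"


def marker_table(tests: list[SplitTest], tiers: tuple[float, float] = (0.05, 0.01)) -> pd.DataFrame:
    """Significant features (p < the loose tier), starred per tier.

    One star for p below the loose tier, two below the strict tier (strict
    inequalities: p exactly at a tier boundary is excluded).  Rows are
    grouped by feature source (HRV / variability / instability / inertia)
    and carry the group means, SDs and p-values.
    """
    loose, strict = max(tiers), min(tiers)
    rows = []
    for t in tests:
        if not t.p_value < loose:
            continue
        rows.append(
            {
                "source": _feature_source(t.feature),
                "feature": t.feature,
                "low_mean": t.low_mean,
                "low_sd": t.low_sd,
                "high_mean": t.high_mean,
                "high_sd": t.high_sd,
                "t_stat": t.t_stat,
                "p_value": t.p_value,
                "stars": "**" if t.p_value < strict else "*",
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "source", "feature", "low_mean", "low_sd",
            "high_mean", "high_sd", "t_stat", "p_value", "stars",
        ],
    )
    order = {"HRV": 0, "variability": 1, "instability": 2, "inertia": 3}
    if len(table):
        table = table.sort_values(
            by=["source", "p_value"], key=lambda col: col.map(order) if col.name == "source" else col
        ).reset_index(drop=True)
    return table


class CutpointSweep(BaseEstimator):
    """Select the score cut-point maximising the significant-feature count.

    Parameters
    ----------
    min_group : int, default 5
        Minimum size of each group; candidate cuts violating it are skipped.
    alpha_tiers : tuple of float, default (0.05, 0.01)
        Loose and strict significance levels; the loose tier drives the
        selection, both are reported.
    equal_var : bool, default False
        Use the pooled-variance Student test instead of Welch.
    fdr : bool, default False
        Apply Benjamini–Hochberg within each candidate split before
        counting.

    Attributes (after :meth:`fit`)
    ------------------------------
    sweep_table_ : DataFrame
        One row per candidate cut: cut_score, n_low, n_high and the
        significant counts at both tiers.
    cut_score_ : float
        Lowest score of the high group at the best split.
    n_low_, n_high_ : int
    tests_ : list of SplitTest
        Per-feature tests at the best split.
    marker_table_ : DataFrame
        Features with p below the loose tier at the best split.
    feature_names_in_ : ndarray of str
    """

    def __init__(self, min_group: int = 5, alpha_tiers: tuple[float, float] = (0.05, 0.01),
                 equal_var: bool = False, fdr: bool = False):
        self.min_group = min_group
        self.alpha_tiers = alpha_tiers
        self.equal_var = equal_var
        self.fdr = fdr

    # -- internals ----------------------------------------------------------
    def _counts_at(self, X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = X[:k], X[k:]
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(lo, hi, equal_var=self.equal_var, axis=0)
        p = np.where(np.isnan(p), 1.0, p)
        if self.fdr:
            from statsmodels.stats.multitest import multipletests

            p = multipletests(p, method="fdr_bh")[1]
        return t, p

    def fit(self, X, y=None, *, scores=None):
        """Sweep all admissible cuts of the score-ordered cohort.

        Parameters
        ----------
        X : DataFrame or 2-D array, shape (n_participants, n_features)
        y : array of float
            Evaluation scores, aligned with the rows of X.  May also be
            passed as the keyword ``scores``.
        """
        if scores is not None:
            y = scores
        if y is None:
            raise SweepError("scores are required")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim != 2:
                raise SweepError("feature table must be 2-D")
            self.feature_names_in_ = np.asarray(
                [f"feature_{j}" for j in range(values.shape[1])], dtype=object
            )
        y = np.asarray(y, dtype=float)
        n = values.shape[0]
        if y.shape != (n,):
            raise SweepError("scores must align with feature rows")
        if n < 2 * self.min_group:
            raise SweepError(
                f"need at least {2 * self.min_group} participants, got {n}"
            )

        order = np.argsort(y, kind="stable")
        y_sorted = y[order]
        X_sorted = values[order]
        if y_sorted[0] == y_sorted[-1]:
            raise SweepError("all scores identical; no valid split")

        loose, strict = max(self.alpha_tiers), min(self.alpha_tiers)
        records = []
        for k in range(self.min_group, n - self.min_group + 1):
            if y_sorted[k - 1] == y_sorted[k]:
                continue  # tied scores are never split
            _, p = self._counts_at(X_sorted, k)
            records.append(
                {
                    "k": k,
                    "cut_score": y_sorted[k],
                    "n_low": k,
                    "n_high": n - k,
                    "significant_count_05": int((p < loose).sum()),
                    "significant_count_01": int((p < strict).sum()),
                }
            )
        if not records:
            raise SweepError("no candidate split satisfies the group-size minimum")
        sweep = pd.DataFrame(records)

        best_count = sweep["significant_count_05"].max()
        tied = sweep[sweep["significant_count_05"] == best_count]
        # most balanced split wins ties; then the lower cut
        imbalance = (tied["n_low"] - tied["n_high"]).abs()
        best_row = tied.loc[imbalance.sort_values(kind="stable").index[0]]

        k = int(best_row["k"])
        t, p = self._counts_at(X_sorted, k)
        lo, hi = X_sorted[:k], X_sorted[k:]
        self.tests_ = [
            SplitTest(
                feature=str(name),
                t_stat=float(t[j]),
                p_value=float(p[j]),
                low_mean=float(lo[:, j].mean()),
                low_sd=float(lo[:, j].std(ddof=1)),
                high_mean=float(hi[:, j].mean()),
                high_sd=float(hi[:, j].std(ddof=1)),
                n_low=k,
                n_high=n - k,
            )
            for j, name in enumerate(self.feature_names_in_)
        ]
        self.sweep_table_ = sweep.drop(columns="k")
        self.cut_score_ = float(best_row["cut_score"])
        self.n_low_ = int(best_row["n_low"])
        self.n_high_ = int(best_row["n_high"])
        self.best_significant_count_ = int(best_row["significant_count_05"])
        self.marker_table_ = marker_table(self.tests_, self.alpha_tiers)
        return self

    def predict(self, scores) -> np.ndarray:
        """Label scores as ``'low'`` or ``'high'`` relative to the fitted cut."""
        check_is_fitted(self, "cut_score_")
        s = np.asarray(scores, dtype=float)
        return np.where(s >= self.cut_score_, "high", "low")


@dataclass(frozen=True)
class SweepResult:
    """Functional-interface view of a fitted :class:`CutpointSweep`."""

    splits: pd.DataFrame
    cut_score: float
    n_low: int
    n_high: int
    significant_count: int
    tests: list[SplitTest]
    markers: pd.DataFrame


def sweep_splits(
    scores,
    features,
    min_group: int = 5,
    alpha_tiers: tuple[float, float] = (0.05, 0.01),
    equal_var: bool = False,
    fdr: bool = False,
) -> SweepResult:
    """Thin functional wrapper over :class:`CutpointSweep`."""
    est = CutpointSweep(
        min_group=min_group, alpha_tiers=alpha_tiers, equal_var=equal_var, fdr=fdr
    ).fit(features, scores)
    return SweepResult(
        splits=est.sweep_table_,
        cut_score=est.cut_score_,
        n_low=est.n_low_,
        n_high=est.n_high_,
        significant_count=est.best_significant_count_,
        tests=est.tests_,
        markers=est.marker_table_,
    )


def check_normality(scores) -> tuple[float, pd.DataFrame]:
    """Shapiro–Wilk normality test plus quantile–quantile coordinates.

    Returns the p-value and a DataFrame with ``theoretical`` and ``sample``
    quantile columns for a Q–Q plot.  Requires n >= 8 and a non-constant
    sample.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 8:
        raise SweepError(f"normality check needs n >= 8, got {x.size}")
    if np.ptp(x) == 0:
        raise SweepError("normality undefined for a constant vector")
    p = float(stats.shapiro(x).pvalue)
    (osm, osr), _ = stats.probplot(x, dist="norm")
    qq = pd.DataFrame({"theoretical": osm, "sample": osr})
    return p, qq
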