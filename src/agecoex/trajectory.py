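"""Age-trajectory breakpoint regression, PCA contrasts, shared signatures.

The trajectory model asks whether a module eigengene changes gradually with
age or shows abrupt slope changes: continuous piecewise-linear least
squares is fitted for every candidate breakpoint set on an age grid, and
the number of breakpoints (0, 1, or 2) is chosen by BIC.  A cubic
smoothing spline of the same data is retained for plotting only.

Also here: PC1 sample scores with the variance fraction captured,
Wilcoxon rank-sum contrasts between cohorts, cross-cohort shared-signature
extraction with a hypergeometric overlap test, and the 2^-ddCt relative
expression helper used when hub genes are re-measured by qPCR.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .containers import ExpressionMatrix
from .enrich import hypergeometric_upper_tail

log = logging.getLogger("agecoex")

_RSS_FLOOR = 1e-12


def _design(ages: np.ndarray, breaks: tuple[float, ...]) -> np.ndarray:
    cols = [np.ones_like(ages), ages]
    for b in breaks:
        cols.append(np.clip(ages - b, 0.0, None))
    return np.column_stack(cols)


class PiecewiseAgeTrajectory:
    """Continuous piecewise-linear age-trend model for one sample profile.

    Parameters
    ----------
    values : array-like
        Per-sample response (typically a module eigengene).
    ages : array-like
        Donor ages in years, same length as values, non-constant.
    max_breaks : int
        Largest breakpoint count considered (0, 1, or 2).
    grid_step : float
        Candidate-breakpoint grid spacing in years (default 1).
    min_gap : float
        Minimum separation between two breakpoints in years (default 10),
        preventing the two-break model from fitting one kink twice.
    """

    def __init__(
        self,
        values,
        ages,
        max_breaks: int = 2,
        grid_step: float = 1.0,
        min_gap: float = 10.0,
    ) -> None:
        self.values = np.asarray(values, dtype=float)
        self.ages = np.asarray(ages, dtype=float)
        if self.values.shape != self.ages.shape:
            raise ValueError("values and ages must have equal length")
        if self.values.size < 8:
            raise ValueError("trajectory fitting needs >= 8 samples")
        if self.ages.std() == 0:
            raise ValueError("ages must not be constant")
        if max_breaks not in (0, 1, 2):
            raise ValueError("max_breaks must be 0, 1, or 2")
        self.max_breaks = max_breaks
        self.grid_step = float(grid_step)
        self.min_gap = float(min_gap)

    def _candidate_grid(self) -> np.ndarray:
        lo, hi = self.ages.min(), self.ages.max()
        grid = np.arange(np.ceil(lo / self.grid_step) * self.grid_step, hi, self.grid_step)
        return grid[(grid > lo) & (grid < hi)]

    def fit(self) -> "TrajectoryFit":
        n = self.values.size
        grid = self._candidate_grid()
        best: dict[int, tuple[float, tuple[float, ...], np.ndarray]] = {}

        def consider(breaks: tuple[float, ...]) -> None:
            X = _design(self.ages, breaks)
            if n <= X.shape[1]:
                raise ValueError("fewer samples than model parameters")
            coef, _, _, _ = np.linalg.lstsq(X, self.values, rcond=None)
            rss = float(((self.values - X @ coef) ** 2).sum())
            nb = len(breaks)
            if nb not in best or rss < best[nb][0]:
                best[nb] = (rss, breaks, coef)

        consider(())
        if self.max_breaks >= 1:
            for b in grid:
                consider((float(b),))
        if self.max_breaks >= 2:
            for b1, b2 in itertools.combinations(grid, 2):
                if b2 - b1 >= self.min_gap:
                    consider((float(b1), float(b2)))

        bic = {}
        for nb, (rss, _, _) in best.items():
            k = 2 + 2 * nb  # intercept+slope, plus location+slope per break
            bic[nb] = n * np.log(max(rss, _RSS_FLOOR) / n) + k * np.log(n)
        chosen = min(sorted(bic), key=lambda nb: bic[nb])
        rss, breaks, coef = best[chosen]

        slopes = [float(coef[1])]
        for j in range(len(breaks)):
            slopes.append(slopes[-1] + float(coef[2 + j]))

        # smoothing spline for visualisation (mean response per unique age)
        order = np.argsort(self.ages)
        uniq_ages, inv = np.unique(self.ages[order], return_inverse=True)
        means = np.bincount(inv, weights=self.values[order]) / np.bincount(inv)
        spline = None
        if uniq_ages.size >= 4:
            spline = UnivariateSpline(uniq_ages, means, k=3, s=len(uniq_ages))

        return TrajectoryFit(
            model=self,
            breakpoints=list(breaks),
            coefficients=coef,
            segment_slopes=slopes,
            rss=rss,
            bic=pd.Series(bic).sort_index(),
            fitted=_design(self.ages, breaks) @ coef,
            spline=spline,
        )


@dataclass
class TrajectoryFit:
    """Fitted piecewise-linear age trajectory."""

    model: PiecewiseAgeTrajectory
    breakpoints: list[float]
    coefficients: np.ndarray
    segment_slopes: list[float]
    rss: float
    bic: pd.Series
    fitted: np.ndarray
    spline: UnivariateSpline | None = None

    @property
    def n_breaks(self) -> int:
        return len(self.breakpoints)

    def predict(self, ages) -> np.ndarray:
        return _design(np.asarray(ages, dtype=float), tuple(self.breakpoints)) @ self.coefficients

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "n_breaks": int(nb),
                "bic": float(b),
                "chosen": int(nb) == self.n_breaks,
            }
            for nb, b in self.bic.items()
        ]
        return pd.DataFrame(rows)


def fit_trajectory(
    values, ages, max_breaks: int = 2, grid_step: float = 1.0, min_gap: float = 10.0
) -> TrajectoryFit:
    """Functional entry point for :class:`PiecewiseAgeTrajectory`."""
    return PiecewiseAgeTrajectory(values, ages, max_breaks, grid_step, min_gap).fit()


# ---------------------------------------------------------------------------
# PCA and cohort contrasts
# ---------------------------------------------------------------------------

def pc1_scores(m: ExpressionMatrix, ages=None) -> tuple[pd.Series, float]:
    """First-principal-component sample scores and PC1 variance fraction.

    Genes are standardized internally; the score sign is oriented so that
    corr(PC1, age) >= 0 when ages are supplied, otherwise so that the score
    correlates non-negatively with mean expression per sample.
    """
    if m.n_samples < 3:
        raise ValueError("PCA needs >= 3 samples")
    vals = m.values
    sd = vals.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    z = (vals[keep] - vals[keep].mean(axis=1, keepdims=True)) / sd[keep]
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0] * s[0]
    frac = float(s[0] ** 2 / (s**2).sum())
    ref = np.asarray(ages, dtype=float) if ages is not None else vals.mean(axis=0)
    if np.std(ref) > 0 and np.corrcoef(scores, ref)[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=m.sample_ids, name="PC1"), frac


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value.

    Exact enumeration when both samples have n <= 8 and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# shared signatures across cohorts
# ---------------------------------------------------------------------------

@dataclass
class SharedSignature:
    """Cross-cohort intersection of age-related module genes and DEGs."""

    genes_a: set[str]
    genes_b: set[str]
    shared: set[str]
    shared_differential: set[str]
    overlap_p: float

    def venn_counts(self) -> tuple[int, int, int]:
        """(A-only, shared, B-only)."""
        return (
            len(self.genes_a - self.shared),
            len(self.shared),
            len(self.genes_b - self.shared),
        )


def shared_signature(genes_a, genes_b, degs_a, degs_b, universe_size: int) -> SharedSignature:
    """Intersect two cohorts' module gene sets and their DEG lists.

    ``shared = genes_a ∩ genes_b``; ``shared_differential`` additionally
    requires membership in both cohorts' significant DEG lists.  Overlap
    significance is the hypergeometric upper tail of |shared| given the two
    set sizes within `universe_size`.
    """
    genes_a, genes_b = set(genes_a), set(genes_b)
    if universe_size < max(len(genes_a), len(genes_b)):
        raise ValueError("universe smaller than an input gene set")
    shared = genes_a & genes_b
    shared_diff = (set(degs_a) & genes_a) & (set(degs_b) & genes_b)
    p = hypergeometric_upper_tail(
        len(shared), len(genes_a), len(genes_b), universe_size
    )
    return SharedSignature(genes_a, genes_b, shared, shared_diff & shared, p)


def delta_delta_ct(
    ct_target: float,
    ct_reference: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) - (Ct_target,cal - Ct_reference,cal);
    returns 2 ** (-ddCt).
    """
    cts = (ct_target, ct_reference, ct_target_calibrator, ct_reference_calibrator)
    if not all(np.isfinite(cts)):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target - ct_reference) - (ct_target_calibrator - ct_reference_calibrator)
    return float(2.0 ** (-ddct))
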