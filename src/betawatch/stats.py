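"""Continuous and group analyses of the attention index.

Three correlation models relate the per-subject beta summary to the task
score and mental-state answers: Pearson (linear), Spearman (rank) and the
skipped correlation — a robust variant that removes bivariate outliers
detected relative to a minimum-covariance-determinant (MCD) centre before
computing Spearman (default) or Pearson on the remainder.

The group analysis contrasts worst against best performers: subjects with
scores within +/-0.5 of the cohort mean are excluded, the rest split at
the pass mark, each group is trimmed to its [5th, 95th] beta-percentile
interval, and the groups are compared with a two-sided Mann-Whitney U
test unless both Shapiro-Wilk normality and Bartlett homogeneity hold, in
which case a two-sample t-test is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.covariance import MinCovDet

from .core import ConstantInputError, EmptyGroupError, InsufficientDataError

__all__ = [
    "CorrelationResult",
    "GroupAssignment",
    "GroupTestResult",
    "correlate",
    "skipped_outliers",
    "correlation_power",
    "form_groups",
    "compare_groups",
]

MODELS = ("pearson", "spearman", "skipped")


@dataclass
class CorrelationResult:
    """One correlation fit with bootstrap CI and post-hoc power."""

    model: str
    r: float
    ci95: tuple[float, float]
    p_value: float
    power: float
    n: int
    n_outliers: int = 0
    outlier_indices: np.ndarray | None = None


@dataclass
class GroupAssignment:
    """Worst/best performer groups after the exclusion and trim rules."""

    worst_idx: np.ndarray
    best_idx: np.ndarray
    excluded_mid_idx: np.ndarray
    trimmed_idx: np.ndarray
    worst_betas: np.ndarray
    best_betas: np.ndarray


@dataclass
class GroupTestResult:
    """Best-vs-worst comparison with the assumption checks that chose the test."""

    group_sizes: tuple[int, int]
    medians: tuple[float, float]
    normality_p: tuple[float, float]
    variance_p: float
    test_used: str
    statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def correlation_power(r: float, n: int, alpha: float = 0.05) -> float:
    """Post-hoc power of the two-sided correlation test, Fisher-z approximation.

    Follows the standard convention for reported correlation power: the
    critical correlation r_c comes from the t distribution with n-2
    degrees of freedom, the observed r is treated as the population value
    through the bias-corrected Fisher transform z = atanh(r) + r/(2(n-1)),
    and power is the probability of exceeding the critical value under
    that alternative with standard error 1/sqrt(n-3).
    """
    if n <= 4:
        return float("nan")
    r = min(abs(r), 0.999999)
    dof = n - 2
    tcrit = sps.t.ppf(1 - alpha / 2, dof)
    rc = np.sqrt(tcrit**2 / (tcrit**2 + dof))
    zr = np.arctanh(r) + r / (2 * (n - 1))
    zrc = np.arctanh(rc)
    s = np.sqrt(n - 3)
    return float(sps.norm.cdf((zr - zrc) * s) + sps.norm.cdf((-zr - zrc) * s))


def _check_xy(x, y, min_n: int = 4) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < min_n:
        raise InsufficientDataError(f"need at least {min_n} observations, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    return x, y


def _ideal_fourths_iqr(x: np.ndarray) -> float:
    """Interquartile range via the ideal fourths (a smoothed quartile rule)."""
    n = len(x)
    j = int(np.floor(n / 4 + 5 / 12))
    y = np.sort(x)
    g = (n / 4) - j + (5 / 12)
    low = (1 - g) * y[j - 1] + g * y[j]
    k = n - j + 1
    up = (1 - g) * y[k - 1] + g * y[k - 2]
    return up - low


def skipped_outliers(x, y, seed: int | None = 42) -> np.ndarray:
    """Bivariate outlier indices for the skipped correlation.

    The robust centre comes from the minimum-covariance-determinant
    estimator; every data point defines a projection direction through the
    centre, all points are projected onto it, and a point is flagged if on
    any direction its projected distance exceeds the boxplot-rule fence
    median + sqrt(chi2(0.975, 2)) x IQR, with the IQR taken as the ideal
    fourths.  Deterministic for a fixed seed (MCD subsampling).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise InsufficientDataError("skipped outlier detection needs n >= 10")
    X = np.column_stack((x, y))
    gval = np.sqrt(sps.chi2.ppf(0.975, 2))
    center = MinCovDet(random_state=seed).fit(X).location_
    B = X - center
    bot = (B**2).sum(axis=1)
    dis = np.zeros((n, n))
    for i in range(n):
        if bot[i] != 0:
            proj = (B @ B[i]) / bot[i]  # scalar coordinate along direction i
            dis[i, :] = np.abs(proj) * np.linalg.norm(B[i])
    iqr = np.apply_along_axis(_ideal_fourths_iqr, 1, dis)
    thresh = np.median(dis, axis=1) + gval * iqr
    flagged = (dis > thresh[:, None]).any(axis=0)
    return np.flatnonzero(flagged)


def _point_estimate(x: np.ndarray, y: np.ndarray, model: str,
                    skipped_basis: str, seed: int | None):
    """(r, p, n_eff, outlier_indices) for one model on one sample."""
    if model == "pearson":
        r, p = sps.pearsonr(x, y)
        return float(r), float(p), len(x), np.array([], dtype=int)
    if model == "spearman":
        r, p = sps.spearmanr(x, y)
        return float(r), float(p), len(x), np.array([], dtype=int)
    if model == "skipped":
        out = skipped_outliers(x, y, seed=seed)
        keep = np.setdiff1d(np.arange(len(x)), out)
        if len(keep) < 4 or np.ptp(x[keep]) == 0 or np.ptp(y[keep]) == 0:
            raise InsufficientDataError("too few points left after outlier removal")
        if skipped_basis == "pearson":
            r, p = sps.pearsonr(x[keep], y[keep])
        else:
            r, p = sps.spearmanr(x[keep], y[keep])
        return float(r), float(p), len(keep), out
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def correlate(x, y, model: str = "skipped", n_boot: int = 2000,
              seed: int | None = 0, skipped_basis: str = "spearman",
              alpha: float = 0.05) -> CorrelationResult:
    """Correlate two vectors under one model, with bootstrap CI and power.

    The 95% CI is the percentile bootstrap over pair resamples.  For the
    skipped model the outlier set is determined once on the full sample
    and resamples are drawn from the cleaned pairs (re-running the MCD
    search inside every resample is prohibitively slow and adds nothing
    once the gross outliers are gone); power uses the Fisher-z
    approximation at the observed r and the effective n.
    """
    x, y = _check_xy(x, y)
    r, p, n_eff, outliers = _point_estimate(x, y, model, skipped_basis, seed)

    if model == "skipped":
        keep = np.setdiff1d(np.arange(len(x)), outliers)
        bx, by = x[keep], y[keep]
        boot_fun = sps.spearmanr if skipped_basis == "spearman" else sps.pearsonr
    else:
        bx, by = x, y
        boot_fun = sps.spearmanr if model == "spearman" else sps.pearsonr
    rng = np.random.default_rng(seed)
    nb = len(bx)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, nb, nb)
        xb, yb = bx[idx], by[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            boots[b] = np.nan
            continue
        boots[b] = boot_fun(xb, yb)[0]
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])

    return CorrelationResult(
        model=model,
        r=r,
        ci95=(float(lo), float(hi)),
        p_value=p,
        power=correlation_power(r, n_eff, alpha),
        n=n_eff,
        n_outliers=len(outliers),
        outlier_indices=outliers,
    )


def form_groups(scores, betas, pass_mark: float = 5.0,
                mid_band: float = 0.5,
                trim_percentiles: tuple[float, float] = (5.0, 95.0)) -> GroupAssignment:
    """Split subjects into worst/best performer groups with the exclusion rules.

    1. Subjects whose score lies within +/- mid_band of the cohort mean
       are excluded (neither clearly worst nor best).
    2. The rest split at the pass mark: worst < pass_mark <= best.
    3. Within each group, subjects whose beta summary falls strictly
       outside that group's [5th, 95th] percentile interval (linear
       interpolation between order statistics) are trimmed as outliers.
    """
    scores = np.asarray(scores, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if scores.shape != betas.shape:
        raise ValueError("scores and betas must be parallel vectors")
    idx = np.arange(len(scores))
    mean = scores.mean()
    mid = np.abs(scores - mean) <= mid_band
    kept = idx[~mid]
    if len(kept) == 0:
        raise EmptyGroupError("mid-band exclusion removed every subject")
    worst = kept[scores[kept] < pass_mark]
    best = kept[scores[kept] >= pass_mark]
    if len(worst) == 0 or len(best) == 0:
        raise EmptyGroupError("pass-mark split left an empty group")

    trimmed: list[int] = []

    def trim(group: np.ndarray) -> np.ndarray:
        if len(group) < 3:
            return group
        lo, hi = np.percentile(betas[group], trim_percentiles)
        inside = group[(betas[group] >= lo) & (betas[group] <= hi)]
        trimmed.extend(np.setdiff1d(group, inside).tolist())
        return inside

    worst_t = trim(worst)
    best_t = trim(best)
    if len(worst_t) == 0 or len(best_t) == 0:
        raise EmptyGroupError("percentile trim left an empty group")
    return GroupAssignment(
        worst_idx=worst_t,
        best_idx=best_t,
        excluded_mid_idx=idx[mid],
        trimmed_idx=np.asarray(sorted(trimmed), dtype=int),
        worst_betas=betas[worst_t],
        best_betas=betas[best_t],
    )


def compare_groups(worst_betas, best_betas, alpha: float = 0.05) -> GroupTestResult:
    """Compare the beta summaries of the two groups.

    Shapiro-Wilk is run per group and Bartlett across groups; only if all
    three p-values exceed alpha are the parametric requirements considered
    met and a two-sample t-test used.  Otherwise the two-sided
    Mann-Whitney U test compares the groups (exact enumeration when both
    groups have at most 8 untied observations, midrank normal
    approximation with tie correction otherwise).
    """
    w = np.asarray(worst_betas, dtype=float)
    b = np.asarray(best_betas, dtype=float)
    if len(w) < 3 or len(b) < 3:
        raise InsufficientDataError("each group needs >= 3 subjects for the normality test")
    sw_w = sps.shapiro(w).pvalue
    sw_b = sps.shapiro(b).pvalue
    bart = sps.bartlett(w, b).pvalue
    parametric = sw_w > alpha and sw_b > alpha and bart > alpha
    if parametric:
        stat, p = sps.ttest_ind(w, b)
        test = "t_test"
    else:
        pooled = np.concatenate([w, b])
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (max(len(w), len(b)) <= 8 and no_ties) else "asymptotic"
        res = sps.mannwhitneyu(w, b, alternative="two-sided", method=method)
        stat, p = res.statistic, res.pvalue
        test = "mann_whitney"
    return GroupTestResult(
        group_sizes=(len(w), len(b)),
        medians=(float(np.median(w)), float(np.median(b))),
        normality_p=(float(sw_w), float(sw_b)),
        variance_p=float(bart),
        test_used=test,
        statistic=float(stat),
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=alpha,
    )
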