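"""Continuous-time quantification of per-stride measures.

Per-stride (or per-step) samples are unevenly spaced in task time and
their count differs between subjects, so summaries are computed on a
shared grid by per-subject Gaussian-kernel smoothing: each subject
contributes one smoothed curve and one kernel-mass weight per grid point,
and every subject weighs equally in group statistics regardless of how
many strides they produced.

Deviations of the smoothed curves from a reference value (CCI = 1) are
tested with a weighted one-sample t-test at each grid point, corrected
for multiple comparisons over the grid by cluster-mass inference: the
null distribution of the maximum cluster mass is built by randomly
sign-flipping each subject's deviation (a seeded bootstrap), so the
family-wise error over the whole time course stays at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

DEFAULT_PER_MINUTE = 60.0


class TimecourseError(ValueError):
    """Invalid input to a time-course statistic."""


def minute_grid(total_duration: float, per_minute: int = 1,
                start: float = 0.0) -> np.ndarray:
    """Grid of quantification times: ``per_minute`` points per minute,
    centered in their bins (the per-minute convention places one point at
    every 30 s + k*60 s)."""
    spacing = 60.0 / per_minute
    return np.arange(start + spacing / 2.0, start + total_duration, spacing)


class KernelSmoother(BaseEstimator):
    """Gaussian-kernel smoother for one subject's (time, value) samples.

    ``predict(grid)`` returns the kernel-weighted mean of the fitted
    samples at each grid time; ``kernel_mass(grid)`` returns the summed
    kernel weight, used downstream to discount sparsely supported grid
    points.  The default bandwidth matches the grid spacing of per-minute
    quantification (resolution-matched smoothing).
    """

    def __init__(self, bandwidth: float = DEFAULT_PER_MINUTE):
        self.bandwidth = bandwidth

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KernelSmoother":
        times = np.asarray(X, dtype=float).ravel()
        values = np.asarray(y, dtype=float).ravel()
        if times.shape != values.shape:
            raise TimecourseError("times and values must align")
        keep = ~np.isnan(values)
        if keep.sum() == 0:
            raise TimecourseError("subject has no valid samples")
        if self.bandwidth <= 0:
            raise TimecourseError("bandwidth must be positive")
        self.times_ = times[keep]
        self.values_ = values[keep]
        return self

    def _kernel(self, grid: np.ndarray) -> np.ndarray:
        d = (np.asarray(grid, dtype=float)[:, None] - self.times_[None, :])
        return np.exp(-0.5 * (d / self.bandwidth) ** 2)

    def predict(self, grid: np.ndarray) -> np.ndarray:
        k = self._kernel(grid)
        mass = k.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (k @ self.values_) / mass
        out[mass <= 0] = np.nan
        return out

    def kernel_mass(self, grid: np.ndarray) -> np.ndarray:
        return self._kernel(grid).sum(axis=1)


@dataclass
class SmoothedSeries:
    """Per-subject smoothed curves on a shared grid."""

    grid: np.ndarray                 # task times, s
    values: np.ndarray               # (n_subjects, n_grid)
    weights: np.ndarray              # kernel mass, same shape
    subjects: list = field(default_factory=list)
    bandwidth: float = DEFAULT_PER_MINUTE

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def group_mean(self) -> np.ndarray:
        """Equal-subject-weight group curve."""
        return np.nanmean(self.values, axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, subject in enumerate(self.subjects or range(self.n_subjects)):
            for g, time_s in enumerate(self.grid):
                rows.append({"grid_s": time_s, "subject": subject,
                             "value": self.values[i, g],
                             "weight": self.weights[i, g]})
        return pd.DataFrame(rows)


def kernel_smooth(
    samples: pd.DataFrame,
    grid: np.ndarray,
    bandwidth: float = DEFAULT_PER_MINUTE,
    time_col: str = "time_s",
    value_col: str = "value",
    subject_col: str = "subject",
) -> SmoothedSeries:
    """Smooth per-subject samples onto a shared grid.

    ``samples`` is tidy with one row per observation.  Subjects with no
    sample within 3 bandwidths of any grid point contribute NaN there;
    subjects with no valid samples at all are excluded with a warning.
    """
    import warnings

    grid = np.asarray(grid, dtype=float)
    subjects = list(pd.unique(samples[subject_col]))
    values = np.full((len(subjects), len(grid)), np.nan)
    weights = np.zeros((len(subjects), len(grid)))
    kept_subjects = []
    row = 0
    for subject in subjects:
        chunk = samples.loc[samples[subject_col] == subject]
        try:
            smoother = KernelSmoother(bandwidth=bandwidth).fit(
                chunk[time_col].to_numpy(), chunk[value_col].to_numpy())
        except TimecourseError:
            warnings.warn(f"subject {subject!r} has no valid samples; excluded")
            continue
        mass = smoother.kernel_mass(grid)
        vals = smoother.predict(grid)
        # discount grid points with no sample within 3 bandwidths
        near = np.min(np.abs(grid[:, None] - smoother.times_[None, :]),
                      axis=1) <= 3 * bandwidth
        vals[~near] = np.nan
        mass[~near] = 0.0
        values[row] = vals
        weights[row] = mass
        kept_subjects.append(subject)
        row += 1
    return SmoothedSeries(grid=grid, values=values[:row], weights=weights[:row],
                          subjects=kept_subjects, bandwidth=bandwidth)


def _weighted_tmap(
    deviations: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise weighted one-sample t-statistics for subject deviations.

    Weights are normalized per grid point; the variance uses the
    reliability-weight correction and the effective sample size
    ``1 / sum(u^2)``.  With equal weights this reduces to the classic
    one-sample t.  Returns (t, df) arrays over the grid; df = n_valid - 1.
    """
    valid = ~np.isnan(deviations) & (weights > 0)
    w = np.where(valid, weights, 0.0)
    totals = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = w / totals
        d = np.where(valid, deviations, 0.0)
        mean = (u * d).sum(axis=0)
        second = (u * d * d).sum(axis=0)
        var = (second - mean**2) / (1.0 - (u**2).sum(axis=0))
        n_eff = 1.0 / (u**2).sum(axis=0)
        t = mean / np.sqrt(var / n_eff)
    df = valid.sum(axis=0) - 1
    t[totals <= 0] = np.nan
    return t, df


def _clusters_from_tmap(
    t: np.ndarray, crit: np.ndarray, direction: str
) -> list[tuple[int, int, float]]:
    """Maximal same-sign runs of supra-threshold t; (start, end, mass)."""
    if direction == "greater":
        supra = t > crit
    elif direction == "less":
        supra = t < -crit
    else:
        supra = np.abs(t) > crit
    supra &= ~np.isnan(t)
    clusters = []
    start = None
    sign = 0.0
    for i, on in enumerate(supra):
        s = np.sign(t[i]) if on else 0.0
        if on and start is not None and s == sign:
            continue
        if start is not None:
            clusters.append((start, i - 1, float(np.abs(t[start:i]).sum())))
            start = None
        if on:
            start = i
            sign = s
    if start is not None:
        clusters.append((start, len(t) - 1,
                         float(np.abs(t[start:]).sum())))
    return clusters


@dataclass
class ClusterResult:
    """Outcome of a cluster-corrected one-sample test."""

    grid: np.ndarray
    tvals: np.ndarray
    clusters: pd.DataFrame   # start_s, end_s, start_idx, end_idx, mass, p
    alpha: float
    n_boot: int
    direction: str
    null_value: float

    def significant_mask(self) -> np.ndarray:
        """Boolean per grid point: inside a significant cluster."""
        mask = np.zeros(len(self.grid), dtype=bool)
        for _, row in self.clusters.iterrows():
            if row["p"] < self.alpha:
                mask[int(row["start_idx"]):int(row["end_idx"]) + 1] = True
        return mask


class ClusterOneSampleTTest(BaseEstimator):
    """Weighted one-sample t-test over a grid with cluster-mass correction.

    ``fit(X, weights)`` takes per-subject smoothed values ``X`` of shape
    ``(n_subjects, n_grid)`` and tests them against ``null_value``.
    Clusters are maximal same-sign runs where the pointwise |t| exceeds
    the two-sided alpha threshold of a t-distribution with ``n_valid - 1``
    df; their mass is the summed |t|.  The null distribution of the
    maximum cluster mass is built by sign-flipping each subject's
    deviation from the null (``n_boot`` seeded resamples), and each
    observed cluster gets ``p = (1 + #null >= mass) / (1 + n_boot)``.

    Attributes (after ``fit``): ``tvals_``, ``clusters_`` (DataFrame),
    ``result_`` (:class:`ClusterResult`), ``null_max_mass_``.
    """

    def __init__(self, null_value: float = 1.0, alpha: float = 0.05,
                 n_boot: int = 1000, direction: str = "two-sided",
                 random_state: int | None = None):
        self.null_value = null_value
        self.alpha = alpha
        self.n_boot = n_boot
        self.direction = direction
        self.random_state = random_state

    def fit(self, X: np.ndarray, weights: np.ndarray | None = None,
            grid: np.ndarray | None = None) -> "ClusterOneSampleTTest":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise TimecourseError("X must be (n_subjects, n_grid)")
        n_subjects, n_grid = X.shape
        if np.sum(~np.all(np.isnan(X), axis=1)) < 5:
            raise TimecourseError(
                f"cluster test needs at least 5 subjects with data, got "
                f"{np.sum(~np.all(np.isnan(X), axis=1))}")
        if self.direction not in ("two-sided", "greater", "less"):
            raise TimecourseError(f"unknown direction {self.direction!r}")
        if self.n_boot < 100:
            import warnings
            warnings.warn(
                f"n_boot={self.n_boot} gives a coarse null distribution; "
                "p-values are unreliable below a few hundred resamples")
        w = (np.ones_like(X) if weights is None
             else np.asarray(weights, dtype=float))
        if w.shape != X.shape:
            raise TimecourseError("weights must match X in shape")
        grid = (np.arange(n_grid, dtype=float) if grid is None
                else np.asarray(grid, dtype=float))

        deviations = X - self.null_value
        t_obs, df = _weighted_tmap(deviations, w)
        # cluster-forming threshold: pointwise two-sided alpha
        crit = stats.t.ppf(1.0 - self.alpha / 2.0, np.maximum(df, 1))
        observed = _clusters_from_tmap(t_obs, crit, self.direction)

        rng = np.random.default_rng(self.random_state)
        signs = rng.choice([-1.0, 1.0], size=(self.n_boot, n_subjects))
        null_max = self._null_max_masses(deviations, w, crit, signs)

        rows = []
        for start, end, mass in observed:
            p = (1.0 + np.sum(null_max >= mass)) / (1.0 + self.n_boot)
            rows.append({"start_idx": start, "end_idx": end,
                         "start_s": grid[start], "end_s": grid[end],
                         "mass": mass, "p": p})
        clusters = pd.DataFrame(
            rows, columns=["start_idx", "end_idx", "start_s", "end_s",
                           "mass", "p"])
        self.tvals_ = t_obs
        self.df_ = df
        self.null_max_mass_ = null_max
        self.clusters_ = clusters
        self.result_ = ClusterResult(
            grid=grid, tvals=t_obs, clusters=clusters, alpha=self.alpha,
            n_boot=self.n_boot, direction=self.direction,
            null_value=self.null_value)
        return self

    def _null_max_masses(self, deviations, weights, crit, signs):
        """Max cluster mass per sign-flip resample.

        The weighted second moment is sign-invariant, so only the
        weighted mean needs recomputing per resample.
        """
        valid = ~np.isnan(deviations) & (weights > 0)
        w = np.where(valid, weights, 0.0)
        totals = w.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(totals > 0, w / totals, 0.0)
            d = np.where(valid, deviations, 0.0)
            second = (u * d * d).sum(axis=0)          # constant across flips
            sum_u2 = (u**2).sum(axis=0)
            means = signs @ (u * d)                   # (n_boot, n_grid)
            var = (second - means**2) / (1.0 - sum_u2)
            tmaps = means / np.sqrt(var / (1.0 / sum_u2))
        tmaps[:, totals <= 0] = np.nan
        out = np.zeros(signs.shape[0])
        for b in range(signs.shape[0]):
            clusters = _clusters_from_tmap(tmaps[b], crit, self.direction)
            if clusters:
                out[b] = max(c[2] for c in clusters)
        return out


def cluster_one_sample_test(
    series: SmoothedSeries,
    null_value: float = 1.0,
    alpha: float = 0.05,
    n_boot: int = 1000,
    direction: str = "two-sided",
    seed: int | None = None,
) -> ClusterResult:
    """Functional wrapper over :class:`ClusterOneSampleTTest`."""
    test = ClusterOneSampleTTest(null_value=null_value, alpha=alpha,
                                 n_boot=n_boot, direction=direction,
                                 random_state=seed)
    test.fit(series.values, weights=series.weights, grid=series.grid)
    return test.result_


def block_endpoint_summary(
    series: SmoothedSeries,
    blocks: Mapping[str, tuple[float, float]],
) -> pd.DataFrame:
    """First and last defined grid values within each block, per subject.

    Emits the input table for downstream repeated-measures comparisons
    (start/end of each block); blocks with no defined grid point yield
    NaN entries.
    """
    rows = []
    for i, subject in enumerate(series.subjects or range(series.n_subjects)):
        for block, (start, end) in blocks.items():
            in_block = (series.grid >= start) & (series.grid < end)
            defined = in_block & ~np.isnan(series.values[i])
            idx = np.flatnonzero(defined)
            rows.append({
                "subject": subject,
                "block": block,
                "start_value": series.values[i, idx[0]] if len(idx) else np.nan,
                "end_value": series.values[i, idx[-1]] if len(idx) else np.nan,
                "start_s": series.grid[idx[0]] if len(idx) else np.nan,
                "end_s": series.grid[idx[-1]] if len(idx) else np.nan,
            })
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    statistic: float
    pvalue: float
    n_removed: int
    n_a: int
    n_b: int


def iqr_outlier_mask(values: np.ndarray, factor: float = 1.5) -> np.ndarray:
    """True for values inside the Tukey fences (Q1 - f*IQR, Q3 + f*IQR)."""
    v = np.asarray(values, dtype=float)
    q1, q3 = np.nanpercentile(v, [25, 75])
    iqr = q3 - q1
    return (v >= q1 - factor * iqr) & (v <= q3 + factor * iqr)


def group_compare(
    group_a: np.ndarray,
    group_b: np.ndarray,
    outlier_rule: str = "iqr",
    iqr_factor: float = 1.5,
) -> GroupComparison:
    """Student t-test between two groups after outlier rejection.

    Per-subject summary values (e.g. per-minute CCI averaged over a block)
    are screened per group with 1.5x-IQR Tukey fences before a two-sample
    Student t-test (equal variances).  At least 3 values per group must
    survive.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    n_before = len(a) + len(b)
    if outlier_rule == "iqr":
        a = a[iqr_outlier_mask(a, iqr_factor)]
        b = b[iqr_outlier_mask(b, iqr_factor)]
    elif outlier_rule not in (None, "none"):
        raise TimecourseError(f"unknown outlier rule {outlier_rule!r}")
    if len(a) < 3 or len(b) < 3:
        raise TimecourseError(
            f"need at least 3 subjects per group after outlier rejection, "
            f"got {len(a)} and {len(b)}")
    pooled = np.concatenate([a - a.mean(), b - b.mean()])
    if np.allclose(pooled, 0.0):
        raise TimecourseError("degenerate (zero) within-group variance")
    stat, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(statistic=float(stat), pvalue=float(p),
                           n_removed=n_before - len(a) - len(b),
                           n_a=len(a), n_b=len(b))
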