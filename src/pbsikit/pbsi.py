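"""Person-based similarity index (PBSI) and regional contributions.

A subject's PBSI is the mean of the pairwise Spearman correlations between
their regional profile and every other same-group subject's profile. The
contribution of region ``i`` is the absolute change in a subject's PBSI when
region ``i`` is removed and the score fully recomputed (ranks included).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProfileMatrix",
    "GroupComparisonResult",
    "pairwise_spearman",
    "compute_pbsi",
    "regional_contributions",
    "group_pbsi",
    "group_contributions",
    "delta_contribution_map",
    "residualize",
    "compare_groups",
    "regionwise_group_difference",
    "correlate_with_covariates",
]


@dataclass
class ProfileMatrix:
    """Subject x region feature matrix with labels.

    values : (n_subjects, n_regions) float array, no missing values
    """

    values: np.ndarray
    subject_ids: list[str]
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subject x region array")
        n, r = self.values.shape
        if len(self.subject_ids) != n:
            raise ValueError(f"{len(self.subject_ids)} subject_ids for {n} rows")
        if len(self.region_labels) != r:
            raise ValueError(f"{len(self.region_labels)} region labels for {r} columns")
        if not np.isfinite(self.values).all():
            raise ValueError("profile values contain missing or non-finite entries")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids in profile matrix")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.region_labels,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ProfileMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            subject_ids=[str(s) for s in df.index],
            region_labels=[str(c) for c in df.columns],
        )


def _rank_rows(values: np.ndarray, context: str, subject_ids=None) -> np.ndarray:
    """Average-ranks per row; raise if any row is constant (undefined Spearman)."""
    spread = np.ptp(values, axis=1)
    if np.any(spread == 0):
        bad = np.flatnonzero(spread == 0)
        names = [subject_ids[i] for i in bad] if subject_ids else list(bad)
        raise ValueError(
            f"{context}: constant profile (zero rank variance) for subject(s) {names}; "
            "Spearman correlation is undefined"
        )
    return stats.rankdata(values, axis=1)


def pairwise_spearman(profiles: ProfileMatrix | np.ndarray) -> np.ndarray:
    """Subject-by-subject Spearman correlation matrix of profile rows.

    Ties receive average ranks. The result is symmetric with unit diagonal.
    """
    if isinstance(profiles, ProfileMatrix):
        values, ids = profiles.values, profiles.subject_ids
    else:
        values, ids = np.asarray(profiles, dtype=float), None
    n, r = values.shape
    if n < 2:
        raise ValueError("pairwise Spearman requires at least 2 subjects")
    if r < 2:
        raise ValueError("pairwise Spearman requires at least 2 regions")
    ranks = _rank_rows(values, "pairwise_spearman", ids)
    corr = np.corrcoef(ranks)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def compute_pbsi(corr: np.ndarray) -> np.ndarray:
    """Per-subject mean of off-diagonal correlations.

    ``corr`` must be symmetric with unit diagonal. With only two subjects
    both scores collapse to their single correlation; a warning is emitted.
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if corr.ndim != 2 or corr.shape[1] != n:
        raise ValueError("correlation matrix must be square")
    if n < 2:
        raise ValueError("PBSI requires at least 2 subjects")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    if n == 2:
        warnings.warn("PBSI on 2 subjects degenerates to a single pairwise "
                      "correlation", stacklevel=2)
    return (corr.sum(axis=1) - np.diag(corr)) / (n - 1)


def regional_contributions(profiles: ProfileMatrix | np.ndarray) -> np.ndarray:
    """Leave-one-region-out contribution matrix (subjects x regions).

    ``contribution[s, i] = |PBSI(all)[s] - PBSI(all minus region i)[s]|``,
    with ranks fully recomputed on each reduced profile.
    """
    values = profiles.values if isinstance(profiles, ProfileMatrix) else np.asarray(profiles, float)
    n, r = values.shape
    if r < 3:
        raise ValueError("regional contributions require at least 3 regions")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = compute_pbsi(pairwise_spearman(values))
        out = np.empty((n, r))
        for i in range(r):
            reduced = np.delete(values, i, axis=1)
            out[:, i] = np.abs(full - compute_pbsi(pairwise_spearman(reduced)))
    return out


def _group_apply(values: np.ndarray, groups: np.ndarray, fn) -> np.ndarray:
    groups = np.asarray(groups)
    out = None
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        if idx.size < 3:
            warnings.warn(f"group {g!r} has only 2 subjects; PBSI is degenerate",
                          stacklevel=3)
        res = fn(values[idx])
        if out is None:
            out = np.empty((values.shape[0],) + res.shape[1:])
        out[idx] = res
    return out


def group_pbsi(profiles: ProfileMatrix | np.ndarray, groups: Sequence) -> np.ndarray:
    """PBSI per subject, computed strictly within each diagnostic group."""
    values = profiles.values if isinstance(profiles, ProfileMatrix) else np.asarray(profiles, float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _group_apply(values, np.asarray(groups),
                            lambda v: compute_pbsi(pairwise_spearman(v)))


def group_contributions(profiles: ProfileMatrix | np.ndarray, groups: Sequence) -> np.ndarray:
    """Leave-one-region-out contributions computed within each group."""
    values = profiles.values if isinstance(profiles, ProfileMatrix) else np.asarray(profiles, float)
    return _group_apply(values, np.asarray(groups), regional_contributions)


def delta_contribution_map(
    contributions: np.ndarray,
    groups: Sequence,
    group_a: str = "ASD",
    group_b: str = "NC",
) -> np.ndarray:
    """Per-region difference of group-mean contributions (``group_a - group_b``)."""
    groups = np.asarray(groups)
    for g in (group_a, group_b):
        if not np.any(groups == g):
            raise ValueError(f"group {g!r} absent; delta map undefined")
    mean_a = contributions[groups == group_a].mean(axis=0)
    mean_b = contributions[groups == group_b].mean(axis=0)
    return mean_a - mean_b


# ---------------------------------------------------------------------------
# covariate-adjusted statistics
# ---------------------------------------------------------------------------

def _design(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n:
        raise ValueError(f"covariate rows ({cov.shape[0]}) != values ({n})")
    X = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient after adding intercept")
    return X


def residualize(values: np.ndarray, covariates=None) -> np.ndarray:
    """OLS residuals of ``values`` on an intercept plus ``covariates``."""
    y = np.asarray(values, dtype=float)
    X = _design(covariates, y.shape[0])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class GroupComparisonResult:
    """Outcome of a two-group comparison on covariate-residualized values."""

    statistic: float
    p_value: float
    test_name: str  # "two-sample t" | "Wilcoxon rank-sum"
    covariates_applied: bool
    group_sizes: dict = field(default_factory=dict)


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    # Shapiro-Wilk; constant samples are treated as non-normal
    if np.ptp(x) == 0:
        return False
    if x.size > 5000:
        return stats.normaltest(x).pvalue > alpha
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(x).pvalue > alpha


def compare_groups(values, group_labels, covariates=None,
                   normality_alpha: float = 0.05) -> GroupComparisonResult:
    """Covariate-adjusted two-group test with distribution-based selection.

    Shapiro-Wilk at ``normality_alpha`` on per-group model residuals selects
    the test. The normal branch is the group-coefficient t test of
    ``values ~ intercept + covariates + group`` (the covariate-adjusted
    two-sample t; identical to the pooled two-sample t when there are no
    covariates, and calibrated even when covariates are confounded with
    group). The non-normal branch is a Wilcoxon rank-sum test on
    covariate-adjusted values, with covariate effects estimated while
    controlling for group.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    uniq = pd.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"exactly 2 groups required, got {uniq.size}: {list(uniq)}")
    n = values.shape[0]
    X = _design(covariates, n)
    g = (labels == uniq[0]).astype(float)
    Xg = np.column_stack([X, g - g.mean()])
    if np.linalg.matrix_rank(Xg) < Xg.shape[1]:
        raise ValueError("group indicator is collinear with the covariates")
    beta, *_ = np.linalg.lstsq(Xg, values, rcond=None)
    model_resid = values - Xg @ beta
    adjusted = values - X @ beta[:-1]  # covariate part removed, group effect kept
    a_mask, b_mask = labels == uniq[0], labels == uniq[1]
    if min(int(a_mask.sum()), int(b_mask.sum())) < 3:
        raise ValueError("each group must have at least 3 subjects")

    if _is_normal(model_resid[a_mask], normality_alpha) and _is_normal(
            model_resid[b_mask], normality_alpha):
        # t test on the group coefficient of the full OLS fit
        dof = n - Xg.shape[1]
        sigma2 = float(model_resid @ model_resid) / dof
        xtx_inv = np.linalg.inv(Xg.T @ Xg)
        se = np.sqrt(sigma2 * xtx_inv[-1, -1])
        stat = float(beta[-1] / se)
        p = float(2.0 * stats.t.sf(abs(stat), dof)) if se > 0 else 1.0
        name = "two-sample t"
    else:
        stat, p = stats.ranksums(adjusted[a_mask], adjusted[b_mask])
        name = "Wilcoxon rank-sum"
    return GroupComparisonResult(
        statistic=float(stat), p_value=float(p), test_name=name,
        covariates_applied=covariates is not None,
        group_sizes={str(uniq[0]): int(a_mask.sum()), str(uniq[1]): int(b_mask.sum())},
    )


def regionwise_group_difference(
    contributions: np.ndarray,
    group_labels,
    covariates=None,
    alpha: float = 0.05,
    region_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-region group comparison with a Bonferroni ``alpha / n_regions`` threshold.

    Returns a DataFrame with columns ``region, statistic, p, test, significant``.
    """
    contributions = np.asarray(contributions, dtype=float)
    n_regions = contributions.shape[1]
    threshold = alpha / n_regions
    labels = region_labels if region_labels is not None else [str(i) for i in range(n_regions)]
    rows = []
    for i in range(n_regions):
        res = compare_groups(contributions[:, i], group_labels, covariates)
        rows.append((labels[i], res.statistic, res.p_value, res.test_name,
                     res.p_value < threshold))
    df = pd.DataFrame(rows, columns=["region", "statistic", "p", "test", "significant"])
    df.attrs["bonferroni_threshold"] = threshold
    return df


def _spearman_exact_p(rho: float, xr: np.ndarray, yr: np.ndarray) -> float:
    """Two-sided exact permutation p for small n (all n! permutations)."""
    n = xr.size
    perms = np.array(list(itertools.permutations(range(n))))
    yperm = yr[perms]  # (n!, n)
    xs = (xr - xr.mean()) / xr.std()
    ys = (yperm - yperm.mean(axis=1, keepdims=True)) / yperm.std(axis=1, keepdims=True)
    rhos = ys @ xs / n
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def correlate_with_covariates(x, y, covariates=None) -> tuple[float, float]:
    """Spearman correlation of two vectors after residualizing on covariates.

    Empty covariates mean a plain Spearman correlation. P-values use the
    large-sample t approximation, or exact permutation for n < 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 5:
        raise ValueError("at least 5 observations required")
    if covariates is not None:
        x = residualize(x, covariates)
        y = residualize(y, covariates)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant residuals; Spearman correlation undefined")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho = float(np.corrcoef(xr, yr)[0, 1])
    if x.size < 10:
        p = _spearman_exact_p(rho, xr, yr)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p
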