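"""Empirical-Bayes batch harmonization (ComBat) and its covariance extension.

Implements the parametric location/scale model: per feature, data are
standardized by a pooled fit of batch + covariates, per-batch location and
scale estimates are shrunk toward parametric priors (normal on location,
inverse-gamma on variance) by iterated empirical-Bayes updates, and the
batch effects are removed while covariate effects are restored.

The covariance extension (CovBat) additionally projects ComBat residuals
onto principal axes and removes residual batch location/scale differences in
the leading component scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pbsi import ProfileMatrix

__all__ = [
    "BatchDesign",
    "HarmonizationResult",
    "BlandAltmanResult",
    "combat",
    "covbat",
    "agreement_bland_altman",
]

EB_CONV_TOL = 1e-4
EB_MAX_ITER = 100


@dataclass
class BatchDesign:
    """Batch labels plus biological covariates to preserve."""

    batch_labels: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.batch_labels = np.asarray(self.batch_labels)
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != self.batch_labels.shape[0]:
                raise ValueError("covariate rows must match batch labels")

    def validate(self) -> tuple[np.ndarray, list]:
        batches = list(dict.fromkeys(self.batch_labels.tolist()))
        for b in batches:
            n_b = int(np.sum(self.batch_labels == b))
            if n_b < 2:
                raise ValueError(
                    f"batch {b!r} has {n_b} subject(s); ComBat requires >= 2 per batch"
                )
        onehot = np.column_stack(
            [(self.batch_labels == b).astype(float) for b in batches]
        )
        design = onehot if self.covariates is None else np.column_stack(
            [onehot, self.covariates]
        )
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("design matrix (batch + covariates) is rank deficient")
        return design, batches


@dataclass
class HarmonizationResult:
    adjusted: ProfileMatrix
    gamma_star: np.ndarray   # (n_batches, n_features) EB-shrunk locations
    delta2_star: np.ndarray  # (n_batches, n_features) EB-shrunk variances
    model: np.ndarray        # pooled regression coefficients (design cols x features)
    batches: list | None = None
    gamma_hat: np.ndarray | None = None   # raw per-batch locations (pre-shrinkage)
    delta2_hat: np.ndarray | None = None  # raw per-batch variances


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m * m) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _eb_fit(z_batch: np.ndarray, gamma_hat: np.ndarray, delta_hat: np.ndarray,
            gamma_bar: float, tau2: float, a: float, b: float
            ) -> tuple[np.ndarray, np.ndarray]:
    """Iterated EB updates for one batch (z_batch: n_b x features)."""
    n_b = z_batch.shape[0]
    gamma_star = gamma_hat.copy()
    delta2_star = delta_hat.copy()
    for _ in range(EB_MAX_ITER):
        g_new = (n_b * tau2 * gamma_hat + delta2_star * gamma_bar) / (
            n_b * tau2 + delta2_star
        )
        sse = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sse + b) / (n_b / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - gamma_star)), np.max(np.abs(d_new - delta2_star))
        )
        gamma_star, delta2_star = g_new, d_new
        if change < EB_CONV_TOL:
            break
    return gamma_star, delta2_star


def combat(data: ProfileMatrix | np.ndarray, design: BatchDesign) -> HarmonizationResult:
    """Parametric empirical-Bayes batch harmonization of a subject x feature matrix.

    With a single batch the input is returned unchanged (nothing to remove);
    EB shrinkage would otherwise rescale residuals without cause.
    """
    if isinstance(data, ProfileMatrix):
        values, subject_ids, labels = data.values, data.subject_ids, data.region_labels
    else:
        values = np.asarray(data, dtype=float)
        subject_ids = [str(i) for i in range(values.shape[0])]
        labels = [str(j) for j in range(values.shape[1])]
    if not np.isfinite(values).all():
        raise ValueError("data contain missing or non-finite values")
    X, batches = design.validate()
    n, p = values.shape
    if X.shape[0] != n:
        raise ValueError("design rows must match data rows")
    n_batches = len(batches)

    if n_batches == 1:
        warnings.warn("single batch: harmonization is a no-op", stacklevel=2)
        adjusted = ProfileMatrix(values.copy(), list(subject_ids), list(labels))
        beta, *_ = np.linalg.lstsq(X, values, rcond=None)
        return HarmonizationResult(adjusted, np.zeros((1, p)), np.ones((1, p)),
                                   beta, batches)

    batch_idx = [np.flatnonzero(design.batch_labels == b) for b in batches]
    sizes = np.array([idx.size for idx in batch_idx], dtype=float)

    # pooled fit: per-batch intercepts + covariates
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    grand_mean = (sizes / n) @ beta[:n_batches]           # (features,)
    resid_full = values - X @ beta
    var_pooled = (resid_full ** 2).mean(axis=0)           # (features,)
    if np.any(var_pooled <= 0):
        bad = [labels[j] for j in np.flatnonzero(var_pooled <= 0)]
        raise ValueError(f"zero pooled residual variance in feature(s) {bad}")

    # standardized data: remove grand mean + covariate effects, scale to unit var
    stand_mean = np.tile(grand_mean, (n, 1))
    if design.covariates is not None:
        stand_mean += design.covariates @ beta[n_batches:]
    z = (values - stand_mean) / np.sqrt(var_pooled)

    gamma_hat = np.vstack([z[idx].mean(axis=0) for idx in batch_idx])
    delta_hat = np.vstack([z[idx].var(axis=0, ddof=1) for idx in batch_idx])
    if np.any(delta_hat <= 0):
        b_i, f_i = np.argwhere(delta_hat <= 0)[0]
        raise ValueError(
            f"zero within-batch variance (batch {batches[b_i]!r}, "
            f"feature {labels[f_i]!r}); cannot standardize"
        )

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta_hat)
    for i, idx in enumerate(batch_idx):
        gamma_bar = gamma_hat[i].mean()
        tau2 = gamma_hat[i].var(ddof=1)
        a, b = _aprior(delta_hat[i]), _bprior(delta_hat[i])
        gamma_star[i], delta2_star[i] = _eb_fit(
            z[idx], gamma_hat[i], delta_hat[i], gamma_bar, tau2, a, b
        )

    z_adj = z.copy()
    for i, idx in enumerate(batch_idx):
        z_adj[idx] = (z[idx] - gamma_star[i]) / np.sqrt(delta2_star[i])
    adjusted_values = z_adj * np.sqrt(var_pooled) + stand_mean

    adjusted = ProfileMatrix(adjusted_values, list(subject_ids), list(labels))
    return HarmonizationResult(adjusted, gamma_star, delta2_star, beta, batches,
                               gamma_hat=gamma_hat, delta2_hat=delta_hat)


def covbat(
    data: ProfileMatrix | np.ndarray,
    design: BatchDesign,
    var_explained: float = 0.95,
) -> HarmonizationResult:
    """ComBat followed by batch harmonization of principal-component scores.

    Residuals of the ComBat output (after removing intercept + covariate
    effects) are projected onto the principal axes capturing
    ``var_explained`` of their variance; each retained score is adjusted to
    common per-batch location and scale, and the data reconstructed.
    """
    if not 0 < var_explained <= 1:
        raise ValueError(f"var_explained must be in (0, 1], got {var_explained}")
    base = combat(data, design)
    values = base.adjusted.values
    n = values.shape[0]
    _, batches = design.validate()
    if len(batches) == 1:
        return base

    # residualize on intercept + covariates (batch effects already removed)
    X = np.ones((n, 1)) if design.covariates is None else np.column_stack(
        [np.ones(n), design.covariates]
    )
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    fitted = X @ beta
    resid = values - fitted

    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    var_frac = np.cumsum(s ** 2) / np.sum(s ** 2)
    k = int(np.searchsorted(var_frac, var_explained - 1e-12) + 1)
    scores = u[:, :k] * s[:k]                     # (n, k)

    batch_idx = [np.flatnonzero(design.batch_labels == b) for b in batches]
    pooled_mean = scores.mean(axis=0)
    pooled_sd = scores.std(axis=0, ddof=1)
    scores_adj = scores.copy()
    for idx in batch_idx:
        m = scores[idx].mean(axis=0)
        sd = scores[idx].std(axis=0, ddof=1)
        sd = np.where(sd <= 0, 1.0, sd)
        scores_adj[idx] = (scores[idx] - m) / sd * pooled_sd + pooled_mean

    resid_adj = resid - scores @ vt[:k] + scores_adj @ vt[:k]
    adjusted_values = fitted + resid_adj
    adjusted = ProfileMatrix(
        adjusted_values, list(base.adjusted.subject_ids),
        list(base.adjusted.region_labels)
    )
    return HarmonizationResult(adjusted, base.gamma_star, base.delta2_star,
                               base.model, base.batches)


@dataclass
class BlandAltmanResult:
    bias: float
    sd: float
    lower: float
    upper: float
    fraction_inside: float


def agreement_bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman agreement between two per-subject measurement vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("at least 3 paired observations required")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lower, upper = bias - 1.96 * sd, bias + 1.96 * sd
    inside = float(np.mean((d >= lower) & (d <= upper)))
    return BlandAltmanResult(bias=bias, sd=sd, lower=lower, upper=upper,
                             fraction_inside=inside)
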