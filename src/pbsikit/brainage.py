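"""Brain-age modelling on regional-contribution features.

Three linear-kernel regressors (epsilon-SVR with nested grid search for C,
sparse-Bayesian relevance vector regression fit by expectation maximization
on a precomputed linear kernel, and Gaussian-process regression with
marginal-likelihood hyperparameter selection) are trained on typically
developing subjects with age-stratified shuffled cross-validation; the
brain age gap is the difference between predicted and chronological age, and
subjects are split into delayed / premature development groups by a
half-standard-deviation rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, DotProduct, WhiteKernel
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .pbsi import GroupComparisonResult, compare_groups

__all__ = [
    "DEFAULT_C_GRID",
    "BrainAgeConfig",
    "ModelPerformance",
    "BrainAgeResult",
    "fit_svr_linear",
    "fit_rvr",
    "fit_gpr_linear",
    "cross_validated_brainage",
    "compare_models_mae",
    "split_ded_prd",
    "compare_ded_prd_cognition",
    "site_residualized_age",
]

# 9-point log grid for the SVR regularization constant
DEFAULT_C_GRID = (2.0 ** -7, 2.0 ** -5, 2.0 ** -3, 2.0 ** -1,
                  1.0, 2.0, 2.0 ** 3, 2.0 ** 5, 2.0 ** 7)


@dataclass(frozen=True)
class BrainAgeConfig:
    model: str = "rvr"  # "svr" | "rvr" | "gpr"
    c_grid: tuple = DEFAULT_C_GRID
    n_folds: int = 10
    n_shuffles: int = 10
    n_age_bins: int = 10
    split_sd_factor: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.model not in ("svr", "rvr", "gpr"):
            raise ValueError(f"unknown model {self.model!r}")
        if any(c <= 0 for c in self.c_grid):
            raise ValueError("C grid must be strictly positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.split_sd_factor <= 0:
            raise ValueError("split_sd_factor must be positive")


class _Standardizer:
    def fit(self, X: np.ndarray) -> "_Standardizer":
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.sd_


# ---------------------------------------------------------------------------
# regressors
# ---------------------------------------------------------------------------

class _SVRPredictor:
    def __init__(self, scaler: _Standardizer, model: SVR, C: float):
        self.scaler, self.model, self.C = scaler, model, C

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(self.scaler.transform(np.asarray(X, float)))


def fit_svr_linear(X, y, c_grid=DEFAULT_C_GRID, inner_folds: int = 5,
                   seed: int = 0) -> tuple[_SVRPredictor, float]:
    """Linear epsilon-SVR; C chosen by inner-CV mean absolute error.

    The grid search sees only the data passed here, so calling this on a
    training fold keeps hyperparameter selection nested.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in features or targets")
    n = X.shape[0]
    inner_folds = min(inner_folds, n)
    if n < inner_folds or n < 2:
        raise ValueError(f"need at least {max(2, inner_folds)} samples, got {n}")
    scaler = _Standardizer().fit(X)
    Xs = scaler.transform(X)
    kf = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xs))
    best_c, best_mae = None, np.inf
    for C in c_grid:
        errs = []
        for tr, va in splits:
            m = SVR(kernel="linear", C=C)
            m.fit(Xs[tr], y[tr])
            errs.append(np.abs(m.predict(Xs[va]) - y[va]).mean())
        mae = float(np.mean(errs))
        if mae < best_mae:
            best_mae, best_c = mae, C
    model = SVR(kernel="linear", C=best_c)
    model.fit(Xs, y)
    return _SVRPredictor(scaler, model, best_c), best_c


class RVRegressor:
    """Sparse Bayesian regression over a precomputed linear kernel.

    Basis functions are a bias term plus one linear-kernel column per
    training sample; per-basis precisions and the noise variance are updated
    by EM until the maximum relative change drops below ``tol``. Bases whose
    precision exceeds ``prune_threshold`` are pruned (their training points
    cease to be relevance vectors).
    """

    def __init__(self, tol: float = 1e-4, max_iter: int = 500,
                 prune_threshold: float = 1e9):
        self.tol = tol
        self.max_iter = max_iter
        self.prune_threshold = prune_threshold

    def fit(self, X, y) -> "RVRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise ValueError("non-finite values in features or targets")
        n = X.shape[0]
        self.scaler_ = _Standardizer().fit(X)
        Xs = self.scaler_.transform(X)
        self.y_mean_ = y.mean()
        t = y - self.y_mean_
        self.degenerate_ = n < 2
        if self.degenerate_:
            warnings.warn("single training point: RVR predicts its target "
                          "everywhere", stacklevel=2)
            self.Xtrain_ = Xs
            self.kept_ = np.array([0])
            self.mu_ = np.array([0.0])
            self.has_bias_ = True
            return self

        K = Xs @ Xs.T
        if not np.isfinite(K).all():
            raise ValueError("non-finite entries in the precomputed kernel")
        Phi = np.column_stack([np.ones(n), K])  # bias + kernel bases
        M = Phi.shape[1]
        alpha = np.full(M, 1e-6)
        y_var = t.var()
        sigma2 = 0.1 * y_var if y_var > 0 else 1e-6
        keep = np.ones(M, dtype=bool)
        mu = np.zeros(M)
        for _ in range(self.max_iter):
            Pk = Phi[:, keep]
            Ak = alpha[keep]
            H = Pk.T @ Pk / sigma2 + np.diag(Ak)
            # jitter for near-singular systems
            H[np.diag_indices_from(H)] += 1e-10
            Sigma = np.linalg.inv(H)
            mu_k = Sigma @ (Pk.T @ t) / sigma2
            diag_S = np.diag(Sigma)
            gamma = 1.0 - Ak * diag_S
            # evidence fixed-point (MacKay) re-estimates: same stationary
            # points as plain EM but without its stall on irrelevant bases
            alpha_new = np.clip(gamma / np.maximum(mu_k ** 2, 1e-300), 1e-12,
                                10 * self.prune_threshold)
            resid = t - Pk @ mu_k
            sigma2_new = (resid @ resid) / max(n - gamma.sum(), 1e-6)
            sigma2_new = max(sigma2_new, 1e-12)
            rel = np.abs(alpha_new - Ak) / np.maximum(Ak, 1e-12)
            rel_s = abs(sigma2_new - sigma2) / max(sigma2, 1e-12)
            alpha[keep] = alpha_new
            sigma2 = sigma2_new
            mu = np.zeros(M)
            mu[keep] = mu_k
            newly_pruned = alpha > self.prune_threshold
            if newly_pruned[keep].any():
                keep &= ~newly_pruned
                if not keep.any():
                    keep[np.argmin(alpha)] = True
                continue
            if max(rel.max(initial=0.0), rel_s) < self.tol:
                break
        self.Xtrain_ = Xs
        self.sigma2_ = sigma2
        self.alpha_ = alpha
        self.keep_mask_ = keep
        self.has_bias_ = bool(keep[0])
        self.kept_ = np.flatnonzero(keep[1:])  # indices of relevance vectors
        self.mu_ = mu[keep]
        return self

    @property
    def n_relevance_vectors(self) -> int:
        return int(self.kept_.size)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xs = self.scaler_.transform(X)
        if self.degenerate_:
            return np.full(X.shape[0], self.y_mean_)
        # assemble design: bias column then kernel columns for kept vectors
        parts = []
        if self.has_bias_:
            parts.append(np.ones((X.shape[0], 1)))
        if self.kept_.size:
            parts.append(Xs @ self.Xtrain_[self.kept_].T)
        Phi = np.hstack(parts) if parts else np.zeros((X.shape[0], 0))
        return Phi @ self.mu_ + self.y_mean_


def fit_rvr(X, y) -> tuple[RVRegressor, np.ndarray]:
    """Fit an RVR; returns the predictor and its relevance weights."""
    model = RVRegressor().fit(X, y)
    return model, model.mu_


class _GPRPredictor:
    def __init__(self, scaler: _Standardizer, model: GaussianProcessRegressor):
        self.scaler, self.model = scaler, model

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(self.scaler.transform(np.asarray(X, float)))


def fit_gpr_linear(X, y, seed: int = 0) -> tuple[_GPRPredictor, dict]:
    """GP regression with a linear kernel + white noise, hyperparameters by
    maximizing the log marginal likelihood."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in features or targets")
    scaler = _Standardizer().fit(X)
    kernel = (ConstantKernel(1.0, (1e-4, 1e4)) * DotProduct(sigma_0=1.0)
              + WhiteKernel(noise_level=1.0, noise_level_bounds=(1e-8, 1e4)))
    gpr = GaussianProcessRegressor(kernel=kernel, alpha=1e-10,
                                   normalize_y=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gpr.fit(scaler.transform(X), y)
    return _GPRPredictor(scaler, gpr), {"kernel": str(gpr.kernel_),
                                        "lml": float(gpr.log_marginal_likelihood_value_)}


def _fit_model(name: str, X, y, c_grid, seed: int):
    if name == "svr":
        return fit_svr_linear(X, y, c_grid=c_grid, seed=seed)[0]
    if name == "rvr":
        return fit_rvr(X, y)[0]
    if name == "gpr":
        return fit_gpr_linear(X, y, seed=seed)[0]
    raise ValueError(f"unknown model {name!r}")


# ---------------------------------------------------------------------------
# cross-validated brain age
# ---------------------------------------------------------------------------

@dataclass
class ModelPerformance:
    """Per-shuffle validation metrics (pooled over folds within a shuffle)."""

    model: str
    rho: np.ndarray
    mae: np.ndarray
    rmse: np.ndarray

    def summary(self) -> dict:
        return {
            "model": self.model,
            "rho_mean": float(self.rho.mean()), "rho_sd": float(self.rho.std(ddof=1)) if self.rho.size > 1 else 0.0,
            "mae_mean": float(self.mae.mean()), "mae_sd": float(self.mae.std(ddof=1)) if self.mae.size > 1 else 0.0,
            "rmse_mean": float(self.rmse.mean()), "rmse_sd": float(self.rmse.std(ddof=1)) if self.rmse.size > 1 else 0.0,
        }


@dataclass
class BrainAgeResult:
    """Per-subject brain age (mean prediction), gap and development label."""

    brain_age: np.ndarray
    age: np.ndarray
    gap: np.ndarray = field(default=None)
    dev_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.gap is None:
            self.gap = self.brain_age - self.age


def stratified_age_folds(age: np.ndarray, n_folds: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Fold assignment balanced over the age distribution.

    Subjects are ordered by age (random tie-breaking) and consecutive blocks
    of ``n_folds`` are dealt to folds in random order, so every fold spans
    the full age range.
    """
    n = age.size
    if n < n_folds:
        raise ValueError(f"{n} subjects cannot fill {n_folds} folds")
    order = np.argsort(age + 1e-9 * rng.standard_normal(n), kind="stable")
    folds = np.empty(n, dtype=int)
    for start in range(0, n, n_folds):
        block = order[start:start + n_folds]
        folds[block] = rng.permutation(n_folds)[: block.size]
    return folds


def cross_validated_brainage(
    nc_X, nc_age, config: BrainAgeConfig, asd_X=None, asd_age=None,
) -> tuple[ModelPerformance, BrainAgeResult, BrainAgeResult | None]:
    """Shuffled, age-stratified k-fold brain-age estimation.

    Per shuffle: NCs are split into age-stratified folds; each fold's model
    is trained on the remaining folds (SVR hyperparameter search stays inside
    the training folds) and predicts the held-out NCs plus, if given, every
    ASD subject. Validation metrics (Spearman rho, MAE, RMSE) are pooled per
    shuffle. Final brain age is the mean held-out prediction over shuffles
    for NCs and the mean over all fold-models and shuffles for ASDs.
    """
    config.validate()
    nc_X = np.asarray(nc_X, dtype=float)
    nc_age = np.asarray(nc_age, dtype=float)
    if nc_X.shape[0] != nc_age.size:
        raise ValueError("NC features and ages are misaligned")
    has_asd = asd_X is not None
    if has_asd:
        asd_X = np.asarray(asd_X, dtype=float)
        asd_age = np.asarray(asd_age, dtype=float)
        if asd_X.shape[0] != asd_age.size:
            raise ValueError("ASD features and ages are misaligned")

    n_nc = nc_X.shape[0]
    rhos, maes, rmses = [], [], []
    nc_pred_sum = np.zeros(n_nc)
    asd_pred_sum = np.zeros(asd_X.shape[0]) if has_asd else None
    fold_assignments = []

    for shuffle in range(config.n_shuffles):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, shuffle]))
        folds = stratified_age_folds(nc_age, config.n_folds, rng)
        fold_assignments.append(folds)
        nc_pred = np.empty(n_nc)
        for k in range(config.n_folds):
            val = folds == k
            tr = ~val
            model = _fit_model(config.model, nc_X[tr], nc_age[tr],
                               config.c_grid, seed=config.seed * 1000 + shuffle)
            nc_pred[val] = model.predict(nc_X[val])
            if has_asd:
                asd_pred_sum += model.predict(asd_X)
        err = nc_pred - nc_age
        rhos.append(stats.spearmanr(nc_pred, nc_age).statistic)
        maes.append(np.abs(err).mean())
        rmses.append(np.sqrt((err ** 2).mean()))
        nc_pred_sum += nc_pred

    perf = ModelPerformance(model=config.model, rho=np.asarray(rhos),
                            mae=np.asarray(maes), rmse=np.asarray(rmses))
    perf.fold_assignments = fold_assignments
    nc_result = BrainAgeResult(brain_age=nc_pred_sum / config.n_shuffles, age=nc_age)
    asd_result = None
    if has_asd:
        asd_result = BrainAgeResult(
            brain_age=asd_pred_sum / (config.n_shuffles * config.n_folds),
            age=asd_age,
        )
    return perf, nc_result, asd_result


def compare_models_mae(*performances: ModelPerformance,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise paired t tests on per-shuffle MAE, Bonferroni over pairs.

    Zero-variance difference vectors are reported as degenerate exact
    differences (p = 1 if identical, p = 0 otherwise).
    """
    if len(performances) < 2:
        raise ValueError("need at least two model performances")
    n_sh = performances[0].mae.size
    for p in performances:
        if p.mae.size != n_sh:
            raise ValueError("mismatched shuffle counts between models")
    pairs = [(i, j) for i in range(len(performances)) for j in range(i + 1, len(performances))]
    threshold = alpha / len(pairs)
    rows = []
    for i, j in pairs:
        a, b = performances[i], performances[j]
        d = a.mae - b.mae
        if np.ptp(d) == 0:
            t, p = (0.0, 1.0) if d[0] == 0 else (np.inf * np.sign(d[0]), 0.0)
        else:
            t, p = stats.ttest_rel(a.mae, b.mae)
        rows.append((a.model, b.model, float(t), float(p), p < threshold))
    df = pd.DataFrame(rows, columns=["model_a", "model_b", "t", "p", "significant"])
    df.attrs["bonferroni_threshold"] = threshold
    return df


def split_ded_prd(result: BrainAgeResult, sd_factor: float = 0.5) -> BrainAgeResult:
    """Partition subjects into delayed (DED) / premature (PRD) / neither.

    SD is the standard deviation of brain age over the given sample.
    DED: brain_age + sd_factor*SD < age; PRD: brain_age - sd_factor*SD > age.
    """
    if result.brain_age.size < 2:
        raise ValueError("need at least 2 subjects to compute the SD")
    sd = float(np.std(result.brain_age, ddof=1))
    labels = np.full(result.brain_age.size, "neither", dtype=object)
    if sd == 0:
        warnings.warn("zero SD of brain age: all subjects labelled 'neither'",
                      stacklevel=2)
    else:
        labels[result.brain_age + sd_factor * sd < result.age] = "DED"
        labels[result.brain_age - sd_factor * sd > result.age] = "PRD"
    return BrainAgeResult(brain_age=result.brain_age, age=result.age,
                          gap=result.gap, dev_label=np.asarray(labels))


COGNITION_SCORES = ("fiq", "adi_rrb", "adi_soc", "adi_ver")


def compare_ded_prd_cognition(
    split: BrainAgeResult, phenotypes: pd.DataFrame,
    scores: tuple[str, ...] = COGNITION_SCORES,
) -> dict[str, GroupComparisonResult]:
    """DED vs PRD comparison of cognition scores with age + sex covariates."""
    if split.dev_label is None:
        raise ValueError("run split_ded_prd first")
    labels = np.asarray(split.dev_label)
    mask = np.isin(labels, ("DED", "PRD"))
    if not (np.any(labels == "DED") and np.any(labels == "PRD")):
        raise ValueError("both DED and PRD groups must be non-empty")
    out = {}
    cov = phenotypes[["age", "sex"]].to_numpy(dtype=float)
    for score in scores:
        y = phenotypes[score].to_numpy(dtype=float)
        ok = mask & np.isfinite(y)
        out[score] = compare_groups(y[ok], labels[ok], cov[ok])
    return out


def site_residualized_age(age, site_labels) -> np.ndarray:
    """Age with per-site mean differences regressed out (grand mean restored)."""
    age = np.asarray(age, dtype=float)
    sites = np.asarray(site_labels)
    uniq = pd.unique(sites)
    if uniq.size < 2:
        warnings.warn("single site: age returned unchanged", stacklevel=2)
        return age.copy()
    adjusted = age.copy()
    grand = age.mean()
    for s in uniq:
        m = sites == s
        adjusted[m] = age[m] - age[m].mean() + grand
    return adjusted
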