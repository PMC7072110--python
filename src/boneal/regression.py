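"""Bone-age regression: age scaling, SVR/KRR, cross-validation, ensembles.

Ages are scaled from [0, 228] months to [0, 1] before fitting and projected
back for evaluation, so every reported MAE/RMSE is in months. The base
regressors are epsilon-insensitive linear support vector regression (SVR,
penalty C = 1.0, stopping tolerance 1e-3) and kernel ridge regression
(KRR, regularization alpha = 1.0) with a linear kernel by default — a
degree-3 polynomial kernel is available as a configuration alternative.
Ensembles bootstrap-aggregate (bagging) or sequentially reweight
(AdaBoost.R2) KRR base estimators. Separate fits for male and female
cohorts are supported, since skeletal maturation timing differs by sex.

Model fitting is delegated to scikit-learn; evaluation uses the package's
own MAE/RMSE/CCC statistics.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np

from .metrics import RegressionEvalReport, regression_report

logger = logging.getLogger(__name__)

MIN_MONTHS = 0.0
MAX_MONTHS = 228.0


class ContractError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


def scale_age(months: np.ndarray | float) -> np.ndarray | float:
    """Map [0, 228] months onto [0, 1]."""
    arr = np.asarray(months, dtype=np.float64)
    if np.any(arr < MIN_MONTHS) or np.any(arr > MAX_MONTHS):
        raise ContractError(f"ages must lie in [{MIN_MONTHS:.0f}, {MAX_MONTHS:.0f}] months")
    out = arr / MAX_MONTHS
    return float(out) if np.isscalar(months) else out


def unscale_age(scaled: np.ndarray | float) -> np.ndarray | float:
    """Map a scaled prediction back to months, clipping to [0, 228] with a warning."""
    arr = np.asarray(scaled, dtype=np.float64)
    months = arr * MAX_MONTHS
    if np.any(months < MIN_MONTHS) or np.any(months > MAX_MONTHS):
        logger.warning("prediction outside [0, 228] months: clipping")
        months = np.clip(months, MIN_MONTHS, MAX_MONTHS)
    return float(months) if np.isscalar(scaled) else months


@dataclasses.dataclass(frozen=True)
class RegressorConfig:
    family: str = "krr"  # "svr" | "krr"
    kernel: str = "linear"  # "linear" | "polynomial"
    svr_penalty: float = 1.0
    svr_tolerance: float = 1e-3
    svr_epsilon: float = 0.01  # scaled age units
    krr_regularization: float = 1.0
    poly_degree: int = 3

    def __post_init__(self) -> None:
        if self.family not in ("svr", "krr"):
            raise ConfigurationError("family must be 'svr' or 'krr'")
        if self.kernel not in ("linear", "polynomial"):
            raise ConfigurationError("kernel must be 'linear' or 'polynomial'")
        if self.svr_penalty <= 0 or self.krr_regularization <= 0:
            raise ConfigurationError("penalty and regularization must be > 0")


@dataclasses.dataclass(frozen=True)
class EnsembleConfig:
    method: str = "bagging"  # "bagging" | "adaboost"
    n_estimators: int = 21
    base: RegressorConfig = dataclasses.field(default_factory=RegressorConfig)
    seed: int = 0
    bootstrap: bool = True  # bagging only; False trains every member on the full set

    def __post_init__(self) -> None:
        if self.method not in ("bagging", "adaboost"):
            raise ConfigurationError("method must be 'bagging' or 'adaboost'")
        if self.n_estimators < 1:
            raise ConfigurationError("n_estimators must be >= 1")


@dataclasses.dataclass
class FittedRegressor:
    """A fitted scaled-age regressor; predicts in scaled [0, 1] units."""

    estimator: object
    config: RegressorConfig | EnsembleConfig
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ContractError(f"expected {self.n_features} features, got {X.shape[1]}")
        return np.asarray(self.estimator.predict(X), dtype=np.float64)

    def predict_months(self, X: np.ndarray) -> np.ndarray:
        return unscale_age(self.predict(X))


def _base_estimator(config: RegressorConfig):
    """SVR or KRR behind the package's estimator convention.

    Features are z-scored on the training data (standard for kernel
    methods; otherwise the regularizer's effect depends on arbitrary
    feature units), and KRR is fit on centered targets since it has no
    native intercept: yhat = ybar + K_x (K + alpha I)^-1 (y - ybar).
    """
    from sklearn.compose import TransformedTargetRegressor
    from sklearn.kernel_ridge import KernelRidge
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVR

    kernel = "linear" if config.kernel == "linear" else "poly"
    if config.family == "svr":
        if kernel == "linear":
            svr = SVR(kernel="linear", C=config.svr_penalty, tol=config.svr_tolerance, epsilon=config.svr_epsilon)
        else:
            svr = SVR(
                kernel="poly", degree=config.poly_degree, C=config.svr_penalty,
                tol=config.svr_tolerance, epsilon=config.svr_epsilon,
            )
        return make_pipeline(StandardScaler(), svr)
    if kernel == "linear":
        krr = KernelRidge(kernel="linear", alpha=config.krr_regularization)
    else:
        krr = KernelRidge(kernel="poly", degree=config.poly_degree, alpha=config.krr_regularization)
    centered = TransformedTargetRegressor(regressor=krr, transformer=StandardScaler(with_std=False))
    return make_pipeline(StandardScaler(), centered)


def _validate_xy(features: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64).ravel()
    if X.ndim != 2:
        raise ContractError("features must be a 2-D matrix")
    if X.shape[0] != y.size:
        raise ContractError(f"{X.shape[0]} feature rows vs {y.size} targets")
    if X.shape[0] < 2:
        raise ContractError("need at least 2 samples")
    if np.allclose(X.var(axis=0), 0):
        warnings.warn("all features have zero variance; fit proceeds but is uninformative")
    return X, y


def fit_regressor(
    features: np.ndarray, scaled_ages: np.ndarray, config: RegressorConfig | None = None
) -> FittedRegressor:
    """Fit a single SVR or KRR on scaled ages. Deterministic given inputs."""
    config = config or RegressorConfig()
    X, y = _validate_xy(features, scaled_ages)
    est = _base_estimator(config)
    est.fit(X, y)
    return FittedRegressor(estimator=est, config=config, n_features=X.shape[1])


def fit_ensemble(
    features: np.ndarray, scaled_ages: np.ndarray, config: EnsembleConfig | None = None
) -> FittedRegressor:
    """Bagging (bootstrap mean) or AdaBoost.R2 ensemble of base regressors."""
    from sklearn.ensemble import AdaBoostRegressor, BaggingRegressor

    config = config or EnsembleConfig()
    X, y = _validate_xy(features, scaled_ages)
    base = _base_estimator(config.base)
    if config.method == "bagging":
        est = BaggingRegressor(
            estimator=base,
            n_estimators=config.n_estimators,
            bootstrap=config.bootstrap,
            random_state=config.seed,
        )
    else:
        est = AdaBoostRegressor(
            estimator=base,
            n_estimators=config.n_estimators,
            loss="linear",
            random_state=config.seed,
        )
    est.fit(X, y)
    return FittedRegressor(estimator=est, config=config, n_features=X.shape[1])


@dataclasses.dataclass(frozen=True)
class CVReport:
    """Per-fold and pooled evaluation of one regression configuration."""

    folds: tuple[RegressionEvalReport, ...]
    pooled: RegressionEvalReport
    fold_assignment: tuple[int, ...]  # fold index of each input row
    predictions_months: np.ndarray  # pooled out-of-fold predictions, input order


def cross_validate(
    features: np.ndarray,
    ages_months: np.ndarray,
    config: RegressorConfig | EnsembleConfig | None = None,
    folds: int = 5,
    seed: int = 0,
    cohort: str = "all",
) -> CVReport:
    """Seeded shuffled k-fold CV; metrics evaluated in months on held-out folds.

    The pooled report concatenates every fold's out-of-fold predictions, so
    each sample contributes exactly once.
    """
    from sklearn.model_selection import KFold

    config = config or RegressorConfig()
    X, y_months = _validate_xy(features, ages_months)
    n = X.shape[0]
    if folds > n:
        raise ConfigurationError(f"folds = {folds} exceeds n = {n}")
    y_scaled = scale_age(y_months)

    assignment = np.empty(n, dtype=int)
    preds_months = np.empty(n, dtype=np.float64)
    fold_reports = []
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for fold_idx, (train, test) in enumerate(kf.split(X)):
        if isinstance(config, EnsembleConfig):
            fitted = fit_ensemble(X[train], y_scaled[train], config)
        else:
            fitted = fit_regressor(X[train], y_scaled[train], config)
        pm = fitted.predict_months(X[test])
        preds_months[test] = pm
        assignment[test] = fold_idx
        fold_reports.append(regression_report(y_months[test], pm, cohort=cohort))
    pooled = regression_report(y_months, preds_months, cohort=cohort)
    return CVReport(
        folds=tuple(fold_reports),
        pooled=pooled,
        fold_assignment=tuple(int(a) for a in assignment),
        predictions_months=preds_months,
    )


def stratified_fit(
    features: np.ndarray,
    ages_months: np.ndarray,
    male_flags: Sequence[bool],
    config: RegressorConfig | EnsembleConfig | None = None,
    folds: int = 5,
    seed: int = 0,
) -> dict[str, tuple[FittedRegressor, CVReport]]:
    """Fit and cross-validate 'all', 'male' and 'female' cohort models."""
    config = config or RegressorConfig()
    X, y = _validate_xy(features, ages_months)
    male = np.asarray(male_flags, dtype=bool)
    if male.size != y.size:
        raise ContractError("male_flags length mismatch")
    out: dict[str, tuple[FittedRegressor, CVReport]] = {}
    for cohort, sel in (("all", np.ones_like(male)), ("male", male), ("female", ~male)):
        if sel.sum() < max(folds, 2):
            warnings.warn(f"cohort {cohort!r} too small ({int(sel.sum())}); skipped")
            continue
        report = cross_validate(X[sel], y[sel], config, folds=folds, seed=seed, cohort=cohort)
        if isinstance(config, EnsembleConfig):
            fitted = fit_ensemble(X[sel], scale_age(y[sel]), config)
        else:
            fitted = fit_regressor(X[sel], scale_age(y[sel]), config)
        out[cohort] = (fitted, report)
    return out


def balance_by_age(
    ages_months: np.ndarray, seed: int = 0, bin_months: int = 12
) -> np.ndarray:
    """Indices of a per-age-bin downsampled subset (equal counts per occupied bin)."""
    ages = np.asarray(ages_months, dtype=np.float64)
    bins = (ages // bin_months).astype(int)
    rng = np.random.default_rng(seed)
    counts = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
    m = min(len(v) for v in counts.values())
    keep = np.concatenate([rng.choice(v, size=m, replace=False) for v in counts.values()])
    return np.sort(keep)
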