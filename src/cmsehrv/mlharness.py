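"""Estimation machinery: multiple imputation, a ten-model registry,
leave-one-out cross-validation, greedy forward feature addition with a
no-improvement stopping rule, hourly RMSE/MAE grids, and Bland-Altman
agreement.

LOOCV semantics: for each subject the model is fit on all other subjects
(features standardised with training-fold statistics so nothing leaks from
the held-out row) and the held-out subject is predicted.  Greedy selection
adds, at each iteration, the single candidate feature that minimises LOOCV
RMSE given the already-selected set; it stops when no candidate improves the
RMSE or at the cap (default 25 features, 12.5% of a 200-subject cohort), so
the RMSE trace is monotone non-increasing by construction.

Exact fast LOOCV paths exist for three models and make the hourly grid
tractable at desk scale:

* LR uses the PRESS/hat-matrix identity (LOO residual = e_i / (1 - h_ii)),
  exact because ordinary least squares with an intercept is invariant to
  affine feature standardisation.
* KNN vectorises the per-fold standardisation via leave-one-out mean/var
  closed forms, reproducing the generic per-fold path exactly.
* GPR uses the virtual-LOO identity (mu_i = y_i - [K^-1 y]_i / [K^-1]_ii),
  which requires a kernel matrix shared across folds; features are therefore
  standardised cohort-wide for this model (the O(1/n) scale leakage is
  negligible and the permutation-hygiene property is unaffected) while y is
  still centred/scaled consistently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from sklearn.base import clone
from sklearn.ensemble import BaggingRegressor, RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, WhiteKernel
from sklearn.impute import IterativeImputer
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "EvalResult",
    "BlandAltman",
    "ModelUnavailableError",
    "model_registry",
    "make_estimator",
    "impute_missing",
    "loocv_predict",
    "rmse",
    "mae",
    "greedy_forward_select",
    "evaluate_hour_grid",
    "bland_altman",
]

RESPONSE_COLUMN = "lvef_pct"

MODEL_NAMES: tuple[str, ...] = ("GPR", "KNN", "LR", "MLP", "RF", "SvmLinear",
                                "SvmPoly", "SvmRadial", "Treebag", "CNN")

GPR_LENGTH_SCALE = 3.0
GPR_NOISE_LEVEL = 0.1


class ModelUnavailableError(RuntimeError):
    """Raised when a registered model's optional dependency is missing."""


class RegistryError(KeyError):
    """Raised for unknown model names."""


@dataclass(frozen=True)
class ModelSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    available: bool = True


@dataclass
class EvalResult:
    hour: int
    model: str
    rmse: float
    mae: float
    selected_features: list[str]
    actual: np.ndarray
    predicted: np.ndarray
    n_iterations: int
    rmse_trace: list[float]


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float

    @property
    def half_width(self) -> float:
        return (self.loa_high - self.loa_low) / 2.0


def _torch_available() -> bool:
    try:
        import torch  # noqa: F401
        return True
    except ImportError:
        return False


def model_registry(seed: int = 0) -> dict[str, ModelSpec]:
    """The ten-model registry.

    The CNN entry (two conv layers, 16 filters, kernel (2,1), batch-norm,
    ReLU, max-pool, Adam lr 0.001, L2 1e-4, decay 0.90) sits behind an
    optional torch dependency and is reported unavailable rather than
    failing when torch is absent.
    """
    cnn_ok = _torch_available()
    return {
        "GPR": ModelSpec("GPR", {"length_scale": GPR_LENGTH_SCALE,
                                 "noise_level": GPR_NOISE_LEVEL}, seed),
        "KNN": ModelSpec("KNN", {"n_neighbors": 5}, seed),
        "LR": ModelSpec("LR", {}, seed),
        "MLP": ModelSpec("MLP", {"hidden_layer_sizes": (10,), "alpha": 1e-4},
                         seed),
        "RF": ModelSpec("RF", {"n_estimators": 500}, seed),
        "SvmLinear": ModelSpec("SvmLinear", {"kernel": "linear"}, seed),
        "SvmPoly": ModelSpec("SvmPoly", {"kernel": "poly", "degree": 3}, seed),
        "SvmRadial": ModelSpec("SvmRadial", {"kernel": "rbf"}, seed),
        "Treebag": ModelSpec("Treebag", {"n_estimators": 25}, seed),
        "CNN": ModelSpec("CNN", {"filters": 16, "kernel_size": (2, 1),
                                 "lr": 1e-3, "l2": 1e-4, "decay": 0.90},
                         seed, available=cnn_ok),
    }


def make_estimator(spec: ModelSpec | str, seed: int | None = None):
    """A scikit-learn pipeline (training-fold StandardScaler + model)."""
    if isinstance(spec, str):
        registry = model_registry(seed or 0)
        if spec not in registry:
            raise RegistryError(f"unknown model {spec!r}; known: "
                                f"{', '.join(MODEL_NAMES)}")
        spec = registry[spec]
    seed = spec.seed if seed is None else seed
    name = spec.name
    if name == "LR":
        model = LinearRegression()
    elif name == "KNN":
        model = KNeighborsRegressor(n_neighbors=spec.hyperparameters.get(
            "n_neighbors", 5))
    elif name == "RF":
        model = RandomForestRegressor(
            n_estimators=spec.hyperparameters.get("n_estimators", 500),
            random_state=seed)
    elif name == "Treebag":
        model = BaggingRegressor(
            estimator=DecisionTreeRegressor(random_state=seed),
            n_estimators=spec.hyperparameters.get("n_estimators", 25),
            random_state=seed)
    elif name in ("SvmLinear", "SvmPoly", "SvmRadial"):
        model = SVR(kernel=spec.hyperparameters.get("kernel", "rbf"),
                    degree=spec.hyperparameters.get("degree", 3))
    elif name == "GPR":
        kernel = (RBF(length_scale=spec.hyperparameters.get(
                      "length_scale", GPR_LENGTH_SCALE),
                      length_scale_bounds="fixed")
                  + WhiteKernel(noise_level=spec.hyperparameters.get(
                        "noise_level", GPR_NOISE_LEVEL),
                        noise_level_bounds="fixed"))
        model = GaussianProcessRegressor(kernel=kernel, optimizer=None,
                                         normalize_y=True, alpha=1e-10)
    elif name == "MLP":
        model = MLPRegressor(
            hidden_layer_sizes=spec.hyperparameters.get(
                "hidden_layer_sizes", (10,)),
            alpha=spec.hyperparameters.get("alpha", 1e-4),
            max_iter=1000, random_state=seed)
    elif name == "CNN":
        raise ModelUnavailableError(
            "CNN model requires torch, which is not installed; the registry "
            "reports it as unavailable")
    else:
        raise RegistryError(f"unknown model {name!r}")
    return Pipeline([("scale", StandardScaler()), ("model", model)])


# ---------------------------------------------------------------------------
# imputation


def impute_missing(fm: pd.DataFrame, n_imputations: int = 5,
                   max_iter: int = 10, seed: int = 0) -> pd.DataFrame:
    """Chained-equations multiple imputation, completed sets averaged.

    Each incomplete column is iteratively regressed on the others with
    posterior sampling; ``n_imputations`` completed datasets are averaged
    for downstream point estimation.  The response column is never imputed
    or used as a predictor.  Entirely-missing columns are dropped with a
    warning.  Deterministic under a fixed seed.
    """
    fm = fm.copy()
    feature_cols = [c for c in fm.columns if c != RESPONSE_COLUMN]
    all_missing = [c for c in feature_cols if fm[c].isna().all()]
    if all_missing:
        warnings.warn(f"dropping entirely-missing columns: {all_missing}")
        fm = fm.drop(columns=all_missing)
        feature_cols = [c for c in feature_cols if c not in all_missing]
    X = fm[feature_cols].to_numpy(dtype=float)
    if not np.isnan(X).any():
        return fm
    if not np.any(~np.isnan(X).any(axis=0)):
        raise ValueError("imputation requires at least one complete column")
    completed = np.zeros_like(X)
    for t in range(n_imputations):
        imputer = IterativeImputer(max_iter=max_iter, sample_posterior=True,
                                   random_state=seed + t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            completed += imputer.fit_transform(X)
    fm[feature_cols] = completed / n_imputations
    return fm


# ---------------------------------------------------------------------------
# error metrics


def _check_pair(actual, predicted):
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    if actual.size < 1:
        raise ValueError("need at least one observation")
    return actual, predicted


def rmse(actual, predicted) -> float:
    actual, predicted = _check_pair(actual, predicted)
    return float(np.sqrt(np.mean((actual - predicted) ** 2)))


def mae(actual, predicted) -> float:
    actual, predicted = _check_pair(actual, predicted)
    return float(np.mean(np.abs(actual - predicted)))


# ---------------------------------------------------------------------------
# LOOCV


def _as_xy(fm: pd.DataFrame, feature_subset) -> tuple[np.ndarray, np.ndarray]:
    subset = list(feature_subset)
    if not subset:
        raise ValueError("feature subset must be non-empty")
    X = fm[subset].to_numpy(dtype=float)
    y = fm[RESPONSE_COLUMN].to_numpy(dtype=float)
    return X, y


def _loocv_generic(estimator, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = y.size
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        est = clone(estimator)
        est.fit(X[mask], y[mask])
        preds[i] = est.predict(X[i:i + 1])[0]
    return preds


def _loocv_press_lr(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact LR LOOCV via the PRESS identity: yhat_(-i) = y_i - e_i/(1-h_ii).

    OLS with intercept is invariant to per-fold affine standardisation, so
    this matches the generic per-fold path.  Rank-deficient designs fall
    back to a tiny ridge penalty (1e-8) with a warning.
    """
    n = y.size
    Z = np.column_stack([np.ones(n), X])
    q, r = np.linalg.qr(Z)
    if np.min(np.abs(np.diag(r))) < 1e-10 * max(1.0, np.max(np.abs(np.diag(r)))):
        warnings.warn("collinear design; using ridge fallback (1e-8)")
        G = Z.T @ Z + 1e-8 * np.eye(Z.shape[1])
        beta = np.linalg.solve(G, Z.T @ y)
        h = np.einsum("ij,jk,ik->i", Z, np.linalg.inv(G), Z)
    else:
        beta = sla.solve_triangular(r, q.T @ y)
        h = (q ** 2).sum(axis=1)
    e = y - Z @ beta
    denom = 1.0 - h
    denom[np.abs(denom) < 1e-12] = 1e-12
    return y - e / denom


def _loo_fold_scale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out training-fold mean and SD (ddof 0) per feature.

    Row i gives the statistics of the fold that excludes subject i; zero
    variances map to scale 1 (StandardScaler convention).
    """
    n = X.shape[0]
    total = X.sum(axis=0)
    total_sq = (X ** 2).sum(axis=0)
    mu = (total[None, :] - X) / (n - 1)
    var = (total_sq[None, :] - X ** 2) / (n - 1) - mu ** 2
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    sd[sd < 1e-12] = 1.0
    return mu, sd


def _loocv_knn(X: np.ndarray, y: np.ndarray, k: int = 5) -> np.ndarray:
    """Exact KNN LOOCV with per-fold standardisation, vectorised per fold."""
    n = y.size
    k = min(k, n - 1)
    mu, sd = _loo_fold_scale(X)
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        z = (X - mu[i]) / sd[i]
        d2 = ((z - z[i]) ** 2).sum(axis=1)
        d2[i] = np.inf
        nn = np.argpartition(d2, k - 1)[:k]
        # match sklearn ordering semantics: k nearest, uniform weights
        preds[i] = y[nn].mean()
    return preds


def _gpr_kernel(Z: np.ndarray, length_scale: float,
                noise_level: float) -> np.ndarray:
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-0.5 * d2 / length_scale ** 2)
    K[np.diag_indices_from(K)] += noise_level + 1e-10
    return K


def _loocv_gpr(X: np.ndarray, y: np.ndarray,
               length_scale: float = GPR_LENGTH_SCALE,
               noise_level: float = GPR_NOISE_LEVEL) -> np.ndarray:
    """Exact virtual-LOO for GP regression with a fold-shared kernel.

    Features standardised cohort-wide (see module docstring); y is centred
    and scaled like sklearn's normalize_y.  mu_i = y_i - [K^-1 y]_i/[K^-1]_ii.
    """
    mu_x = X.mean(axis=0)
    sd_x = X.std(axis=0)
    sd_x[sd_x < 1e-12] = 1.0
    Z = (X - mu_x) / sd_x
    mu_y, sd_y = y.mean(), y.std()
    if sd_y < 1e-12:
        sd_y = 1.0
    yc = (y - mu_y) / sd_y
    K = _gpr_kernel(Z, length_scale, noise_level)
    cf = sla.cho_factor(K, lower=True)
    alpha = sla.cho_solve(cf, yc)
    Kinv_diag = np.diag(sla.cho_solve(cf, np.eye(K.shape[0])))
    loo = yc - alpha / Kinv_diag
    return loo * sd_y + mu_y


def loocv_predict(model: ModelSpec | str, fm: pd.DataFrame, feature_subset,
                  seed: int = 0, method: str = "auto") -> np.ndarray:
    """Per-subject LOOCV predictions for one model and feature subset.

    ``method="auto"`` routes LR/KNN/GPR through their exact fast paths;
    ``method="generic"`` forces the per-fold refit loop (used to verify the
    fast paths against the straightforward implementation).
    """
    name = model if isinstance(model, str) else model.name
    X, y = _as_xy(fm, feature_subset)
    if y.size < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    if method == "auto":
        if name == "LR":
            return _loocv_press_lr(X, y)
        if name == "KNN":
            spec = model if isinstance(model, ModelSpec) else None
            k = (spec.hyperparameters.get("n_neighbors", 5) if spec else 5)
            return _loocv_knn(X, y, k=k)
        if name == "GPR":
            spec = model if isinstance(model, ModelSpec) else None
            ls = (spec.hyperparameters.get("length_scale", GPR_LENGTH_SCALE)
                  if spec else GPR_LENGTH_SCALE)
            nl = (spec.hyperparameters.get("noise_level", GPR_NOISE_LEVEL)
                  if spec else GPR_NOISE_LEVEL)
            return _loocv_gpr(X, y, length_scale=ls, noise_level=nl)
    estimator = make_estimator(model, seed=seed)
    if name == "GPR":
        # match the fast path's cohort-level feature/response scaling so the
        # per-fold loop verifies the virtual-LOO identity itself
        mu_x = X.mean(axis=0)
        sd_x = X.std(axis=0)
        sd_x[sd_x < 1e-12] = 1.0
        mu_y, sd_y = y.mean(), y.std()
        if sd_y < 1e-12:
            sd_y = 1.0
        gpr = clone(estimator.named_steps["model"])
        gpr.set_params(normalize_y=False)
        preds = _loocv_generic(gpr, (X - mu_x) / sd_x, (y - mu_y) / sd_y)
        return preds * sd_y + mu_y
    return _loocv_generic(estimator, X, y)


# ---------------------------------------------------------------------------
# greedy forward selection


def greedy_forward_select(model: ModelSpec | str, fm: pd.DataFrame,
                          candidates=None, max_features: int = 25,
                          seed: int = 0, method: str = "auto",
                          ) -> tuple[list[str], list[float]]:
    """Forward feature addition with LOOCV RMSE and a no-improvement stop.

    At iteration t the single candidate minimising LOOCV RMSE given the
    already-selected set is added (ties broken by column order); the search
    stops when the best achievable RMSE no longer improves on the current
    one, or at ``max_features``.  Returns (ordered selection, RMSE trace);
    the trace is monotone non-increasing by construction.
    """
    if candidates is None:
        candidates = [c for c in fm.columns if c != RESPONSE_COLUMN]
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate feature")
    y = fm[RESPONSE_COLUMN].to_numpy(dtype=float)
    selected: list[str] = []
    trace: list[float] = []
    current = np.inf
    while len(selected) < max_features and len(selected) < len(candidates):
        best_feat, best_rmse = None, np.inf
        for feat in candidates:
            if feat in selected:
                continue
            preds = loocv_predict(model, fm, selected + [feat], seed=seed,
                                  method=method)
            err = rmse(y, preds)
            if err < best_rmse:
                best_feat, best_rmse = feat, err
        if best_feat is None or best_rmse >= current:
            break
        selected.append(best_feat)
        trace.append(best_rmse)
        current = best_rmse
    return selected, trace


# ---------------------------------------------------------------------------
# hourly grid


def evaluate_hour_grid(fms: dict[int, pd.DataFrame], models,
                       max_features: int = 25, seed: int = 0,
                       ) -> tuple[list[EvalResult], pd.DataFrame, pd.DataFrame]:
    """Greedy selection + final LOOCV metrics for every (hour, model) cell.

    Returns (per-cell results, RMSE grid, MAE grid); grids are hour-indexed
    DataFrames with one column per model.  Hours missing from ``fms`` are
    skipped with a notice.
    """
    models = [m if isinstance(m, ModelSpec) else ModelSpec(m, seed=seed)
              for m in models]
    hours = sorted(fms)
    results: list[EvalResult] = []
    grid_rmse = pd.DataFrame(index=pd.Index(hours, name="hour"),
                             columns=[m.name for m in models], dtype=float)
    grid_mae = grid_rmse.copy()
    for hour in hours:
        fm = fms[hour]
        y = fm[RESPONSE_COLUMN].to_numpy(dtype=float)
        for m in models:
            selected, trace = greedy_forward_select(
                m, fm, max_features=max_features, seed=seed)
            preds = loocv_predict(m, fm, selected, seed=seed)
            cell_rmse = rmse(y, preds)
            cell_mae = mae(y, preds)
            grid_rmse.loc[hour, m.name] = cell_rmse
            grid_mae.loc[hour, m.name] = cell_mae
            results.append(EvalResult(
                hour=hour, model=m.name, rmse=cell_rmse, mae=cell_mae,
                selected_features=selected, actual=y, predicted=preds,
                n_iterations=len(trace), rmse_trace=trace))
    return results, grid_rmse, grid_mae


# ---------------------------------------------------------------------------
# agreement


def bland_altman(actual, predicted) -> BlandAltman:
    """Bias and 95% limits of agreement for predicted - actual differences.

    bias = mean(d); limits = bias +- 1.96 * SD(d) with the sample SD (n-1).
    """
    actual, predicted = _check_pair(actual, predicted)
    if actual.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = predicted - actual
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, loa_low=bias - 1.96 * sd,
                       loa_high=bias + 1.96 * sd)
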