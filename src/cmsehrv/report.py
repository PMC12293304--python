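"""Interpretability and reporting: standardised-coefficient importance,
sampling-based Shapley attribution, and tabular/graphic grid summaries.

Importance for linear models follows the standardised-coefficient
convention: features are z-scored, the model refit, and |coefficient|
rescaled so the largest equals 100.  Shapley attribution uses Monte-Carlo
permutation sampling with marginal (interventional) replacement from a
background sample; per-permutation telescoping makes the attributions sum
to prediction minus base value exactly for each sampled background, so
efficiency holds up to Monte-Carlo error in the base value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

from .cmse import FEATURE_SUFFIXES
from .mlharness import RESPONSE_COLUMN

__all__ = [
    "std_coef_importance",
    "shapley_importance",
    "ShapleyResult",
    "summarize_grid",
]


def _rank_table(features, scores, method: str) -> pd.DataFrame:
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(scores.size, dtype=int)
    ranks[order] = np.arange(1, scores.size + 1)
    return pd.DataFrame({"feature": list(features), "score": scores,
                         "method": method, "rank": ranks})


def std_coef_importance(fm: pd.DataFrame, subset) -> pd.DataFrame:
    """|standardised coefficient| importance, scaled to a 0-100 axis.

    Fits ordinary least squares on z-scored features; the feature with the
    largest absolute coefficient scores 100.
    """
    subset = list(subset)
    X = fm[subset].to_numpy(dtype=float)
    y = fm[RESPONSE_COLUMN].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    model = LinearRegression().fit((X - mu) / sd, y)
    scores = np.abs(model.coef_)
    top = scores.max()
    if top > 0:
        scores = 100.0 * scores / top
    return _rank_table(subset, scores, "std_coef")


@dataclass
class ShapleyResult:
    table: pd.DataFrame          # global mean |phi| per feature (+ranks)
    attributions: np.ndarray     # (n_subjects, n_features) phi values
    base_value: float            # mean prediction over sampled backgrounds


def shapley_importance(predict, fm: pd.DataFrame, subset, n_mc: int = 256,
                       seed: int = 0, background: pd.DataFrame | None = None,
                       ) -> ShapleyResult:
    """Monte-Carlo permutation-sampling Shapley values.

    ``predict`` maps an (n, p) array to predictions.  For each of ``n_mc``
    iterations a feature permutation and a background row are drawn; walking
    the permutation from background to subject accumulates each feature's
    marginal contribution.  The global score is mean |phi| per feature.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    subset = list(subset)
    X = fm[subset].to_numpy(dtype=float)
    bg = (background[subset].to_numpy(dtype=float)
          if background is not None else X)
    rng = np.random.default_rng(seed)
    n, p = X.shape
    phi = np.zeros((n, p))
    base = 0.0
    for _ in range(n_mc):
        perm = rng.permutation(p)
        z = bg[rng.integers(0, bg.shape[0], size=n)]
        current = z.copy()
        prev = predict(current)
        base += prev.mean()
        for j in perm:
            current[:, j] = X[:, j]
            nxt = predict(current)
            phi[:, j] += nxt - prev
            prev = nxt
    phi /= n_mc
    base /= n_mc
    table = _rank_table(subset, np.abs(phi).mean(axis=0), "shapley")
    return ShapleyResult(table=table, attributions=phi, base_value=base)


def group_importance_by_parameter(table: pd.DataFrame) -> pd.DataFrame:
    """Sum importance scores by multiscale-parameter suffix; covariates are
    grouped under 'covariate'."""
    def suffix(name: str) -> str:
        tail = name.rsplit("_", 1)[-1]
        return tail if tail in FEATURE_SUFFIXES else "covariate"

    grouped = (table.assign(group=table["feature"].map(suffix))
               .groupby("group")["score"].sum().reset_index())
    return grouped.sort_values("score", ascending=False, ignore_index=True)


def summarize_grid(grid_rmse: pd.DataFrame, grid_mae: pd.DataFrame,
                   importance: pd.DataFrame | None = None,
                   out_dir: str | Path | None = None,
                   manifest: dict | None = None) -> dict:
    """Report bundle: best cells, per-parameter grouped importance, heat-grid
    and ranked-bar figures, and a reproducibility manifest."""
    if grid_rmse.empty:
        raise ValueError("results grid is empty")
    flat = grid_rmse.stack()
    best_hour, best_model = flat.idxmin()
    bundle = {
        "best_cell": {"hour": int(best_hour), "model": str(best_model),
                      "rmse": float(flat.min()),
                      "mae": float(grid_mae.loc[best_hour, best_model])},
        "best_model_per_hour": {
            int(h): str(grid_rmse.loc[h].idxmin()) for h in grid_rmse.index},
    }
    if importance is not None:
        bundle["grouped_importance"] = group_importance_by_parameter(
            importance).to_dict(orient="records")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        grid_rmse.to_csv(out / "grid_rmse.csv")
        grid_mae.to_csv(out / "grid_mae.csv")

        fig, ax = plt.subplots(figsize=(6, max(3, 0.3 * len(grid_rmse))))
        im = ax.imshow(grid_rmse.to_numpy(dtype=float), aspect="auto",
                       cmap="RdBu")
        ax.set_xticks(range(grid_rmse.shape[1]),
                      labels=list(grid_rmse.columns), rotation=45)
        ax.set_yticks(range(grid_rmse.shape[0]),
                      labels=[str(h) for h in grid_rmse.index])
        ax.set_ylabel("clock hour")
        fig.colorbar(im, ax=ax, label="LOOCV RMSE (%)")
        fig.tight_layout()
        fig.savefig(out / "grid_rmse.png", dpi=120)
        plt.close(fig)

        if importance is not None:
            top = importance.nsmallest(20, "rank")
            fig, ax = plt.subplots(figsize=(6, 5))
            ax.barh(top["feature"][::-1], top["score"][::-1])
            ax.set_xlabel("importance (0-100)")
            fig.tight_layout()
            fig.savefig(out / "importance.png", dpi=120)
            plt.close(fig)
            importance.to_csv(out / "importance.csv", index=False)

        (out / "manifest.json").write_text(
            json.dumps(manifest or {}, indent=2, sort_keys=True))
    return bundle
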