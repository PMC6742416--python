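"""Model-based feature-importance framework.

Two complementary selectors rank TF binding features by how well they
predict allelic skew: LASSO stability selection (the fraction of
subsampled L1 fits in which a feature's coefficient is nonzero) and
Random-Forest impurity importance. Each selector's scores are min-max
scaled to [0, 1] and averaged to give the overall ranking. A companion
benchmark compares named feature sets by k-fold cross-validated MSE under
LASSO, SVR and Random-Forest regressors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, LassoCV, lasso_path
from sklearn.model_selection import KFold
from sklearn.svm import SVR


@dataclass
class ImportanceReport:
    tf_ids: list[str]
    stability_frequency: np.ndarray
    rf_importance_scaled: np.ndarray
    mean_importance: np.ndarray
    ranking: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "tf_id": self.tf_ids,
                "stability_frequency": self.stability_frequency,
                "rf_importance_scaled": self.rf_importance_scaled,
                "mean_importance": self.mean_importance,
            }
        )
        rank = {t: k + 1 for k, t in enumerate(self.ranking)}
        df["rank"] = [rank[t] for t in self.tf_ids]
        return df.sort_values("rank").reset_index(drop=True)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with rows matching y")
    if np.ptp(y) == 0:
        raise ValueError("degenerate target: y is constant")
    return X, y


def default_lambda_grid(
    X: np.ndarray, y: np.ndarray, n: int = 20, decades: float = 0.7
) -> np.ndarray:
    """Log-spaced grid from the smallest lambda that zeroes all
    coefficients (lambda_max) down by ``decades``.

    The grid stays in the sparse region of the path: descending much
    further makes every subsampled fit select nearly all features, which
    washes out the selection frequencies.
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    lam_max = np.abs(Xc.T @ yc).max() / len(y)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n)


def stability_selection(
    X: np.ndarray,
    y: np.ndarray,
    n_subsamples: int = 100,
    subsample_fraction: float = 0.5,
    lambda_grid: Sequence[float] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Selection frequency per feature over (subsample, lambda) L1 fits.

    Each of ``n_subsamples`` rounds draws a without-replacement subsample
    of the rows and fits the LASSO coefficient path over ``lambda_grid``;
    a feature is "selected" in a (round, lambda) cell when its coefficient
    is nonzero. Frequencies are the fraction of cells selecting it.
    """
    X, y = _check_xy(X, y)
    V, N = X.shape
    if V < 20:
        raise ValueError("need at least 20 rows for stability selection")
    if n_subsamples < 50:
        raise ValueError("need at least 50 subsamples")
    rng = np.random.default_rng(seed)
    fixed_grid = None
    if lambda_grid is not None:
        fixed_grid = np.sort(np.asarray(lambda_grid, float))[::-1]  # decreasing
    m = max(2, int(round(subsample_fraction * V)))
    n_lam = 20 if fixed_grid is None else len(fixed_grid)
    hits = np.zeros(N)
    for _ in range(n_subsamples):
        rows = rng.choice(V, size=m, replace=False)
        # the sparse region of the path depends on the subsample, so the
        # grid is anchored at each subsample's own lambda_max
        alphas = (
            fixed_grid
            if fixed_grid is not None
            else default_lambda_grid(X[rows], y[rows])
        )
        _, coefs, _ = lasso_path(X[rows], y[rows], alphas=alphas)
        hits += (np.abs(coefs) > 1e-10).sum(axis=1)
    return hits / (n_subsamples * n_lam)


def rf_importance(
    X: np.ndarray, y: np.ndarray, n_trees: int = 500, seed: int = 0
) -> np.ndarray:
    """Impurity-based importances from a Random-Forest regressor
    (nonnegative, summing to 1)."""
    X, y = _check_xy(X, y)
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return rf.feature_importances_


def _minmax(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    span = np.ptp(v)
    if span == 0:
        return np.zeros_like(v)
    return (v - v.min()) / span


def combine_importance(
    stability: np.ndarray,
    rf: np.ndarray,
    tf_ids: Sequence[str] | None = None,
) -> ImportanceReport:
    """Min-max scale each selector to [0, 1] and take their mean; rank
    descending with lexicographic tf_id tie-break."""
    stability = np.asarray(stability, float)
    rf = np.asarray(rf, float)
    if stability.shape != rf.shape:
        raise ValueError("selector vectors must share shape")
    if tf_ids is None:
        tf_ids = [f"TF{k:03d}" for k in range(len(stability))]
    tf_ids = [str(t) for t in tf_ids]
    s_scaled = _minmax(stability)
    r_scaled = _minmax(rf)
    mean = (s_scaled + r_scaled) / 2.0
    ranking = sorted(range(len(tf_ids)), key=lambda j: (-mean[j], tf_ids[j]))
    return ImportanceReport(
        tf_ids=tf_ids,
        stability_frequency=s_scaled,
        rf_importance_scaled=r_scaled,
        mean_importance=mean,
        ranking=[tf_ids[j] for j in ranking],
    )


def rank_features(
    X: np.ndarray,
    y: np.ndarray,
    tf_ids: Sequence[str] | None = None,
    n_subsamples: int = 100,
    subsample_fraction: float = 0.5,
    lambda_grid: Sequence[float] | None = None,
    n_trees: int = 500,
    seed: int = 0,
) -> ImportanceReport:
    """Convenience wrapper: stability selection + RF importance + combine."""
    freq = stability_selection(
        X, y, n_subsamples=n_subsamples, subsample_fraction=subsample_fraction,
        lambda_grid=lambda_grid, seed=seed,
    )
    imp = rf_importance(X, y, n_trees=n_trees, seed=seed)
    return combine_importance(freq, imp, tf_ids)


def _make_model(name: str, seed: int):
    if name == "lasso":
        return LassoCV(eps=1e-6, alphas=40, cv=3, random_state=seed,
                       max_iter=200_000, tol=1e-10)
    if name == "svr":
        return SVR(kernel="rbf", C=1.0)
    if name == "random_forest":
        return RandomForestRegressor(n_estimators=200, random_state=seed, n_jobs=1)
    raise ValueError(f"unknown model {name!r}")


def benchmark_feature_sets(
    feature_sets: Mapping[str, np.ndarray],
    y: np.ndarray,
    models: Sequence[str] = ("lasso", "svr", "random_forest"),
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """k-fold CV mean squared error per (feature set, model).

    All feature sets must share variant rows (same length as y). Returns a
    tidy DataFrame with columns feature_set, model, mse.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y, dtype=float)
    for name, X in feature_sets.items():
        if np.asarray(X).shape[0] != len(y):
            raise ValueError(f"feature set {name!r}: row count != len(y)")
    rows = []
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for name, X in feature_sets.items():
        X = np.asarray(X, dtype=float)
        for model_name in models:
            errs = []
            for tr, te in kf.split(X):
                model = _make_model(model_name, seed)
                model.fit(X[tr], y[tr])
                pred = model.predict(X[te])
                errs.append(float(np.mean((pred - y[te]) ** 2)))
            rows.append({"feature_set": name, "model": model_name, "mse": float(np.mean(errs))})
    return pd.DataFrame(rows)
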