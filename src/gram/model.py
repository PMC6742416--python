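"""The three-step generalized model.

Step 1 (universal activity): a Random-Forest classifier F1 maps an
allele's TF binding-score vector to the probability U in [0, 1] that the
element drives reporter expression, independent of cell type. The
allelic contrast enters step 3 as Odds = |log2 of the odds ratio of
U_mut vs U_wt|.

Step 2 (cell-type modifiers): two Random-Forest classifiers predict the
high/low Vodds class — S_b from the binding-score vector, S_e from the
rank-reordered TF expression vector — giving scores in [0, 1] that adjust
the universal effect to a cellular context.

Step 3 (integration): an L1-regularized logistic regression combines the
three scores, M = logistic(b_u*Odds + b_s1*S_b + b_s2*S_e + b'), with the
penalty lambda chosen by minimal mean cross-validated deviance over a
grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from . import mpra
from .features import reorder_expression
from .io import (
    BindingScoreMatrix,
    ExpressionProfile,
    GramModelBundle,
    GramScore,
    MpraCountTable,
    SchemaError,
)

logger = logging.getLogger(__name__)

DEFAULT_EPS = 1e-6


@dataclass
class TrainingConfig:
    """Hyperparameters and labeling rules for a full training run."""

    n_trees: int = 500
    seed: int = 0
    activity_mode: str = "count_test"
    fc_cutoff: float = 1.5
    alpha: float = 0.05
    skew_threshold: float = mpra.DEFAULT_SKEW_THRESHOLD
    lower_q: float = 0.25
    upper_q: float = 0.75
    key_allele: str = "ref"  # ranking key for expression reordering
    lambda_grid: tuple[float, ...] | None = None
    step3_cv_folds: int = 5
    # probability clip for the odds feature; matched to the vote-fraction
    # resolution of a few-hundred-tree forest rather than the generic
    # odds_feature default, so near-saturated predictions do not turn
    # single-tree vote flips into huge log-odds swings
    eps: float = 1e-3
    class_weight: str | None = None


@dataclass
class GramDataset:
    """A complete training dataset: binding scores for both alleles,
    per-cell-type TF expression profiles, and MPRA count tables."""

    bsm: BindingScoreMatrix
    profiles: Mapping[str, ExpressionProfile]  # cell_type -> profile
    counts: Sequence[MpraCountTable]

    def __post_init__(self) -> None:
        known = set(self.bsm.variant_ids)
        for t in self.counts:
            if t.variant_id not in known:
                raise SchemaError(f"counts reference unknown variant {t.variant_id!r}")
            if t.cell_type not in self.profiles:
                raise SchemaError(f"counts reference unknown cell type {t.cell_type!r}")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.bsm.variant_ids)

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.profiles)


# ---------------------------------------------------------------------------
# Label construction
# ---------------------------------------------------------------------------

def activity_label_table(dataset: GramDataset, cfg: TrainingConfig) -> pd.DataFrame:
    """Per-(variant, allele) activity: an allele counts as active when it
    is called active in at least one assayed cell type."""
    rows: dict[tuple[str, str], bool] = {}
    for t in dataset.counts:
        ref_lab, alt_lab = mpra.call_activity(
            t, mode=cfg.activity_mode, fc_cutoff=cfg.fc_cutoff, alpha=cfg.alpha
        )
        for lab in (ref_lab, alt_lab):
            key = (t.variant_id, lab.allele)
            rows[key] = rows.get(key, False) or lab.active
    return pd.DataFrame(
        [{"variant_id": v, "allele": a, "active": act} for (v, a), act in rows.items()]
    )


def emvar_label_table(dataset: GramDataset, cfg: TrainingConfig) -> pd.DataFrame:
    """Per-(variant, cell type) emVAR labels, logSkew and Vodds."""
    rows = []
    for t in dataset.counts:
        ls = mpra.log_skew(t)
        sig = mpra.allelic_skew_test(t) < cfg.alpha
        lab = mpra.label_emvar(ls, sig, cfg.skew_threshold, variant_id=t.variant_id)
        rows.append(
            {
                "variant_id": t.variant_id,
                "cell_type": t.cell_type,
                "log_skew": ls,
                "significant": sig,
                "is_emvar": lab.is_emvar,
                "vodds": mpra.vodds(t),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Step fits
# ---------------------------------------------------------------------------

def _check_two_classes(y: np.ndarray, what: str) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError(f"{what}: need both classes present")


def fit_step1(
    X: np.ndarray, y: np.ndarray, n_trees: int = 500, seed: int = 0,
    class_weight: str | None = None,
) -> RandomForestClassifier:
    """Fit the universal-activity forest on stacked per-allele rows."""
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    _check_two_classes(y, "step 1")
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed,
        n_jobs=1, class_weight=class_weight, oob_score=True,
    )
    rf.fit(X, y)
    return rf


def predict_U(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Predicted probability of the active class, in [0, 1]."""
    X = np.atleast_2d(np.asarray(X, float))
    proba = model.predict_proba(X)
    active_col = int(np.where(model.classes_ == 1)[0][0])
    return proba[:, active_col]


def oob_U(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Out-of-bag probability of the active class for the forest's own
    training rows; rows never out of bag fall back to the in-sample
    prediction. Used to build unbiased step-3 stacking features."""
    active_col = int(np.where(model.classes_ == 1)[0][0])
    oob = model.oob_decision_function_[:, active_col]
    bad = ~np.isfinite(oob)
    if bad.any():
        oob = oob.copy()
        oob[bad] = predict_U(model, np.asarray(X, float)[bad])
    return oob


def odds_feature(
    u_mut: float | np.ndarray, u_wt: float | np.ndarray, eps: float = DEFAULT_EPS
) -> float | np.ndarray:
    """|log2 odds ratio| of the two universal scores, clipped to keep the
    value finite: Odds = |log2((U_mut/(1-U_mut)) / (U_wt/(1-U_wt)))|.

    Symmetric under swapping U_mut and U_wt; zero iff they agree after
    clipping to [eps, 1-eps].
    """
    if not (0.0 < eps < 0.5):
        raise ValueError("eps must be in (0, 0.5)")
    um = np.clip(np.asarray(u_mut, float), eps, 1.0 - eps)
    uw = np.clip(np.asarray(u_wt, float), eps, 1.0 - eps)
    val = np.abs(np.log2((um / (1.0 - um)) / (uw / (1.0 - uw))))
    return float(val) if np.ndim(u_mut) == 0 and np.ndim(u_wt) == 0 else val


fit_step2 = fit_step1  # same estimator family, different targets (high/low Vodds)


@dataclass
class Step3Fit:
    b_u: float
    b_s1: float
    b_s2: float
    b0: float
    lambda_: float
    cv_deviance: pd.DataFrame = field(repr=False, default=None)


def default_step3_lambda_grid() -> np.ndarray:
    return np.logspace(-4, 1.5, 25)


def fit_l1_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-9,
    max_iter: int = 50_000,
) -> tuple[float, np.ndarray]:
    """L1-penalized logistic regression by accelerated proximal gradient.

    Minimizes mean log-loss + lam * ||slopes||_1 with an unpenalized
    intercept; soft-thresholding keeps the solution exact in both penalty
    limits (lam -> 0: the MLE; lam -> inf: zero slopes and intercept equal
    to the log-odds of the class prevalence). Deterministic.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    # Lipschitz constant of the mean-log-loss gradient
    L = float(np.linalg.norm(Xd, 2) ** 2) / (4.0 * n)
    t = 1.0 / L
    thresh = lam * t
    b = np.zeros(p + 1)
    z = b.copy()
    momentum = 1.0
    for _ in range(max_iter):
        pz = _logistic(Xd @ z)
        grad = Xd.T @ (pz - y) / n
        b_new = z - t * grad
        b_new[1:] = np.sign(b_new[1:]) * np.maximum(np.abs(b_new[1:]) - thresh, 0.0)
        momentum_new = (1.0 + np.sqrt(1.0 + 4.0 * momentum**2)) / 2.0
        z = b_new + ((momentum - 1.0) / momentum_new) * (b_new - b)
        delta = float(np.max(np.abs(b_new - b)))
        b, momentum = b_new, momentum_new
        if delta < tol:
            break
    return float(b[0]), b[1:]


def _l1_logistic_predict(intercept: float, coefs: np.ndarray, X: np.ndarray) -> np.ndarray:
    return _logistic(np.asarray(X, float) @ coefs + intercept)


def fit_step3(
    odds: np.ndarray,
    s_b: np.ndarray,
    s_e: np.ndarray,
    y: np.ndarray,
    lambda_grid: Sequence[float] | None = None,
    k: int = 5,
    seed: int = 0,
) -> Step3Fit:
    """L1-penalized logistic regression of the emVAR label on
    (Odds, S_b, S_e); lambda chosen by minimal mean k-fold CV deviance."""
    X = np.column_stack([np.asarray(odds, float), np.asarray(s_b, float), np.asarray(s_e, float)])
    y = np.asarray(y).astype(int)
    if len(y) != X.shape[0]:
        raise ValueError("feature vectors and labels must align")
    _check_two_classes(y, "step 3")
    if lambda_grid is None:
        lambda_grid = default_step3_lambda_grid()
    lambda_grid = np.asarray(list(lambda_grid), float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")

    n = len(y)
    k_eff = min(k, int(np.bincount(y).min()))
    if k_eff < 2:
        raise ValueError("too few samples in the minority class for CV")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    mean_dev = []
    for lam in lambda_grid:
        devs = []
        for tr, te in splits:
            b0, coefs = fit_l1_logistic(X[tr], y[tr], lam)
            p = np.clip(_l1_logistic_predict(b0, coefs, X[te]), 1e-12, 1 - 1e-12)
            devs.append(float(-np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))))
        mean_dev.append(float(np.mean(devs)))
    best = int(np.argmin(mean_dev))
    lam_star = float(lambda_grid[best])
    b0, b = fit_l1_logistic(X, y, lam_star)
    return Step3Fit(
        b_u=float(b[0]), b_s1=float(b[1]), b_s2=float(b[2]),
        b0=float(b0), lambda_=lam_star,
        cv_deviance=pd.DataFrame({"lambda": lambda_grid, "mean_cv_deviance": mean_dev}),
    )


# ---------------------------------------------------------------------------
# Training orchestration
# ---------------------------------------------------------------------------

def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _reordered_matrix(
    bsm: BindingScoreMatrix,
    variant_ids: Sequence[str],
    profile: ExpressionProfile,
    key_allele: str,
) -> np.ndarray:
    return np.vstack(
        [reorder_expression(bsm, v, profile, key_allele).values for v in variant_ids]
    )


def train_on(
    dataset: GramDataset, train_ids: Sequence[str], cfg: TrainingConfig
) -> GramModelBundle:
    """Fit all three steps using only the given training variants.

    Quantile boundaries for the modifier labels are computed from the
    training variants alone, so held-out variants never influence any
    stage of the fit.
    """
    train_ids = list(train_ids)
    train_set = set(train_ids)
    bsm = dataset.bsm

    activity = activity_label_table(dataset, cfg)
    activity = activity[activity.variant_id.isin(train_set)]
    emvar = emvar_label_table(dataset, cfg)
    emvar_train = emvar[emvar.variant_id.isin(train_set)]

    # Step 1: stacked (variant, allele) binding rows vs activity.
    activity = activity.sort_values(["variant_id", "allele"]).reset_index(drop=True)
    X1, y1, row_of = [], [], {}
    for r in activity.itertuples(index=False):
        i = bsm.row_index(r.variant_id)
        row_of[(r.variant_id, r.allele)] = len(X1)
        X1.append(bsm.scores_ref[i] if r.allele == "ref" else bsm.scores_alt[i])
        y1.append(int(r.active))
    X1 = np.vstack(X1)
    f1 = fit_step1(X1, np.array(y1), cfg.n_trees, cfg.seed, cfg.class_weight)
    u_oob = oob_U(f1, X1)

    # Step 2: per-cell quartile labels on training Vodds; high=1, low=0.
    Xb, Xe, y2, keys2 = [], [], [], []
    for cell, grp in emvar_train.groupby("cell_type"):
        labels = mpra.modifier_labels(
            grp.vodds.to_numpy(), grp.variant_id.tolist(), cell,
            cfg.lower_q, cfg.upper_q,
        )
        profile = dataset.profiles[cell]
        for lab in labels:
            if lab.klass == "excluded":
                continue
            i = bsm.row_index(lab.variant_id)
            keys2.append((lab.variant_id, cell))
            Xb.append(bsm.scores_ref[i])
            Xe.append(reorder_expression(bsm, lab.variant_id, profile, cfg.key_allele).values)
            y2.append(1 if lab.klass == "high" else 0)
    y2 = np.array(y2)
    f2b = fit_step2(np.vstack(Xb), y2, cfg.n_trees, cfg.seed + 1, cfg.class_weight)
    f2e = fit_step2(np.vstack(Xe), y2, cfg.n_trees, cfg.seed + 2, cfg.class_weight)

    # Step 3: integrate on per-(variant, cell) rows of the training set.
    # Stacking features come from out-of-bag forest predictions so the
    # logistic weights are not distorted by in-sample forest optimism.
    sb_oob = dict(zip(keys2, oob_U(f2b, np.vstack(Xb))))
    se_oob = dict(zip(keys2, oob_U(f2e, np.vstack(Xe))))
    partial = GramModelBundle(
        step1_model=f1, step2_binding_model=f2b, step2_expression_model=f2e,
        b_u=0.0, b_s1=0.0, b_s2=0.0, b0=0.0, lambda_=0.0,
        tf_ids=list(bsm.tf_ids),
    )
    feats = _score_components(partial, bsm, dataset.profiles, emvar_train, cfg)
    u_wt = np.array([u_oob[row_of[(v, "ref")]] for v in feats.variant_id])
    u_mut = np.array([u_oob[row_of[(v, "alt")]] for v in feats.variant_id])
    odds = odds_feature(u_mut, u_wt, cfg.eps)
    s_b = np.array([
        sb_oob.get((v, c), d)
        for v, c, d in zip(feats.variant_id, feats.cell_type, feats.s_b)
    ])
    s_e = np.array([
        se_oob.get((v, c), d)
        for v, c, d in zip(feats.variant_id, feats.cell_type, feats.s_e)
    ])
    fit3 = fit_step3(
        odds, s_b, s_e,
        emvar_train.is_emvar.to_numpy().astype(int),
        cfg.lambda_grid, cfg.step3_cv_folds, cfg.seed + 3,
    )
    return GramModelBundle(
        step1_model=f1, step2_binding_model=f2b, step2_expression_model=f2e,
        b_u=fit3.b_u, b_s1=fit3.b_s1, b_s2=fit3.b_s2, b0=fit3.b0,
        lambda_=fit3.lambda_, tf_ids=list(bsm.tf_ids),
        training_metadata={
            "seed": cfg.seed,
            "n_trees": cfg.n_trees,
            "n_training_variants": len(train_ids),
            "activity_mode": cfg.activity_mode,
            "skew_threshold": cfg.skew_threshold,
            "quantiles": [cfg.lower_q, cfg.upper_q],
            "key_allele": cfg.key_allele,
        },
    )


def train_full(dataset: GramDataset, cfg: TrainingConfig | None = None) -> GramModelBundle:
    """Fit the model on every variant in the dataset."""
    cfg = cfg or TrainingConfig()
    return train_on(dataset, dataset.variant_ids, cfg)


def _score_components(
    bundle: GramModelBundle,
    bsm: BindingScoreMatrix,
    profiles: Mapping[str, ExpressionProfile],
    rows: pd.DataFrame,
    cfg: TrainingConfig,
) -> pd.DataFrame:
    """U/Odds/S_b/S_e for the (variant_id, cell_type) rows of ``rows``."""
    if list(bsm.tf_ids) != list(bundle.tf_ids):
        bsm = bsm.reorder_tfs(bundle.tf_ids)
    vids = rows.variant_id.tolist()
    cells = rows.cell_type.tolist()
    idx = np.array([bsm.row_index(v) for v in vids])
    u_wt = predict_U(bundle.step1_model, bsm.scores_ref[idx])
    u_mut = predict_U(bundle.step1_model, bsm.scores_alt[idx])
    odds = odds_feature(u_mut, u_wt, cfg.eps)
    s_b = predict_U(bundle.step2_binding_model, bsm.scores_ref[idx])
    Xe = np.vstack(
        [
            reorder_expression(bsm, v, profiles[c], cfg.key_allele).values
            for v, c in zip(vids, cells)
        ]
    )
    s_e = predict_U(bundle.step2_expression_model, Xe)
    return pd.DataFrame(
        {
            "variant_id": vids, "cell_type": cells,
            "u_wt": u_wt, "u_mut": u_mut, "odds": odds, "s_b": s_b, "s_e": s_e,
        }
    )


def predict_scores(
    bundle: GramModelBundle,
    bsm: BindingScoreMatrix,
    profiles: Mapping[str, ExpressionProfile],
    variant_ids: Sequence[str] | None = None,
    cell_types: Sequence[str] | None = None,
    cfg: TrainingConfig | None = None,
) -> pd.DataFrame:
    """Batch scoring: one row per (variant, cell/sample) with all
    intermediates and the final M."""
    cfg = cfg or TrainingConfig()
    if variant_ids is None:
        variant_ids = bsm.variant_ids
    if cell_types is None:
        cell_types = sorted(profiles)
    rows = pd.DataFrame(
        [(v, c) for v in variant_ids for c in cell_types],
        columns=["variant_id", "cell_type"],
    )
    feats = _score_components(bundle, bsm, profiles, rows, cfg)
    z = (
        bundle.b_u * feats.odds.to_numpy()
        + bundle.b_s1 * feats.s_b.to_numpy()
        + bundle.b_s2 * feats.s_e.to_numpy()
        + bundle.b0
    )
    feats["m"] = _logistic(z)
    return feats


def predict_gram(
    bundle: GramModelBundle,
    bsm: BindingScoreMatrix,
    variant_id: str,
    profile: ExpressionProfile,
    cfg: TrainingConfig | None = None,
) -> GramScore:
    """Score one (variant, sample) pair, returning all intermediates."""
    df = predict_scores(bundle, bsm, {profile.sample_id: profile}, [variant_id], cfg=cfg)
    r = df.iloc[0]
    return GramScore(
        variant_id=variant_id, sample_id=profile.sample_id,
        u_wt=float(r.u_wt), u_mut=float(r.u_mut), odds=float(r.odds),
        s_b=float(r.s_b), s_e=float(r.s_e), m=float(r.m),
    )
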