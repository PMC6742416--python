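"""Leakage-free multi-step cross-validation and ranking metrics.

The fold unit is the variant: both alleles and every per-cell row of a
variant share its fold, and for each held-out fold ALL submodels (the
activity forest, both modifier forests, and the final logistic
integration — including the modifier-label quantile boundaries) are
re-fit on the remaining variants only. Held-out predictions are
concatenated across folds and scored once with AUROC / AUPRC.

AUROC is computed as the Mann-Whitney U statistic normalized by
n_pos * n_neg, with half credit for ties; AUPRC uses step-interpolated
precision-recall integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import GramDataset, TrainingConfig, emvar_label_table, predict_scores, train_on

logger = logging.getLogger(__name__)


@dataclass
class FoldAssignment:
    assignment: dict[str, int]  # variant_id -> fold index in 1..k
    k: int
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [v for v, f in self.assignment.items() if f == fold]


def make_folds(variant_ids, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Randomly permute variants and chunk them into k folds whose sizes
    differ by at most one."""
    variant_ids = list(variant_ids)
    if k > len(variant_ids):
        raise ValueError(f"k={k} exceeds the number of variants ({len(variant_ids)})")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(variant_ids))
    chunks = np.array_split(order, k)
    assignment = {}
    for fold, chunk in enumerate(chunks, start=1):
        for j in chunk:
            assignment[variant_ids[j]] = fold
    return FoldAssignment(assignment=assignment, k=k, seed=seed)


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC with 0.5 credit for tied scores."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes to compute AUROC")
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Step-interpolated area under the precision-recall curve."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("need at least one positive to compute AUPRC")
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # collapse tied-score blocks to their final cumulative counts
    distinct = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    # step integration: precision at each level times recall increment
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum(precision * (recall - prev_recall)))


@dataclass
class CvResult:
    predictions: pd.DataFrame  # held-out rows: variant_id, cell_type, m, is_emvar, fold
    auroc: float
    auprc: float
    folds: FoldAssignment


def _fold_is_trainable(dataset: GramDataset, train_ids, cfg: TrainingConfig) -> bool:
    """Both emVAR classes must be present in every training partition."""
    emvar = emvar_label_table(dataset, cfg)
    sub = emvar[emvar.variant_id.isin(set(train_ids))]
    return sub.is_emvar.nunique() == 2


def cross_validate(
    dataset: GramDataset,
    k: int = 10,
    seed: int = 0,
    cfg: TrainingConfig | None = None,
    submodel_scope: str = "fold",
    max_redraws: int = 10,
) -> CvResult:
    """Variant-level k-fold CV of the full three-step pipeline.

    submodel_scope="fold" (the correct protocol) trains every step on the
    training partition only. submodel_scope="full" is a deliberate
    leakage diagnostic: the three submodels are fit once on ALL variants
    and only the final evaluation is split — useful to demonstrate the
    score inflation that per-step fold leakage causes.
    """
    cfg = cfg or TrainingConfig()
    if submodel_scope not in {"fold", "full"}:
        raise ValueError("submodel_scope must be 'fold' or 'full'")
    ids = dataset.variant_ids
    emvar = emvar_label_table(dataset, cfg).set_index(["variant_id", "cell_type"])

    folds = None
    for attempt in range(max_redraws):
        cand = make_folds(ids, k=k, seed=seed + attempt)
        ok = all(
            _fold_is_trainable(dataset, [v for v in ids if cand.assignment[v] != f], cfg)
            for f in range(1, k + 1)
        )
        if ok:
            folds = cand
            if attempt:
                logger.info("fold assignment redrawn %d time(s)", attempt)
            break
    if folds is None:
        raise ValueError(f"could not draw trainable folds in {max_redraws} attempts")

    leaky_bundle = None
    if submodel_scope == "full":
        leaky_bundle = train_on(dataset, ids, cfg)

    pred_frames = []
    for fold in range(1, k + 1):
        test_ids = folds.fold_ids(fold)
        train_ids = [v for v in ids if folds.assignment[v] != fold]
        bundle = leaky_bundle if leaky_bundle is not None else train_on(
            dataset, train_ids, replace(cfg, seed=cfg.seed + 1000 * fold)
        )
        df = predict_scores(
            bundle, dataset.bsm, dataset.profiles,
            variant_ids=test_ids, cell_types=dataset.cell_types, cfg=cfg,
        )
        df["fold"] = fold
        pred_frames.append(df)
    preds = pd.concat(pred_frames, ignore_index=True)
    preds["is_emvar"] = [
        bool(emvar.loc[(v, c), "is_emvar"])
        for v, c in zip(preds.variant_id, preds.cell_type)
    ]
    return CvResult(
        predictions=preds,
        auroc=auroc(preds.m, preds.is_emvar),
        auprc=auprc(preds.m, preds.is_emvar),
        folds=folds,
    )
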