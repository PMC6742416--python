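"""Feature construction for the three-step model.

Allele-level binding vectors feed the universal-activity classifier;
binding deltas (alt - ref, a motif-break-like signal) quantify how much
the SNV perturbs each TF's site; the rank-reordered expression vector
carries the cellular context into the expression modifier arm: position k
holds the expression of the TF with the k-th highest binding score on the
variant's element, so the vector reads "expression of the most influential
TF first" regardless of which TF that is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BindingScoreMatrix, ExpressionProfile


@dataclass
class ReorderedExpressionVector:
    variant_id: str
    sample_id: str
    values: np.ndarray  # length N; position k = expression of k-th ranked TF
    ranked_tf_ids: list[str]


def allele_feature_vector(
    bsm: BindingScoreMatrix, variant_id: str, allele: str
) -> np.ndarray:
    """The variant's binding-score row for one allele, in tf_ids order."""
    i = bsm.row_index(variant_id)
    if allele == "ref":
        return bsm.scores_ref[i].copy()
    if allele == "alt":
        return bsm.scores_alt[i].copy()
    raise ValueError(f"allele must be 'ref' or 'alt', got {allele!r}")


def binding_delta(bsm: BindingScoreMatrix, variant_id: str) -> np.ndarray:
    """Elementwise alt - ref binding score for one variant."""
    i = bsm.row_index(variant_id)
    return bsm.scores_alt[i] - bsm.scores_ref[i]


def rank_tfs(
    bsm: BindingScoreMatrix, variant_id: str, key_allele: str = "ref"
) -> np.ndarray:
    """Column indices of TFs sorted by binding score descending.

    key_allele "ref" (default), "alt", or "max" (elementwise max of the
    two alleles). Ties break lexicographically by TF id, so rankings are
    deterministic.
    """
    i = bsm.row_index(variant_id)
    if key_allele == "ref":
        scores = bsm.scores_ref[i]
    elif key_allele == "alt":
        scores = bsm.scores_alt[i]
    elif key_allele == "max":
        scores = np.maximum(bsm.scores_ref[i], bsm.scores_alt[i])
    else:
        raise ValueError(f"key_allele must be ref/alt/max, got {key_allele!r}")
    order = sorted(range(bsm.n_tfs), key=lambda j: (-scores[j], bsm.tf_ids[j]))
    return np.array(order, dtype=int)


def reorder_expression(
    bsm: BindingScoreMatrix,
    variant_id: str,
    profile: ExpressionProfile,
    key_allele: str = "ref",
    log1p: bool = False,
) -> ReorderedExpressionVector:
    """Place each TF's expression at its binding rank for this variant."""
    if bsm.n_tfs == 0:
        raise ValueError("empty TF set")
    order = rank_tfs(bsm, variant_id, key_allele)
    ranked_ids = [bsm.tf_ids[j] for j in order]
    values = profile.lookup(ranked_ids)
    if log1p:
        values = np.log1p(values)
    return ReorderedExpressionVector(
        variant_id=variant_id,
        sample_id=profile.sample_id,
        values=values,
        ranked_tf_ids=ranked_ids,
    )
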