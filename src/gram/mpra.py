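"""MPRA-derived statistics and training-label construction.

A reporter-assay experiment on one variant yields the 2x2 count table
(assay/control x reference/alternative). From it this module derives:

* ``log_skew`` — the log2 odds ratio, alt over ref: how much more the
  alternative allele modulates reporter expression than the reference.
* ``vodds`` — sqrt(1/n1 + 1/n2 + 1/n3 + 1/n4), the delta-method standard
  deviation of the log odds ratio; a cell-type-specific variability signal.
* activity calls per allele (fold-change, optionally gated by a
  conditional binomial count test).
* emVAR labels: significant allelic skew with |logSkew| > log2(1.5).
* modifier labels: top/bottom Vodds quartiles as high/low classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import MpraCountTable

#: |log2(1.5)| rounded to 4 d.p. — the allelic-skew filter used to call emVARs.
DEFAULT_SKEW_THRESHOLD = 0.5849

#: Haldane-Anscombe pseudocount applied to tables containing zeros.
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class ActivityLabel:
    variant_id: str
    allele: str  # "ref" or "alt"
    active: bool
    fold_change: float
    p_value: float | None = None


@dataclass
class EmvarLabel:
    variant_id: str
    log_skew: float
    is_emvar: bool
    passes_skew_filter: bool


@dataclass
class ModifierLabel:
    variant_id: str
    cell_type: str
    vodds: float
    klass: str  # "high" | "low" | "excluded"


def _auto_pseudocount(counts: np.ndarray, pseudocount: float | None) -> float:
    """Default policy: 0 when all counts positive, 0.5 on tables with zeros."""
    if pseudocount is not None:
        return pseudocount
    return 0.0 if (counts > 0).all() else DEFAULT_PSEUDOCOUNT


def log_skew(table: MpraCountTable, pseudocount: float | None = None) -> float:
    """log2 odds ratio of the 2x2 table, alternative over reference.

    Antisymmetric under swapping the two allele columns.
    """
    c = table.counts()
    if (c == 0).all():
        raise ValueError(f"{table.variant_id}: empty table")
    ps = _auto_pseudocount(c, pseudocount)
    n1, n2, n3, n4 = c + ps
    if min(n1, n2, n3, n4) <= 0:
        raise ValueError(f"{table.variant_id}: zero count; use a pseudocount")
    return float(np.log2((n3 / n4) / (n1 / n2)))


def vodds(table: MpraCountTable, pseudocount: float | None = None) -> float:
    """Delta-method SD of the table's log odds: sqrt(sum of 1/count)."""
    c = table.counts()
    ps = _auto_pseudocount(c, pseudocount)
    n = c + ps
    if (n <= 0).any():
        raise ValueError(f"{table.variant_id}: zero count; use pseudocount")
    return float(np.sqrt((1.0 / n).sum()))


def call_activity(
    table: MpraCountTable,
    mode: str = "count_test",
    fc_cutoff: float = 1.5,
    alpha: float = 0.05,
    pseudocount: float | None = None,
) -> tuple[ActivityLabel, ActivityLabel]:
    """Call regulatory activity for each allele of one variant.

    fold_change = (assay + ps) / (control + ps) per allele, where the
    default pseudocount is 0 when both counts are positive and 0.5
    (Haldane-Anscombe) when the pair contains a zero. In
    ``fold_change`` mode an allele is active iff fold_change > fc_cutoff
    (strict). In ``count_test`` mode the fold-change rule is additionally
    gated by a two-sided conditional binomial test of assay vs control
    counts; activity calls computed by external differential-expression
    tools can be supplied instead of using this mode.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if mode not in {"count_test", "fold_change"}:
        raise ValueError(f"unknown mode {mode!r}")

    def one(allele: str, assay: float, control: float) -> ActivityLabel:
        ps = _auto_pseudocount(np.array([assay, control]), pseudocount)
        fc = (assay + ps) / (control + ps)
        p = None
        active = fc > fc_cutoff
        if mode == "count_test":
            k, n = int(round(assay)), int(round(assay + control))
            p = stats.binomtest(k, n, 0.5).pvalue if n > 0 else 1.0
            active = active and p < alpha
        return ActivityLabel(table.variant_id, allele, bool(active), float(fc), p)

    return (one("ref", table.n1, table.n2), one("alt", table.n3, table.n4))


def allelic_skew_test(table: MpraCountTable) -> float:
    """Two-sided Fisher exact p-value for differential allelic activity
    on the (rounded) 2x2 table; the significance gate of the emVAR call."""
    c = np.round(table.counts()).astype(int)
    contingency = np.array([[c[0], c[1]], [c[2], c[3]]])
    return float(stats.fisher_exact(contingency, alternative="two-sided")[1])


def label_emvar(
    log_skew_value: float,
    significant: bool,
    skew_threshold: float = DEFAULT_SKEW_THRESHOLD,
    variant_id: str = "",
) -> EmvarLabel:
    """An expression-modulating variant shows a significant allelic
    difference AND |logSkew| above the threshold (default |log2 1.5|)."""
    if skew_threshold <= 0:
        raise ValueError("skew_threshold must be > 0")
    passes = abs(log_skew_value) > skew_threshold
    return EmvarLabel(
        variant_id=variant_id,
        log_skew=float(log_skew_value),
        passes_skew_filter=bool(passes),
        is_emvar=bool(significant and passes),
    )


def modifier_labels(
    vodds_values: Sequence[float],
    variant_ids: Sequence[str] | None = None,
    cell_type: str = "",
    lower_q: float = 0.25,
    upper_q: float = 0.75,
) -> list[ModifierLabel]:
    """Quartile-based cell-type-modifier classes from per-variant Vodds.

    Variants at or above the upper quantile boundary are "high", at or
    below the lower boundary "low", the rest "excluded". Boundaries use
    the linear-interpolation empirical-quantile convention; exact boundary
    ties are labeled inward (into high/low).
    """
    v = np.asarray(vodds_values, dtype=float)
    if len(v) < 8:
        raise ValueError("need at least 8 variants for quantile labeling")
    if not (0.0 < lower_q < upper_q < 1.0):
        raise ValueError("require 0 < lower_q < upper_q < 1")
    if np.ptp(v) == 0:
        raise ValueError("degenerate distribution: constant vodds vector")
    if variant_ids is None:
        variant_ids = [str(i) for i in range(len(v))]
    lo = float(np.quantile(v, lower_q))
    hi = float(np.quantile(v, upper_q))
    out = []
    for vid, val in zip(variant_ids, v):
        if val >= hi:
            klass = "high"
        elif val <= lo:
            klass = "low"
        else:
            klass = "excluded"
        out.append(ModifierLabel(str(vid), cell_type, float(val), klass))
    return out


def pca_vodds(vodds_by_cell: np.ndarray, cell_ids: Sequence[str] | None = None):
    """Centered PCA of the cells x variants Vodds matrix.

    Returns (loadings, explained_variance_ratio): loadings[c, k] is the
    projection of cell row c on component k. Used for the qualitative
    check that related cell lines cluster together.
    """
    X = np.asarray(vodds_by_cell, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 cell rows")
    if X.shape[1] < 3:
        raise ValueError("need >= 3 variant columns")
    if np.isnan(X).any():
        raise ValueError("missing values not allowed")
    from sklearn.decomposition import PCA

    pca = PCA(n_components=min(X.shape))
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
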