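"""Per-sample fine-mapping workflow.

Given a cohort with genotypes and per-sample expression, every candidate
variant in a region is scored in every sample using that sample's
expression as the cellular context. Variants are then ranked by their
average score across samples — the highest-ranked being the best
candidates for direct expression modulation — and each variant's
per-sample scores are correlated (Pearson) with the expression of its
eQTL target gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import BindingScoreMatrix, ExpressionProfile, GramModelBundle
from .model import TrainingConfig, predict_scores

logger = logging.getLogger(__name__)


@dataclass
class CohortInput:
    """A genotyped cohort over one region's candidate variants."""

    region: str
    genotypes: pd.DataFrame           # samples x variants dosages {0,1,2}
    expression: Mapping[str, ExpressionProfile]  # sample -> TF profile
    eqtl_targets: Mapping[str, str]   # variant -> target gene id
    target_expression: pd.DataFrame   # samples x genes

    def __post_init__(self) -> None:
        samples = list(self.genotypes.index)
        missing = [s for s in samples if s not in self.expression]
        if missing:
            raise ValueError(f"samples lack expression profiles: {missing[:5]}")
        missing = [s for s in samples if s not in self.target_expression.index]
        if missing:
            raise ValueError(f"samples lack target expression: {missing[:5]}")

    @property
    def samples(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def variants(self) -> list[str]:
        return list(self.genotypes.columns)


@dataclass
class FineMapResult:
    region: str
    score_matrix: pd.DataFrame   # variants x samples of M(i, c); NaN = masked
    mean_score: pd.Series        # per variant, over scored samples
    ranking: list[str]           # variants by mean score descending
    correlations: pd.DataFrame   # variant_id, target_gene, r, p_value, reason


def score_cohort(
    cohort: CohortInput,
    bundle: GramModelBundle,
    bsm: BindingScoreMatrix,
    mode: str = "all_samples",
    cfg: TrainingConfig | None = None,
) -> pd.DataFrame:
    """Score every (variant, sample) pair; variants x samples frame.

    mode="carriers_only" masks (as NaN) samples carrying no copy of the
    alternative allele; masked cells are excluded from mean scores.
    """
    if mode not in {"all_samples", "carriers_only"}:
        raise ValueError(f"unknown mode {mode!r}")
    variants = cohort.variants
    known = set(bsm.variant_ids)
    unknown = [v for v in variants if v not in known]
    if unknown:
        raise ValueError(f"binding matrix lacks variants: {unknown[:5]}")
    long = predict_scores(
        bundle, bsm, dict(cohort.expression),
        variant_ids=variants, cell_types=cohort.samples, cfg=cfg,
    )
    mat = long.pivot(index="variant_id", columns="cell_type", values="m")
    mat = mat.loc[variants, cohort.samples]
    if mode == "carriers_only":
        carrier = cohort.genotypes.T.loc[variants, cohort.samples] > 0
        mat = mat.where(carrier)
    mat.columns.name = "sample_id"
    return mat


def rank_variants(score_matrix: pd.DataFrame) -> tuple[list[str], pd.Series]:
    """Variants by mean score (over non-masked samples) descending; ties
    break by variant id."""
    mean = score_matrix.mean(axis=1, skipna=True)
    order = sorted(mean.index, key=lambda v: (-mean[v], v))
    return order, mean


def correlate_scores_expression(
    score_matrix: pd.DataFrame,
    target_expression: pd.DataFrame,
    eqtl_targets: Mapping[str, str],
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson r (and two-sided t-test p) between each variant's
    per-sample scores and its target gene's expression."""
    rows = []
    for v in score_matrix.index:
        gene = eqtl_targets.get(v)
        row = {"variant_id": v, "target_gene": gene, "r": np.nan, "p_value": np.nan,
               "reason": ""}
        if gene is None or gene not in target_expression.columns:
            row["reason"] = "no target gene"
        else:
            scores = score_matrix.loc[v]
            expr = target_expression.loc[score_matrix.columns, gene]
            mask = scores.notna() & expr.notna()
            s, e = scores[mask].to_numpy(float), expr[mask].to_numpy(float)
            if len(s) < min_pairs:
                row["reason"] = f"fewer than {min_pairs} paired samples"
            elif np.ptp(s) == 0 or np.ptp(e) == 0:
                row["reason"] = "constant series"
            else:
                r, p = stats.pearsonr(s, e)
                row.update(r=float(r), p_value=float(p), reason="")
        rows.append(row)
    return pd.DataFrame(rows)


def finemap_region(
    cohort: CohortInput,
    bundle: GramModelBundle,
    bsm: BindingScoreMatrix,
    mode: str = "all_samples",
    cfg: TrainingConfig | None = None,
) -> FineMapResult:
    """Full workflow for one region: score, rank, correlate."""
    mat = score_cohort(cohort, bundle, bsm, mode=mode, cfg=cfg)
    ranking, mean = rank_variants(mat)
    corr = correlate_scores_expression(mat, cohort.target_expression, cohort.eqtl_targets)
    return FineMapResult(
        region=cohort.region, score_matrix=mat, mean_score=mean,
        ranking=ranking, correlations=corr,
    )


def render_region_report(
    results: FineMapResult | Mapping[str, FineMapResult],
    out_dir: str | Path,
    plot: bool = True,
) -> list[Path]:
    """Write per-region TSVs (long-form scores, summary with means, ranks
    and correlations) and, when plotting is enabled, a score heatmap per
    region. Returns the written paths."""
    if isinstance(results, FineMapResult):
        results = {results.region: results}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise ValueError(f"not a writable directory: {out}")
    written: list[Path] = []
    for region, res in sorted(results.items()):
        safe = str(region).replace(":", "_").replace("/", "_")
        long = res.score_matrix.reset_index().melt(
            id_vars="variant_id", var_name="sample_id", value_name="m"
        )
        long.insert(0, "region", region)
        scores_path = out / f"{safe}.scores.tsv"
        long.to_csv(scores_path, sep="\t", index=False)
        written.append(scores_path)

        rank = {v: k + 1 for k, v in enumerate(res.ranking)}
        summary = res.correlations.copy()
        summary.insert(1, "mean_score", [res.mean_score[v] for v in summary.variant_id])
        summary.insert(2, "rank", [rank[v] for v in summary.variant_id])
        summary = summary.sort_values("rank")
        summary_path = out / f"{safe}.summary.tsv"
        summary.to_csv(summary_path, sep="\t", index=False)
        written.append(summary_path)

        if res.score_matrix.shape[0] == 0:
            logger.info("region %s is empty; no heatmap", region)
            continue
        if plot:
            written.append(_heatmap(res, out / f"{safe}.heatmap.png"))
    return written


def _heatmap(res: FineMapResult, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = res.score_matrix.loc[res.ranking]
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.12 * mat.shape[1]), max(3.0, 0.18 * mat.shape[0]))
    )
    im = ax.imshow(mat.to_numpy(float), aspect="auto", cmap="viridis",
                   vmin=0.0, vmax=1.0)
    ax.set_xlabel("sample")
    ax.set_ylabel("variant (ranked by mean score)")
    ax.set_title(f"per-sample scores: {res.region}")
    fig.colorbar(im, ax=ax, label="M")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
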