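"""Self-contained synthetic data with the statistical structure the
model assumes.

The generator mirrors the input contract rather than raw sequence: TF
binding scores are drawn directly (per variant and allele), a sparse set
of "signal" TFs carries the causal link from binding to reporter
activity, and each cell type expresses a subset of the signal TFs. For a
variant i in cell c:

* reference-allele activity is logistic in the mean signal-TF binding
  score (slope ``effect_size``);
* the alternative allele shifts the activity log-odds by ``skew_effect``
  times the sum of its signal-TF binding deltas, each gated by that TF's
  expression state in cell c (an unexpressed TF contributes a factor of
  1 - ``expression_coupling``);
* assay counts are negative-binomial around depth * activity, control
  counts around depth * (1 - activity), so the expected log odds ratio of
  the 2x2 count table equals the latent allelic log-odds shift (Poisson
  counts in the dispersion -> 0 limit).

The true expression-modulating label is defined on the latent
(noise-free) allelic log-odds shift, so label noise is controlled only by
sequencing depth and dispersion. Ground truth (latent skew, activities,
perturbed TFs) is emitted alongside every dataset for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
import pandas as pd

from . import mpra
from .io import BindingScoreMatrix, ExpressionProfile, MpraCountTable

LOG2 = np.log(2.0)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the "strong signal" scenario used for end-to-end
    benchmarks: 2000 variants x 50 TFs of which 5 carry signal, two cell
    types with complementary signal-TF expression, and a mean read depth
    of 200 with mild overdispersion. ``skew_effect=0`` gives the matched
    null scenario in which allelic deltas carry no label information.
    """

    V: int = 2000
    N: int = 50
    n_signal_tfs: int = 5
    cell_types: tuple[str, ...] = ("cellA", "cellB")
    effect_size: float = 0.5      # binding -> baseline-activity log-odds slope
    skew_effect: float = 1.5      # binding delta -> allelic log-odds slope
    expression_coupling: float = 0.9  # 1 - gate of an unexpressed signal TF
    count_depth: float = 500.0
    dispersion: float = 0.01
    p_signal_perturb: float = 0.5  # chance the SNV perturbs its dominant signal TF
    n_background_perturb: int = 3
    signal_binding_shift: float = 1.5  # mean ref-binding elevation of signal TFs
    signal_delta_mean: float = 1.2  # |delta| of a dominant-TF motif disruption
    signal_delta_sd: float = 0.4
    background_delta_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_signal_tfs <= self.N):
            raise ValueError("require 0 < n_signal_tfs <= N")
        if self.count_depth <= 0:
            raise ValueError("count_depth must be > 0")

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{j:03d}" for j in range(self.N)]

    @property
    def signal_tfs(self) -> list[str]:
        return self.tf_ids[: self.n_signal_tfs]

    @property
    def variant_ids(self) -> list[str]:
        return [f"var{i:05d}" for i in range(self.V)]


def null_config(config: SimulationConfig) -> SimulationConfig:
    """The matched null scenario: allelic deltas decoupled from counts."""
    return replace(config, skew_effect=0.0)


@dataclass
class BindingTruth:
    delta: np.ndarray          # V x N alt-minus-ref deltas
    perturbed: np.ndarray      # V x N boolean mask of perturbed TFs
    signal_idx: np.ndarray     # column indices of signal TFs
    dominant_tf: np.ndarray    # per variant, the strongest-bound signal TF


def simulate_binding(config: SimulationConfig) -> tuple[BindingScoreMatrix, BindingTruth]:
    """Draw ref binding scores and sparse alt-allele deltas.

    Signal TFs are the high-affinity regulators of these elements, so
    their reference binding scores are elevated by
    ``signal_binding_shift`` and they concentrate at the top of the
    per-variant binding ranking. A SNV disrupts motifs of TFs actually
    bound at its site: with probability ``p_signal_perturb`` the variant
    perturbs its dominant (strongest-bound) signal TF; it additionally
    perturbs ``n_background_perturb`` random non-signal TFs. Deltas are
    standard normal on perturbed TFs, zero elsewhere.
    """
    rng = np.random.default_rng(config.seed)
    V, N = config.V, config.N
    ref = rng.normal(0.0, 1.0, size=(V, N))
    ref[:, : config.n_signal_tfs] += config.signal_binding_shift
    perturbed = np.zeros((V, N), dtype=bool)
    background = np.arange(config.n_signal_tfs, N)
    dominant = np.argmax(ref[:, : config.n_signal_tfs], axis=1)
    hit = rng.random(V) < config.p_signal_perturb
    perturbed[np.arange(V)[hit], dominant[hit]] = True
    for i in range(V):
        if len(background) and config.n_background_perturb:
            k = min(config.n_background_perturb, len(background))
            perturbed[i, rng.choice(background, size=k, replace=False)] = True
    # background perturbations are weak nuisance wobble; a hit on the
    # dominant bound TF is a clear motif disruption or gain
    delta = np.where(perturbed, rng.normal(0.0, config.background_delta_sd, size=(V, N)), 0.0)
    if hit.any():
        rows = np.arange(V)[hit]
        mag = np.maximum(0.2, rng.normal(config.signal_delta_mean, config.signal_delta_sd, size=len(rows)))
        sign = rng.choice([-1.0, 1.0], size=len(rows))
        delta[rows, dominant[rows]] = sign * mag
    bsm = BindingScoreMatrix(
        variant_ids=config.variant_ids,
        tf_ids=config.tf_ids,
        scores_ref=ref,
        scores_alt=ref + delta,
        assay_types={t: "SELEX" for t in config.tf_ids},
    )
    return bsm, BindingTruth(
        delta=delta, perturbed=perturbed,
        signal_idx=np.arange(config.n_signal_tfs), dominant_tf=dominant,
    )


@dataclass
class ExpressionTruth:
    gates: dict[str, np.ndarray]  # cell -> length-N gate in (0, 1]
    on_mask: dict[str, np.ndarray]  # cell -> boolean "expressed" mask (signal TFs)


def simulate_expression(
    config: SimulationConfig,
) -> tuple[dict[str, ExpressionProfile], ExpressionTruth]:
    """Per-cell-type log-scale TF expression.

    Signal TF s is "on" (highly expressed) in cell type s mod n_cells, so
    cell types have complementary signal-TF repertoires and the modifier
    classes are learnable from expression. Background TFs share a per-TF
    baseline across cell types plus small cell-specific noise.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_cells = len(config.cell_types)
    baseline = rng.normal(4.0, 1.0, size=config.N)
    profiles: dict[str, ExpressionProfile] = {}
    gates: dict[str, np.ndarray] = {}
    on_masks: dict[str, np.ndarray] = {}
    for c_idx, cell in enumerate(config.cell_types):
        expr = baseline + rng.normal(0.0, 0.3, size=config.N)
        on = np.zeros(config.N, dtype=bool)
        for s in range(config.n_signal_tfs):
            if s % n_cells == c_idx:
                on[s] = True
                expr[s] = rng.normal(6.0, 0.5)
            else:
                expr[s] = rng.normal(2.0, 0.5)
        expr = np.clip(expr, 0.0, None)
        gate = np.ones(config.N)
        gate[: config.n_signal_tfs] = np.where(
            on[: config.n_signal_tfs], 1.0, 1.0 - config.expression_coupling
        )
        profiles[cell] = ExpressionProfile(
            sample_id=cell, tf_ids=config.tf_ids, expression=expr
        )
        gates[cell] = gate
        on_masks[cell] = on[: config.n_signal_tfs].copy()
    return profiles, ExpressionTruth(gates=gates, on_mask=on_masks)


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = mean + dispersion * mean^2;
    Poisson when dispersion == 0."""
    mean = np.maximum(np.asarray(mean, float), 1e-9)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def simulate_mpra_counts(
    config: SimulationConfig,
    binding_truth: BindingTruth,
    bsm: BindingScoreMatrix,
    expression_truth: ExpressionTruth,
) -> tuple[list[MpraCountTable], pd.DataFrame]:
    """Reporter count tables per (variant, cell type) plus latent truth.

    The truth frame carries the latent log2 allelic skew, both latent
    activities and the true expression-modulating label
    (|latent log2 skew| > the emVAR filter threshold).
    """
    rng = np.random.default_rng(config.seed + 2)
    sig = binding_truth.signal_idx
    tables: list[MpraCountTable] = []
    truth_rows = []
    for cell in config.cell_types:
        gate = expression_truth.gates[cell][sig]
        # activity is driven by the strongest expressed signal TF bound to
        # the element; centered per cell so baseline activity straddles 0.5
        gated_ref = (bsm.scores_ref[:, sig] * gate).max(axis=1)
        eta_ref = config.effect_size * (gated_ref - gated_ref.mean())
        latent_shift = config.skew_effect * (binding_truth.delta[:, sig] * gate).sum(axis=1)
        eta_alt = eta_ref + latent_shift
        act_ref = 1.0 / (1.0 + np.exp(-eta_ref))
        act_alt = 1.0 / (1.0 + np.exp(-eta_alt))
        n1 = _draw_counts(rng, config.count_depth * act_ref, config.dispersion)
        n2 = _draw_counts(rng, config.count_depth * (1.0 - act_ref), config.dispersion)
        n3 = _draw_counts(rng, config.count_depth * act_alt, config.dispersion)
        n4 = _draw_counts(rng, config.count_depth * (1.0 - act_alt), config.dispersion)
        latent_log2 = latent_shift / LOG2
        for i, vid in enumerate(config.variant_ids):
            tables.append(
                MpraCountTable(
                    variant_id=vid, cell_type=cell,
                    n1=float(n1[i]), n2=float(n2[i]),
                    n3=float(n3[i]), n4=float(n4[i]),
                )
            )
            truth_rows.append(
                {
                    "variant_id": vid,
                    "cell_type": cell,
                    "latent_log2_skew": float(latent_log2[i]),
                    "activity_ref": float(act_ref[i]),
                    "activity_alt": float(act_alt[i]),
                    "true_emvar": bool(
                        abs(latent_log2[i]) > mpra.DEFAULT_SKEW_THRESHOLD
                    ),
                }
            )
    return tables, pd.DataFrame(truth_rows)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    bsm: BindingScoreMatrix
    profiles: dict[str, ExpressionProfile]
    counts: list[MpraCountTable]
    truth: pd.DataFrame
    binding_truth: BindingTruth
    expression_truth: ExpressionTruth


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a complete dataset (binding, expression, counts, truth)."""
    config = config or SimulationConfig()
    bsm, btruth = simulate_binding(config)
    profiles, etruth = simulate_expression(config)
    counts, truth = simulate_mpra_counts(config, btruth, bsm, etruth)
    return SyntheticDataset(
        config=config, bsm=bsm, profiles=profiles, counts=counts,
        truth=truth, binding_truth=btruth, expression_truth=etruth,
    )


# ---------------------------------------------------------------------------
# Fine-mapping cohorts
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    bsm: BindingScoreMatrix
    genotypes: pd.DataFrame       # samples x variants dosages in {0,1,2}
    expression: dict[str, ExpressionProfile]  # sample -> TF profile
    eqtl_targets: dict[str, str]  # variant -> target gene
    target_expression: pd.DataFrame  # samples x genes
    causal_variant: str


def simulate_cohort(
    config: SimulationConfig,
    n_variants: int = 50,
    n_samples: int = 60,
    causal_delta: float = 2.5,
    causal_site_boost: float = 2.0,
    background_delta_sd: float = 0.1,
    maf: float = 0.3,
    eqtl_beta: float = 1.5,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SyntheticCohort:
    """A genotyped cohort in which one planted causal variant breaks the
    motif of a strongly bound signal TF and drives its target gene's
    expression through dosage; all other variants carry only small
    background deltas.

    The causal site's reference binding is elevated to at least
    ``signal_binding_shift + causal_site_boost`` — a clearly occupied
    high-affinity site — and the alternative allele loses
    ``causal_delta`` of it, the canonical motif-break mechanism. The TF
    universe matches ``config`` so a model trained on the corresponding
    synthetic reporter dataset can score the cohort directly.
    """
    rng = np.random.default_rng(seed)
    tf_ids = config.tf_ids
    variant_ids = [f"rs{seed:03d}_{i:04d}" for i in range(n_variants)]
    causal = variant_ids[int(rng.integers(n_variants))]
    ref = rng.normal(0.0, 1.0, size=(n_variants, len(tf_ids)))
    ref[:, : config.n_signal_tfs] += config.signal_binding_shift
    delta = rng.normal(0.0, background_delta_sd, size=ref.shape)
    ci = variant_ids.index(causal)
    # the causal SNV breaks the motif of the TF dominantly bound at its
    # site (binding loss), mirroring the canonical emVAR mechanism; the
    # element depends on that single high-affinity site — no redundant
    # second strong site buffers the loss
    dom = int(np.argmax(ref[ci, : config.n_signal_tfs]))
    ref[ci, dom] = max(ref[ci, dom], config.signal_binding_shift + causal_site_boost)
    others = [j for j in range(config.n_signal_tfs) if j != dom]
    ref[ci, others] = np.minimum(ref[ci, others], config.signal_binding_shift - 0.5)
    delta[ci, dom] = -abs(causal_delta)
    bsm = BindingScoreMatrix(
        variant_ids=variant_ids, tf_ids=tf_ids,
        scores_ref=ref, scores_alt=ref + delta,
    )
    sample_ids = [f"S{j:03d}" for j in range(n_samples)]
    dosages = rng.binomial(2, maf, size=(n_samples, n_variants)).astype(int)
    genotypes = pd.DataFrame(dosages, index=sample_ids, columns=variant_ids)
    profiles = {}
    for s in sample_ids:
        expr = rng.normal(4.0, 1.0, size=len(tf_ids))
        expr[: config.n_signal_tfs] = rng.normal(6.0, 0.5, size=config.n_signal_tfs)
        profiles[s] = ExpressionProfile(
            sample_id=s, tf_ids=tf_ids, expression=np.clip(expr, 0.0, None)
        )
    gene = "GENE_T"
    target = eqtl_beta * genotypes[causal].to_numpy(float) + rng.normal(
        0.0, noise_sd, size=n_samples
    )
    target_expression = pd.DataFrame({gene: target}, index=sample_ids)
    return SyntheticCohort(
        bsm=bsm, genotypes=genotypes, expression=profiles,
        eqtl_targets={v: gene for v in variant_ids},
        target_expression=target_expression, causal_variant=causal,
    )


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Write the fixture set (variants, binding, expression, counts,
    truth) as TSVs under ``out_dir``."""
    from pathlib import Path

    from .io import write_binding_matrix, write_counts, write_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_binding_matrix(ds.bsm, out / "binding_ref.tsv", out / "binding_alt.tsv")
    write_expression(list(ds.profiles.values()), out / "expression.tsv")
    write_counts(ds.counts, out / "counts.tsv")
    ds.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
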