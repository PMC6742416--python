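"""Domain types and file I/O.

Variants are 1-based (VCF convention); element intervals are 0-based
half-open (BED convention). All sequences are reported on the forward
strand. Binding-score and expression matrices are headered TSV with row
ids in the first column. Model bundles are directories holding the three
fitted submodels (joblib) plus a JSON manifest with the step-3
coefficients, lambda, feature schema and training metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
DEFAULT_FLANK = 74
BUNDLE_FORMAT_VERSION = 1


class SchemaError(ValueError):
    """Raised when on-disk data does not match the expected schema."""


@dataclass
class VariantElement:
    """A biallelic SNV with (optionally) its flanking element sequences."""

    variant_id: str
    chrom: str
    pos: int  # 1-based genomic position of the SNV
    ref_allele: str
    alt_allele: str
    element_start: int | None = None  # 0-based half-open interval
    element_end: int | None = None
    ref_sequence: str | None = None
    alt_sequence: str | None = None

    def __post_init__(self) -> None:
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValueError(
                f"{self.variant_id}: alleles must be single bases in ACGT, "
                f"got {self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.variant_id}: ref and alt alleles are identical")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")

    @property
    def has_sequences(self) -> bool:
        return self.ref_sequence is not None and self.alt_sequence is not None

    def validate_sequences(self) -> None:
        """Check the element invariants once sequences are attached."""
        if not self.has_sequences:
            raise ValueError(f"{self.variant_id}: sequences not set")
        L = len(self.ref_sequence)
        if len(self.alt_sequence) != L:
            raise ValueError(f"{self.variant_id}: ref/alt sequence length mismatch")
        if L % 2 != 1:
            raise ValueError(f"{self.variant_id}: element length must be odd")
        if self.element_end - self.element_start != L:
            raise ValueError(f"{self.variant_id}: interval length != sequence length")
        if not (self.element_start < self.pos <= self.element_end):
            raise ValueError(f"{self.variant_id}: interval does not contain pos")
        center = L // 2
        diffs = [
            k for k, (a, b) in enumerate(zip(self.ref_sequence, self.alt_sequence)) if a != b
        ]
        if diffs != [center]:
            raise ValueError(
                f"{self.variant_id}: sequences must differ exactly at the center"
            )
        if self.ref_sequence[center] != self.ref_allele:
            raise ValueError(f"{self.variant_id}: center base != ref allele")
        if self.alt_sequence[center] != self.alt_allele:
            raise ValueError(f"{self.variant_id}: center base != alt allele")


@dataclass
class MpraCountTable:
    """The 2x2 assay/control x ref/alt read-count table for one variant.

    n1: assay, reference    n3: assay, alternative
    n2: control, reference  n4: control, alternative

    Counts are averages over replicates and may be non-integer.
    """

    variant_id: str
    cell_type: str
    n1: float
    n2: float
    n3: float
    n4: float

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "n3", "n4"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{self.variant_id}: negative count {name}={v}")

    def counts(self) -> np.ndarray:
        return np.array([self.n1, self.n2, self.n3, self.n4], dtype=float)


@dataclass
class BindingScoreMatrix:
    """Variant x TF binding scores, one layer per allele."""

    variant_ids: list[str]
    tf_ids: list[str]
    scores_ref: np.ndarray  # shape (V, N)
    scores_alt: np.ndarray  # shape (V, N)
    assay_types: dict[str, str] | None = None  # tf_id -> {"SELEX", "ChIP-Seq"}
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.scores_ref = np.asarray(self.scores_ref, dtype=float)
        self.scores_alt = np.asarray(self.scores_alt, dtype=float)
        V, N = len(self.variant_ids), len(self.tf_ids)
        if self.scores_ref.shape != (V, N) or self.scores_alt.shape != (V, N):
            raise ValueError("scores_ref/scores_alt must both be V x N")
        if len(set(self.variant_ids)) != V:
            raise ValueError("duplicate variant ids")
        if len(set(self.tf_ids)) != N:
            raise ValueError("duplicate TF ids")
        if np.isnan(self.scores_ref).any() or np.isnan(self.scores_alt).any():
            raise ValueError("missing entries must be imputed before construction")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    def row_index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"unknown variant_id {variant_id!r}") from None

    def reorder_tfs(self, tf_ids: Sequence[str]) -> "BindingScoreMatrix":
        """Return a copy with TF columns aligned to ``tf_ids`` (by id, not position)."""
        missing = [t for t in tf_ids if t not in set(self.tf_ids)]
        if missing:
            raise SchemaError(f"binding matrix lacks TFs: {missing[:5]}")
        cols = [self.tf_ids.index(t) for t in tf_ids]
        return BindingScoreMatrix(
            variant_ids=list(self.variant_ids),
            tf_ids=list(tf_ids),
            scores_ref=self.scores_ref[:, cols],
            scores_alt=self.scores_alt[:, cols],
            assay_types=self.assay_types,
        )

    def subset(self, variant_ids: Sequence[str]) -> "BindingScoreMatrix":
        rows = [self.row_index(v) for v in variant_ids]
        return BindingScoreMatrix(
            variant_ids=list(variant_ids),
            tf_ids=list(self.tf_ids),
            scores_ref=self.scores_ref[rows],
            scores_alt=self.scores_alt[rows],
            assay_types=self.assay_types,
        )


@dataclass
class ExpressionProfile:
    """Per-sample (or per-cell-type) TF expression vector."""

    sample_id: str
    tf_ids: list[str]
    expression: np.ndarray
    imputed_tfs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        if self.expression.shape != (len(self.tf_ids),):
            raise ValueError("expression vector length must match tf_ids")
        if (self.expression < 0).any():
            raise ValueError("expression values must be nonnegative")

    def lookup(self, tf_ids: Sequence[str], fill: str = "median") -> np.ndarray:
        """Expression values for ``tf_ids``; missing TFs imputed with the
        profile median and recorded in ``imputed_tfs``."""
        idx = {t: k for k, t in enumerate(self.tf_ids)}
        med = float(np.median(self.expression)) if len(self.expression) else 0.0
        out = np.empty(len(tf_ids))
        for k, t in enumerate(tf_ids):
            if t in idx:
                out[k] = self.expression[idx[t]]
            else:
                if fill != "median":
                    raise KeyError(f"profile {self.sample_id} lacks TF {t!r}")
                out[k] = med
                if t not in self.imputed_tfs:
                    self.imputed_tfs.append(t)
        return out


@dataclass
class GramModelBundle:
    """The fitted three-step model.

    step1_model predicts universal regulatory activity U from binding
    scores; the two step-2 models predict the cell-type modifier scores
    S_b (binding) and S_e (rank-reordered expression); step3_coefficients
    (b_u, b_s1, b_s2, b') and lambda define the final logistic
    integration M = logistic(b_u*Odds + b_s1*S_b + b_s2*S_e + b').
    """

    step1_model: object
    step2_binding_model: object
    step2_expression_model: object
    b_u: float
    b_s1: float
    b_s2: float
    b0: float
    lambda_: float
    tf_ids: list[str]
    training_metadata: dict = field(default_factory=dict)

    @property
    def step3_coefficients(self) -> tuple[float, float, float, float]:
        return (self.b_u, self.b_s1, self.b_s2, self.b0)


@dataclass
class GramScore:
    """All intermediates and the final score for one (variant, sample)."""

    variant_id: str
    sample_id: str
    u_wt: float
    u_mut: float
    odds: float
    s_b: float
    s_e: float
    m: float


# ---------------------------------------------------------------------------
# Variant readers
# ---------------------------------------------------------------------------

def read_variants(path: str | Path, fmt: str | None = None) -> list[VariantElement]:
    """Read biallelic SNVs from a VCF or a headered TSV.

    TSV columns: chrom, pos, ref, alt and optionally variant_id. Non-SNV
    records (indels, multi-allelic) are skipped with a logged warning;
    the skip count is attached to the returned list as ``.skipped``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in {".vcf", ".bcf"} or str(path).endswith(
            ".vcf.gz"
        ) else "tsv"
    if fmt.lower() == "vcf":
        variants, skipped = _read_variants_vcf(path)
    elif fmt.lower() == "tsv":
        variants, skipped = _read_variants_tsv(path)
    else:
        raise ValueError(f"unknown variant format {fmt!r}")
    if skipped:
        logger.warning("skipped %d non-SNV record(s) in %s", skipped, path)
    out = _VariantList(variants)
    out.skipped = skipped
    return out


class _VariantList(list):
    """List of VariantElement carrying a non-SNV skip count."""

    skipped: int = 0


def _read_variants_tsv(path: Path) -> tuple[list[VariantElement], int]:
    variants: list[VariantElement] = []
    skipped = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c.strip().lower(): k for k, c in enumerate(header)}
        for req in ("chrom", "pos", "ref", "alt"):
            if req not in cols:
                raise SchemaError(f"{path}: missing required column {req!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(cols):
                raise SchemaError(f"line {lineno}: expected {len(cols)} fields")
            raw_pos = parts[cols["pos"]]
            try:
                pos = int(raw_pos)
            except ValueError:
                raise SchemaError(f"line {lineno}: non-integer position {raw_pos!r}")
            ref = parts[cols["ref"]].upper()
            alt = parts[cols["alt"]].upper()
            vid = (
                parts[cols["variant_id"]]
                if "variant_id" in cols
                else f"{parts[cols['chrom']]}:{pos}:{ref}>{alt}"
            )
            if len(ref) != 1 or len(alt) != 1 or not {ref, alt} <= VALID_BASES:
                skipped += 1
                continue
            if ref == alt:
                raise ValueError(f"line {lineno}: ref == alt for {vid}")
            variants.append(
                VariantElement(
                    variant_id=vid, chrom=parts[cols["chrom"]], pos=pos,
                    ref_allele=ref, alt_allele=alt,
                )
            )
    return variants, skipped


def _read_variants_vcf(path: Path) -> tuple[list[VariantElement], int]:
    import pysam

    variants: list[VariantElement] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                skipped += 1
                continue
            ref, alt = rec.ref.upper(), alts[0].upper()
            if not {ref, alt} <= VALID_BASES or ref == alt:
                skipped += 1
                continue
            vid = rec.id or f"{rec.chrom}:{rec.pos}:{ref}>{alt}"
            variants.append(
                VariantElement(
                    variant_id=vid, chrom=rec.chrom, pos=rec.pos,
                    ref_allele=ref, alt_allele=alt,
                )
            )
    return variants, skipped


def extract_element_sequences(
    variants: Iterable[VariantElement],
    genome: str | Path | Mapping[str, str],
    flank: int = DEFAULT_FLANK,
    strict: bool = True,
) -> list[VariantElement]:
    """Attach (2*flank + 1)-bp element sequences centered on each SNV.

    ``genome`` is a FASTA path (indexed via pyfaidx) or a chrom -> sequence
    mapping. The genome base at the SNV position must equal the ref allele;
    in strict mode a mismatch raises, otherwise the variant is flagged,
    skipped and logged.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(genome), sequence_always_upper=True)
        fetch = lambda chrom, s, e: str(fa[chrom][s:e])  # noqa: E731
        length = lambda chrom: len(fa[chrom])  # noqa: E731
    else:
        fetch = lambda chrom, s, e: genome[chrom][s:e].upper()  # noqa: E731
        length = lambda chrom: len(genome[chrom])  # noqa: E731

    out: list[VariantElement] = []
    mismatches: list[str] = []
    for v in variants:
        start = v.pos - 1 - flank  # 0-based half-open
        end = v.pos + flank
        if start < 0 or end > length(v.chrom):
            raise ValueError(
                f"{v.variant_id}: element [{start}, {end}) out of bounds on {v.chrom}"
            )
        seq = fetch(v.chrom, start, end).upper()
        center = flank
        if seq[center] != v.ref_allele:
            if strict:
                raise ValueError(
                    f"{v.variant_id}: genome base {seq[center]!r} at {v.chrom}:{v.pos} "
                    f"!= ref allele {v.ref_allele!r}"
                )
            mismatches.append(v.variant_id)
            continue
        alt_seq = seq[:center] + v.alt_allele + seq[center + 1:]
        out.append(
            VariantElement(
                variant_id=v.variant_id, chrom=v.chrom, pos=v.pos,
                ref_allele=v.ref_allele, alt_allele=v.alt_allele,
                element_start=start, element_end=end,
                ref_sequence=seq, alt_sequence=alt_seq,
            )
        )
    if mismatches:
        logger.warning(
            "skipped %d variant(s) with reference mismatch: %s",
            len(mismatches), ", ".join(mismatches[:10]),
        )
    return out


# ---------------------------------------------------------------------------
# Matrix readers / writers
# ---------------------------------------------------------------------------

COUNT_COLUMNS = ("assay_ref", "ctrl_ref", "assay_alt", "ctrl_alt")


def _read_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise SchemaError(f"{path}: empty matrix")
    if df.index.duplicated().any():
        raise SchemaError(f"{path}: duplicate row ids")
    if df.columns.duplicated().any():
        raise SchemaError(f"{path}: duplicate column ids")
    return df


def _impute_column_median(df: pd.DataFrame, label: str) -> pd.DataFrame:
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        df = df.fillna(df.median(axis=0))
        logger.info("%s: imputed %d missing entr(ies) with column medians", label, n_missing)
        if df.isna().any().any():
            raise SchemaError(f"{label}: column(s) entirely missing")
    return df


def read_matrix(
    path: str | Path,
    kind: str,
    alt_path: str | Path | None = None,
):
    """Read a typed matrix from TSV.

    kind="binding": ``path`` holds reference-allele scores, ``alt_path``
    alternative-allele scores (rows = variant ids, columns = TF ids);
    missing cells are imputed with the column (TF) median. Returns a
    BindingScoreMatrix.
    kind="expression": rows = sample/cell ids, columns = TF ids. Returns a
    list of ExpressionProfile.
    kind="counts": columns variant_id, cell_type, assay_ref, ctrl_ref,
    assay_alt, ctrl_alt. Returns a list of MpraCountTable.
    """
    if kind == "binding":
        if alt_path is None:
            raise ValueError("kind='binding' requires alt_path")
        ref = _impute_column_median(_read_frame(path), str(path))
        alt = _impute_column_median(_read_frame(alt_path), str(alt_path))
        if list(ref.index) != list(alt.index):
            raise SchemaError("binding ref/alt variant ids differ")
        if set(ref.columns) != set(alt.columns):
            raise SchemaError("binding ref/alt TF sets differ")
        alt = alt[ref.columns]
        return BindingScoreMatrix(
            variant_ids=[str(i) for i in ref.index],
            tf_ids=[str(c) for c in ref.columns],
            scores_ref=ref.to_numpy(float),
            scores_alt=alt.to_numpy(float),
        )
    if kind == "expression":
        df = _impute_column_median(_read_frame(path), str(path))
        return [
            ExpressionProfile(
                sample_id=str(idx),
                tf_ids=[str(c) for c in df.columns],
                expression=row.to_numpy(float),
            )
            for idx, row in df.iterrows()
        ]
    if kind == "counts":
        df = pd.read_csv(path, sep="\t")
        required = {"variant_id", "cell_type", *COUNT_COLUMNS}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")
        if df[list(COUNT_COLUMNS)].isna().any().any():
            raise SchemaError(f"{path}: missing counts")
        if (df[list(COUNT_COLUMNS)].to_numpy(float) < 0).any():
            raise ValueError(f"{path}: negative count")
        return [
            MpraCountTable(
                variant_id=str(r.variant_id), cell_type=str(r.cell_type),
                n1=float(r.assay_ref), n2=float(r.ctrl_ref),
                n3=float(r.assay_alt), n4=float(r.ctrl_alt),
            )
            for r in df.itertuples(index=False)
        ]
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_binding_matrix(bsm: BindingScoreMatrix, ref_path: str | Path, alt_path: str | Path) -> None:
    for scores, path in ((bsm.scores_ref, ref_path), (bsm.scores_alt, alt_path)):
        pd.DataFrame(scores, index=bsm.variant_ids, columns=bsm.tf_ids).to_csv(
            path, sep="\t", index_label="variant_id"
        )


def write_expression(profiles: Sequence[ExpressionProfile], path: str | Path) -> None:
    df = pd.DataFrame(
        [p.expression for p in profiles],
        index=[p.sample_id for p in profiles],
        columns=profiles[0].tf_ids,
    )
    df.to_csv(path, sep="\t", index_label="sample_id")


def write_counts(tables: Sequence[MpraCountTable], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "variant_id": [t.variant_id for t in tables],
            "cell_type": [t.cell_type for t in tables],
            "assay_ref": [t.n1 for t in tables],
            "ctrl_ref": [t.n2 for t in tables],
            "assay_alt": [t.n3 for t in tables],
            "ctrl_alt": [t.n4 for t in tables],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Model-bundle serialization
# ---------------------------------------------------------------------------

def save_bundle(bundle: GramModelBundle, path: str | Path) -> None:
    """Serialize a fitted bundle to a directory (submodels + JSON manifest)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(bundle.step1_model, path / "step1.joblib")
    joblib.dump(bundle.step2_binding_model, path / "step2_binding.joblib")
    joblib.dump(bundle.step2_expression_model, path / "step2_expression.joblib")
    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "step3_coefficients": {
            "b_u": bundle.b_u, "b_s1": bundle.b_s1,
            "b_s2": bundle.b_s2, "b0": bundle.b0,
        },
        "lambda": bundle.lambda_,
        "feature_schema": {"tf_ids": bundle.tf_ids},
        "training_metadata": bundle.training_metadata,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_bundle(path: str | Path) -> GramModelBundle:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    version = manifest.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise SchemaError(
            f"bundle format version {version!r} != supported {BUNDLE_FORMAT_VERSION}"
        )
    if "step3_coefficients" not in manifest:
        raise SchemaError("manifest missing step3_coefficients")
    coef = manifest["step3_coefficients"]
    for key in ("b_u", "b_s1", "b_s2", "b0"):
        if key not in coef:
            raise SchemaError(f"manifest step3_coefficients missing {key!r}")
    return GramModelBundle(
        step1_model=joblib.load(path / "step1.joblib"),
        step2_binding_model=joblib.load(path / "step2_binding.joblib"),
        step2_expression_model=joblib.load(path / "step2_expression.joblib"),
        b_u=float(coef["b_u"]), b_s1=float(coef["b_s1"]),
        b_s2=float(coef["b_s2"]), b0=float(coef["b0"]),
        lambda_=float(manifest["lambda"]),
        tf_ids=list(manifest["feature_schema"]["tf_ids"]),
        training_metadata=manifest.get("training_metadata", {}),
    )
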