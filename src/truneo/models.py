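"""Domain types shared across the pipeline.

All records are plain dataclasses; readers validate on construction via the
``validate`` helpers so malformed input fails loudly with the offending field
named.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS + "*")

HLA_ALLELE_RE = re.compile(r"^HLA-[ABC]\*\d{2}:\d{2}$")

VALID_CONSEQUENCES = frozenset(
    {"missense", "frameshift", "inframe_indel", "silent", "fusion", "other"}
)
VALID_VTYPES = frozenset({"SNV", "insertion", "deletion", "fusion"})


class ValidationError(ValueError):
    """Raised when an input record violates its documented contract."""


@dataclass
class VariantRecord:
    """One annotated somatic variant with per-read metric summaries.

    Positions are 1-based (VCF convention).  ``mq_*``, ``bq_*`` and
    ``dend_*`` are per-read vectors for mutant-supporting vs
    reference-supporting reads (``dend`` = distance to the nearer read end
    in bp); they may be empty only when the corresponding filter is
    disabled.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str
    depth_tumor: int
    depth_normal: int
    vaf_tumor: float
    vaf_normal: float
    mq_mut: list[float] = field(default_factory=list)
    mq_ref: list[float] = field(default_factory=list)
    bq_mut: list[float] = field(default_factory=list)
    bq_ref: list[float] = field(default_factory=list)
    dend_mut: list[float] = field(default_factory=list)
    dend_ref: list[float] = field(default_factory=list)
    gene: str = ""
    protein_change: str = ""
    consequence: str = "other"

    def validate(self) -> "VariantRecord":
        if self.vtype not in VALID_VTYPES:
            raise ValidationError(f"{self.variant_id}: unknown vtype {self.vtype!r}")
        if self.consequence not in VALID_CONSEQUENCES:
            raise ValidationError(
                f"{self.variant_id}: unknown consequence {self.consequence!r}"
            )
        for name in ("vaf_tumor", "vaf_normal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"{self.variant_id}: {name}={v} outside [0, 1]"
                )
        for name in ("mq_mut", "mq_ref", "bq_mut", "bq_ref", "dend_mut", "dend_ref"):
            if any(x < 0 for x in getattr(self, name)):
                raise ValidationError(f"{self.variant_id}: negative value in {name}")
        if self.pos < 1:
            raise ValidationError(f"{self.variant_id}: pos must be 1-based positive")
        return self

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))


def infer_vtype(ref: str, alt: str, consequence: str = "other") -> str:
    if consequence == "fusion":
        return "fusion"
    if len(ref) == len(alt) == 1:
        return "SNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


@dataclass(frozen=True)
class Genotype:
    """A 6-allele class-I genotype: two alleles per gene for A, B, C."""

    alleles: tuple[str, ...]

    def __post_init__(self):
        if len(self.alleles) != 6:
            raise ValidationError(f"genotype needs 6 alleles, got {len(self.alleles)}")
        for a in self.alleles:
            if not HLA_ALLELE_RE.match(a):
                raise ValidationError(f"malformed HLA allele {a!r}")
        for gene in "ABC":
            if len(self.gene_alleles(gene)) != 2:
                raise ValidationError(f"genotype needs exactly 2 HLA-{gene} alleles")

    def gene_alleles(self, gene: str) -> tuple[str, ...]:
        """Sorted allele pair for one gene (multiset semantics)."""
        return tuple(sorted(a for a in self.alleles if a.startswith(f"HLA-{gene}")))


@dataclass
class HlaCallSet:
    """Genotype calls from two callers on tumor and normal samples."""

    poly_tumor: Genotype
    poly_normal: Genotype
    bwa_tumor: Genotype
    bwa_normal: Genotype


@dataclass
class HlaGenotype:
    alleles: tuple[str, ...]
    confidence: str  # high | low
    source: str  # caller1 | caller2 | normal_agreement | caller1_normal_fallback
    gene_sources: dict[str, str] = field(default_factory=dict)


@dataclass
class LohInput:
    """Paired tumor/normal unique-read counts per polymorphic site per allele."""

    gene: str
    allele1: str
    allele2: str
    sites: list[str]
    tumor1: list[float]
    normal1: list[float]
    tumor2: list[float]
    normal2: list[float]


@dataclass
class LohResult:
    gene: str
    p_value: float
    loh: bool
    lost_allele: Optional[str] = None
    applicable: bool = True
    warning: Optional[str] = None


@dataclass
class ProteinContext:
    """Protein-space neighbourhood of a variant used for peptide enumeration."""

    variant_id: str
    wt_context: Optional[str]
    mut_context: str
    mutant_positions: frozenset[int]
    is_neoorf: bool = False

    def validate(self) -> "ProteinContext":
        if any(c not in AA_SET for c in self.mut_context):
            raise ValidationError(f"{self.variant_id}: non amino-acid context")
        if self.mutant_positions and max(self.mutant_positions) >= len(self.mut_context):
            raise ValidationError(f"{self.variant_id}: mutant position out of range")
        return self

    @property
    def empty(self) -> bool:
        return len(self.mut_context) == 0 or not self.mutant_positions


@dataclass(frozen=True)
class PeptideCandidate:
    sequence: str
    allele: str
    variant_id: str
    mutant_offsets: frozenset[int]
    wt_sequence: Optional[str] = None  # None for neoORF-derived peptides

    def __post_init__(self):
        if not 8 <= len(self.sequence) <= 11:
            raise ValidationError(f"peptide length {len(self.sequence)} outside 8-11")
        if not self.mutant_offsets:
            raise ValidationError("candidate must carry >= 1 mutant residue")
        if max(self.mutant_offsets) >= len(self.sequence) or min(self.mutant_offsets) < 0:
            raise ValidationError("mutant offset outside peptide")

    @property
    def is_neoorf(self) -> bool:
        return self.wt_sequence is None


@dataclass
class PredictorScores:
    """Uniform score container for a (peptide, allele) pair."""

    affinity_nM: float
    cleavage: float
    tap: float
    dl_identified: bool = False
    dl_rank: Optional[int] = None

    def validate(self) -> "PredictorScores":
        if self.affinity_nM <= 0:
            raise ValidationError("affinity_nM must be positive")
        if self.dl_rank is not None and self.dl_rank < 1:
            raise ValidationError("dl_rank must be a positive integer")
        return self


@dataclass
class ScoredNeoantigen:
    candidate: PeptideCandidate
    scores: PredictorScores
    vaf: float
    tpm: float
    mhc_binding_score: float = 0.0
    tap_score: float = 0.0
    cleavage_score: float = 0.0
    combine_score: float = 0.0
    expression_score: float = 0.0
    neo_class: int = 6
    type_weight: float = 0.125
    dl_weight: float = 0.125
    peptide_weight: float = 0.0
    peptide_score: float = 0.0
    rank: int = 0
    high_confidence: bool = False
    loh_lost_allele: bool = False


@dataclass
class ClonotypeCount:
    cdr3: str
    count_pre: int
    count_post: int
    total_pre: int
    total_post: int
    p: float = 1.0
    q: float = 1.0
    odds_ratio: float = 1.0
    expanded: bool = False
    degenerate: bool = False


@dataclass
class PatientBundle:
    """Everything the pipeline consumes for one patient."""

    patient_id: str
    variants: list[VariantRecord]
    expression: dict[str, float]
    rna_mut_reads: dict[str, int]
    hla_calls: HlaCallSet
    loh_inputs: list[LohInput]
    proteome: dict[str, str]
    predictor_scores: dict[tuple[str, str], PredictorScores]
    contexts: dict[str, ProteinContext] = field(default_factory=dict)
    design: dict[str, str] = field(default_factory=dict)  # generator audit trail

    def validate(self) -> "PatientBundle":
        ids = {v.variant_id for v in self.variants}
        for vid in self.rna_mut_reads:
            if vid not in ids:
                raise ValidationError(f"rna_mut_reads references unknown variant {vid}")
        for g, tpm in self.expression.items():
            if tpm < 0:
                raise ValidationError(f"negative TPM for {g}")
        for pid, seq in self.proteome.items():
            if any(c not in AA_SET for c in seq):
                raise ValidationError(f"proteome entry {pid} has non amino-acid chars")
        return self
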