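"""Mutant peptide enumeration and candidate-level filters.

Contexts are built in protein space: a window of up to 10 residues on each
side of the altered residue(s) (a 21-mer for an internal missense change),
the full novel C-terminal tail for frameshifts, and 10 residues each side of
the junction for fusions.  All 8-11-mer windows containing at least one
mutant residue are crossed with the patient's distinct HLA alleles.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

from .models import PeptideCandidate, ProteinContext, ValidationError, VariantRecord

FLANK = 10
KMER_RANGE = range(8, 12)

_HGVS_MISSENSE = re.compile(r"^p\.([A-Y\*])(\d+)([A-Y\*])$")


class ContractError(ValueError):
    pass


@dataclass
class FilterVerdict:
    expressed: bool
    non_self: bool
    affinity: bool

    @property
    def overall(self) -> bool:
        return self.expressed and self.non_self and self.affinity


def missense_context(
    variant_id: str, protein: str, aa_pos: int, alt_aa: str
) -> ProteinContext:
    """Window of up to FLANK residues each side of the substituted residue.

    ``aa_pos`` is 1-based.  A full 21-mer results when both flanks suffice.
    """
    if not 1 <= aa_pos <= len(protein):
        raise ContractError(f"{variant_id}: aa_pos {aa_pos} outside protein")
    i = aa_pos - 1
    lo = max(0, i - FLANK)
    hi = min(len(protein), i + FLANK + 1)
    wt = protein[lo:hi]
    mut = protein[lo:i] + alt_aa + protein[i + 1 : hi]
    return ProteinContext(
        variant_id=variant_id,
        wt_context=wt,
        mut_context=mut,
        mutant_positions=frozenset({i - lo}),
        is_neoorf=False,
    ).validate()


def frameshift_context(
    variant_id: str, protein: str, aa_pos: int, novel_tail: str
) -> ProteinContext:
    """Up-to-FLANK upstream wild-type residues plus the novel tail to stop.

    ``novel_tail`` may contain '*'; translation stops before it.  A stop at
    the first novel position yields an empty context (no candidates).
    """
    if not 1 <= aa_pos <= len(protein) + 1:
        raise ContractError(f"{variant_id}: aa_pos {aa_pos} outside protein")
    tail = novel_tail.split("*")[0]
    i = aa_pos - 1
    upstream = protein[max(0, i - FLANK) : i]
    return ProteinContext(
        variant_id=variant_id,
        wt_context=None,
        mut_context=upstream + tail,
        mutant_positions=frozenset(range(len(upstream), len(upstream) + len(tail))),
        is_neoorf=True,
    ).validate()


def inframe_indel_context(
    variant_id: str, protein: str, aa_pos: int, removed: int, inserted: str
) -> ProteinContext:
    """FLANK residues each side of the altered segment.

    For a pure deletion the single residue following the join is treated as
    the altered position so downstream windows must cross the join.
    """
    i = aa_pos - 1
    lo = max(0, i - FLANK)
    hi = min(len(protein), i + removed + FLANK)
    left = protein[lo:i]
    right = protein[i + removed : hi]
    mut = left + inserted + right
    if inserted:
        positions = frozenset(range(len(left), len(left) + len(inserted)))
    else:
        if not right:
            raise ContractError(f"{variant_id}: deletion at protein end has no join residue")
        positions = frozenset({len(left)})
    wt = protein[lo:hi]
    return ProteinContext(
        variant_id=variant_id,
        wt_context=wt if len(wt) == len(mut) else None,
        mut_context=mut,
        mutant_positions=positions,
        is_neoorf=False,
    ).validate()


def fusion_context(variant_id: str, left: str, right: str) -> ProteinContext:
    """FLANK residues each side of the fusion junction (neoORF-like)."""
    lseq = left[-FLANK:]
    rseq = right.split("*")[0][:FLANK]
    if not lseq or not rseq:
        return ProteinContext(variant_id, None, "", frozenset(), is_neoorf=True)
    return ProteinContext(
        variant_id=variant_id,
        wt_context=None,
        mut_context=lseq + rseq,
        mutant_positions=frozenset({len(lseq)}),  # first residue past the junction
        is_neoorf=True,
    ).validate()


def build_context(
    v: VariantRecord,
    transcript_protein: str,
    aa_pos: int,
    *,
    alt_aa: str | None = None,
    novel_tail: str | None = None,
) -> ProteinContext:
    """Dispatch on consequence; missense parses ``protein_change`` when
    ``alt_aa`` is not given (HGVS p. single-substitution dialect)."""
    if v.consequence == "silent":
        raise ContractError(f"{v.variant_id}: silent variants yield no neoantigens")
    if v.consequence == "missense":
        if alt_aa is None:
            m = _HGVS_MISSENSE.match(v.protein_change)
            if not m:
                raise ValidationError(
                    f"{v.variant_id}: cannot parse protein_change {v.protein_change!r}"
                )
            ref_aa, pos_s, alt_aa = m.groups()
            aa_pos = int(pos_s)
            if transcript_protein[aa_pos - 1] != ref_aa:
                raise ValidationError(
                    f"{v.variant_id}: protein_change ref {ref_aa} does not match protein"
                )
        return missense_context(v.variant_id, transcript_protein, aa_pos, alt_aa)
    if v.consequence == "frameshift":
        if novel_tail is None:
            raise ContractError(f"{v.variant_id}: frameshift context needs novel_tail")
        return frameshift_context(v.variant_id, transcript_protein, aa_pos, novel_tail)
    if v.consequence == "inframe_indel":
        removed = max(0, len(v.ref) - len(v.alt)) // 3
        inserted = novel_tail or ""
        return inframe_indel_context(v.variant_id, transcript_protein, aa_pos, removed, inserted)
    if v.consequence == "fusion":
        if novel_tail is None:
            raise ContractError(f"{v.variant_id}: fusion context needs partner sequence")
        return fusion_context(v.variant_id, transcript_protein, novel_tail)
    raise ContractError(f"{v.variant_id}: no context for consequence {v.consequence!r}")


def enumerate_candidates(
    ctx: ProteinContext, alleles: list[str] | tuple[str, ...]
) -> list[PeptideCandidate]:
    """All 8-11-mer windows containing >= 1 mutant position, per distinct allele."""
    if ctx.empty:
        return []
    seq = ctx.mut_context
    distinct_alleles = sorted(set(alleles))
    seen: set[tuple[str, str]] = set()
    out: list[PeptideCandidate] = []
    for k in KMER_RANGE:
        for start in range(0, len(seq) - k + 1):
            window_positions = set(range(start, start + k))
            hits = ctx.mutant_positions & window_positions
            if not hits:
                continue
            pep = seq[start : start + k]
            wt = None
            if not ctx.is_neoorf and ctx.wt_context is not None:
                wt = ctx.wt_context[start : start + k]
            for allele in distinct_alleles:
                key = (pep, allele)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    PeptideCandidate(
                        sequence=pep,
                        allele=allele,
                        variant_id=ctx.variant_id,
                        mutant_offsets=frozenset(h - start for h in hits),
                        wt_sequence=wt,
                    )
                )
    return out


def window_count(L: int, m: int, k: int) -> int:
    """Closed-form number of k-windows of a length-L string containing index m."""
    return max(0, min(m, L - k) - max(0, m - k + 1) + 1)


def is_self_peptide(sequence: str, proteome: dict[str, str]) -> bool:
    """Exact-substring self-homology check against the reference proteome."""
    return any(sequence in entry for entry in proteome.values())


def candidate_filters(
    c: PeptideCandidate,
    rna_mut_reads: int,
    proteome: dict[str, str],
    affinity_nM: float,
    *,
    min_rna_mut_reads: int = 1,
    affinity_cutoff_nM: float = 500.0,
) -> FilterVerdict:
    """The three candidate filters: expression, self-homology, binding affinity.

    A candidate at exactly the affinity cutoff is retained (only strictly
    weaker binders are removed).
    """
    if affinity_nM is None:
        raise ValueError(f"{c.variant_id}/{c.sequence}: affinity not predicted")
    return FilterVerdict(
        expressed=rna_mut_reads >= min_rna_mut_reads,
        non_self=not is_self_peptide(c.sequence, proteome),
        affinity=affinity_nM <= affinity_cutoff_nM,
    )


def detect_anchor_change(c: PeptideCandidate) -> bool:
    """True when a mutant residue sits at an MHC anchor position (P2 or the
    C-terminus).  Only meaningful for substitution-derived peptides."""
    if c.is_neoorf:
        raise ContractError("anchor classification applies to substitution peptides")
    return 1 in c.mutant_offsets or (len(c.sequence) - 1) in c.mutant_offsets
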