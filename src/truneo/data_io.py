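"""Readers and writers for the pipeline's flat-file interfaces.

Variants travel either as VCF 4.x (INFO keys DP_T, DP_N, VAF_T, VAF_N plus
comma-delimited per-read vectors MQ_MUT, MQ_REF, BQ_MUT, BQ_REF, DEND_MUT,
DEND_REF and an ANN field ``gene|protein_change|consequence``) or as a flat
TSV with the same column names.  Everything else is simple TSV/FASTA.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

from .models import (
    ClonotypeCount,
    Genotype,
    HlaCallSet,
    LohInput,
    PeptideCandidate,
    PredictorScores,
    ScoredNeoantigen,
    ValidationError,
    VariantRecord,
    infer_vtype,
)

VARIANT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "vtype",
    "depth_tumor",
    "depth_normal",
    "vaf_tumor",
    "vaf_normal",
    "mq_mut",
    "mq_ref",
    "bq_mut",
    "bq_ref",
    "dend_mut",
    "dend_ref",
    "gene",
    "protein_change",
    "consequence",
]

_VECTOR_FIELDS = ("mq_mut", "mq_ref", "bq_mut", "bq_ref", "dend_mut", "dend_ref")


class ParseError(ValueError):
    pass


def _parse_vector(text: str) -> list[float]:
    text = text.strip()
    if text in ("", ".", "NA"):
        return []
    return [float(x) for x in text.split(",")]


def _fmt_vector(vec: Iterable[float]) -> str:
    items = [f"{x:g}" for x in vec]
    return ",".join(items) if items else "."


def read_variants(path: str | Path, dialect: str = "tsv") -> list[VariantRecord]:
    """Read a variant table; one record per row (TSV) or per ALT (VCF)."""
    if dialect == "tsv":
        return _read_variants_tsv(path)
    if dialect == "vcf":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(VARIANT_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = VariantRecord(
                    variant_id=row["variant_id"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    vtype=row["vtype"]
                    or infer_vtype(row["ref"], row["alt"], row["consequence"]),
                    depth_tumor=int(row["depth_tumor"]),
                    depth_normal=int(row["depth_normal"]),
                    vaf_tumor=float(row["vaf_tumor"]),
                    vaf_normal=float(row["vaf_normal"]),
                    gene=row["gene"],
                    protein_change=row["protein_change"],
                    consequence=row["consequence"],
                    **{f: _parse_vector(row[f]) for f in _VECTOR_FIELDS},
                ).validate()
            except (KeyError, ValueError) as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise ParseError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def _read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info

        # one VariantRecord per ALT
            for i, alt in enumerate(rec.alts or ()):
                ann = info.get("ANN")
                gene, pchange, csq = "", "", "other"
                if ann:
                    ann_str = ann[i] if isinstance(ann, tuple) and i < len(ann) else (
                        ann[0] if isinstance(ann, tuple) else ann
                    )
                    parts = str(ann_str).split("|")
                    gene = parts[0] if len(parts) > 0 else ""
                    pchange = parts[1] if len(parts) > 1 else ""
                    csq = parts[2] if len(parts) > 2 else "other"

                def _vec(key):
                    try:
                        val = info.get(key)
                    except (KeyError, ValueError):  # key not declared in header
                        return []
                    if val is None:
                        return []
                    if isinstance(val, (tuple, list)):
                        return [float(x) for x in val]
                    return _parse_vector(str(val))

                vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
                records.append(
                    VariantRecord(
                        variant_id=vid,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        vtype=infer_vtype(rec.ref, alt, csq),
                        depth_tumor=int(info.get("DP_T", 0)),
                        depth_normal=int(info.get("DP_N", 0)),
                        vaf_tumor=float(_scalar(info.get("VAF_T", 0.0))),
                        vaf_normal=float(_scalar(info.get("VAF_N", 0.0))),
                        mq_mut=_vec("MQ_MUT"),
                        mq_ref=_vec("MQ_REF"),
                        bq_mut=_vec("BQ_MUT"),
                        bq_ref=_vec("BQ_REF"),
                        dend_mut=_vec("DEND_MUT"),
                        dend_ref=_vec("DEND_REF"),
                        gene=gene,
                        protein_change=pchange,
                        consequence=csq,
                    ).validate()
                )
    return records


def _scalar(val):
    if isinstance(val, (tuple, list)):
        return val[0]
    return val


def write_variants(records: list[VariantRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.variant_id,
                    r.chrom,
                    r.pos,
                    r.ref,
                    r.alt,
                    r.vtype,
                    r.depth_tumor,
                    r.depth_normal,
                    repr(r.vaf_tumor),
                    repr(r.vaf_normal),
                    _fmt_vector(r.mq_mut),
                    _fmt_vector(r.mq_ref),
                    _fmt_vector(r.bq_mut),
                    _fmt_vector(r.bq_ref),
                    _fmt_vector(r.dend_mut),
                    _fmt_vector(r.dend_ref),
                    r.gene,
                    r.protein_change,
                    r.consequence,
                ]
            )


def read_expression(path: str | Path) -> dict[str, float]:
    """Two-column TSV (gene_id, TPM) with header; duplicates are errors."""
    out: dict[str, float] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ParseError(f"{path}: empty file, expected a header")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}: malformed row at line {lineno}")
            gene, tpm_s = row[0], row[1]
            if gene in out:
                raise ValidationError(f"{path}: duplicate gene_id {gene!r} at line {lineno}")
            try:
                tpm = float(tpm_s)
            except ValueError as exc:
                raise ParseError(f"{path}: bad TPM at line {lineno}: {tpm_s!r}") from exc
            if tpm < 0:
                raise ValidationError(f"{path}: negative TPM for {gene!r} at line {lineno}")
            out[gene] = tpm
    return out


def read_rna_mut_reads(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader, None)  # header
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            vid, n = row[0], int(row[1])
            if n < 0:
                raise ValidationError(f"{path}: negative read count at line {lineno}")
            out[vid] = n
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning {id: sequence} (id = first token)."""
    seqs: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                if current in seqs:
                    raise ValidationError(f"{path}: duplicate FASTA id {current!r}")
                seqs[current] = []
            else:
                if current is None:
                    raise ParseError(f"{path}: sequence before header")
                seqs[current].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_hla_calls(path: str | Path) -> HlaCallSet:
    """4-column TSV: caller (poly|bwa), sample (tumor|normal), gene, allele."""
    groups: dict[tuple[str, str], list[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader, None)
        for row in reader:
            if not row:
                continue
            caller, sample, _gene, allele = row[:4]
            groups.setdefault((caller, sample), []).append(allele)
    try:
        return HlaCallSet(
            poly_tumor=Genotype(tuple(sorted(groups[("poly", "tumor")]))),
            poly_normal=Genotype(tuple(sorted(groups[("poly", "normal")]))),
            bwa_tumor=Genotype(tuple(sorted(groups[("bwa", "tumor")]))),
            bwa_normal=Genotype(tuple(sorted(groups[("bwa", "normal")]))),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing caller/sample group {exc}") from exc


def read_loh_inputs(path: str | Path) -> list[LohInput]:
    """TSV: gene, allele, site_id, tumor_unique, normal_unique."""
    per_gene: dict[str, dict[str, dict[str, tuple[float, float]]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader, None)
        for row in reader:
            if not row:
                continue
            gene, allele, site, t, n = row[:5]
            per_gene.setdefault(gene, {}).setdefault(allele, {})[site] = (
                float(t),
                float(n),
            )
    out = []
    for gene, alleles in per_gene.items():
        names = sorted(alleles)
        if len(names) != 2:
            raise ValidationError(f"LOH input for gene {gene}: need exactly 2 alleles")
        a1, a2 = names
        sites = sorted(set(alleles[a1]) & set(alleles[a2]))
        out.append(
            LohInput(
                gene=gene,
                allele1=a1,
                allele2=a2,
                sites=sites,
                tumor1=[alleles[a1][s][0] for s in sites],
                normal1=[alleles[a1][s][1] for s in sites],
                tumor2=[alleles[a2][s][0] for s in sites],
                normal2=[alleles[a2][s][1] for s in sites],
            )
        )
    return out


def read_fixture_scores(path: str | Path) -> dict[tuple[str, str], PredictorScores]:
    """TSV: peptide, allele, affinity_nM, cleavage, tap, dl_identified, dl_rank."""
    out: dict[tuple[str, str], PredictorScores] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            ident = row["dl_identified"].strip().lower() in ("1", "true", "yes")
            rank_s = row.get("dl_rank", "").strip()
            rank = int(rank_s) if rank_s not in ("", ".", "NA") else None
            out[(row["peptide"], row["allele"])] = PredictorScores(
                affinity_nM=float(row["affinity_nM"]),
                cleavage=float(row["cleavage"]),
                tap=float(row["tap"]),
                dl_identified=ident,
                dl_rank=rank if ident else None,
            ).validate()
    return out


def write_fixture_scores(
    scores: dict[tuple[str, str], PredictorScores], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["peptide", "allele", "affinity_nM", "cleavage", "tap", "dl_identified", "dl_rank"])
        for (pep, allele), s in scores.items():
            w.writerow(
                [pep, allele, repr(s.affinity_nM), repr(s.cleavage), repr(s.tap),
                 int(s.dl_identified), s.dl_rank if s.dl_rank is not None else "."]
            )


def write_candidates(cands: list[PeptideCandidate], tsv_path: str | Path) -> None:
    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["variant_id", "allele", "sequence", "mutant_offsets", "wt_sequence"])
        for c in cands:
            w.writerow(
                [
                    c.variant_id,
                    c.allele,
                    c.sequence,
                    ",".join(str(i) for i in sorted(c.mutant_offsets)),
                    c.wt_sequence or ".",
                ]
            )


def write_scored(scored: list[ScoredNeoantigen], path: str | Path) -> None:
    cols = [
        "rank", "variant_id", "peptide", "allele", "affinity_nM", "cleavage", "tap",
        "mhc_binding_score", "cleavage_score", "tap_score", "combine_score",
        "expression_score", "vaf", "tpm", "neo_class", "type_weight", "dl_weight",
        "peptide_weight", "peptide_score", "high_confidence", "loh_lost_allele",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for s in scored:
            w.writerow(
                [
                    s.rank, s.candidate.variant_id, s.candidate.sequence,
                    s.candidate.allele, repr(s.scores.affinity_nM),
                    repr(s.scores.cleavage), repr(s.scores.tap),
                    f"{s.mhc_binding_score:.10g}", f"{s.cleavage_score:.10g}",
                    f"{s.tap_score:.10g}", f"{s.combine_score:.10g}",
                    f"{s.expression_score:.10g}", repr(s.vaf), repr(s.tpm),
                    s.neo_class, s.type_weight, s.dl_weight, s.peptide_weight,
                    f"{s.peptide_score:.10g}", int(s.high_confidence),
                    int(s.loh_lost_allele),
                ]
            )


def read_clonotypes(path: str | Path) -> dict[str, list[ClonotypeCount]]:
    """TSV: culture, cdr3, count, total → per-culture clone count lists.

    Pre/post pairing is done by the caller (control culture vs stimulated).
    """
    out: dict[str, list] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.setdefault(row["culture"], []).append(
                (row["cdr3"], int(row["count"]), int(row["total"]))
            )
    return out
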