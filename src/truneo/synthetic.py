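"""Synthetic patient-bundle generator.

Builds a complete desk-scale patient (variants with per-read metric vectors,
expression, RNA mutant reads, HLA calls, LOH coverage, proteome, predictor
fixture scores) in which a chosen set of "planted" variants is constructed
to pass every stage of the pipeline, while each remaining decoy is
constructed to fail exactly one designated stage.  The generator is a pure
function of its arguments, so bundles double as regression fixtures.

Decoy failure modes cycle through ``DECOY_MODES``; ``bundle.design`` records
the mode of every variant for auditing expected per-stage counts.
"""
from __future__ import annotations

import numpy as np

from .models import (
    AMINO_ACIDS,
    Genotype,
    HlaCallSet,
    LohInput,
    PatientBundle,
    PredictorScores,
    VariantRecord,
)
from .peptides import frameshift_context, missense_context

ALLELES = (
    "HLA-A*02:01",
    "HLA-A*11:01",
    "HLA-B*07:02",
    "HLA-B*40:01",
    "HLA-C*07:02",
    "HLA-C*08:01",
)
LOST_ALLELE = "HLA-C*08:01"  # gene C carries an LOH event in every bundle
SAFE_ALLELES = tuple(a for a in ALLELES if a != LOST_ALLELE)

DECOY_MODES = (
    "fail_depth",        # rule1: depth_tumor < 10
    "fail_vaf_tumor",    # rule1: vaf_tumor < 0.05
    "fail_indel_vaf",    # indel filter: vaf_tumor <= 0.10
    "fail_adjacent",     # rule2: two SNVs 5 bp apart (emitted as a pair)
    "fail_mq",           # rule3: low mutant mapping quality
    "fail_bq",           # rule4: low mutant base quality
    "fail_read_end",     # rule5: mutant reads hug read ends
    "fail_rna",          # expressed filter: 0 RNA mutant reads (frameshift)
    "fail_homology",     # self-homology: mutant peptide planted in proteome
    "fail_affinity",     # candidate filter: affinity > 500 nM
    "hc_fail_affinity",  # survives to ranking; affinity in (100, 500]
    "hc_fail_tpm",       # survives to ranking; TPM < 15
    "hc_fail_vaf",       # survives to ranking; VAF in (0.05, 0.1)
    "hc_fail_loh",       # survives to ranking; presented on the lost allele
)

# modes that survive the variant-level filters
PASS_VARIANT_FILTER = frozenset(
    {"planted", "fail_rna", "fail_homology", "fail_affinity",
     "hc_fail_affinity", "hc_fail_tpm", "hc_fail_vaf", "hc_fail_loh"}
)
# modes that survive all candidate filters and get scored/ranked
PASS_CANDIDATE_FILTER = frozenset(
    {"planted", "hc_fail_affinity", "hc_fail_tpm", "hc_fail_vaf", "hc_fail_loh"}
)

_PROT_LEN = 41
_AA_POS = 21  # mutation centred in the transcript protein


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _read_vectors(rng: np.random.Generator, low: float, high: float, n: int = 15):
    """Identical mutant/reference vectors: rank-sum p is ~0.5 by symmetry."""
    vals = [round(float(x), 1) for x in rng.uniform(low, high, size=n)]
    return list(vals), list(vals)


def generate_synthetic_bundle(
    n_variants: int, n_immunogenic: int, seed: int
) -> tuple[PatientBundle, set[str]]:
    """Return (bundle, planted variant_ids).

    Planted variants satisfy every filter plus the high-confidence criteria
    (affinity < 100 nM, TPM > 15, VAF > 0.1, allele without LOH) with fully
    separated predictor scores; every decoy violates exactly one designated
    stage.  Deterministic given (n_variants, n_immunogenic, seed).
    """
    if not 0 <= n_immunogenic <= n_variants:
        raise ValueError("need 0 <= n_immunogenic <= n_variants")
    rng = np.random.default_rng(seed)

    variants: list[VariantRecord] = []
    expression: dict[str, float] = {}
    rna_mut_reads: dict[str, int] = {}
    proteome: dict[str, str] = {}
    fixture: dict[tuple[str, str], PredictorScores] = {}
    contexts = {}
    design: dict[str, str] = {}
    self_bait: list[str] = []  # mutant peptides to embed for homology decoys

    # background expression so quartiles are well defined
    for i in range(50):
        expression[f"BG{i:03d}"] = round(float(rng.uniform(0.5, 10.0)), 3)
    for i in range(5):
        proteome[f"REF{i:02d}"] = _random_protein(rng, 200)

    modes: list[str] = ["planted"] * n_immunogenic
    i = 0
    while len(modes) < n_variants:
        mode = DECOY_MODES[i % len(DECOY_MODES)]
        i += 1
        if mode == "fail_adjacent":
            if n_variants - len(modes) >= 2:
                modes.extend(["fail_adjacent", "fail_adjacent_pair"])
            continue
        modes.append(mode)

    pos_cursor = 0
    for idx, mode in enumerate(modes):
        vid = f"V{idx:04d}"
        gene = f"G{idx:04d}"
        design[vid] = mode
        if mode == "fail_adjacent_pair":
            pos = 1000 * pos_cursor + 5  # 5 bp after its partner
        else:
            pos_cursor += 1
            pos = 1000 * pos_cursor

        depth_t, depth_n = 50, 60
        vaf_t = round(float(rng.uniform(0.15, 0.4)), 3)
        vaf_n = 0.0
        vtype, ref, alt, consequence = "SNV", "A", "T", "missense"
        mq_mut, mq_ref = _read_vectors(rng, 50, 60)
        bq_mut, bq_ref = _read_vectors(rng, 28, 40)
        de_mut, de_ref = _read_vectors(rng, 10, 40)
        tpm = round(float(rng.uniform(16.0, 25.0)), 3)
        rna = int(rng.integers(5, 50))

        if mode == "fail_depth":
            depth_t = 9
        elif mode == "fail_vaf_tumor":
            vaf_t = 0.03
        elif mode == "fail_indel_vaf":
            vtype, ref, alt, consequence = "deletion", "ATG", "A", "inframe_indel"
            vaf_t = 0.08
        elif mode == "fail_mq":
            mq_mut = [round(float(x), 1) for x in rng.uniform(5, 25, size=15)]
        elif mode == "fail_bq":
            bq_mut = [round(float(x), 1) for x in rng.uniform(2, 15, size=15)]
        elif mode == "fail_read_end":
            de_mut = [round(float(x), 1) for x in rng.uniform(1, 3, size=15)]
            de_ref = [round(float(x), 1) for x in rng.uniform(20, 40, size=15)]
        elif mode == "fail_rna":
            vtype, ref, alt, consequence = "insertion", "A", "AT", "frameshift"
            rna = 0
        elif mode == "hc_fail_tpm":
            tpm = round(float(rng.uniform(1.0, 10.0)), 3)
        elif mode == "hc_fail_vaf":
            vaf_t = round(float(rng.uniform(0.06, 0.09)), 3)
        elif mode == "planted":
            tpm = round(float(rng.uniform(60.0, 200.0)), 3)

        # transcript protein with the variant centred at position 21
        protein = _random_protein(rng, _PROT_LEN)
        wt_aa = protein[_AA_POS - 1]
        alt_aa = rng.choice([a for a in AMINO_ACIDS if a != wt_aa])
        protein_change = f"p.{wt_aa}{_AA_POS}{alt_aa}"
        proteome[gene] = protein

        if consequence == "frameshift":
            tail = _random_protein(rng, 12) + "*"
            contexts[vid] = frameshift_context(vid, protein, _AA_POS, tail)
            protein_change = f"p.{wt_aa}{_AA_POS}fs"
        elif consequence == "inframe_indel":
            protein_change = f"p.{wt_aa}{_AA_POS}del"

        variants.append(
            VariantRecord(
                variant_id=vid,
                chrom="chr1",
                pos=pos,
                ref=ref,
                alt=alt,
                vtype=vtype,
                depth_tumor=depth_t,
                depth_normal=depth_n,
                vaf_tumor=vaf_t,
                vaf_normal=vaf_n,
                mq_mut=mq_mut,
                mq_ref=mq_ref,
                bq_mut=bq_mut,
                bq_ref=bq_ref,
                dend_mut=de_mut,
                dend_ref=de_ref,
                gene=gene,
                protein_change=protein_change,
                consequence=consequence,
            ).validate()
        )
        expression[gene] = tpm
        rna_mut_reads[vid] = rna

        # designated peptide: the 9-mer with the mutant residue at P5
        if consequence == "missense":
            ctx = missense_context(vid, protein, _AA_POS, str(alt_aa))
            designated = ctx.mut_context[6:15]
            allele = (
                LOST_ALLELE if mode == "hc_fail_loh" else SAFE_ALLELES[idx % len(SAFE_ALLELES)]
            )
            if mode == "fail_homology":
                self_bait.append(designated)
            if mode in PASS_VARIANT_FILTER:
                affinity = float(rng.uniform(20.0, 80.0))
                if mode == "fail_affinity":
                    affinity = float(rng.uniform(1000.0, 5000.0))
                elif mode == "hc_fail_affinity":
                    affinity = float(rng.uniform(150.0, 400.0))
                fixture[(designated, allele)] = PredictorScores(
                    affinity_nM=round(affinity, 2),
                    cleavage=round(float(rng.uniform(0.5, 1.0)), 3),
                    tap=round(float(rng.uniform(0.5, 2.0)), 3),
                    dl_identified=(mode == "planted"),
                    dl_rank=(idx % 20) + 1 if mode == "planted" else None,
                )

    if self_bait:
        proteome["SELF00"] = "".join(self_bait)

    genotype = Genotype(tuple(sorted(ALLELES)))
    hla_calls = HlaCallSet(genotype, genotype, genotype, genotype)

    loh_inputs = []
    for gene_letter, (a1, a2) in (
        ("A", ("HLA-A*02:01", "HLA-A*11:01")),
        ("B", ("HLA-B*07:02", "HLA-B*40:01")),
        ("C", ("HLA-C*07:02", "HLA-C*08:01")),
    ):
        n_sites = 30
        normal1 = [int(x) for x in rng.integers(80, 120, size=n_sites)]
        normal2 = [int(x) for x in rng.integers(80, 120, size=n_sites)]
        tumor1 = list(normal1)
        if gene_letter == "C":
            jitter = rng.normal(0.0, 0.05, size=n_sites)
            tumor2 = [
                max(1, int(round(n * 0.5 * 2**j))) for n, j in zip(normal2, jitter)
            ]
        else:
            tumor2 = list(normal2)
        loh_inputs.append(
            LohInput(
                gene=gene_letter,
                allele1=a1,
                allele2=a2,
                sites=[f"s{i}" for i in range(n_sites)],
                tumor1=[float(x) for x in tumor1],
                normal1=[float(x) for x in normal1],
                tumor2=[float(x) for x in tumor2],
                normal2=[float(x) for x in normal2],
            )
        )

    bundle = PatientBundle(
        patient_id=f"SYN{seed}",
        variants=variants,
        expression=expression,
        rna_mut_reads=rna_mut_reads,
        hla_calls=hla_calls,
        loh_inputs=loh_inputs,
        proteome=proteome,
        predictor_scores=fixture,
        contexts=contexts,
        design=design,
    ).validate()
    return bundle, {vid for vid, m in design.items() if m == "planted"}
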