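# truneo

Neoantigen identification and ranking from annotated somatic variants.
Given a patient's annotated somatic variant table (with per-read metric
summaries), class-I HLA genotype calls from two callers × two samples,
gene-level expression (TPM), RNA mutant-read counts, a reference proteome
and per-(peptide, allele) predictor scores, `truneo`:

1. filters SNVs/InDels to a high-confidence somatic set (depth/VAF
   thresholds, adjacency, mapping/base-quality and read-end rank-sum tests);
2. resolves a consensus HLA genotype and tests each gene for loss of
   heterozygosity (paired t-test of per-site log2 tumor/normal coverage
   ratios, α = 2×10⁻⁴);
3. enumerates all 8–11-mer mutant peptides from 21-mer protein contexts
   (missense, frameshift neoORFs, in-frame indels, fusion junctions) and
   filters them by RNA expression, self-homology and binding affinity
   (≤ 500 nM);
4. computes a composite score per candidate —
   `PeptideScore = CombineScore · ExpressionScore · VAF · TypeWeight · DLWeight`
   with tanh-transformed binding/cleavage/TAP components, quartile-banded
   expression, a 6-class epitope taxonomy and a presentation-model weight —
   then ranks candidates and flags the high-confidence subset
   (VAF > 0.1, affinity < 100 nM, TPM > 15, presenting allele without LOH);
5. evaluates rankings (recall@k, random baseline, Elispot true-positive
   rate, TPM-threshold sweeps) and calls antigen-specific TCR clonotype
   expansion (one-sided Fisher + Benjamini–Hochberg FDR, odds ratio > 1,
   single-culture specificity).

External predictors (binding affinity, cleavage, TAP, presentation) are
consumed through a uniform adapter contract; a deterministic mock backend
and a desk-scale surrogate presentation network (one-hot peptide + 74-dim
allele embedding, 256→74 dense relu layers, sigmoid output) are included so
everything runs offline. A synthetic patient-bundle generator plants
known-immunogenic variants and per-stage decoys, making the full pipeline
testable end to end without any downloads.

## CLI

```sh
truneo simulate --n-variants 50 --n-immunogenic 5 --seed 1 --out bundle/
truneo filter-variants --in bundle/variants.tsv --out filtered.tsv --report report.tsv
truneo hla-consensus --in bundle/hla_calls.tsv --out consensus.json
truneo hla-loh --in bundle/loh.tsv --alpha 0.0002 --out loh.tsv
truneo enumerate --contexts contexts.tsv --alleles HLA-A*02:01,HLA-B*07:02 --out cands.tsv
truneo score --candidates cands.tsv --expression expr.tsv --vaf vaf.tsv --out scored.tsv
truneo rank --n-variants 200 --n-immunogenic 20 --seed 1 --out ranked.tsv
truneo evaluate --metric recall@10 --method TruNeo
truneo tcr-expansion --in clones.tsv --alpha 0.05 --out expanded.tsv
```

All thresholds live in `RunConfig` (YAML/JSON via `--config`); an empty
config reproduces the published defaults.

## Layout

| module | contents |
| --- | --- |
| `truneo.models` | domain dataclasses and validation |
| `truneo.config` | `RunConfig` thresholds + YAML/JSON loading |
| `truneo.data_io` | TSV/VCF/FASTA readers and writers |
| `truneo.synthetic` | planted-truth patient-bundle generator |
| `truneo.variant_filtering` | SNV/InDel filters, exact/approx rank-sum test |
| `truneo.hla` | consensus genotyping, LOH paired t-test |
| `truneo.peptides` | protein contexts, 8–11-mer enumeration, candidate filters |
| `truneo.predictors` | adapter contract, mock backend, surrogate network |
| `truneo.scoring` | score components, 6-class taxonomy, ranking, high-confidence |
| `truneo.evaluation` | recall@k, positive rate, Fisher/BH, clonotype expansion |
| `truneo.pipeline` | end-to-end orchestration over a `PatientBundle` |
| `truneo.cli` | `truneo` command group |
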