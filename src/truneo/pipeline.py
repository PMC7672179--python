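"""End-to-end orchestration over a PatientBundle.

Stages: variant filters -> HLA consensus + LOH -> protein contexts ->
peptide enumeration -> predictor scores -> candidate filters -> composite
scoring -> ranking -> high-confidence flag.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import RunConfig
from .hla import consensus_genotype, loh_lost_alleles
from .models import (
    HlaGenotype,
    PatientBundle,
    ScoredNeoantigen,
    ValidationError,
)
from .peptides import ContractError, build_context, enumerate_candidates, is_self_peptide
from .predictors import PoorBinderFallback
from .scoring import expression_quartiles, rank_candidates, score_candidate
from .variant_filtering import FilterReport, filter_variants

logger = logging.getLogger("truneo.pipeline")


@dataclass
class PipelineResult:
    ranked: list[ScoredNeoantigen]
    reports: dict[str, FilterReport]
    genotype: HlaGenotype
    lost_alleles: set[str]
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def high_confidence_ids(self) -> set[str]:
        return {s.candidate.variant_id for s in self.ranked if s.high_confidence}

    def top(self, k: int) -> list[ScoredNeoantigen]:
        return self.ranked[:k]


def run_pipeline(
    bundle: PatientBundle,
    cfg: RunConfig | None = None,
    collapse: str | None = "variant",
    predictor=None,
) -> PipelineResult:
    """Run the full pipeline on one patient bundle.

    ``predictor`` is any backend with ``predict(peptide, allele) ->
    PredictorScores``; by default the bundle's fixture table backed by a
    weak-binder fallback, so results depend only on the scores, never on the
    backend that produced them.
    """
    cfg = cfg or RunConfig()
    predictor = predictor or PoorBinderFallback(cfg.seed, fixture=bundle.predictor_scores)

    reports = filter_variants(bundle.variants, cfg)
    passing = [v for v in bundle.variants if reports[v.variant_id].overall]

    genotype = consensus_genotype(bundle.hla_calls)
    lost = loh_lost_alleles(bundle.loh_inputs, cfg.loh_alpha, cfg.loh_pseudocount)
    lower_q, upper_q = expression_quartiles(
        bundle.expression, cfg.expression_quartile_population
    )

    scored: list[ScoredNeoantigen] = []
    n_candidates = 0
    n_filtered = 0
    for v in passing:
        if v.consequence in ("silent", "other"):
            continue
        ctx = bundle.contexts.get(v.variant_id)
        if ctx is None:
            protein = bundle.proteome.get(v.gene)
            if protein is None:
                logger.debug("variant=%s no context/protein available", v.variant_id)
                continue
            try:
                ctx = build_context(v, protein, 0)
            except (ContractError, ValidationError) as exc:
                logger.debug("variant=%s context failed: %s", v.variant_id, exc)
                continue
        candidates = enumerate_candidates(ctx, genotype.alleles)
        n_candidates += len(candidates)
        rna = bundle.rna_mut_reads.get(v.variant_id, 0)
        tpm = bundle.expression.get(v.gene, 0.0)
        for c in candidates:
            s = predictor.predict(c.sequence, c.allele)
            # candidate filters, cheapest first; verdict identical to
            # candidate_filters() since overall is a conjunction
            if s.affinity_nM > cfg.affinity_filter_nM:
                continue
            if rna < cfg.min_rna_mut_reads:
                logger.debug("variant=%s rule=expressed verdict=fail", v.variant_id)
                continue
            if is_self_peptide(c.sequence, bundle.proteome):
                logger.debug("variant=%s rule=homology verdict=fail", v.variant_id)
                continue
            n_filtered += 1
            scored.append(
                score_candidate(c, s, v.vaf_tumor, tpm, lower_q, upper_q, lost, cfg)
            )

    ranked = rank_candidates(scored, collapse=collapse)
    return PipelineResult(
        ranked=ranked,
        reports=reports,
        genotype=genotype,
        lost_alleles=lost,
        stage_counts={
            "input_variants": len(bundle.variants),
            "pass_variant_filter": len(passing),
            "candidates_enumerated": n_candidates,
            "candidates_filtered": n_filtered,
            "ranked": len(ranked),
            "high_confidence": sum(1 for s in ranked if s.high_confidence),
        },
    )
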