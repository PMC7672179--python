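"""Composite neoantigen scoring, classing, ranking and the final filter.

PeptideScore = CombineScore * ExpressionScore * VAF * PeptideWeight, with
CombineScore = 0.8 MHCBindingScore + 0.15 ProteasomalCleavageScore
             + 0.05 TAPTransportScore
MHCBindingScore        = tanh((500 - affinity_nM) / 200)
TAPTransportScore      = tanh(2.5 * tap) / 2 + 0.5
ProteasomalCleavageScore = tanh(3 * cleavage)
ExpressionScore in {0, 0.33, 0.66, 1} by TPM quartile band, and
PeptideWeight = NeoantigenTypeWeight (6-class taxonomy) * DeepLearningWeight.
"""
from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .config import RunConfig
from .models import PeptideCandidate, PredictorScores, ScoredNeoantigen
from .peptides import detect_anchor_change


class ContractError(ValueError):
    pass


def mhc_binding_score(affinity_nM: float) -> float:
    if affinity_nM <= 0:
        raise ValueError("affinity must be positive nM")
    return math.tanh((500.0 - affinity_nM) / 200.0)


def tap_transport_score(tap: float) -> float:
    if not math.isfinite(tap):
        raise ValueError("TAP prediction must be finite")
    return math.tanh(tap * 2.5) / 2.0 + 0.5


def cleavage_score(c: float) -> float:
    if not math.isfinite(c):
        raise ValueError("cleavage prediction must be finite")
    return math.tanh(c * 3.0)


def combine_score(
    mhc_s: float, cleav_s: float, tap_s: float, cfg: RunConfig | None = None
) -> float:
    cfg = cfg or RunConfig()
    return cfg.combine_w_mhc * mhc_s + cfg.combine_w_cleavage * cleav_s + cfg.combine_w_tap * tap_s


def expression_quartiles(
    expression: dict[str, float], population: str = "positive"
) -> tuple[float, float]:
    """(lower, upper) TPM quartiles over the expressed-gene population."""
    values = [v for v in expression.values() if (v > 0 if population == "positive" else True)]
    if not values:
        return 0.0, 0.0
    lower = float(np.percentile(values, 25))
    upper = float(np.percentile(values, 75))
    return lower, upper


def expression_score(tpm: float, lower_q: float, upper_q: float) -> float:
    """Quartile-banded expression score; boundary TPMs fall in the middle band."""
    if tpm < 0:
        raise ValueError("TPM must be non-negative")
    if not lower_q <= upper_q:
        raise ValueError("quartiles must satisfy lower <= upper")
    if tpm == 0:
        return 0.0
    if tpm > upper_q:
        return 1.0
    if tpm < lower_q:
        return 0.33
    return 0.66


def assign_class(
    is_neoorf: bool,
    anchor_changed: bool,
    affinity_nM: float,
    cfg: RunConfig | None = None,
) -> int:
    """6-class taxonomy: neoORF/anchor-SNV/other-SNV x high/low affinity.

    High affinity is < 150 nM; 150-500 nM is the low-affinity tier.  Exactly
    150 nM lands in the low tier; affinity above the 500 nM candidate filter
    is a contract violation here.
    """
    cfg = cfg or RunConfig()
    if affinity_nM > cfg.affinity_filter_nM:
        raise ContractError("classing applies to filtered candidates (affinity <= 500 nM)")
    high = affinity_nM < cfg.class_high_affinity_nM
    if is_neoorf:
        return 1 if high else 4
    if anchor_changed:
        return 2 if high else 5
    return 3 if high else 6


def type_weight(neo_class: int, cfg: RunConfig | None = None) -> float:
    cfg = cfg or RunConfig()
    return cfg.type_weights[neo_class]


def dl_weight(
    both_identified: bool,
    tpm: float,
    affinity_nM: float,
    dl_rank: Optional[int],
    cfg: RunConfig | None = None,
) -> float:
    """Weight from the learned presentation model's agreement with the
    affinity predictor.  Branches use strict inequalities; equality cases
    fall through to the 0.125 default."""
    cfg = cfg or RunConfig()
    tpm_hi = tpm > cfg.dl_tpm_cutoff
    aff_hi = affinity_nM < cfg.dl_affinity_cutoff_nM
    if both_identified and tpm_hi and aff_hi:
        return 1.0
    if both_identified and (tpm_hi or aff_hi):
        return 0.5
    if (
        both_identified
        and tpm < cfg.dl_tpm_cutoff
        and affinity_nM > cfg.dl_affinity_cutoff_nM
        and dl_rank is not None
        and dl_rank < cfg.dl_rank_cutoff
    ):
        return 0.25
    return 0.125


def peptide_score(
    combine_s: float, expression_s: float, vaf: float, type_w: float, dl_w: float
) -> float:
    return combine_s * expression_s * vaf * type_w * dl_w


def score_candidate(
    candidate: PeptideCandidate,
    scores: PredictorScores,
    vaf: float,
    tpm: float,
    lower_q: float,
    upper_q: float,
    lost_alleles: set[str] | frozenset[str] = frozenset(),
    cfg: RunConfig | None = None,
) -> ScoredNeoantigen:
    """Compute every component for one filtered candidate."""
    cfg = cfg or RunConfig()
    mhc_s = mhc_binding_score(scores.affinity_nM)
    tap_s = tap_transport_score(scores.tap)
    cleav_s = cleavage_score(scores.cleavage)
    comb = combine_score(mhc_s, cleav_s, tap_s, cfg)
    expr_s = expression_score(tpm, lower_q, upper_q)
    anchor = False if candidate.is_neoorf else detect_anchor_change(candidate)
    neo_class = assign_class(candidate.is_neoorf, anchor, scores.affinity_nM, cfg)
    t_w = type_weight(neo_class, cfg)
    d_w = dl_weight(scores.dl_identified, tpm, scores.affinity_nM, scores.dl_rank, cfg)
    p_w = t_w * d_w
    score = peptide_score(comb, expr_s, vaf, t_w, d_w)
    lost = candidate.allele in lost_alleles
    s = ScoredNeoantigen(
        candidate=candidate,
        scores=scores,
        vaf=vaf,
        tpm=tpm,
        mhc_binding_score=mhc_s,
        tap_score=tap_s,
        cleavage_score=cleav_s,
        combine_score=comb,
        expression_score=expr_s,
        neo_class=neo_class,
        type_weight=t_w,
        dl_weight=d_w,
        peptide_weight=p_w,
        peptide_score=score,
        loh_lost_allele=lost,
    )
    s.high_confidence = high_confidence_filter(s, cfg)
    return s


def high_confidence_filter(s: ScoredNeoantigen, cfg: RunConfig | None = None) -> bool:
    """VAF > 0.1, affinity < 100 nM, TPM > 15, presenting allele not lost."""
    cfg = cfg or RunConfig()
    return (
        s.vaf > cfg.hc_min_vaf
        and s.scores.affinity_nM < cfg.hc_max_affinity_nM
        and s.tpm > cfg.hc_min_tpm
        and not s.loh_lost_allele
    )


def rank_candidates(
    scored: list[ScoredNeoantigen], collapse: str | None = None
) -> list[ScoredNeoantigen]:
    """Sort descending by peptide_score; ties by ascending affinity then
    lexicographic peptide.  ``collapse='variant'`` keeps only the best
    candidate per source variant before ranking."""
    items = list(scored)
    key = lambda s: (-s.peptide_score, s.scores.affinity_nM, s.candidate.sequence, s.candidate.allele)
    if collapse == "variant":
        best: dict[str, ScoredNeoantigen] = {}
        for s in items:
            vid = s.candidate.variant_id
            if vid not in best or key(s) < key(best[vid]):
                best[vid] = s
        items = list(best.values())
    elif collapse == "peptide":
        best = {}
        for s in items:
            pid = s.candidate.sequence
            if pid not in best or key(s) < key(best[pid]):
                best[pid] = s
        items = list(best.values())
    items.sort(key=key)
    for i, s in enumerate(items, start=1):
        s.rank = i
    return items
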