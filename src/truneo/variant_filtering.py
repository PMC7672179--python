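"""High-confidence somatic SNV / InDel filters.

SNV rules:
  rule1_depth_vaf   depth_tumor >= 10, vaf_tumor >= 0.05, vaf_normal < 0.02
  rule2_adjacency   nearest other candidate SNV on the same chromosome > 10 bp away
  rule3_mq          median mutant mapping quality >= 30 and the mutant-vs-reference
                    one-sided rank-sum test (mutant lower) is NOT significant at 0.2
  rule4_bq          same for base quality at >= 20 / p 0.05
  rule5_read_end    mutant reads not significantly closer to read ends (p 0.1)

InDel rule: depth_tumor >= 10, vaf_tumor > 0.10, vaf_normal < 0.02.

Rules 3-5 pair an absolute threshold with a Wilcoxon rank-sum comparison of
mutant-supporting vs reference-supporting reads; a variant fails when the
"mutant worse" alternative is significant at the printed cutoff.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from statistics import median

from scipy.stats import norm

from .config import RunConfig
from .models import VariantRecord

logger = logging.getLogger("truneo.filter")

SNV_RULES = ("rule1_depth_vaf", "rule2_adjacency", "rule3_mq", "rule4_bq", "rule5_read_end")
INDEL_RULES = ("indel_depth_vaf",)


class ContractError(ValueError):
    pass


@dataclass
class FilterReport:
    variant_id: str
    verdicts: dict[str, str] = field(default_factory=dict)  # pass | fail | not_applicable

    @property
    def overall(self) -> bool:
        return all(v != "fail" for v in self.verdicts.values())


def _midranks(pooled: list[float]) -> list[float]:
    """Midranks (1-based, ties averaged) aligned with the pooled order."""
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j + 2) / 2.0  # average of 1-based positions i+1..j+1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _exact_ranksum_cdf(doubled_ranks: list[int], nx: int, w_obs: int, tail: str) -> float:
    """Exact tail probability of the rank-sum W over all C(N, nx) subsets.

    Subset-sum counting DP; identical to brute-force enumeration of rank
    assignments, including ties (tied positions carry equal midranks).
    """
    total = sum(doubled_ranks)
    # ways[k][s] = number of k-subsets with doubled-rank sum s
    ways = [[0] * (total + 1) for _ in range(nx + 1)]
    ways[0][0] = 1
    for r in doubled_ranks:
        for k in range(nx - 1, -1, -1):
            row, nxt = ways[k], ways[k + 1]
            for s in range(total - r, -1, -1):
                if row[s]:
                    nxt[s + r] += row[s]
    counts = ways[nx]
    denom = math.comb(len(doubled_ranks), nx)
    if tail == "less":
        num = sum(counts[: w_obs + 1])
    else:
        num = sum(counts[w_obs:])
    return num / denom


def rank_sum_test(x: list[float], y: list[float], alternative: str = "less") -> float:
    """Two-sample Wilcoxon rank-sum p-value with midrank ties.

    Exact subset enumeration for combined n <= 25 (config default), normal
    approximation with tie correction and continuity correction beyond that.
    ``alternative='less'`` tests whether x tends to be smaller than y.
    """
    if alternative not in ("less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if not x or not y:
        raise ValueError("rank_sum_test requires non-empty samples")
    pooled = list(x) + list(y)
    nx, ny = len(x), len(y)
    n = nx + ny
    ranks = _midranks(pooled)
    w = sum(ranks[:nx])
    if n <= 25:
        doubled = [int(round(2 * r)) for r in ranks]
        return _exact_ranksum_cdf(doubled, nx, int(round(2 * w)), alternative)
    mean = nx * (n + 1) / 2.0
    # tie-corrected variance
    tie_counts: dict[float, int] = {}
    for v in pooled:
        tie_counts[v] = tie_counts.get(v, 0) + 1
    tie_term = sum(t**3 - t for t in tie_counts.values())
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0  # all observations tied: no evidence either way
    sd = math.sqrt(var)
    if alternative == "less":
        return float(norm.cdf((w - mean + 0.5) / sd))
    return float(norm.sf((w - mean - 0.5) / sd))


def filter_snv(
    v: VariantRecord, all_variants: list[VariantRecord], cfg: RunConfig | None = None
) -> FilterReport:
    """Apply the five SNV filter rules; overall pass = conjunction."""
    cfg = cfg or RunConfig()
    if v.vtype != "SNV":
        raise ContractError(f"filter_snv requires an SNV, got {v.vtype}")
    rep = FilterReport(v.variant_id)

    ok1 = (
        v.depth_tumor >= cfg.snv_min_depth
        and v.vaf_tumor >= cfg.snv_min_vaf_tumor
        and v.vaf_normal < cfg.snv_max_vaf_normal
    )
    rep.verdicts["rule1_depth_vaf"] = "pass" if ok1 else "fail"

    # adjacency among raw candidate SNVs, per chromosome, strict > 10 bp
    ok2 = True
    for other in all_variants:
        if other.vtype != "SNV" or other.variant_id == v.variant_id:
            continue
        if other.chrom == v.chrom and abs(other.pos - v.pos) <= cfg.snv_min_adjacent_distance:
            ok2 = False
            break
    rep.verdicts["rule2_adjacency"] = "pass" if ok2 else "fail"

    rep.verdicts["rule3_mq"] = _quality_rule(
        v.mq_mut, v.mq_ref, cfg.snv_min_mq_median, cfg.snv_mq_p_cutoff
    )
    rep.verdicts["rule4_bq"] = _quality_rule(
        v.bq_mut, v.bq_ref, cfg.snv_min_bq_median, cfg.snv_bq_p_cutoff
    )

    if v.dend_mut and v.dend_ref:
        p = rank_sum_test(v.dend_mut, v.dend_ref, alternative="less")
        rep.verdicts["rule5_read_end"] = "pass" if p >= cfg.snv_dend_p_cutoff else "fail"
    else:
        rep.verdicts["rule5_read_end"] = "not_applicable"

    for rule, verdict in rep.verdicts.items():
        logger.debug("variant=%s rule=%s verdict=%s", v.variant_id, rule, verdict)
    return rep


def _quality_rule(mut: list[float], ref: list[float], min_median: float, p_cutoff: float) -> str:
    if not mut:
        return "not_applicable"
    if median(mut) < min_median:
        return "fail"
    if ref:
        p = rank_sum_test(mut, ref, alternative="less")
        if p < p_cutoff:
            return "fail"
    return "pass"


def filter_indel(v: VariantRecord, cfg: RunConfig | None = None) -> FilterReport:
    cfg = cfg or RunConfig()
    if v.vtype not in ("insertion", "deletion"):
        raise ContractError(f"filter_indel requires an indel, got {v.vtype}")
    ok = (
        v.depth_tumor >= cfg.indel_min_depth
        and v.vaf_tumor > cfg.indel_min_vaf_tumor
        and v.vaf_normal < cfg.indel_max_vaf_normal
    )
    rep = FilterReport(v.variant_id, {"indel_depth_vaf": "pass" if ok else "fail"})
    logger.debug("variant=%s rule=indel_depth_vaf verdict=%s", v.variant_id, rep.verdicts["indel_depth_vaf"])
    return rep


def filter_variants(
    variants: list[VariantRecord], cfg: RunConfig | None = None
) -> dict[str, FilterReport]:
    """Filter a cohort of variants; fusions pass through unfiltered."""
    cfg = cfg or RunConfig()
    out: dict[str, FilterReport] = {}
    for v in variants:
        if v.vtype == "SNV":
            out[v.variant_id] = filter_snv(v, variants, cfg)
        elif v.vtype in ("insertion", "deletion"):
            out[v.variant_id] = filter_indel(v, cfg)
        else:
            out[v.variant_id] = FilterReport(v.variant_id, {})
    return out
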