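"""Consensus class-I HLA genotyping and HLA loss-of-heterozygosity.

Consensus resolves two callers x two samples per gene with a fixed
precedence: caller-1 tumor/normal agreement, then caller-2 tumor/normal
agreement, then cross-caller agreement in the normal sample, and finally
caller 1's normal-sample call flagged low-confidence.

LOH is called per gene from per-site log2(tumor unique reads / normal unique
reads) ratios of the two alleles, compared by a paired two-sided t-test at
alpha = 2e-4; the allele with the lower mean ratio is reported as lost.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .models import HlaCallSet, HlaGenotype, LohInput, LohResult

# decision-tree branches in precedence order
_SOURCES = ("caller1", "caller2", "normal_agreement", "caller1_normal_fallback")


def resolve_gene(
    poly_tumor: tuple[str, ...],
    poly_normal: tuple[str, ...],
    bwa_tumor: tuple[str, ...],
    bwa_normal: tuple[str, ...],
) -> tuple[tuple[str, ...], str, str]:
    """Resolve one gene's allele pair: (alleles, source, confidence)."""
    pt, pn = tuple(sorted(poly_tumor)), tuple(sorted(poly_normal))
    bt, bn = tuple(sorted(bwa_tumor)), tuple(sorted(bwa_normal))
    if pt == pn:
        return pn, "caller1", "high"
    if bt == bn:
        return bn, "caller2", "high"
    if pn == bn:
        return pn, "normal_agreement", "high"
    return pn, "caller1_normal_fallback", "low"


def consensus_genotype(calls: HlaCallSet) -> HlaGenotype:
    """Per-gene consensus over the four calls, aggregated to 6 alleles.

    Overall ``source`` is the lowest-precedence branch used by any gene, so
    the low-confidence flag and the fallback source stay in lockstep.
    """
    alleles: list[str] = []
    gene_sources: dict[str, str] = {}
    worst = 0
    for gene in "ABC":
        pair, source, _conf = resolve_gene(
            calls.poly_tumor.gene_alleles(gene),
            calls.poly_normal.gene_alleles(gene),
            calls.bwa_tumor.gene_alleles(gene),
            calls.bwa_normal.gene_alleles(gene),
        )
        alleles.extend(pair)
        gene_sources[gene] = source
        worst = max(worst, _SOURCES.index(source))
    source = _SOURCES[worst]
    confidence = "low" if source == "caller1_normal_fallback" else "high"
    return HlaGenotype(
        alleles=tuple(alleles),
        confidence=confidence,
        source=source,
        gene_sources=gene_sources,
    )


def loh_test(
    inp: LohInput, alpha: float = 0.0002, pseudocount: float | None = None
) -> LohResult:
    """Paired t-test of allelic imbalance on per-site log2 coverage ratios."""
    if inp.allele1 == inp.allele2:
        return LohResult(inp.gene, p_value=1.0, loh=False, applicable=False)

    r1, r2 = [], []
    for t1, n1, t2, n2 in zip(inp.tumor1, inp.normal1, inp.tumor2, inp.normal2):
        if pseudocount is not None:
            t1, n1, t2, n2 = (x + pseudocount for x in (t1, n1, t2, n2))
        if min(t1, n1, t2, n2) <= 0:
            continue  # uninformative site
        r1.append(math.log2(t1 / n1))
        r2.append(math.log2(t2 / n2))
    if len(r1) < 2:
        raise ValueError(f"gene {inp.gene}: fewer than 2 usable sites for LOH test")

    d = np.asarray(r1) - np.asarray(r2)
    warning = None
    if np.allclose(d, 0.0):
        p = 1.0
    elif np.allclose(d, d[0]):
        # constant non-zero shift: infinite t statistic
        p = 0.0
        warning = "zero-variance non-zero differences"
    else:
        p = float(stats.ttest_rel(r1, r2).pvalue)

    loh = p < alpha
    lost = None
    if loh:
        lost = inp.allele1 if float(np.mean(r1)) < float(np.mean(r2)) else inp.allele2
    return LohResult(inp.gene, p_value=p, loh=loh, lost_allele=lost, warning=warning)


def loh_lost_alleles(
    inputs: list[LohInput], alpha: float = 0.0002, pseudocount: float | None = None
) -> set[str]:
    """Convenience: set of allele strings called lost across all genes."""
    lost: set[str] = set()
    for inp in inputs:
        res = loh_test(inp, alpha=alpha, pseudocount=pseudocount)
        if res.loh and res.lost_allele:
            lost.add(res.lost_allele)
    return lost
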