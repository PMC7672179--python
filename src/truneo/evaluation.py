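"""Benchmark metrics (recall@k, random baseline, Elispot positive rate,
TPM-threshold sensitivity) and the TCR clonotype-expansion test.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
from scipy import stats

from .models import ClonotypeCount

DATA_DIR = Path(__file__).parent / "data"


def round_half_up(x: float, places: int = 2) -> float:
    """Half-up rounding to match reported percentages (e.g. 52.63)."""
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -places, rounding=ROUND_HALF_UP))


@dataclass
class RankedCohort:
    """Per-patient ordered candidate lists with immunogenicity labels.

    ``table`` columns: patient_id, method, rank, candidate_id,
    immunogenic (1/0/NA) and optionally tpm.  Unlabelled candidates occupy
    ranked slots but never count as positives.
    """

    table: pd.DataFrame
    method: str
    total_immunogenic: int
    total_assayed: int = 0

    def __post_init__(self):
        df = self.table
        df = df[df["method"] == self.method].copy()
        if df.empty:
            raise ValueError(f"no rows for method {self.method!r}")
        dup = df.duplicated(subset=["patient_id", "rank"])
        if dup.any():
            raise ValueError(f"duplicate ranks within a patient for {self.method}")
        n_pos = int((df["immunogenic"] == 1).sum())
        if n_pos > self.total_immunogenic:
            raise ValueError("more labelled positives than the cohort denominator")
        self.table = df


def positives_in_top_k(cohort: RankedCohort, k: int) -> int:
    """Immunogenic candidates with rank <= k, summed over patients."""
    df = cohort.table
    return int(((df["immunogenic"] == 1) & (df["rank"] <= k)).sum())


def recall_at_k(cohort: RankedCohort, k: int) -> float:
    """Percentage of the cohort's immunogenic epitopes in per-patient top-k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if cohort.total_immunogenic == 0:
        raise ValueError("cohort denominator is zero")
    return round_half_up(100.0 * positives_in_top_k(cohort, k) / cohort.total_immunogenic)


def mean_patient_recall_at_k(cohort: RankedCohort, k: int) -> float:
    """Alternative metric: mean of per-patient recalls (not the headline one)."""
    df = cohort.table
    vals = []
    for _, sub in df.groupby("patient_id"):
        npos = int((sub["immunogenic"] == 1).sum())
        if npos == 0:
            continue
        vals.append(((sub["immunogenic"] == 1) & (sub["rank"] <= k)).sum() / npos)
    if not vals:
        raise ValueError("no patients with labelled positives")
    return round_half_up(100.0 * sum(vals) / len(vals))


def random_baseline(total_immunogenic: int, total_assayed: int) -> float:
    """Expected per-candidate hit rate of a uniform random ranker, as %."""
    if total_assayed <= 0:
        raise ValueError("total_assayed must be positive")
    if total_immunogenic < 0:
        raise ValueError("total_immunogenic must be non-negative")
    return round_half_up(100.0 * total_immunogenic / total_assayed)


def positive_rate(outcomes: list[bool]) -> float:
    """True positives / (true + false positives) over a validated top-k list."""
    if not outcomes:
        raise ValueError("empty outcome list")
    return round_half_up(100.0 * sum(bool(o) for o in outcomes) / len(outcomes))


def tpm_threshold_sweep(
    cohort: RankedCohort, thresholds: list[float], k: int = 10
) -> dict[float, float]:
    """Recall@k after dropping candidates below each TPM threshold.

    Survivors are re-ranked preserving their original order within patient.
    """
    if "tpm" not in cohort.table.columns:
        raise ValueError("cohort table has no tpm column")
    out = {}
    for t in thresholds:
        kept = cohort.table[cohort.table["tpm"] >= t].copy()
        kept["rank"] = kept.sort_values("rank").groupby("patient_id").cumcount() + 1
        sub = RankedCohort(kept, cohort.method, cohort.total_immunogenic, cohort.total_assayed)
        out[t] = recall_at_k(sub, k)
    return out


def fisher_exact_one_sided(
    count_pre: int, total_pre: int, count_post: int, total_post: int
) -> tuple[float, float]:
    """One-sided Fisher test for post-stimulation enrichment.

    Table [[count_post, rest_post], [count_pre, rest_pre]], alternative =
    greater.  Returns (p, sample odds ratio); a 0/0 odds ratio is reported
    as 1.0 (no signal), and a division by zero alone as inf.
    """
    for c, t in ((count_pre, total_pre), (count_post, total_post)):
        if c < 0 or t <= 0 or c > t:
            raise ValueError("counts must satisfy 0 <= count <= total, total > 0")
    rest_pre = total_pre - count_pre
    rest_post = total_post - count_post
    p = float(
        stats.fisher_exact(
            [[count_post, rest_post], [count_pre, rest_pre]], alternative="greater"
        ).pvalue
    )
    num = count_post * rest_pre
    den = count_pre * rest_post
    if den == 0:
        odds = 1.0 if num == 0 else float("inf")
    else:
        odds = num / den
    return p, odds


def benjamini_hochberg(p: list[float]) -> list[float]:
    """Step-up BH q-values: q_i = min_{j >= i} p_(j) * n / j, monotone."""
    n = len(p)
    for x in p:
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"p-value {x} outside [0, 1]")
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    running_min = 1.0
    for idx in range(n - 1, -1, -1):
        i = order[idx]
        running_min = min(running_min, p[i] * n / (idx + 1))
        q[i] = running_min
    return q


def call_expanded_clones(
    cultures: dict[str, list[tuple[str, int, int]]],
    control: list[tuple[str, int, int]],
    alpha: float = 0.05,
) -> dict[str, list[ClonotypeCount]]:
    """Antigen-specific clonotype expansion per stimulated culture.

    Inputs are (cdr3, count, total) triples.  A clone is expanded in a
    culture iff its BH q-value (family = that culture's clones) < alpha,
    its odds ratio > 1, and it is not significant in any other culture.
    Clones absent from the control are treated as count 0 there.
    """
    ctrl_counts = {cdr3: c for cdr3, c, _t in control}
    ctrl_total = control[0][2] if control else 1

    tested: dict[str, list[ClonotypeCount]] = {}
    for culture, clones in cultures.items():
        recs = []
        for cdr3, count, total in clones:
            pre = ctrl_counts.get(cdr3, 0)
            p, odds = fisher_exact_one_sided(pre, ctrl_total, count, total)
            recs.append(
                ClonotypeCount(
                    cdr3=cdr3,
                    count_pre=pre,
                    count_post=count,
                    total_pre=ctrl_total,
                    total_post=total,
                    p=p,
                    odds_ratio=odds,
                    degenerate=(pre == 0 and count == 0),
                )
            )
        qs = benjamini_hochberg([r.p for r in recs])
        for r, q in zip(recs, qs):
            r.q = q
        tested[culture] = recs

    significant = {
        culture: {r.cdr3 for r in recs if r.q < alpha} for culture, recs in tested.items()
    }
    for culture, recs in tested.items():
        others = set().union(
            *(sig for other, sig in significant.items() if other != culture)
        ) if len(tested) > 1 else set()
        for r in recs:
            r.expanded = r.q < alpha and r.odds_ratio > 1.0 and r.cdr3 not in others
    return tested


# ---------------------------------------------------------------------------
# packaged benchmark tables


def load_cohort_table() -> pd.DataFrame:
    """Published 13-patient validation-cohort rank table (see data/README)."""
    return pd.read_csv(DATA_DIR / "cohort_ranks.tsv", sep="\t")


def load_elispot_table() -> pd.DataFrame:
    """Patient-01 top-10 Elispot outcomes per method."""
    df = pd.read_csv(DATA_DIR / "elispot_top10.tsv", sep="\t")
    df["elispot"] = df["elispot"].astype(bool)
    return df


def cohort(method: str, total_immunogenic: int = 19, total_assayed: int = 1599) -> RankedCohort:
    return RankedCohort(load_cohort_table(), method, total_immunogenic, total_assayed)
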