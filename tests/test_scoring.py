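"""Scoring equations against direct evaluation, classing, weights, ranking."""
import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from truneo.config import RunConfig
from truneo.models import PeptideCandidate, PredictorScores
from truneo.scoring import (
    ContractError,
    assign_class,
    cleavage_score,
    combine_score,
    dl_weight,
    expression_quartiles,
    expression_score,
    high_confidence_filter,
    mhc_binding_score,
    peptide_score,
    rank_candidates,
    score_candidate,
    tap_transport_score,
    type_weight,
)


class TestComponentScores:
    def test_mhc_binding_values(self):
        assert mhc_binding_score(500) == pytest.approx(0.0)
        assert mhc_binding_score(100) == pytest.approx(math.tanh(2.0), abs=1e-4)
        assert mhc_binding_score(300) == pytest.approx(math.tanh(1.0), abs=1e-4)

    def test_mhc_binding_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mhc_binding_score(0)

    def test_tap_values(self):
        assert tap_transport_score(0) == pytest.approx(0.5)
        assert tap_transport_score(1) == pytest.approx(0.9933, abs=1e-4)
        assert tap_transport_score(-1) == pytest.approx(0.0067, abs=1e-4)

    def test_cleavage_values(self):
        assert cleavage_score(0) == pytest.approx(0.0)
        assert cleavage_score(1) == pytest.approx(0.9951, abs=1e-4)
        assert cleavage_score(0.5) == pytest.approx(0.9051, abs=1e-4)

    def test_combine_values(self):
        assert combine_score(1, 1, 1) == pytest.approx(1.0)
        assert combine_score(0, 0, 0.5) == pytest.approx(0.025)
        assert combine_score(0.9640, 0.9951, 0.9933) == pytest.approx(0.9702, abs=1e-3)


class TestExpressionScore:
    def test_bands(self):
        assert expression_score(0.0, 5, 20) == 0.0
        assert expression_score(2.0, 5, 20) == 0.33
        assert expression_score(10.0, 5, 20) == 0.66
        assert expression_score(25.0, 5, 20) == 1.0

    def test_boundaries_go_to_middle_band(self):
        assert expression_score(5.0, 5, 20) == 0.66
        assert expression_score(20.0, 5, 20) == 0.66

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            expression_score(-1.0, 5, 20)

    def test_only_four_values_occur(self):
        rng = random.Random(0)
        expr = {f"G{i}": rng.uniform(0, 100) for i in range(200)}
        expr["Z"] = 0.0
        lo, hi = expression_quartiles(expr)
        vals = {expression_score(t, lo, hi) for t in expr.values()}
        assert vals <= {0.0, 0.33, 0.66, 1.0}

    def test_quartiles_permutation_invariant(self):
        rng = random.Random(1)
        expr = {f"G{i}": rng.uniform(0, 100) for i in range(100)}
        lo1, hi1 = expression_quartiles(expr)
        items = list(expr.items())
        rng.shuffle(items)
        lo2, hi2 = expression_quartiles(dict(items))
        assert (lo1, hi1) == (lo2, hi2)


class TestClassAndWeights:
    def test_six_classes(self):
        assert assign_class(True, False, 100) == 1
        assert assign_class(False, True, 100) == 2
        assert assign_class(False, False, 100) == 3
        assert assign_class(True, False, 300) == 4
        assert assign_class(False, True, 300) == 5
        assert assign_class(False, False, 300) == 6

    def test_boundary_150_goes_low_tier(self):
        assert assign_class(True, False, 150.0) == 4

    def test_above_500_contract_error(self):
        with pytest.raises(ContractError):
            assign_class(False, False, 501)

    def test_type_weights(self):
        assert [type_weight(c) for c in range(1, 7)] == [1.0, 0.6, 0.5, 0.25, 0.15, 0.125]

    def test_dl_weight_branches(self):
        assert dl_weight(True, 20, 80, 5) == 1.0
        assert dl_weight(True, 20, 200, 50) == 0.5
        assert dl_weight(True, 5, 90, 50) == 0.5
        assert dl_weight(True, 5, 200, 5) == 0.25
        assert dl_weight(True, 5, 200, 50) == 0.125
        assert dl_weight(False, 100, 50, None) == 0.125

    def test_dl_weight_equality_gaps_fall_through(self):
        assert dl_weight(True, 15.0, 200, 5) == 0.125  # TPM exactly 15
        assert dl_weight(True, 5, 100.0, 5) == 0.125  # affinity exactly 100


class TestPeptideScore:
    def test_product_examples(self):
        assert peptide_score(1, 1, 0.5, 1, 1) == pytest.approx(0.5)
        assert peptide_score(0.7, 0.0, 0.5, 1, 1) == 0.0
        assert peptide_score(0.9702, 0.66, 0.3, 0.6, 0.5) == pytest.approx(0.05764, abs=1e-4)

    @given(
        affinity=st.floats(min_value=1.0, max_value=500.0),
        cleavage=st.floats(min_value=0.0, max_value=1.0),
        tap=st.floats(min_value=-3.0, max_value=3.0),
        vaf=st.floats(min_value=0.0, max_value=1.0),
        expr=st.sampled_from([0.0, 0.33, 0.66, 1.0]),
        neo_class=st.integers(min_value=1, max_value=6),
        dl_w=st.sampled_from([1.0, 0.5, 0.25, 0.125]),
    )
    @settings(max_examples=300, deadline=None)
    def test_bounded_zero_one(self, affinity, cleavage, tap, vaf, expr, neo_class, dl_w):
        comb = combine_score(
            mhc_binding_score(affinity), cleavage_score(cleavage), tap_transport_score(tap)
        )
        s = peptide_score(comb, expr, vaf, type_weight(neo_class), dl_w)
        assert 0.0 <= s <= 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_nonincreasing_in_affinity(self, seed):
        rng = random.Random(seed)
        cleav = rng.uniform(0, 1)
        tap = rng.uniform(-3, 3)
        tpm = rng.choice([5.0, 20.0])
        vaf = rng.uniform(0.05, 0.6)
        is_neoorf = rng.random() < 0.3
        anchor = (not is_neoorf) and rng.random() < 0.5
        both = rng.random() < 0.5
        rank = rng.choice([5, 50])
        grid = sorted(rng.uniform(1, 500) for _ in range(50))
        scores = []
        for aff in grid:
            comb = combine_score(
                mhc_binding_score(aff), cleavage_score(cleav), tap_transport_score(tap)
            )
            tw = type_weight(assign_class(is_neoorf, anchor, aff))
            dw = dl_weight(both, tpm, aff, rank)
            scores.append(peptide_score(comb, 0.66, vaf, tw, dw))
        for a, b in zip(scores, scores[1:]):
            assert b <= a + 1e-12


def _mk_scored(score, affinity, pep="ACDEFGHIK", vid="v"):
    c = PeptideCandidate(pep, "HLA-A*02:01", vid, frozenset({4}), wt_sequence=pep)
    from truneo.models import ScoredNeoantigen

    s = ScoredNeoantigen(
        candidate=c,
        scores=PredictorScores(affinity_nM=affinity, cleavage=0.5, tap=0.0),
        vaf=0.2,
        tpm=20.0,
        peptide_score=score,
    )
    return s


class TestRanking:
    def test_descending_by_score(self):
        ranked = rank_candidates([_mk_scored(0.5, 50, "ACDEFGHIK"), _mk_scored(0.9, 50, "CCDEFGHIK")])
        assert [s.peptide_score for s in ranked] == [0.9, 0.5]
        assert [s.rank for s in ranked] == [1, 2]

    def test_tie_break_by_affinity(self):
        a = _mk_scored(0.5, 120, "ACDEFGHIK")
        b = _mk_scored(0.5, 80, "CCDEFGHIK")
        ranked = rank_candidates([a, b])
        assert ranked[0] is b

    def test_empty(self):
        assert rank_candidates([]) == []

    def test_permutation_and_idempotence(self):
        rng = random.Random(3)
        items = [
            _mk_scored(rng.random(), rng.uniform(1, 500), pep, f"v{i}")
            for i, pep in enumerate(["ACDEFGHIK", "CCDEFGHIK", "DCDEFGHIK", "ECDEFGHIK"])
        ]
        ranked = rank_candidates(items)
        assert sorted(s.rank for s in ranked) == list(range(1, len(items) + 1))
        again = rank_candidates(ranked)
        assert [s.candidate.sequence for s in again] == [s.candidate.sequence for s in ranked]

    def test_collapse_variant_keeps_best(self):
        a = _mk_scored(0.5, 50, "ACDEFGHIK", "v1")
        b = _mk_scored(0.9, 50, "CCDEFGHIK", "v1")
        c = _mk_scored(0.7, 50, "DCDEFGHIK", "v2")
        ranked = rank_candidates([a, b, c], collapse="variant")
        assert len(ranked) == 2 and ranked[0] is b and ranked[1] is c


class TestHighConfidence:
    def _scored(self, vaf=0.2, affinity=80.0, tpm=20.0, lost=False):
        s = _mk_scored(0.5, affinity)
        s.vaf = vaf
        s.tpm = tpm
        s.loh_lost_allele = lost
        return s

    def test_pass(self):
        assert high_confidence_filter(self._scored())

    def test_vaf_exactly_01_fails(self):
        assert not high_confidence_filter(self._scored(vaf=0.1))

    def test_affinity_100_fails(self):
        assert not high_confidence_filter(self._scored(affinity=100.0))

    def test_tpm_15_fails(self):
        assert not high_confidence_filter(self._scored(tpm=15.0))

    def test_lost_allele_fails(self):
        assert not high_confidence_filter(self._scored(lost=True))


def straight_line_score(affinity, cleav, tap, tpm, lower_q, upper_q, vaf,
                        is_neoorf, anchor, both_identified, dl_rank):
    """Independent re-implementation of the printed formulas (oracle)."""
    mhc = math.tanh((500 - affinity) / 200)
    cle = math.tanh(cleav * 3)
    tp = math.tanh(tap * 2.5) / 2 + 0.5
    comb = 0.8 * mhc + 0.15 * cle + 0.05 * tp
    if tpm == 0:
        expr = 0.0
    elif tpm > upper_q:
        expr = 1.0
    elif tpm < lower_q:
        expr = 0.33
    else:
        expr = 0.66
    high = affinity < 150
    if is_neoorf:
        cls = 1 if high else 4
    elif anchor:
        cls = 2 if high else 5
    else:
        cls = 3 if high else 6
    tw = {1: 1, 2: 0.6, 3: 0.5, 4: 0.25, 5: 0.15, 6: 0.125}[cls]
    if both_identified and tpm > 15 and affinity < 100:
        dw = 1.0
    elif both_identified and (tpm > 15 or affinity < 100):
        dw = 0.5
    elif both_identified and tpm < 15 and affinity > 100 and dl_rank is not None and dl_rank < 30:
        dw = 0.25
    else:
        dw = 0.125
    return comb * expr * vaf * tw * dw


def test_pipeline_agrees_with_straight_line_oracle():
    """1000 random candidates, agreement to 1e-9."""
    rng = random.Random(42)
    cfg = RunConfig()
    lower_q, upper_q = 4.0, 30.0
    for i in range(1000):
        affinity = rng.uniform(1, 500)
        cleav = rng.uniform(-0.2, 1.2)
        tap = rng.uniform(-3, 3)
        tpm = rng.choice([0.0, rng.uniform(0.1, 100)])
        vaf = rng.uniform(0, 1)
        is_neoorf = rng.random() < 0.3
        anchor_offset = rng.choice([1, 4, 8])
        both = rng.random() < 0.5
        dl_rank = rng.choice([None, 5, 29, 30, 100]) if both else None
        pep = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(9))
        cand = PeptideCandidate(
            pep, "HLA-A*02:01", f"v{i}", frozenset({anchor_offset}),
            wt_sequence=None if is_neoorf else pep,
        )
        scores = PredictorScores(
            affinity_nM=affinity, cleavage=cleav, tap=tap,
            dl_identified=both, dl_rank=dl_rank,
        )
        got = score_candidate(cand, scores, vaf, tpm, lower_q, upper_q, set(), cfg)
        anchor = (not is_neoorf) and anchor_offset in (1, 8)
        expected = straight_line_score(
            affinity, cleav, tap, tpm, lower_q, upper_q, vaf,
            is_neoorf, anchor, both, dl_rank,
        )
        assert got.peptide_score == pytest.approx(expected, abs=1e-9)
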