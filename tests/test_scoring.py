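"""Score computations: maximal, ETD, CID, predicted, targets, concordance."""

import pytest
from hypothesis import given, settings, strategies as st

from ptmpanel import (
    FilterConfig,
    ModifiedPeptide,
    Peptide,
    PredictionTable,
    ProteinRecord,
    TargetList,
    annotate_sites,
    cid_score,
    concordance,
    etd_score,
    maximal_score,
    mono_modified_count,
    predicted_scores,
    score_setting,
    target_coverage,
)
from ptmpanel.synthetic import generate_fixture_protein


def mp(start, end, sites, seq=None):
    seq = seq or "S" * (end - start + 1)
    pep = Peptide("p", start, end, seq, 0, "t")
    return ModifiedPeptide(peptide=pep, site_positions=tuple(sites))


class TestMaximalScore:
    def test_counts_modifiable_residues(self):
        protein = ProteinRecord("p", "ARTKQTARKSTGGKAPR")
        assert maximal_score(protein, "STY") == 4  # T3 T6 S10 T11

    def test_zero_when_no_sites(self):
        assert maximal_score(ProteinRecord("p", "AAAA"), "STY") == 0


class TestEtdScore:
    def test_union_of_distinct_positions(self):
        assert etd_score([mp(9, 12, (10, 11)), mp(1, 5, (3,))]) == 3

    def test_overlapping_peptides_deduplicate(self):
        assert etd_score([mp(9, 12, (10, 11)), mp(8, 12, (10, 11))]) == 2

    def test_empty(self):
        assert etd_score([]) == 0


class TestCidScore:
    @pytest.mark.parametrize("n,expected", [(1, 1.0), (2, 0.5), (3, 1 / 3), (4, 0.25)])
    def test_single_peptide_weight_is_reciprocal_site_count(self, n, expected):
        assert cid_score([mp(1, n, tuple(range(1, n + 1)))]) == pytest.approx(expected)

    def test_sum_over_peptides(self):
        peps = [mp(1, 1, (1,)), mp(3, 4, (3, 4)), mp(6, 9, (6, 7, 8, 9))]
        assert cid_score(peps) == pytest.approx(1.75)

    def test_zero_sites_is_invalid(self):
        with pytest.raises(ValueError):
            mp(1, 3, ())


class TestPredictedScores:
    def test_per_peptide_sum(self):
        table = PredictionTable("p", {10: 0.8, 11: 0.2})
        matched, unmatched = predicted_scores([mp(9, 12, (10, 11))], [], table)
        assert (matched, unmatched) == (pytest.approx(1.0), 0.0)

    def test_rejected_pool_symmetry(self):
        table = PredictionTable("p", {10: 0.8, 11: 0.2})
        matched, unmatched = predicted_scores([], [mp(9, 12, (10, 11))], table)
        assert (matched, unmatched) == (0.0, pytest.approx(1.0))

    def test_unscored_sites_contribute_zero(self):
        matched, unmatched = predicted_scores([mp(1, 2, (1, 2))], [], PredictionTable("p", {}))
        assert matched == 0.0 and unmatched == 0.0

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), min_len=st.integers(1, 10),
           span=st.integers(0, 60))
    def test_conservation_under_any_length_window(self, seed, min_len, span, rules):
        """matched + unmatched is invariant to the length window: the window
        only moves site-bearing peptides between the two pools."""
        protein = generate_fixture_protein(120, seed=seed)
        table = PredictionTable(
            protein.id,
            {p: 0.5 for p, aa in enumerate(protein.sequence, 1) if aa in "STY"},
        )
        totals = []
        for lo, hi in [(1, 10**6), (min_len, min_len + span), (7, 40)]:
            cfg = FilterConfig(min_length=lo, max_length=hi)
            rec = score_setting(protein, [rules["trypsin/P"]], cfg,
                                prediction_table=table)
            totals.append(rec.predicted_matched + rec.predicted_unmatched)
        assert totals[0] == pytest.approx(totals[1])
        assert totals[0] == pytest.approx(totals[2])


class TestMonoModified:
    def test_counts_single_site_peptides(self):
        peps = [mp(1, 1, (1,)), mp(3, 4, (3, 4)), mp(6, 6, (6,))]
        assert mono_modified_count(peps) == 2

    def test_zero_cases(self):
        assert mono_modified_count([]) == 0
        assert mono_modified_count([mp(1, 2, (1, 2))]) == 0


class TestTargetCoverage:
    def test_intersection_split(self):
        targets = TargetList("p", frozenset({10, 6}))
        covered, uncovered = target_coverage([mp(9, 12, (10, 11))], targets)
        assert covered == frozenset({10}) and uncovered == frozenset({6})

    def test_full_coverage_and_empty_retained(self):
        targets = TargetList("p", frozenset({10}))
        assert target_coverage([mp(9, 12, (10,))], targets)[1] == frozenset()
        assert target_coverage([], targets) == (frozenset(), frozenset({10}))


class TestConcordance:
    def test_jaccard_percent_and_classes(self):
        res = concordance({1, 2, 3}, {2, 3, 4})
        assert res.matched == frozenset({2, 3})
        assert res.false_positives == frozenset({1})
        assert res.false_negatives == frozenset({4})
        assert res.concordance_percent == pytest.approx(50.0)

    def test_identical_sets_and_degenerate(self):
        assert concordance({1, 2}, {1, 2}).concordance_percent == 100.0
        empty = concordance(set(), set())
        assert empty.concordance_percent == 0.0
        assert not (empty.matched | empty.false_positives | empty.false_negatives)

    def test_symmetry_under_argument_exchange(self):
        a, b = {1, 2, 5}, {2, 7}
        fwd, rev = concordance(a, b), concordance(b, a)
        assert fwd.concordance_percent == rev.concordance_percent
        assert fwd.false_positives == rev.false_negatives

    def test_alternative_denominators(self):
        assert concordance({1, 2, 3}, {2, 3, 4}, "observed").concordance_percent == pytest.approx(200 / 3)
        assert concordance({1, 2, 3}, {2}, "simulated").concordance_percent == pytest.approx(100 / 3)
        with pytest.raises(ValueError):
            concordance({1}, {1}, "nonsense")


class TestScoreSetting:
    def test_etd_bounded_by_maximal_on_random_proteins(self, rules):
        cfg = FilterConfig()
        for seed in range(50):
            protein = generate_fixture_protein(100, seed=seed)
            rec = score_setting(protein, [rules["trypsin/P"], rules["V8-E"]], cfg)
            assert 0 <= rec.etd <= rec.maximal
            assert rec.cid >= 0

    def test_annotate_sites_positions(self):
        protein = ProteinRecord("p", "A" * 9 + "STGGK" + "A" * 3)
        pep = Peptide("p", 10, 14, "STGGK", 0, "t")
        annotated = annotate_sites(pep, protein, "STY")
        assert annotated.site_positions == (10, 11)
        assert annotate_sites(Peptide("p", 15, 17, "AAA", 0, "t"), protein, "STY") is None
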