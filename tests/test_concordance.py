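"""The four-class allele-match taxonomy and its aggregation."""

import itertools

import numpy as np
import pytest

from impuconcord import (
    ContractError,
    MatchClass,
    MatchResult,
    classify_match,
    classify_variants,
    extract_overlap,
    observed_alleles,
    summarize_concordance,
)
from impuconcord.concordance import ConcordanceSummary
from conftest import make_gm, make_variant
from oracles import all_allele_multisets, match_oracle


class TestClassifyMatch:
    @pytest.mark.parametrize("imputed, truth, expected, ambiguous", [
        ({"A", "G"}, {"A", "G"}, MatchClass.COMPLETE, False),
        ({"A", "G"}, {"T", "C"}, MatchClass.FLIP, False),
        ({"A", "G"}, {"A", "C"}, MatchClass.HALF, False),
        ({"A", "T"}, {"G", "C"}, MatchClass.NONE, True),
        ({"A"}, {"A", "G"}, MatchClass.HALF, False),       # monomorphic imputation
        ({"A", "T"}, {"A", "T"}, MatchClass.COMPLETE, False),  # palindromic identity
        ({"A"}, {"T"}, MatchClass.FLIP, False),
        ({"A"}, {"G"}, MatchClass.NONE, False),
        ({"C"}, {"A", "G"}, MatchClass.NONE, False),
    ])
    def test_examples(self, imputed, truth, expected, ambiguous):
        res = classify_match(imputed, truth)
        assert res.match_class is expected
        assert res.ambiguous is ambiguous

    def test_exhaustive_oracle_equivalence(self):
        """Agreement with an independent brute-force oracle on all 196
        ordered pairs of size-1/2 allele multisets."""
        sets = all_allele_multisets()
        assert len(sets) == 14
        n_checked = 0
        for si, st in itertools.product(sets, sets):
            expected_cls, expected_amb = match_oracle(si, st)
            res = classify_match(set(si), set(st))
            assert res.match_class.value == expected_cls, (si, st)
            assert res.ambiguous == expected_amb, (si, st)
            n_checked += 1
        assert n_checked == 196

    def test_symmetry(self):
        """Swapping imputed and truth sides preserves class and flag."""
        sets = all_allele_multisets()
        for si, st in itertools.product(sets, sets):
            a = classify_match(set(si), set(st))
            b = classify_match(set(st), set(si))
            assert a == b

    def test_invalid_alleles_rejected(self):
        with pytest.raises(ContractError):
            classify_match({"A", "N"}, {"A", "G"})
        with pytest.raises(ContractError):
            classify_match(set(), {"A"})

    def test_ambiguous_only_on_none(self):
        with pytest.raises(ContractError):
            MatchResult(MatchClass.HALF, ambiguous=True)


class TestObservedAlleles:
    @pytest.mark.parametrize("calls, expected", [
        ([0, 1, 2], {"A", "G"}),
        ([0, 0, 0], {"A"}),
        ([2, 2], {"G"}),
        ([1, -1], {"A", "G"}),
    ])
    def test_examples(self, calls, expected):
        v = make_variant(alleles=("A", "G"))
        assert observed_alleles(v, np.array(calls)) == frozenset(expected)

    def test_all_missing_is_uninformative(self):
        with pytest.raises(ContractError, match="uninformative"):
            observed_alleles(make_variant(), np.array([-1, -1]))


class TestExtractOverlap:
    def test_position_intersection(self):
        imp = make_gm(np.zeros((2, 3)))                      # pos 100,200,300
        tru = make_gm(np.zeros((2, 3)))
        tru.variants = [make_variant(pos=p, vid=f"t{p}") for p in (200, 300, 400)]
        a, b, per_chrom = extract_overlap(imp, tru)
        assert [v.pos for v in a.variants] == [200, 300]
        assert [v.pos for v in b.variants] == [200, 300]
        assert per_chrom == {"1": 2}

    def test_pre_imputation_exclusion(self):
        imp = make_gm(np.zeros((2, 3)))
        tru = make_gm(np.zeros((2, 3)))
        a, b, _ = extract_overlap(imp, tru, pre_imputation_variants=[("1", 200)])
        assert [v.pos for v in a.variants] == [100, 300]

    def test_disjoint_samples_error(self):
        imp = make_gm(np.zeros((2, 2)), samples=["a", "b"])
        tru = make_gm(np.zeros((2, 2)), samples=["c", "d"])
        with pytest.raises(ContractError, match="shared samples"):
            extract_overlap(imp, tru)

    def test_zero_shared_variants_error(self):
        imp = make_gm(np.zeros((2, 1)))
        tru = make_gm(np.zeros((2, 1)))
        tru.variants = [make_variant(pos=999)]
        with pytest.raises(ContractError, match="shared variants"):
            extract_overlap(imp, tru)

    def test_sample_order_follows_imputed(self):
        imp = make_gm(np.zeros((3, 2)), samples=["c", "a", "b"])
        tru = make_gm(np.zeros((3, 2)), samples=["a", "b", "c"])
        a, b, _ = extract_overlap(imp, tru)
        assert a.samples == ["c", "a", "b"] == b.samples


class TestSummaries:
    def _summary(self, counts, n_ambiguous=0):
        s = ConcordanceSummary(stratum="all", n_ambiguous=n_ambiguous)
        s.counts = {MatchClass.COMPLETE: counts[0], MatchClass.FLIP: counts[1],
                    MatchClass.HALF: counts[2], MatchClass.NONE: counts[3]}
        return s

    def test_accuracy_arithmetic(self):
        s = self._summary((850, 43, 65, 42))
        assert s.n_overlap == 1000
        assert s.accuracy_pct == pytest.approx(89.3)
        assert s.error_pct == pytest.approx(10.7)
        assert s.accuracy_pct + s.error_pct == pytest.approx(100.0, abs=1e-12)

    def test_adjusted_accuracy_counts_ambiguous_correct(self):
        s = self._summary((850, 43, 20, 87), n_ambiguous=70)
        assert s.accuracy_pct == pytest.approx(89.3)
        assert s.adjusted_accuracy_pct == pytest.approx(96.3)
        assert s.adjusted_accuracy_pct >= s.accuracy_pct

    def test_all_complete(self):
        s = self._summary((5, 0, 0, 0))
        assert s.accuracy_pct == 100.0
        assert s.adjusted_accuracy_pct == 100.0

    def test_empty_stratum_is_nan(self):
        s = self._summary((0, 0, 0, 0))
        assert np.isnan(s.accuracy_pct) and np.isnan(s.adjusted_accuracy_pct)

    def test_end_to_end_strata_and_exclusion(self):
        # two autosomal variants (one complete, one half via monomorphic
        # imputation), one X variant flipped, one uninformative variant
        imp = make_gm(
            [[0, 0, 2, -1], [1, 0, 2, -1]],
            alleles=[("A", "G"), ("A", "G"), ("T", "C"), ("A", "G")])
        imp.variants[2] = make_variant(chrom="X", pos=300, vid="x1",
                                       alleles=("T", "C"))
        imp.variants[3] = make_variant(pos=400, vid="v3")
        tru = make_gm(
            [[0, 0, 2, 1], [1, 1, 2, 1]],
            alleles=[("A", "G"), ("A", "G"), ("A", "G"), ("A", "G")])
        tru.variants[2] = make_variant(chrom="X", pos=300, vid="x1t",
                                       alleles=("A", "G"))
        tru.variants[3] = make_variant(pos=400, vid="v3t")
        summaries = {s.stratum: s for s in summarize_concordance(imp, tru)}
        assert summaries["autosomes"].counts[MatchClass.COMPLETE] == 1
        assert summaries["autosomes"].counts[MatchClass.HALF] == 1
        assert summaries["autosomes"].n_excluded == 1
        assert summaries["X"].counts[MatchClass.FLIP] == 1
        # partition: counts + excluded reconstruct the shared-variant total
        s_all = summaries["all"]
        assert s_all.n_overlap + s_all.n_excluded == 4

    def test_classify_variants_requires_alignment(self):
        imp = make_gm(np.zeros((1, 2)))
        tru = make_gm(np.zeros((1, 1)))
        with pytest.raises(ContractError):
            classify_variants(imp, tru)
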