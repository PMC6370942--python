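"""The admixed-cohort generator and its corruption channels."""

import numpy as np
import pandas as pd
import pytest

from impuconcord import (
    MISSING,
    CallingConfig,
    ContractError,
    MatchClass,
    SimulationConfig,
    call_genotypes,
    classify_variants,
    corrupt_as_imputed,
    expected_no_call_fraction,
    extract_overlap,
    simulate_cohort,
    split_arrays,
    summarize_concordance,
)


class TestSimulateCohort:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_samples=30, n_variants=200, seed=77)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a.samples == b.samples
        assert [v.key for v in a.variants] == [v.key for v in b.variants]
        assert (a.calls == b.calls).all()
        c = simulate_cohort(cfg.with_(seed=78))
        assert not (a.calls == c.calls).all()

    def test_x_fraction_and_valid_values(self, small_cohort):
        chroms = small_cohort.chroms
        assert (chroms == "X").sum() == round(0.05 * small_cohort.n_variants)
        assert set(np.unique(small_cohort.calls)) <= {0, 1, 2}

    def test_concentrated_alpha_restores_hwe(self):
        """With admixture collapsed onto one population every sample shares
        the same variant frequency, so per-variant heterozygosity matches
        the binomial expectation 2p(1-p) (no Wahlund deficit)."""
        cfg = SimulationConfig(n_samples=400, n_variants=500, seed=5,
                               alpha=np.array([1000.0, 1e-3, 1e-3, 1e-3, 1e-3]))
        gm = simulate_cohort(cfg)
        freq = gm.calls.mean(axis=0) / 2.0
        obs_het = (gm.calls == 1).mean(axis=0)
        exp_het = 2 * freq * (1 - freq)
        # pooled across variants; 3 SE of the mean difference
        diff = obs_het - exp_het
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se + 1e-3

    def test_low_fst_limit_keeps_ancestral_frequency_spread(self):
        """As F_ST -> 0 population frequencies collapse onto the ancestral
        Uniform(p_range) draw, whose mean B-allele frequency is 0.5."""
        cfg = SimulationConfig(n_samples=200, n_variants=800, seed=6, fst=1e-3)
        gm = simulate_cohort(cfg)
        freq = gm.calls.mean(axis=0) / 2.0
        se = freq.std(ddof=1) / np.sqrt(len(freq))
        assert abs(freq.mean() - 0.5) < 3 * se


class TestSplitArrays:
    def test_shared_counts_and_partition(self, small_cohort):
        gm_a, gm_b, shared = split_arrays(small_cohort, 0.5, 0.2, 0.3, seed=1)
        n_shared_s = len(set(gm_a.samples) & set(gm_b.samples))
        assert n_shared_s == round(0.5 * small_cohort.n_samples)
        assert len(shared) == round(0.2 * small_cohort.n_variants)
        shared_keys = {v.key for v in shared}
        a_keys = {v.key for v in gm_a.variants}
        b_keys = {v.key for v in gm_b.variants}
        assert shared_keys == a_keys & b_keys
        # arrays jointly cover the cohort, each side ordered as the input
        assert a_keys | b_keys == {v.key for v in small_cohort.variants}

    def test_degenerate_fractions_rejected(self, small_cohort):
        with pytest.raises(ContractError):
            split_arrays(small_cohort, 0.0, 0.2, 0.3)
        with pytest.raises(ContractError):
            split_arrays(small_cohort, 0.5, 1.0, 0.3)


class TestCorruptAsImputed:
    def test_clean_channel_gives_perfect_accuracy(self):
        cfg = SimulationConfig(n_samples=40, n_variants=300, seed=2)
        truth = simulate_cohort(cfg)
        pgm, labels = corrupt_as_imputed(truth, cfg)
        assert (labels["label"] == "clean").all()
        gm, _ = call_genotypes(pgm, CallingConfig(threshold=0.0))
        imp, tru, _ = extract_overlap(gm, truth)
        pooled = summarize_concordance(imp, tru)[0]
        assert pooled.accuracy_pct == pytest.approx(100.0)

    def test_all_flip_still_counts_as_match(self):
        cfg = SimulationConfig(n_samples=40, n_variants=300, seed=3,
                               flip_rate=1.0, palindromic_frac=0.0)
        truth = simulate_cohort(cfg)
        pgm, labels = corrupt_as_imputed(truth, cfg)
        assert (labels["label"] == "flip").all()
        gm, _ = call_genotypes(pgm, CallingConfig(threshold=0.0))
        imp, tru, _ = extract_overlap(gm, truth)
        pooled = summarize_concordance(imp, tru)[0]
        assert pooled.counts[MatchClass.FLIP] == pooled.n_overlap
        assert pooled.accuracy_pct == pytest.approx(100.0)

    def test_flip_reassigned_on_palindromic_variants(self):
        cfg = SimulationConfig(n_samples=20, n_variants=400, seed=4,
                               flip_rate=0.5, palindromic_frac=0.5)
        truth = simulate_cohort(cfg)
        pgm, labels = corrupt_as_imputed(truth, cfg)
        pal = np.array([v.is_palindromic for v in truth.variants])
        assert not ((labels["label"] == "flip") & pal).any()
        assert labels.loc[labels["reassigned"], "label"].eq("clean").all()
        # flipped output variants carry complemented alleles at same key
        for v_out, v_in, lab in zip(pgm.variants, truth.variants, labels["label"]):
            assert v_out.key == v_in.key
            if lab == "flip":
                assert set(v_out.alleles) != set(v_in.alleles)

    def test_label_recovery_is_exact_at_zero_threshold(self, corrupt_cfg):
        truth = simulate_cohort(corrupt_cfg)
        pgm, labels = corrupt_as_imputed(truth, corrupt_cfg)
        gm, _ = call_genotypes(pgm, CallingConfig(threshold=0.0))
        imp, tru, _ = extract_overlap(gm, truth)
        classified = classify_variants(imp, tru).merge(
            labels[["vid", "label"]], on="vid")
        got = classified.set_index("vid")["match_class"]
        lab = classified.set_index("vid")["label"]
        assert (got[lab == "flip"] == "FLIP").all()
        assert (got[lab == "error"] == "NONE").all()
        # monomorphic collapse half-matches unless truth itself is
        # monomorphic for the major allele (then the sets coincide)
        assert got[lab == "mono"].isin(["HALF", "COMPLETE"]).all()
        assert (got[lab == "clean"] == "COMPLETE").all()

    def test_injected_rates_within_binomial_se(self):
        cfg = SimulationConfig(n_samples=50, n_variants=4000, seed=8,
                               error_rate=0.10, flip_rate=0.05, mono_rate=0.02,
                               palindromic_frac=0.0)
        _, labels = corrupt_as_imputed(simulate_cohort(cfg), cfg)
        n = len(labels)
        for label, rate in (("error", 0.10), ("flip", 0.05), ("mono", 0.02)):
            got = (labels["label"] == label).mean()
            se = np.sqrt(rate * (1 - rate) / n)
            assert abs(got - rate) < 3 * se, label

    def test_missing_truth_becomes_zero_triple(self):
        cfg = SimulationConfig(n_samples=3, n_variants=10, seed=9)
        truth = simulate_cohort(cfg)
        truth.calls[0, 0] = MISSING
        pgm, _ = corrupt_as_imputed(truth, cfg)
        np.testing.assert_array_equal(pgm.probs[0, 0], (0.0, 0.0, 0.0))
        assert pgm.probs[1:, 0].sum(axis=1) == pytest.approx(1.0)

    def test_quality_attenuated_on_corrupted_variants(self, corrupt_cfg):
        truth = simulate_cohort(corrupt_cfg)
        pgm, labels = corrupt_as_imputed(truth, corrupt_cfg)
        q = pd.Series(pgm.quality, index=labels["label"].values)
        assert q[q.index.isin(["error", "mono"])].median() < q["clean"].median()


class TestExpectedNoCall:
    @pytest.mark.parametrize("threshold, expected", [
        (0.5, 0.0), (0.7, 0.4), (1.0, 1.0), (0.4, 0.0), (0.9, 0.8),
    ])
    def test_uniform_cdf(self, threshold, expected):
        cfg = SimulationConfig(gp_max_range=(0.5, 1.0))
        assert expected_no_call_fraction(cfg, threshold) == pytest.approx(expected)

    def test_observed_matches_expected(self):
        cfg = SimulationConfig(n_samples=60, n_variants=700, seed=10)
        pgm, _ = corrupt_as_imputed(simulate_cohort(cfg), cfg)
        for t in (0.6, 0.7, 0.85):
            _, ncf = call_genotypes(pgm, CallingConfig(threshold=t))
            exp = expected_no_call_fraction(cfg, t)
            se = np.sqrt(exp * (1 - exp) / (60 * 700))
            assert abs(ncf - exp) < 3 * se
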