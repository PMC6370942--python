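"""Synthetic admixed-cohort generator.

Stands in for restricted array data: truth genotypes come from a
Balding-Nichols model with Dirichlet admixture (K ancestral populations,
per-population drift F_ST, per-sample admixture proportions q ~ Dir(alpha)),
and a pseudo-imputation step corrupts a copy of the truth into posterior
probability triples with controllable failure channels:

* ``clean`` — posterior mass on the true genotype;
* ``error`` — the allele pair is replaced by the disjoint pair and every
  sample is concentrated on one homozygous genotype, so the observed allele
  set shares nothing with the truth (a no-match; a heterozygous draw would
  be indistinguishable from a strand flip, so the channel stays homozygous);
* ``flip``  — alleles strand-complemented, genotype codes preserved
  (skipped on palindromic variants, where a flip is unobservable);
* ``mono``  — every sample concentrated on the homozygous-major genotype,
  collapsing the variant to monomorphic (a half-match against a
  polymorphic truth).

The winning posterior is drawn Uniform(gp_max_range) so the no-call
fraction under a calling threshold has a closed form; per-variant quality
scores are a logistic function of MAF with noise, attenuated on corrupted
variants.  All draws flow from the config seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import (
    AUTOSOMES,
    COMPLEMENT,
    MISSING,
    ContractError,
    GenotypeMatrix,
    ProbGenotypeMatrix,
    SimulationConfig,
    VariantRecord,
)

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"))
_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("C", "A"), ("A", "G"), ("G", "A"),
    ("C", "T"), ("T", "C"), ("G", "T"), ("T", "G"),
)

LABEL_CLEAN, LABEL_ERROR, LABEL_FLIP, LABEL_MONO = "clean", "error", "flip", "mono"


def _make_variants(cfg: SimulationConfig, rng: np.random.Generator) -> list[VariantRecord]:
    n = cfg.n_variants
    n_x = int(round(cfg.frac_x * n))
    chroms = [AUTOSOMES[j % len(AUTOSOMES)] for j in range(n - n_x)] + ["X"] * n_x
    pal = rng.random(n) < cfg.palindromic_frac
    pair_idx_p = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n)
    pair_idx_n = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=n)
    counters: dict[str, int] = {}
    variants = []
    for j, c in enumerate(chroms):
        counters[c] = counters.get(c, 0) + 1
        pair = (_PALINDROMIC_PAIRS[pair_idx_p[j]] if pal[j]
                else _NONPALINDROMIC_PAIRS[pair_idx_n[j]])
        variants.append(VariantRecord(chrom=c, pos=counters[c] * 1000,
                                      vid=f"var{j:07d}", alleles=pair))
    return variants


def simulate_cohort(cfg: SimulationConfig) -> GenotypeMatrix:
    """Draw a truth genotype matrix under Balding-Nichols admixture.

    Per variant j: ancestral frequency p_j ~ Uniform(p_range) and
    population frequencies p_kj ~ Beta(p_j (1-F)/F, (1-p_j)(1-F)/F); per
    sample i: admixture q_i ~ Dirichlet(alpha) and genotype
    ~ Binomial(2, sum_k q_ik p_kj).  The X chromosome is simulated diploid
    for every sample.  Deterministic under cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    variants = _make_variants(cfg, rng)
    p = rng.uniform(*cfg.p_range, size=cfg.n_variants)
    ratio = (1.0 - cfg.fst) / cfg.fst
    pk = rng.beta(p * ratio, (1.0 - p) * ratio,
                  size=(cfg.k, cfg.n_variants))  # (K, V)
    q = rng.dirichlet(cfg.alpha, size=cfg.n_samples)  # (N, K)
    pi = q @ pk  # (N, V)
    calls = rng.binomial(2, pi).astype(np.int8)
    samples = [f"S{i:05d}" for i in range(cfg.n_samples)]
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


def split_arrays(truth: GenotypeMatrix, frac_shared_samples: float,
                 frac_shared_variants: float, frac_array_a_only: float,
                 seed: int = 0
                 ) -> tuple[GenotypeMatrix, GenotypeMatrix, list[VariantRecord]]:
    """Split one truth cohort into two partially overlapping "arrays".

    Array A plays the sparser imputation-input role, array B the denser
    truth role.  A known shared-sample subset and the shared-variant list
    (the pre-imputation overlap) are returned for overlap testing.
    Non-shared samples and variants are split between the arrays;
    ``frac_array_a_only`` controls the variant share going to A.
    """
    for name, frac in (("frac_shared_samples", frac_shared_samples),
                       ("frac_shared_variants", frac_shared_variants),
                       ("frac_array_a_only", frac_array_a_only)):
        if not (0.0 < frac < 1.0):
            raise ContractError(f"{name} must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_s, n_v = truth.n_samples, truth.n_variants

    s_perm = rng.permutation(n_s)
    n_shared_s = int(round(frac_shared_samples * n_s))
    shared_s = s_perm[:n_shared_s]
    rest = s_perm[n_shared_s:]
    a_only_s, b_only_s = rest[: len(rest) // 2], rest[len(rest) // 2:]

    v_perm = rng.permutation(n_v)
    n_shared_v = int(round(frac_shared_variants * n_v))
    shared_v = v_perm[:n_shared_v]
    rest_v = v_perm[n_shared_v:]
    n_a_only = int(round(frac_array_a_only * len(rest_v)))
    a_only_v, b_only_v = rest_v[:n_a_only], rest_v[n_a_only:]

    a_samples = np.sort(np.concatenate([shared_s, a_only_s]))
    b_samples = np.sort(np.concatenate([shared_s, b_only_s]))
    a_variants = np.sort(np.concatenate([shared_v, a_only_v]))
    b_variants = np.sort(np.concatenate([shared_v, b_only_v]))
    if min(len(a_samples), len(b_samples), len(a_variants), len(b_variants)) == 0:
        raise ContractError("degenerate empty split")

    gm_a = truth.subset(sample_idx=a_samples, variant_idx=a_variants)
    gm_b = truth.subset(sample_idx=b_samples, variant_idx=b_variants)
    shared = [truth.variants[j] for j in np.sort(shared_v)]
    return gm_a, gm_b, shared


def _disjoint_pair(alleles: tuple[str, str]) -> tuple[str, str]:
    rest = sorted(set("ACGT") - set(alleles))
    return (rest[0], rest[1])


def corrupt_as_imputed(truth: GenotypeMatrix, cfg: SimulationConfig
                       ) -> tuple[ProbGenotypeMatrix, pd.DataFrame]:
    """Corrupt truth genotypes into pseudo-imputed posterior probabilities.

    Every variant is assigned a label in {clean, error, flip, mono} with
    probabilities (1-e-f-m, e, f, m); a flip drawn on a palindromic variant
    is reassigned to clean (flagged in the label table, column
    ``reassigned``).  Returns the probabilistic matrix plus the per-variant
    injected-label table — the ground truth the concordance evaluator
    should recover.
    """
    e, f, m = cfg.error_rate, cfg.flip_rate, cfg.mono_rate
    rng = np.random.default_rng((cfg.seed, 7919))
    n_s, n_v = truth.n_samples, truth.n_variants

    u = rng.random(n_v)
    labels = np.full(n_v, LABEL_CLEAN, dtype=object)
    labels[u < e] = LABEL_ERROR
    labels[(u >= e) & (u < e + f)] = LABEL_FLIP
    labels[(u >= e + f) & (u < e + f + m)] = LABEL_MONO

    reassigned = np.zeros(n_v, dtype=bool)
    pal = np.array([v.is_palindromic for v in truth.variants])
    hit = (labels == LABEL_FLIP) & pal
    labels[hit] = LABEL_CLEAN
    reassigned[hit] = True

    # Per-variant target genotype construction
    calls = truth.calls
    called = calls != MISSING
    n_called = called.sum(axis=0)
    dose = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(n_called > 0, dose / (2.0 * n_called), 0.0)
    major_geno = np.where(freq_b > 0.5, 2, 0).astype(np.int8)
    error_geno = rng.choice(np.array([0, 2], dtype=np.int8), size=n_v)

    target = calls.copy()
    is_err = labels == LABEL_ERROR
    is_mono = labels == LABEL_MONO
    target[:, is_err] = error_geno[is_err]
    target[:, is_mono] = major_geno[is_mono]

    variants_out = []
    for j, v in enumerate(truth.variants):
        if labels[j] == LABEL_ERROR:
            alleles = _disjoint_pair(v.alleles)
        elif labels[j] == LABEL_FLIP:
            alleles = (COMPLEMENT[v.alleles[0]], COMPLEMENT[v.alleles[1]])
        else:
            alleles = v.alleles
        variants_out.append(VariantRecord(chrom=v.chrom, pos=v.pos, vid=v.vid,
                                          alleles=alleles))

    # Posterior triples: winning mass on the target genotype, remainder
    # split randomly between the two losers; missing targets -> zero triple.
    lo, hi = cfg.gp_max_range
    mstar = rng.uniform(lo, hi, size=(n_s, n_v))
    split = rng.random((n_s, n_v))
    rem = 1.0 - mstar
    probs = np.zeros((n_s, n_v, 3))
    t = np.where(target == MISSING, 0, target).astype(np.intp)
    np.put_along_axis(probs, t[..., None], mstar[..., None], axis=2)
    np.put_along_axis(probs, ((t + 1) % 3)[..., None], (split * rem)[..., None], axis=2)
    np.put_along_axis(probs, ((t + 2) % 3)[..., None], ((1 - split) * rem)[..., None],
                      axis=2)
    probs[target == MISSING] = 0.0

    # Quality correlated with MAF; attenuated on corrupted variants
    maf = np.minimum(freq_b, 1.0 - freq_b)
    noise = rng.normal(0.0, cfg.quality_noise_sd, size=n_v)
    quality = expit(cfg.quality_maf_slope * maf + cfg.quality_intercept + noise)
    quality = np.where(is_err | is_mono, 0.5 * quality, quality)
    quality = np.clip(quality, 0.0, 1.0)

    pgm = ProbGenotypeMatrix(samples=list(truth.samples), variants=variants_out,
                             probs=probs, quality=quality)
    label_table = pd.DataFrame({
        "vid": [v.vid for v in truth.variants],
        "chrom": [v.chrom for v in truth.variants],
        "pos": [v.pos for v in truth.variants],
        "label": labels,
        "reassigned": reassigned,
    })
    return pgm, label_table


def expected_no_call_fraction(cfg: SimulationConfig, threshold: float) -> float:
    """Closed-form clean-channel no-call fraction at a calling threshold.

    With the winning posterior ~ Uniform(lo, hi) and an inclusive
    threshold t, P(no-call) = 0 for t <= lo, (t-lo)/(hi-lo) inside the
    interval, and 1 for t >= hi.
    """
    lo, hi = cfg.gp_max_range
    if threshold <= lo:
        return 0.0
    if threshold >= hi:
        return 1.0
    return (threshold - lo) / (hi - lo)
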