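import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles importable

from impuconcord import (
    GenotypeMatrix,
    SimulationConfig,
    VariantRecord,
    simulate_cohort,
)


def make_variant(chrom="1", pos=100, vid="rs1", alleles=("A", "G")) -> VariantRecord:
    return VariantRecord(chrom=chrom, pos=pos, vid=vid, alleles=alleles)


def make_gm(calls, alleles=None, chrom="1", samples=None) -> GenotypeMatrix:
    """Small hand-built matrix; ``calls`` is (n_samples, n_variants)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_s, n_v = calls.shape
    alleles = alleles or [("A", "G")] * n_v
    variants = [make_variant(chrom=chrom, pos=100 * (j + 1), vid=f"v{j}",
                             alleles=alleles[j]) for j in range(n_v)]
    samples = samples or [f"s{i}" for i in range(n_s)]
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


@pytest.fixture(scope="session")
def small_cohort() -> GenotypeMatrix:
    return simulate_cohort(SimulationConfig(n_samples=60, n_variants=600, seed=42))


@pytest.fixture(scope="session")
def corrupt_cfg() -> SimulationConfig:
    return SimulationConfig(n_samples=60, n_variants=600, seed=42,
                            error_rate=0.10, flip_rate=0.05, mono_rate=0.02)


def build_cascade_fixture(seed: int = 11):
    """Matrix where a heterozygosity-outlier sample removed in pass 1
    pushes one variant's missingness above 2% in pass 2.

    50 samples x 60 variants, B-allele frequencies near 0.5.  Sample
    ``het_outlier`` is heterozygous everywhere (F ~ -1).  Variant
    ``cascade`` is missing for exactly one other sample: 1/50 = 2% is not
    above the threshold, but 1/49 after the outlier's removal is.
    """
    rng = np.random.default_rng(seed)
    n_s, n_v = 50, 60
    calls = rng.binomial(2, 0.5, size=(n_s, n_v)).astype(np.int8)
    calls[0, :] = 1           # all-het outlier
    calls[1, 0] = -1          # the planted missing cell on the cascade variant
    gm = make_gm(calls)
    return gm, gm.samples[0], gm.variants[0].vid
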