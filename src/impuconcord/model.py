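"""Domain types for the imputation-concordance pipeline.

Genotypes are stored as counts of the B allele (the second allele of the
variant's pair, the ALT allele in VCF terms): 0, 1, 2, with ``MISSING``
(-1) for no-calls.  Probabilistic genotypes are posterior triples
(p0, p1, p2) for the three genotype states of a biallelic variant, plus a
per-variant imputation quality score in [0, 1] (INFO score or r-squared,
depending on the imputation engine; NaN when the engine reported none).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

MISSING: int = -1
"""Sentinel for a missing hard call."""

AUTOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23))
VALID_CHROMS: frozenset[str] = frozenset(AUTOSOMES) | {"X"}
BASES: frozenset[str] = frozenset("ACGT")

COMPLEMENT: dict[str, str] = {"A": "T", "T": "A", "C": "G", "G": "C"}

_PALINDROMIC_SETS = (frozenset("AT"), frozenset("GC"))


class ContractError(ValueError):
    """A data contract (type invariant, precondition) was violated."""


class ParseError(ContractError):
    """An input file could not be parsed."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic site.

    ``alleles`` is stored as an ordered (A, B) pair because hard calls
    count copies of the B allele, but two records are the same *site*
    regardless of allele order.
    """

    chrom: str
    pos: int
    vid: str
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if self.chrom not in VALID_CHROMS:
            raise ContractError(f"invalid chromosome {self.chrom!r}")
        if not (isinstance(self.pos, (int, np.integer)) and self.pos >= 1):
            raise ContractError(f"position must be a 1-based integer, got {self.pos!r}")
        a, b = self.alleles
        if a == b:
            raise ContractError(f"{self.vid}: alleles must be distinct, got {a!r}/{b!r}")
        for al in (a, b):
            if len(al) < 1 or not set(al) <= BASES:
                raise ContractError(f"{self.vid}: invalid allele {al!r}")

    @property
    def is_snp(self) -> bool:
        return len(self.alleles[0]) == 1 and len(self.alleles[1]) == 1

    @property
    def is_palindromic(self) -> bool:
        return frozenset(self.alleles) in _PALINDROMIC_SETS

    @property
    def key(self) -> tuple[str, int]:
        """(chrom, pos) — the cross-dataset pairing key."""
        return (self.chrom, self.pos)


def complement_alleles(alleles: Iterable[str]) -> frozenset[str]:
    """Base-complement image of an allele set (single-base alleles only)."""
    out = set()
    for al in alleles:
        if al not in COMPLEMENT:
            raise ContractError(f"cannot complement allele {al!r}")
        out.add(COMPLEMENT[al])
    return frozenset(out)


def _check_unique(items: Sequence, what: str) -> None:
    if len(set(items)) != len(items):
        raise ContractError(f"duplicate {what}")


@dataclass
class GenotypeMatrix:
    """Hard-call genotypes: samples x variants in {0, 1, 2, MISSING}."""

    samples: list[str]
    variants: list[VariantRecord]
    calls: np.ndarray  # int8, shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ContractError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        _check_unique(self.samples, "sample IDs")
        _check_unique([v.key for v in self.variants], "(chrom, pos) keys")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ContractError("calls contain values outside {0,1,2,MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        """Row/column subset preserving the given index order."""
        si = (np.arange(self.n_samples) if sample_idx is None
              else np.asarray(sample_idx, dtype=np.intp))
        vi = (np.arange(self.n_variants) if variant_idx is None
              else np.asarray(variant_idx, dtype=np.intp))
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            variants=[self.variants[j] for j in vi],
            calls=self.calls[np.ix_(si, vi)],
        )

    def genotyping_rate(self) -> float:
        if self.calls.size == 0:
            return float("nan")
        return float((self.calls != MISSING).mean())


@dataclass
class ProbGenotypeMatrix:
    """Posterior genotype probabilities plus per-variant quality scores.

    Each (sample, variant) entry is a triple (p0, p1, p2) with p_i >= 0 and
    sum within 1 +/- 1e-3; an all-zero triple is permitted and denotes a
    no-call at the probability level (Oxford GEN convention).  ``quality``
    holds the per-variant INFO/r2 score, NaN where undefined.
    """

    samples: list[str]
    variants: list[VariantRecord]
    probs: np.ndarray  # float64, shape (n_samples, n_variants, 3)
    quality: np.ndarray  # float64, shape (n_variants,)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.quality = np.asarray(self.quality, dtype=np.float64)
        n_s, n_v = len(self.samples), len(self.variants)
        if self.probs.shape != (n_s, n_v, 3):
            raise ContractError(
                f"probs shape {self.probs.shape} != ({n_s}, {n_v}, 3)"
            )
        if self.quality.shape != (n_v,):
            raise ContractError("quality must have one entry per variant")
        _check_unique(self.samples, "sample IDs")
        _check_unique([v.key for v in self.variants], "(chrom, pos) keys")
        if (self.probs < 0).any():
            raise ContractError("negative genotype probability")
        tot = self.probs.sum(axis=2)
        ok = (np.abs(tot - 1.0) <= 1e-3) | (tot == 0.0)
        if not ok.all():
            raise ContractError("genotype probabilities do not sum to 1 +/- 1e-3")
        q = self.quality[~np.isnan(self.quality)]
        if ((q < 0) | (q > 1)).any():
            raise ContractError("quality scores must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    def subset_variants(self, variant_idx) -> "ProbGenotypeMatrix":
        vi = np.asarray(variant_idx, dtype=np.intp)
        return ProbGenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[j] for j in vi],
            probs=self.probs[:, vi, :],
            quality=self.quality[vi],
        )


def _check_fraction(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ContractError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class QCThresholds:
    """Array-QC thresholds.

    Defaults follow standard GWAS practice: drop samples missing more than
    10% of genotypes, variants with more than 2% missingness or MAF below
    5%, samples whose heterozygosity-derived inbreeding statistic F lies
    more than 3 SD from the cohort mean, and sex-discordant samples judged
    by X-chromosome F (< 0.2 female, > 0.8 male).
    """

    sample_missing_max: float = 0.10
    variant_missing_max: float = 0.02
    maf_min: float = 0.05
    het_sd_multiplier: float = 3.0
    sex_f_female_max: float = 0.2
    sex_f_male_min: float = 0.8

    def __post_init__(self) -> None:
        for name in ("sample_missing_max", "variant_missing_max", "maf_min",
                     "sex_f_female_max", "sex_f_male_min"):
            _check_fraction(getattr(self, name), name)
        if self.het_sd_multiplier <= 0:
            raise ContractError("het_sd_multiplier must be positive")


@dataclass(frozen=True)
class CallingConfig:
    """Hard-calling configuration (posterior threshold default 0.7)."""

    threshold: float = 0.7
    drop_indels: bool = True
    uncalled_variant_rule: str = "all_missing"  # or "any_missing"

    def __post_init__(self) -> None:
        _check_fraction(self.threshold, "threshold")
        if self.uncalled_variant_rule not in ("all_missing", "any_missing"):
            raise ContractError(
                f"unknown uncalled_variant_rule {self.uncalled_variant_rule!r}"
            )


@dataclass(frozen=True)
class MafBinning:
    """Half-open MAF bins (lo, hi], first bin closed at 0."""

    edges: tuple[float, ...] = (0.0, 0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or (np.diff(e) <= 0).any():
            raise ContractError("bin edges must be strictly increasing")
        if e[0] != 0.0 or e[-1] != 0.5:
            raise ContractError("MAF bin edges must span [0, 0.5]")

    @property
    def labels(self) -> list[str]:
        e = self.edges
        return [f"({e[i]:g},{e[i + 1]:g}]" for i in range(len(e) - 1)]


def sac_like_alpha() -> np.ndarray:
    """Dirichlet concentration preset for a five-way admixed cohort with a
    dominant first (KhoeSan-like) ancestral component."""
    return np.array([4.4, 3.0, 1.6, 0.6, 0.4])


@dataclass
class SimulationConfig:
    """All generative parameters of the synthetic admixed cohort.

    The cohort model is Balding-Nichols with Dirichlet admixture: variant
    ancestral frequency p ~ Uniform(p_range); population frequencies
    p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F); per-sample admixture q ~ Dir(alpha);
    genotype ~ Binomial(2, sum_k q_k p_k).  Corruption rates e/f/m control
    the fraction of variants with discordant alleles, strand flips, and
    monomorphic collapse in the pseudo-imputed output.
    """

    n_samples: int = 200
    n_variants: int = 5000
    frac_x: float = 0.05
    k: int = 5
    fst: float = 0.1
    alpha: np.ndarray = field(default_factory=sac_like_alpha)
    p_range: tuple[float, float] = (0.05, 0.95)
    palindromic_frac: float = 0.2
    error_rate: float = 0.0
    flip_rate: float = 0.0
    mono_rate: float = 0.0
    gp_max_range: tuple[float, float] = (0.5, 1.0)
    quality_maf_slope: float = 8.0
    quality_intercept: float = 0.0
    quality_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.n_samples < 1 or self.n_variants < 1:
            raise ContractError("n_samples and n_variants must be positive")
        _check_fraction(self.frac_x, "frac_x")
        _check_fraction(self.palindromic_frac, "palindromic_frac")
        if not (0.0 < self.fst < 1.0):
            raise ContractError("fst must lie in (0, 1)")
        if self.alpha.shape != (self.k,) or (self.alpha <= 0).any():
            raise ContractError("alpha must be a strictly positive vector of length k")
        for name in ("error_rate", "flip_rate", "mono_rate"):
            _check_fraction(getattr(self, name), name)
        if self.error_rate + self.flip_rate + self.mono_rate > 1.0:
            raise ContractError("error_rate + flip_rate + mono_rate must be <= 1")
        lo, hi = self.p_range
        if not (0.0 < lo < hi < 1.0):
            raise ContractError("p_range must satisfy 0 < lo < hi < 1")
        lo, hi = self.gp_max_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ContractError("gp_max_range must satisfy 0 <= lo < hi <= 1")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)
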