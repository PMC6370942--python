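"""Allele-level concordance between imputed and truth genotype data.

Matching is variant-level on *observed* allele sets: a variant whose calls
are all homozygous for one allele contributes a singleton set, so a
monomorphically imputed site can only half-match a polymorphic truth site.
The four match classes are

* COMPLETE — observed sets identical;
* FLIP     — the base-complement of the imputed set equals the truth set
             (alleles correct, strand swapped);
* HALF     — exactly one allele shared, in direct orientation;
* NONE     — no allele shared and not a flip.

A NONE between two palindromic pairs ({A,T} vs {G,C}) is flagged
*ambiguous*: strand orientation alone could explain it.  A palindromic
pair matched against itself resolves as COMPLETE (a flip is unobservable
there).  Flips count as matches for accuracy, because a flipped variant
can be aligned to a reference by strand-flipping; accuracy is therefore
100 * (COMPLETE + FLIP) / n_overlap, and the genome-wide error rate is its
complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .model import (
    BASES,
    MISSING,
    ContractError,
    GenotypeMatrix,
    VariantRecord,
    complement_alleles,
)

_PALINDROMES = (frozenset("AT"), frozenset("GC"))


class MatchClass(str, Enum):
    COMPLETE = "COMPLETE"
    FLIP = "FLIP"
    HALF = "HALF"
    NONE = "NONE"


@dataclass(frozen=True)
class MatchResult:
    match_class: MatchClass
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.ambiguous and self.match_class is not MatchClass.NONE:
            raise ContractError("only NONE matches may be ambiguous")


@dataclass
class ConcordanceSummary:
    """Aggregated match counts and accuracy statistics for one stratum."""

    stratum: str
    counts: dict[MatchClass, int] = field(default_factory=dict)
    n_ambiguous: int = 0
    n_excluded: int = 0

    @property
    def n_overlap(self) -> int:
        return sum(self.counts.values())

    @property
    def accuracy_pct(self) -> float:
        n = self.n_overlap
        if n == 0:
            return float("nan")
        good = self.counts.get(MatchClass.COMPLETE, 0) + self.counts.get(MatchClass.FLIP, 0)
        return 100.0 * good / n

    @property
    def error_pct(self) -> float:
        acc = self.accuracy_pct
        return acc if np.isnan(acc) else 100.0 - acc

    @property
    def adjusted_accuracy_pct(self) -> float:
        """Accuracy with ambiguous no-matches counted as correct."""
        n = self.n_overlap
        if n == 0:
            return float("nan")
        good = (self.counts.get(MatchClass.COMPLETE, 0)
                + self.counts.get(MatchClass.FLIP, 0) + self.n_ambiguous)
        return 100.0 * good / n


def observed_alleles(variant: VariantRecord, calls: np.ndarray) -> frozenset[str]:
    """Alleles actually carried by the called genotypes of one variant.

    Returns the full {A, B} pair when both alleles have nonzero counts,
    the observed singleton when the variant is monomorphic in these calls.
    """
    calls = np.asarray(calls)
    called = calls[calls != MISSING]
    if called.size == 0:
        raise ContractError(f"{variant.vid}: uninformative variant (all calls missing)")
    a, b = variant.alleles
    n_b = int(called.sum())
    n_a = int(2 * called.size - n_b)
    if n_a > 0 and n_b > 0:
        return frozenset((a, b))
    return frozenset((b,)) if n_b > 0 else frozenset((a,))


def classify_match(imputed_alleles, truth_alleles) -> MatchResult:
    """Classify a pair of observed allele sets into the four-class taxonomy."""
    s_i, s_t = frozenset(imputed_alleles), frozenset(truth_alleles)
    for s in (s_i, s_t):
        if not (1 <= len(s) <= 2) or not s <= BASES:
            raise ContractError(f"invalid allele set {set(s)}")
    if s_i == s_t:
        return MatchResult(MatchClass.COMPLETE)
    if complement_alleles(s_i) == s_t:
        return MatchResult(MatchClass.FLIP)
    if len(s_i & s_t) == 1:
        return MatchResult(MatchClass.HALF)
    ambiguous = s_i in _PALINDROMES and s_t in _PALINDROMES
    return MatchResult(MatchClass.NONE, ambiguous=ambiguous)


def extract_overlap(imputed: GenotypeMatrix, truth: GenotypeMatrix,
                    pre_imputation_variants=None
                    ) -> tuple[GenotypeMatrix, GenotypeMatrix, dict[str, int]]:
    """Restrict both matrices to shared samples and shared (chrom, pos) sites.

    Variants present in ``pre_imputation_variants`` (VariantRecords or
    (chrom, pos) pairs — sites genotyped on both arrays before imputation)
    are removed from both sides so they cannot inflate the accuracy.
    Ordering follows the imputed matrix.  Returns the two aligned matrices
    and the per-chromosome overlap size.
    """
    if imputed.n_variants == 0 or truth.n_variants == 0:
        raise ContractError("empty input matrix")
    shared_samples = [s for s in imputed.samples if s in set(truth.samples)]
    if not shared_samples:
        raise ContractError("zero shared samples")

    exclude: set[tuple[str, int]] = set()
    if pre_imputation_variants is not None:
        for v in pre_imputation_variants:
            exclude.add(v.key if isinstance(v, VariantRecord) else (str(v[0]), int(v[1])))

    truth_by_key = {v.key: j for j, v in enumerate(truth.variants)}
    imp_idx, tru_idx = [], []
    for j, v in enumerate(imputed.variants):
        if v.key in exclude:
            continue
        tj = truth_by_key.get(v.key)
        if tj is not None:
            imp_idx.append(j)
            tru_idx.append(tj)
    if not imp_idx:
        raise ContractError("zero shared variants")

    t_sample_pos = {s: i for i, s in enumerate(truth.samples)}
    i_sample_pos = {s: i for i, s in enumerate(imputed.samples)}
    imp_s = [i_sample_pos[s] for s in shared_samples]
    tru_s = [t_sample_pos[s] for s in shared_samples]

    imp_sub = imputed.subset(sample_idx=imp_s, variant_idx=imp_idx)
    tru_sub = truth.subset(sample_idx=tru_s, variant_idx=tru_idx)
    per_chrom: dict[str, int] = {}
    for v in imp_sub.variants:
        per_chrom[v.chrom] = per_chrom.get(v.chrom, 0) + 1
    return imp_sub, tru_sub, per_chrom


def classify_variants(imputed: GenotypeMatrix, truth: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant match classification of two aligned matrices.

    Returns one row per shared variant: chrom, pos, vid, match_class,
    ambiguous, excluded.  Variants uninformative (all calls missing) on
    either side are marked excluded with a null class.
    """
    if imputed.n_variants != truth.n_variants:
        raise ContractError("matrices are not aligned")
    rows = []
    for j, (vi, vt) in enumerate(zip(imputed.variants, truth.variants)):
        if vi.key != vt.key:
            raise ContractError(f"variant {j}: (chrom,pos) keys differ")
        row = {"chrom": vi.chrom, "pos": vi.pos, "vid": vi.vid,
               "match_class": None, "ambiguous": False, "excluded": False}
        try:
            s_i = observed_alleles(vi, imputed.calls[:, j])
            s_t = observed_alleles(vt, truth.calls[:, j])
        except ContractError:
            row["excluded"] = True
        else:
            res = classify_match(s_i, s_t)
            row["match_class"] = res.match_class.value
            row["ambiguous"] = res.ambiguous
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "pos", "vid", "match_class",
                                       "ambiguous", "excluded"])


def _summarize_stratum(df: pd.DataFrame, name: str) -> ConcordanceSummary:
    s = ConcordanceSummary(stratum=name)
    s.n_excluded = int(df["excluded"].sum())
    kept = df[~df["excluded"]]
    for mc in MatchClass:
        s.counts[mc] = int((kept["match_class"] == mc.value).sum())
    s.n_ambiguous = int(kept["ambiguous"].sum())
    return s


def summarize_concordance(imputed: GenotypeMatrix, truth: GenotypeMatrix,
                          per_chromosome: bool = False
                          ) -> list[ConcordanceSummary]:
    """Aggregate the match taxonomy into accuracy/error summaries.

    Always emits the pooled "all", "autosomes" and "X" strata (absent
    strata carry zero counts and NaN statistics); with ``per_chromosome``
    adds one "chr*" stratum per chromosome present.
    """
    df = classify_variants(imputed, truth)
    strata: list[ConcordanceSummary] = [
        _summarize_stratum(df, "all"),
        _summarize_stratum(df[df["chrom"] != "X"], "autosomes"),
        _summarize_stratum(df[df["chrom"] == "X"], "X"),
    ]
    if per_chromosome:
        for c in dict.fromkeys(df["chrom"]):
            strata.append(_summarize_stratum(df[df["chrom"] == c], f"chr{c}"))
    return strata


def summaries_to_frame(summaries: list[ConcordanceSummary]) -> pd.DataFrame:
    """Tabular view of summaries (one row per stratum)."""
    rows = []
    for s in summaries:
        rows.append({
            "stratum": s.stratum,
            "n_overlap": s.n_overlap,
            "n_excluded": s.n_excluded,
            "n_complete": s.counts.get(MatchClass.COMPLETE, 0),
            "n_flip": s.counts.get(MatchClass.FLIP, 0),
            "n_half": s.counts.get(MatchClass.HALF, 0),
            "n_none": s.counts.get(MatchClass.NONE, 0),
            "n_ambiguous": s.n_ambiguous,
            "accuracy_pct": s.accuracy_pct,
            "error_pct": s.error_pct,
            "adjusted_accuracy_pct": s.adjusted_accuracy_pct,
        })
    return pd.DataFrame(rows)
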