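"""Iterative pre-imputation quality control of hard-call genotype data.

One pass applies, in order: sample missingness, variant missingness
(recomputed on the surviving samples), minor-allele frequency, and a
heterozygosity-outlier filter on the per-sample inbreeding statistic
F = 1 - observed het / expected het.  Passes repeat until a pass removes
nothing; strict monotone shrinkage guarantees termination.  All boundary
comparisons are strict ("more than" / "below").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import MISSING, ContractError, GenotypeMatrix, QCThresholds

RULE_SAMPLE_MISSINGNESS = "sample_missingness"
RULE_VARIANT_MISSINGNESS = "variant_missingness"
RULE_MAF = "maf"
RULE_HETEROZYGOSITY = "heterozygosity"
RULE_SEX = "sex_discordance"


@dataclass
class Removal:
    """One removed sample or variant: its ID, the rule, and the statistic
    value that triggered the removal."""

    item_id: str
    rule: str
    value: float


@dataclass
class QCIteration:
    removed_samples: list[Removal] = field(default_factory=list)
    removed_variants: list[Removal] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed_samples) + len(self.removed_variants)


@dataclass
class QCReport:
    iterations: list[QCIteration] = field(default_factory=list)
    final_genotyping_rate: float = float("nan")
    sample_f: dict[str, float] = field(default_factory=dict)

    @property
    def all_removed_samples(self) -> list[Removal]:
        return [r for it in self.iterations for r in it.removed_samples]

    @property
    def all_removed_variants(self) -> list[Removal]:
        return [r for it in self.iterations for r in it.removed_variants]


def b_allele_freq(gm: GenotypeMatrix) -> np.ndarray:
    """Per-variant B-allele frequency over called genotypes (NaN if none)."""
    called = gm.calls != MISSING
    n_called = called.sum(axis=0)
    dose = np.where(called, gm.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, dose / (2.0 * n_called), np.nan)


def sample_inbreeding_f(gm: GenotypeMatrix, freq: np.ndarray | None = None) -> np.ndarray:
    """Per-sample inbreeding statistic F = 1 - O(het)/E(het).

    Expected heterozygosity sums 2p(1-p) over the variants called in that
    sample, with p the cohort B-allele frequency; monomorphic variants
    contribute nothing to either count.
    """
    if freq is None:
        freq = b_allele_freq(gm)
    exp_het_var = 2.0 * freq * (1.0 - freq)  # NaN-free only where freq defined
    exp_het_var = np.nan_to_num(exp_het_var, nan=0.0)
    called = gm.calls != MISSING
    obs = ((gm.calls == 1) & called).sum(axis=1).astype(float)
    exp = called @ exp_het_var
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(exp > 0, 1.0 - obs / exp, np.nan)
    return f


def qc_pass(gm: GenotypeMatrix, thr: QCThresholds) -> tuple[GenotypeMatrix, QCIteration]:
    """One QC pass; returns the filtered matrix and its removal ledger."""
    if gm.n_samples == 0 or gm.n_variants == 0:
        raise ContractError("empty cohort")
    it = QCIteration()

    # (1) sample missingness, strict >
    miss_s = (gm.calls == MISSING).mean(axis=1) if gm.n_variants else np.zeros(gm.n_samples)
    keep_s = miss_s <= thr.sample_missing_max
    for i in np.nonzero(~keep_s)[0]:
        it.removed_samples.append(Removal(gm.samples[i], RULE_SAMPLE_MISSINGNESS,
                                          float(miss_s[i])))
    gm = gm.subset(sample_idx=np.nonzero(keep_s)[0])
    if gm.n_samples == 0:
        raise ContractError("empty cohort: all samples removed")

    # (2) variant missingness on remaining samples, strict >
    miss_v = (gm.calls == MISSING).mean(axis=0)
    keep_v = miss_v <= thr.variant_missing_max
    for j in np.nonzero(~keep_v)[0]:
        it.removed_variants.append(Removal(gm.variants[j].vid, RULE_VARIANT_MISSINGNESS,
                                           float(miss_v[j])))
    gm = gm.subset(variant_idx=np.nonzero(keep_v)[0])

    # (3) MAF over called genotypes, strict <; undefined MAF (no calls) removed
    if gm.n_variants:
        freq = b_allele_freq(gm)
        maf = np.minimum(freq, 1.0 - freq)
        drop = np.isnan(maf) | (maf < thr.maf_min)
        for j in np.nonzero(drop)[0]:
            it.removed_variants.append(Removal(gm.variants[j].vid, RULE_MAF,
                                               float(maf[j])))
        gm = gm.subset(variant_idx=np.nonzero(~drop)[0])

    # (4) heterozygosity outliers: |F - mean(F)| > k * sd(F)
    if gm.n_variants:
        f = sample_inbreeding_f(gm)
        valid = ~np.isnan(f)
        if valid.sum() >= 2:
            mu, sd = f[valid].mean(), f[valid].std()
            if sd > 0:
                out = valid & (np.abs(f - mu) > thr.het_sd_multiplier * sd)
                for i in np.nonzero(out)[0]:
                    it.removed_samples.append(Removal(gm.samples[i],
                                                      RULE_HETEROZYGOSITY, float(f[i])))
                gm = gm.subset(sample_idx=np.nonzero(~out)[0])
    if gm.n_samples == 0:
        raise ContractError("empty cohort: all samples removed")
    return gm, it


def run_iterative_qc(gm: GenotypeMatrix, thr: QCThresholds) -> tuple[GenotypeMatrix, QCReport]:
    """Repeat :func:`qc_pass` until a pass removes nothing.

    The report records every iteration (the final one removes nothing),
    the final genotyping rate, and the final per-sample F values.
    """
    report = QCReport()
    max_iter = gm.n_samples + gm.n_variants + 1  # strict-shrinkage bound
    for _ in range(max_iter):
        gm, it = qc_pass(gm, thr)
        report.iterations.append(it)
        if it.n_removed == 0:
            break
    else:  # pragma: no cover - unreachable by the shrinkage argument
        raise RuntimeError("iterative QC failed to reach a fixed point")
    report.final_genotyping_rate = gm.genotyping_rate()
    f = sample_inbreeding_f(gm)
    report.sample_f = dict(zip(gm.samples, f.tolist()))
    return gm, report


def sex_concordance_check(gm_x: GenotypeMatrix, reported_sex: dict[str, str],
                          thr: QCThresholds) -> list[str]:
    """Samples whose X-heterozygosity F contradicts their reported sex.

    F < ``sex_f_female_max`` infers female, F > ``sex_f_male_min`` infers
    male, the band between abstains; unknown reported sex never flags.
    """
    if gm_x.n_variants == 0:
        raise ContractError("no X data")
    if any(v.chrom != "X" for v in gm_x.variants):
        raise ContractError("sex_concordance_check expects X-chromosome variants only")
    f = sample_inbreeding_f(gm_x)
    discordant = []
    for i, s in enumerate(gm_x.samples):
        rep = reported_sex.get(s, "unknown")
        if rep not in ("male", "female") or np.isnan(f[i]):
            continue
        if f[i] < thr.sex_f_female_max:
            inferred = "female"
        elif f[i] > thr.sex_f_male_min:
            inferred = "male"
        else:
            continue
        if inferred != rep:
            discordant.append(s)
    return discordant
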