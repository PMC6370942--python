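"""MAF computation and MAF- / match-class-stratified quality summaries.

Imputation engines report a per-variant quality score in [0, 1] (INFO for
IMPUTE2, r2 for PBWT/Minimac); these summaries describe its distribution
within one dataset.  MAF bins are half-open (lo, hi] with the first bin
closed at 0; both the median and the mean are available as the central
statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import MISSING, ContractError, GenotypeMatrix, MafBinning


def compute_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Per-variant minor-allele frequency over called genotypes.

    MAF = min(f_B, 1 - f_B) with f_B the B-allele frequency; NaN where a
    variant has no called genotype.
    """
    from .qc import b_allele_freq

    freq = b_allele_freq(gm)
    return np.minimum(freq, 1.0 - freq)


def _check_scores(quality: np.ndarray) -> np.ndarray:
    q = np.asarray(quality, dtype=float)
    finite = q[~np.isnan(q)]
    if ((finite < 0) | (finite > 1)).any():
        raise ContractError("quality scores must lie in [0, 1]")
    return q


def quality_by_maf(quality, maf, bins: MafBinning | None = None,
                   stat: str = "median") -> pd.DataFrame:
    """Central quality statistic per MAF bin.

    ``stat`` is ``median``, ``mean`` or ``both``.  Variants with undefined
    MAF or quality are dropped; empty bins report n = 0 and NaN statistics.
    """
    bins = bins or MafBinning()
    if stat not in ("median", "mean", "both"):
        raise ContractError(f"unknown stat {stat!r}")
    q = _check_scores(quality)
    m = np.asarray(maf, dtype=float)
    if q.shape != m.shape:
        raise ContractError("quality and maf are not aligned")
    ok = ~(np.isnan(q) | np.isnan(m))
    q, m = q[ok], m[ok]
    edges = np.asarray(bins.edges)
    # (lo, hi] bins, first bin closed at 0
    idx = np.searchsorted(edges, m, side="left") - 1
    idx[m == 0.0] = 0
    rows = []
    for b, label in enumerate(bins.labels):
        sel = q[idx == b]
        row = {"bin": label, "n": int(sel.size)}
        if stat in ("median", "both"):
            row["median"] = float(np.median(sel)) if sel.size else np.nan
        if stat in ("mean", "both"):
            row["mean"] = float(np.mean(sel)) if sel.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def quality_histogram(quality, bin_width: float = 0.05,
                      chroms=None) -> pd.DataFrame:
    """Variant counts per half-open quality bin (lo, hi]; the first bin is
    closed at 0 and a score of exactly 1.0 lands in the top bin.

    With ``chroms`` given (aligned array of chromosome labels) one column
    of counts per chromosome stratum is added next to the total.
    """
    q = _check_scores(quality)
    if np.isnan(q).any():
        q = q[~np.isnan(q)]
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)

    def _counts(values: np.ndarray) -> np.ndarray:
        idx = np.ceil(values / bin_width).astype(int) - 1
        idx = np.clip(idx, 0, n_bins - 1)
        return np.bincount(idx, minlength=n_bins)

    out = pd.DataFrame({
        "bin": [f"({edges[i]:.2f},{edges[i + 1]:.2f}]" for i in range(n_bins)],
        "n": _counts(q),
    })
    if chroms is not None:
        chroms = np.asarray(chroms)
        qq = np.asarray(quality, dtype=float)
        for c in dict.fromkeys(chroms.tolist()):
            sel = qq[(chroms == c) & ~np.isnan(qq)]
            out[f"n_chr{c}"] = _counts(sel)
    return out


def quality_by_match_class(classified: pd.DataFrame, quality,
                           by_stratum: bool = True) -> pd.DataFrame:
    """Median quality for all overlap variants and for the HALF and NONE
    match classes, per autosome/X stratum.

    ``classified`` is the per-variant frame from
    :func:`impuconcord.concordance.classify_variants`, aligned with
    ``quality``.
    """
    q = _check_scores(quality)
    if len(classified) != len(q):
        raise ContractError("classification table and quality are not aligned")
    df = classified.copy()
    df["quality"] = q
    df = df[~df["excluded"]]

    strata = [("autosomes", df[df["chrom"] != "X"]), ("X", df[df["chrom"] == "X"])] \
        if by_stratum else [("all", df)]
    rows = []
    for name, sub in strata:
        for cls, sel in (("total", sub),
                         ("HALF", sub[sub["match_class"] == "HALF"]),
                         ("NONE", sub[sub["match_class"] == "NONE"])):
            vals = sel["quality"].dropna()
            rows.append({"stratum": name, "class": cls, "n": int(len(sel)),
                         "median_quality": float(vals.median()) if len(vals) else np.nan})
    return pd.DataFrame(rows)
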