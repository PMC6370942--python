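"""Hard-calling of imputed genotypes from posterior probabilities.

An entry is called to the most probable genotype when that posterior is
unique and reaches the calling threshold (default 0.7, inclusive);
otherwise it is a no-call.  Ties at the maximum abstain: no genotype has
posterior dominance.  Indel removal and pruning of uncalled variants
reproduce the standard post-call cleanup.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .model import (
    MISSING,
    CallingConfig,
    ContractError,
    GenotypeMatrix,
    ProbGenotypeMatrix,
)

log = logging.getLogger(__name__)


def call_genotypes(pgm: ProbGenotypeMatrix,
                   cfg: CallingConfig | None = None) -> tuple[GenotypeMatrix, float]:
    """Threshold the posterior triples into hard calls.

    Returns the called matrix and the no-call fraction (share of
    sample x variant entries left MISSING).  All-zero triples are
    no-calls at any threshold.
    """
    cfg = cfg or CallingConfig()
    p = pgm.probs
    if p.size == 0:
        return (GenotypeMatrix(samples=list(pgm.samples), variants=list(pgm.variants),
                               calls=np.zeros(p.shape[:2], dtype=np.int8)), 0.0)
    m = p.max(axis=2)
    top = p.argmax(axis=2)
    unique = (p == m[..., None]).sum(axis=2) == 1
    callable_ = unique & (m >= cfg.threshold) & (p.sum(axis=2) > 0.0)
    calls = np.where(callable_, top, MISSING).astype(np.int8)
    no_call_fraction = float((calls == MISSING).mean())
    gm = GenotypeMatrix(samples=list(pgm.samples), variants=list(pgm.variants),
                        calls=calls)
    return gm, no_call_fraction


def remove_indels(data):
    """Drop every variant that is not a single-base SNP; works on either
    matrix type; the dropped count is logged."""
    keep = [j for j, v in enumerate(data.variants) if v.is_snp]
    n_dropped = len(data.variants) - len(keep)
    if n_dropped:
        log.info("removed %d indel/non-SNP variants", n_dropped)
    if isinstance(data, ProbGenotypeMatrix):
        return data.subset_variants(keep)
    return data.subset(variant_idx=keep)


def prune_uncalled_variants(gm: GenotypeMatrix,
                            rule: str = "all_missing") -> GenotypeMatrix:
    """Drop variants with no-call alleles.

    ``all_missing`` (default) drops only variants where every genotype is
    MISSING; ``any_missing`` drops variants with at least one MISSING call.
    """
    if rule not in ("all_missing", "any_missing"):
        raise ContractError(f"unknown uncalled-variant rule {rule!r}")
    if gm.n_variants == 0:
        return gm
    missing = gm.calls == MISSING
    drop = missing.all(axis=0) if rule == "all_missing" else missing.any(axis=0)
    return gm.subset(variant_idx=np.nonzero(~drop)[0])


def sweep_threshold(pgm: ProbGenotypeMatrix, truth: GenotypeMatrix,
                    thresholds: Iterable[float],
                    pre_imputation_variants=None) -> pd.DataFrame:
    """Accuracy / yield trade-off across calling thresholds.

    For each threshold: hard-call, prune fully-uncalled variants, extract
    the overlap with the truth matrix and compute concordance accuracy.
    One row per threshold with the number of surviving variants, the
    no-call fraction and the pooled accuracy (%).
    """
    from .concordance import extract_overlap, summarize_concordance

    rows = []
    for t in thresholds:
        gm, ncf = call_genotypes(pgm, CallingConfig(threshold=float(t)))
        gm = prune_uncalled_variants(gm, "all_missing")
        if gm.n_variants == 0:
            rows.append({"threshold": t, "n_called_variants": 0,
                         "no_call_fraction": ncf, "accuracy_pct": np.nan})
            continue
        try:
            imp, tru, _ = extract_overlap(gm, truth, pre_imputation_variants)
        except ContractError:
            rows.append({"threshold": t, "n_called_variants": gm.n_variants,
                         "no_call_fraction": ncf, "accuracy_pct": np.nan})
            continue
        summaries = summarize_concordance(imp, tru)
        pooled = [s for s in summaries if s.stratum == "all"]
        acc = pooled[0].accuracy_pct if pooled else np.nan
        rows.append({"threshold": t, "n_called_variants": gm.n_variants,
                     "no_call_fraction": ncf, "accuracy_pct": acc})
    return pd.DataFrame(rows)
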