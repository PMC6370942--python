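"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with different code paths than the
package (plain loops, no vectorisation, no shared helpers) so agreement
is evidence, not tautology.
"""

from __future__ import annotations

import itertools

_COMP = str.maketrans("ACGT", "TGCA")


def all_allele_multisets():
    """The 14 allele multisets of size 1-2 over ACGT: 6 distinct pairs,
    4 doubled pairs and 4 singletons (a doubled pair observes as its
    singleton set)."""
    bases = "ACGT"
    out = []
    for a, b in itertools.combinations(bases, 2):
        out.append((a, b))
    for a in bases:
        out.append((a, a))
    for a in bases:
        out.append((a,))
    return out


def match_oracle(imputed, truth):
    """Brute-force four-class match logic on two allele collections.

    Returns (class_name, ambiguous).  Written with string translation and
    sorted-list comparison rather than set algebra.
    """
    si = sorted(set(imputed))
    st = sorted(set(truth))
    if si == st:
        return "COMPLETE", False
    flipped = sorted({a.translate(_COMP) for a in si})
    if flipped == st:
        return "FLIP", False
    shared = [a for a in si if a in st]
    if len(shared) == 1:
        return "HALF", False
    pal = (["A", "T"], ["C", "G"])
    ambiguous = si in pal and st in pal
    return "NONE", ambiguous


def iterative_qc_oracle(calls, sample_ids, variant_ids, thr):
    """Exhaustive filtering until stable, with plain Python loops.

    ``calls`` is a list of per-sample lists with -1 for missing.  Returns
    (kept_sample_ids, kept_variant_ids, events) where events is a list of
    (iteration, kind, id, rule) in removal order.
    """
    samples = list(sample_ids)
    variants = list(variant_ids)
    data = {(s, v): calls[i][j]
            for i, s in enumerate(samples) for j, v in enumerate(variants)}
    events = []
    iteration = 0
    while True:
        iteration += 1
        removed_any = False

        for s in list(samples):
            vals = [data[(s, v)] for v in variants]
            if vals and sum(1 for x in vals if x == -1) / len(vals) > thr.sample_missing_max:
                samples.remove(s)
                events.append((iteration, "sample", s, "sample_missingness"))
                removed_any = True

        for v in list(variants):
            vals = [data[(s, v)] for s in samples]
            if vals and sum(1 for x in vals if x == -1) / len(vals) > thr.variant_missing_max:
                variants.remove(v)
                events.append((iteration, "variant", v, "variant_missingness"))
                removed_any = True

        for v in list(variants):
            vals = [data[(s, v)] for s in samples if data[(s, v)] != -1]
            if not vals:
                variants.remove(v)
                events.append((iteration, "variant", v, "maf"))
                removed_any = True
                continue
            freq = sum(vals) / (2 * len(vals))
            if min(freq, 1 - freq) < thr.maf_min:
                variants.remove(v)
                events.append((iteration, "variant", v, "maf"))
                removed_any = True

        freqs = {}
        for v in variants:
            vals = [data[(s, v)] for s in samples if data[(s, v)] != -1]
            freqs[v] = sum(vals) / (2 * len(vals)) if vals else None
        fs = {}
        for s in samples:
            obs = 0
            exp = 0.0
            for v in variants:
                g = data[(s, v)]
                if g == -1 or freqs[v] is None:
                    continue
                exp += 2 * freqs[v] * (1 - freqs[v])
                if g == 1:
                    obs += 1
            fs[s] = 1 - obs / exp if exp > 0 else None
        vals = [f for f in fs.values() if f is not None]
        if len(vals) >= 2:
            mu = sum(vals) / len(vals)
            sd = (sum((x - mu) ** 2 for x in vals) / len(vals)) ** 0.5
            if sd > 0:
                for s in list(samples):
                    if fs[s] is not None and abs(fs[s] - mu) > thr.het_sd_multiplier * sd:
                        samples.remove(s)
                        events.append((iteration, "sample", s, "heterozygosity"))
                        removed_any = True

        if not removed_any:
            break
    return samples, variants, events
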