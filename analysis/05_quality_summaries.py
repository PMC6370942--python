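#!/usr/bin/env python
"""Quality-score summaries: MAF-stratified curves, histograms, per-class medians.

Summarises the per-variant imputation quality scores of the pseudo-imputed
dataset: median/mean quality per MAF bin (the quality-vs-MAF curve),
the SNP-count-by-quality histogram for chromosome 1 and X, and the median
quality of half- and no-match variants against the overlap total.
Writes results/quality/*.tsv and, if matplotlib is importable, two figures.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from impuconcord import (
    CallingConfig,
    call_genotypes,
    classify_variants,
    compute_maf,
    extract_overlap,
    quality_by_maf,
    quality_by_match_class,
    quality_histogram,
    read_vcf,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fixtures", type=Path, default=ROOT / "scratch" / "fixtures")
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results" / "quality")
    args = ap.parse_args()

    pgm = read_vcf(args.fixtures / "imputed.vcf", require_gp=True)
    truth = read_vcf(args.fixtures / "truth.vcf")
    gm, _ = call_genotypes(pgm, CallingConfig(threshold=0.0))
    maf = compute_maf(gm)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    curve = quality_by_maf(pgm.quality, maf, stat="both")
    curve.to_csv(args.out_dir / "quality_by_maf.tsv", sep="\t", index=False,
                 float_format="%.4f")
    hist = quality_histogram(pgm.quality, chroms=pgm.chroms)
    hist[["bin", "n", "n_chr1", "n_chrX"]].to_csv(
        args.out_dir / "quality_histogram.tsv", sep="\t", index=False)

    imp, tru, _ = extract_overlap(gm, truth)
    classified = classify_variants(imp, tru)
    q_by_vid = {v.vid: q for v, q in zip(pgm.variants, pgm.quality)}
    overlap_q = np.array([q_by_vid[v.vid] for v in imp.variants])
    by_class = quality_by_match_class(classified, overlap_q)
    by_class.to_csv(args.out_dir / "quality_by_class.tsv", sep="\t",
                    index=False, float_format="%.4f")

    print("median quality per MAF bin:")
    print(curve.to_string(index=False))
    print("\nmedian quality by match class:")
    print(by_class.to_string(index=False))

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("\nmatplotlib unavailable; skipping figures")
        return
    fig_dir = ROOT / "scratch" / "quality"
    fig_dir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 4))
    pop = curve[curve["n"] > 0]
    ax.plot(range(len(pop)), pop["median"], marker="o", label="median")
    ax.plot(range(len(pop)), pop["mean"], marker="s", label="mean")
    ax.set_xticks(range(len(pop)), pop["bin"], rotation=45, ha="right")
    ax.set_xlabel("MAF bin")
    ax.set_ylabel("quality score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(fig_dir / "quality_by_maf.png", dpi=120)
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(hist))
    ax.bar(x - 0.2, hist["n_chr1"], width=0.4, label="chr1")
    ax.bar(x + 0.2, hist["n_chrX"], width=0.4, label="chrX")
    ax.set_xticks(x[::4], hist["bin"][::4], rotation=45, ha="right")
    ax.set_xlabel("quality bin")
    ax.set_ylabel("variants")
    ax.legend()
    fig.tight_layout()
    fig.savefig(fig_dir / "snp_count_by_quality.png", dpi=120)
    print(f"\ntables written to {args.out_dir}, figures to {fig_dir}")


if __name__ == "__main__":
    main()
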