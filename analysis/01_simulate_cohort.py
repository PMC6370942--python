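#!/usr/bin/env python
"""Simulate the synthetic study cohort and its pseudo-imputed rendering.

Generates a five-way admixed truth cohort (Balding-Nichols + Dirichlet
admixture), splits it into two partially overlapping genotyping arrays,
and corrupts a copy into posterior-probability "imputation output" with
known error / strand-flip / monomorphic rates.  Writes the fixtures and
the injected-label table under results/fixtures/.
"""

import argparse
from pathlib import Path

import pandas as pd

from impuconcord import (
    SimulationConfig,
    corrupt_as_imputed,
    simulate_cohort,
    split_arrays,
    write_gen_sample,
    write_vcf,
)

STUDY = dict(n_samples=200, n_variants=20_000, frac_x=0.05,
             error_rate=0.10, flip_rate=0.05, mono_rate=0.02)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    # fixtures are bulky regenerable artifacts -> scratch/, not results/
    ap.add_argument("--out-dir", type=Path,
                    default=Path(__file__).resolve().parents[1] / "scratch" / "fixtures")
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed, **STUDY)
    truth = simulate_cohort(cfg)
    gm_a, gm_b, shared = split_arrays(truth, frac_shared_samples=0.5,
                                      frac_shared_variants=0.15,
                                      frac_array_a_only=0.3, seed=args.seed + 1)
    pgm, labels = corrupt_as_imputed(truth, cfg)

    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(truth, out / "truth.vcf")
    write_vcf(gm_b, out / "array_b_truth.vcf")
    write_vcf(pgm, out / "imputed.vcf")
    write_gen_sample(pgm, out / "imputed.gen", out / "imputed.sample")
    labels.to_csv(out / "labels.tsv", sep="\t", index=False)
    pd.DataFrame({"chrom": [v.chrom for v in shared],
                  "pos": [v.pos for v in shared],
                  "vid": [v.vid for v in shared]}
                 ).to_csv(out / "shared_variants.tsv", sep="\t", index=False)

    counts = labels["label"].value_counts()
    print(f"cohort: {truth.n_samples} samples x {truth.n_variants} variants "
          f"({(truth.chroms == 'X').sum()} X-linked)")
    print(f"arrays: A {gm_a.n_samples}x{gm_a.n_variants}, "
          f"B {gm_b.n_samples}x{gm_b.n_variants}, "
          f"{len(shared)} variants genotyped on both")
    print("injected labels:", counts.to_dict(),
          f"({labels['reassigned'].sum()} palindromic flips reassigned to clean)")
    print(f"fixtures written to {out}")


if __name__ == "__main__":
    main()
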