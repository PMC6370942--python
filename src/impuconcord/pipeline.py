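"""End-to-end orchestration: simulate -> qc -> call -> concord -> quality.

A pipeline run owns one run directory.  In simulated mode the generator
plays the role of the two genotyping arrays and the imputation server:
the full cohort is simulated once, split into a sparser "array A"
(imputation input role) and a denser "array B" (truth role), array B is
passed through iterative QC, and a corrupted copy of the cohort restricted
to array-A samples stands in for the imputation output.  The concordance
evaluation then excludes the pre-imputation shared-variant list, exactly
as a real post-imputation accuracy assessment would.  A manifest records
the config hash, seed and a checksum of every output, so a rerun with the
same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calling import call_genotypes, prune_uncalled_variants, remove_indels
from .concordance import (
    classify_variants,
    extract_overlap,
    summaries_to_frame,
    summarize_concordance,
)
from .io import read_gen_sample, read_vcf, write_gen_sample, write_report_tables, write_tsv, write_vcf
from .model import (
    CallingConfig,
    ContractError,
    MafBinning,
    QCThresholds,
    SimulationConfig,
)
from .qc import run_iterative_qc
from .quality import compute_maf, quality_by_maf, quality_by_match_class
from .simulate import corrupt_as_imputed, simulate_cohort, split_arrays

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline invocation needs.

    Either ``simulation`` is set (simulated mode) or ``imputed_path`` /
    ``truth_path`` point at existing files (``imputed_path`` a VCF with
    FORMAT/GP, or a GEN file with ``sample_path``; ``truth_path`` a VCF
    with hard GT calls).
    """

    out_dir: Path = Path("impuconcord_run")
    seed: int = 0
    simulation: SimulationConfig | None = None
    imputed_path: Path | None = None
    sample_path: Path | None = None
    truth_path: Path | None = None
    exclude_path: Path | None = None
    qc_thresholds: QCThresholds = field(default_factory=QCThresholds)
    calling: CallingConfig = field(default_factory=CallingConfig)
    maf_bins: MafBinning = field(default_factory=MafBinning)
    run_qc: bool = True
    frac_shared_samples: float = 0.5
    frac_shared_variants: float = 0.15
    frac_array_a_only: float = 0.3

    def validate(self) -> None:
        if self.simulation is None:
            if self.imputed_path is None or self.truth_path is None:
                raise ContractError(
                    "need either a simulation config or imputed+truth input paths")
            for p in (self.imputed_path, self.truth_path, self.sample_path,
                      self.exclude_path):
                if p is not None and not Path(p).exists():
                    raise ContractError(f"input file {p} does not exist")


def _config_dict(cfg: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, (list, tuple)):
            return [enc(x) for x in obj]
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj

    return enc(cfg)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the enabled stages and return the run directory.

    Outputs: the simulated fixtures (simulated mode), QC report, called
    genotypes, the four report TSVs, ``report.txt`` and ``manifest.json``.
    Any stage failure raises; nothing is written past the failing stage.
    """
    cfg.validate()
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    if cfg.simulation is not None:
        sim = cfg.simulation
        truth_full = simulate_cohort(sim)
        gm_a, gm_b, shared_vars = split_arrays(
            truth_full, cfg.frac_shared_samples, cfg.frac_shared_variants,
            cfg.frac_array_a_only, seed=sim.seed + 1)
        a_sample_idx = [i for i, s in enumerate(truth_full.samples)
                        if s in set(gm_a.samples)]
        pgm, labels = corrupt_as_imputed(truth_full.subset(sample_idx=a_sample_idx),
                                         sim)
        truth = gm_b
        exclude = shared_vars
        write_vcf(truth_full, run_dir / "truth_full.vcf")
        write_vcf(pgm, run_dir / "imputed.vcf")
        write_gen_sample(pgm, run_dir / "imputed.gen", run_dir / "imputed.sample")
        write_tsv(labels, run_dir / "labels.tsv")
        pd.DataFrame({"chrom": [v.chrom for v in shared_vars],
                      "pos": [v.pos for v in shared_vars],
                      "vid": [v.vid for v in shared_vars]}
                     ).to_csv(run_dir / "shared_variants.tsv", sep="\t", index=False)
        outputs += [run_dir / n for n in ("truth_full.vcf", "imputed.vcf",
                                          "imputed.gen", "imputed.sample",
                                          "labels.tsv", "shared_variants.tsv")]
    else:
        if cfg.sample_path is not None:
            pgm = read_gen_sample(cfg.imputed_path, cfg.sample_path)
        else:
            pgm = read_vcf(cfg.imputed_path, require_gp=True)
        truth = read_vcf(cfg.truth_path, require_gp=False)
        exclude = None
        if cfg.exclude_path is not None:
            ex = pd.read_csv(cfg.exclude_path, sep="\t")
            exclude = list(zip(ex["chrom"].astype(str), ex["pos"].astype(int)))

    # --- QC of the truth array ---
    if cfg.run_qc:
        truth, qc_report = run_iterative_qc(truth, cfg.qc_thresholds)
        qc_out = {
            "n_iterations": len(qc_report.iterations),
            "final_genotyping_rate": qc_report.final_genotyping_rate,
            "removed_samples": [[r.item_id, r.rule, r.value]
                                for r in qc_report.all_removed_samples],
            "removed_variants": [[r.item_id, r.rule, r.value]
                                 for r in qc_report.all_removed_variants],
        }
        (run_dir / "qc_report.json").write_text(json.dumps(qc_out, indent=1))
        outputs.append(run_dir / "qc_report.json")

    # --- Calling ---
    if cfg.calling.drop_indels:
        pgm = remove_indels(pgm)
    called, no_call_fraction = call_genotypes(pgm, cfg.calling)
    called = prune_uncalled_variants(called, cfg.calling.uncalled_variant_rule)
    write_vcf(called, run_dir / "called.vcf")
    outputs.append(run_dir / "called.vcf")

    # --- Concordance ---
    imp, tru, per_chrom = extract_overlap(called, truth, exclude)
    summaries = summarize_concordance(imp, tru, per_chromosome=True)
    classified = classify_variants(imp, tru)

    # --- Quality summaries (scores follow the imputed variants) ---
    q_by_vid = {v.vid: q for v, q in zip(pgm.variants, pgm.quality)}
    overlap_quality = np.array([q_by_vid.get(v.vid, np.nan) for v in imp.variants])
    qbc = quality_by_match_class(classified, overlap_quality)
    maf = compute_maf(imp)
    qbm = quality_by_maf(overlap_quality, maf, cfg.maf_bins, stat="both")

    counts = summaries_to_frame(summaries)[
        ["stratum", "n_overlap", "n_excluded", "n_complete", "n_flip",
         "n_half", "n_none", "n_ambiguous"]]
    counts.insert(1, "n_imputed", [
        sum(1 for v in called.variants if (s.stratum == "all")
            or (s.stratum == "autosomes" and v.chrom != "X")
            or (s.stratum == "X" and v.chrom == "X")
            or (s.stratum == f"chr{v.chrom}"))
        for s in summaries])
    counts.insert(2, "pct_no_calls", 100.0 * no_call_fraction)
    accuracy = summaries_to_frame(summaries)[
        ["stratum", "n_overlap", "accuracy_pct", "error_pct",
         "adjusted_accuracy_pct"]]
    paths = write_report_tables(run_dir, counts, accuracy, qbc, qbm)
    outputs += list(paths.values())

    report_path = make_summary_report(run_dir)
    outputs.append(report_path)

    cfg_json = json.dumps(_config_dict(cfg), sort_keys=True)
    manifest = {
        "tool": "impuconcord",
        "version": __version__,
        "seed": cfg.seed,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return run_dir


def make_summary_report(run_dir) -> Path:
    """Assemble the three-section summary file from a run's report TSVs.

    Section 1 mirrors the counts table (imputed n, overlap n, % no calls),
    section 2 the accuracy/error table, section 3 the per-class quality
    table; NA marks absent strata.  The accuracy identities
    (error = 100 - accuracy; class counts sum to the overlap) are
    re-verified at render time.
    """
    run_dir = Path(run_dir)
    frames = {}
    for stage, name in (("concordance counts", "counts.tsv"),
                        ("accuracy", "accuracy.tsv"),
                        ("quality-by-class", "quality_by_class.tsv")):
        p = run_dir / name
        if not p.exists():
            raise ContractError(f"missing stage output for {stage}: {p}")
        frames[name] = pd.read_csv(p, sep="\t", na_values="NA")

    acc = frames["accuracy.tsv"]
    for _, row in acc.iterrows():
        a, e = row["accuracy_pct"], row["error_pct"]
        if not (pd.isna(a) or pd.isna(e)) and abs((a + e) - 100.0) > 0.011:
            raise ContractError(
                f"render check failed: accuracy {a} + error {e} != 100")
    cnt = frames["counts.tsv"]
    for _, row in cnt.iterrows():
        if pd.isna(row["n_overlap"]):
            continue
        total = sum(row[k] for k in ("n_complete", "n_flip", "n_half", "n_none"))
        if total != row["n_overlap"]:
            raise ContractError("render check failed: class counts != overlap")

    lines = ["# Imputation evaluation summary", ""]
    for title, name in (("Variant counts and no-call rate", "counts.tsv"),
                        ("Accuracy and genome-wide error (%)", "accuracy.tsv"),
                        ("Median quality by match class", "quality_by_class.tsv")):
        lines.append(f"## {title}")
        lines.append((run_dir / name).read_text().rstrip())
        lines.append("")
    out = run_dir / "report.txt"
    out.write_text("\n".join(lines))
    return out
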