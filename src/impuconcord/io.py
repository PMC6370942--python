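"""Readers and writers for the genotype formats the pipeline touches.

VCF parsing is delegated to cyvcf2 (htslib); Oxford GEN/SAMPLE, which no
installed library reads, is parsed directly.  Genotype probabilities are
normalised to 6 decimal places on read — the text precision both writers
emit — so a GEN file and its equivalent VCF yield bit-identical matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    MISSING,
    VALID_CHROMS,
    ContractError,
    GenotypeMatrix,
    ParseError,
    ProbGenotypeMatrix,
    VariantRecord,
)

log = logging.getLogger(__name__)

#: INFO-field keys probed for the per-variant quality score, in precedence
#: order (IMPUTE2's INFO, Minimac/PBWT's R2, Beagle's DR2).
QUALITY_KEYS = ("INFO", "R2", "DR2")

_GP_DECIMALS = 6
# cyvcf2 surfaces FORMAT floats as float32; rounding to the written text
# precision restores the decimal value exactly for probabilities in [0, 1].

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
# cyvcf2 gt_types codes: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_GT_TYPE_MAP = np.array([0, 1, MISSING, 2], dtype=np.int8)


@dataclass
class ReadLog:
    """Per-file account of records excluded during parsing."""

    n_kept: int = 0
    skipped_multiallelic: int = 0
    skipped_nonacgt: int = 0
    skipped_other_chrom: int = 0

    @property
    def n_skipped(self) -> int:
        return self.skipped_multiallelic + self.skipped_nonacgt + self.skipped_other_chrom


def _normalise_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def read_vcf(path, require_gp: bool = False, read_log: ReadLog | None = None):
    """Read a VCF into a genotype matrix.

    With ``require_gp`` the FORMAT/GP posterior triples are read into a
    :class:`ProbGenotypeMatrix` (per-variant quality from the first INFO key
    among ``INFO``, ``R2``, ``DR2``; NaN when absent); otherwise hard GT
    calls are read into a :class:`GenotypeMatrix` with ``./.`` as MISSING.
    Multiallelic, symbolic-allele and off-target-chromosome records are
    skipped and counted in ``read_log``, never fatal.
    """
    path = str(path)
    rlog = read_log if read_log is not None else ReadLog()
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib raises plain OSError/Exception
        raise ParseError(f"{path}: cannot open as VCF: {exc}") from exc
    samples = list(vcf.samples)
    header_lines = vcf.raw_header.count("\n")

    variants: list[VariantRecord] = []
    gt_rows: list[np.ndarray] = []
    gp_rows: list[np.ndarray] = []
    quality: list[float] = []

    record_no = 0
    iterator = iter(vcf)
    while True:
        try:
            v = next(iterator)
        except StopIteration:
            break
        except Exception as exc:
            raise ParseError(
                f"{path}: malformed record at line {header_lines + record_no + 1}: {exc}"
            ) from exc
        record_no += 1
        line_no = header_lines + record_no
        if len(v.ALT) != 1:
            rlog.skipped_multiallelic += 1
            continue
        ref, alt = v.REF, v.ALT[0]
        if not (set(ref) <= set("ACGT") and set(alt) <= set("ACGT")):
            rlog.skipped_nonacgt += 1
            continue
        chrom = _normalise_chrom(v.CHROM)
        if chrom not in VALID_CHROMS:
            rlog.skipped_other_chrom += 1
            continue
        try:
            rec = VariantRecord(chrom=chrom, pos=v.POS, vid=v.ID or f"{chrom}:{v.POS}",
                                alleles=(ref, alt))
        except ContractError as exc:
            raise ParseError(f"{path}: line {line_no}: {exc}") from exc

        if require_gp:
            gp = v.format("GP")
            if gp is None:
                raise ParseError(
                    f"{path}: line {line_no}: FORMAT/GP required but absent"
                )
            gp = np.asarray(gp, dtype=np.float64)
            if gp.shape != (len(samples), 3):
                raise ParseError(
                    f"{path}: line {line_no}: GP must carry 3 values per sample"
                )
            gp_rows.append(np.round(gp, _GP_DECIMALS))
            q = np.nan
            for key in QUALITY_KEYS:
                val = v.INFO.get(key)
                if val is not None:
                    q = float(val)
                    break
            quality.append(q)
        else:
            gt_rows.append(_GT_TYPE_MAP[np.asarray(v.gt_types, dtype=np.intp)])
        variants.append(rec)

    rlog.n_kept = len(variants)
    if rlog.n_skipped:
        log.info("%s: skipped %d records (multiallelic %d, non-ACGT %d, other chrom %d)",
                 path, rlog.n_skipped, rlog.skipped_multiallelic,
                 rlog.skipped_nonacgt, rlog.skipped_other_chrom)

    if require_gp:
        probs = (np.stack(gp_rows, axis=1) if gp_rows
                 else np.zeros((len(samples), 0, 3)))
        return ProbGenotypeMatrix(samples=samples, variants=variants,
                                  probs=probs, quality=np.array(quality, dtype=float))
    calls = (np.stack(gt_rows, axis=1) if gt_rows
             else np.zeros((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


def write_vcf(data, path) -> None:
    """Write a GenotypeMatrix (GT) or ProbGenotypeMatrix (GT:GP, INFO/R2)
    as an uncompressed VCF v4.2 text file."""
    path = Path(path)
    is_prob = isinstance(data, ProbGenotypeMatrix)
    chroms_seen = []
    for v in data.variants:
        if v.chrom not in chroms_seen:
            chroms_seen.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=impuconcord\n')
        for c in chroms_seen:
            fh.write(f"##contig=<ID={c}>\n")
        if is_prob:
            fh.write('##INFO=<ID=R2,Number=1,Type=Float,'
                     'Description="Imputation quality score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if is_prob:
            fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,'
                     'Description="Genotype posterior probabilities">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(data.samples) + "\n")
        for j, var in enumerate(data.variants):
            ref, alt = var.alleles
            if is_prob:
                q = data.quality[j]
                info = "." if np.isnan(q) else f"R2={q:.6f}"
                cols = []
                for i in range(data.n_samples):
                    p = data.probs[i, j]
                    if p.sum() == 0.0:
                        gt = "./."
                    else:
                        top = int(np.argmax(p))
                        gt = _GT_STRINGS[top] if (p == p[top]).sum() == 1 else "./."
                    cols.append(gt + ":" + ",".join(f"{x:.6f}" for x in p))
                fmt = "GT:GP"
            else:
                info = "."
                cols = [_GT_STRINGS[int(c)] for c in data.calls[:, j]]
                fmt = "GT"
            fh.write(f"{var.chrom}\t{var.pos}\t{var.vid}\t{ref}\t{alt}\t.\t.\t"
                     f"{info}\t{fmt}\t" + "\t".join(cols) + "\n")


def read_gen_sample(gen_path, sample_path) -> ProbGenotypeMatrix:
    """Read Oxford GEN/SAMPLE files.

    GEN lines carry 5 leading columns (chrom, id, pos, alleleA, alleleB)
    followed by an (AA, AB, BB) probability triple per sample; an all-zero
    triple is kept as (0, 0, 0) and becomes a no-call at calling time.
    The SAMPLE file has the usual two header lines.
    """
    sample_path, gen_path = Path(sample_path), Path(gen_path)
    with open(sample_path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise ParseError(f"{sample_path}: SAMPLE file needs 2 header lines + data")
    id_col = 1 if len(lines[0]) >= 2 else 0
    samples = [row[id_col] for row in lines[2:]]
    n = len(samples)

    variants: list[VariantRecord] = []
    probs_rows: list[np.ndarray] = []
    with open(gen_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 5 + 3 * n:
                raise ParseError(
                    f"{gen_path}: line {line_no}: expected {5 + 3 * n} columns "
                    f"for {n} samples, got {len(fields)}"
                )
            chrom, vid, pos, a, b = fields[:5]
            try:
                trip = np.array(fields[5:], dtype=np.float64).reshape(n, 3)
            except ValueError as exc:
                raise ParseError(f"{gen_path}: line {line_no}: {exc}") from exc
            if (trip < 0).any():
                raise ParseError(f"{gen_path}: line {line_no}: negative probability")
            try:
                rec = VariantRecord(chrom=_normalise_chrom(chrom), pos=int(pos),
                                    vid=vid, alleles=(a, b))
            except (ContractError, ValueError) as exc:
                raise ParseError(f"{gen_path}: line {line_no}: {exc}") from exc
            variants.append(rec)
            probs_rows.append(np.round(trip, _GP_DECIMALS))

    probs = np.stack(probs_rows, axis=1) if probs_rows else np.zeros((n, 0, 3))
    return ProbGenotypeMatrix(samples=samples, variants=variants, probs=probs,
                              quality=np.full(len(variants), np.nan))


def write_gen_sample(pgm: ProbGenotypeMatrix, gen_path, sample_path) -> None:
    """Write a ProbGenotypeMatrix in Oxford GEN/SAMPLE text format."""
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for s in pgm.samples:
            fh.write(f"{s} {s} 0\n")
    with open(gen_path, "w") as fh:
        for j, var in enumerate(pgm.variants):
            a, b = var.alleles
            head = f"{var.chrom} {var.vid} {var.pos} {a} {b}"
            body = " ".join(f"{x:.6f}" for x in pgm.probs[:, j, :].ravel())
            fh.write(head + " " + body + "\n")


# ---------------------------------------------------------------------------
# Report tables


def _format_cell(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, (float, np.floating)):
        return "NA" if np.isnan(x) else f"{x:.2f}"
    return str(x)


def write_tsv(df: pd.DataFrame, path, na_columns: list[str] | None = None) -> None:
    """Write a DataFrame as TSV with floats at 2 decimals and NaN as NA.

    An empty frame is written as a single all-NA row so downstream
    consumers always see the column schema.
    """
    path = Path(path)
    if df.empty:
        df = pd.DataFrame([{c: np.nan for c in df.columns}])
    out = df.copy()
    for c in out.columns:
        out[c] = out[c].map(_format_cell)
    out.to_csv(path, sep="\t", index=False)


def write_report_tables(out_dir, counts: pd.DataFrame, accuracy: pd.DataFrame,
                        quality_by_class: pd.DataFrame,
                        quality_by_maf: pd.DataFrame) -> dict[str, Path]:
    """Emit the four fixed-schema report TSVs into ``out_dir``.

    ``counts.tsv``: per stratum the imputed and overlap variant counts and
    the % of calls below the calling threshold; ``accuracy.tsv``: accuracy,
    genome-wide error and adjusted accuracy (ambiguous counted correct);
    ``quality_by_class.tsv`` and ``quality_by_maf.tsv``: imputation-quality
    summaries.  Floats are formatted at 2 decimals; absent strata print NA.
    """
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise ContractError(f"output directory {out_dir} does not exist")
    paths = {}
    for name, df in (("counts", counts), ("accuracy", accuracy),
                     ("quality_by_class", quality_by_class),
                     ("quality_by_maf", quality_by_maf)):
        p = out_dir / f"{name}.tsv"
        write_tsv(df, p)
        paths[name] = p
    return paths
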