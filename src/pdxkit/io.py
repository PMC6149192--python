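"""Readers and writers for the interchange formats.

Conventions: BED is 0-based half-open; variant positions are 1-based (VCF
convention); conversion is centralized here. Floating-point outputs are
serialized with 6 significant digits; tests compare numerically with
explicit tolerances, never serialized strings.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .wescnv import CopyNumberProfile, GeneModel

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


# --- FASTA / FASTQ ---------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """List of (read_id, sequence, quality-string)."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq), qual))
    return out


def write_fastq(path, reads: list[tuple[str, str, str]]) -> None:
    """Write (read_id, sequence, quality) triples; Sanger (phred+33) quality."""
    records = []
    for rid, seq, qual in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_reads_fastq(path, reads, quality: int = 30) -> None:
    """Write simulated reads (constant quality) and no label information."""
    q = chr(quality + 33)
    write_fastq(path, [(r.read_id, r.sequence, q * len(r.sequence)) for r in reads])


def write_read_labels(path, reads) -> None:
    """JSON sidecar: read_id -> hidden true origin."""
    with open(path, "w") as fh:
        json.dump({r.read_id: r.origin for r in reads}, fh, indent=0)


# --- BED gene models -------------------------------------------------------

def read_bed(path) -> list[GeneModel]:
    """4+ column BED (chrom, start, end, gene_id) -> merged gene models.

    Exons of one gene are merged (overlaps collapse with a warning);
    malformed lines are rejected with their line number.
    """
    raw: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"{path}:{lineno}: expected >= 4 BED columns")
            chrom, start, end, gene = parts[0], parts[1], parts[2], parts[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i >= end_i:
                raise ValidationError(
                    f"{path}:{lineno}: start >= end ({start_i} >= {end_i})"
                )
            entry = raw.setdefault(gene, {"chromosome": chrom, "intervals": []})
            if entry["chromosome"] != chrom:
                raise ValidationError(
                    f"{path}:{lineno}: gene {gene} spans multiple chromosomes"
                )
            entry["intervals"].append((start_i, end_i))
    models = []
    for gene, entry in raw.items():
        ivs = sorted(entry["intervals"])
        overlapping = any(b1 > a2 for (_, b1), (a2, _) in zip(ivs, ivs[1:]))
        if overlapping:
            log.warning("gene %s has overlapping exons; merging", gene)
        models.append(
            GeneModel(gene_id=gene, chromosome=entry["chromosome"], exon_intervals=tuple(ivs))
        )
    return models


def write_bed(path, gene_models: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        for m in gene_models:
            for a, b in m.exon_intervals:
                fh.write(f"{m.chromosome}\t{a}\t{b}\t{m.gene_id}\n")


# --- count tables ----------------------------------------------------------

def read_counts_tsv(path) -> pd.DataFrame:
    """Counts TSV: gene_id index column plus one numeric column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative counts")
    return df


def write_counts_tsv(path, counts: pd.DataFrame | pd.Series) -> None:
    frame = counts.to_frame() if isinstance(counts, pd.Series) else counts
    frame.rename_axis("gene_id").to_csv(path, sep="\t")


# --- variant tables --------------------------------------------------------

DEFAULT_COLUMN_MAP = {
    "sample_id": "sample_id",
    "chromosome": "chromosome",
    "position": "position",
    "ref_base": "ref_base",
    "alt_base": "alt_base",
    "coverage": "coverage",
    "vaf": "vaf",
    "population_maf": "population_maf",
    "consequence": "consequence",
}


def read_variant_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Typed variant records from a TSV (``column_map`` maps canonical ->
    file column names) or a VCF (by extension).

    Rows violating the record invariants are rejected together with their
    reasons; non-SNV rows (indels) are skipped with a logged count.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _read_vcf(path)
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    df = pd.read_csv(path, sep="\t")
    missing = [src for src in cmap.values() if src not in df.columns and src != "consequence"]
    missing = [m for m in missing if cmap.get("consequence") != m]
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {missing}")
    renamed = df.rename(columns={v: k for k, v in cmap.items()})
    if "consequence" not in renamed.columns:
        renamed["consequence"] = "other"
    return _validate_rows(renamed, str(path))


def _validate_rows(df: pd.DataFrame, source: str) -> pd.DataFrame:
    is_snv = df["ref_base"].astype(str).str.len().eq(1) & df["alt_base"].astype(str).str.len().eq(1)
    n_indels = int((~is_snv).sum())
    if n_indels:
        log.info("%s: skipped %d non-SNV record(s)", source, n_indels)
    df = df[is_snv].copy()
    problems = []
    vaf = pd.to_numeric(df["vaf"], errors="coerce")
    for idx in df.index[(vaf < 0) | (vaf > 1) | vaf.isna()]:
        problems.append(f"row {idx}: vaf {df.loc[idx, 'vaf']!r} outside [0, 1]")
    cov = pd.to_numeric(df["coverage"], errors="coerce")
    for idx in df.index[(cov < 0) | cov.isna()]:
        problems.append(f"row {idx}: invalid coverage {df.loc[idx, 'coverage']!r}")
    for idx in df.index[df["ref_base"] == df["alt_base"]]:
        problems.append(f"row {idx}: ref_base equals alt_base")
    if problems:
        raise ValidationError(f"{source}: invalid rows:\n" + "\n".join(problems))
    df["position"] = df["position"].astype(int)
    df["coverage"] = cov.astype(int)
    df["vaf"] = vaf.astype(float)
    df["population_maf"] = pd.to_numeric(df["population_maf"], errors="coerce")
    return df.reset_index(drop=True)


def _read_vcf(path) -> pd.DataFrame:
    """Minimal VCF reader: DP/AF/MAF/CSQ INFO keys, sample from the file."""
    import pysam

    rows = []
    n_indels = 0
    with pysam.VariantFile(str(path)) as vf:
        sample_ids = list(vf.header.samples) or [Path(path).stem]
        for rec in vf:
            alts = rec.alts or ()
            for alt in alts:
                if len(rec.ref) != 1 or len(alt) != 1:
                    n_indels += 1
                    continue
                info = rec.info
                rows.append(
                    {
                        "sample_id": sample_ids[0],
                        "chromosome": rec.chrom,
                        "position": rec.pos,
                        "ref_base": rec.ref,
                        "alt_base": alt,
                        "coverage": int(_info_get(info, "DP", 0)),
                        "vaf": float(_scalar(_info_get(info, "AF", np.nan))),
                        "population_maf": float(_scalar(_info_get(info, "MAF", np.nan))),
                        "consequence": str(_scalar(_info_get(info, "CSQ", "other"))),
                    }
                )
    if n_indels:
        log.info("%s: skipped %d indel record(s)", path, n_indels)
    cols = list(DEFAULT_COLUMN_MAP)
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        return df
    return _validate_rows(df, str(path))


def _info_get(info, key, default):
    # pysam raises on keys absent from the header, not just from the record
    try:
        return info[key]
    except (KeyError, ValueError):
        return default


def _scalar(value):
    if isinstance(value, tuple):
        return value[0]
    return value


def write_variant_table(path, records: pd.DataFrame) -> None:
    records.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# --- plasma / qPCR tables --------------------------------------------------

def read_plasma_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("patient_id", "ebv_copies_per_ml"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    if (df["ebv_copies_per_ml"] < 0).any():
        raise ValidationError(f"{path}: negative EBV load")
    return df


def write_plasma_csv(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_qpcr_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("sample_id", "target", "replicate", "ct"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return df


def write_qpcr_csv(path, measurements: pd.DataFrame) -> None:
    measurements.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# --- copy-number profiles --------------------------------------------------

def write_profile_tsv(path, profile: CopyNumberProfile, calls: pd.Series | None = None) -> None:
    frame = profile.to_frame()
    if calls is not None:
        frame = frame.join(calls)
    frame.rename_axis("gene_id").to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_profile_tsv(path, sample_id: str | None = None) -> CopyNumberProfile:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return CopyNumberProfile(
        sample_id=sample_id or Path(path).stem,
        cn=df["cn"],
        baseline=df["baseline"],
    )


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
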