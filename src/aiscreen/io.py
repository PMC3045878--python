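"""Readers/writers for the pipeline's tabular and genomic formats.

All tables are TSV with a header, UTF-8, LF line endings; "0" codes a missing
allele.  Genomic intervals are 1-based inclusive in memory and in the TSV
region format; BED input/output (0-based half-open, score in column 5) is
converted at this boundary.  Writers are deterministic: fixed column order,
input row order, so identical inputs give byte-identical files.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .screen import BindingSite, EnhancerElement, GenomicInterval, Variant

__all__ = [
    "SchemaError",
    "read_peak_table",
    "read_genotype_table",
    "read_clinic_table",
    "read_variant_table",
    "write_variant_table",
    "read_regions_table",
    "packaged_ld_regions",
    "read_bed_elements",
    "read_bed_sites",
    "write_bed_elements",
    "write_bed_sites",
    "read_fasta",
    "write_fasta",
    "write_table",
    "write_json",
    "sha256_file",
    "write_manifest",
]


class SchemaError(ValueError):
    """A table violates its schema; the message names the row and column."""


PEAK_COLUMNS = [
    "patient_id", "snp_id", "risk_allele", "neutral_allele",
    "normal_h_risk", "normal_h_neutral", "tumor_h_risk", "tumor_h_neutral",
]
GENOTYPE_COLUMNS = ["sample_id", "group", "snp_id", "allele1", "allele2"]
VARIANT_COLUMNS = ["chrom", "pos_1based", "snp_id", "ref_allele", "alt_allele"]
REGION_COLUMNS = ["chrom", "start_1based", "end_1based", "locus_name"]


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a tumour/normal peak-height table.

    Strictly negative heights are physically impossible and rejected here;
    zero or empty heights load fine and mark the record non-evaluable
    downstream.  Duplicate (patient, SNP) keys are rejected.
    """
    df = _read_tsv(path, PEAK_COLUMNS)
    for col in PEAK_COLUMNS[4:]:
        vals = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        bad_type = df.index[df[col].ne("") & vals.isna()]
        if len(bad_type):
            raise SchemaError(
                f"{path}: row {int(bad_type[0]) + 2}: column {col!r} is not numeric")
        neg = df.index[vals < 0]
        if len(neg):
            raise SchemaError(
                f"{path}: row {int(neg[0]) + 2}: negative peak height in {col!r}")
        df[col] = vals
    dup = df.duplicated(subset=["patient_id", "snp_id"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise SchemaError(f"{path}: row {row}: duplicate (patient_id, snp_id) key")
    hom = df["risk_allele"] == df["neutral_allele"]
    if hom.any():
        row = int(df.index[hom][0]) + 2
        raise SchemaError(
            f"{path}: row {row}: risk and neutral alleles identical "
            "(homozygous records are not evaluable)")
    return df


def read_genotype_table(path: str | Path) -> pd.DataFrame:
    """Load and validate a case-control genotype table."""
    df = _read_tsv(path, GENOTYPE_COLUMNS)
    bad = df.index[~df["group"].isin(["case", "control"])]
    if len(bad):
        raise SchemaError(
            f"{path}: row {int(bad[0]) + 2}: group must be 'case' or 'control'")
    empty = df.index[(df["allele1"] == "") | (df["allele2"] == "")]
    if len(empty):
        raise SchemaError(
            f"{path}: row {int(empty[0]) + 2}: empty allele (use '0' for missing)")
    dup = df.duplicated(subset=["sample_id", "snp_id"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise SchemaError(f"{path}: row {row}: duplicate (sample_id, snp_id) key")
    return df


def read_clinic_table(path: str | Path) -> pd.DataFrame:
    """Load the optional per-patient clinicopathological table."""
    df = _read_tsv(path, ["patient_id"])
    keep = ["patient_id"] + [c for c in ("stage", "grade") if c in df.columns]
    return df[keep].replace("", np.nan)


def read_variant_table(path: str | Path) -> list[Variant]:
    """Load a variant list TSV into Variant objects."""
    df = _read_tsv(path, VARIANT_COLUMNS)
    variants = []
    for idx, row in df.iterrows():
        try:
            variants.append(Variant(
                chrom=row["chrom"], pos=int(row["pos_1based"]),
                snp_id=row["snp_id"], allele_a=row["ref_allele"],
                allele_b=row["alt_allele"]))
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: row {int(idx) + 2}: {exc}") from None
    return variants


def write_variant_table(variants: Sequence[Variant], path: str | Path) -> None:
    df = pd.DataFrame([
        {"chrom": v.chrom, "pos_1based": v.pos, "snp_id": v.snp_id,
         "ref_allele": v.allele_a, "alt_allele": v.allele_b}
        for v in variants], columns=VARIANT_COLUMNS)
    write_table(df, path)


def read_regions_table(path: str | Path) -> list[GenomicInterval]:
    """Load an LD-region TSV (1-based inclusive coordinates)."""
    df = _read_tsv(path, REGION_COLUMNS)
    regions = []
    for idx, row in df.iterrows():
        try:
            regions.append(GenomicInterval(
                chrom=row["chrom"], start=int(row["start_1based"]),
                end=int(row["end_1based"]), label=row["locus_name"]))
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: row {int(idx) + 2}: {exc}") from None
    return regions


def packaged_ld_regions() -> list[GenomicInterval]:
    """The seven packaged colorectal-cancer LD regions (build-36 coordinates)."""
    ref = importlib.resources.files("aiscreen").joinpath("data/ld_regions.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_regions_table(path)


def read_bed_elements(path: str | Path) -> list[EnhancerElement]:
    """Load enhancer elements from BED (0-based half-open; score column 5)."""
    out = []
    for lineno, fields in _bed_rows(path, min_fields=5):
        chrom, start, end, name, score = fields[:5]
        out.append(EnhancerElement(
            interval=_bed_interval(chrom, start, end, name, path, lineno),
            score=float(score)))
    return out


def read_bed_sites(path: str | Path) -> list[BindingSite]:
    """Load binding sites from BED6; name column is ``tf:pattern``."""
    out = []
    for lineno, fields in _bed_rows(path, min_fields=6):
        chrom, start, end, name, score, strand = fields[:6]
        tf, _, pattern = name.partition(":")
        out.append(BindingSite(
            interval=_bed_interval(chrom, start, end, name, path, lineno),
            tf_name=tf, pattern=pattern, strand=strand,
            score=None if score in (".", "") else float(score)))
    return out


def _bed_rows(path: str | Path, min_fields: int):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise SchemaError(
                    f"{path}: line {lineno}: expected >= {min_fields} BED fields")
            yield lineno, fields


def _bed_interval(chrom, start, end, name, path, lineno) -> GenomicInterval:
    try:
        # BED is 0-based half-open; in-memory coordinates are 1-based inclusive
        return GenomicInterval(chrom=chrom, start=int(start) + 1, end=int(end),
                               label=name)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: line {lineno}: {exc}") from None


def write_bed_elements(elements: Sequence[EnhancerElement], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for e in elements:
            iv = e.interval
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.label}\t{e.score:g}\t.\n")


def write_bed_sites(sites: Sequence[BindingSite], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in sites:
            iv = s.interval
            score = "." if s.score is None else f"{s.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t"
                     f"{s.tf_name}:{s.pattern}\t{score}\t{s.strand}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load FASTA into a {name: sequence} mapping (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_table(df: pd.DataFrame, path: str | Path,
                float_format: str | None = None) -> None:
    """Deterministic TSV writer: fixed column order, input row order, LF."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n",
              float_format=float_format)


def write_json(obj, path: str | Path) -> None:
    """Full-precision JSON sidecar writer."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, default=default, allow_nan=True)
        fh.write("\n")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    *,
    command: str,
    config: Mapping,
    seed: int | None,
    inputs: Mapping[str, str | Path],
    status: str,
) -> Path:
    """Write the run manifest: config echo, seed, version, input checksums."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "package_version": __version__,
        "seed": seed,
        "config": dict(config),
        "inputs": {
            name: {"path": str(p), "sha256": sha256_file(p)}
            for name, p in inputs.items() if p is not None and Path(p).exists()
        },
        "status": status,
    }
    path = outdir / "run_manifest.json"
    write_json(manifest, path)
    return path
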