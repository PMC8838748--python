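"""Readers and writers for the formats the pipeline touches.

VCF 4.2 is read through :mod:`pysam`; per-sample ref/alt read counts come
from ``RO``/``AO`` (freebayes-style) or ``AD`` FORMAT fields. Multi-allelic
records are decomposed into one biallelic site per alternate base, with all
non-focal reads assigned to the reference count. GFF3 annotation is read
through :mod:`gffutils`, FASTA through Biopython. A human-diffable TSV count
dialect ("ref:alt" integer pairs per cell) is supported for both reading and
writing and round-trips exactly.
"""

from __future__ import annotations

import logging
import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .model import (
    BASES,
    GenomeAnnotation,
    ORF,
    SampleMeta,
    Treatment,
    VariantSite,
    VariantTable,
)

logger = logging.getLogger(__name__)

SHEET_COLUMNS = ["sample_id", "replicate_id", "treatment", "day", "batch_id"]


def read_sample_sheet(path: str) -> list[SampleMeta]:
    """Read a TSV sample sheet into a list of :class:`SampleMeta`.

    Columns: sample_id, replicate_id, treatment, day, batch_id. ``day`` may
    be empty for ancestor samples only.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet is missing columns: {sorted(missing)}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate sample_id in sheet: {dupes}")
    samples = []
    for _, row in df.iterrows():
        try:
            treatment = Treatment(row["treatment"])
        except ValueError:
            raise ValueError(
                f"sample {row['sample_id']!r}: unknown treatment "
                f"{row['treatment']!r} (expected one of "
                f"{[t.value for t in Treatment]})"
            ) from None
        day_str = row["day"].strip()
        if day_str == "":
            day: Optional[int] = None
        else:
            try:
                day = int(day_str)
            except ValueError:
                raise ValueError(
                    f"sample {row['sample_id']!r}: day must be an integer, "
                    f"got {day_str!r}"
                ) from None
        samples.append(
            SampleMeta(
                sample_id=row["sample_id"],
                replicate_id=row["replicate_id"],
                treatment=treatment,
                day=day,
                batch_id=row["batch_id"],
            )
        )
    return samples


def write_sample_sheet(samples: Sequence[SampleMeta], path: str) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "replicate_id": s.replicate_id,
            "treatment": s.treatment.value,
            "day": "" if s.day is None else s.day,
            "batch_id": s.batch_id,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------


def _counts_from_record(rec, sample_name: str, alt_index: int) -> tuple[int, int]:
    """(ref_count, alt_count) for one decomposed alt; residual alts -> ref."""
    fmt = rec.samples[sample_name]
    if "AO" in fmt and fmt.get("AO") is not None:
        ao = fmt["AO"]
        if not isinstance(ao, tuple):
            ao = (ao,)
        ao = [0 if a is None else int(a) for a in ao]
        ro = fmt.get("RO")
        ro = 0 if ro is None else int(ro)
        alt = ao[alt_index]
        ref = ro + sum(a for i, a in enumerate(ao) if i != alt_index)
        return ref, alt
    if "AD" in fmt and fmt.get("AD") is not None:
        ad = [0 if a is None else int(a) for a in fmt["AD"]]
        alt = ad[alt_index + 1]
        ref = ad[0] + sum(
            a for i, a in enumerate(ad[1:]) if i != alt_index
        )
        return ref, alt
    raise ValueError(
        f"sample {sample_name}: no RO/AO or AD FORMAT fields in record at "
        f"{rec.chrom}:{rec.pos}"
    )


def read_vcf(
    path: str,
    samples: Sequence[SampleMeta],
    min_depth: int = 10,
    min_qual: float = 20.0,
) -> VariantTable:
    """Read pooled variant calls from a VCF into a :class:`VariantTable`.

    Keeps biallelic-SNP records with QUAL >= ``min_qual``; multi-allelic
    records are decomposed into one site per alt base; indel alleles are
    skipped (a count is logged). Samples listed in the sheet must be present.
    """
    vcf = pysam.VariantFile(path)
    vcf_samples = set(vcf.header.samples)
    for s in samples:
        if s.sample_id not in vcf_samples:
            raise ValueError(f"sample {s.sample_id!r} not present in VCF {path}")

    sites: list[VariantSite] = []
    ref_rows: list[list[int]] = []
    alt_rows: list[list[int]] = []
    n_skipped_nonsnp = 0
    for rec in vcf:
        qual = rec.qual if rec.qual is not None else 0.0
        if qual < min_qual:
            continue
        if rec.ref is None or len(rec.ref) != 1 or rec.ref.upper() not in BASES:
            n_skipped_nonsnp += len(rec.alts or ())
            continue
        for alt_index, alt in enumerate(rec.alts or ()):
            if len(alt) != 1 or alt.upper() not in BASES or alt.upper() == rec.ref.upper():
                n_skipped_nonsnp += 1
                continue
            site = VariantSite(
                contig=rec.chrom,
                pos=rec.pos,
                ref_base=rec.ref.upper(),
                alt_base=alt.upper(),
                qual=float(qual),
            )
            refs, alts_ = [], []
            for s in samples:
                r, a = _counts_from_record(rec, s.sample_id, alt_index)
                refs.append(r)
                alts_.append(a)
            sites.append(site)
            ref_rows.append(refs)
            alt_rows.append(alts_)
    if n_skipped_nonsnp:
        logger.info("skipped %d non-SNP alleles in %s", n_skipped_nonsnp, path)
    shape = (len(sites), len(samples))
    return VariantTable(
        sites=sites,
        samples=list(samples),
        ref_counts=np.array(ref_rows, dtype=np.int64).reshape(shape),
        alt_counts=np.array(alt_rows, dtype=np.int64).reshape(shape),
        min_depth=min_depth,
    )


def read_count_table(
    path: str,
    samples: Sequence[SampleMeta],
    min_depth: int = 10,
    min_qual: float = 20.0,
) -> VariantTable:
    """Read the TSV count dialect: one row per site, "ref:alt" per sample."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    fixed = ["contig", "pos", "ref", "alt", "qual"]
    missing = set(fixed) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    for s in samples:
        if s.sample_id not in df.columns:
            raise ValueError(f"sample {s.sample_id!r} not present in {path}")
    sites, ref_rows, alt_rows = [], [], []
    for _, row in df.iterrows():
        qual = float(row["qual"])
        if qual < min_qual:
            continue
        sites.append(
            VariantSite(
                contig=row["contig"],
                pos=int(row["pos"]),
                ref_base=row["ref"],
                alt_base=row["alt"],
                qual=qual,
            )
        )
        refs, alts_ = [], []
        for s in samples:
            r, a = row[s.sample_id].split(":")
            refs.append(int(r))
            alts_.append(int(a))
        ref_rows.append(refs)
        alt_rows.append(alts_)
    shape = (len(sites), len(samples))
    return VariantTable(
        sites=sites,
        samples=list(samples),
        ref_counts=np.array(ref_rows, dtype=np.int64).reshape(shape),
        alt_counts=np.array(alt_rows, dtype=np.int64).reshape(shape),
        min_depth=min_depth,
    )


def read_variant_table(
    path: str,
    samples: Sequence[SampleMeta],
    min_depth: int = 10,
    min_qual: float = 20.0,
) -> VariantTable:
    """Read a variant table from VCF (.vcf/.vcf.gz/.bcf) or count TSV."""
    lower = str(path).lower()
    if lower.endswith((".vcf", ".vcf.gz", ".bcf")):
        return read_vcf(path, samples, min_depth=min_depth, min_qual=min_qual)
    return read_count_table(path, samples, min_depth=min_depth, min_qual=min_qual)


def write_variant_table(
    table: VariantTable,
    path: str,
    format: str = "tsv",
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write a table as count TSV or VCF 4.2 (FORMAT RO:AO:DP).

    Round-trip safe: reading the written file with the same ``min_depth`` and
    a ``min_qual`` at or below the table's smallest QUAL reproduces counts,
    quals, and missingness exactly.
    """
    if format == "tsv":
        _write_tsv(table, path)
    elif format == "vcf":
        _write_vcf(table, path, contig_lengths or {})
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'vcf')")


def _write_tsv(table: VariantTable, path: str) -> None:
    cols = ["contig", "pos", "ref", "alt", "qual"] + [
        s.sample_id for s in table.samples
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, site in enumerate(table.sites):
            cells = [
                site.contig,
                str(site.pos),
                site.ref_base,
                site.alt_base,
                repr(site.qual),
            ]
            cells += [
                f"{table.ref_counts[i, j]}:{table.alt_counts[i, j]}"
                for j in range(table.n_samples)
            ]
            fh.write("\t".join(cells) + "\n")


def _write_vcf(
    table: VariantTable, path: str, contig_lengths: dict[str, int]
) -> None:
    contigs = {}
    for site in table.sites:
        length = contig_lengths.get(site.contig)
        contigs.setdefault(site.contig, length)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=poolsweep\n")
        for contig, length in contigs.items():
            if length is not None:
                fh.write(f"##contig=<ID={contig},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Reference allele observation count">\n')
        fh.write('##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += [s.sample_id for s in table.samples]
        fh.write("\t".join(header) + "\n")
        for i, site in enumerate(table.sites):
            row = [
                site.contig,
                str(site.pos),
                ".",
                site.ref_base,
                site.alt_base,
                repr(site.qual),
                "PASS",
                f"DP={int(table.depth[i].sum())}",
                "RO:AO:DP",
            ]
            for j in range(table.n_samples):
                r = int(table.ref_counts[i, j])
                a = int(table.alt_counts[i, j])
                row.append(f"{r}:{a}:{r + a}")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# annotation & sequence
# ---------------------------------------------------------------------------


def _strand_from_name(name: str) -> str:
    # Chlorovirus gene tags encode transcription direction: trailing R = "+",
    # trailing L = "-" (e.g. A540L, A078R).
    stripped = name.rstrip("0123456789")
    if stripped.endswith("R"):
        return "+"
    if stripped.endswith("L"):
        return "-"
    raise ValueError(
        f"cannot infer strand for ORF {name!r}: no explicit strand and no "
        f"R/L suffix"
    )


def read_annotation(
    path: str,
    genome_length: Optional[int] = None,
    contig: Optional[str] = None,
    sequence: Optional[str] = None,
) -> GenomeAnnotation:
    """Read ORF annotation from GFF3 (CDS grouped by parent) or TSV.

    The TSV dialect has columns name, start, end and optionally strand; when
    strand is absent it is inferred from the R/L suffix of the gene name.
    ORFs whose total CDS length is not a multiple of 3 are kept but flagged
    (``frame_ok=False``): excluded from codon classification, included in
    enrichment scans.
    """
    lower = str(path).lower()
    if lower.endswith((".gff", ".gff3")):
        return _read_gff3(path, genome_length, contig, sequence)
    return _read_annotation_tsv(path, genome_length, contig, sequence)


def _read_annotation_tsv(path, genome_length, contig, sequence):
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"name", "start", "end"} <= set(df.columns):
        raise ValueError("annotation TSV needs columns name, start, end[, strand]")
    orfs: dict[str, dict] = {}
    for _, row in df.iterrows():
        name = row["name"]
        strand = row.get("strand", "").strip() or None
        if strand in ("−",):  # tolerate unicode minus
            strand = "-"
        if strand is None:
            strand = _strand_from_name(name)
        entry = orfs.setdefault(name, {"segments": [], "strand": strand})
        entry["segments"].append((int(row["start"]), int(row["end"])))
    built = [
        ORF(name=name, segments=tuple(sorted(e["segments"])), strand=e["strand"])
        for name, e in orfs.items()
    ]
    return _finish_annotation(built, genome_length, contig, sequence)


def _read_gff3(path, genome_length, contig, sequence):
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    region_length, region_contig = None, None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                region_contig, region_length = parts[1], int(parts[3])
            elif not line.startswith("#"):
                break
    groups: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent") or cds.attributes.get("ID") or ["cds"]
        key = parents[0]
        names = cds.attributes.get("gene") or cds.attributes.get("Name") or [key]
        entry = groups.setdefault(
            key, {"segments": [], "strand": cds.strand, "name": names[0]}
        )
        entry["segments"].append((cds.start, cds.end))
    built = [
        ORF(
            name=e["name"],
            segments=tuple(sorted(e["segments"])),
            strand=e["strand"],
        )
        for e in groups.values()
    ]
    built.sort(key=lambda o: o.start)
    return _finish_annotation(
        built, genome_length or region_length, contig or region_contig, sequence
    )


def _finish_annotation(orfs, genome_length, contig, sequence):
    if genome_length is None and sequence is not None:
        genome_length = len(sequence)
    if genome_length is None:
        raise ValueError(
            "genome_length is required (no ##sequence-region directive, no "
            "sequence, and no explicit length given)"
        )
    for orf in orfs:
        if not orf.frame_ok:
            logger.warning(
                "ORF %s: CDS length %d not a multiple of 3; excluded from "
                "codon classification",
                orf.name,
                orf.length,
            )
    return GenomeAnnotation(
        contig=contig or "contig1",
        genome_length=genome_length,
        orfs=list(orfs),
        sequence=sequence,
    )


def read_fasta(path: str) -> tuple[str, str]:
    """Read the first record of a FASTA file as (name, sequence)."""
    rec = next(SeqIO.parse(path, "fasta"))
    return rec.id, str(rec.seq).upper()


def write_fasta(name: str, sequence: str, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


__all__ = [
    "read_sample_sheet",
    "write_sample_sheet",
    "read_vcf",
    "read_count_table",
    "read_variant_table",
    "write_variant_table",
    "read_annotation",
    "read_fasta",
    "write_fasta",
]
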