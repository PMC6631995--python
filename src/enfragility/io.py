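"""Readers and writers for the plain-text formats the pipeline touches.

FASTA (case-sensitive), BED3/BED6, bedGraph and a minimal VCF surface
(CHROM/POS/REF/ALT only).  Every path may be gzip-compressed (``.gz``).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, List, Tuple, Union

import pandas as pd
from Bio import SeqIO

from .core import Genome, GenomicInterval, SignalTrack, VariantRecord

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> Genome:
    """Read a FASTA file into a :class:`Genome`, preserving case and order.

    Duplicate record names, empty records and non-``ACGTN`` characters are
    hard errors (validated by the ``Genome`` constructor).
    """
    with _open_text(path) as fh:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
    return Genome(records)


def write_fasta(genome: Genome, path: PathLike, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: PathLike) -> List[GenomicInterval]:
    """Read BED3/BED6 intervals (0-based half-open; col 4 = id, col 6 = strand)."""
    out: List[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = fields[:3]
            start, end = int(start_s), int(end_s)
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: end {end} <= start {start}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike,
              extra_cols=None) -> None:
    """Write BED6; ``extra_cols`` (parallel list of lists) appends columns."""
    extra_cols = extra_cols or {}
    with _open_text(path, "wt") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end),
                      iv.id or ".", "0", iv.strand]
            if extra_cols:
                fields += [str(c[i]) for c in extra_cols]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: PathLike, name: str | None = None) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Intervals are sorted; adjacent intervals with equal value are coalesced;
    overlaps and negative values are rejected.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: fewer than 4 columns")
            value = float(fields[3])
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative value {value}")
            rows.append((fields[0], int(fields[1]), int(fields[2]), value))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    # coalesce adjacent equal-valued intervals
    merged = []
    for chrom, grp in df.groupby("chrom", sort=False):
        cur = None
        for r in grp.itertuples():
            if cur is not None and r.start == cur[2] and r.value == cur[3]:
                cur = (cur[0], cur[1], r.end, cur[3])
            else:
                if cur is not None:
                    merged.append(cur)
                cur = (chrom, r.start, r.end, r.value)
        if cur is not None:
            merged.append(cur)
    out = pd.DataFrame(merged, columns=["chrom", "start", "end", "value"])
    return SignalTrack(name or Path(path).stem, out)


def write_bedgraph(track: SignalTrack, path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for r in track.data.itertuples():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.value:g}\n")


# ---------------------------------------------------------------------------
# minimal VCF


def read_vcf_lite(path: PathLike, genome: Genome) -> List[VariantRecord]:
    """Read CHROM/POS/REF/ALT from a VCF; other columns and headers ignored.

    POS is converted from 1-based to the package's 0-based convention;
    multiallelic ALT fields are split into one record per allele; indels
    (multi-base REF or ALT) are rejected; REF must match the genome base
    (case-insensitively).
    """
    out: List[VariantRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: fewer than 5 VCF columns")
            chrom, pos_s, _id, ref, alt_field = fields[:5]
            pos = int(pos_s) - 1
            if len(ref) != 1:
                raise ValueError(
                    f"{path}:{lineno}: indel REF {ref!r} not supported"
                )
            for alt in alt_field.split(","):
                if len(alt) != 1:
                    raise ValueError(
                        f"{path}:{lineno}: indel ALT {alt!r} not supported"
                    )
                rec = VariantRecord(chrom, pos, ref, alt)
                rec.check_against(genome)
                out.append(rec)
    return out


def write_vcf_lite(variants: Iterable[VariantRecord], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n")
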