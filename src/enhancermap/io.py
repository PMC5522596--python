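"""Readers and writers for BED, bedGraph, fixed-step WIG, GFF3 and the
tab-delimited methylation and expression tables.

BED and bedGraph files are the interchange formats for peaks, low-methylation
regions, masks and signal; GFF3 carries gene and TE annotation (1-based closed
coordinates, converted to 0-based half-open on read). All writers emit sorted,
deterministic output.
"""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Tuple

import gffutils
import numpy as np
import pandas as pd

from .intervals import Genome, GenomicInterval, IntervalSet, SignalTrack
from .partition import GeneModel
from .te_stats import TEAnnotation

__all__ = [
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_wig",
    "read_gff3_genes",
    "read_gff3_tes",
    "read_methylation_table",
    "write_methylation_table",
    "read_expression_table",
    "write_expression_table",
    "read_genome_file",
    "write_genome_file",
]

METHYLATION_COLUMNS = ["chrom", "pos", "context", "frequency", "coverage"]
EXPRESSION_COLUMNS = [
    "gene_id",
    "rpkm_v2_ist",
    "rpkm_husk",
    "significant_de",
    "higher_tissue",
]


class BedParseError(ValueError):
    """Malformed BED/bedGraph line; message carries the 1-based line number."""


def read_bed(path: str) -> IntervalSet:
    """Read a BED3/BED6 file into an :class:`IntervalSet`."""
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: coordinates must be integers"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, strand=strand, name=name)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals)


def write_bed(ivset: IntervalSet, path: str) -> None:
    with open(path, "w") as fh:
        for iv in ivset:
            if iv.name is None and iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = iv.name if iv.name is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bedgraph(path: str) -> SignalTrack:
    steps: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 fields")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: malformed bedGraph line") from exc
            if end <= start:
                raise BedParseError(f"{path}:{lineno}: end must exceed start")
            steps.setdefault(fields[0], []).append((start, end, value))
    return SignalTrack(steps)


def write_bedgraph(track: SignalTrack, path: str, skip_zero: bool = True) -> None:
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            for start, end, value in track.steps_on(chrom):
                if skip_zero and value == 0:
                    continue
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_wig(path: str) -> SignalTrack:
    """Read a fixed-step WIG file and convert to a step track.

    Only ``fixedStep`` declarations are supported; WIG is 1-based, converted
    to 0-based half-open steps of ``span`` bp.
    """
    steps: Dict[str, List[Tuple[int, int, float]]] = {}
    chrom: Optional[str] = None
    pos = 0
    step = span = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                params = dict(
                    kv.split("=") for kv in line.split()[1:] if "=" in kv
                )
                chrom = params["chrom"]
                pos = int(params["start"]) - 1
                step = int(params.get("step", 1))
                span = int(params.get("span", step))
                continue
            if line.startswith("variableStep"):
                raise BedParseError(
                    f"{path}:{lineno}: variableStep WIG is not supported"
                )
            if chrom is None:
                raise BedParseError(
                    f"{path}:{lineno}: data line before fixedStep declaration"
                )
            value = float(line)
            steps.setdefault(chrom, []).append((pos, pos + span, value))
            pos += step
    return SignalTrack(steps)


def read_gff3_genes(path: str) -> List[GeneModel]:
    """Read gene models (gene + exon features) from GFF3."""
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    genes: List[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(g, featuretype="exon", order_by="start")
        ]
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand if g.strand in ("+", "-") else "+",
                exons=exons,
            )
        )
    genes.sort(key=lambda gm: (gm.chrom, gm.start, gm.end))
    return genes


def read_gff3_tes(path: str) -> List[TEAnnotation]:
    """Read TE annotation from GFF3; family/superfamily from attributes."""
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    tes: List[TEAnnotation] = []
    for f in db.all_features():
        family = f.attributes.get("family", [None])[0] or f.attributes.get(
            "Name", [None]
        )[0]
        if family is None:
            continue
        superfamily = f.attributes.get("superfamily", ["other"])[0]
        tes.append(
            TEAnnotation(
                interval=GenomicInterval(f.seqid, f.start - 1, f.end, name=f.id),
                family=family,
                superfamily=superfamily,
            )
        )
    tes.sort(key=lambda t: (t.interval.chrom, t.interval.start, t.interval.end))
    return tes


def read_methylation_table(path: str) -> pd.DataFrame:
    """Per-cytosine methylation: chrom, pos (0-based), context, frequency, coverage."""
    df = pd.read_csv(
        path, sep="\t",
        names=METHYLATION_COLUMNS if _headerless(path, "chrom") else None,
        header=None if _headerless(path, "chrom") else 0,
        dtype={"chrom": str, "pos": np.int64, "context": str,
               "frequency": float, "coverage": np.int64},
    )
    bad = df[(df["frequency"] < 0) | (df["frequency"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: methylation frequencies outside [0, 1]")
    return df


def _headerless(path: str, first_col: str) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return not first.startswith(first_col)


def write_methylation_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, columns=METHYLATION_COLUMNS)


def read_expression_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing expression columns {sorted(missing)}")
    df["significant_de"] = df["significant_de"].astype(bool)
    return df


def write_expression_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_genome_file(path: str) -> Genome:
    """Two-column chrom-sizes file (samtools faidx style: name, length)."""
    lengths: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.split("\t")
            lengths[fields[0]] = int(fields[1])
    return Genome(lengths)


def write_genome_file(genome: Genome, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chromosomes:
            fh.write(f"{chrom}\t{genome[chrom]}\n")
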