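"""Partition of the genome into promoter, exon, intron, flanking, TE and
distal classes, and feature distribution/occupancy statistics.

Every base of the genome belongs to exactly one class. Where definitions
overlap, precedence is exon > intron > promoter > flanking > TE > distal, so
"TE" means intergenic TE space outside promoters and gene-flanking regions,
and TEs inside introns count as intron.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .config import PipelineConfig
from .intervals import Genome, GenomicInterval, IntervalSet

__all__ = ["GeneModel", "RegionPartition", "partition", "classify_features", "REGION_CLASSES"]

REGION_CLASSES = ("exon", "intron", "promoter", "flanking", "TE", "distal")


@dataclass
class GeneModel:
    """A gene with exon structure; TSS/TTS are strand-aware half-open ends."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            warnings.warn(
                f"gene {self.gene_id} has no annotated exons; treating as single-exon"
            )
            self.exons = [(self.start, self.end)]
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) outside gene body")

    @property
    def tss(self) -> int:
        """Position of the first transcribed base (start if +, end-1 if -)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Position of the last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               strand=self.strand, name=self.gene_id)


@dataclass
class RegionPartition:
    """Mapping region class -> merged IntervalSet; disjoint and exhaustive."""

    classes: Dict[str, IntervalSet]
    genome: Genome

    def __getitem__(self, cls: str) -> IntervalSet:
        return self.classes[cls]

    @property
    def genic_and_promoter(self) -> IntervalSet:
        """Exon + intron + promoter bp: the exclusion zone for intergenic candidates."""
        combined = [iv for cls in ("exon", "intron", "promoter")
                    for iv in self.classes[cls]]
        return IntervalSet(combined).merge()

    @property
    def intergenic(self) -> IntervalSet:
        """flanking + TE + distal (everything outside genes and promoters)."""
        combined = [iv for cls in ("flanking", "TE", "distal")
                    for iv in self.classes[cls]]
        return IntervalSet(combined).merge()

    def class_of(self, iv: GenomicInterval) -> str:
        """Class of the interval's midpoint."""
        mid = GenomicInterval(iv.chrom, iv.midpoint, iv.midpoint + 1)
        for cls in REGION_CLASSES:
            if self.classes[cls].overlaps(mid):
                return cls
        raise ValueError(
            f"position {iv.chrom}:{iv.midpoint} not covered by the partition"
        )

    def check_exhaustive(self) -> None:
        total = sum(self.classes[c].total_bp() for c in REGION_CLASSES)
        if total != self.genome.total_bp():
            raise AssertionError(
                f"partition covers {total} bp, genome has {self.genome.total_bp()}"
            )


def _clip(chrom: str, start: int, end: int, genome: Genome) -> Optional[GenomicInterval]:
    start = max(0, start)
    end = min(end, genome[chrom])
    if end <= start:
        return None
    return GenomicInterval(chrom, start, end)


def partition(
    genes: Sequence[GeneModel],
    tes: IntervalSet,
    genome: Genome,
    config: Optional[PipelineConfig] = None,
) -> RegionPartition:
    """Assign every base to one region class.

    Promoters span ``promoter_upstream_bp`` upstream to
    ``promoter_downstream_bp`` downstream of the TSS (strand-aware) minus
    genic bp; flanking regions extend ``flank_upstream_bp`` upstream of the
    promoter and ``flank_downstream_bp`` downstream of the TTS.
    """
    config = config or PipelineConfig()
    genic = IntervalSet([g.interval for g in genes]).merge()
    exon = IntervalSet(
        [GenomicInterval(g.chrom, s, e) for g in genes for s, e in g.exons]
    ).merge()
    intron = genic.subtract(exon)

    prom_raw: List[GenomicInterval] = []
    flank_raw: List[GenomicInterval] = []
    up, down = config.promoter_upstream_bp, config.promoter_downstream_bp
    fup, fdown = config.flank_upstream_bp, config.flank_downstream_bp
    for g in genes:
        if g.chrom not in genome:
            warnings.warn(f"gene {g.gene_id} on unknown chromosome {g.chrom}; skipped")
            continue
        if g.strand == "+":
            prom = _clip(g.chrom, g.start - up, g.start + down, genome)
            flank_u = _clip(g.chrom, g.start - up - fup, g.start - up, genome)
            flank_d = _clip(g.chrom, g.end, g.end + fdown, genome)
        else:
            prom = _clip(g.chrom, g.end - down, g.end + up, genome)
            flank_u = _clip(g.chrom, g.end + up, g.end + up + fup, genome)
            flank_d = _clip(g.chrom, g.start - fdown, g.start, genome)
        for iv, dest in ((prom, prom_raw), (flank_u, flank_raw), (flank_d, flank_raw)):
            if iv is not None:
                dest.append(iv)

    promoter = IntervalSet(prom_raw).merge().subtract(genic)
    higher = IntervalSet(list(genic) + list(promoter)).merge()
    flanking = IntervalSet(flank_raw).merge().subtract(higher)
    higher = IntervalSet(list(higher) + list(flanking)).merge()
    te_class = tes.merge().subtract(higher)
    covered = IntervalSet(list(higher) + list(te_class)).merge()
    distal = genome.as_interval_set().subtract(covered)

    part = RegionPartition(
        classes={
            "exon": exon,
            "intron": intron,
            "promoter": promoter,
            "flanking": flanking,
            "TE": te_class,
            "distal": distal,
        },
        genome=genome,
    )
    part.check_exhaustive()
    return part


def classify_features(
    features: IntervalSet,
    part: RegionPartition,
    mappable_mask: Optional[IntervalSet] = None,
) -> Dict[str, Dict[str, float]]:
    """Per-class feature counts (by midpoint) and occupied bp within the mask.

    Returns ``{class: {"count": n, "occupied_bp": bp, "fraction": occupied/mask bp}}``.
    """
    mask = mappable_mask if mappable_mask is not None else part.genome.as_interval_set()
    out: Dict[str, Dict[str, float]] = {
        cls: {"count": 0, "occupied_bp": 0, "fraction": 0.0} for cls in REGION_CLASSES
    }
    for iv in features:
        out[part.class_of(iv)]["count"] += 1
    feat_in_mask = features.merge().intersect(mask)
    for cls in REGION_CLASSES:
        cls_in_mask = part[cls].intersect(mask)
        occupied = feat_in_mask.intersect(cls_in_mask).total_bp()
        denom = cls_in_mask.total_bp()
        out[cls]["occupied_bp"] = occupied
        out[cls]["fraction"] = occupied / denom if denom else 0.0
    return out
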