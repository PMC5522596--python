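"""Linking enhancer candidates to putative target genes.

Enhancers are assumed to regulate their nearest upstream or downstream gene.
A tissue-specific candidate is linked to a flanking gene when that gene is
significantly differentially expressed with the higher expression in the
candidate's tissue; a shared candidate is linked to flanking genes expressed
(>= 1 RPKM) in both tissues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .candidates import EnhancerCandidate
from .config import PipelineConfig
from .intervals import IntervalSet, nearest_flanking
from .partition import GeneModel

__all__ = ["TargetLink", "link_targets"]


@dataclass
class TargetLink:
    """Target-gene assignment for one candidate."""

    candidate_id: str
    link_category: str  # "one_gene" | "both_genes" | "unlinked"
    genes: List[str] = field(default_factory=list)
    directions: List[str] = field(default_factory=list)  # "upstream"/"downstream"

    def __post_init__(self) -> None:
        expected = {"one_gene": 1, "both_genes": 2, "unlinked": 0}[self.link_category]
        if len(self.genes) != expected:
            raise ValueError(
                f"{self.link_category} link must name {expected} gene(s), got {self.genes}"
            )


def _gene_links(
    cand: EnhancerCandidate,
    gene: Optional[GeneModel],
    expr: pd.DataFrame,
    min_rpkm: float,
) -> bool:
    if gene is None or gene.gene_id not in expr.index:
        return False
    rec = expr.loc[gene.gene_id]
    if cand.specificity == "shared":
        return rec["rpkm_v2_ist"] >= min_rpkm and rec["rpkm_husk"] >= min_rpkm
    tissue = cand.specificity.removesuffix("-specific")
    return bool(rec["significant_de"]) and rec["higher_tissue"] == tissue


def link_targets(
    candidates: Sequence[EnhancerCandidate],
    genes: Sequence[GeneModel],
    expression: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
) -> Dict[str, TargetLink]:
    """Assign target genes to every candidate; keyed by a stable candidate id.

    ``expression`` must carry gene_id, rpkm_v2_ist, rpkm_husk,
    significant_de and higher_tissue columns. Genes overlapping a candidate
    (which intergenic filtering should preclude) are excluded defensively.
    """
    config = config or PipelineConfig()
    expr = expression.set_index("gene_id") if "gene_id" in expression.columns else expression
    gene_set = IntervalSet([g.interval for g in genes])
    by_id = {g.gene_id: g for g in genes}
    links: Dict[str, TargetLink] = {}
    for cand in candidates:
        if cand.specificity is None:
            raise ValueError("candidates must carry a specificity label before linking")
        cid = next(iter(cand.candidate_id.values()), None) or (
            f"{cand.region.chrom}:{cand.region.start}-{cand.region.end}"
        )
        up_iv, down_iv, _, _ = nearest_flanking(cand.region, gene_set)
        up = by_id.get(up_iv.name) if up_iv is not None else None
        down = by_id.get(down_iv.name) if down_iv is not None else None
        if up is None and down is None:
            warnings.warn(f"candidate {cid} has no flanking gene on either side")
        linked: List[str] = []
        directions: List[str] = []
        for gene, direction in ((up, "upstream"), (down, "downstream")):
            if gene is not None and gene.interval.overlaps(cand.region):
                continue
            if _gene_links(cand, gene, expr, config.expressed_min_rpkm):
                linked.append(gene.gene_id)
                directions.append(direction)
        category = {0: "unlinked", 1: "one_gene", 2: "both_genes"}[len(linked)]
        links[cid] = TargetLink(
            candidate_id=cid, link_category=category,
            genes=linked, directions=directions,
        )
    return links


def link_category_counts(links: Dict[str, TargetLink]) -> Dict[str, int]:
    counts = {"one_gene": 0, "both_genes": 0, "unlinked": 0}
    for link in links.values():
        counts[link.link_category] += 1
    return counts
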