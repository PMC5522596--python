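"""End-to-end orchestration: from replicate peaks, methylation and
annotation to ranked, linked, profiled enhancer candidates.

The stages follow the three-step integration design: (1) per-dataset feature
calling (replicate consensus for DNase and H3K9ac, LUMR segmentation for
methylation), (2) intersection of the three features outside genes and
promoters, (3) tissue-contrast ranking, then target-gene linking and the
descriptive analyses (orientation/clustering, TE and motif enrichment,
overlap tables).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import candidates as cand_mod
from . import methylation as meth_mod
from .candidates import EnhancerCandidate, TISSUES
from .config import PipelineConfig
from .consensus import ReplicatePeakSet, consensus
from .intervals import Genome, GenomicInterval, IntervalSet, SignalTrack
from .linking import TargetLink, link_category_counts, link_targets
from .partition import GeneModel, RegionPartition, classify_features, partition
from .profiling import OrientedDHS, build_matrix, kmeans_categories, orient_dhs
from .reporting import distance_stats, overlap_table
from .te_stats import (
    TEAnnotation,
    cns_overlap,
    family_enrichment,
    resolve_nested_and_filter,
    te_containment,
)

__all__ = ["PipelineResult", "run_pipeline", "evaluate_against_truth"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    partition: RegionPartition
    dhs_consensus: Dict[str, IntervalSet]
    k9_consensus: Dict[str, IntervalSet]
    lumrs: IntervalSet
    candidates: List[EnhancerCandidate]
    ranked: Dict[str, List[EnhancerCandidate]]
    links: Dict[str, TargetLink]
    link_counts: Dict[str, int]
    oriented: Dict[str, List[OrientedDHS]]
    categories: Dict[str, np.ndarray]
    family_enrichment: List
    te_pairs: list
    cns_count: int
    tables: Dict
    distances: Dict[str, Dict[str, float]]

    @property
    def counts(self) -> Dict[str, int]:
        by = {"V2-IST": 0, "husk": 0, "shared": 0}
        for c in self.candidates:
            if c.specificity == "shared":
                by["shared"] += 1
            else:
                by[c.specificity.removesuffix("-specific")] += 1
        per_tissue = {
            t: sum(1 for c in self.candidates if t in c.tissues_detected)
            for t in TISSUES
        }
        return {
            "n_v2": per_tissue["V2-IST"],
            "n_husk": per_tissue["husk"],
            "n_shared": by["shared"],
            "n_v2_specific": by["V2-IST"],
            "n_husk_specific": by["husk"],
            "n_union": len(self.candidates),
        }

    def candidate_table(self, tissue: str) -> pd.DataFrame:
        rows = []
        for c in self.ranked[tissue]:
            rows.append({
                "chrom": c.region.chrom,
                "start": c.region.start,
                "end": c.region.end,
                "candidate_id": c.candidate_id[tissue],
                "dnase_rank": c.dnase_rank[tissue],
                "k9_rank": c.k9_rank[tissue],
                "rank_sum": c.rank_sum[tissue],
                "overall_rank": c.overall_rank[tissue],
                "rank_p": c.rank_p.get(tissue, np.nan),
                "specificity": c.specificity,
                "cns": c.cns,
            })
        return pd.DataFrame(rows)


def run_pipeline(
    genes: Sequence[GeneModel],
    tes: Sequence[TEAnnotation],
    genome: Genome,
    replicate_peaks: Dict[str, Dict[str, List[IntervalSet]]],
    tracks: Dict[str, Dict[str, SignalTrack]],
    methylation: pd.DataFrame,
    expression: pd.DataFrame,
    mask: Optional[IntervalSet] = None,
    cns: Optional[IntervalSet] = None,
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
) -> PipelineResult:
    """Run candidate identification, ranking, linking and enrichment."""
    config = config or PipelineConfig()
    mask = mask if mask is not None else genome.as_interval_set()

    part = partition(genes, IntervalSet([t.interval for t in tes]), genome, config)

    def _consensus(assay: str) -> Dict[str, IntervalSet]:
        out = {}
        for tissue in TISSUES:
            reps = [
                ReplicatePeakSet(tissue, assay, f"{assay}-{tissue}-{i}", peaks)
                for i, peaks in enumerate(replicate_peaks[assay][tissue], start=1)
            ]
            out[tissue] = consensus(reps, min_frac=config.replicate_overlap_frac)
        return out

    dhs_consensus = _consensus("DNase")
    k9_consensus = _consensus("H3K9ac")

    lumrs = meth_mod.call_lumrs(
        methylation,
        threshold=config.methylation_threshold,
        min_sites=config.methylation_min_sites,
        max_gap_bp=config.methylation_max_gap_bp,
        window=config.methylation_window_bp,
    )

    per_tissue = cand_mod.integrate(lumrs, dhs_consensus, k9_consensus, part)
    candidates = cand_mod.classify_specificity(per_tissue["V2-IST"], per_tissue["husk"])

    ranked: Dict[str, List[EnhancerCandidate]] = {}
    for i, tissue in enumerate(TISSUES):
        ranked[tissue] = cand_mod.rank_candidates(
            candidates, tracks["DNase"], tracks["H3K9ac"], tissue
        )
        if ranked[tissue]:
            sums = [c.rank_sum[tissue] for c in ranked[tissue]]
            p = cand_mod.rank_permutation_p(
                len(sums), sums, n_perm=config.n_permutations,
                seed=seed * 10 + i, n_features=2,
            )
            for c, pv in zip(ranked[tissue], p):
                c.rank_p[tissue] = float(pv)

    links = link_targets(candidates, genes, expression, config)
    link_counts = link_category_counts(links)

    # orientation and profile categories per tissue, on candidate DHSs
    oriented: Dict[str, List[OrientedDHS]] = {}
    categories: Dict[str, np.ndarray] = {}
    for tissue in TISSUES:
        dhs_ivs: List[GenomicInterval] = []
        ids: List[str] = []
        for c in ranked[tissue]:
            for dhs in c.dhs_list.get(tissue, []):
                dhs_ivs.append(dhs)
                ids.append(c.candidate_id[tissue])
        oriented[tissue] = orient_dhs(
            dhs_ivs, tracks["H3K9ac"][tissue],
            flank=config.orientation_flank_bp,
            min_rpm=config.asym_min_rpm, fold=config.asym_fold,
            genome=genome, candidate_ids=ids,
        )
        if len(oriented[tissue]) >= config.kmeans_k:
            mat = build_matrix(
                oriented[tissue], tracks["H3K9ac"][tissue],
                flank_bp=config.heatmap_flank_bp,
                body_bins=config.body_bins, flank_bin_bp=config.flank_bin_bp,
                genome=genome,
            )
            categories[tissue], _ = kmeans_categories(
                mat, k=config.kmeans_k, seed=seed
            )
        else:
            categories[tissue] = np.array([], dtype=int)

    baseline = resolve_nested_and_filter(
        tes, part["intron"], min_len=config.te_baseline_min_len_bp
    )
    containment = te_containment(
        [c.region for c in candidates], baseline,
        min_frac=config.te_containment_frac,
    )
    fam = family_enrichment(containment.pairs, baseline)

    cns_count = 0
    if cns is not None:
        flags, cns_count = cns_overlap([c.region for c in candidates], cns)
        for c, f in zip(candidates, flags):
            c.cns = f

    intergenic_dhs = {
        t: IntervalSet([iv for iv in dhs_consensus[t]
                        if not part.genic_and_promoter.overlaps(iv)])
        for t in TISSUES
    }
    intergenic_k9 = {
        t: IntervalSet([iv for iv in k9_consensus[t]
                        if not part.genic_and_promoter.overlaps(iv)])
        for t in TISSUES
    }
    tables = overlap_table(intergenic_dhs, intergenic_k9, lumrs)

    gene_set = IntervalSet([g.interval for g in genes])
    distances = {
        tissue: distance_stats(ranked[tissue], gene_set) for tissue in TISSUES
    }

    return PipelineResult(
        config=config, partition=part,
        dhs_consensus=dhs_consensus, k9_consensus=k9_consensus,
        lumrs=lumrs, candidates=candidates, ranked=ranked,
        links=links, link_counts=link_counts,
        oriented=oriented, categories=categories,
        family_enrichment=fam, te_pairs=containment.pairs,
        cns_count=cns_count, tables=tables, distances=distances,
    )


def evaluate_against_truth(result: PipelineResult, truth) -> Dict[str, float]:
    """Precision/recall of candidates against planted enhancers.

    A planted enhancer is recovered when a candidate overlaps it by >= 1 bp;
    its label is correct when that candidate was detected in exactly the
    planted tissue pattern. Precision counts candidates overlapping any
    planted enhancer.
    """
    planted = [e for e in truth.enhancers]
    planted_set = IntervalSet([e.interval for e in planted])
    n_recovered = 0
    n_correct_label = 0
    for enh in planted:
        hits = [c for c in result.candidates if c.region.overlaps(enh.interval)]
        if hits:
            n_recovered += 1
            if any(sorted(c.tissues_detected) == sorted(enh.tissues) for c in hits):
                n_correct_label += 1
    n_true_pos = sum(
        1 for c in result.candidates if planted_set.overlaps(c.region)
    )
    n_candidates = len(result.candidates)
    return {
        "n_planted": len(planted),
        "n_candidates": n_candidates,
        "recall": n_recovered / len(planted) if planted else float("nan"),
        "precision": n_true_pos / n_candidates if n_candidates else float("nan"),
        "label_accuracy": n_correct_label / n_recovered if n_recovered else float("nan"),
    }
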