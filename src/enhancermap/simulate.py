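"""Truth-annotated synthetic dataset exercising every pipeline stage.

The generator emulates the processed forms of the study's inputs on a small
two-chromosome genome: per-replicate DNase and H3K9ac peak calls with
boundary jitter and replicate dropout, pooled RPM signal tracks with planted
DNase peaks and one-sided H3K9ac flanks, a per-cytosine methylation table
with Beta-distributed background centred at the genome-wide means of maize
(mCG 0.86, mCHG 0.74, mCHH 0.02) and planted low-methylation valleys, a gene
annotation with expression and differential-expression flags consistent with
the planted tissue patterns, TE annotation with one family enriched for
enhancer-containing elements, a mappability mask, and a random genome
sequence with the GGCCCA motif planted in a configurable fraction of
enhancers.

Every planted enhancer is a low-methylation valley containing a central DHS
and a 300-bp H3K9ac block on one side (the asymmetry side); detection
requires all three features, so DHS-only, H3K9ac-only and bare-valley decoys
are also planted to exercise the integration filter. Outputs are
deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .intervals import Genome, GenomicInterval, IntervalSet, SignalTrack
from .partition import GeneModel
from .te_stats import TEAnnotation

__all__ = ["SimulationConfig", "PlantedEnhancer", "SyntheticTruth", "SyntheticBundle", "generate"]

TISSUES = ("V2-IST", "husk")


@dataclass
class SimulationConfig:
    """Sizes, rates and noise levels of the synthetic genome."""

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    genes_per_chrom: int = 100
    gene_pitch: int = 10_000          # one gene per pitch window
    n_enhancers_v2: int = 15
    n_enhancers_husk: int = 30
    n_enhancers_shared: int = 15
    valley_length: Tuple[int, int] = (1000, 1500)
    dhs_length: int = 300
    k9_block_bp: int = 300
    dhs_rpm: float = 6.0
    dhs_other_tissue_rpm: float = 0.2
    k9_rpm: float = 2.0
    asymmetry_fold: float = 5.0
    background_rpm: float = 0.02
    n_decoy_valleys: int = 20
    n_decoy_dhs_only: int = 10        # per tissue
    n_decoy_k9_only: int = 10         # per tissue
    n_promoter_peaks: int = 30        # genes with promoter DHS+H3K9ac
    mcg_mean: float = 0.86
    mchg_mean: float = 0.74
    mchh_mean: float = 0.02
    valley_methylation: float = 0.05
    chh_boundary_mean: float = 0.15   # mCHH bump at valley 5' edges
    # Beta a+b for per-site frequencies. The run-based segmenter breaks a
    # region at any single site at/above threshold, so the per-site spread
    # must stay small enough that planted valleys survive segmentation
    # (at 50, a 5%-methylated site exceeds 20% with p ~ 1e-5).
    beta_concentration: float = 50.0
    site_spacing: Dict[str, int] = field(
        default_factory=lambda: {"CG": 29, "CHG": 31, "CHH": 11}
    )
    mean_coverage: int = 20
    jitter_bp: int = 30               # replicate peak boundary jitter (uniform +/-)
    dropout: float = 0.05             # per enhancer and tissue: evidence lost in one replicate
    n_replicates: Dict[str, Dict[str, int]] = field(
        default_factory=lambda: {
            "DNase": {"V2-IST": 2, "husk": 2},
            "H3K9ac": {"V2-IST": 2, "husk": 3},
        }
    )
    te_families: Dict[str, str] = field(
        default_factory=lambda: {
            "RLG_SIM_A": "LTR", "RLG_SIM_B": "LTR", "RLG_SIM_C": "LTR",
            "DTT_SIM_D": "TIR", "DHH_SIM_E": "helitron", "DTT_SIM_F": "TIR",
        }
    )
    enriched_family: str = "RLG_SIM_A"
    n_enhancer_wrapping_tes: int = 10  # TEs planted around enhancers
    enriched_family_wrap_count: int = 8
    n_background_tes_per_family: int = 20
    n_short_tes: int = 10             # below the baseline length filter
    n_intronic_tes: int = 10
    n_nested_tes: int = 8
    motif_fraction: float = 0.6
    cns_fraction: float = 0.3
    n_mask_gaps_per_chrom: int = 3
    mask_gap_bp: int = 4000
    noise: float = 1.0                # 0 disables jitter, dropout and Beta noise

    def n_enhancers(self) -> int:
        return self.n_enhancers_v2 + self.n_enhancers_husk + self.n_enhancers_shared


@dataclass
class PlantedEnhancer:
    chrom: str
    start: int            # valley == expected candidate region
    end: int
    tissues: List[str]    # ["V2-IST"], ["husk"] or both
    dhs: Tuple[int, int]
    k9_block: Tuple[int, int]
    asym_side: str        # "5p" | "3p"
    fold: float
    target_gene: Optional[str]
    target_direction: Optional[str]
    other_flank_gene: Optional[str]
    te_family: Optional[str] = None
    motif_planted: bool = False
    has_cns: bool = False

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def pattern(self) -> str:
        return "shared" if len(self.tissues) == 2 else f"{self.tissues[0]}-specific"


@dataclass
class SyntheticTruth:
    enhancers: List[PlantedEnhancer]
    decoy_valleys: List[GenomicInterval]
    decoy_dhs_only: Dict[str, List[GenomicInterval]]
    decoy_k9_only: Dict[str, List[GenomicInterval]]
    promoter_peak_genes: List[str]
    mask_gaps: List[GenomicInterval]

    def to_json(self, path: str) -> None:
        def iv(i: GenomicInterval) -> Dict:
            return {"chrom": i.chrom, "start": i.start, "end": i.end}

        payload = {
            "enhancers": [
                {**dataclasses.asdict(e)} for e in self.enhancers
            ],
            "decoy_valleys": [iv(i) for i in self.decoy_valleys],
            "decoy_dhs_only": {t: [iv(i) for i in v] for t, v in self.decoy_dhs_only.items()},
            "decoy_k9_only": {t: [iv(i) for i in v] for t, v in self.decoy_k9_only.items()},
            "promoter_peak_genes": self.promoter_peak_genes,
            "mask_gaps": [iv(i) for i in self.mask_gaps],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class SyntheticBundle:
    """In-memory handles plus the files written for CLI-style consumption."""

    genome: Genome
    genes: List[GeneModel]
    tes: List[TEAnnotation]
    mask: IntervalSet
    methylation: pd.DataFrame
    expression: pd.DataFrame
    replicate_peaks: Dict[str, Dict[str, List[IntervalSet]]]  # assay -> tissue -> reps
    tracks: Dict[str, Dict[str, SignalTrack]]                 # assay -> tissue
    cns: IntervalSet
    sequences: Dict[str, str]
    truth: SyntheticTruth
    paths: Dict[str, str] = field(default_factory=dict)


# --------------------------------------------------------------------------- #
# placement helpers


def _make_genes(cfg: SimulationConfig, rng: np.random.Generator) -> List[GeneModel]:
    genes: List[GeneModel] = []
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        for g in range(cfg.genes_per_chrom):
            base = g * cfg.gene_pitch
            length = int(rng.integers(2000, 4001))
            start = base + 3000
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 5))
            edges = np.sort(rng.choice(
                np.arange(start + 100, end - 100), size=2 * (n_exons - 1), replace=False
            )) if n_exons > 1 else np.array([], dtype=int)
            bounds = [start, *edges.tolist(), end]
            exons = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds) - 1, 2)]
            genes.append(GeneModel(
                gene_id=f"Zm_sim_{chrom}_{g:03d}", chrom=chrom,
                start=start, end=end, strand=strand, exons=exons,
            ))
    return genes


def _usable_gaps(cfg: SimulationConfig, genes: List[GeneModel]) -> List[Tuple[str, int, int, Optional[GeneModel], Optional[GeneModel]]]:
    """Intergenic windows with >= 1.2 kb clearance from gene bodies.

    The clearance keeps planted features outside promoter (1 kb + 200 bp)
    definitions. Returns (chrom, lo, hi, upstream_gene, downstream_gene).
    """
    margin = 1300
    gaps = []
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, chrom_genes in sorted(by_chrom.items()):
        chrom_genes.sort(key=lambda g: g.start)
        for left, right in zip(chrom_genes[:-1], chrom_genes[1:]):
            lo, hi = left.end + margin, right.start - margin
            if hi - lo >= 2200:
                gaps.append((chrom, lo, hi, left, right))
    return gaps


def _plant_enhancers(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    gaps: List[Tuple[str, int, int, Optional[GeneModel], Optional[GeneModel]]],
) -> List[PlantedEnhancer]:
    patterns = (
        [["V2-IST"]] * cfg.n_enhancers_v2
        + [["husk"]] * cfg.n_enhancers_husk
        + [["V2-IST", "husk"]] * cfg.n_enhancers_shared
    )
    # even gap indices only, so no gene flanks two enhancers and expression
    # constraints never conflict
    even_gaps = gaps[::2]
    if len(even_gaps) < len(patterns):
        raise ValueError(
            f"not enough intergenic space: {len(even_gaps)} usable gaps "
            f"for {len(patterns)} enhancers"
        )
    chosen = rng.choice(len(even_gaps), size=len(patterns), replace=False)
    chosen.sort()
    out: List[PlantedEnhancer] = []
    for (gap_i, tissues) in zip(chosen, patterns):
        chrom, lo, hi, left, right = even_gaps[int(gap_i)]
        v_len = int(rng.integers(cfg.valley_length[0], cfg.valley_length[1] + 1))
        v_len = min(v_len, hi - lo)
        start = lo + int(rng.integers(0, hi - lo - v_len + 1))
        end = start + v_len
        mid = (start + end) // 2
        dhs = (mid - cfg.dhs_length // 2, mid + cfg.dhs_length - cfg.dhs_length // 2)
        asym_side = "3p" if rng.random() < 0.5 else "5p"
        if asym_side == "3p":
            k9 = (dhs[1], min(dhs[1] + cfg.k9_block_bp, end))
        else:
            k9 = (max(dhs[0] - cfg.k9_block_bp, start), dhs[0])
        target_direction = "upstream" if rng.random() < 0.5 else "downstream"
        target = left if target_direction == "upstream" else right
        other = right if target_direction == "upstream" else left
        out.append(PlantedEnhancer(
            chrom=chrom, start=start, end=end, tissues=list(tissues),
            dhs=dhs, k9_block=k9, asym_side=asym_side, fold=cfg.asymmetry_fold,
            target_gene=target.gene_id if target else None,
            target_direction=target_direction if target else None,
            other_flank_gene=other.gene_id if other else None,
        ))
    return out


def _plant_decoys(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    gaps: List[Tuple[str, int, int, Optional[GeneModel], Optional[GeneModel]]],
    n_needed: int,
) -> List[GenomicInterval]:
    odd_gaps = gaps[1::2]
    if len(odd_gaps) < n_needed:
        raise ValueError("not enough intergenic space for decoys")
    chosen = rng.choice(len(odd_gaps), size=n_needed, replace=False)
    chosen.sort()
    out = []
    for gap_i in chosen:
        chrom, lo, hi, _, _ = odd_gaps[int(gap_i)]
        v_len = int(rng.integers(cfg.valley_length[0], cfg.valley_length[1] + 1))
        v_len = min(v_len, hi - lo)
        start = lo + int(rng.integers(0, hi - lo - v_len + 1))
        out.append(GenomicInterval(chrom, start, start + v_len))
    return out


# --------------------------------------------------------------------------- #
# track / peak / methylation synthesis


def _jitter(iv: Tuple[int, int], rng: np.random.Generator, j: int) -> Tuple[int, int]:
    if j == 0:
        return iv
    s = iv[0] + int(rng.integers(-j, j + 1))
    e = iv[1] + int(rng.integers(-j, j + 1))
    if e <= s:
        e = s + 1
    return max(0, s), e


def _build_tracks_and_peaks(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    genome: Genome,
    genes: List[GeneModel],
    enhancers: List[PlantedEnhancer],
    decoy_dhs: Dict[str, List[GenomicInterval]],
    decoy_k9: Dict[str, List[GenomicInterval]],
    promoter_genes: List[GeneModel],
) -> Tuple[Dict[str, Dict[str, SignalTrack]], Dict[str, Dict[str, List[IntervalSet]]]]:
    jitter = cfg.jitter_bp if cfg.noise > 0 else 0
    dropout = cfg.dropout if cfg.noise > 0 else 0.0
    arrays: Dict[Tuple[str, str], Dict[str, np.ndarray]] = {}
    for assay in ("DNase", "H3K9ac"):
        for tissue in TISSUES:
            arrays[(assay, tissue)] = {
                chrom: np.full(genome[chrom], cfg.background_rpm)
                for chrom in genome.chromosomes
            }
    peak_lists: Dict[str, Dict[str, List[List[GenomicInterval]]]] = {
        assay: {t: [[] for _ in range(cfg.n_replicates[assay][t])] for t in TISSUES}
        for assay in ("DNase", "H3K9ac")
    }

    def add_signal(assay: str, tissue: str, chrom: str, s: int, e: int, v: float) -> None:
        arr = arrays[(assay, tissue)][chrom]
        arr[s:e] = np.maximum(arr[s:e], v)

    def add_peak(assay: str, tissue: str, chrom: str, s: int, e: int,
                 drop_rep: Optional[int]) -> None:
        for r in range(cfg.n_replicates[assay][tissue]):
            if drop_rep is not None and r == drop_rep:
                continue
            js, je = _jitter((s, e), rng, jitter)
            peak_lists[assay][tissue][r].append(GenomicInterval(chrom, js, je))

    for enh in enhancers:
        for tissue in TISSUES:
            detected = tissue in enh.tissues
            dhs_v = cfg.dhs_rpm if detected else cfg.dhs_other_tissue_rpm
            add_signal("DNase", tissue, enh.chrom, *enh.dhs, dhs_v)
            if detected:
                k9_hi = cfg.k9_rpm
                k9_lo = cfg.k9_rpm / enh.fold
                if enh.asym_side == "3p":
                    hi_iv, lo_iv = enh.k9_block, (max(enh.dhs[0] - cfg.k9_block_bp, enh.start), enh.dhs[0])
                else:
                    hi_iv, lo_iv = enh.k9_block, (enh.dhs[1], min(enh.dhs[1] + cfg.k9_block_bp, enh.end))
                add_signal("H3K9ac", tissue, enh.chrom, *hi_iv, k9_hi)
                if lo_iv[1] > lo_iv[0]:
                    add_signal("H3K9ac", tissue, enh.chrom, *lo_iv, k9_lo)
                # one dropout event per enhancer-tissue: evidence lost in one
                # randomly chosen replicate of one assay
                drop_assay = drop_rep = None
                if dropout > 0 and rng.random() < dropout:
                    drop_assay = "DNase" if rng.random() < 0.5 else "H3K9ac"
                    drop_rep = int(rng.integers(0, cfg.n_replicates[drop_assay][tissue]))
                add_peak("DNase", tissue, enh.chrom, *enh.dhs,
                         drop_rep if drop_assay == "DNase" else None)
                add_peak("H3K9ac", tissue, enh.chrom, *hi_iv,
                         drop_rep if drop_assay == "H3K9ac" else None)

    for tissue, ivs in decoy_dhs.items():
        for iv in ivs:
            add_signal("DNase", tissue, iv.chrom, iv.midpoint - 150, iv.midpoint + 150, cfg.dhs_rpm)
            add_peak("DNase", tissue, iv.chrom, iv.midpoint - 150, iv.midpoint + 150, None)
    for tissue, ivs in decoy_k9.items():
        for iv in ivs:
            add_signal("H3K9ac", tissue, iv.chrom, iv.midpoint - 150, iv.midpoint + 150, cfg.k9_rpm)
            add_peak("H3K9ac", tissue, iv.chrom, iv.midpoint - 150, iv.midpoint + 150, None)

    # promoter peaks at expressed genes, both tissues (excluded by the
    # intergenic rule but exercised by partitioning and gene metaprofiles)
    for g in promoter_genes:
        if g.strand == "+":
            s, e = max(0, g.start - 250), g.start + 150
        else:
            s, e = g.end - 150, min(genome[g.chrom], g.end + 250)
        for tissue in TISSUES:
            add_signal("DNase", tissue, g.chrom, s, e, cfg.dhs_rpm / 2)
            add_signal("H3K9ac", tissue, g.chrom, s, min(e + 300, genome[g.chrom]), cfg.k9_rpm)
            add_peak("DNase", tissue, g.chrom, s, e, None)
            add_peak("H3K9ac", tissue, g.chrom, s, e + 300, None)

    tracks: Dict[str, Dict[str, SignalTrack]] = {"DNase": {}, "H3K9ac": {}}
    for (assay, tissue), chrom_arrays in arrays.items():
        steps: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, arr in chrom_arrays.items():
            change = np.flatnonzero(np.diff(arr)) + 1
            edges = np.concatenate([[0], change, [len(arr)]])
            steps[chrom] = [
                (int(edges[i]), int(edges[i + 1]), float(arr[edges[i]]))
                for i in range(len(edges) - 1)
            ]
        tracks[assay][tissue] = SignalTrack(steps)

    replicate_sets = {
        assay: {
            tissue: [IntervalSet(peaks).merge() for peaks in reps]
            for tissue, reps in by_tissue.items()
        }
        for assay, by_tissue in peak_lists.items()
    }
    return tracks, replicate_sets


def _make_methylation(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    genome: Genome,
    valleys: List[GenomicInterval],
) -> pd.DataFrame:
    """Per-cytosine table with Beta background and planted valleys."""
    context_means = {"CG": cfg.mcg_mean, "CHG": cfg.mchg_mean, "CHH": cfg.mchh_mean}
    rows: List[pd.DataFrame] = []
    valley_by_chrom: Dict[str, List[GenomicInterval]] = {}
    for v in valleys:
        valley_by_chrom.setdefault(v.chrom, []).append(v)
    for chrom in genome.chromosomes:
        length = genome[chrom]
        vs = sorted(valley_by_chrom.get(chrom, []), key=lambda v: v.start)
        starts = np.array([v.start for v in vs])
        ends = np.array([v.end for v in vs])
        for context, spacing in cfg.site_spacing.items():
            pos = np.arange(spacing // 2, length, spacing)
            mean = np.full(len(pos), context_means[context])
            if len(vs):
                idx = np.searchsorted(starts, pos, side="right") - 1
                in_valley = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
                if context == "CHH":
                    # boundary bump at valley 5' edges, low inside otherwise
                    near_edge = in_valley & (pos < starts[np.clip(idx, 0, None)] + 60)
                    mean[in_valley] = cfg.mchh_mean
                    mean[near_edge] = cfg.chh_boundary_mean
                else:
                    mean[in_valley] = cfg.valley_methylation
            if cfg.noise > 0:
                c = cfg.beta_concentration
                freq = rng.beta(np.maximum(mean * c, 1e-3),
                                np.maximum((1 - mean) * c, 1e-3))
                coverage = rng.poisson(cfg.mean_coverage, size=len(pos))
            else:
                freq = mean
                coverage = np.full(len(pos), cfg.mean_coverage)
            rows.append(pd.DataFrame({
                "chrom": chrom, "pos": pos, "context": context,
                "frequency": freq, "coverage": coverage,
            }))
    df = pd.concat(rows, ignore_index=True)
    return df.sort_values(["chrom", "pos", "context"], kind="stable").reset_index(drop=True)


def _make_tes(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    genome: Genome,
    genes: List[GeneModel],
    enhancers: List[PlantedEnhancer],
    used: List[GenomicInterval],
) -> List[TEAnnotation]:
    tes: List[TEAnnotation] = []
    families = list(cfg.te_families)
    other_families = [f for f in families if f != cfg.enriched_family]

    # wrap TEs around a subset of enhancers (the enriched family gets most)
    wrap_idx = rng.choice(len(enhancers), size=cfg.n_enhancer_wrapping_tes, replace=False)
    wrap_idx.sort()
    for j, ei in enumerate(wrap_idx):
        enh = enhancers[int(ei)]
        fam = (cfg.enriched_family if j < cfg.enriched_family_wrap_count
               else other_families[j % len(other_families)])
        iv = GenomicInterval(enh.chrom, max(0, enh.start - 200),
                             min(genome[enh.chrom], enh.end + 300))
        enh.te_family = fam
        tes.append(TEAnnotation(iv, family=fam, superfamily=cfg.te_families[fam]))

    # background TEs in free intergenic space
    used_set = IntervalSet(used + [t.interval for t in tes] + [g.interval for g in genes]).merge()
    free = genome.as_interval_set().subtract(used_set)
    free_segs = [s for s in free if len(s) >= 5000]

    def place(length: int) -> Optional[GenomicInterval]:
        candidates = [s for s in free_segs if len(s) >= length + 200]
        if not candidates:
            return None
        seg = candidates[int(rng.integers(0, len(candidates)))]
        offset = int(rng.integers(100, len(seg) - length - 100 + 1))
        iv = GenomicInterval(seg.chrom, seg.start + offset, seg.start + offset + length)
        # shrink the free segment bookkeeping
        free_segs.remove(seg)
        if iv.start - seg.start >= 5000:
            free_segs.append(GenomicInterval(seg.chrom, seg.start, iv.start))
        if seg.end - iv.end >= 5000:
            free_segs.append(GenomicInterval(seg.chrom, iv.end, seg.end))
        return iv

    for fam in families:
        n = (max(cfg.n_background_tes_per_family - cfg.enriched_family_wrap_count, 2)
             if fam == cfg.enriched_family else cfg.n_background_tes_per_family)
        for _ in range(n):
            iv = place(int(rng.integers(800, 4001)))
            if iv is not None:
                tes.append(TEAnnotation(iv, family=fam, superfamily=cfg.te_families[fam]))

    # elements the baseline filter must remove
    for _ in range(cfg.n_short_tes):
        iv = place(int(rng.integers(100, 635)))
        if iv is not None:
            fam = other_families[int(rng.integers(0, len(other_families)))]
            tes.append(TEAnnotation(iv, family=fam, superfamily=cfg.te_families[fam]))
    long_tes = [t for t in tes if len(t.interval) >= 2000]
    for k in range(min(cfg.n_nested_tes, len(long_tes))):
        outer = long_tes[k].interval
        inner = GenomicInterval(outer.chrom, outer.start + 300, outer.start + 300 + 800)
        fam = other_families[k % len(other_families)]
        tes.append(TEAnnotation(inner, family=fam, superfamily=cfg.te_families[fam]))
    intron_hosts = [g for g in genes if any(
        g.exons[i + 1][0] - g.exons[i][1] >= 900 for i in range(len(g.exons) - 1)
    )]
    for k in range(min(cfg.n_intronic_tes, len(intron_hosts))):
        g = intron_hosts[k]
        for i in range(len(g.exons) - 1):
            gap_s, gap_e = g.exons[i][1], g.exons[i + 1][0]
            if gap_e - gap_s >= 900:
                fam = other_families[k % len(other_families)]
                tes.append(TEAnnotation(
                    GenomicInterval(g.chrom, gap_s + 25, gap_s + 25 + 700),
                    family=fam, superfamily=cfg.te_families[fam],
                ))
                break
    tes.sort(key=lambda t: (t.interval.chrom, t.interval.start, t.interval.end))
    return tes


def _make_expression(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    genes: List[GeneModel],
    enhancers: List[PlantedEnhancer],
) -> pd.DataFrame:
    records: Dict[str, Dict] = {}
    for g in genes:
        base = float(np.exp(rng.normal(1.0, 1.0)))
        records[g.gene_id] = {
            "gene_id": g.gene_id,
            "rpkm_v2_ist": base * float(np.exp(rng.normal(0, 0.1))),
            "rpkm_husk": base * float(np.exp(rng.normal(0, 0.1))),
            "significant_de": False,
            "higher_tissue": "none",
        }
    for enh in enhancers:
        if enh.target_gene is None:
            continue
        rec = records[enh.target_gene]
        if enh.pattern == "shared":
            rec["rpkm_v2_ist"] = float(rng.uniform(2, 20))
            rec["rpkm_husk"] = float(rng.uniform(2, 20))
            rec["significant_de"] = False
            rec["higher_tissue"] = "none"
        else:
            tissue = enh.tissues[0]
            hi, lo = float(rng.uniform(8, 40)), float(rng.uniform(0.05, 0.5))
            rec["rpkm_v2_ist"] = hi if tissue == "V2-IST" else lo
            rec["rpkm_husk"] = hi if tissue == "husk" else lo
            rec["significant_de"] = True
            rec["higher_tissue"] = tissue
        if enh.other_flank_gene is not None:
            other = records[enh.other_flank_gene]
            other["significant_de"] = False
            other["higher_tissue"] = "none"
            if enh.pattern == "shared":
                # keep the non-target flank unexpressed in one tissue
                other["rpkm_husk"] = float(rng.uniform(0.0, 0.5))
    return pd.DataFrame(records.values())


_BASES = np.array(list("ACGT"))


def _make_sequences(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    genome: Genome,
    enhancers: List[PlantedEnhancer],
    motif: str = "GGCCCA",
) -> Dict[str, str]:
    seqs: Dict[str, np.ndarray] = {
        chrom: _BASES[rng.integers(0, 4, size=genome[chrom])]
        for chrom in genome.chromosomes
    }
    for enh in enhancers:
        if rng.random() < cfg.motif_fraction:
            mid = (enh.dhs[0] + enh.dhs[1]) // 2
            seqs[enh.chrom][mid:mid + len(motif)] = list(motif)
            enh.motif_planted = True
    return {chrom: "".join(arr) for chrom, arr in seqs.items()}


def generate(
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
    outdir: Optional[str] = None,
    write_fasta: bool = True,
) -> SyntheticBundle:
    """Generate the full synthetic input bundle plus ground truth.

    With ``outdir`` set, every input is also written in the formats the
    pipeline reads (GFF3, BED, bedGraph, tab tables, FASTA, truth JSON).
    Deterministic given ``seed``.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    genome = Genome({f"chr{c + 1}": cfg.chrom_length for c in range(cfg.n_chromosomes)})

    genes = _make_genes(cfg, rng)
    gaps = _usable_gaps(cfg, genes)
    enhancers = _plant_enhancers(cfg, rng, gaps)

    n_decoys = cfg.n_decoy_valleys + 2 * (cfg.n_decoy_dhs_only + cfg.n_decoy_k9_only)
    decoy_ivs = _plant_decoys(cfg, rng, gaps, n_decoys)
    k = cfg.n_decoy_valleys
    decoy_valleys = decoy_ivs[:k]
    decoy_dhs = {
        "V2-IST": decoy_ivs[k:k + cfg.n_decoy_dhs_only],
        "husk": decoy_ivs[k + cfg.n_decoy_dhs_only:k + 2 * cfg.n_decoy_dhs_only],
    }
    k += 2 * cfg.n_decoy_dhs_only
    decoy_k9 = {
        "V2-IST": decoy_ivs[k:k + cfg.n_decoy_k9_only],
        "husk": decoy_ivs[k + cfg.n_decoy_k9_only:k + 2 * cfg.n_decoy_k9_only],
    }

    promoter_genes = [genes[int(i)] for i in
                      rng.choice(len(genes), size=cfg.n_promoter_peaks, replace=False)]
    promoter_genes.sort(key=lambda g: (g.chrom, g.start))

    tracks, replicate_peaks = _build_tracks_and_peaks(
        cfg, rng, genome, genes, enhancers, decoy_dhs, decoy_k9, promoter_genes
    )

    valleys = (
        [e.interval for e in enhancers]
        + decoy_valleys
        + [iv for ivs in decoy_dhs.values() for iv in ivs]
        + [iv for ivs in decoy_k9.values() for iv in ivs]
    )
    methylation = _make_methylation(cfg, rng, genome, valleys)

    used = valleys + [g.interval for g in genes]
    tes = _make_tes(cfg, rng, genome, genes, enhancers, used)
    expression = _make_expression(cfg, rng, genes, enhancers)
    sequences = _make_sequences(cfg, rng, genome, enhancers)

    # CNSs inside a fraction of enhancers
    cns_ivs = []
    for enh in enhancers:
        if rng.random() < cfg.cns_fraction:
            enh.has_cns = True
            mid = (enh.start + enh.end) // 2
            cns_ivs.append(GenomicInterval(enh.chrom, mid - 50, mid + 50))
    cns = IntervalSet(cns_ivs)

    # mappability mask: everything except a few blocks in unused space
    used_all = IntervalSet(
        used + [t.interval for t in tes]
    ).merge()
    free = genome.as_interval_set().subtract(used_all)
    gap_candidates = [s for s in free if len(s) >= cfg.mask_gap_bp + 200]
    mask_gaps: List[GenomicInterval] = []
    per_chrom: Dict[str, int] = {}
    for seg in gap_candidates:
        if per_chrom.get(seg.chrom, 0) >= cfg.n_mask_gaps_per_chrom:
            continue
        mid = seg.midpoint
        mask_gaps.append(GenomicInterval(
            seg.chrom, mid - cfg.mask_gap_bp // 2, mid + cfg.mask_gap_bp // 2
        ))
        per_chrom[seg.chrom] = per_chrom.get(seg.chrom, 0) + 1
    mask = genome.as_interval_set().subtract(IntervalSet(mask_gaps))

    truth = SyntheticTruth(
        enhancers=enhancers,
        decoy_valleys=decoy_valleys,
        decoy_dhs_only=decoy_dhs,
        decoy_k9_only=decoy_k9,
        promoter_peak_genes=[g.gene_id for g in promoter_genes],
        mask_gaps=mask_gaps,
    )
    bundle = SyntheticBundle(
        genome=genome, genes=genes, tes=tes, mask=mask,
        methylation=methylation, expression=expression,
        replicate_peaks=replicate_peaks, tracks=tracks,
        cns=cns, sequences=sequences, truth=truth,
    )
    if outdir is not None:
        _write_bundle(bundle, cfg, outdir, write_fasta=write_fasta)
    return bundle


# --------------------------------------------------------------------------- #
# serialisation


def _write_gff3_genes(genes: List[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def _write_gff3_tes(tes: List[TEAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, t in enumerate(tes):
            iv = t.interval
            fh.write(
                f"{iv.chrom}\tsim\ttransposable_element\t{iv.start + 1}\t{iv.end}\t.\t+\t.\t"
                f"ID=TE{i:04d};family={t.family};superfamily={t.superfamily}\n"
            )


def _write_fasta(sequences: Dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sequences):
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _write_bundle(
    bundle: SyntheticBundle, cfg: SimulationConfig, outdir: str, write_fasta: bool
) -> None:
    from . import io as emio

    os.makedirs(outdir, exist_ok=True)
    paths = bundle.paths

    paths["genes"] = os.path.join(outdir, "genes.gff3")
    _write_gff3_genes(bundle.genes, paths["genes"])
    paths["tes"] = os.path.join(outdir, "tes.gff3")
    _write_gff3_tes(bundle.tes, paths["tes"])
    paths["mask"] = os.path.join(outdir, "mappable_mask.bed")
    emio.write_bed(bundle.mask, paths["mask"])
    paths["cns"] = os.path.join(outdir, "cns.bed")
    emio.write_bed(bundle.cns, paths["cns"])
    paths["methylation"] = os.path.join(outdir, "methylation.tsv")
    emio.write_methylation_table(bundle.methylation, paths["methylation"])
    paths["expression"] = os.path.join(outdir, "expression.tsv")
    emio.write_expression_table(bundle.expression, paths["expression"])
    paths["genome"] = os.path.join(outdir, "genome.chrom.sizes")
    emio.write_genome_file(bundle.genome, paths["genome"])
    for assay, by_tissue in bundle.replicate_peaks.items():
        for tissue, reps in by_tissue.items():
            slug_t = "v2" if tissue == "V2-IST" else "husk"
            slug_a = "dnase" if assay == "DNase" else "k9"
            for r, peaks in enumerate(reps, start=1):
                key = f"peaks_{slug_a}_{slug_t}_rep{r}"
                paths[key] = os.path.join(outdir, f"{key}.bed")
                emio.write_bed(peaks, paths[key])
    for assay, by_tissue in bundle.tracks.items():
        for tissue, track in by_tissue.items():
            slug_t = "v2" if tissue == "V2-IST" else "husk"
            slug_a = "dnase" if assay == "DNase" else "k9"
            key = f"track_{slug_a}_{slug_t}"
            paths[key] = os.path.join(outdir, f"{key}.bedgraph")
            emio.write_bedgraph(bundle.tracks[assay][tissue], paths[key])
    if write_fasta:
        paths["fasta"] = os.path.join(outdir, "genome.fa")
        _write_fasta(bundle.sequences, paths["fasta"])
    paths["truth"] = os.path.join(outdir, "truth.json")
    bundle.truth.to_json(paths["truth"])
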