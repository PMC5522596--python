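"""Orientation of DHSs by flanking H3K9ac asymmetry, scaled signal matrices,
k-means profile categories, and expression-binned gene metaprofiles.

Each DHS is oriented so that the flank with the higher mean H3K9ac
enrichment (over 300-bp windows) becomes its 3' end. A DHS is eligible for
asymmetry classification when either flank reaches 0.5 RPM, and asymmetric
when the flank ratio is at least twofold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .intervals import Genome, GenomicInterval, SignalTrack
from .partition import GeneModel

__all__ = [
    "OrientedDHS",
    "ProfileMatrix",
    "orient_dhs",
    "build_matrix",
    "kmeans_categories",
    "expression_bins",
    "gene_metaprofile",
]


@dataclass
class OrientedDHS:
    """A DHS with its H3K9ac-derived orientation and asymmetry call."""

    dhs: GenomicInterval
    candidate_id: Optional[str]
    orientation: str  # "keep" | "flip"
    flank_up_rpm: float
    flank_down_rpm: float
    eligible: bool
    asymmetric: bool
    tie: bool = False
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.asymmetric and not self.eligible:
            raise ValueError("asymmetric DHS must be eligible")


@dataclass
class ProfileMatrix:
    """Feature x bin signal matrix: fixed flank bins around a scaled body."""

    values: np.ndarray
    row_ids: List[str]
    n_flank_bins: int
    n_body_bins: int

    @property
    def mean_profile(self) -> np.ndarray:
        return self.values.mean(axis=0)


def orient_dhs(
    dhs_set: Sequence[GenomicInterval],
    k9_track: SignalTrack,
    flank: int = 300,
    min_rpm: float = 0.5,
    fold: float = 2.0,
    genome: Optional[Genome] = None,
    candidate_ids: Optional[Sequence[Optional[str]]] = None,
) -> List[OrientedDHS]:
    """Orient each DHS by mean H3K9ac over its two ``flank``-bp windows.

    If the downstream flank mean exceeds the upstream one the DHS keeps its
    orientation; otherwise it is flipped (ties keep, flagged). Flanks running
    past a chromosome edge are clipped and flagged.
    """
    if flank <= 0:
        raise ValueError(f"flank must be > 0, got {flank}")
    ids = candidate_ids if candidate_ids is not None else [None] * len(dhs_set)
    out: List[OrientedDHS] = []
    for dhs, cid in zip(dhs_set, ids):
        chrom_end = (
            genome[dhs.chrom] if genome is not None and dhs.chrom in genome
            else k9_track.chrom_extent(dhs.chrom)
        )
        up_s, up_e = max(0, dhs.start - flank), dhs.start
        down_s, down_e = dhs.end, min(chrom_end, dhs.end + flank)
        clipped = (up_s != dhs.start - flank) or (down_e != dhs.end + flank)
        up = (
            k9_track.mean(GenomicInterval(dhs.chrom, up_s, up_e)) if up_e > up_s else 0.0
        )
        down = (
            k9_track.mean(GenomicInterval(dhs.chrom, down_s, down_e))
            if down_e > down_s else 0.0
        )
        tie = up == down
        orientation = "keep" if down >= up else "flip"
        hi, lo = max(up, down), min(up, down)
        eligible = hi >= min_rpm
        asymmetric = eligible and (lo == 0 or hi / lo >= fold)
        out.append(
            OrientedDHS(
                dhs=dhs, candidate_id=cid, orientation=orientation,
                flank_up_rpm=up, flank_down_rpm=down,
                eligible=eligible, asymmetric=asymmetric, tie=tie, clipped=clipped,
            )
        )
    return out


def _row_for_feature(
    track: SignalTrack,
    iv: GenomicInterval,
    flip: bool,
    flank_bp: int,
    body_bins: int,
    flank_bin_bp: int,
    chrom_end: int,
) -> np.ndarray:
    n_flank_bins = flank_bp // flank_bin_bp
    up_edges = np.clip(
        iv.start - flank_bp + flank_bin_bp * np.arange(n_flank_bins + 1), 0, None
    )
    down_edges = np.clip(
        iv.end + flank_bin_bp * np.arange(n_flank_bins + 1), None, chrom_end
    )
    whole = GenomicInterval(
        iv.chrom,
        int(min(up_edges[0], iv.start)),
        int(max(down_edges[-1], iv.end)),
    )
    up = track.binned_means(whole, up_edges.astype(float))
    down = track.binned_means(whole, down_edges.astype(float))
    if len(iv) >= body_bins:
        body_edges = iv.start + np.round(
            np.linspace(0, len(iv), body_bins + 1)
        ).astype(float)
        body = track.binned_means(whole, body_edges)
    else:
        # feature shorter than the bin count: interpolate per-bp values
        per_bp_edges = np.arange(iv.start, iv.end + 1, dtype=float)
        per_bp = track.binned_means(whole, per_bp_edges)
        x_src = np.linspace(0, 1, len(per_bp))
        x_dst = np.linspace(0, 1, body_bins)
        body = np.interp(x_dst, x_src, per_bp)
    row = np.concatenate([up, body, down])
    if flip:
        row = row[::-1]
    return row


def build_matrix(
    features: Sequence[OrientedDHS | GenomicInterval],
    track: SignalTrack,
    flank_bp: int = 1000,
    body_bins: int = 50,
    flank_bin_bp: int = 20,
    genome: Optional[Genome] = None,
) -> ProfileMatrix:
    """Signal matrix over scaled feature bodies with fixed-width flank bins.

    Features given as :class:`OrientedDHS` contribute their orientation:
    flipped rows are reversed so all rows read 5' to 3'.
    """
    rows: List[np.ndarray] = []
    ids: List[str] = []
    for k, feat in enumerate(features):
        if isinstance(feat, OrientedDHS):
            iv, flip = feat.dhs, feat.orientation == "flip"
            ids.append(feat.candidate_id or f"row{k}")
        else:
            iv, flip = feat, feat.strand == "-"
            ids.append(feat.name or f"row{k}")
        chrom_end = (
            genome[iv.chrom] if genome is not None and iv.chrom in genome
            else track.chrom_extent(iv.chrom)
        )
        rows.append(
            _row_for_feature(track, iv, flip, flank_bp, body_bins, flank_bin_bp, chrom_end)
        )
    return ProfileMatrix(
        values=np.vstack(rows),
        row_ids=ids,
        n_flank_bins=flank_bp // flank_bin_bp,
        n_body_bins=body_bins,
    )


def kmeans_categories(
    matrix: ProfileMatrix, k: int = 4, seed: int = 0
) -> Tuple[np.ndarray, Dict[int, np.ndarray]]:
    """k-means categories 1..k on the rows, deterministically relabeled.

    Clusters are ordered by descending total mean enrichment so category 1
    is the most enriched; the same labels are reused to order companion
    matrices. Returns (labels per row, mean profile per category).
    """
    n_rows = matrix.values.shape[0]
    if k > n_rows:
        raise ValueError(f"k={k} exceeds number of rows ({n_rows})")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(matrix.values)
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="stable")
    relabel = {int(old): new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel[int(r)] for r in raw])
    if len(np.unique(labels)) < k:
        warnings.warn("some k-means categories are empty (degenerate input)")
    profiles = {
        cat: matrix.values[labels == cat].mean(axis=0)
        if np.any(labels == cat) else np.full(matrix.values.shape[1], np.nan)
        for cat in range(1, k + 1)
    }
    return labels, profiles


def expression_bins(
    expr: pd.DataFrame, tissue_column: str, n_var_bins: int = 6
) -> Tuple[pd.Series, List[float]]:
    """Bin genes by expression: bin 0 is < 1 RPKM, the rest equal-count bins.

    Returns (bin per gene indexed like ``expr``, upper thresholds of bins
    1..n-1 in RPKM). Raises if fewer than ``n_var_bins`` genes reach 1 RPKM.
    """
    rpkm = expr[tissue_column]
    if (rpkm < 0).any():
        raise ValueError("RPKM values must be >= 0")
    expressed = rpkm[rpkm >= 1.0]
    if len(expressed) < n_var_bins:
        raise ValueError(
            f"need >= {n_var_bins} genes with >= 1 RPKM, got {len(expressed)}"
        )
    bins = pd.Series(0, index=expr.index, dtype=int)
    order = expressed.sort_values(kind="stable").index
    chunks = np.array_split(np.asarray(order), n_var_bins)
    thresholds: List[float] = []
    for b, chunk in enumerate(chunks, start=1):
        bins.loc[chunk] = b
        if b < n_var_bins:
            thresholds.append(float(rpkm.loc[chunk].max()))
    return bins, thresholds


def gene_metaprofile(
    genes: Sequence[GeneModel],
    track: SignalTrack,
    bin_assignment: pd.Series,
    flank_bp: int = 1000,
    body_bins: int = 50,
    flank_bin_bp: int = 20,
    genome: Optional[Genome] = None,
) -> Dict[int, np.ndarray]:
    """Mean signal profile over scaled gene bodies +/- flanks, per expression bin.

    Profiles are oriented 5' to 3' using gene strand. Empty bins yield NaN
    profiles with a warning.
    """
    by_bin: Dict[int, List[GenomicInterval]] = {}
    for g in genes:
        if g.gene_id not in bin_assignment.index:
            continue
        by_bin.setdefault(int(bin_assignment.loc[g.gene_id]), []).append(g.interval)
    out: Dict[int, np.ndarray] = {}
    for b in sorted(set(bin_assignment)):
        ivs = by_bin.get(b, [])
        if not ivs:
            warnings.warn(f"expression bin {b} contains no profiled genes")
            width = 2 * (flank_bp // flank_bin_bp) + body_bins
            out[b] = np.full(width, np.nan)
            continue
        mat = build_matrix(
            ivs, track, flank_bp=flank_bp, body_bins=body_bins,
            flank_bin_bp=flank_bin_bp, genome=genome,
        )
        out[b] = mat.mean_profile
    return out
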