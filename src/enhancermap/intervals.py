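"""Genomic interval data model, interval algebra, and signal tracks.

All coordinates are 0-based half-open (BED convention). GFF3 input, which is
1-based closed, is converted on read by the annotation readers in
:mod:`enhancermap.io`. Interval-set operations are strand-blind; strand is
carried as metadata only.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "SignalTrack",
    "Genome",
    "overlap_stats",
    "nearest_flanking",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def overlap_stats(
    a: GenomicInterval, b: GenomicInterval
) -> Tuple[int, float, float]:
    """Overlap in bp and as a fraction of each interval's length.

    Intervals on different chromosomes overlap by zero. ``overlap_bp`` is
    symmetric in its arguments.
    """
    if a.chrom != b.chrom:
        return 0, 0.0, 0.0
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    return ov, ov / len(a), ov / len(b)


class IntervalSet:
    """A collection of intervals grouped by chromosome, sorted by start.

    May contain overlapping intervals; the results of :meth:`merge`,
    :meth:`intersect` and :meth:`subtract` are always merged-disjoint.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), merged: bool = False):
        by_chrom: Dict[str, List[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom in by_chrom:
            by_chrom[chrom].sort(key=lambda iv: (iv.start, iv.end))
        self._by_chrom = by_chrom
        self.merged = merged
        # cached coordinate arrays per chromosome for fast queries
        self._arrays: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}

    # -- basic container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return [(i.chrom, i.start, i.end) for i in self] == [
            (i.chrom, i.start, i.end) for i in other
        ]

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._by_chrom)

    def on(self, chrom: str) -> List[GenomicInterval]:
        return list(self._by_chrom.get(chrom, []))

    def _coords(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        if chrom not in self._arrays:
            ivs = self._by_chrom.get(chrom, [])
            self._arrays[chrom] = (
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
            )
        return self._arrays[chrom]

    def total_bp(self) -> int:
        """Number of covered base pairs (on the merged set)."""
        return sum(len(iv) for iv in self.merge())

    # -- algebra ------------------------------------------------------------------
    def merge(self, gap: int = 0) -> "IntervalSet":
        """Union of overlapping or book-ended intervals (<= ``gap`` bp apart)."""
        out: List[GenomicInterval] = []
        for chrom in sorted(self._by_chrom):
            cur_s = cur_e = None
            for iv in self._by_chrom[chrom]:
                if cur_s is None:
                    cur_s, cur_e = iv.start, iv.end
                elif iv.start <= cur_e + gap:
                    cur_e = max(cur_e, iv.end)
                else:
                    out.append(GenomicInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = iv.start, iv.end
            if cur_s is not None:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
        return IntervalSet(out, merged=True)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Maximal regions covered by both sets (merged-disjoint)."""
        a, b = self.merge(), other.merge()
        out: List[GenomicInterval] = []
        for chrom in a.chromosomes:
            bi = b.on(chrom)
            if not bi:
                continue
            ai = a.on(chrom)
            i = j = 0
            while i < len(ai) and j < len(bi):
                s = max(ai[i].start, bi[j].start)
                e = min(ai[i].end, bi[j].end)
                if s < e:
                    out.append(GenomicInterval(chrom, s, e))
                if ai[i].end <= bi[j].end:
                    i += 1
                else:
                    j += 1
        return IntervalSet(out, merged=True)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Base pairs of this set not covered by ``other`` (merged-disjoint)."""
        a, b = self.merge(), other.merge()
        out: List[GenomicInterval] = []
        for chrom in a.chromosomes:
            bi = b.on(chrom)
            for iv in a.on(chrom):
                cursor = iv.start
                for biv in bi:
                    if biv.end <= cursor or biv.start >= iv.end:
                        continue
                    if biv.start > cursor:
                        out.append(GenomicInterval(chrom, cursor, biv.start))
                    cursor = max(cursor, biv.end)
                    if cursor >= iv.end:
                        break
                if cursor < iv.end:
                    out.append(GenomicInterval(chrom, cursor, iv.end))
        return IntervalSet(out, merged=True)

    # -- queries ------------------------------------------------------------------
    def overlapping(self, iv: GenomicInterval) -> List[GenomicInterval]:
        """All member intervals overlapping ``iv`` by >= 1 bp."""
        ivs = self._by_chrom.get(iv.chrom, [])
        if not ivs:
            return []
        starts, ends = self._coords(iv.chrom)
        # candidates: start < iv.end; among those, end > iv.start
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        return [ivs[k] for k in range(hi) if ends[k] > iv.start]

    def overlap_bp(self, iv: GenomicInterval) -> int:
        """Covered base pairs of ``iv`` (overlaps within the set counted once)."""
        total = 0
        for m in self.merge().overlapping(iv):
            total += min(m.end, iv.end) - max(m.start, iv.start)
        return total

    def overlaps(self, iv: GenomicInterval) -> bool:
        return bool(self.overlapping(iv))


class Genome:
    """Mapping of chromosome name to length in bp."""

    def __init__(self, lengths: Dict[str, int]):
        for chrom, length in lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        self.lengths = dict(lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self.lengths)

    def total_bp(self) -> int:
        return sum(self.lengths.values())

    def as_interval_set(self) -> IntervalSet:
        return IntervalSet(
            [GenomicInterval(c, 0, l) for c, l in self.lengths.items()], merged=True
        )


class SignalTrack:
    """Per-chromosome stepwise coverage in RPM.

    Steps are non-overlapping, sorted; any position not covered by a step has
    value 0. Step values must be >= 0 (RPM).
    """

    def __init__(self, steps: Dict[str, Sequence[Tuple[int, int, float]]]):
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        self._values: Dict[str, np.ndarray] = {}
        for chrom, chrom_steps in steps.items():
            ordered = sorted(chrom_steps)
            starts = np.array([s for s, _, _ in ordered], dtype=np.int64)
            ends = np.array([e for _, e, _ in ordered], dtype=np.int64)
            values = np.array([v for _, _, v in ordered], dtype=float)
            if np.any(ends <= starts):
                raise ValueError(f"empty step on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping steps on {chrom}")
            if np.any(values < 0):
                raise ValueError(f"negative signal value on {chrom}")
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = values

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._starts)

    def steps_on(self, chrom: str) -> List[Tuple[int, int, float]]:
        if chrom not in self._starts:
            return []
        return list(
            zip(
                self._starts[chrom].tolist(),
                self._ends[chrom].tolist(),
                self._values[chrom].tolist(),
            )
        )

    def _check_chrom(self, chrom: str) -> None:
        if chrom not in self._starts:
            raise KeyError(f"chromosome {chrom!r} not present in signal track")

    def chrom_extent(self, chrom: str) -> int:
        self._check_chrom(chrom)
        return int(self._ends[chrom][-1])

    def segments(self, iv: GenomicInterval) -> List[Tuple[int, int, float]]:
        """Piecewise-constant segments exactly covering ``iv`` (gaps as 0)."""
        self._check_chrom(iv.chrom)
        starts, ends, values = (
            self._starts[iv.chrom],
            self._ends[iv.chrom],
            self._values[iv.chrom],
        )
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        out: List[Tuple[int, int, float]] = []
        cursor = iv.start
        for k in range(lo, len(starts)):
            if starts[k] >= iv.end:
                break
            s, e, v = int(starts[k]), int(ends[k]), float(values[k])
            if s > cursor:
                out.append((cursor, s, 0.0))
            out.append((max(s, cursor), min(e, iv.end), v))
            cursor = min(e, iv.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append((cursor, iv.end, 0.0))
        return out

    def mean(self, iv: GenomicInterval) -> float:
        """bp-weighted mean over ``iv``, uncovered positions counting as 0."""
        total = 0.0
        for s, e, v in self.segments(iv):
            total += (e - s) * v
        return total / len(iv)

    def max(self, iv: GenomicInterval) -> float:
        """Maximum value over ``iv`` including uncovered (zero) positions."""
        return max(v for _, _, v in self.segments(iv))

    def binned_means(self, iv: GenomicInterval, edges: np.ndarray) -> np.ndarray:
        """bp-weighted means over sub-intervals delimited by ``edges``.

        ``edges`` are absolute positions, monotonically non-decreasing,
        spanning ``iv``. Zero-width bins get the value at their left edge.
        """
        segs = self.segments(iv)
        seg_starts = np.array([s for s, _, _ in segs], dtype=float)
        seg_ends = np.array([e for _, e, _ in segs], dtype=float)
        seg_vals = np.array([v for _, _, v in segs], dtype=float)
        out = np.zeros(len(edges) - 1)
        for i in range(len(edges) - 1):
            lo, hi = edges[i], edges[i + 1]
            if hi <= lo:
                k = int(np.searchsorted(seg_ends, lo, side="right"))
                k = min(k, len(seg_vals) - 1)
                out[i] = seg_vals[k]
                continue
            w = np.clip(np.minimum(seg_ends, hi) - np.maximum(seg_starts, lo), 0, None)
            out[i] = float(np.dot(w, seg_vals)) / (hi - lo)
        return out

    def max_difference(self, other: "SignalTrack", iv: GenomicInterval) -> float:
        """Maximum of (self - other) over any position of ``iv``.

        Both tracks are step functions, so the maximum is attained on one of
        the sub-segments delimited by the union of breakpoints.
        """
        segs_a = self.segments(iv)
        segs_b = other.segments(iv)
        edges = sorted(
            {p for s, e, _ in segs_a for p in (s, e)}
            | {p for s, e, _ in segs_b for p in (s, e)}
        )

        def value_at(segs: List[Tuple[int, int, float]], pos: int) -> float:
            for s, e, v in segs:
                if s <= pos < e:
                    return v
            return 0.0

        best = -np.inf
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi <= lo:
                continue
            best = max(best, value_at(segs_a, lo) - value_at(segs_b, lo))
        return float(best)


def signal_stat(
    track: SignalTrack,
    iv: GenomicInterval,
    stat: str = "mean",
    genome: Optional[Genome] = None,
) -> float:
    """Mean or max RPM of ``track`` over ``iv``.

    The interval is clipped (with a warning) to chromosome bounds when a
    genome is given; an unknown chromosome raises ``KeyError`` naming it.
    """
    if genome is not None and iv.chrom in genome:
        clipped_end = min(iv.end, genome[iv.chrom])
        clipped_start = max(iv.start, 0)
        if (clipped_start, clipped_end) != (iv.start, iv.end):
            warnings.warn(
                f"interval [{iv.start},{iv.end}) clipped to chromosome bounds on {iv.chrom}"
            )
            iv = GenomicInterval(iv.chrom, clipped_start, clipped_end)
    if stat == "mean":
        return track.mean(iv)
    if stat == "max":
        return track.max(iv)
    raise ValueError(f"unknown stat {stat!r}; expected 'mean' or 'max'")


def nearest_flanking(
    iv: GenomicInterval, genes: IntervalSet
) -> Tuple[Optional[GenomicInterval], Optional[GenomicInterval], Optional[int], Optional[int]]:
    """Nearest gene entirely upstream and downstream of ``iv`` by coordinate.

    Upstream: the gene with the largest end such that end <= iv.start.
    Downstream: the gene with the smallest start such that start >= iv.end.
    Gene strand is ignored. Distances are the gap in bp (0 if book-ended);
    ``None`` is returned past the chromosome edges.
    """
    candidates = genes.on(iv.chrom)
    upstream = None
    downstream = None
    for g in candidates:
        if g.end <= iv.start and (upstream is None or g.end > upstream.end):
            upstream = g
    starts = [g.start for g in candidates]
    k = bisect.bisect_left(starts, iv.end)
    if k < len(candidates):
        downstream = candidates[k]
    d_up = iv.start - upstream.end if upstream is not None else None
    d_down = downstream.start - iv.end if downstream is not None else None
    return upstream, downstream, d_up, d_down
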