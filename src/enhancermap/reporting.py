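"""Bookkeeping tables: overlap summaries per tissue, distance-to-gene
statistics, and the percentage formatting used in all printed counts.

Percentages are rounded half-away-from-zero (so 38/175 prints as 22%, and
9057/9212 as 98.3%); banker's rounding would not reproduce the printed
values.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .candidates import EnhancerCandidate
from .intervals import GenomicInterval, IntervalSet, nearest_flanking

__all__ = ["percent", "overlap_table", "distance_stats"]


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * num / den rounded half-away-from-zero to ``decimals`` places."""
    if denominator == 0:
        raise ValueError("percentage denominator must be non-zero")
    value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def _count_overlapping(regions: IntervalSet, other: IntervalSet) -> int:
    return sum(1 for iv in regions if other.overlaps(iv))


def _table_rows(
    per_tissue: Dict[str, IntervalSet],
    columns: Dict[str, IntervalSet | Dict[str, IntervalSet]],
) -> Dict[str, Dict[str, object]]:
    """Rows V2-IST / Husk / Common / Total with any-overlap columns.

    Common counts regions of the first tissue overlapping the second by
    >= 1 bp (first tissue's coordinate space); Total is the union of the two
    merged tissue sets, labeled as such.
    """
    tissues = list(per_tissue)
    t1, t2 = tissues[0], tissues[1]
    common = IntervalSet(
        [iv for iv in per_tissue[t1] if per_tissue[t2].overlaps(iv)]
    )
    union = IntervalSet(
        list(per_tissue[t1]) + list(per_tissue[t2])
    ).merge()
    row_sets = {t1: per_tissue[t1], t2: per_tissue[t2],
                "Common": common, "Total (union)": union}
    out: Dict[str, Dict[str, object]] = {}
    for row_name, regions in row_sets.items():
        row: Dict[str, object] = {"all": len(regions)}
        for col_name, col_set in columns.items():
            if isinstance(col_set, dict):
                # per-tissue column: use the row's own tissue, union for the rest
                if row_name in col_set:
                    target = col_set[row_name]
                else:
                    target = IntervalSet(
                        [iv for s in col_set.values() for iv in s]
                    ).merge()
            else:
                target = col_set
            n = _count_overlapping(regions, target)
            row[col_name] = n
            row[f"{col_name}_pct"] = (
                percent(n, len(regions), 1) if len(regions) else 0.0
            )
        out[row_name] = row
    return out


def overlap_table(
    dhs: Dict[str, IntervalSet],
    k9: Dict[str, IntervalSet],
    lumrs: IntervalSet,
) -> Dict[str, Dict[str, Dict[str, object]]]:
    """Per-tissue overlap summary of intergenic regions of interest.

    Section "DHS": DHS rows with overlap counts against LUMRs and H3K9ac;
    section "H3K9ac": the converse. All overlaps are >= 1 bp.
    """
    return {
        "DHS": _table_rows(dhs, {"lumr": lumrs, "k9": k9}),
        "H3K9ac": _table_rows(k9, {"lumr": lumrs, "dhs": dhs}),
    }


def distance_stats(
    candidates: Sequence[EnhancerCandidate | GenomicInterval],
    genes: IntervalSet,
) -> Dict[str, float]:
    """Distance from each candidate to its closest flanking gene.

    Reports the median and maximum distance plus counts of candidates more
    than 5 kb and 10 kb from their closest gene. Candidates with no flanking
    gene on either side are excluded from the distance distribution.
    """
    distances: List[int] = []
    for cand in candidates:
        iv = cand.region if isinstance(cand, EnhancerCandidate) else cand
        _, _, d_up, d_down = nearest_flanking(iv, genes)
        options = [d for d in (d_up, d_down) if d is not None]
        if options:
            distances.append(min(options))
    arr = np.array(distances) if distances else np.array([], dtype=int)
    return {
        "n": len(arr),
        "median_bp": float(np.median(arr)) if len(arr) else float("nan"),
        "max_bp": float(arr.max()) if len(arr) else float("nan"),
        "n_beyond_5kb": int((arr > 5000).sum()),
        "n_beyond_10kb": int((arr > 10000).sum()),
    }
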