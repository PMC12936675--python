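"""Location-independent ordered-value (OV) analysis of subregional changes.

For each knee the 16 subregional 2-year thickness changes are sorted by
signed value: OV1 is the most negative change (greatest thinning), OV16
the most positive (greatest thickening).  Sorting by signed value rather
than absolute magnitude is what makes OV16/OV15 the thickening extremes.
Ties are broken by the fixed subregion listing order and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .regions import OV_LABELS, SUBREGIONS, DEFAULT_OV_RANKS

log = logging.getLogger(__name__)


@dataclass
class OvResult:
    """Ascending 16-vector of changes with their source subregions."""

    values: np.ndarray            # (16,) change, ascending
    labels: tuple[str, ...]       # source subregion per rank

    def value(self, rank: int) -> float:
        """Change at OV rank 1..16."""
        return float(self.values[rank - 1])

    def label(self, rank: int) -> str:
        return self.labels[rank - 1]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(OV_LABELS))


def rank_ov(changes: Mapping[str, float]) -> OvResult:
    """Rank the 16 subregional changes of one knee in ascending order."""
    missing = [s for s in SUBREGIONS if s not in changes]
    if missing:
        raise ValueError(f"missing subregion change(s): {missing}")
    extra = set(changes) - set(SUBREGIONS)
    if extra:
        raise ValueError(f"unknown subregion label(s): {sorted(extra)}")
    vals = np.array([float(changes[s]) for s in SUBREGIONS])
    if not np.all(np.isfinite(vals)):
        bad = [s for s, v in zip(SUBREGIONS, vals) if not np.isfinite(v)]
        raise ValueError(f"non-finite change for subregion(s): {bad}")
    order = np.lexsort((np.arange(len(SUBREGIONS)), vals))  # value, then listing order
    if len(np.unique(vals)) < len(vals):
        log.info("tied subregional changes; tie-break by listing order")
    return OvResult(values=vals[order],
                    labels=tuple(SUBREGIONS[k] for k in order))


@dataclass
class OvOccurrenceTable:
    """Counts and percentages of source subregions per group x OV rank."""

    table: pd.DataFrame           # group, rank, subregion, count, percent
    group_sizes: dict[str, int]

    def cell(self, group: str, rank: str, subregion: str) -> tuple[int, float]:
        sel = self.table[(self.table.group == group) & (self.table["rank"] == rank)
                         & (self.table.subregion == subregion)]
        if sel.empty:
            return 0, 0.0
        return int(sel["count"].iloc[0]), float(sel.percent.iloc[0])


def tabulate_ov_occurrences(ov_results: Mapping[str, OvResult],
                            groups: Mapping[str, str],
                            ranks: tuple[str, ...] = DEFAULT_OV_RANKS,
                            ) -> OvOccurrenceTable:
    """How often each subregion supplies each reported OV rank, per group.

    ``ov_results`` maps knee id -> OvResult, ``groups`` knee id -> group.
    Percentages are 100 * count / group size; per group and rank the
    counts over subregions sum to the group's knee count.
    """
    missing = set(ov_results) - set(groups)
    if missing:
        raise ValueError(f"knees without group assignment: {sorted(missing)}")
    sizes: dict[str, int] = {}
    for knee in ov_results:
        sizes[groups[knee]] = sizes.get(groups[knee], 0) + 1
    rows = []
    for grp in sizes:
        knees = [k for k in ov_results if groups[k] == grp]
        for rank in ranks:
            ridx = int(rank[2:])
            labs = [ov_results[k].label(ridx) for k in knees]
            for sub in SUBREGIONS:
                count = labs.count(sub)
                rows.append({"group": grp, "rank": rank, "subregion": sub,
                             "count": count,
                             "percent": 100.0 * count / sizes[grp]})
    return OvOccurrenceTable(table=pd.DataFrame(rows), group_sizes=sizes)
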