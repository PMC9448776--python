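"""Exclusive-intersection overlap taxonomy of significance masks.

Given one thresholded mask per pipeline (same sign and regime), every voxel
in the union of significant voxels is assigned to exactly the subset of
pipelines that contain it ({CAT}, {CAT, FSLVBM}, ..., full intersection).
Subset percentages use the union as denominator and therefore sum to 100
exactly before rounding.  The rendered table mirrors the standard layout:
unique rows first, then pairwise, triple and full intersections, with absent
subsets shown as an em-dash.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["OverlapTaxonomy", "overlap_taxonomy", "render_overlap_table"]


@dataclass
class OverlapTaxonomy:
    """Exclusive subset counts/percentages over the union of significant voxels."""

    pipelines: tuple[str, ...]
    subsets: dict[frozenset, tuple[int, float]]  # subset -> (count, percent)
    union_size: int
    sign: str = ""
    regime: str = ""
    params: dict = field(default_factory=dict)

    def percent(self, *names: str) -> float:
        """Percent of union voxels found by exactly this pipeline subset."""
        entry = self.subsets.get(frozenset(names))
        return entry[1] if entry else 0.0

    def count(self, *names: str) -> int:
        entry = self.subsets.get(frozenset(names))
        return entry[0] if entry else 0


def overlap_taxonomy(
    masks: dict[str, np.ndarray], sign: str = "", regime: str = ""
) -> OverlapTaxonomy:
    """Exclusive-intersection taxonomy of >= 2 boolean masks on one grid.

    Each union voxel is counted once, under the exact subset of pipelines
    containing it; empty subsets are absent from the result.  An empty union
    yields an empty taxonomy with union_size 0 (not an error): a regime in
    which no pipeline finds anything is a legitimate outcome.
    """
    names = list(masks)
    if len(names) < 2:
        raise ValueError("need >= 2 pipelines")
    shape = np.asarray(masks[names[0]]).shape
    stack = []
    for n in names:
        m = np.asarray(masks[n], dtype=bool)
        if m.shape != shape:
            raise ValueError("masks must share one grid")
        stack.append(m.ravel())
    bits = np.zeros(stack[0].size, dtype=np.int64)
    for i, m in enumerate(stack):
        bits |= m.astype(np.int64) << i
    union = bits > 0
    union_size = int(union.sum())
    subsets: dict[frozenset, tuple[int, float]] = {}
    if union_size:
        counts = np.bincount(bits[union], minlength=2 ** len(names))
        for code in np.flatnonzero(counts):
            subset = frozenset(names[i] for i in range(len(names))
                               if code & (1 << i))
            c = int(counts[code])
            subsets[subset] = (c, 100.0 * c / union_size)
    return OverlapTaxonomy(pipelines=tuple(names), subsets=subsets,
                           union_size=union_size, sign=sign, regime=regime)


def _subset_rows(pipelines: tuple[str, ...]) -> list[frozenset]:
    """Row order: unique -> pairwise -> triple -> ... -> full intersection."""
    rows = []
    for size in range(1, len(pipelines) + 1):
        for combo in combinations(pipelines, size):
            rows.append(frozenset(combo))
    return rows


def _row_label(subset: frozenset, pipelines: tuple[str, ...]) -> str:
    ordered = [p for p in pipelines if p in subset]
    if len(ordered) == 1:
        return f"{ordered[0]} (unique)"
    return " ∩ ".join(ordered)


def render_overlap_table(
    taxonomies: dict[str, OverlapTaxonomy], absent: str = "—"
) -> pd.DataFrame:
    """Render taxonomies (one column per sign/regime) as a percent table.

    Percentages are formatted to two decimals; absent subsets and empty
    unions render as the ``absent`` marker.
    """
    if not taxonomies:
        raise ValueError("no taxonomies to render")
    pipelines = next(iter(taxonomies.values())).pipelines
    for t in taxonomies.values():
        if t.pipelines != pipelines:
            raise ValueError("taxonomies must share one pipeline set")
    rows = _subset_rows(pipelines)
    data = {}
    for col, tax in taxonomies.items():
        vals = []
        for subset in rows:
            entry = tax.subsets.get(subset)
            vals.append(f"{entry[1]:.2f}%" if entry else absent)
        data[col] = vals
    return pd.DataFrame(data, index=[_row_label(s, pipelines) for s in rows])
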