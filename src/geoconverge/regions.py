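"""Region maps: labelled spatial units, adjacency edges, and macro-region groups.

A :class:`RegionMap` is the minimal geographic substrate the rest of the
package needs: an ordered set of region labels, an undirected adjacency
edge list (two regions sharing a border), and a partition of the regions
into three macro-regions (east / central / west) used for heterogeneity
analysis.  Real study runs supply the edge list from a contiguity table;
synthetic runs build a rook-adjacency lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GROUPS = ("east", "central", "west")


@dataclass(frozen=True)
class RegionMap:
    """Ordered regions, undirected adjacency edges, and a group partition.

    Parameters
    ----------
    region_ids
        Ordered unique region labels; this ordering is the canonical one
        used for weight matrices and panel arrays.
    edges
        Unordered pairs of region ids sharing a border.  Self-loops are
        rejected; duplicates are tolerated here and collapsed when a
        weight matrix is built.
    region_group
        Mapping region id -> one of ``east``, ``central``, ``west``.
    """

    region_ids: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    region_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = list(self.region_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("region_ids contains duplicates")
        known = set(ids)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop edge on region {a!r}")
            if a not in known or b not in known:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown region")
        if self.region_group:
            if set(self.region_group) != known:
                raise ValueError("region_group must cover exactly the region set")
            bad = set(self.region_group.values()) - set(GROUPS)
            if bad:
                raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.region_ids)

    def group_members(self, group: str) -> list[str]:
        """Regions belonging to ``group``, in canonical order."""
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return [r for r in self.region_ids if self.region_group.get(r) == group]


def make_lattice_map(
    rows: int,
    cols: int,
    group_split: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> RegionMap:
    """Build a rook-adjacency grid of ``rows`` x ``cols`` regions.

    Regions are labelled ``R01``, ``R02``, ... in row-major order and
    assigned to east/central/west by contiguous column bands whose widths
    follow ``group_split`` (fractions summing to 1).  A rook lattice has
    ``rows*(cols-1) + cols*(rows-1)`` edges.
    """
    if rows < 1 or cols < 1 or rows * cols < 4:
        raise ValueError("lattice must have at least 4 regions (rows*cols >= 4)")
    if abs(sum(group_split) - 1.0) > 1e-9:
        raise ValueError("group_split fractions must sum to 1")

    width = max(len(str(rows * cols)), 2)
    ids = tuple(f"R{i + 1:0{width}d}" for i in range(rows * cols))

    def at(r: int, c: int) -> str:
        return ids[r * cols + c]

    edges: list[tuple[str, str]] = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append((at(r, c), at(r, c + 1)))
            if r + 1 < rows:
                edges.append((at(r, c), at(r + 1, c)))

    cuts = np.round(np.cumsum(group_split) * cols).astype(int)
    group_of_col = {}
    start = 0
    for g, cut in zip(GROUPS, cuts):
        for c in range(start, cut):
            group_of_col[c] = g
        start = cut
    for c in range(start, cols):  # rounding slack goes to the last group
        group_of_col[c] = GROUPS[-1]
    region_group = {at(r, c): group_of_col[c] for r in range(rows) for c in range(cols)}

    return RegionMap(region_ids=ids, edges=tuple(edges), region_group=region_group)
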