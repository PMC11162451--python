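"""Voxel layouts: polygon-per-voxel slide geometry.

A layout is a rectangular grid of unit-square polygons numbered row-major
starting at 1, mirroring how a macrodissected tissue slide is voxelated.
Voxels can be flagged *excluded* (e.g. suspected contamination) without being
deleted: they keep their polygon and number, but downstream analyses operate
on the retained voxels only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import InvalidArgumentError

__all__ = ["VoxelLayout", "generate_layout", "read_layout", "write_layout"]


@dataclass(frozen=True)
class VoxelLayout:
    """Polygon-per-voxel slide geometry with exclusion flags.

    Attributes
    ----------
    polygons:
        Mapping of voxel id to a list of ``[x, y]`` vertices (>= 3 per voxel).
    excluded:
        Ids flagged as excluded from analysis; always a subset of the ids.
    """

    polygons: dict[int, list[tuple[float, float]]]
    excluded: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        for vid, poly in self.polygons.items():
            if len(poly) < 3:
                raise InvalidArgumentError(f"voxel {vid}: polygon needs >=3 vertices")
        unknown = set(self.excluded) - set(self.polygons)
        if unknown:
            raise InvalidArgumentError(f"excluded ids not in layout: {sorted(unknown)}")

    @property
    def voxel_ids(self) -> list[int]:
        return sorted(self.polygons)

    @property
    def retained(self) -> list[int]:
        """Analysis voxels: all ids minus the excluded ones, ascending."""
        return [v for v in sorted(self.polygons) if v not in self.excluded]

    def __len__(self) -> int:
        return len(self.polygons)


def generate_layout(n_rows: int, n_cols: int, excluded: set[int] = frozenset()) -> VoxelLayout:
    """Build a rectangular grid layout numbered row-major from 1.

    Each voxel is a unit square; voxel 1 sits at the top-left corner
    (x to the right, y downward, as in slide/SVG coordinates).

    Parameters
    ----------
    n_rows, n_cols:
        Grid shape; both must be >= 1.
    excluded:
        Voxel ids to flag excluded. Must fall in ``1..n_rows*n_cols``.
    """
    if n_rows < 1 or n_cols < 1:
        raise InvalidArgumentError("n_rows and n_cols must be >= 1")
    total = n_rows * n_cols
    excluded = frozenset(int(v) for v in excluded)
    bad = [v for v in excluded if not 1 <= v <= total]
    if bad:
        raise InvalidArgumentError(f"excluded ids outside 1..{total}: {sorted(bad)}")
    polygons: dict[int, list[tuple[float, float]]] = {}
    vid = 1
    for r in range(n_rows):
        for c in range(n_cols):
            x, y = float(c), float(r)
            polygons[vid] = [(x, y), (x + 1, y), (x + 1, y + 1), (x, y + 1)]
            vid += 1
    return VoxelLayout(polygons=polygons, excluded=excluded)


def grid_position(layout_or_cols, voxel_id: int, n_cols: int | None = None) -> tuple[int, int]:
    """Row/column (0-based) of a voxel in a row-major grid with ``n_cols`` columns."""
    if n_cols is None:
        n_cols = layout_or_cols
    idx = voxel_id - 1
    return idx // n_cols, idx % n_cols


def write_layout(layout: VoxelLayout, path) -> None:
    """Serialize to JSON: a list of {voxel_id, polygon, excluded} objects."""
    records = [
        {
            "voxel_id": vid,
            "polygon": [[float(x), float(y)] for x, y in layout.polygons[vid]],
            "excluded": vid in layout.excluded,
        }
        for vid in layout.voxel_ids
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)
        fh.write("\n")


def read_layout(path) -> VoxelLayout:
    with open(path) as fh:
        records = json.load(fh)
    polygons = {
        int(r["voxel_id"]): [(float(x), float(y)) for x, y in r["polygon"]] for r in records
    }
    excluded = frozenset(int(r["voxel_id"]) for r in records if r.get("excluded"))
    return VoxelLayout(polygons=polygons, excluded=excluded)
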