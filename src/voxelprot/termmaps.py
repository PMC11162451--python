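"""Term-summed spatial intensity maps, heatmap scaling, SVG rendering, and a
local hypergeometric enrichment.

A *term map* sums the intensity of a named protein set (a GO/BTO term, a
pathway, a recovered module) in every voxel and paints it on the slide
layout as a dark-blue -> dark-red choropleth. Enrichment of a query set
against term membership uses the upper-tail hypergeometric test with
Benjamini-Hochberg adjustment; it is a database-local stand-in for web
enrichment services, so p-values depend only on the supplied annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptySelectionError, InvalidArgumentError
from .layout import VoxelLayout

__all__ = [
    "TermMap",
    "term_summed_intensity",
    "heatmap_scale",
    "render_svg",
    "hypergeometric_enrichment",
]

# heatmap color ramp endpoints
_DARK_BLUE = (0, 0, 139)
_DARK_RED = (139, 0, 0)
_GREY = (128, 128, 128)


@dataclass
class TermMap:
    """Per-voxel summed intensity for a named protein set."""

    term: str
    members_used: list[str]
    members_absent: list[str]
    values: pd.Series  # per-voxel sum
    scale: str  # "linear" | "log2"


def term_summed_intensity(
    m: pd.DataFrame, members: set[str], scale: str = "linear", term: str = ""
) -> TermMap:
    """Sum member-protein intensity per voxel.

    ``scale="linear"`` back-transforms log2 entries (sums 2**x), which is the
    physically meaningful way to add protein amounts; ``scale="log2"`` sums
    the log2 values directly. Members absent from the matrix are reported,
    not an error; zero present members is.
    """
    if scale not in ("linear", "log2"):
        raise InvalidArgumentError(f"unknown scale {scale!r}")
    present = sorted(set(members) & set(m.index), key=str)
    absent = sorted(set(members) - set(m.index), key=str)
    if not present:
        raise EmptySelectionError(f"no term members present in matrix (term {term!r})")
    sub = m.loc[present]
    values = np.power(2.0, sub).sum(axis=0) if scale == "linear" else sub.sum(axis=0)
    return TermMap(
        term=term, members_used=present, members_absent=absent, values=values, scale=scale
    )


def heatmap_scale(values: pd.Series) -> pd.Series:
    """Scale per-voxel values linearly onto [0, 1] (min -> 0, max -> 1).

    A degenerate all-equal map lands mid-ramp at 0.5 everywhere.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidArgumentError("need >= 1 voxel")
    if not np.isfinite(arr).all():
        raise InvalidArgumentError("non-finite heatmap values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        out = np.full_like(arr, 0.5)
    else:
        out = (arr - lo) / (hi - lo)
    return pd.Series(out, index=values.index)


def _ramp(x: float) -> str:
    rgb = tuple(
        int(round(b + (r - b) * x)) for b, r in zip(_DARK_BLUE, _DARK_RED)
    )
    return f"rgb({rgb[0]},{rgb[1]},{rgb[2]})"


def render_svg(layout: VoxelLayout, scaled: dict | pd.Series, title: str = "") -> str:
    """Render a voxel choropleth as a standalone SVG document string.

    One polygon per voxel: retained voxels are filled along the linear
    dark-blue (0,0,139) -> dark-red (139,0,0) ramp from their scaled value;
    excluded voxels, and retained voxels missing a value (warned), are grey.
    Output is deterministic in its inputs.
    """
    scaled = dict(pd.Series(scaled).items()) if not isinstance(scaled, dict) else dict(scaled)
    retained = set(layout.retained)
    unknown = set(scaled) - retained
    if unknown:
        raise InvalidArgumentError(f"values for non-retained voxels: {sorted(unknown)[:5]}")
    xs = [x for poly in layout.polygons.values() for x, _ in poly]
    ys = [y for poly in layout.polygons.values() for _, y in poly]
    pad = 0.05 * max(max(xs) - min(xs), max(ys) - min(ys), 1.0)
    x0, y0 = min(xs) - pad, min(ys) - pad
    w, h = max(xs) - min(xs) + 2 * pad, max(ys) - min(ys) + 2 * pad
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="{x0:g} {y0:g} {w:g} {h:g}" '
        f'width="400" height="{400 * h / w:g}">',
    ]
    if title:
        lines.append(f"<title>{title}</title>")
    for vid in layout.voxel_ids:
        poly = layout.polygons[vid]
        points = " ".join(f"{x:g},{y:g}" for x, y in poly)
        if vid in layout.excluded:
            fill = f"rgb({_GREY[0]},{_GREY[1]},{_GREY[2]})"
        elif vid not in scaled:
            warnings.warn(f"voxel {vid} has no value; rendered grey")
            fill = f"rgb({_GREY[0]},{_GREY[1]},{_GREY[2]})"
        else:
            x = float(scaled[vid])
            if not 0.0 <= x <= 1.0:
                raise InvalidArgumentError(f"scaled value for voxel {vid} outside [0,1]")
            fill = _ramp(x)
        lines.append(
            f'<polygon points="{points}" fill="{fill}" stroke="white" '
            f'stroke-width="0.02"><title>voxel {vid}</title></polygon>'
        )
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def hypergeometric_enrichment(
    query: set[str], annotation: dict[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query set per term.

    For each term with >= 1 member in the universe, the p-value is the
    probability of drawing at least the observed overlap when |query|
    proteins are sampled from the universe without replacement; BH adjustment
    runs across all tested terms. Rows sorted by p then term id.
    """
    if not query <= universe:
        raise InvalidArgumentError("query must be a subset of the universe")
    rows = []
    n_universe = len(universe)
    n_query = len(query)
    for term in sorted(annotation, key=str):
        members = annotation[term] & universe
        if not members:
            continue
        overlap = len(query & members)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(members), n_query))
        rows.append((term, overlap, len(members), min(p, 1.0)))
    if not rows:
        return pd.DataFrame(columns=["term", "overlap", "term_size", "p_value", "fdr"])
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p_value"])
    df["fdr"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    return df
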