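"""Exact pyramidal slide geometry.

Whole-slide images are stored as resolution pyramids; every tile-based
method in this package starts from the same geometric primitives:

* **grid tiling** — each magnification is tiled independently into
  non-overlapping ``tile_size``-pixel squares; a tile at magnification
  ``m`` covers exactly ``(m'/m)**2`` tiles at a higher magnification
  ``m'`` (a 1:N parent/child linkage),
* **concentric tiling** — for every highest-magnification grid tile one
  tile per lower magnification shares its center, giving a strict 1:1
  correspondence at the price of overlapping low-mag footprints.

All coordinates are 0-based, half-open footprints expressed in
base-magnification pixels, which makes cross-magnification arithmetic
exact integer arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PyramidSpec",
    "TileCoordinate",
    "TileLineage",
    "ConcentricSet",
    "QCMask",
    "enumerate_grid_tiles",
    "link_grid_children",
    "enumerate_concentric_sets",
    "concentric_members_for_anchor",
    "qc_filter_tiles",
    "tile_tissue_fraction",
    "write_tile_manifest",
    "read_tile_manifest",
]

#: background fill value used when a concentric member extends past the slide
PAD_VALUE = 255


@dataclass(frozen=True)
class PyramidSpec:
    """Geometry of one slide pyramid.

    Parameters
    ----------
    slide_id : str
        Opaque identifier.
    base_width, base_height : int
        Slide dimensions in pixels at the base magnification.
    base_mag : float
        Objective power of the base level (default 20).
    mags : tuple of float
        Available magnifications; each must divide ``base_mag`` with an
        integer quotient (the downsample factor).
    tile_size : int
        Tile edge length in pixels at *every* magnification (default 224).
    """

    slide_id: str
    base_width: int
    base_height: int
    base_mag: float = 20
    mags: tuple = (5, 10, 20)
    tile_size: int = 224

    def __post_init__(self):
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        if not self.mags:
            raise ValueError("pyramid needs at least one magnification")
        if max(self.mags) != self.base_mag:
            raise ValueError("base_mag must equal max(mags)")
        for m in self.mags:
            d = self.base_mag / m
            if abs(d - round(d)) > 1e-9:
                raise ValueError(
                    f"magnification {m} does not divide base_mag {self.base_mag}"
                )

    def downsample(self, mag) -> int:
        """Integer downsample factor d(m) = base_mag / m."""
        if mag not in self.mags:
            raise ValueError("magnification not in pyramid")
        return int(round(self.base_mag / mag))

    def tile_span(self, mag) -> int:
        """Footprint side of one tile at ``mag``, in base pixels."""
        return self.tile_size * self.downsample(mag)

    def grid_shape(self, mag) -> tuple:
        """(rows, cols) of complete grid tiles at ``mag``."""
        span = self.tile_span(mag)
        return (self.base_height // span, self.base_width // span)

    @property
    def has_complete_lowmag_tile(self) -> bool:
        """False flags a slide too small for even one lowest-mag tile."""
        rows, cols = self.grid_shape(min(self.mags))
        return rows >= 1 and cols >= 1


@dataclass(frozen=True)
class TileCoordinate:
    """One tile footprint: half-open square in base-magnification pixels."""

    slide_id: str
    mag: float
    row: int
    col: int
    origin_base_x: int
    origin_base_y: int
    size_base: int
    pad_fraction: float = 0.0
    needs_padding: bool = False

    @property
    def center_base(self) -> tuple:
        return (
            self.origin_base_x + self.size_base / 2,
            self.origin_base_y + self.size_base / 2,
        )


@dataclass(frozen=True)
class TileLineage:
    """A parent tile and the higher-magnification tiles that partition it."""

    parent: TileCoordinate
    children: tuple


@dataclass(frozen=True)
class ConcentricSet:
    """A base-mag anchor tile plus one co-centered member per lower mag."""

    anchor: TileCoordinate
    members: tuple  # one TileCoordinate per magnification below base


@dataclass
class QCMask:
    """Binary usable-tissue raster at a (usually coarse) magnification.

    1 = usable tissue, 0 = background / artifact / adipose.  The raster
    dimensions are the slide dimensions divided by the mask downsample
    factor, rounded down.
    """

    slide_id: str
    mask_mag: float
    raster: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.raster = np.asarray(self.raster)
        vals = np.unique(self.raster)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("QC mask must be binary")


def enumerate_grid_tiles(spec: PyramidSpec, mag) -> list:
    """All complete grid tiles at ``mag`` in row-major order.

    Partial tiles at the right/bottom edge are dropped (floor division);
    every returned tile has ``pad_fraction = 0``.
    """
    if mag not in spec.mags:
        raise ValueError("magnification not in pyramid")
    span = spec.tile_span(mag)
    rows, cols = spec.grid_shape(mag)
    return [
        TileCoordinate(
            slide_id=spec.slide_id,
            mag=mag,
            row=r,
            col=c,
            origin_base_x=c * span,
            origin_base_y=r * span,
            size_base=span,
        )
        for r in range(rows)
        for c in range(cols)
    ]


def link_grid_children(spec: PyramidSpec, parent: TileCoordinate, child_mag) -> TileLineage:
    """Materialize the 1:N grid linkage from the parent side.

    The ``f**2`` children (``f = child_mag / parent.mag``) are the grid
    tiles whose footprints partition the parent footprint.
    """
    if child_mag not in spec.mags or parent.mag not in spec.mags:
        raise ValueError("magnification not in pyramid")
    ratio = child_mag / parent.mag
    f = int(round(ratio))
    if f < 1 or abs(ratio - f) > 1e-9:
        raise ValueError("incompatible magnifications")
    if f == 1:
        return TileLineage(parent=parent, children=(parent,))
    span = spec.tile_span(child_mag)
    children = tuple(
        TileCoordinate(
            slide_id=spec.slide_id,
            mag=child_mag,
            row=r,
            col=c,
            origin_base_x=c * span,
            origin_base_y=r * span,
            size_base=span,
        )
        for r in range(f * parent.row, f * parent.row + f)
        for c in range(f * parent.col, f * parent.col + f)
    )
    return TileLineage(parent=parent, children=children)


def _clipped_area_fraction(spec: PyramidSpec, x0: float, y0: float, size: float) -> float:
    """Fraction of a square footprint lying outside the slide bounds."""
    cx0, cx1 = max(x0, 0), min(x0 + size, spec.base_width)
    cy0, cy1 = max(y0, 0), min(y0 + size, spec.base_height)
    inside = max(cx1 - cx0, 0) * max(cy1 - cy0, 0)
    return 1.0 - inside / (size * size)


def concentric_members_for_anchor(spec: PyramidSpec, anchor: TileCoordinate) -> ConcentricSet:
    """Build the co-centered lower-magnification members for one anchor.

    Each member at magnification ``m`` has footprint side
    ``tile_size * d(m)`` base pixels centered on the anchor center.
    Members that extend past the slide carry ``pad_fraction`` (area
    outside / footprint area) and ``needs_padding``; at read time that
    area is filled with a constant background (:data:`PAD_VALUE`).
    """
    cx = anchor.origin_base_x + anchor.size_base / 2
    cy = anchor.origin_base_y + anchor.size_base / 2
    members = []
    for m in sorted(spec.mags, reverse=True):
        if m == spec.base_mag:
            continue
        span = spec.tile_span(m)
        x0 = int(round(cx - span / 2))
        y0 = int(round(cy - span / 2))
        pad = _clipped_area_fraction(spec, x0, y0, span)
        members.append(
            TileCoordinate(
                slide_id=spec.slide_id,
                mag=m,
                row=anchor.row,
                col=anchor.col,
                origin_base_x=x0,
                origin_base_y=y0,
                size_base=span,
                pad_fraction=pad,
                needs_padding=pad > 0,
            )
        )
    return ConcentricSet(anchor=anchor, members=tuple(members))


def enumerate_concentric_sets(spec: PyramidSpec) -> list:
    """One :class:`ConcentricSet` per base-magnification grid tile (1:1)."""
    if len(spec.mags) < 2:
        raise ValueError("concentric tiling needs at least two magnifications")
    return [
        concentric_members_for_anchor(spec, anchor)
        for anchor in enumerate_grid_tiles(spec, spec.base_mag)
    ]


def tile_tissue_fraction(tile: TileCoordinate, mask: QCMask, spec: PyramidSpec) -> float:
    """Area-weighted tissue fraction of a tile footprint under a QC mask.

    The footprint is clipped to the slide bounds; partial mask cells
    contribute proportionally to their overlap so the result is exact.
    """
    d = spec.base_mag / mask.mask_mag
    x0 = max(tile.origin_base_x, 0)
    y0 = max(tile.origin_base_y, 0)
    x1 = min(tile.origin_base_x + tile.size_base, spec.base_width)
    y1 = min(tile.origin_base_y + tile.size_base, spec.base_height)
    if x1 <= x0 or y1 <= y0:
        return 0.0
    nrow, ncol = mask.raster.shape
    j0, j1 = int(np.floor(x0 / d)), int(np.ceil(x1 / d))
    i0, i1 = int(np.floor(y0 / d)), int(np.ceil(y1 / d))
    j1, i1 = min(j1, ncol), min(i1, nrow)
    cols = np.arange(j0, j1)
    rows = np.arange(i0, i1)
    # overlap width of the footprint with each mask cell, in base px
    wx = np.minimum((cols + 1) * d, x1) - np.maximum(cols * d, x0)
    wy = np.minimum((rows + 1) * d, y1) - np.maximum(rows * d, y0)
    weights = np.outer(np.clip(wy, 0, None), np.clip(wx, 0, None))
    sub = mask.raster[i0:i1, j0:j1]
    total = weights.sum()
    if total <= 0:
        return 0.0
    return float((weights * sub).sum() / total)


def qc_filter_tiles(tiles, mask: QCMask, min_tissue_fraction: float = 0.5, spec: PyramidSpec = None) -> list:
    """Keep tiles whose clipped footprint has tissue fraction >= threshold.

    Order is preserved.  ``spec`` may be omitted when it can be inferred
    from the mask raster shape (mask covers the whole slide).
    """
    if not 0 <= min_tissue_fraction <= 1:
        raise ValueError("min_tissue_fraction must lie in [0, 1]")
    tiles = list(tiles)
    if not tiles:
        return []
    if any(t.slide_id != mask.slide_id for t in tiles):
        raise ValueError("mask/slide mismatch")
    if spec is None:
        raise ValueError("a PyramidSpec is required to resample the mask")
    if spec.slide_id != mask.slide_id:
        raise ValueError("mask/slide mismatch")
    eps = 1e-12
    return [
        t
        for t in tiles
        if tile_tissue_fraction(t, mask, spec) + eps >= min_tissue_fraction
    ]


def write_tile_manifest(path, tiles, qc_pass=None) -> pd.DataFrame:
    """Write the deterministic TSV tile manifest (one row per tile)."""
    if qc_pass is None:
        qc_pass = [True] * len(tiles)
    df = pd.DataFrame(
        {
            "slide_id": [t.slide_id for t in tiles],
            "mag": [t.mag for t in tiles],
            "row": [t.row for t in tiles],
            "col": [t.col for t in tiles],
            "origin_base_x": [t.origin_base_x for t in tiles],
            "origin_base_y": [t.origin_base_y for t in tiles],
            "size_base": [t.size_base for t in tiles],
            "pad_fraction": [t.pad_fraction for t in tiles],
            "qc_pass": list(qc_pass),
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def read_tile_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
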