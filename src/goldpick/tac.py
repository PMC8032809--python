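"""Threshold-area-circularity (TAC) baseline detector.

The classical computer-vision approach the learned detector is compared
against: a fixed gray-level threshold keeps dark pixels (colloidal gold is
electron-dense), connected components are filtered by per-size-class area
bands, and a roundness cut ``4*pi*area / perimeter**2`` removes elongated
shadow fragments.  Its known failure mode — no single threshold works across
a micrograph with strongly varying background — is what motivates the
learned detector, and the synthetic gradient scenes reproduce it.

Perimeter is measured on the closed polygon traced through the centers of
the component's boundary pixels (Moore neighbor tracing).  For an ``h x w``
rectangle this gives ``2*(h + w) - 4``; a single pixel has zero perimeter
and its circularity is defined as 1.0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .extraction import component_stats, connected_components
from .types import ImagePlane, ParticleRecord

__all__ = ["TacParams", "bands_from_diameters", "circularity", "tac_detect"]

# clockwise Moore neighborhood starting north
_MOORE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


@dataclass(frozen=True)
class TacParams:
    """Fixed detector parameters.

    ``area_bands`` holds one ``(min_px, max_px)`` interval per expected size
    class, ascending and non-overlapping; a detection's ``group`` is the
    index of the band containing its area.
    """

    gray_threshold: float
    area_bands: tuple[tuple[float, float], ...]
    circularity_min: float = 0.6
    pixel_size_nm: float = 1.11

    def __post_init__(self) -> None:
        if not self.area_bands:
            raise ValueError("at least one area band is required")
        for lo, hi in self.area_bands:
            if lo >= hi:
                raise ValueError(f"area band ({lo}, {hi}) must have min < max")
        ordered = sorted(self.area_bands)
        for (_, hi), (lo, _) in zip(ordered, ordered[1:]):
            if lo < hi:
                raise ValueError("area bands may not overlap")
        if not 0.0 <= self.circularity_min <= 1.0:
            raise ValueError("circularity_min must lie in [0, 1]")


def bands_from_diameters(
    diameters_nm: tuple[float, ...], pixel_size_nm: float = 1.11
) -> tuple[tuple[float, float], ...]:
    """Default area bands: [0.5x, 2.0x] the equivalent-disk pixel area of
    each nominal diameter (clipped so adjacent bands abut rather than
    overlap)."""
    bands = []
    for d in sorted(diameters_nm):
        a = math.pi * (d / pixel_size_nm / 2.0) ** 2
        bands.append([0.5 * a, 2.0 * a])
    for prev, nxt in zip(bands, bands[1:]):
        if nxt[0] < prev[1]:
            mid = math.sqrt(prev[1] * nxt[0])  # geometric midpoint between scales
            prev[1] = nxt[0] = mid
    return tuple((lo, hi) for lo, hi in bands)


def _trace_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Moore-neighbor boundary trace of an 8-connected component.

    Returns the closed sequence of boundary pixel centers starting (and
    implicitly ending) at the topmost-leftmost pixel.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("component is empty")
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))
    h, w = mask.shape

    def filled(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < h and 0 <= p[1] < w and bool(mask[p])

    boundary = [start]
    prev = (start[0], start[1] - 1)  # entered from the west
    cur = start
    first_move: tuple[tuple[int, int], tuple[int, int]] | None = None
    for _ in range(4 * rows.size + 8):  # safe upper bound on trace length
        base = _MOORE.index((prev[0] - cur[0], prev[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            cand = (
                cur[0] + _MOORE[(base + k) % 8][0],
                cur[1] + _MOORE[(base + k) % 8][1],
            )
            if filled(cand):
                nxt = cand
                prev = (
                    cur[0] + _MOORE[(base + k - 1) % 8][0],
                    cur[1] + _MOORE[(base + k - 1) % 8][1],
                )
                break
        if nxt is None:  # isolated pixel
            return boundary
        if first_move is None:
            first_move = (cur, nxt)
        elif (cur, nxt) == first_move:  # Jacob's stopping criterion
            return boundary
        boundary.append(nxt)
        cur = nxt
    return boundary  # pragma: no cover - bound never reached for valid masks


def circularity(component: np.ndarray) -> float:
    """Roundness ``4*pi*area / perimeter**2`` clipped to [0, 1].

    ``component`` is a boolean raster containing a single component.
    Single-pixel (zero-perimeter) components return 1.0 by convention.
    """
    rows, cols = np.nonzero(component)
    if rows.size == 0:
        raise ValueError("component is empty")
    trace = _trace_boundary(component)
    if len(trace) < 3:
        return 1.0
    pts = np.array(trace + [trace[0]], dtype=np.float64)
    perimeter = float(np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum())
    if perimeter == 0.0:
        return 1.0
    return float(min(1.0, 4.0 * math.pi * rows.size / perimeter**2))


def tac_detect(image: ImagePlane, params: TacParams) -> list[ParticleRecord]:
    """Run the fixed-parameter baseline on a whole image.

    Pixels with intensity <= ``gray_threshold`` are candidate foreground;
    components are kept when their area falls in one of the bands and their
    circularity reaches ``circularity_min``.  Deterministic; may return an
    empty list.
    """
    fg = image.data <= params.gray_threshold
    labels = connected_components(fg, connectivity=8)
    n_comp = int(labels.max())
    records: list[ParticleRecord] = []
    slices = ndimage.find_objects(labels)
    for lab in range(1, n_comp + 1):
        sl = slices[lab - 1]
        comp = labels[sl] == lab
        x, y, area = component_stats(comp)
        band = next(
            (i for i, (lo, hi) in enumerate(params.area_bands) if lo <= area <= hi),
            None,
        )
        if band is None:
            continue
        if circularity(comp) < params.circularity_min:
            continue
        records.append(
            ParticleRecord(
                x_px=x + sl[1].start,
                y_px=y + sl[0].start,
                area_px=area,
                group=band,
                diameter_nm_est=2.0 * math.sqrt(area / math.pi) * params.pixel_size_nm,
            )
        )
    records.sort(key=lambda r: (r.y_px, r.x_px))
    return records
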