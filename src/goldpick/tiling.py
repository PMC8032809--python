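"""Tile planning, lazy splitting, and mask stitching for images of any size.

Micrographs (tile-scanned FRIL montages can exceed 16,000 px on a side) are
processed in fixed-size square windows so the whole raster never has to be
resident at once for the model-input path.  Windows are laid out row-major
on a stride of ``tile_px - overlap_px``; windows that would overrun the
image are shifted inward so they end exactly at the edge (end-anchored),
and only images smaller than one tile are reflect-padded.  Overlapping
predictions combine by per-pixel maximum, which is order-independent and
lets a particle split across one window boundary be seen whole in a
neighboring window.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np

from .types import ImagePlane, MaskImage

__all__ = ["TilePlan", "plan_tiles", "split", "stitch", "detect_image"]

DEFAULT_TILE_PX = 256
DEFAULT_OVERLAP_PX = 32  # > twice the largest expected particle footprint at 1.11 nm/px


@dataclass(frozen=True)
class TilePlan:
    """Row-major windows ``(row0, col0, row1, col1)``, 0-based half-open.

    Windows are clipped to the image; :func:`split` pads clipped windows
    back up to ``tile_px`` (reflect mode) before yielding them.
    """

    height: int
    width: int
    tile_px: int
    overlap_px: int
    windows: tuple[tuple[int, int, int, int], ...]
    padding_mode: str = "reflect"


def _starts(extent: int, tile_px: int, overlap_px: int) -> list[int]:
    stride = tile_px - overlap_px
    if extent <= tile_px:
        return [0]
    n = -(-(extent - overlap_px) // stride)  # ceil
    starts = [min(i * stride, extent - tile_px) for i in range(n)]
    # dedupe while preserving order (possible when the last stride collapses)
    out: list[int] = []
    for s in starts:
        if not out or s != out[-1]:
            out.append(s)
    return out


def plan_tiles(
    height: int,
    width: int,
    tile_px: int = DEFAULT_TILE_PX,
    overlap_px: int = 0,
) -> TilePlan:
    """Plan the window grid covering a ``height x width`` raster."""
    if height < 1 or width < 1:
        raise ValueError("image dimensions must be >= 1")
    if not 0 <= overlap_px < tile_px:
        raise ValueError(f"overlap_px={overlap_px} must satisfy 0 <= overlap < tile_px")
    windows = tuple(
        (r, c, min(r + tile_px, height), min(c + tile_px, width))
        for r in _starts(height, tile_px, overlap_px)
        for c in _starts(width, tile_px, overlap_px)
    )
    return TilePlan(height, width, tile_px, overlap_px, windows)


def split(image: ImagePlane, plan: TilePlan) -> Iterator[tuple[int, ImagePlane]]:
    """Lazily yield ``(window_index, tile)`` with every tile padded to
    ``tile_px`` square; at most one window is materialized at a time."""
    data = image.data
    if data.shape != (plan.height, plan.width):
        raise ValueError(f"plan is {plan.height}x{plan.width}, image is {data.shape}")
    t = plan.tile_px
    for i, (r0, c0, r1, c1) in enumerate(plan.windows):
        tile = data[r0:r1, c0:c1]
        if tile.shape != (t, t):
            pr, pc = t - tile.shape[0], t - tile.shape[1]
            tile = _pad_reflect(tile, pr, pc, plan.padding_mode)
        yield i, ImagePlane(tile, image.pixel_size_nm)


def _pad_reflect(tile: np.ndarray, pr: int, pc: int, mode: str) -> np.ndarray:
    # np.pad "reflect" needs pad < dim - 1; degenerate slivers fall back to
    # edge replication.
    h, w = tile.shape
    if mode == "reflect" and (pr > h - 1 or pc > w - 1):
        mode = "edge"
    return np.pad(tile, ((0, pr), (0, pc)), mode=mode)


def stitch(
    plan: TilePlan, tiles: Iterator[tuple[int, MaskImage]]
) -> MaskImage:
    """Reassemble per-window masks into a full-size mask, combining
    overlapping pixels by maximum."""
    out = np.full((plan.height, plan.width), -np.inf, dtype=np.float32)
    seen = np.zeros((plan.height, plan.width), dtype=bool)
    for i, mask in tiles:
        r0, c0, r1, c1 = plan.windows[i]
        chunk = mask.data[: r1 - r0, : c1 - c0]
        np.maximum(out[r0:r1, c0:c1], chunk, out=out[r0:r1, c0:c1])
        seen[r0:r1, c0:c1] = True
    if not seen.all():
        raise ValueError("stitch received tiles that do not cover the image")
    return MaskImage(out)


def detect_image(
    model_or_fn,
    image: ImagePlane,
    plan: TilePlan | None = None,
) -> MaskImage:
    """Run the per-tile detector over a whole image and stitch the result.

    ``model_or_fn`` is a :class:`~goldpick.cgan.ModelBundle` or any
    ``tile -> MaskImage`` callable (useful for pass-through tests).
    """
    if callable(model_or_fn):
        predict: Callable[[ImagePlane], MaskImage] = model_or_fn
        tile_px = plan.tile_px if plan is not None else DEFAULT_TILE_PX
    else:
        from .cgan import make_predictor

        predict = make_predictor(model_or_fn)
        tile_px = model_or_fn.cfg.tile_px
        if plan is not None and plan.tile_px != tile_px:
            raise ValueError(
                f"plan tile_px={plan.tile_px} != model tile_px={tile_px}"
            )
    h, w = image.shape
    if plan is None:
        plan = plan_tiles(h, w, tile_px, min(DEFAULT_OVERLAP_PX, tile_px - 1))

    def _run() -> Iterator[tuple[int, MaskImage]]:
        for i, tile in split(image, plan):
            try:
                yield i, predict(tile)
            except Exception as exc:  # annotate failures with the window
                raise RuntimeError(
                    f"detector failed on tile {i} (window {plan.windows[i]})"
                ) from exc

    return stitch(plan, _run())
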