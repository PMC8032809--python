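"""From predicted masks to discrete particle records.

The pipeline is: binarize the (possibly continuous) mask, label connected
components, measure each component's center of mass and pixel area, drop
specks below ``min_area_px``, then cluster areas into size groups so that
differently sized gold labels (e.g. 6 nm vs 12 nm conjugates) can be
separated in one image.

Clustering is exact 1-D k-means — the optimal partition by dynamic
programming on sorted sqrt(area) — so assignments are deterministic and can
be checked against an exhaustive oracle.  sqrt(area) is proportional to
particle diameter, which keeps group boundaries linear in the quantity of
interest.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import MaskImage, ParticleRecord

__all__ = [
    "ExtractionParams",
    "binarize",
    "connected_components",
    "component_stats",
    "cluster_sizes",
    "extract_particles",
]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
    8: np.ones((3, 3), bool),
}


@dataclass(frozen=True)
class ExtractionParams:
    binarize_threshold: float = 0.5  # midpoint of the generator's [0, 1] output
    connectivity: int = 8
    min_area_px: int = 4  # suppress single-pixel generator noise
    n_groups: int = 2
    pixel_size_nm: float = 1.11

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.min_area_px < 0 or self.pixel_size_nm <= 0:
            raise ValueError("invalid extraction parameters")


def binarize(mask: MaskImage | np.ndarray, threshold: float) -> np.ndarray:
    """Boolean foreground: pixel true iff value >= threshold."""
    data = mask.data if isinstance(mask, MaskImage) else np.asarray(mask)
    return data >= threshold


def connected_components(binary: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label foreground under 4- or 8-adjacency.

    Returns an int32 label raster; labels 1..n in first-encounter raster
    order, 0 is background.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    labels, _ = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    return labels.astype(np.int32)


def component_stats(component: np.ndarray | tuple[np.ndarray, np.ndarray]) -> tuple[float, float, int]:
    """Centroid ``(x_px, y_px)`` and pixel area of one component.

    ``component`` is a boolean raster or an ``(rows, cols)`` index pair.
    The centroid is the unweighted mean of member pixel coordinates.
    """
    if isinstance(component, tuple):
        rows, cols = np.asarray(component[0]), np.asarray(component[1])
    else:
        rows, cols = np.nonzero(component)
    if rows.size == 0:
        raise ValueError("component is empty")
    return float(cols.mean()), float(rows.mean()), int(rows.size)


def _segment_cost(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    """Within-segment sum of squared deviations for sorted values v[i..j]."""
    n = j - i + 1
    s = prefix[j + 1] - prefix[i]
    s2 = prefix2[j + 1] - prefix2[i]
    return s2 - s * s / n


def cluster_sizes(
    areas: list[int] | np.ndarray, n_groups: int
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal 1-D k-means of particle areas on the sqrt(area) scale.

    Returns ``(labels, group_mean_areas)``; group labels are 0-based and
    ordered by ascending mean area.  Deterministic, and invariant (up to
    that relabeling) under permutation of the input.
    """
    areas = np.asarray(areas, dtype=np.float64)
    n = areas.size
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} areas, got {n}")
    order = np.argsort(areas, kind="stable")
    v = np.sqrt(areas[order])
    prefix = np.concatenate([[0.0], np.cumsum(v)])
    prefix2 = np.concatenate([[0.0], np.cumsum(v * v)])

    # dp[k][j]: optimal cost of splitting v[0..j] into k+1 groups
    dp = np.full((n_groups, n), np.inf)
    cut = np.zeros((n_groups, n), dtype=np.int64)
    for j in range(n):
        dp[0, j] = _segment_cost(prefix, prefix2, 0, j)
    for k in range(1, n_groups):
        for j in range(k, n):
            for i in range(k, j + 1):  # group k is v[i..j]
                c = dp[k - 1, i - 1] + _segment_cost(prefix, prefix2, i, j)
                if c < dp[k, j]:
                    dp[k, j] = c
                    cut[k, j] = i

    bounds = np.empty(n_groups + 1, dtype=np.int64)
    bounds[-1] = n
    j = n - 1
    for k in range(n_groups - 1, 0, -1):
        bounds[k] = cut[k, j]
        j = cut[k, j] - 1
    bounds[0] = 0

    labels_sorted = np.empty(n, dtype=np.int64)
    means = np.empty(n_groups)
    for k in range(n_groups):
        labels_sorted[bounds[k] : bounds[k + 1]] = k
        seg = areas[order][bounds[k] : bounds[k + 1]]
        means[k] = seg.mean() if seg.size else np.nan
    labels = np.empty(n, dtype=np.int64)
    labels[order] = labels_sorted
    return labels, means


def extract_particles(
    mask: MaskImage | np.ndarray, params: ExtractionParams
) -> list[ParticleRecord]:
    """Full mask-to-records pipeline; records sorted by ``(y_px, x_px)``.

    ``diameter_nm_est`` is the equivalent-circle diameter
    ``2*sqrt(area/pi)*pixel_size_nm`` (the annotation masks are squares, so
    this is a convention, not a measurement; only the group split matters
    downstream).  Returns an empty list when nothing survives the filters.
    """
    fg = binarize(mask, params.binarize_threshold)
    labels = connected_components(fg, params.connectivity)
    n_comp = int(labels.max())
    if n_comp == 0:
        return []
    comps = ndimage.find_objects(labels)
    stats = []
    for lab in range(1, n_comp + 1):
        sl = comps[lab - 1]
        rows, cols = np.nonzero(labels[sl] == lab)
        x, y, area = component_stats((rows + sl[0].start, cols + sl[1].start))
        if area >= params.min_area_px:
            stats.append((x, y, area))
    if not stats:
        return []
    areas = np.array([s[2] for s in stats])
    if len(stats) >= params.n_groups:
        groups, _ = cluster_sizes(areas, params.n_groups)
    else:  # too few survivors to form the requested groups
        groups, _ = cluster_sizes(areas, len(stats))
    records = [
        ParticleRecord(
            x_px=x,
            y_px=y,
            area_px=area,
            group=int(g),
            diameter_nm_est=2.0 * np.sqrt(area / np.pi) * params.pixel_size_nm,
        )
        for (x, y, area), g in zip(stats, groups)
    ]
    records.sort(key=lambda r: (r.y_px, r.x_px))
    return records
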