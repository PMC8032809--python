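"""Synthetic FRIL-like micrograph simulator with exact ground truth.

Freeze-fracture replica immunogold labeling (FRIL) micrographs show dark,
quasi-circular colloidal gold particles on an uneven background: slowly
varying gray level from sample topography, directional dark streaks from the
platinum shadowing, detector noise, and mild defocus blur.  This module
renders such scenes together with the exact particle positions/sizes and the
paired square-mask annotation target, so every downstream stage (tiling,
detection, extraction, evaluation) is testable without real EM data.

Rendering model, per scene:

1. background ``b(x, y) = background_mean + gradient_amplitude * ramp`` where
   ``ramp`` is a linear gradient in [-1, 1] along a seed-chosen direction;
2. each shadow multiplies the background by ``1 - shadow_intensity * p`` with
   ``p`` a soft-edged band profile around a random segment at
   ``shadow_angle_deg`` (shadow gray values overlap the particle gray range
   on purpose, so a pure gray threshold cannot separate the two);
3. each particle is a dark disk of pixel diameter ``diameter_nm /
   pixel_size_nm`` whose core level is ``particle_intensity`` times the local
   background (particles darken multiplicatively, as in shadowed replicas),
   with a 1-px anti-aliased edge;
4. Gaussian blur ``blur_sigma_px``, then additive Gaussian noise
   ``noise_sigma``, then clipping to [0, 1].
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .types import GroundTruthParticle, ImagePlane, MaskImage

__all__ = [
    "SceneSpec",
    "RenderedPair",
    "SceneTooCrowdedError",
    "render_scene",
    "render_target_mask",
    "make_dataset",
    "faux_magnification",
    "write_dataset",
]

_MAX_PLACEMENT_ATTEMPTS = 10_000


class SceneTooCrowdedError(RuntimeError):
    """Raised when particle placement cannot satisfy ``min_separation_px``."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Defaults mirror the source imaging conditions: 1.11 nm/pixel with 6 nm
    and 12 nm colloidal gold.  ``min_separation_px=None`` means twice the
    largest particle pixel diameter, which keeps truth-to-detection matching
    unambiguous.
    """

    height_px: int = 256
    width_px: int = 256
    pixel_size_nm: float = 1.11
    particle_diameters_nm: tuple[float, ...] = (6.0, 12.0)
    counts_per_diameter: tuple[int, ...] = (6, 6)
    particle_intensity: float = 0.45
    background_mean: float = 0.55
    gradient_amplitude: float = 0.12
    shadow_count: int = 2
    shadow_intensity: float = 0.55
    shadow_angle_deg: float = 30.0
    noise_sigma: float = 0.02
    blur_sigma_px: float = 0.5
    min_separation_px: float | None = None
    mask_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ValueError("raster dimensions must be positive")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if len(self.counts_per_diameter) != len(self.particle_diameters_nm):
            raise ValueError(
                "counts_per_diameter must align with particle_diameters_nm"
            )
        if any(d <= 0 for d in self.particle_diameters_nm):
            raise ValueError("particle diameters must be positive")
        if any(c < 0 for c in self.counts_per_diameter):
            raise ValueError("particle counts must be non-negative")
        if not 0.0 <= self.particle_intensity <= 1.0:
            raise ValueError("particle_intensity must lie in [0, 1]")
        object.__setattr__(
            self,
            "particle_diameters_nm",
            tuple(float(d) for d in self.particle_diameters_nm),
        )
        object.__setattr__(
            self, "counts_per_diameter", tuple(int(c) for c in self.counts_per_diameter)
        )

    @property
    def diameters_px(self) -> tuple[float, ...]:
        return tuple(d / self.pixel_size_nm for d in self.particle_diameters_nm)

    @property
    def separation_px(self) -> float:
        if self.min_separation_px is not None:
            return float(self.min_separation_px)
        return 2.0 * max(self.diameters_px, default=1.0)


@dataclass
class RenderedPair:
    """A training/evaluation pair: micrograph, target mask, and ground truth."""

    input_image: ImagePlane
    target_mask: MaskImage
    truth: list[GroundTruthParticle]


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    bg = np.full((h, w), spec.background_mean, dtype=np.float64)
    if spec.gradient_amplitude > 0:
        theta = rng.uniform(0.0, 2.0 * math.pi)
        proj = xx * math.cos(theta) + yy * math.sin(theta)
        lo, hi = proj.min(), proj.max()
        ramp = np.zeros_like(proj) if hi == lo else (proj - lo) / (hi - lo) * 2.0 - 1.0
        bg += spec.gradient_amplitude * ramp
    for _ in range(spec.shadow_count):
        cx = rng.uniform(0, w)
        cy = rng.uniform(0, h)
        length = rng.uniform(0.25, 0.6) * max(h, w)
        width = rng.uniform(1.5, 4.0)
        ang = math.radians(spec.shadow_angle_deg + rng.normal(0.0, 5.0))
        ux, uy = math.cos(ang), math.sin(ang)
        # distance to the segment [c - L/2 u, c + L/2 u]
        t = np.clip((xx - cx) * ux + (yy - cy) * uy, -length / 2, length / 2)
        d2 = (xx - cx - t * ux) ** 2 + (yy - cy - t * uy) ** 2
        profile = np.exp(-d2 / (2.0 * width**2))
        bg *= 1.0 - spec.shadow_intensity * profile
    return bg


def _place_particles(
    spec: SceneSpec, rng: np.random.Generator
) -> list[GroundTruthParticle]:
    h, w = spec.height_px, spec.width_px
    sep2 = spec.separation_px**2
    largest_px = max(spec.diameters_px, default=1.0)
    margin = largest_px / 2.0 + 2.0
    if 2 * margin >= min(h, w) and sum(spec.counts_per_diameter) > 0:
        raise SceneTooCrowdedError(
            f"scene {h}x{w} too small for particles of {largest_px:.1f} px"
        )
    placed: list[GroundTruthParticle] = []
    for dia_nm, count in zip(spec.particle_diameters_nm, spec.counts_per_diameter):
        for _ in range(count):
            for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
                x = rng.uniform(margin, w - 1 - margin)
                y = rng.uniform(margin, h - 1 - margin)
                if all((p.x_px - x) ** 2 + (p.y_px - y) ** 2 >= sep2 for p in placed):
                    placed.append(GroundTruthParticle(x, y, dia_nm))
                    break
            else:
                raise SceneTooCrowdedError(
                    f"could not place particle {len(placed) + 1} of "
                    f"{sum(spec.counts_per_diameter)} after "
                    f"{_MAX_PLACEMENT_ATTEMPTS} attempts "
                    f"(min separation {spec.separation_px:.1f} px)"
                )
    return placed


def _stamp_particle(
    img: np.ndarray, bg: np.ndarray, p: GroundTruthParticle, spec: SceneSpec
) -> None:
    r = (p.diameter_nm / spec.pixel_size_nm) / 2.0
    h, w = img.shape
    r0 = max(0, int(math.floor(p.y_px - r - 2)))
    r1 = min(h, int(math.ceil(p.y_px + r + 3)))
    c0 = max(0, int(math.floor(p.x_px - r - 2)))
    c1 = min(w, int(math.ceil(p.x_px + r + 3)))
    yy, xx = np.mgrid[r0:r1, c0:c1].astype(np.float64)
    dist = np.sqrt((xx - p.x_px) ** 2 + (yy - p.y_px) ** 2)
    alpha = np.clip(r + 0.5 - dist, 0.0, 1.0)  # 1-px anti-aliased edge
    core = bg[r0:r1, c0:c1] * spec.particle_intensity
    img[r0:r1, c0:c1] = img[r0:r1, c0:c1] * (1.0 - alpha) + core * alpha


def render_target_mask(
    truth: list[GroundTruthParticle],
    height_px: int,
    width_px: int,
    pixel_size_nm: float,
    mask_scale: float = 1.0,
) -> MaskImage:
    """Render the square-mask annotation target.

    Each particle contributes an axis-aligned square of side
    ``round(mask_scale * diameter_nm / pixel_size_nm)`` (at least 1 px)
    centered on its rounded center; overlapping squares merge by union.
    """
    if mask_scale <= 0:
        raise ValueError("mask_scale must be positive")
    mask = np.zeros((height_px, width_px), dtype=np.float32)
    for p in truth:
        ri, ci = int(round(p.y_px)), int(round(p.x_px))
        if not (0 <= ri < height_px and 0 <= ci < width_px):
            raise ValueError(
                f"particle center ({p.x_px:.1f}, {p.y_px:.1f}) outside "
                f"{height_px}x{width_px} raster"
            )
        side = max(1, int(round(mask_scale * p.diameter_nm / pixel_size_nm)))
        r0 = max(0, ri - side // 2)
        c0 = max(0, ci - side // 2)
        mask[r0 : min(height_px, r0 + side), c0 : min(width_px, c0 + side)] = 1.0
    return MaskImage(mask)


def render_scene(spec: SceneSpec, seed: int) -> RenderedPair:
    """Render one scene deterministically from ``(spec, seed)``."""
    rng = np.random.default_rng(seed)
    bg = _background(spec, rng)
    truth = _place_particles(spec, rng)
    img = bg.copy()
    for p in truth:
        _stamp_particle(img, bg, p, spec)
    if spec.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma_px)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    mask = render_target_mask(
        truth, spec.height_px, spec.width_px, spec.pixel_size_nm, spec.mask_scale
    )
    return RenderedPair(
        input_image=ImagePlane(img.astype(np.float32), spec.pixel_size_nm),
        target_mask=mask,
        truth=truth,
    )


def make_dataset(
    spec_template: SceneSpec,
    n_pairs: int,
    empty_fraction: float = 0.5,
    seed: int = 0,
) -> list[RenderedPair]:
    """Render ``n_pairs`` scenes, a ``round(empty_fraction * n_pairs)`` subset
    of them particle-free (balanced training sets avoid labeling bias).

    Per-pair seeds are derived deterministically from ``seed``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not 0.0 <= empty_fraction <= 1.0:
        raise ValueError("empty_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_empty = int(round(empty_fraction * n_pairs))
    empty_idx = set(rng.choice(n_pairs, size=n_empty, replace=False).tolist())
    child_seeds = np.random.SeedSequence(seed).generate_state(n_pairs) % (2**31)
    empty_spec = replace(
        spec_template,
        counts_per_diameter=tuple(0 for _ in spec_template.counts_per_diameter),
    )
    pairs = []
    for i in range(n_pairs):
        spec_i = empty_spec if i in empty_idx else spec_template
        pairs.append(render_scene(spec_i, int(child_seeds[i])))
    return pairs


def faux_magnification(pair: RenderedPair, scale: float) -> RenderedPair:
    """Rescale a rendered pair to emulate a different microscope magnification.

    The raster, mask, and truth coordinates scale by ``scale``; particle
    diameters stay fixed in nm while the effective pixel size becomes
    ``pixel_size_nm / scale`` (e.g. 2x on 1.11 nm/px emulates 0.55 nm/px
    imaging).
    """
    from skimage.transform import resize

    if scale <= 0:
        raise ValueError("scale must be positive")
    h, w = pair.input_image.shape
    nh, nw = int(round(h * scale)), int(round(w * scale))
    if nh < 1 or nw < 1:
        raise ValueError(f"scale {scale} collapses {h}x{w} below 1 px")
    img = resize(
        pair.input_image.data, (nh, nw), order=1, anti_aliasing=scale < 1.0
    ).astype(np.float32)
    mask = resize(pair.target_mask.data, (nh, nw), order=0, anti_aliasing=False)
    fy, fx = nh / h, nw / w
    truth = [
        GroundTruthParticle(
            (p.x_px + 0.5) * fx - 0.5, (p.y_px + 0.5) * fy - 0.5, p.diameter_nm
        )
        for p in pair.truth
    ]
    new_ps = pair.input_image.pixel_size_nm * w / nw
    return RenderedPair(
        input_image=ImagePlane(img, new_ps),
        target_mask=MaskImage(mask.astype(np.float32)),
        truth=truth,
    )


def write_dataset(pairs: list[RenderedPair], out_dir: str | Path) -> list[Path]:
    """Write paired input TIFFs, mask PNGs, and ground-truth CSVs.

    Produces ``scene_<i>.tif`` (16-bit input), ``scene_<i>_mask.png`` (binary
    mask), ``scene_<i>_truth.csv`` (header ``x_px,y_px,diameter_nm``).
    """
    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for i, pair in enumerate(pairs):
        stem = f"scene_{i:04d}"
        tif = out / f"{stem}.tif"
        tifffile.imwrite(
            tif, (np.clip(pair.input_image.data, 0, 1) * 65535).astype(np.uint16)
        )
        png = out / f"{stem}_mask.png"
        iio.imwrite(png, ((pair.target_mask.data >= 0.5) * 255).astype(np.uint8))
        csv = out / f"{stem}_truth.csv"
        with open(csv, "w") as fh:
            fh.write(f"# pixel_size_nm={pair.input_image.pixel_size_nm}\n")
            fh.write("x_px,y_px,diameter_nm\n")
            for p in pair.truth:
                fh.write(f"{p.x_px:.3f},{p.y_px:.3f},{p.diameter_nm:g}\n")
        written += [tif, png, csv]
    return written
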