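"""Canonical desk-scale study conditions used by tests and benchmark scripts.

All families image 6 nm and 12 nm colloidal gold at 1.11 nm/pixel on 64 px
tiles (the CPU-scale configuration of the detector).  Particles darken the
local background to 45% of its value, so their absolute gray level shifts
with the background — the property that defeats a fixed gray threshold once
the background varies strongly.

``TRAIN_FAMILY``
    heterogeneous training scenes: strong linear background gradient
    (amplitude 0.4 around mean 0.55, seed-chosen orientation) plus one
    directional shadow streak.
``FLAT_FAMILY`` / ``GRADIENT_FAMILY``
    evaluation scenes isolating the background-variation failure mode of
    the threshold baseline: identical particle content on a flat background
    vs the same strong gradient (no shadows, so the comparison measures the
    gradient effect alone).
``PRETRAIN_FAMILY``
    particle-free textured scenes from a different background family
    (darker mean, heavy shadowing, stronger blur) for transfer-learning
    experiments.

``TAC_PARAMS`` fixes the baseline at a gray threshold of 0.35 — midway
between particle cores (~0.25) and background (0.55) on flat scenes — with
the default per-size area bands and a 0.6 roundness cut.  On the gradient
family roughly half the particles become unresolvable at this threshold:
on the dark side the background itself drops below it, on the bright side
particle cores rise above it.
"""
from __future__ import annotations

from dataclasses import replace

from .synthetic import SceneSpec
from .tac import TacParams, bands_from_diameters

__all__ = [
    "TRAIN_FAMILY",
    "FLAT_FAMILY",
    "GRADIENT_FAMILY",
    "PRETRAIN_FAMILY",
    "TAC_PARAMS",
]

TRAIN_FAMILY = SceneSpec(
    height_px=64,
    width_px=64,
    pixel_size_nm=1.11,
    particle_diameters_nm=(6.0, 12.0),
    counts_per_diameter=(2, 1),
    particle_intensity=0.45,
    background_mean=0.55,
    gradient_amplitude=0.4,
    shadow_count=1,
    shadow_intensity=0.55,
    noise_sigma=0.02,
    blur_sigma_px=0.5,
)

FLAT_FAMILY = replace(TRAIN_FAMILY, gradient_amplitude=0.0, shadow_count=0)

GRADIENT_FAMILY = replace(TRAIN_FAMILY, shadow_count=0)

PRETRAIN_FAMILY = replace(
    TRAIN_FAMILY,
    counts_per_diameter=(0, 0),
    background_mean=0.4,
    gradient_amplitude=0.3,
    shadow_count=4,
    blur_sigma_px=1.0,
)

TAC_PARAMS = TacParams(
    gray_threshold=0.35,
    area_bands=bands_from_diameters((6.0, 12.0), 1.11),
    circularity_min=0.6,
    pixel_size_nm=1.11,
)
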