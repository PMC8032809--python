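"""Readers and writers: images, particle CSV tables, and overlays.

Particle tables are plain CSV with ``#``-prefixed metadata lines (image
identifier, pixel size, detector provenance and a parameter digest) so the
files stay readable by any CSV consumer.  Coordinates are written 0-based
in pixel units — downstream viewers are often 1-based, so this is stated in
the file header comment as well.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .types import ImagePlane, ParticleRecord

__all__ = [
    "ParticleTable",
    "params_digest",
    "read_image",
    "write_image",
    "write_particle_csv",
    "read_particle_csv",
    "render_overlay",
]

logger = logging.getLogger("goldpick")

_HEADER = "x_px,y_px,area_px,group,diameter_nm_est"

GROUP_COLORS = (
    (255, 64, 64),
    (64, 255, 64),
    (96, 96, 255),
    (255, 224, 32),
    (255, 64, 255),
    (64, 255, 255),
)


@dataclass
class ParticleTable:
    """Detected particles plus provenance, the unit the CSV files carry."""

    records: list[ParticleRecord]
    image_id: str = ""
    pixel_size_nm: float = 1.11
    detector: str = ""  # "cgan" | "tac"
    params_digest: str = ""

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.y_px, r.x_px))


def params_digest(params) -> str:
    """Stable 12-hex digest of a parameter mapping, for provenance lines."""
    from dataclasses import asdict, is_dataclass

    if is_dataclass(params):
        params = asdict(params)
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def read_image(path: str | Path, pixel_size_nm: float) -> ImagePlane:
    """Load a single-channel 8/16-bit TIFF or PNG, rescaled to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim == 3:  # tolerate gray saved as RGB
        data = data.mean(axis=2)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image, got shape {data.shape}")
    if data.dtype == np.uint8:
        data = data / 255.0
    elif data.dtype == np.uint16:
        data = data / 65535.0
    else:
        data = np.clip(data.astype(np.float64), 0.0, 1.0)
    return ImagePlane(data.astype(np.float32), pixel_size_nm)


def write_image(path: str | Path, data: np.ndarray) -> None:
    """Write a [0, 1] float raster as 8-bit PNG or 16-bit TIFF by suffix."""
    path = Path(path)
    arr = np.clip(np.asarray(data, dtype=np.float64), 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, (arr * 65535).astype(np.uint16))
    else:
        import imageio.v3 as iio

        iio.imwrite(path, (arr * 255).astype(np.uint8))


def _format_row(r: ParticleRecord) -> str:
    return f"{r.x_px:.2f},{r.y_px:.2f},{r.area_px:d},{r.group:d},{r.diameter_nm_est:.4f}"


def write_particle_csv(
    table: ParticleTable, path: str | Path, split_by_group: bool = False
) -> list[Path]:
    """Write the particle table; with ``split_by_group`` one file per group,
    suffixed ``_g<k>``.  Centroids carry 2 decimals, areas are integers."""
    path = Path(path)
    groups = sorted({r.group for r in table.records}) if split_by_group else [None]
    written: list[Path] = []
    for g in groups:
        target = (
            path
            if g is None
            else path.with_name(f"{path.stem}_g{g}{path.suffix}")
        )
        recs = [r for r in table.records if g is None or r.group == g]
        try:
            with open(target, "w") as fh:
                fh.write("# goldpick particle table; coordinates 0-based, pixel units\n")
                fh.write(f"# image={table.image_id}\n")
                fh.write(f"# pixel_size_nm={table.pixel_size_nm:g}\n")
                fh.write(f"# detector={table.detector}\n")
                fh.write(f"# params={table.params_digest}\n")
                fh.write(_HEADER + "\n")
                for r in recs:
                    fh.write(_format_row(r) + "\n")
        except OSError as exc:
            raise OSError(f"failed writing particle CSV {target}: {exc}") from exc
        written.append(target)
    return written


def read_particle_csv(path: str | Path) -> ParticleTable:
    """Inverse of :func:`write_particle_csv` at the declared precision."""
    path = Path(path)
    meta = {"image": "", "pixel_size_nm": "1.11", "detector": "", "params": ""}
    records: list[ParticleRecord] = []
    with open(path) as fh:
        header_seen = False
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            if not header_seen:
                if line != _HEADER:
                    raise ValueError(
                        f"{path}:{ln}: malformed header {line!r}, expected {_HEADER!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 5:
                raise ValueError(f"{path}:{ln}: expected 5 columns, got {len(parts)}")
            try:
                records.append(
                    ParticleRecord(
                        x_px=float(parts[0]),
                        y_px=float(parts[1]),
                        area_px=int(parts[2]),
                        group=int(parts[3]),
                        diameter_nm_est=float(parts[4]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
        if not header_seen:
            raise ValueError(f"{path}: missing header line {_HEADER!r}")
    return ParticleTable(
        records=records,
        image_id=meta["image"],
        pixel_size_nm=float(meta["pixel_size_nm"]),
        detector=meta["detector"],
        params_digest=meta["params"],
    )


def render_overlay(
    image: ImagePlane,
    table: ParticleTable,
    mark_style: str = "cross",
    mark_radius: int = 4,
) -> np.ndarray:
    """RGB uint8 copy of the grayscale image with per-group colored markers.

    Gray values outside markers are untouched; out-of-bounds records are
    skipped with a logged warning.
    """
    h, w = image.shape
    gray = (np.clip(image.data, 0, 1) * 255).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=2)
    for r in table.records:
        ci, ri = int(round(r.x_px)), int(round(r.y_px))
        if not (0 <= ri < h and 0 <= ci < w):
            logger.warning(
                "overlay: record at (%.1f, %.1f) outside %dx%d image, skipped",
                r.x_px, r.y_px, w, h,
            )
            continue
        color = GROUP_COLORS[r.group % len(GROUP_COLORS)]
        if mark_style == "cross":
            for d in range(-mark_radius, mark_radius + 1):
                if 0 <= ri + d < h:
                    rgb[ri + d, ci] = color
                if 0 <= ci + d < w:
                    rgb[ri, ci + d] = color
        else:  # ring
            for ang in np.linspace(0, 2 * np.pi, 8 * mark_radius, endpoint=False):
                rr = int(round(ri + mark_radius * np.sin(ang)))
                cc = int(round(ci + mark_radius * np.cos(ang)))
                if 0 <= rr < h and 0 <= cc < w:
                    rgb[rr, cc] = color
            rgb[ri, ci] = color
    return rgb
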