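"""Synthetic two-class cell-image generator.

Produces labelled crops that emulate segmented histology cells: "healthy"
cells have a smooth interior (radial ramp, concentric modulation, a darker
elliptical nucleus) whose gradient directions are spatially coherent;
"dying" cells carry fine-grained speckle and fragmented blobs riding on a
similar smooth base, so their gradient directions are disordered while
their raw-intensity statistics stay close to the healthy class.  Mean
intensities of the two classes overlap by a configurable amount so that
brightness alone is a weak discriminator.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

LABELS = ("healthy", "dying")


class ConfigError(ValueError):
    """Invalid synthetic-dataset configuration."""


@dataclass
class SynthConfig:
    """Parameters of a synthetic dataset.

    ``intensity_overlap`` slides the "dying" class's mean-intensity
    distribution: 1.0 means both classes draw cell means from the same
    distribution (brightness carries no signal), 0.0 fully separates them.
    """

    n_per_class: int = 500
    size_range: tuple[int, int] = (20, 100)
    noise_sd: float = 0.008
    intensity_overlap: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ConfigError(f"n_per_class must be >= 1, got {self.n_per_class}")
        lo, hi = self.size_range
        if lo < 16:
            raise ConfigError(f"size_range minimum must be >= 16, got {lo}")
        if hi < lo:
            raise ConfigError(f"size_range must be (min, max) with max >= min, got {self.size_range}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.intensity_overlap <= 1.0:
            raise ConfigError(
                f"intensity_overlap must be in [0, 1], got {self.intensity_overlap}"
            )


@dataclass
class CellImage:
    """One segmented cell: grey map in [0, 1], interior mask, class label."""

    pixels: np.ndarray
    mask: np.ndarray
    label: str
    cell_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.shape != self.mask.shape:
            raise ValueError("pixels and mask must share shape")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


def _elliptical_radius(size: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Normalized elliptical radius field and the interior mask it defines."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = cx = (size - 1) / 2.0
    a = size / 2.0 * rng.uniform(0.82, 0.95)          # semi-major, px
    b = a * rng.uniform(0.72, 1.0)                    # semi-minor
    phi = rng.uniform(0, np.pi)
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    return r, r <= 1.0


def _smooth_noise(size: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean gaussian-filtered white noise, normalized to unit std."""
    z = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma)
    sd = z.std()
    return z / sd if sd > 0 else z


def _healthy_texture(size: int, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth coherent interior: radial ramp-with-rings + dark nucleus.

    The radial profile is a sawtooth, so the gradient keeps a constant,
    cell-size-independent magnitude and a consistent (outward) radial
    direction everywhere except the thin ring-reset lines.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = cx = (size - 1) / 2.0
    rad_px = np.hypot(yy - cy, xx - cx)

    tex = -rng.uniform(0.18, 0.3) * r ** rng.uniform(1.0, 1.6)
    # monotone sawtooth rings: |gradient| = amp / wavelength at every pixel
    wavelength = rng.uniform(14.0, 18.0)
    amp = rng.uniform(0.28, 0.38)
    phase = rng.uniform(0.0, wavelength)
    tex -= amp * (np.mod(rad_px + phase, wavelength) / wavelength)
    # darker, slightly off-centre nucleus
    ny = cy + rng.uniform(-0.12, 0.12) * size
    nx = cx + rng.uniform(-0.12, 0.12) * size
    nr = size * rng.uniform(0.12, 0.2)
    tex -= rng.uniform(0.1, 0.2) * np.exp(-(((yy - ny) ** 2 + (xx - nx) ** 2) / (2 * nr ** 2)))
    # mild low-frequency irregularity
    tex += 0.02 * _smooth_noise(size, max(3.0, size / 5.0), rng)
    return tex


def _dying_texture(size: int, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Disordered interior with healthy-like intensity statistics.

    The same sawtooth banding as the healthy class is evaluated over a
    rough random field whose gradient has unit magnitude on average but a
    direction that decorrelates within about a pixel.  Grey-value steps and
    band-reset jumps therefore match the healthy class closely (keeping
    raw-intensity texture weakly discriminative) while the gradient
    directions are scrambled.  A few condensed dark fragments stand in for
    fragmented chromatin.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = cx = (size - 1) / 2.0
    tex = -rng.uniform(0.18, 0.3) * r ** rng.uniform(1.0, 1.6)
    # direction scrambler: small in grey range, steep per pixel, so it owns
    # the local gradient without dominating the cell's intensity spread
    rough = _smooth_noise(size, rng.uniform(0.4, 0.55), rng)
    gy, gx = np.gradient(rough)
    mean_grad = np.hypot(gx, gy).mean()
    u = rough / (mean_grad if mean_grad > 0 else 1.0)
    tex += rng.uniform(0.025, 0.04) * u
    # nucleus-sized dark blob, as in the healthy class
    ny = cy + rng.uniform(-0.12, 0.12) * size
    nx = cx + rng.uniform(-0.12, 0.12) * size
    nr = size * rng.uniform(0.12, 0.2)
    tex -= rng.uniform(0.1, 0.2) * np.exp(-(((yy - ny) ** 2 + (xx - nx) ** 2) / (2 * nr ** 2)))
    tex += 0.02 * _smooth_noise(size, max(3.0, size / 5.0), rng)
    # sparse debris: isolated pixels resampled across the cell's grey range,
    # mimicking the healthy class's band-reset jump tail in the pair stats
    salt = rng.random((size, size)) < rng.uniform(0.05, 0.08)
    lo, hi = tex.min(), tex.max()
    tex[salt] = rng.uniform(lo, hi, size=int(salt.sum()))
    # a few condensed fragments
    for _ in range(rng.integers(2, 6)):
        by, bx = rng.uniform(0.2, 0.8, size=2) * size
        bs = rng.uniform(1.0, 2.5)
        tex -= rng.uniform(0.05, 0.1) * np.exp(-(((yy - by) ** 2 + (xx - bx) ** 2) / (2 * bs ** 2)))
    return tex


def _make_cell(label: str, size: int, mean_lo: float, mean_hi: float,
               noise_sd: float, cell_id: str, rng: np.random.Generator) -> CellImage:
    r, mask = _elliptical_radius(size, rng)
    if label == "healthy":
        tex = _healthy_texture(size, r, rng)
    else:
        tex = _dying_texture(size, r, rng)
    # rank-uniformize the in-mask values: a strictly monotone map, so
    # gradient directions are preserved exactly while every cell of either
    # class ends up with an identical (uniform) grey-level histogram --
    # raw-intensity statistics then carry almost no class signal
    flat = tex[mask]
    ranks = np.empty(flat.size)
    ranks[np.argsort(flat, kind="stable")] = np.arange(flat.size)
    span = rng.uniform(0.5, 0.7)
    tex[mask] = span * ranks / max(flat.size - 1, 1)
    tex += noise_sd * rng.standard_normal((size, size))
    # pin the in-mask mean so class brightness is controlled by the config
    target_mean = rng.uniform(mean_lo, mean_hi)
    tex = tex - tex[mask].mean() + target_mean
    pixels = np.clip(tex, 0.0, 1.0)
    pixels[~mask] = np.clip(0.85 + 0.02 * rng.standard_normal((~mask).sum()), 0, 1)
    return CellImage(pixels=pixels, mask=mask, label=label, cell_id=cell_id)


def generate_dataset(config: SynthConfig) -> list[CellImage]:
    """Generate ``2 * n_per_class`` labelled cells, deterministic in the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.size_range
    shift = 0.3 * (1.0 - config.intensity_overlap)
    cells: list[CellImage] = []
    for label in LABELS:
        mean_lo, mean_hi = 0.38, 0.62
        if label == "dying":
            mean_lo, mean_hi = mean_lo + shift, mean_hi + shift
        for i in range(config.n_per_class):
            size = int(rng.integers(lo, hi + 1))
            cells.append(_make_cell(label, size, mean_lo, min(mean_hi, 0.95),
                                    config.noise_sd, f"{label}_{i:04d}", rng))
    return cells


def write_dataset(cells: list[CellImage], out_dir: str | Path) -> Path:
    """Write one 8-bit PNG per cell image and mask plus a CSV manifest.

    Returns the manifest path.  Round-trips through :func:`read_dataset`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_id", "image_path", "mask_path", "label"])
        for cell in cells:
            img_name = f"{cell.cell_id}.png"
            mask_name = f"{cell.cell_id}_mask.png"
            iio.imwrite(out_dir / img_name,
                        np.round(cell.pixels * 255).astype(np.uint8))
            iio.imwrite(out_dir / mask_name,
                        (cell.mask.astype(np.uint8) * 255))
            writer.writerow([cell.cell_id, img_name, mask_name, cell.label])
    return manifest


def read_dataset(manifest: str | Path) -> list[CellImage]:
    """Load cells from a manifest CSV written by :func:`write_dataset`.

    Paths in the manifest are resolved relative to the manifest's directory
    unless absolute.  Missing ``mask_path`` entries yield an all-true mask.
    """
    manifest = Path(manifest)
    base = manifest.parent
    cells: list[CellImage] = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            img = np.asarray(iio.imread(base / row["image_path"]))
            from .gradients import rgb_to_grey

            pixels = rgb_to_grey(img)
            mask_path = row.get("mask_path", "")
            if mask_path:
                mask = np.asarray(iio.imread(base / mask_path)) > 0
                if mask.ndim == 3:
                    mask = mask[..., 0]
            else:
                mask = np.ones(pixels.shape, dtype=bool)
            cells.append(CellImage(pixels=pixels, mask=mask,
                                   label=row["label"], cell_id=row["cell_id"]))
    return cells
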