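"""Gradient maps (magnitude and direction) and grey-level quantization.

The per-pixel gradient vector of an image ``f`` is estimated by finite
differences; its magnitude is ``sqrt(gx**2 + gy**2)`` and its direction an
angle in a declared principal range.  Either map (or the raw intensity) is
then linearly rescaled to N grey levels for co-occurrence counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

ALLOWED_LEVELS = (8, 16, 32, 64)

#: luminance weights used by :func:`rgb_to_grey` (ITU-R BT.601)
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: sentinel stored at out-of-mask pixels of a quantized map
MASKED = 0


class SizeError(ValueError):
    """Image too small for the requested operation."""


@dataclass
class GradientMaps:
    """Per-pixel gradient fields of one cell image.

    Attributes
    ----------
    gx, gy : ndarray
        Partial derivatives along x (columns) and y (rows).
    magnitude : ndarray
        ``sqrt(gx**2 + gy**2)``, elementwise.
    direction : ndarray
        Gradient angle in radians, within ``principal_range``.
    mask : ndarray of bool
        Cell-interior mask aligned with the source image.
    convention : str
        ``"atan2"`` or ``"eq3"`` (see :func:`compute_gradients`).
    """

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    direction: np.ndarray
    mask: np.ndarray
    convention: str = "atan2"

    @property
    def principal_range(self) -> tuple[float, float]:
        if self.convention == "eq3":
            return (-np.pi / 2, np.pi / 2)
        return (-np.pi, np.pi)


@dataclass
class QuantizedMap:
    """Integer map with in-mask values in ``1..n_levels``; 0 marks masked-out."""

    levels: np.ndarray
    n_levels: int
    source_kind: str = "intensity"  # one of {"GM", "GD", "intensity"}
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = self.levels != MASKED


def rgb_to_grey(pixels: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to a single luminance channel in [0, 1].

    Already-grey (2-D) input is passed through unchanged, which makes the
    conversion idempotent.  Integer input is assumed to span 0..255.
    """
    pixels = np.asarray(pixels)
    if np.issubdtype(pixels.dtype, np.integer):
        pixels = pixels.astype(np.float64) / 255.0
    else:
        pixels = pixels.astype(np.float64)
    if pixels.ndim == 2:
        return pixels
    if pixels.ndim != 3 or pixels.shape[-1] != 3:
        raise ValueError(
            f"expected a 2-D grey map or an (H, W, 3) colour map, got shape {pixels.shape}"
        )
    return pixels @ np.asarray(LUMA_WEIGHTS)


def _finite_differences(f: np.ndarray, scheme: str) -> tuple[np.ndarray, np.ndarray]:
    if scheme == "central":
        # np.gradient: central differences, one-sided at the borders
        gy, gx = np.gradient(f)
    elif scheme == "sobel":
        gx = ndimage.sobel(f, axis=1) / 8.0
        gy = ndimage.sobel(f, axis=0) / 8.0
    else:
        raise ValueError(f"unknown derivative scheme {scheme!r}; use 'central' or 'sobel'")
    return gx, gy


def compute_gradients(cell, scheme: str = "central", convention: str = "atan2") -> GradientMaps:
    """Compute gradient magnitude/direction maps of a cell image.

    Parameters
    ----------
    cell
        A :class:`~gdglcm.synthetic.CellImage` or any object with ``pixels``
        (2-D float array) and ``mask`` attributes; a bare 2-D array is also
        accepted (all-true mask).
    scheme
        ``"central"`` (default) for central differences with one-sided
        differences at the borders, or ``"sobel"``.
    convention
        ``"atan2"`` (default): direction = atan2(gy, gx), range (-pi, pi].
        ``"eq3"``: direction = atan(gx / gy), range (-pi/2, pi/2], with 0
        wherever gy == 0.  Zero-gradient pixels get direction 0 under both.
    """
    if hasattr(cell, "pixels"):
        f = np.asarray(cell.pixels, dtype=np.float64)
        mask = np.asarray(cell.mask, dtype=bool)
    else:
        f = np.asarray(cell, dtype=np.float64)
        mask = np.ones(f.shape, dtype=bool)
    if f.ndim != 2 or min(f.shape) < 3:
        raise SizeError(f"image must be 2-D and at least 3x3, got shape {f.shape}")

    gx, gy = _finite_differences(f, scheme)
    magnitude = np.hypot(gx, gy)

    if convention == "atan2":
        direction = np.arctan2(gy, gx)  # 0 at gx=gy=0 by atan2 convention
    elif convention == "eq3":
        with np.errstate(divide="ignore", invalid="ignore"):
            direction = np.arctan(np.divide(gx, gy, out=np.zeros_like(gx), where=gy != 0))
        direction[gy == 0] = 0.0
    else:
        raise ValueError(f"unknown direction convention {convention!r}")
    direction = np.where(magnitude == 0, 0.0, direction)

    return GradientMaps(gx=gx, gy=gy, magnitude=magnitude,
                        direction=direction, mask=mask, convention=convention)


def quantize(
    values: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    range_policy: str = "minmax",
    fixed_range: tuple[float, float] | None = None,
    source_kind: str = "intensity",
) -> QuantizedMap:
    """Linearly bin a real-valued map into integer levels ``1..n_levels``.

    ``range_policy="minmax"`` (default) rescales using the in-mask min/max,
    which makes the result invariant to affine rescaling of the input; a
    constant map lands entirely on level 1.  ``range_policy="fixed"`` bins
    over an explicit ``fixed_range`` instead (values outside are clipped).
    Out-of-mask pixels are set to the sentinel 0 and never counted.
    """
    if n_levels not in ALLOWED_LEVELS:
        raise ValueError(f"n_levels must be one of {ALLOWED_LEVELS}, got {n_levels}")
    values = np.asarray(values, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("values and mask must share shape")
    if not mask.any():
        raise ValueError("empty mask: nothing to quantize")

    if range_policy == "minmax":
        lo = values[mask].min()
        hi = values[mask].max()
    elif range_policy == "fixed":
        if fixed_range is None:
            raise ValueError("range_policy='fixed' requires fixed_range=(lo, hi)")
        lo, hi = fixed_range
    else:
        raise ValueError(f"unknown range_policy {range_policy!r}")

    levels = np.full(values.shape, MASKED, dtype=np.int32)
    if hi > lo:
        scaled = (values - lo) / (hi - lo) * n_levels
        binned = np.clip(np.floor(scaled).astype(np.int32) + 1, 1, n_levels)
    else:
        binned = np.ones(values.shape, dtype=np.int32)
    levels[mask] = binned[mask]
    return QuantizedMap(levels=levels, n_levels=n_levels,
                        source_kind=source_kind, mask=mask)


def quantized_map_for(cell, map_kind: str, n_levels: int,
                      range_policy: str = "minmax",
                      scheme: str = "central",
                      convention: str = "atan2") -> QuantizedMap:
    """Produce the quantized map of one cell for a given representation.

    ``map_kind`` is ``"GD"`` (gradient direction), ``"GM"`` (gradient
    magnitude) or ``"intensity"`` (raw grey values).
    """
    kind = map_kind.upper() if map_kind.lower() != "intensity" else "intensity"
    if kind == "intensity":
        f = np.asarray(cell.pixels, dtype=np.float64)
        mask = np.asarray(cell.mask, dtype=bool)
        fixed = (0.0, 1.0)
        return quantize(f, mask, n_levels, range_policy, fixed, source_kind="intensity")
    grads = compute_gradients(cell, scheme=scheme, convention=convention)
    if kind == "GM":
        fixed = (0.0, float(grads.magnitude[grads.mask].max()) or 1.0)
        return quantize(grads.magnitude, grads.mask, n_levels, range_policy,
                        fixed, source_kind="GM")
    if kind == "GD":
        return quantize(grads.direction, grads.mask, n_levels, range_policy,
                        grads.principal_range, source_kind="GD")
    raise ValueError(f"unknown map_kind {map_kind!r}; use 'GD', 'GM' or 'intensity'")
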