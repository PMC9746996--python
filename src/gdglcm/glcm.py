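"""Grey-level co-occurrence matrices over quantized maps.

A GLCM counts how often a pair of quantized levels ``(i, j)`` occurs at a
fixed pixel displacement (distance ``d`` along one of the four standard
angles).  Counting both the forward and reversed displacement makes the
matrix symmetric.  Because the matrix is N x N regardless of the image
size, variably sized cells all map to a fixed-width classifier input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gradients import MASKED, QuantizedMap, quantized_map_for

log = logging.getLogger(__name__)

ANGLES = (0, 45, 90, 135)
MAX_DISTANCE = 15

#: distances per group: 4, 8 or 15 nested distances x 4 angles -> 16/32/60
GROUP_DISTANCES = {1: range(1, 5), 2: range(1, 9), 3: range(1, 16)}

# row index grows downward; angle -> (row step, col step) per unit distance
_ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class Offset:
    """A (distance, angle) co-occurrence displacement."""

    distance: int
    angle: int

    def __post_init__(self) -> None:
        if not 1 <= self.distance <= MAX_DISTANCE:
            raise ValueError(f"distance must be in 1..{MAX_DISTANCE}, got {self.distance}")
        if self.angle not in ANGLES:
            raise ValueError(f"angle must be one of {ANGLES}, got {self.angle}")

    @property
    def step(self) -> tuple[int, int]:
        dr, dc = _ANGLE_STEPS[self.angle]
        return dr * self.distance, dc * self.distance


@dataclass
class GLCM:
    """Co-occurrence matrix for one (cell, offset) pair."""

    counts: np.ndarray
    n_levels: int
    offset: Offset
    normalized: bool

    @property
    def vector(self) -> np.ndarray:
        """Row-major flattening; reshape to (N, N) recovers the matrix."""
        return self.counts.ravel()


@dataclass
class GLCMStack:
    """All GLCMs of one cell for a given offset group."""

    glcms: list[GLCM]
    group: int
    cell_id: str
    label: str


def offsets_for_group(group: int) -> list[Offset]:
    """The ordered (angle-major, then distance) offset grid of a group.

    Group 1: 4 angles x distances 1..4 = 16 offsets; group 2: x 1..8 = 32;
    group 3: x 1..15 = 60.
    """
    if group not in GROUP_DISTANCES:
        raise ValueError(f"group must be one of {sorted(GROUP_DISTANCES)}, got {group}")
    return [Offset(d, a) for a in ANGLES for d in GROUP_DISTANCES[group]]


def compute_glcm(qmap: QuantizedMap, offset: Offset,
                 symmetric: bool = True, normalize: bool = True) -> GLCM:
    """Count level co-occurrences of ``qmap`` at one displacement.

    Pairs with either endpoint outside the mask (sentinel level) are
    skipped.  With ``symmetric`` (default) the reversed displacement is
    counted too, so ``counts == counts.T``.  ``normalize`` divides by the
    total pair count; an offset admitting no valid pair yields an all-zero
    matrix (with a warning) rather than an error.
    """
    levels = qmap.levels
    n = qmap.n_levels
    dr, dc = offset.step
    h, w = levels.shape

    counts = np.zeros((n, n), dtype=np.float64)
    # overlapping windows: a[r, c] pairs with a[r + dr, c + dc]
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r1 > r0 and c1 > c0:
        src = levels[r0:r1, c0:c1]
        dst = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        valid = (src != MASKED) & (dst != MASKED)
        i = src[valid] - 1
        j = dst[valid] - 1
        np.add.at(counts, (i, j), 1.0)
    if symmetric:
        counts = counts + counts.T

    total = counts.sum()
    if total == 0:
        log.warning("no valid pixel pair for offset %s on a %dx%d map", offset, h, w)
        return GLCM(counts=counts, n_levels=n, offset=offset, normalized=normalize)
    if normalize:
        counts = counts / total
    return GLCM(counts=counts, n_levels=n, offset=offset, normalized=normalize)


def compute_stack(cell, map_kind: str, n_levels: int, group: int,
                  symmetric: bool = True, normalize: bool = True,
                  **conventions) -> GLCMStack:
    """All GLCMs of one cell for a group's offset grid (16/32/60 matrices)."""
    qmap = quantized_map_for(cell, map_kind, n_levels, **conventions)
    glcms = [compute_glcm(qmap, off, symmetric=symmetric, normalize=normalize)
             for off in offsets_for_group(group)]
    return GLCMStack(glcms=glcms, group=group, cell_id=cell.cell_id, label=cell.label)


def build_dataset(cells, map_kind: str, n_levels: int, group: int,
                  symmetric: bool = True, normalize: bool = True,
                  **conventions) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorise every GLCM of every cell into one design matrix.

    Each GLCM is one sample: a row of length ``n_levels**2`` (row-major).
    Returns ``(X, labels, cell_ids)`` with ``len(X) == n_cells * per-group
    GLCM count``; labels are the cells' class strings repeated per sample.
    """
    cells = list(cells)
    if not cells:
        raise ValueError("no cells to featurize")
    n_offsets = len(offsets_for_group(group))
    X = np.empty((len(cells) * n_offsets, n_levels * n_levels), dtype=np.float64)
    labels = np.empty(len(cells) * n_offsets, dtype=object)
    cell_ids = np.empty(len(cells) * n_offsets, dtype=object)
    row = 0
    for cell in cells:
        stack = compute_stack(cell, map_kind, n_levels, group,
                              symmetric=symmetric, normalize=normalize, **conventions)
        for g in stack.glcms:
            X[row] = g.vector
            labels[row] = cell.label
            cell_ids[row] = cell.cell_id
            row += 1
    return X, labels, cell_ids


def dataset_grid() -> list[tuple[int, int]]:
    """The 12 (n_levels, group) dataset configurations per map kind."""
    return [(n, g) for n in (8, 16, 32, 64) for g in sorted(GROUP_DISTANCES)]
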