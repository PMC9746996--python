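"""Ten-feature Haralick reduction of a normalized GLCM (the baseline).

Definitions follow the classical co-occurrence texture statistics with
natural logarithms and levels indexed 1..N: contrast, energy (angular
second moment), entropy, homogeneity (inverse difference moment), variance
(sum of squares about the GLCM mean), plus the sum/difference-marginal
statistics.  ``difference_variance`` is the variance of the |i-j| marginal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glcm import GLCM, offsets_for_group

FEATURE_NAMES = (
    "contrast", "energy", "entropy", "homogeneity", "variance",
    "sum_average", "sum_variance", "sum_entropy",
    "difference_variance", "difference_entropy",
)


@dataclass
class HaralickVector:
    contrast: float
    energy: float
    entropy: float
    homogeneity: float
    variance: float
    sum_average: float
    sum_variance: float
    sum_entropy: float
    difference_variance: float
    difference_entropy: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def haralick_features(glcm: GLCM | np.ndarray) -> HaralickVector:
    """Compute the ten texture statistics from a normalized GLCM."""
    p = glcm.counts if isinstance(glcm, GLCM) else np.asarray(glcm, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1] or p.shape[0] < 2:
        raise ValueError(f"expected a square GLCM of size >= 2, got shape {p.shape}")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero GLCM: no co-occurrence mass to summarise")
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"GLCM must be normalized (sum 1), got sum {total:g}")

    n = p.shape[0]
    idx = np.arange(1, n + 1)
    i = idx[:, None]
    j = idx[None, :]

    contrast = float(((i - j) ** 2 * p).sum())
    energy = float((p ** 2).sum())
    entropy = _entropy(p)
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())
    mu = float((i * p).sum() + (j * p).sum()) / 2.0
    variance = float(((i - mu) ** 2 * p).sum())

    # marginals of i+j (2..2N) and |i-j| (0..N-1)
    p_sum = np.zeros(2 * n - 1)
    p_diff = np.zeros(n)
    np.add.at(p_sum, (i + j - 2).ravel(), p.ravel())
    np.add.at(p_diff, np.abs(i - j).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * n + 1)
    k_diff = np.arange(0, n)

    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _entropy(p_sum)
    diff_mean = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    difference_entropy = _entropy(p_diff)

    return HaralickVector(
        contrast=contrast, energy=energy, entropy=entropy,
        homogeneity=homogeneity, variance=variance,
        sum_average=sum_average, sum_variance=sum_variance,
        sum_entropy=sum_entropy, difference_variance=difference_variance,
        difference_entropy=difference_entropy,
    )


def build_standard_dataset(cells, n_levels: int, group: int,
                           **conventions) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-GLCM 10-feature samples from intensity-quantized maps.

    Mirrors :func:`gdglcm.glcm.build_dataset` but reduces each GLCM to the
    ten Haralick statistics instead of vectorising it.
    """
    from .glcm import compute_stack

    cells = list(cells)
    if not cells:
        raise ValueError("no cells to featurize")
    n_offsets = len(offsets_for_group(group))
    X = np.empty((len(cells) * n_offsets, len(FEATURE_NAMES)), dtype=np.float64)
    labels = np.empty(len(cells) * n_offsets, dtype=object)
    cell_ids = np.empty(len(cells) * n_offsets, dtype=object)
    row = 0
    for cell in cells:
        stack = compute_stack(cell, "intensity", n_levels, group,
                              symmetric=True, normalize=True, **conventions)
        for g in stack.glcms:
            if g.counts.sum() == 0:
                X[row] = 0.0  # degenerate offset on a tiny cell; keep the row
            else:
                X[row] = haralick_features(g).as_array()
            labels[row] = cell.label
            cell_ids[row] = cell.cell_id
            row += 1
    return X, labels, cell_ids
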