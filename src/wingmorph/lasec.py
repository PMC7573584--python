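"""Landmark sampling evaluation curve (LaSEC).

Quantifies how faithfully a random subset of the landmarks reproduces
the shape space of the full landmark set, as the subset grows from 3 to
k.  Within each iteration landmark subsets are nested (grown one
landmark at a time from a random permutation), the subsetted
configurations are re-superimposed, and the fit at each size is the
Pearson correlation between the inter-specimen tangent-space distance
vectors of the subsampled and the full data.  A curve saturating well
below k indicates oversampled landmarks; a curve still climbing at k
indicates the landmark scheme is not redundant.

The fit statistic is this package's documented choice of fidelity
measure; the curve construction (nested subsets, per-size median and
5th/95th percentile envelope over iterations) is standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .gpa import generalized_procrustes, tangent_projection
from .io import LandmarkDataset


@dataclass
class LasecCurve:
    """Per-size fidelity summary of the landmark sampling curve."""
    sizes: np.ndarray
    median_fit: np.ndarray
    p05: np.ndarray
    p95: np.ndarray
    n_iterations: int
    seed: int | None
    n_resampled: int = 0          # degenerate iterations that were redrawn


def _distance_vector(coords) -> np.ndarray:
    aligned = generalized_procrustes(coords)
    return pdist(tangent_projection(aligned))


def lasec_curve(dataset, n_iterations: int = 1000,
                seed: int | None = None) -> LasecCurve:
    """Compute the landmark sampling evaluation curve.

    ``dataset`` is a :class:`~wingmorph.io.LandmarkDataset` or an
    (n, k, 2) array with k >= 4 and at least 3 specimens.  Fit at size
    k is 1 by construction (self-comparison).  Iterations whose random
    3-landmark start yields a degenerate (zero-variance) shape space
    are redrawn and counted in ``n_resampled``.
    """
    coords = dataset.coords if isinstance(dataset, LandmarkDataset) \
        else np.asarray(dataset, dtype=float)
    n, k = coords.shape[0], coords.shape[1]
    if k < 4:
        raise ValueError("LaSEC needs k >= 4 landmarks")
    if n < 3:
        raise ValueError("LaSEC needs at least 3 specimens")
    rng = np.random.default_rng(seed)
    full = _distance_vector(coords)
    full_c = full - full.mean()
    full_norm = np.linalg.norm(full_c)
    if full_norm == 0:
        raise ValueError("no shape variation in the full dataset")

    sizes = np.arange(3, k + 1)
    fits = np.empty((n_iterations, len(sizes)))
    n_resampled = 0
    it = 0
    while it < n_iterations:
        perm = rng.permutation(k)
        row = np.empty(len(sizes))
        ok = True
        for s_idx, s in enumerate(sizes):
            if s == k:
                row[s_idx] = 1.0          # self-comparison by definition
                continue
            sub = _distance_vector(coords[:, perm[:s], :])
            sub_c = sub - sub.mean()
            denom = np.linalg.norm(sub_c) * full_norm
            if denom == 0:
                ok = False
                break
            row[s_idx] = float(sub_c @ full_c) / denom
        if not ok:
            n_resampled += 1
            continue
        fits[it] = row
        it += 1

    return LasecCurve(sizes, np.median(fits, axis=0),
                      np.percentile(fits, 5, axis=0),
                      np.percentile(fits, 95, axis=0),
                      n_iterations, seed, n_resampled)
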