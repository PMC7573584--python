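"""Procrustes superimposition of 2-D landmark configurations.

Shape is what remains of a landmark configuration after translation,
scale and rotation are removed.  Configurations are centred, scaled to
unit centroid size and rotated to a consensus by least squares; the
rotation is restricted to determinant +1 (no reflections — the data are
single-side wings, so chirality is fixed).  The iterative generalized
Procrustes analysis (GPA) alternates aligning every configuration to the
current consensus with re-estimating the consensus until it stabilizes.

The aligned coordinates live on a curved shape manifold; downstream
multivariate statistics operate on the orthogonal projection onto the
linear tangent space at the consensus (`tangent_projection`), which is
accurate when shape variation is small, as it is for congeneric wings.

`GeneralizedProcrustes` exposes the procedure as a scikit-learn style
transformer: `fit` runs GPA on a training sample, `transform` maps raw
configurations (training or new) to tangent shape variables by aligning
them to the fitted consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import LandmarkDataset


class DegenerateConfigurationError(ValueError):
    """Raised when a configuration has zero centroid size."""


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def centroid_size(config) -> float:
    """Square root of the summed squared landmark distances to the centroid.

    A rotation-invariant size measure in the input coordinate units;
    homogeneous of degree one under uniform scaling.
    """
    config = np.asarray(config, dtype=float)
    centred = config - config.mean(axis=0)
    return float(np.sqrt((centred ** 2).sum()))


def _centred(config):
    config = np.asarray(config, dtype=float)
    return config - config.mean(axis=0)


def _rotation_angle(reference, target) -> float:
    """Angle rotating ``target`` onto ``reference`` by least squares.

    Both inputs must be centred.  The closed-form planar solution is
    ``atan2(sum of cross products, sum of dot products)``; the resulting
    rotation always has determinant +1.
    """
    dots = float((reference * target).sum())
    crosses = float((target[:, 0] * reference[:, 1]
                     - target[:, 1] * reference[:, 0]).sum())
    return float(np.arctan2(crosses, dots))


def _rotate(config, angle):
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return config @ rot.T


@dataclass
class PairAlignment:
    """Similarity transform of a target onto a reference, and the residual."""
    aligned: np.ndarray
    angle: float
    scale: float
    distance: float


def align_pair(reference, target, scale: bool = True) -> PairAlignment:
    """Optimally superimpose ``target`` on ``reference``.

    Translation and rotation (determinant +1) are always removed; with
    ``scale`` both configurations are first scaled to unit centroid size
    and the reported distance is the partial Procrustes distance — the
    root summed squared landmark difference between the two unit-size,
    optimally rotated shapes.
    """
    reference = np.asarray(reference, dtype=float)
    target = np.asarray(target, dtype=float)
    if reference.shape != target.shape:
        raise ValueError(
            f"shape mismatch: {reference.shape} vs {target.shape}")
    cs_ref, cs_tgt = centroid_size(reference), centroid_size(target)
    if cs_ref == 0 or cs_tgt == 0:
        raise DegenerateConfigurationError(
            "zero centroid size: all landmarks coincide")
    ref_c, tgt_c = _centred(reference), _centred(target)
    if scale:
        ref_u, tgt_u = ref_c / cs_ref, tgt_c / cs_tgt
        factor = cs_ref / cs_tgt
    else:
        ref_u, tgt_u = ref_c, tgt_c
        factor = 1.0
    angle = _rotation_angle(ref_u, tgt_u)
    rotated = _rotate(tgt_u, angle)
    distance = float(np.linalg.norm(ref_u - rotated))
    aligned = (rotated * cs_ref if scale else rotated) + reference.mean(axis=0)
    return PairAlignment(aligned, angle, factor, distance)


def procrustes_distance(a, b) -> float:
    """Partial Procrustes distance between two configurations."""
    return align_pair(a, b, scale=True).distance


# ---------------------------------------------------------------------------
# generalized Procrustes analysis
# ---------------------------------------------------------------------------

@dataclass
class AlignedDataset:
    """Output of GPA: superimposed coordinates plus size and consensus.

    ``aligned_coords`` have centroid at the origin and unit centroid
    size per specimen; ``centroid_sizes`` keep the original sizes in
    input units.  Metadata travels unchanged from the input dataset.
    """
    aligned_coords: np.ndarray          # (n, k, 2)
    centroid_sizes: np.ndarray          # (n,)
    consensus: np.ndarray               # (k, 2), unit centroid size
    converged: bool
    iterations: int
    meta: "object" = None               # pandas DataFrame or None

    @property
    def n_specimens(self) -> int:
        return self.aligned_coords.shape[0]

    @property
    def k(self) -> int:
        return self.aligned_coords.shape[1]


def _canonical_rotation(consensus):
    """Deterministic orientation for a consensus shape.

    The major principal axis of the landmark scatter is rotated onto the
    x axis; the remaining 180-degree ambiguity is fixed by requiring a
    non-negative third moment along x (falling back to y for shapes that
    are symmetric along x).  Near-isotropic shapes keep a stable but
    arbitrary orientation.
    """
    _, _, vt = np.linalg.svd(consensus, full_matrices=False)
    angle = -np.arctan2(vt[0, 1], vt[0, 0])
    rotated = _rotate(consensus, angle)
    m3x = float((rotated[:, 0] ** 3).sum())
    m3y = float((rotated[:, 1] ** 3).sum())
    if m3x < -1e-12 or (abs(m3x) <= 1e-12 and m3y < -1e-12):
        angle += np.pi
    return angle


def generalized_procrustes(dataset, tol: float = 1e-8,
                           max_iter: int = 100) -> AlignedDataset:
    """Iterative least-squares superimposition of a landmark sample.

    Every configuration is centred and scaled to unit centroid size,
    then repeatedly rotated to the running consensus; the consensus is
    the rescaled mean of the aligned configurations.  Iteration stops
    when the consensus moves by less than ``tol`` (root summed squared
    coordinate change) or after ``max_iter`` rounds, in which case the
    result carries ``converged=False`` and a warning is emitted.

    The final solution is rotated to a canonical orientation (principal
    axis along x) so that the output is invariant — not merely up to
    rotation — under similarity transforms of any input configuration.

    Accepts a :class:`~wingmorph.io.LandmarkDataset` or a raw
    ``(n, k, 2)`` array.
    """
    if isinstance(dataset, LandmarkDataset):
        coords, meta = dataset.coords, dataset.meta
    else:
        coords, meta = np.asarray(dataset, dtype=float), None
    n = coords.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least two configurations")
    centred = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centred ** 2).sum(axis=(1, 2)))
    if np.any(sizes <= 1e-12 * sizes.max()):
        bad = int(np.argmin(sizes))
        name = meta.at[bad, "specimen_id"] if meta is not None else str(bad)
        raise DegenerateConfigurationError(
            f"specimen {name} has zero centroid size")
    unit = centred / sizes[:, None, None]

    consensus = unit[0].copy()
    converged = False
    iterations = 0
    x, y = unit[:, :, 0], unit[:, :, 1]
    for iterations in range(1, max_iter + 1):
        # closed-form rotation of every pristine unit configuration onto
        # the current consensus
        dots = (unit * consensus).sum(axis=(1, 2))
        crosses = (unit[:, :, 0] * consensus[:, 1]
                   - unit[:, :, 1] * consensus[:, 0]).sum(axis=1)
        angles = np.arctan2(crosses, dots)
        cos, sin = np.cos(angles), np.sin(angles)
        aligned = np.stack([cos[:, None] * x - sin[:, None] * y,
                            sin[:, None] * x + cos[:, None] * y], axis=2)
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt((new_consensus ** 2).sum())
        delta = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    else:  # pragma: no cover - loop exhausts only on hard datasets
        pass
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations", RuntimeWarning)

    # canonical orientation, then one exact final alignment pass
    consensus = _rotate(consensus, _canonical_rotation(consensus))
    dots = (unit * consensus).sum(axis=(1, 2))
    crosses = (unit[:, :, 0] * consensus[:, 1]
               - unit[:, :, 1] * consensus[:, 0]).sum(axis=1)
    angles = np.arctan2(crosses, dots)
    cos, sin = np.cos(angles), np.sin(angles)
    x, y = unit[:, :, 0], unit[:, :, 1]
    aligned = np.stack([cos[:, None] * x - sin[:, None] * y,
                        sin[:, None] * x + cos[:, None] * y], axis=2)
    # numerically exact centring and unit size per specimen
    aligned -= aligned.mean(axis=1, keepdims=True)
    aligned /= np.sqrt((aligned ** 2).sum(axis=(1, 2)))[:, None, None]

    return AlignedDataset(aligned, sizes, consensus, converged,
                          iterations, meta)


def tangent_projection(aligned: AlignedDataset) -> np.ndarray:
    """Orthogonal projection of aligned shapes onto the tangent space.

    Returns the (n, 2k) shape-variable matrix, column order
    x1, y1, ..., xk, yk.  The tangent space is the hyperplane through
    the consensus orthogonal to it; the projection leaves the consensus
    fixed and never increases distances to it.
    """
    c = aligned.consensus.reshape(-1)
    c = c / np.linalg.norm(c)
    rows = aligned.aligned_coords.reshape(aligned.n_specimens, -1)
    return rows + (1.0 - rows @ c)[:, None] * c


def mean_shape(aligned: AlignedDataset, selector=None) -> np.ndarray:
    """Mean of selected aligned configurations, rescaled to unit size.

    ``selector`` is a boolean mask or integer index over specimens;
    ``None`` averages everything (reproducing the GPA consensus).  Used
    for genus/species overlay plots of mean landmark configurations.
    """
    coords = aligned.aligned_coords
    if selector is not None:
        selector = np.asarray(selector)
        if selector.dtype == bool:
            selector = np.flatnonzero(selector)
        if len(selector) == 0:
            raise ValueError("empty specimen selection")
        coords = coords[selector]
    mean = coords.mean(axis=0)
    mean -= mean.mean(axis=0)
    norm = np.sqrt((mean ** 2).sum())
    if norm == 0:
        raise DegenerateConfigurationError("mean shape degenerate")
    return mean / norm


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------

class GeneralizedProcrustes(BaseEstimator, TransformerMixin):
    """GPA as a transformer from raw landmarks to tangent shape variables.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the consensus update.
    max_iter : int
        Iteration cap for the superimposition.
    project : bool
        If True (default) ``transform`` returns tangent-projected shape
        variables; if False, raw superimposed (Procrustes) coordinates.

    Attributes
    ----------
    consensus_ : ndarray of shape (k, 2)
        Unit-size mean shape of the training sample.
    centroid_sizes_ : ndarray of shape (n_samples,)
        Original centroid sizes of the training configurations.
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100,
                 project: bool = True):
        self.tol = tol
        self.max_iter = max_iter
        self.project = project

    @staticmethod
    def _as_coords(X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X.reshape(X.shape[0], -1, 2)
        if X.ndim != 3 or X.shape[2] != 2:
            raise ValueError("X must be (n, k, 2) or (n, 2k)")
        return X

    def fit(self, X, y=None):
        if isinstance(X, LandmarkDataset):
            coords = X.coords
        else:
            coords = self._as_coords(X)
        result = generalized_procrustes(coords, tol=self.tol,
                                        max_iter=self.max_iter)
        self.consensus_ = result.consensus
        self.centroid_sizes_ = result.centroid_sizes
        self.converged_ = result.converged
        self.n_iter_ = result.iterations
        return self

    def transform(self, X):
        """Align configurations to the fitted consensus and project."""
        if not hasattr(self, "consensus_"):
            raise ValueError("GeneralizedProcrustes instance is not fitted")
        if isinstance(X, LandmarkDataset):
            coords = X.coords
        else:
            coords = self._as_coords(X)
        centred = coords - coords.mean(axis=1, keepdims=True)
        sizes = np.sqrt((centred ** 2).sum(axis=(1, 2)))
        if np.any(sizes <= 0):
            raise DegenerateConfigurationError("zero centroid size in X")
        unit = centred / sizes[:, None, None]
        dots = (unit * self.consensus_).sum(axis=(1, 2))
        crosses = (unit[:, :, 0] * self.consensus_[:, 1]
                   - unit[:, :, 1] * self.consensus_[:, 0]).sum(axis=1)
        angles = np.arctan2(crosses, dots)
        cos, sin = np.cos(angles), np.sin(angles)
        x, y = unit[:, :, 0], unit[:, :, 1]
        aligned = np.stack([cos[:, None] * x - sin[:, None] * y,
                            sin[:, None] * x + cos[:, None] * y], axis=2)
        rows = aligned.reshape(aligned.shape[0], -1)
        if not self.project:
            return rows
        c = self.consensus_.reshape(-1)
        c = c / np.linalg.norm(c)
        return rows + (1.0 - rows @ c)[:, None] * c
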