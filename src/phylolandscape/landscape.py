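"""Metric MDS (principal coordinate analysis) of a tree-distance matrix.

PCoA double-centres the squared-distance matrix (Gower centring),
eigendecomposes it, and scales eigenvectors by the square roots of their
positive eigenvalues, yielding coordinates whose Euclidean distances best
approximate the input distances. Distances produced as norms of vector
differences (Kendall-Colijn and the other vector metrics) are Euclidean by
construction, so their centred matrix is positive semi-definite and no
correction is needed. Robinson-Foulds distances generally are not
Euclidean; for those the Cailliez correction adds the smallest constant c
to every off-diagonal entry that makes the matrix Euclidean, obtained as
the largest eigenvalue of the standard 2n x 2n companion matrix

    [[ 0,   2 * D1 ],
     [ -I,  -4 * D2 ]]

with D1 the Gower-centred -D^2/2 and D2 the Gower-centred -D/2.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix
from .trees import PreconditionError

__all__ = [
    "LandscapeEmbedding",
    "pcoa",
    "cailliez",
    "scree",
    "is_euclidean",
    "PCoA",
]

#: relative tolerance below which a negative centred eigenvalue triggers
#: (and the Cailliez correction must clear) non-Euclidean treatment
NEG_EIG_RTOL = 1e-8
#: absolute magnitude under which an eigenvalue is treated as exactly 0
ZERO_EIG_TOL = 1e-10


@dataclass
class LandscapeEmbedding:
    """MDS coordinates, eigenvalue spectrum and Cailliez bookkeeping."""

    coordinates: np.ndarray  # (n_trees, n_axes_retained)
    eigenvalues: np.ndarray  # full spectrum, descending
    n_axes_retained: int
    cailliez_constant: float
    metric: str
    tree_names: list[str] | None = None


def _as_array(dm) -> np.ndarray:
    if isinstance(dm, DistanceMatrix):
        return dm.values
    return np.asarray(dm, dtype=float)


def _gower_centre(A: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = J @ A @ J
    return (B + B.T) / 2.0


def _centred_eigvals(D: np.ndarray) -> np.ndarray:
    return np.linalg.eigvalsh(_gower_centre(-0.5 * D * D))


def is_euclidean(dm, rtol: float = NEG_EIG_RTOL) -> bool:
    """True iff the Gower-centred matrix has no meaningfully negative
    eigenvalue (below ``-rtol * largest eigenvalue``)."""
    w = _centred_eigvals(_as_array(dm))
    wmax = max(w.max(), 0.0)
    if wmax == 0.0:
        return w.min() >= -ZERO_EIG_TOL
    return w.min() >= -rtol * wmax


def _cailliez_constant(D: np.ndarray) -> float:
    n = D.shape[0]
    d1 = _gower_centre(-0.5 * D * D)
    d2 = _gower_centre(-0.5 * D)
    comp = np.block([
        [np.zeros((n, n)), 2.0 * d1],
        [-np.eye(n), -4.0 * d2],
    ])
    ev = np.linalg.eigvals(comp)
    return float(max(ev.real.max(), 0.0))


def cailliez(dm):
    """Smallest additive constant rendering a dissimilarity Euclidean.

    Returns ``(corrected, c)`` where ``corrected`` has ``D[i, j] + c`` on
    every off-diagonal entry. When the input is already Euclidean (no
    centred eigenvalue below ``-1e-8 * max``), c = 0 and the matrix is
    returned unchanged.

    Accepts and returns either a :class:`DistanceMatrix` (metadata kept)
    or a plain square array.
    """
    D = _as_array(dm)
    if is_euclidean(D):
        return dm, 0.0
    c = _cailliez_constant(D)
    corrected = D + c
    np.fill_diagonal(corrected, 0.0)
    if isinstance(dm, DistanceMatrix):
        out = DistanceMatrix(corrected, dm.tree_names, dm.metric, dm.lam)
    else:
        out = corrected
    return out, c


def pcoa(dm, n_axes: int = 3, correction: str = "auto") -> LandscapeEmbedding:
    """Principal coordinate analysis of a tree-distance matrix.

    Parameters
    ----------
    dm : DistanceMatrix or square ndarray
    n_axes : int
        Number of axes requested; must satisfy ``1 <= n_axes <= n - 1``.
        If fewer positive eigenvalues exist, the retained axes are
        truncated with a warning (not an error).
    correction : {"auto", "none"}
        "auto" applies the Cailliez correction iff the most negative
        centred eigenvalue is below ``-1e-8 *`` the largest one.

    Returns
    -------
    LandscapeEmbedding
        Coordinates ordered by descending eigenvalue. Axis signs are fixed
        by forcing the largest-magnitude loading on each axis to be
        positive, so repeated runs are byte-identical.
    """
    D = _as_array(dm)
    n = D.shape[0]
    if n < 2:
        raise PreconditionError("PCoA needs at least 2 trees")
    if not 1 <= n_axes <= n - 1:
        raise PreconditionError(
            f"n_axes must be in [1, {n - 1}] for {n} trees, got {n_axes}"
        )
    if correction not in ("auto", "none"):
        raise ValueError(f"unknown correction policy {correction!r}")
    c = 0.0
    if correction == "auto" and not is_euclidean(D):
        corrected, c = cailliez(D)
        D = corrected
    B = _gower_centre(-0.5 * D * D)
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    w[np.abs(w) < ZERO_EIG_TOL] = 0.0
    n_pos = int(np.sum(w > 0))
    r = min(n_axes, n_pos)
    if r < n_axes:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; retaining {r} axes "
            f"instead of the requested {n_axes}",
            stacklevel=2,
        )
    coords = V[:, :r] * np.sqrt(w[:r])
    for k in range(r):  # deterministic axis orientation
        col = coords[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    names = dm.tree_names if isinstance(dm, DistanceMatrix) else None
    metric = dm.metric if isinstance(dm, DistanceMatrix) else "precomputed"
    return LandscapeEmbedding(coords, w, r, c, metric, names)


def scree(emb: LandscapeEmbedding) -> np.ndarray:
    """Eigenvalue proportions relative to the sum of positive eigenvalues,
    descending; sums to 1 (empty for a degenerate all-zero spectrum)."""
    pos = emb.eigenvalues[emb.eigenvalues > 0]
    if pos.size == 0:
        return pos
    return pos / pos.sum()


class PCoA:
    """Sklearn-style PCoA estimator over a precomputed tree-distance matrix.

    Parameters
    ----------
    n_axes : int, default 3
    correction : {"auto", "none"}, default "auto"

    Attributes (after :meth:`fit`)
    ------------------------------
    embedding_ : LandscapeEmbedding
    coordinates_ : ndarray (n_trees, n_axes_retained)
    eigenvalues_ : ndarray, descending
    cailliez_constant_ : float
    """

    def __init__(self, n_axes: int = 3, correction: str = "auto"):
        self.n_axes = n_axes
        self.correction = correction

    def get_params(self, deep: bool = True) -> dict:
        return {"n_axes": self.n_axes, "correction": self.correction}

    def set_params(self, **params) -> "PCoA":
        for k, v in params.items():
            if k not in ("n_axes", "correction"):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "PCoA":
        emb = pcoa(X, n_axes=self.n_axes, correction=self.correction)
        self.embedding_ = emb
        self.coordinates_ = emb.coordinates
        self.eigenvalues_ = emb.eigenvalues
        self.cailliez_constant_ = emb.cailliez_constant
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self.coordinates_
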