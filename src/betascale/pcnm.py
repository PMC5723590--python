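"""Spatial eigenfunctions: PCNM (principal coordinates of neighbour matrices).

Classical construction: truncate the inter-site Euclidean distance matrix at
a threshold t (default: the longest edge of the minimum spanning tree, which
keeps the site graph connected), replace the truncated distances by 4t,
Gower-center -1/2 * D*^2 and eigendecompose. Eigenvectors with positive
eigenvalue and Moran's I above its null expectation -1/(n-1) form the
spatial predictor basis, ordered from broadest to finest spatial scale.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .io import ValidationError


@dataclass
class MEMBasis:
    """Retained spatial eigenvectors with their eigenvalues and Moran's I."""

    vectors: np.ndarray        # n x m, unit-norm, centered columns
    eigenvalues: np.ndarray    # descending, length m
    morans_i: np.ndarray       # length m
    truncation: float
    n: int
    positive_eigenvalues: np.ndarray  # all eigenvalues above tolerance, pre-screen

    @property
    def m(self) -> int:
        return self.vectors.shape[1]


def mst_longest_edge(coords: np.ndarray) -> float:
    """Longest edge of the Euclidean minimum spanning tree of the points."""
    D = squareform(pdist(np.asarray(coords, float)))
    T = minimum_spanning_tree(D)
    return float(T.toarray().max())


def connectivity_from_truncation(coords: np.ndarray, t: float) -> np.ndarray:
    """Binary neighbour weights: w_ih = 1 iff 0 < d_ih <= t."""
    if t <= 0:
        raise ValueError("truncation distance must be positive")
    D = squareform(pdist(np.asarray(coords, float)))
    W = ((D > 0) & (D <= t + 1e-12)).astype(float)
    if W.sum() == 0:
        raise ValidationError(
            f"truncation {t} is below the minimum inter-point distance; empty graph"
        )
    return W


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I = (n/W) * (sum_ih w_ih z_i z_h) / (sum_i z_i^2), z centered."""
    z = np.asarray(values, float)
    if z.ndim != 1 or len(z) < 2:
        raise ValidationError("Moran's I needs a vector of at least two values")
    W = np.asarray(weights, float)
    if W.shape != (len(z), len(z)):
        raise ValidationError("weight matrix shape does not match values")
    z = z - z.mean()
    denom = (z**2).sum()
    if denom <= 0:
        raise ValidationError("Moran's I undefined for zero-variance values")
    wsum = W.sum()
    if wsum <= 0:
        raise ValidationError("weight total must be positive")
    return float(len(z) / wsum * (z @ W @ z) / denom)


def pcnm(coords: np.ndarray, truncation: float | None = None) -> MEMBasis:
    """PCNM spatial eigenvector basis for a set of site coordinates.

    Retains eigenvectors with eigenvalue > 1e-8 * max eigenvalue whose
    Moran's I (binary weights within the truncation distance) exceeds the
    null expectation -1/(n-1). Columns are unit norm with the sign fixed so
    the largest-magnitude loading is positive.
    """
    P = np.asarray(coords, float)
    if P.ndim != 2 or P.shape[0] < 3:
        raise ValidationError("PCNM requires at least 3 site coordinates")
    n = P.shape[0]
    D = squareform(pdist(P))
    offdiag = D[~np.eye(n, dtype=bool)]
    if (offdiag < 1e-12).any():
        raise ValidationError("duplicate site coordinates")
    t = float(truncation) if truncation is not None else mst_longest_edge(P)
    if t <= 0:
        raise ValueError("truncation distance must be positive")
    Dstar = np.where(D > t + 1e-12, 4.0 * t, D)
    np.fill_diagonal(Dstar, 0.0)
    A = -0.5 * Dstar**2
    # Gower centering
    A = A - A.mean(axis=0, keepdims=True) - A.mean(axis=1, keepdims=True) + A.mean()
    lam, V = np.linalg.eigh((A + A.T) / 2.0)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    lam_max = lam[0]
    if lam_max <= 0:
        raise ValidationError("no positive eigenvalue; PCNM basis empty")
    pos = lam > 1e-8 * lam_max
    lam_pos, V_pos = lam[pos], V[:, pos]
    # unit norm (eigh already returns unit vectors) and reproducible sign
    for j in range(V_pos.shape[1]):
        V_pos[:, j] /= np.linalg.norm(V_pos[:, j])
        k = np.argmax(np.abs(V_pos[:, j]))
        if V_pos[k, j] < 0:
            V_pos[:, j] = -V_pos[:, j]
    Wn = connectivity_from_truncation(P, t)
    moran = np.array([morans_i(V_pos[:, j], Wn) for j in range(V_pos.shape[1])])
    keep = moran > -1.0 / (n - 1)
    if not keep.any():
        raise ValidationError(
            f"no eigenvector passed the Moran screen (n={n}, t={t:.3g}); "
            "check the site configuration"
        )
    return MEMBasis(
        vectors=V_pos[:, keep],
        eigenvalues=lam_pos[keep],
        morans_i=moran[keep],
        truncation=t,
        n=n,
        positive_eigenvalues=lam_pos,
    )
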