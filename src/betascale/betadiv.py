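"""Beta diversity as total community variance, with local contributions.

The community table X (grains x species) is Hellinger-transformed,

    y_ij = sqrt( x_ij / sum_k x_ik ),

and beta diversity is the unbiased total variance of Y,

    BD_Total = SS_Total / (n - 1),

where SS_Total = sum_ij (y_ij - ybar_j)^2. The same quantity equals
(1/n) * sum_{i<h} D^2_ih over pairwise Euclidean distances between rows of
Y; both forms are implemented and agree to machine precision. Each grain's
share LCBD_i = SS_i / SS_Total measures its compositional uniqueness; the
shares sum to one. On Hellinger data BD_Total lies in [0, 1].
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .io import ValidationError


@dataclass
class BetaDiversityResult:
    """Total variance of a (transformed) community table and per-grain shares."""

    ss_total: float
    bd_total: float
    ss_i: np.ndarray
    lcbd: np.ndarray
    grain_ids: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"grain": self.grain_ids, "ss_i": self.ss_i, "lcbd": self.lcbd}
        )


def _as_array(X) -> np.ndarray:
    A = X.to_numpy(dtype=float) if hasattr(X, "to_numpy") else np.asarray(X, dtype=float)
    if A.ndim != 2:
        raise ValidationError("community table must be 2-dimensional")
    return A


def hellinger_transform(X, on_empty: str = "drop"):
    """Row-wise square root of relative abundances.

    Rows with zero total abundance have no defined transform; by default they
    are dropped with a warning (``on_empty='drop'``); ``'error'`` raises and
    ``'keep'`` retains them as zero rows.

    Returns an object of the same kind as the input (DataFrame in,
    DataFrame out, preserving the index of retained rows).
    """
    A = _as_array(X)
    if (A < 0).any():
        raise ValidationError("negative abundance in community table")
    rowsum = A.sum(axis=1)
    empty = rowsum == 0
    if empty.any():
        if on_empty == "error":
            raise ValidationError(
                f"{int(empty.sum())} grain(s) contain no stems; Hellinger transform undefined"
            )
        if on_empty == "drop":
            warnings.warn(
                f"dropping {int(empty.sum())} empty grain(s) before the Hellinger transform",
                stacklevel=2,
            )
            if isinstance(X, pd.DataFrame):
                X = X.loc[~empty]
            A = A[~empty]
            rowsum = rowsum[~empty]
        elif on_empty != "keep":
            raise ValueError(f"unknown on_empty policy {on_empty!r}")
    safe = np.where(rowsum > 0, rowsum, 1.0)
    Y = np.sqrt(A / safe[:, None])
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(Y, index=X.index, columns=X.columns)
    return Y


def total_sum_of_squares(Y, method: str = "centered") -> float:
    """SS_Total of a (transformed) community table.

    ``centered`` sums squared deviations from column means; ``pairwise``
    uses the identity SS_Total = (1/n) * sum_{i<h} D^2_ih on Euclidean row
    distances. The two agree to floating-point accuracy.
    """
    A = _as_array(Y)
    n = A.shape[0]
    if n < 2:
        raise ValidationError("SS_Total requires at least two grains")
    if method == "centered":
        dev = A - A.mean(axis=0)
        return float((dev**2).sum())
    if method == "pairwise":
        return float((pdist(A) ** 2).sum() / n)
    raise ValueError(f"unknown method {method!r}")


def bd_total(Y) -> float:
    """Beta diversity: SS_Total / (n - 1), in [0, 1] for Hellinger data."""
    A = _as_array(Y)
    return total_sum_of_squares(A) / (A.shape[0] - 1)


def lcbd(Y) -> np.ndarray:
    """Local contributions to beta diversity, LCBD_i = SS_i / SS_Total."""
    A = _as_array(Y)
    if A.shape[0] < 2:
        raise ValidationError("LCBD requires at least two grains")
    dev = A - A.mean(axis=0)
    ss_i = (dev**2).sum(axis=1)
    ss_total = ss_i.sum()
    if ss_total <= 0:
        raise ValidationError(
            "SS_Total is zero (all grains have identical composition); LCBD undefined"
        )
    return ss_i / ss_total


def beta_diversity(X, transform: bool = True, on_empty: str = "drop") -> BetaDiversityResult:
    """Full beta-diversity summary of a community table.

    ``transform=True`` applies the Hellinger transformation first; pass
    ``transform=False`` for a table that is already transformed.
    """
    if transform:
        Y = hellinger_transform(X, on_empty=on_empty)
    else:
        Y = X
    A = _as_array(Y)
    ids = (
        Y.index.to_numpy()
        if isinstance(Y, pd.DataFrame)
        else np.arange(A.shape[0])
    )
    dev = A - A.mean(axis=0)
    ss_i = (dev**2).sum(axis=1)
    ss_total = float(ss_i.sum())
    if ss_total <= 0:
        raise ValidationError("SS_Total is zero; beta diversity degenerate")
    return BetaDiversityResult(
        ss_total=ss_total,
        bd_total=ss_total / (A.shape[0] - 1),
        ss_i=ss_i,
        lcbd=ss_i / ss_total,
        grain_ids=np.asarray(ids),
    )
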