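"""Eigenvector alignment (EA) of channels.

Channels are embedded in a Euclidean space spanned by a selection of the
connectivity matrix's dominant eigenvectors; channel i's position vector is
(v_2[i], v_3[i], v_4[i]) by default.  The alignment angle between channels i
and j is

    theta_ij = arccos( r_i . r_j / (|r_i| |r_j|) )   [degrees],

small when the two channels share a similar pattern of connectivity to the
rest of the network — regardless of their direct weight.  The leading
(Perron-Frobenius) eigenvector of a nonnegative matrix has entries of a
single sign and cannot express network division, so ranks start at 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .connectivity import ConnectivityMatrix
from .epochs import _label_indices

__all__ = [
    "Embedding",
    "AlignmentMatrix",
    "embed",
    "alignment_angles",
    "eigenvector_alignment",
    "EigenvectorAlignment",
]

#: rows with Euclidean norm below this (relative to the largest row norm)
#: have an undefined direction and produce NaN angles
_NORM_EPS = 1e-12


@dataclass
class Embedding:
    """Channel coordinates in the selected-eigenvector space."""

    coords: np.ndarray  # (n_channels, k)
    eig_indices: tuple[int, ...]  # 1-based ranks, e.g. (2, 3, 4)
    eigenvalues: np.ndarray  # (k,)
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] < 2:
            raise ValueError("embedding needs at least two coordinate axes")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")


@dataclass
class AlignmentMatrix:
    """Pairwise alignment angles in degrees; NaN marks undefined pairs."""

    theta: np.ndarray  # (n, n), degrees
    eig_indices: tuple[int, ...]
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        n = self.theta.shape[0]
        if self.theta.ndim != 2 or self.theta.shape[1] != n:
            raise ValueError("alignment matrix must be square")
        if not self.channel_labels:
            self.channel_labels = [f"CH{i + 1:03d}" for i in range(n)]
        defined = ~np.isnan(self.theta)
        vals = self.theta[defined]
        if vals.size and (vals.min() < -1e-9 or vals.max() > 180 + 1e-9):
            raise ValueError("alignment angles must lie in [0, 180] degrees")

    @property
    def n_channels(self) -> int:
        return self.theta.shape[0]

    def pair_values(self) -> np.ndarray:
        """Upper-triangle angles in row-major (i<j) order; NaN = undefined."""
        iu = np.triu_indices(self.n_channels, k=1)
        return self.theta[iu]

    def subset(self, keep: list[str]) -> "AlignmentMatrix":
        idx = _label_indices(self.channel_labels, keep)
        return AlignmentMatrix(self.theta[np.ix_(idx, idx)], self.eig_indices, list(keep))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.theta, index=self.channel_labels, columns=self.channel_labels).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path, eig_indices=(2, 3, 4)) -> "AlignmentMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), tuple(eig_indices), [str(c) for c in df.columns])


def _canonical_eigh(W: np.ndarray, order: str) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition with deterministic ordering and sign convention.

    Eigenvalues are sorted descending by algebraic value (or by magnitude).
    Each eigenvector's sign is fixed so its first component of significant
    magnitude is positive; within numerically degenerate eigenvalue groups
    the (orthonormal) basis columns are additionally ordered lexicographically
    by their rounded loadings so ties break reproducibly.
    """
    vals, vecs = np.linalg.eigh(W)
    if order == "algebraic":
        idx = np.argsort(-vals, kind="stable")
    elif order == "magnitude":
        idx = np.argsort(-np.abs(vals), kind="stable")
    else:
        raise ValueError(f"order must be 'algebraic' or 'magnitude', got {order!r}")
    vals, vecs = vals[idx], vecs[:, idx]
    scale = max(1.0, np.abs(vals).max())
    for j in range(vecs.shape[1]):
        col = vecs[:, j]
        sig = np.flatnonzero(np.abs(col) > 1e-9)
        if sig.size and col[sig[0]] < 0:
            vecs[:, j] = -col
    # reorder within degenerate groups for reproducible tie-breaking
    tol = 1e-9 * scale
    j = 0
    while j < vals.size:
        k = j + 1
        while k < vals.size and abs(vals[k] - vals[j]) <= tol:
            k += 1
        if k - j > 1:
            block = vecs[:, j:k]
            keys = [tuple(np.round(block[:, c], 9)) for c in range(k - j)]
            vecs[:, j:k] = block[:, sorted(range(k - j), key=lambda c: keys[c])]
        j = k
    return vals, vecs


def embed(W, eig_indices=(2, 3, 4), order: str = "algebraic") -> Embedding:
    """Embed channels using the eigenvectors at 1-based ranks ``eig_indices``.

    ``W`` is a :class:`ConnectivityMatrix` or a symmetric array.  Rank 1 is
    the dominant (for nonnegative W, Perron-Frobenius) eigenvector and is
    excluded by the default ranks (2, 3, 4).
    """
    if isinstance(W, ConnectivityMatrix):
        labels, A = list(W.channel_labels), W.W
    else:
        A = np.asarray(W, dtype=float)
        labels = [f"CH{i + 1:03d}" for i in range(A.shape[0])]
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if not np.all(np.isfinite(A)):
        raise ValueError("connectivity matrix must be finite")
    if not np.allclose(A, A.T, atol=1e-9):
        raise ValueError("connectivity matrix must be symmetric")
    eig_indices = tuple(int(r) for r in eig_indices)
    if len(eig_indices) < 2:
        raise ValueError("need at least two eigenvector ranks")
    if min(eig_indices) < 1:
        raise ValueError("eigenvector ranks are 1-based and must be >= 1")
    if max(eig_indices) > A.shape[0]:
        raise ValueError(
            f"rank {max(eig_indices)} exceeds matrix dimension {A.shape[0]}"
        )
    vals, vecs = _canonical_eigh(0.5 * (A + A.T), order)
    sel = [r - 1 for r in eig_indices]
    return Embedding(vecs[:, sel], eig_indices, vals[sel], labels)


def alignment_angles(emb: Embedding) -> AlignmentMatrix:
    """Pairwise angles between channel position vectors, in degrees.

    The cosine is clamped to [-1, 1] before arccos.  Rows with (near) zero
    norm have no direction; their pairs are NaN.  If every row is degenerate
    the embedding is unusable and an error is raised.
    """
    norms = np.linalg.norm(emb.coords, axis=1)
    defined = norms > _NORM_EPS * max(1.0, norms.max())
    if not np.any(defined):
        raise ValueError("all embedding rows have zero norm; alignment undefined everywhere")
    unit = np.zeros_like(emb.coords)
    unit[defined] = emb.coords[defined] / norms[defined, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    theta = np.degrees(np.arccos(cos))
    theta[~defined, :] = np.nan
    theta[:, ~defined] = np.nan
    theta = 0.5 * (theta + theta.T)
    np.fill_diagonal(theta, np.where(defined, 0.0, np.nan))
    return AlignmentMatrix(theta, emb.eig_indices, list(emb.channel_labels))


def eigenvector_alignment(W, eig_indices=(2, 3, 4), order: str = "algebraic") -> AlignmentMatrix:
    """Compose :func:`embed` and :func:`alignment_angles`."""
    return alignment_angles(embed(W, eig_indices, order))


class EigenvectorAlignment(TransformerMixin, BaseEstimator):
    """Transform connectivity matrices into alignment-angle matrices.

    Parameters
    ----------
    eig_indices : tuple of int
        1-based eigenvector ranks spanning the embedding space; (2, 3, 4)
        skips the Perron-Frobenius eigenvector.
    order : {"algebraic", "magnitude"}
        Eigenvalue ordering used to define ranks.  Algebraic ordering is the
        natural choice for nonnegative matrices, where the top eigenvalue is
        the Perron root.

    ``transform`` accepts a ConnectivityMatrix (or symmetric array), a dict
    of them, or a list, and returns the matching structure of
    :class:`AlignmentMatrix`.
    """

    def __init__(self, eig_indices=(2, 3, 4), order: str = "algebraic"):
        self.eig_indices = eig_indices
        self.order = order

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        if isinstance(X, dict):
            return {k: eigenvector_alignment(v, self.eig_indices, self.order) for k, v in X.items()}
        if isinstance(X, (list, tuple)):
            return [eigenvector_alignment(v, self.eig_indices, self.order) for v in X]
        return eigenvector_alignment(X, self.eig_indices, self.order)
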