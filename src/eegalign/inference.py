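"""Null-model significance testing of alignments and connectivities.

Randomised null models are built by permuting the off-diagonal entries of a
subject's connectivity matrix, preserving the exact multiset of connectivity
values while destroying their arrangement.  A large ensemble (1000 by
default) of such matrices — cycling round-robin through the group's subjects
so every subject's value distribution is represented — yields, for each
channel pair, a reference distribution of alignment angles (or connectivity
weights).  The group's per-subject values are compared against the null
distribution pair-by-pair with Welch's unequal-variance t-test; two-sided
p-values are converted to Benjamini-Hochberg q-values within the family of
all testable pairs, and pairs with q below threshold are labelled
"increased" (subject angles smaller than null: closer alignment) or
"decreased" (larger).  A significant pair is "consistent" when it recurs
with the same direction in at least 3 of the 4 canonical bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .alignment import AlignmentMatrix, eigenvector_alignment
from .connectivity import ConnectivityMatrix

__all__ = [
    "NullEnsemble",
    "SignificanceMap",
    "ConsistencySet",
    "randomize_connectivity",
    "build_null_ensemble",
    "pairwise_welch_test",
    "bh_fdr",
    "consistency_filter",
    "expand_cohort",
    "NullModelTest",
]


def randomize_connectivity(W: ConnectivityMatrix, seed) -> ConnectivityMatrix:
    """Permute the off-diagonal entries of ``W`` uniformly at random.

    The upper-triangle values are shuffled and mirrored, so the output is
    symmetric, keeps a zero diagonal, and has exactly the same multiset of
    connectivity values as the input.  ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = W.n_channels
    iu = np.triu_indices(n, k=1)
    vals = rng.permutation(W.W[iu])
    R = np.zeros_like(W.W)
    R[iu] = vals
    R += R.T
    return ConnectivityMatrix(R, W.measure, W.band, list(W.channel_labels), dict(W.meta))


@dataclass
class NullEnsemble:
    """Randomised matrices (and their alignments) with provenance."""

    matrices: list[ConnectivityMatrix]
    alignments: list[AlignmentMatrix]
    n_null: int
    seed: int
    provenance: np.ndarray  # source subject index per null
    eig_indices: tuple[int, ...] = (2, 3, 4)

    def theta_stack(self) -> np.ndarray:
        """Null alignment angles as an (n_null, n_pairs) array."""
        return np.stack([a.pair_values() for a in self.alignments])

    def weight_stack(self) -> np.ndarray:
        """Null connectivity weights as an (n_null, n_pairs) array."""
        return np.stack([m.pair_values() for m in self.matrices])


def build_null_ensemble(
    group: list[ConnectivityMatrix],
    n_null: int = 1000,
    eig_indices=(2, 3, 4),
    seed: int = 0,
    order: str = "algebraic",
) -> NullEnsemble:
    """Build ``n_null`` randomised matrices cycling round-robin over ``group``.

    Each null is a value-preserving permutation of one subject's matrix; the
    subject of null i is ``group[i % len(group)]``, so provenance counts
    differ by at most one across subjects.  Eigenvector alignment is computed
    for every null with the same eigenvector ranks used for the subjects.
    """
    if not group:
        raise ValueError("group of subject matrices must be nonempty")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(seed)
    matrices, alignments = [], []
    provenance = np.arange(n_null) % len(group)
    for i in range(n_null):
        R = randomize_connectivity(group[provenance[i]], rng)
        matrices.append(R)
        alignments.append(eigenvector_alignment(R, eig_indices, order))
    return NullEnsemble(matrices, alignments, n_null, int(seed), provenance, tuple(eig_indices))


@dataclass
class SignificanceMap:
    """Per-pair Welch statistics against the null ensemble."""

    channel_labels: list[str]
    pairs: np.ndarray  # (n_pairs, 2) channel indices, i < j
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    direction: np.ndarray  # 'increased' | 'decreased' | 'none' (object array)
    group_size: int
    n_null: int
    q_threshold: float = 0.05
    artificially_expanded: bool = False

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]

    def significant_pairs(self) -> np.ndarray:
        """Indices (into ``pairs``) of pairs with q below threshold."""
        with np.errstate(invalid="ignore"):
            return np.flatnonzero(self.q < self.q_threshold)

    def to_frame(self) -> pd.DataFrame:
        labels = np.asarray(self.channel_labels, dtype=object)
        df = pd.DataFrame(
            {
                "chan_a": labels[self.pairs[:, 0]],
                "chan_b": labels[self.pairs[:, 1]],
                "t": self.t,
                "p": self.p,
                "q": self.q,
                "direction": self.direction,
            }
        )
        if self.artificially_expanded:
            df.attrs["artificially_expanded"] = True
        return df

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            if self.artificially_expanded:
                fh.write("# artificially expanded cohort: illustrative only\n")
            df.to_csv(fh, sep="\t", index=False)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} ( p_(j) * m / j ) on the sorted p-values, mapped
    back to the input order and capped at 1.  NaN entries (untestable
    hypotheses) are excluded from m and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if np.any(finite):
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def _pair_index(n: int) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


def _as_samples(x, what: str) -> tuple[np.ndarray, list[str] | None]:
    """Stack per-subject AlignmentMatrix/ConnectivityMatrix into (n, n_pairs)."""
    if isinstance(x, np.ndarray):
        return np.atleast_2d(np.asarray(x, dtype=float)), None
    rows, labels = [], None
    for m in x:
        rows.append(m.pair_values())
        lab = list(m.channel_labels)
        if labels is None:
            labels = lab
        elif lab != labels:
            raise ValueError(f"{what}: channel labels differ between matrices")
    return np.stack(rows), labels


def pairwise_welch_test(
    group_thetas,
    null_thetas,
    q_threshold: float = 0.05,
    channel_labels: list[str] | None = None,
    artificially_expanded: bool = False,
) -> SignificanceMap:
    """Welch (unequal-variance) t-test of subjects against nulls, per pair.

    ``group_thetas`` and ``null_thetas`` are (n_subjects, n_pairs) and
    (n_null, n_pairs) arrays, or lists of matrices to be stacked.  Pairs with
    any undefined (NaN) value in either sample are excluded from testing and
    from the FDR family.  Direction is labelled from the mean difference
    ("increased" alignment = subject angles smaller than null) and reset to
    "none" wherever q is at or above threshold.
    """
    A, labels_a = _as_samples(group_thetas, "group")
    B, labels_b = _as_samples(null_thetas, "nulls")
    labels = channel_labels or labels_a or labels_b
    if A.shape[1] != B.shape[1]:
        raise ValueError("group and null samples disagree on the number of pairs")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least two subjects and two nulls")
    if labels_a and labels_b and labels_a != labels_b:
        raise ValueError("group and null channel labels differ")
    n_pairs = A.shape[1]
    if labels is None:
        # infer channel count from the pair count
        n = int(round((1 + np.sqrt(1 + 8 * n_pairs)) / 2))
        labels = [f"CH{i + 1:03d}" for i in range(n)]
    pairs = _pair_index(len(labels))
    if pairs.shape[0] != n_pairs:
        raise ValueError("channel labels do not match the number of pairs")

    testable = ~(np.any(np.isnan(A), axis=0) | np.any(np.isnan(B), axis=0))
    t = np.full(n_pairs, np.nan)
    p = np.full(n_pairs, np.nan)
    if np.any(testable):
        At, Bt = A[:, testable], B[:, testable]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(At, Bt, axis=0, equal_var=False)
        tt, pt = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
        # degenerate zero-variance pairs
        var0 = (At.var(axis=0) == 0) & (Bt.var(axis=0) == 0)
        same = var0 & (At.mean(axis=0) == Bt.mean(axis=0))
        diff = var0 & ~same
        tt[same], pt[same] = 0.0, 1.0
        if np.any(diff):
            warnings.warn(
                f"{int(diff.sum())} pair(s) have zero variance in both samples but "
                "unequal means; p set to 0 (degenerate)",
                RuntimeWarning,
                stacklevel=2,
            )
            tt[diff] = np.where(At.mean(axis=0)[diff] > Bt.mean(axis=0)[diff], np.inf, -np.inf)
            pt[diff] = 0.0
        t[testable], p[testable] = tt, pt
    q = bh_fdr(p)
    direction = np.full(n_pairs, "none", dtype=object)
    with np.errstate(invalid="ignore"):
        sig = q < q_threshold
    mean_diff = np.nanmean(A, axis=0) - np.nanmean(B, axis=0)
    direction[sig & (mean_diff < 0)] = "increased"
    direction[sig & (mean_diff > 0)] = "decreased"
    return SignificanceMap(
        list(labels),
        pairs,
        t,
        p,
        q,
        direction,
        group_size=A.shape[0],
        n_null=B.shape[0],
        q_threshold=q_threshold,
        artificially_expanded=artificially_expanded,
    )


@dataclass
class ConsistencySet:
    """Cross-band consistency of significant pairs."""

    channel_labels: list[str]
    pairs: np.ndarray
    band_names: list[str]
    directions: np.ndarray  # (n_pairs, n_bands) object array of per-band labels
    consistent: np.ndarray  # (n_pairs,) bool
    direction: np.ndarray  # (n_pairs,) consensus direction or 'none'
    min_bands: int
    artificially_expanded: bool = False

    def consistent_pairs(self) -> np.ndarray:
        return np.flatnonzero(self.consistent)

    def to_frame(self) -> pd.DataFrame:
        labels = np.asarray(self.channel_labels, dtype=object)
        bands_sig = [
            ",".join(b for b, d in zip(self.band_names, row) if d != "none")
            for row in self.directions
        ]
        return pd.DataFrame(
            {
                "chan_a": labels[self.pairs[:, 0]],
                "chan_b": labels[self.pairs[:, 1]],
                "bands_significant": bands_sig,
                "direction": self.direction,
                "consistent": self.consistent,
            }
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            if self.artificially_expanded:
                fh.write("# artificially expanded cohort: illustrative only\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def consistency_filter(maps: dict[str, SignificanceMap], min_bands: int = 3) -> ConsistencySet:
    """Mark pairs significant with the same direction in >= ``min_bands`` bands.

    ``maps`` is a dict band-name -> SignificanceMap over identical channel
    sets.  A pair significant "increased" in some bands and "decreased" in
    others only counts the larger same-direction tally.
    """
    if len(maps) < min_bands:
        raise ValueError(
            f"min_bands={min_bands} but only {len(maps)} band map(s) supplied"
        )
    band_names = list(maps)
    first = maps[band_names[0]]
    for name in band_names[1:]:
        if maps[name].channel_labels != first.channel_labels:
            raise ValueError(f"band {name!r} has mismatched channel labels")
    directions = np.stack([maps[name].direction for name in band_names], axis=1)
    n_inc = np.sum(directions == "increased", axis=1)
    n_dec = np.sum(directions == "decreased", axis=1)
    consistent = (n_inc >= min_bands) | (n_dec >= min_bands)
    consensus = np.full(first.n_pairs, "none", dtype=object)
    consensus[n_inc >= min_bands] = "increased"
    consensus[n_dec >= min_bands] = "decreased"
    expanded = any(maps[name].artificially_expanded for name in band_names)
    return ConsistencySet(
        list(first.channel_labels),
        first.pairs,
        band_names,
        directions,
        consistent,
        consensus,
        min_bands,
        artificially_expanded=expanded,
    )


def expand_cohort(group: list[ConnectivityMatrix], factor: int = 2) -> list[ConnectivityMatrix]:
    """Artificially expand a cohort by duplicating each subject ``factor`` times.

    Duplication inflates the apparent sample size and hence significance;
    the copies are flagged so downstream reports mark results as
    illustrative.  ``factor=1`` returns unflagged copies (identity).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    out = []
    for _ in range(factor):
        for m in group:
            meta = dict(m.meta)
            if factor > 1:
                meta["artificially_expanded"] = True
            out.append(ConnectivityMatrix(m.W.copy(), m.measure, m.band, list(m.channel_labels), meta))
    return out


class NullModelTest(BaseEstimator):
    """Significance of a subject group's alignments against randomised nulls.

    Parameters
    ----------
    n_null : int
        Ensemble size (1000 gives stable discovery sets; see the methods
        note).
    eig_indices : tuple of int
        Eigenvector ranks for the alignment embedding.
    q : float
        Benjamini-Hochberg discovery threshold.
    compare : {"alignment", "connectivity"}
        Test alignment angles (the primary analysis) or the connectivity
        weights themselves against the randomised matrices.
    random_state : int
        Seed for the null randomisations.

    Attributes (after ``fit`` on a list of ConnectivityMatrix)
    ----------
    null_ensemble_ : NullEnsemble
    subject_alignments_ : list of AlignmentMatrix (alignment mode)
    significance_ : SignificanceMap
    """

    def __init__(
        self,
        n_null: int = 1000,
        eig_indices=(2, 3, 4),
        q: float = 0.05,
        compare: str = "alignment",
        order: str = "algebraic",
        random_state: int = 0,
    ):
        self.n_null = n_null
        self.eig_indices = eig_indices
        self.q = q
        self.compare = compare
        self.order = order
        self.random_state = random_state

    def fit(self, X: list[ConnectivityMatrix], y=None):
        if self.compare not in ("alignment", "connectivity"):
            raise ValueError(f"compare must be 'alignment' or 'connectivity', got {self.compare!r}")
        group = list(X)
        if len(group) < 2:
            raise ValueError("need at least two subjects")
        expanded = any(m.meta.get("artificially_expanded", False) for m in group)
        self.null_ensemble_ = build_null_ensemble(
            group, self.n_null, self.eig_indices, self.random_state, self.order
        )
        if self.compare == "alignment":
            self.subject_alignments_ = [
                eigenvector_alignment(m, self.eig_indices, self.order) for m in group
            ]
            subj = self.subject_alignments_
            null = self.null_ensemble_.theta_stack()
        else:
            subj = np.stack([m.pair_values() for m in group])
            null = self.null_ensemble_.weight_stack()
        self.significance_ = pairwise_welch_test(
            subj,
            null,
            q_threshold=self.q,
            channel_labels=list(group[0].channel_labels),
            artificially_expanded=expanded,
        )
        return self
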