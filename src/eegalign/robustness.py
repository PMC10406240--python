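"""Robustness of eigenvector alignment to connection alteration.

iCOH erases genuinely instantaneous coupling, so the weakest iCOH entries
are the ones most likely to hide true connectivity.  These experiments
probe how much the alignment picture would move if those entries were wrong:
either erase the corresponding connections from a correlation matrix, or
create them in the iCOH matrix (set to its maximum entry), then recompute
the alignment and summarise the disturbance as

    dEA = mean over channel pairs of |theta_altered - theta_original|   [deg].

Sweeping the percentage of altered connections maps out how gracefully the
embedding degrades.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import AlignmentMatrix, eigenvector_alignment
from .connectivity import BandSpec, ConnectivityMatrix

__all__ = [
    "RobustnessResult",
    "erase_lowest",
    "create_lowest",
    "delta_ea",
    "robustness_sweep",
]


@dataclass
class RobustnessResult:
    """dEA summary for one alteration level across a group of subjects."""

    percent_altered: float
    k: int
    delta_ea_mean: float
    delta_ea_sd: float
    mode: str  # 'erase_correlation' | 'create_icoh'
    band: BandSpec | None
    n_subjects: int

    def __post_init__(self) -> None:
        if not (0 <= self.percent_altered <= 100):
            raise ValueError("percent_altered must be in [0, 100]")
        if self.delta_ea_mean < 0:
            raise ValueError("delta_ea_mean cannot be negative")


def _lowest_pairs(reference: ConnectivityMatrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the k smallest-weight undirected pairs.

    Ties are broken by (row, column) index so the selection is deterministic.
    """
    n = reference.n_channels
    n_pairs = reference.n_pairs
    if not (0 <= k <= n_pairs):
        raise ValueError(f"k={k} out of range for {n_pairs} undirected pairs")
    iu = np.triu_indices(n, k=1)
    order = np.lexsort((iu[1], iu[0], reference.W[iu]))  # value, then row, then col
    sel = order[:k]
    return iu[0][sel], iu[1][sel]


def erase_lowest(
    target: ConnectivityMatrix, reference_icoh: ConnectivityMatrix, k: int
) -> ConnectivityMatrix:
    """Zero the k undirected pairs of ``target`` with smallest reference iCOH.

    Both triangle entries are cleared (2k directional edges).  ``target`` and
    ``reference_icoh`` must share the same channel set.
    """
    if target.channel_labels != reference_icoh.channel_labels:
        raise ValueError("target and reference matrices have different channel sets")
    rows, cols = _lowest_pairs(reference_icoh, k)
    W = target.W.copy()
    W[rows, cols] = 0.0
    W[cols, rows] = 0.0
    return ConnectivityMatrix(W, target.measure, target.band, list(target.channel_labels), dict(target.meta))


def create_lowest(
    icoh: ConnectivityMatrix, k: int, reference: ConnectivityMatrix | None = None
) -> ConnectivityMatrix:
    """Set the k lowest-reference pairs of ``icoh`` to its maximum entry.

    By default the matrix is its own reference (its lowest entries are
    raised).  An all-zero matrix has maximum 0, making the operation the
    identity; a warning is emitted.
    """
    ref = icoh if reference is None else reference
    if ref.channel_labels != icoh.channel_labels:
        raise ValueError("reference matrix has a different channel set")
    rows, cols = _lowest_pairs(ref, k)
    w_max = float(icoh.pair_values().max()) if icoh.n_pairs else 0.0
    if w_max == 0.0:
        warnings.warn(
            "all-zero connectivity matrix: maximum entry is 0, creation is a no-op",
            RuntimeWarning,
            stacklevel=2,
        )
    W = icoh.W.copy()
    W[rows, cols] = w_max
    W[cols, rows] = w_max
    return ConnectivityMatrix(W, icoh.measure, icoh.band, list(icoh.channel_labels), dict(icoh.meta))


def delta_ea(theta_a: AlignmentMatrix, theta_b: AlignmentMatrix) -> float:
    """Mean absolute alignment-angle difference over defined channel pairs."""
    if theta_a.channel_labels != theta_b.channel_labels:
        raise ValueError("alignment matrices have different channel sets")
    if tuple(theta_a.eig_indices) != tuple(theta_b.eig_indices):
        raise ValueError("alignment matrices use different eigenvector ranks")
    a = theta_a.pair_values()
    b = theta_b.pair_values()
    ok = ~(np.isnan(a) | np.isnan(b))
    if not np.any(ok):
        raise ValueError("no channel pair is defined in both alignment matrices")
    return float(np.mean(np.abs(a[ok] - b[ok])))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def robustness_sweep(
    subjects: list[tuple[ConnectivityMatrix, ConnectivityMatrix]],
    percents,
    mode: str,
    eig_indices=(2, 3, 4),
    order: str = "algebraic",
) -> list[RobustnessResult]:
    """dEA versus percentage of altered connections, across subjects.

    ``subjects`` is a list of (target, reference_icoh) matrix pairs; for
    ``mode='erase_correlation'`` the target is a correlation matrix whose
    lowest-reference-iCOH pairs are zeroed, for ``mode='create_icoh'`` the
    target is the iCOH matrix whose lowest pairs are raised to its maximum.
    For each percentage, k = round(percent * n_pairs / 100) pairs (half-away
    rounding) are altered per subject, the alignment recomputed, and the mean
    and standard deviation of dEA across subjects reported.
    """
    if not subjects:
        raise ValueError("subject list must be nonempty")
    if mode not in ("erase_correlation", "create_icoh"):
        raise ValueError(f"mode must be 'erase_correlation' or 'create_icoh', got {mode!r}")
    percents = [float(p) for p in percents]
    for p in percents:
        if not (0 <= p <= 100):
            raise ValueError(f"percent {p} outside [0, 100]")
    baselines = [
        eigenvector_alignment(target, eig_indices, order) for target, _ in subjects
    ]
    band = subjects[0][0].band
    results = []
    for p in percents:
        deltas = []
        for (target, reference), base in zip(subjects, baselines):
            k = _round_half_away(p * target.n_pairs / 100.0)
            if mode == "erase_correlation":
                altered = erase_lowest(target, reference, k)
            else:
                altered = create_lowest(target, k, reference=reference)
            deltas.append(delta_ea(base, eigenvector_alignment(altered, eig_indices, order)))
        deltas = np.asarray(deltas)
        results.append(
            RobustnessResult(
                percent_altered=p,
                k=_round_half_away(p * subjects[0][0].n_pairs / 100.0),
                delta_ea_mean=float(deltas.mean()),
                delta_ea_sd=float(deltas.std(ddof=1)) if deltas.size > 1 else 0.0,
                mode=mode,
                band=band,
                n_subjects=len(subjects),
            )
        )
    return results


def sweep_to_frame(results: list[RobustnessResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mode": [r.mode for r in results],
            "band": [r.band.name if r.band else "" for r in results],
            "percent": [r.percent_altered for r in results],
            "k": [r.k for r in results],
            "delta_ea_mean": [r.delta_ea_mean for r in results],
            "delta_ea_sd": [r.delta_ea_sd for r in results],
            "n_subjects": [r.n_subjects for r in results],
        }
    )
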