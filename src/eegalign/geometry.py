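"""Sensor layouts, distance-bounded edge filtering and channel subsetting.

Connection lists reported by the significance stage are usually filtered by
sensor distance before visualisation: nearest-neighbour sensors share nearly
identical connectivity patterns (so their close alignment is uninformative)
and very distant sensors tend to decreased alignment for purely geometric
reasons.  The bounds are derived from the layout itself: the upper bound is a
fraction of the anterior-posterior (y-axis) extent of the montage and the
lower bound a multiple of the smallest inter-sensor spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SensorLayout",
    "DistanceBounds",
    "distance_bounds",
    "filter_edges",
    "subset_channels",
    "spherical_cap_layout",
    "layout_from_montage",
]


@dataclass
class SensorLayout:
    """Sensor labels with 3-D positions in millimetres."""

    labels: list[str]
    coords: np.ndarray  # (n, 3) in mm

    def __post_init__(self) -> None:
        self.labels = [str(c) for c in self.labels]
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_sensors, 3)")
        if len(self.labels) != self.coords.shape[0]:
            raise ValueError("label count does not match coordinate rows")
        if len(self.labels) < 2:
            raise ValueError("a layout needs at least two sensors")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("sensor labels must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("sensor coordinates must be finite")

    @property
    def n_sensors(self) -> int:
        return len(self.labels)

    def distance_matrix(self) -> np.ndarray:
        return squareform(pdist(self.coords))

    def position(self, label: str) -> np.ndarray:
        try:
            return self.coords[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"unknown sensor label: {label!r}") from None

    def subset(self, keep: list[str]) -> "SensorLayout":
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in keep if lab not in pos]
        if missing:
            raise KeyError(f"unknown sensor label(s): {missing}")
        idx = [pos[lab] for lab in keep]
        return SensorLayout(list(keep), self.coords[idx])

    @classmethod
    def from_tsv(cls, path) -> "SensorLayout":
        """Read a layout TSV with columns label, x_mm, y_mm, z_mm."""
        df = pd.read_csv(path, sep="\t")
        required = ["label", "x_mm", "y_mm", "z_mm"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"layout file missing column(s): {missing}")
        return cls(list(df["label"].astype(str)), df[["x_mm", "y_mm", "z_mm"]].to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "label": self.labels,
                "x_mm": self.coords[:, 0],
                "y_mm": self.coords[:, 1],
                "z_mm": self.coords[:, 2],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class DistanceBounds:
    """Inclusive distance window [min_mm, max_mm] for reported connections."""

    min_mm: float
    max_mm: float
    max_frac: float = 0.65
    min_mult: float = 2.5

    def __post_init__(self) -> None:
        if not (0 <= self.min_mm < self.max_mm):
            raise ValueError(
                f"invalid distance bounds: min_mm={self.min_mm:.3g} must be "
                f"non-negative and below max_mm={self.max_mm:.3g}"
            )


def distance_bounds(
    layout: SensorLayout, max_frac: float = 0.65, min_mult: float = 2.5
) -> DistanceBounds:
    """Derive reporting bounds from a layout.

    max_mm = ``max_frac`` times the y-coordinate range (anterior-posterior
    extent); min_mm = ``min_mult`` times the smallest pairwise sensor
    distance.  Degenerate layouts where the resulting window is empty raise.
    """
    y = layout.coords[:, 1]
    y_range = float(y.max() - y.min())
    d_min = float(pdist(layout.coords).min())
    if d_min <= 0:
        raise ValueError("layout contains coincident sensors (zero minimum distance)")
    return DistanceBounds(
        min_mm=min_mult * d_min, max_mm=max_frac * y_range, max_frac=max_frac, min_mult=min_mult
    )


def filter_edges(pairs, layout: SensorLayout, bounds: DistanceBounds):
    """Keep pairs whose Euclidean sensor distance lies within ``bounds``.

    ``pairs`` is an iterable of (label_a, label_b) tuples (extra per-pair
    payload after the two labels is carried through untouched).  Unknown
    labels raise ``KeyError`` naming the offender.  Filtering is idempotent
    and order-independent.
    """
    kept = []
    for pair in pairs:
        a, b = pair[0], pair[1]
        d = float(np.linalg.norm(layout.position(a) - layout.position(b)))
        if bounds.min_mm <= d <= bounds.max_mm:
            kept.append(pair)
    return kept


def subset_channels(obj, keep: list[str]):
    """Restrict epochs, a connectivity/alignment matrix or a layout to ``keep``.

    Dispatches on the object's own ``subset`` method so the returned object
    has the same type, with rows/columns (or channels) in ``keep`` order.
    """
    if not hasattr(obj, "subset"):
        raise TypeError(f"cannot subset object of type {type(obj).__name__}")
    return obj.subset(list(keep))


def spherical_cap_layout(
    n_sensors: int, radius_mm: float = 95.0, cap_fraction: float = 0.65
) -> SensorLayout:
    """Deterministic synthetic EEG montage on a spherical cap.

    Sensors are placed on the upper cap of a sphere of ``radius_mm`` using a
    Fibonacci spiral, giving near-uniform spacing.  ``cap_fraction`` is the
    fraction of the sphere's polar angle covered (0.65 reaches below the
    equatorial band, roughly matching how far EEG caps extend).  This is a
    synthetic stand-in layout for testing; it is not a vendor coordinate file.
    """
    if n_sensors < 2:
        raise ValueError("need at least two sensors")
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_sensors)
    # polar angle from the vertex down to cap_fraction * pi
    cos_max = np.cos(cap_fraction * np.pi)
    z = 1.0 - (1.0 - cos_max) * (i + 0.5) / n_sensors
    theta = np.arccos(z)
    phi = golden * i
    coords = radius_mm * np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    labels = [f"S{k + 1:03d}" for k in i]
    return SensorLayout(labels, coords)


def layout_from_montage(name: str) -> SensorLayout:
    """Build a layout from one of mne's bundled standard montages.

    These montages place electrodes on an idealised spherical head (default
    radius 95 mm); positions differ from vendor-measured coordinate files, so
    distance bounds computed from them are approximations.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("standard montages require the 'mne' package") from exc
    montage = mne.channels.make_standard_montage(name)
    pos = montage.get_positions()["ch_pos"]
    labels = list(pos)
    coords = np.array([pos[lab] for lab in labels]) * 1000.0  # m -> mm
    return SensorLayout(labels, coords)
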