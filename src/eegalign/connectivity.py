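"""Spectral and correlation connectivity estimation.

The central measure is the imaginary part of coherency (iCOH).  Coherency
between channels i and j at frequency f is the normalised cross-spectrum

    COH_ij(f) = S_ij(f) / sqrt(S_ii(f) S_jj(f)),

a complex number whose magnitude is the linear coupling strength and whose
phase is the relative lag.  Volume conduction spreads one source to many
sensors instantaneously (zero or pi phase), so its contribution to COH is
purely real; |Im(COH)| is therefore blind to it while retaining genuinely
lagged synchrony.  Band iCOH is |Im(COH)| averaged over the frequency bins
inside a band.

Cross-spectra are estimated per trial with a single Hann taper and averaged
over trials; trials are zero-padded so the discrete frequency grid has an
exact user-chosen step (0.5 Hz by default).  A single trial is rejected:
one-taper one-trial coherency has magnitude identically 1 and carries no
information.

Band-limited Pearson correlation (zero-phase Butterworth band-pass, per-trial
coefficient, averaged, absolute value) is provided as the classical
volume-conduction-sensitive comparison measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .epochs import TimeSeriesEpochs, _label_indices

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "CrossSpectrum",
    "Coherency",
    "ConnectivityMatrix",
    "estimate_cross_spectra",
    "coherency",
    "icoh_band",
    "correlation_matrix",
    "SpectralConnectivity",
]

_SYM_TOL = 1e-9


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [f_lo, f_hi] in Hz, inclusive on grid bins."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 <= f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]"
            )


#: Canonical EEG analysis bands (delta, theta, alpha, beta).
DEFAULT_BANDS = (
    BandSpec("delta", 0.1, 4.0),
    BandSpec("theta", 4.0, 7.0),
    BandSpec("alpha", 7.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
)


@dataclass
class CrossSpectrum:
    """Trial-averaged cross-spectral matrices S(f), Hermitian per frequency."""

    freqs: np.ndarray  # (n_freqs,)
    S: np.ndarray  # (n_freqs, n_ch, n_ch) complex
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.S = np.asarray(self.S, dtype=complex)
        if self.S.ndim != 3 or self.S.shape[1] != self.S.shape[2]:
            raise ValueError("S must have shape (n_freqs, n_ch, n_ch)")
        if self.S.shape[0] != self.freqs.size:
            raise ValueError("frequency grid does not match S")


@dataclass
class Coherency:
    """Complex coherency per frequency; C[f] Hermitian with unit diagonal."""

    freqs: np.ndarray
    C: np.ndarray  # (n_freqs, n_ch, n_ch) complex, NaN for excluded bins
    channel_labels: list[str]


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative channel-by-channel weights for one measure/band."""

    W: np.ndarray
    measure: str = "icoh"
    band: BandSpec | None = None
    channel_labels: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("connectivity matrix must be square")
        n = self.W.shape[0]
        if n < 2:
            raise ValueError("connectivity matrix needs at least two channels")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("connectivity weights must be finite")
        if not np.allclose(self.W, self.W.T, atol=_SYM_TOL):
            raise ValueError("connectivity matrix must be symmetric")
        self.W = 0.5 * (self.W + self.W.T)
        if np.any(np.abs(np.diag(self.W)) > _SYM_TOL):
            raise ValueError("connectivity matrix must have zero diagonal")
        np.fill_diagonal(self.W, 0.0)
        if self.W.min() < -_SYM_TOL or self.W.max() > 1 + _SYM_TOL:
            raise ValueError("connectivity weights must lie in [0, 1]")
        self.W = np.clip(self.W, 0.0, 1.0)
        if not self.channel_labels:
            self.channel_labels = [f"CH{i + 1:03d}" for i in range(n)]
        if len(self.channel_labels) != n or len(set(self.channel_labels)) != n:
            raise ValueError("channel labels must be unique and match the matrix")

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    @property
    def n_pairs(self) -> int:
        n = self.n_channels
        return n * (n - 1) // 2

    def pair_values(self) -> np.ndarray:
        """Upper-triangle weights in row-major (i<j) order."""
        iu = np.triu_indices(self.n_channels, k=1)
        return self.W[iu]

    def subset(self, keep: list[str]) -> "ConnectivityMatrix":
        idx = _label_indices(self.channel_labels, keep)
        return ConnectivityMatrix(
            self.W[np.ix_(idx, idx)], self.measure, self.band, list(keep), dict(self.meta)
        )

    @classmethod
    def from_tsv(cls, path, measure: str = "icoh", band: BandSpec | None = None):
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = [str(c) for c in df.columns]
        return cls(df.to_numpy(dtype=float), measure, band, labels)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.W, index=self.channel_labels, columns=self.channel_labels).to_csv(
            path, sep="\t"
        )


def _fft_layout(n_samples: int, fs: float, resolution_hz: float) -> tuple[int, int]:
    """Zero-padded FFT length and bin stride giving an exact resolution grid.

    The base length fs/resolution must be integral; trials longer than one
    base length are padded to the next multiple and the finer grid subsampled
    back to the requested step.
    """
    if resolution_hz <= 0:
        raise ValueError("resolution_hz must be positive")
    base = fs / resolution_hz
    if abs(base - round(base)) > 1e-9:
        raise ValueError(
            f"fs={fs} Hz does not support an exact {resolution_hz} Hz grid "
            "(fs/resolution must be an integer)"
        )
    base = int(round(base))
    mult = max(1, int(np.ceil(n_samples / base)))
    return base * mult, mult


def estimate_cross_spectra(
    epochs: TimeSeriesEpochs,
    resolution_hz: float = 0.5,
    fmax: float | None = None,
) -> CrossSpectrum:
    """Trial-averaged Hann-tapered cross-spectral matrices on an exact grid.

    Parameters
    ----------
    epochs : TimeSeriesEpochs
        At least two trials (a single Hann-tapered trial gives degenerate
        unit-magnitude coherency, so it is rejected).
    resolution_hz : float
        Frequency grid step; trials are zero-padded to achieve it exactly.
    fmax : float, optional
        Truncate the grid above this frequency (defaults to Nyquist).
    """
    if epochs.n_trials < 2:
        raise ValueError(
            "cross-spectral estimation needs >= 2 trials: coherency from a "
            "single trial and taper has magnitude identically 1"
        )
    nfft, stride = _fft_layout(epochs.n_samples, epochs.fs, resolution_hz)
    window = signal.windows.hann(epochs.n_samples, sym=False)
    X = np.fft.rfft(epochs.data * window, n=nfft, axis=2)
    X = X[:, :, ::stride]  # exact resolution_hz grid
    freqs = np.arange(X.shape[2]) * resolution_hz
    if fmax is None:
        fmax = epochs.fs / 2
    keep = freqs <= fmax + 1e-9
    X = X[:, :, keep]
    freqs = freqs[keep]
    # S[f] = mean over trials of x(f) x(f)^H  -> Hermitian by construction
    S = np.einsum("tif,tjf->fij", X, np.conj(X)) / epochs.n_trials
    return CrossSpectrum(freqs, S, list(epochs.channel_labels))


def coherency(cs: CrossSpectrum) -> Coherency:
    """Normalise a cross-spectrum to complex coherency per frequency.

    Bins where any autospectrum vanishes are excluded (set to NaN) with a
    warning; the magnitude is clipped to 1 against round-off.
    """
    auto = np.real(np.diagonal(cs.S, axis1=1, axis2=2))  # (n_freqs, n_ch)
    bad = np.any(auto <= 0, axis=1)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} frequency bin(s) have a zero autospectrum and are excluded",
            RuntimeWarning,
            stacklevel=2,
        )
    denom = np.sqrt(auto[:, :, None] * auto[:, None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        C = cs.S / denom
    C[bad] = np.nan
    mag = np.abs(C)
    over = mag > 1
    if np.any(over):
        C[over] /= mag[over]
    return Coherency(cs.freqs, C, list(cs.channel_labels))


def icoh_band(coh: Coherency, band: BandSpec) -> ConnectivityMatrix:
    """Average |Im(COH)| over the grid bins inside ``band`` (closed interval)."""
    mask = (coh.freqs >= band.f_lo - 1e-9) & (coh.freqs <= band.f_hi + 1e-9)
    # bins excluded by coherency() (zero autospectrum) do not enter the mean
    mask &= ~np.all(np.isnan(coh.C), axis=(1, 2))
    if not np.any(mask):
        raise ValueError(
            f"band {band.name!r} [{band.f_lo}, {band.f_hi}] Hz contains no frequency grid bins"
        )
    W = np.nanmean(np.abs(np.imag(coh.C[mask])), axis=0)
    np.fill_diagonal(W, 0.0)
    W = 0.5 * (W + W.T)
    return ConnectivityMatrix(np.clip(W, 0.0, 1.0), "icoh", band, list(coh.channel_labels))


def correlation_matrix(epochs: TimeSeriesEpochs, band: BandSpec) -> ConnectivityMatrix:
    """Band-limited absolute Pearson correlation, averaged across trials.

    Each trial is band-pass filtered with a zero-phase (forward-backward)
    4th-order Butterworth filter, the per-trial Pearson coefficient computed
    for every pair, coefficients averaged across trials and the absolute
    value taken (keeping the matrix nonnegative for the downstream spectral
    embedding).  Constant channels yield undefined coefficients; their pairs
    are set to 0 with a warning.
    """
    if epochs.n_samples < 2:
        raise ValueError("need at least two samples per trial")
    nyq = epochs.fs / 2
    if band.f_hi >= nyq:
        raise ValueError(f"band {band.name!r} upper edge {band.f_hi} Hz is above Nyquist {nyq} Hz")
    lo = max(band.f_lo, 1e-6)
    sos = signal.butter(4, [lo, band.f_hi], btype="bandpass", fs=epochs.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=2)
    n_ch = epochs.n_channels
    acc = np.zeros((n_ch, n_ch))
    saw_constant = False
    for t in range(epochs.n_trials):
        x = filtered[t]
        sd = x.std(axis=1)
        constant = sd <= 1e-15 * max(1.0, np.abs(x).max())
        if np.any(constant):
            saw_constant = True
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(x)
        r[constant, :] = 0.0
        r[:, constant] = 0.0
        np.fill_diagonal(r, 1.0)
        acc += np.nan_to_num(r, nan=0.0)
    if saw_constant:
        warnings.warn(
            "constant channel(s) encountered; their correlations were set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    W = np.abs(acc / epochs.n_trials)
    np.fill_diagonal(W, 0.0)
    W = np.clip(0.5 * (W + W.T), 0.0, 1.0)
    return ConnectivityMatrix(W, "correlation_abs", band, list(epochs.channel_labels))


class SpectralConnectivity(TransformerMixin, BaseEstimator):
    """Transform epochs into per-band connectivity matrices.

    Parameters
    ----------
    measure : {"icoh", "correlation"}
        Band iCOH (volume-conduction suppressing) or band-limited absolute
        Pearson correlation.
    bands : sequence of BandSpec
        Bands to estimate; defaults to delta/theta/alpha/beta.
    resolution_hz : float
        Frequency grid step for the spectral estimate (iCOH only).

    ``transform`` maps a :class:`TimeSeriesEpochs` (or list of them) to a
    dict band-name -> :class:`ConnectivityMatrix` (or list of dicts).
    """

    def __init__(self, measure: str = "icoh", bands=DEFAULT_BANDS, resolution_hz: float = 0.5):
        self.measure = measure
        self.bands = bands
        self.resolution_hz = resolution_hz

    def fit(self, X=None, y=None):
        if self.measure not in ("icoh", "correlation"):
            raise ValueError(f"unknown measure {self.measure!r}")
        if len(self.bands) < 1:
            raise ValueError("need at least one band")
        return self

    def transform(self, X):
        self.fit()
        if isinstance(X, TimeSeriesEpochs):
            return self._one(X)
        return [self._one(e) for e in X]

    def _one(self, epochs: TimeSeriesEpochs) -> dict[str, ConnectivityMatrix]:
        if self.measure == "icoh":
            fmax = max(b.f_hi for b in self.bands) + self.resolution_hz
            coh = coherency(estimate_cross_spectra(epochs, self.resolution_hz, fmax=fmax))
            return {b.name: icoh_band(coh, b) for b in self.bands}
        return {b.name: correlation_matrix(epochs, b) for b in self.bands}
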