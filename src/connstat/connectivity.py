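"""Band-limited phase connectivity from region-level time series.

The pipeline mirrors common practice for source-space EEG functional
connectivity: each region signal is zero-phase band-pass filtered into a
narrow frequency band, the analytic signal is obtained with the Hilbert
transform, the weighted phase lag index (wPLI) is estimated on short
sliding windows (dynamic connectivity), and the windowed matrices are
averaged over all windows of all epochs into a single static matrix per
band.

wPLI weights each sample's phase difference by the magnitude of the
imaginary part of the cross term ``z_i * conj(z_j)``:

    wPLI_ij = | mean_t Im(z_i conj(z_j)) |  /  mean_t | Im(z_i conj(z_j)) |

It is therefore insensitive to zero-phase-lag (volume-conduction-like)
coupling: a shared instantaneous component contributes nothing to the
imaginary cross term.  When every imaginary cross term vanishes (identical
or strictly zero-lag signals) the estimator is defined to be 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "BandDefinition",
    "RegionTimeSeries",
    "WindowSpec",
    "DEFAULT_BANDS",
    "bandpass",
    "analytic_signal",
    "dynamic_wpli",
    "static_fc",
    "compute_fc",
    "WPLIConnectivity",
]

#: Denominator below this is treated as "no lagged coupling" -> wPLI = 0.
_ZERO_LAG_EPS = 1e-12


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [f_low, f_high] in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self):
        if not (0 < self.f_low < self.f_high):
            raise ValueError(f"invalid band edges ({self.f_low}, {self.f_high})")

    def validate_fs(self, fs: float) -> None:
        if self.f_high >= fs / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.f_high} Hz >= Nyquist ({fs / 2} Hz)"
            )


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("low_gamma", 30.0, 45.0),
)


@dataclass
class RegionTimeSeries:
    """Region-by-sample signal matrix for one subject, in atlas order."""

    subject_id: str
    fs: float
    data: np.ndarray  # (n_regions, n_samples)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (regions x samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains non-finite values")
        if self.data.shape[1] < self.fs:
            raise ValueError("need at least one second of signal")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window and epoch layout for dynamic connectivity.

    Defaults follow the convention of 1-s windows with 50 % overlap inside
    30-s epochs, six epochs (180 s) per subject.
    """

    window_s: float = 1.0
    overlap: float = 0.5
    epoch_s: float = 30.0
    n_epochs: int = 6

    def __post_init__(self):
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")
        if self.window_s <= 0 or self.epoch_s <= 0 or self.n_epochs < 1:
            raise ValueError("window_s, epoch_s and n_epochs must be positive")

    def window_samples(self, fs: float) -> int:
        n = int(round(self.window_s * fs))
        if n < 8:
            raise ValueError("window must span at least 8 samples")
        return n

    def hop_samples(self, fs: float) -> int:
        return max(1, int(round(self.window_s * (1 - self.overlap) * fs)))


def bandpass(ts: RegionTimeSeries, band: BandDefinition) -> RegionTimeSeries:
    """Zero-phase band-pass filter (4th-order Butterworth, forward-backward).

    The effective magnitude response is the squared 4th-order response,
    giving > 40 dB attenuation one octave outside the band; reflect padding
    keeps edge transients small.
    """
    band.validate_fs(ts.fs)
    sos = sps.butter(4, [band.f_low, band.f_high], btype="bandpass", fs=ts.fs, output="sos")
    padlen = min(ts.data.shape[1] - 1, int(3 * ts.fs))
    out = sps.sosfiltfilt(sos, ts.data, axis=-1, padtype="even", padlen=padlen)
    return RegionTimeSeries(ts.subject_id, ts.fs, out)


def analytic_signal(ts: RegionTimeSeries | np.ndarray) -> np.ndarray:
    """Complex analytic extension via the Hilbert transform.

    The real part equals the input; the argument is the instantaneous
    phase.  Input is expected to be band-limited.  For an all-zero channel
    the amplitude is 0 and the phase undefined; downstream wPLI treats such
    channels through the zero-denominator convention.
    """
    data = ts.data if isinstance(ts, RegionTimeSeries) else np.asarray(ts, dtype=float)
    if not np.isfinite(data).all():
        raise ValueError("non-finite values in input")
    return sps.hilbert(data, axis=-1)


def _wpli_from_windows(z: np.ndarray, starts: np.ndarray, wlen: int) -> np.ndarray:
    """wPLI per window from analytic signals.

    Parameters
    ----------
    z : complex array (R, T)
    starts : int array of window start samples
    wlen : window length in samples

    Returns
    -------
    array (n_windows, R, R)
    """
    r = z.shape[0]
    a, b = z.real, z.imag
    out = np.empty((len(starts), r, r))
    for w, s in enumerate(starts):
        aw = np.ascontiguousarray(a[:, s : s + wlen])
        bw = np.ascontiguousarray(b[:, s : s + wlen])
        # Im(z_i conj z_j) = b_i a_j - a_i b_j, per sample
        num = (bw @ aw.T - aw @ bw.T) / wlen
        im = bw[:, None, :] * aw[None, :, :] - aw[:, None, :] * bw[None, :, :]
        den = np.abs(im).mean(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            wpli = np.abs(num) / den
        wpli[den < _ZERO_LAG_EPS] = 0.0
        np.fill_diagonal(wpli, 0.0)
        out[w] = 0.5 * (wpli + wpli.T)  # numerically symmetric by construction
    return out


def dynamic_wpli(analytic: np.ndarray, spec: WindowSpec, fs: float) -> np.ndarray:
    """Windowed wPLI matrices for one contiguous segment.

    Parameters
    ----------
    analytic : complex array (R, T)
        Analytic (Hilbert-transformed, band-limited) region signals.
    spec : WindowSpec
    fs : float
        Sampling rate in Hz.

    Returns
    -------
    array (n_windows, R, R)
        One symmetric, zero-diagonal wPLI matrix in [0, 1] per window.
    """
    z = np.asarray(analytic)
    wlen = spec.window_samples(fs)
    hop = spec.hop_samples(fs)
    t = z.shape[-1]
    if wlen > t:
        raise ValueError(f"window of {wlen} samples longer than segment of {t}")
    starts = np.arange(0, t - wlen + 1, hop)
    return _wpli_from_windows(z, starts, wlen)


def static_fc(windows: np.ndarray) -> np.ndarray:
    """Average dynamic matrices into one static matrix (element-wise mean)."""
    w = np.asarray(windows, dtype=float)
    if w.ndim != 3 or w.shape[0] < 1:
        raise ValueError("need a (n_windows, R, R) stack with at least one window")
    return w.mean(axis=0)


class WPLIConnectivity(TransformerMixin, BaseEstimator):
    """Static per-band wPLI connectivity transformer.

    A stateless transformer in the scikit-learn sense: ``fit`` only records
    input dimensions, ``transform`` maps an array of region time series to
    static connectivity matrices.

    Parameters
    ----------
    fs : float
        Sampling rate of the input signals, Hz.
    bands : sequence of BandDefinition
        Frequency bands to analyze (default theta/alpha/beta/low-gamma).
    window : WindowSpec
        Sliding-window and epoch layout.
    trim_s : float
        Seconds to drop from each end of the filtered signal before phase
        statistics, to suppress residual filter transients.  Only surplus
        beyond the epoch budget is trimmed, so a recording that exactly
        covers ``n_epochs * epoch_s`` is used in full.
    """

    def __init__(
        self,
        fs: float = 1024.0,
        bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
        window: WindowSpec = WindowSpec(),
        trim_s: float = 1.0,
    ):
        self.fs = fs
        self.bands = bands
        self.window = window
        self.trim_s = trim_s

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_subjects, n_regions, n_samples)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Compute static wPLI matrices.

        Parameters
        ----------
        X : array (n_subjects, n_regions, n_samples)

        Returns
        -------
        array (n_subjects, n_bands, R, R)
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_subjects, n_regions, n_samples)")
        out = np.empty((X.shape[0], len(self.bands), X.shape[1], X.shape[1]))
        for s in range(X.shape[0]):
            ts = RegionTimeSeries(str(s), self.fs, X[s])
            fc = self.transform_subject(ts)
            for bi, band in enumerate(self.bands):
                out[s, bi] = fc[band.name]
        return out

    def transform_subject(self, ts: RegionTimeSeries) -> dict[str, np.ndarray]:
        """Per-band static wPLI for a single subject."""
        spec = self.window
        fs = ts.fs
        epoch_len = int(round(spec.epoch_s * fs))
        needed = spec.n_epochs * epoch_len
        if ts.data.shape[1] < needed:
            raise ValueError(
                f"recording of {ts.data.shape[1]} samples shorter than "
                f"{spec.n_epochs} x {spec.epoch_s} s epoch budget"
            )
        surplus = ts.data.shape[1] - needed
        trim = min(int(round(self.trim_s * fs)), surplus // 2)
        result: dict[str, np.ndarray] = {}
        for band in self.bands:
            filtered = bandpass(ts, band)
            z = analytic_signal(filtered)
            if trim:
                z = z[:, trim : trim + needed]
            else:
                z = z[:, :needed]
            windows = [
                dynamic_wpli(z[:, e * epoch_len : (e + 1) * epoch_len], spec, fs)
                for e in range(spec.n_epochs)
            ]
            result[band.name] = static_fc(np.concatenate(windows, axis=0))
        return result


def compute_fc(
    ts: RegionTimeSeries,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    spec: WindowSpec = WindowSpec(),
    trim_s: float = 1.0,
) -> dict[str, np.ndarray]:
    """Band-pass -> Hilbert -> dynamic wPLI per epoch -> static average.

    Thin functional wrapper over :class:`WPLIConnectivity`.
    """
    est = WPLIConnectivity(fs=ts.fs, bands=tuple(bands), window=spec, trim_s=trim_s)
    return est.transform_subject(ts)
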