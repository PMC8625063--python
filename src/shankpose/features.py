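"""Signal conditioning and the 100 time/frequency-domain window features.

Each window's three axes are low-pass filtered (4th-order Butterworth,
5 Hz cut-off, applied forward-backward so the result is zero-phase) and
combined into a vector-magnitude (VM) signal.  For each of the four
signals (X, Y, Z, VM) 25 features are computed:

* time domain: mean, population standard deviation, mean absolute
  deviation about the mean, maximum, minimum, signal magnitude area
  (mean absolute value), signal energy (mean squared value),
  interquartile range;
* frequency domain: lag-1 autocorrelation coefficient; the powers and
  frequencies of the 6 largest spectral peaks (strict local maxima of
  the periodogram of the mean-removed signal, zero-padded when fewer
  than 6 peaks exist); and the total power in 4 equal adjacent bands
  partitioning (0, Nyquist].

The periodogram is normalized so that its total power over (0, Nyquist]
equals the population variance of the signal; the 4 band powers
therefore sum exactly to that total.  SMA and energy are normalized by
the sample count so features are comparable across window lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .io_formats import ValidationError
from .windowing import LabeledWindow, WindowedDataset

_SIGNALS = ("x", "y", "z", "vm")
_PER_SIGNAL = (
    ["mean", "std", "mean_abs_dev", "max", "min", "sma", "energy", "iqr",
     "autocorr_lag1"]
    + [f"peak_power_{i}" for i in range(1, 7)]
    + [f"peak_freq_{i}" for i in range(1, 7)]
    + [f"band_power_{i}" for i in range(1, 5)]
)

#: Fixed registry of the 100 feature names, `<signal>_<feature>`.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{s}_{f}" for s in _SIGNALS for f in _PER_SIGNAL
)

N_PEAKS = 6
N_BANDS = 4


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth specification for signal conditioning."""

    order: int = 4
    cutoff: float = 5.0  # Hz
    sample_rate: float = 20.0  # Hz

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValidationError(f"filter order must be >= 1, got {self.order}")
        if not 0 < self.cutoff < self.sample_rate / 2:
            raise ValidationError(
                f"cutoff must lie in (0, Nyquist={self.sample_rate / 2} Hz), "
                f"got {self.cutoff}"
            )

    @property
    def min_signal_length(self) -> int:
        # filtfilt needs strictly more samples than its default pad length
        return 3 * (self.order + 1) + 1

    def coefficients(self):
        return butter(self.order, self.cutoff, btype="low", fs=self.sample_rate)


def lowpass_filter(signal: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Zero-phase low-pass filter one or more signals (last axis = time)."""
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] < spec.min_signal_length:
        raise ValidationError(
            f"signal of length {signal.shape[-1]} is too short to filter; "
            f"need at least {spec.min_signal_length} samples"
        )
    if not np.all(np.isfinite(signal)):
        raise ValidationError("non-finite value in signal")
    b, a = spec.coefficients()
    return filtfilt(b, a, signal, axis=-1)


def vector_magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of the three axes."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValidationError(
            f"axis shapes differ: {x.shape}, {y.shape}, {z.shape}"
        )
    return np.sqrt(x * x + y * y + z * z)


def periodogram(signal: np.ndarray, sample_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of the mean-removed signal (last axis = time).

    Returns ``(freqs, power)`` where ``power`` sums (over f > 0) to the
    population variance of the input.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[-1]
    centered = signal - signal.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(centered, axis=-1)
    power = np.abs(spec) ** 2 / n**2
    # fold negative frequencies into the positive half
    if n % 2 == 0:
        power[..., 1:-1] *= 2.0
    else:
        power[..., 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    return freqs, power


def _autocorr_lag1(batch: np.ndarray) -> np.ndarray:
    a = batch[..., :-1]
    b = batch[..., 1:]
    am = a - a.mean(axis=-1, keepdims=True)
    bm = b - b.mean(axis=-1, keepdims=True)
    cov = (am * bm).mean(axis=-1)
    sd_a = np.sqrt((am**2).mean(axis=-1))
    sd_b = np.sqrt((bm**2).mean(axis=-1))
    # numerically constant signals have undefined autocorrelation: report 0
    tol = 1e-9 * np.maximum(1.0, np.abs(batch).max(axis=-1))
    out = np.zeros(batch.shape[:-1])
    ok = (sd_a > tol) & (sd_b > tol)
    out[ok] = cov[ok] / (sd_a[ok] * sd_b[ok])
    return out


def _spectral_peaks(freqs: np.ndarray, power: np.ndarray):
    """Top-``N_PEAKS`` strict local maxima of each row's periodogram.

    The DC and Nyquist bins cannot be peaks; missing peaks are padded
    with zero power at zero frequency.  Returns (powers, freqs_of_peaks)
    with powers sorted descending.
    """
    p = np.atleast_2d(power)
    n_rows, n_bins = p.shape
    is_peak = np.zeros_like(p, dtype=bool)
    if n_bins >= 3:
        interior = (p[:, 1:-1] > p[:, :-2]) & (p[:, 1:-1] > p[:, 2:])
        is_peak[:, 1:-1] = interior
    masked = np.where(is_peak, p, -np.inf)
    order = np.argsort(-masked, axis=1, kind="stable")[:, :N_PEAKS]
    peak_p = np.take_along_axis(masked, order, axis=1)
    peak_f = freqs[order]
    pad = ~np.isfinite(peak_p)
    peak_p[pad] = 0.0
    peak_f[pad] = 0.0
    if peak_p.shape[1] < N_PEAKS:  # very short windows: fewer bins than peaks
        extra = N_PEAKS - peak_p.shape[1]
        peak_p = np.pad(peak_p, ((0, 0), (0, extra)))
        peak_f = np.pad(peak_f, ((0, 0), (0, extra)))
    return peak_p, peak_f


def _band_powers(freqs: np.ndarray, power: np.ndarray, sample_rate: float) -> np.ndarray:
    """Total periodogram power in 4 equal adjacent bands over (0, Nyquist]."""
    nyq = sample_rate / 2.0
    edges = np.linspace(0.0, nyq, N_BANDS + 1)
    p = np.atleast_2d(power)
    out = np.empty((p.shape[0], N_BANDS))
    for i in range(N_BANDS):
        mask = (freqs > edges[i] + 1e-12) & (freqs <= edges[i + 1] + 1e-12)
        out[:, i] = p[:, mask].sum(axis=1)
    return out


def _signal_features(batch: np.ndarray, sample_rate: float) -> np.ndarray:
    """25 features per row of a (n_windows, n_samples) signal batch."""
    mean = batch.mean(axis=-1)
    std = batch.std(axis=-1)  # population
    mad = np.abs(batch - mean[..., None]).mean(axis=-1)
    mx = batch.max(axis=-1)
    mn = batch.min(axis=-1)
    sma = np.abs(batch).mean(axis=-1)
    energy = (batch**2).mean(axis=-1)
    q75, q25 = np.percentile(batch, [75, 25], axis=-1)
    iqr = q75 - q25
    ac1 = _autocorr_lag1(batch)
    freqs, power = periodogram(batch, sample_rate)
    peak_p, peak_f = _spectral_peaks(freqs, np.atleast_2d(power))
    bands = _band_powers(freqs, np.atleast_2d(power), sample_rate)
    time_part = np.stack([mean, std, mad, mx, mn, sma, energy, iqr, ac1], axis=-1)
    return np.concatenate([np.atleast_2d(time_part), peak_p, peak_f, bands], axis=-1)


def _featurize_batch(samples: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Compute the 100 features for a (n_windows, n_samples, 3) batch."""
    if not np.all(np.isfinite(samples)):
        raise ValidationError("non-finite sample in window batch")
    fx = lowpass_filter(samples[..., 0], spec)
    fy = lowpass_filter(samples[..., 1], spec)
    fz = lowpass_filter(samples[..., 2], spec)
    vm = vector_magnitude(fx, fy, fz)
    parts = [_signal_features(s, spec.sample_rate) for s in (fx, fy, fz, vm)]
    return np.concatenate(parts, axis=-1)


def compute_features(window: LabeledWindow, spec: FilterSpec | None = None) -> pd.Series:
    """The 100 named features of one labelled window."""
    if spec is None:
        spec = FilterSpec()
    values = _featurize_batch(window.samples[None, :, :], spec)[0]
    return pd.Series(values, index=list(FEATURE_NAMES))


def featurize_dataset(
    dataset: WindowedDataset, spec: FilterSpec | None = None
) -> pd.DataFrame:
    """One feature row per window, plus label and provenance columns."""
    if len(dataset) == 0:
        raise ValidationError("cannot featurize an empty dataset")
    if spec is None:
        spec = FilterSpec(sample_rate=dataset.sample_rate)
    samples = np.stack([w.samples for w in dataset.windows])
    try:
        values = _featurize_batch(samples, spec)
    except ValidationError as exc:
        # locate the offending window for a useful message
        for w in dataset.windows:
            if not np.all(np.isfinite(w.samples)):
                raise ValidationError(
                    f"window starting at {w.start} s: non-finite sample"
                ) from exc
        raise
    df = pd.DataFrame(values, columns=list(FEATURE_NAMES))
    df["label"] = [w.label for w in dataset.windows]
    df["window_start_s"] = [w.start for w in dataset.windows]
    df["window_length_s"] = dataset.window_length
    df["subject_id"] = [w.subject_id for w in dataset.windows]
    return df
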