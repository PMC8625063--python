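"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the vectorized/FFT code paths of the package:
scalar statistics are computed with plain Python arithmetic, the
discrete Fourier transform by direct summation per frequency bin, and
window extraction by exhaustive enumeration of candidate starts with
containment testing.
"""

import math

import numpy as np


def naive_percentile(values, q):
    """Linear-interpolation percentile on the sorted sample."""
    s = sorted(float(v) for v in values)
    if len(s) == 1:
        return s[0]
    pos = q / 100.0 * (len(s) - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def naive_periodogram(sig, fs):
    """Direct-summation one-sided periodogram of the mean-removed signal."""
    n = len(sig)
    mean = sum(sig) / n
    c = np.asarray([v - mean for v in sig])
    j = np.arange(n)
    freqs, powers = [], []
    for k in range(n // 2 + 1):
        ang = 2 * math.pi * k * j / n
        re = float(np.sum(c * np.cos(ang)))
        im = float(-np.sum(c * np.sin(ang)))
        p = (re * re + im * im) / n**2
        if 0 < k and not (n % 2 == 0 and k == n // 2):
            p *= 2.0
        freqs.append(k * fs / n)
        powers.append(p)
    return freqs, powers


def naive_signal_features(sig, fs, n_peaks=6, n_bands=4):
    """The 25 per-signal features by brute force, in registry order."""
    sig = [float(v) for v in sig]
    n = len(sig)
    mean = sum(sig) / n
    std = math.sqrt(sum((v - mean) ** 2 for v in sig) / n)
    mad = sum(abs(v - mean) for v in sig) / n
    mx = max(sig)
    mn = min(sig)
    sma = sum(abs(v) for v in sig) / n
    energy = sum(v * v for v in sig) / n
    iqr = naive_percentile(sig, 75) - naive_percentile(sig, 25)

    a = sig[:-1]
    b = sig[1:]
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / len(a)
    va = sum((x - ma) ** 2 for x in a) / len(a)
    vb = sum((y - mb) ** 2 for y in b) / len(b)
    ac1 = cov / math.sqrt(va * vb) if va > 0 and vb > 0 else 0.0

    freqs, powers = naive_periodogram(sig, fs)
    k_last = len(powers) - 1
    peaks = []
    for k in range(1, len(powers) - 1):
        if k == k_last:
            continue
        if powers[k] > powers[k - 1] and powers[k] > powers[k + 1]:
            peaks.append((powers[k], freqs[k], k))
    peaks.sort(key=lambda t: (-t[0], t[2]))
    peak_p = [p for p, _, _ in peaks[:n_peaks]]
    peak_f = [f for _, f, _ in peaks[:n_peaks]]
    while len(peak_p) < n_peaks:
        peak_p.append(0.0)
        peak_f.append(0.0)

    nyq = fs / 2.0
    bands = [0.0] * n_bands
    for f, p in zip(freqs, powers):
        if f <= 1e-12:
            continue
        for i in range(n_bands):
            lo = nyq * i / n_bands
            hi = nyq * (i + 1) / n_bands
            if lo + 1e-12 < f <= hi + 1e-12:
                bands[i] += p
                break
    return (
        [mean, std, mad, mx, mn, sma, energy, iqr, ac1]
        + peak_p
        + peak_f
        + bands
    )


def enumerate_windows(events, recording_duration, length, overlap=0.5, tol=1e-9):
    """All (start, label) pairs kept by exhaustive candidate enumeration."""
    step = length * (1.0 - overlap)
    out = []
    i = 0
    while i * step + length <= recording_duration + tol:
        s = i * step
        i += 1
        for ev in events:
            if ev.start <= s + tol and s + length <= ev.end + tol:
                out.append((s, ev.code))
                break
    return out
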