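"""Spectral quality metrics: squared FFT amplitudes and the index of dispersion.

Per channel, the squared single-sided FFT amplitude ``A²(f)`` is computed on
0-65 Hz, normalized so a pure sinusoid of amplitude *a* contributes *a²* at its
bin. Band means average ``A²(f)`` over a 2 Hz span around every integer center
frequency 1-64 Hz (half-open ``[c-1, c+1)``). The index of dispersion — the
across-electrode variance of a band mean divided by its across-electrode mean —
is the spatial-inhomogeneity statistic: it is zero when all electrodes carry
the same power and grows with topographic structure, and it scales linearly
with an overall gain applied to all electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import EEGRecording, EpochedEEG

__all__ = [
    "SpectralSummary", "DispersionCurve", "fft_sq_amplitude", "band_means",
    "band_mean_range", "index_of_dispersion", "dispersion_curve",
]


@dataclass
class SpectralSummary:
    """Per-channel squared FFT amplitudes and 2 Hz band means (μV²)."""
    channels: list[str]
    freqs: np.ndarray                    # Hz grid, <= fmax
    a2: np.ndarray                       # (n_channels, n_freqs), μV²
    band_centers: np.ndarray = field(default_factory=lambda: np.array([]))
    band_means: np.ndarray = field(default_factory=lambda: np.array([]))
    n_segments: int = 1

    def __post_init__(self):
        if np.any(self.a2 < 0):
            raise ValueError("squared amplitudes must be non-negative")


@dataclass
class DispersionCurve:
    """Index of dispersion per band center frequency (μV²)."""
    band_centers: np.ndarray
    dispersion: np.ndarray
    condition_tag: str | None = None

    def __post_init__(self):
        if np.any(self.dispersion < -1e-12):
            raise ValueError("dispersion must be non-negative")


def _a2_segment(seg: np.ndarray, fs: float, window: str) -> tuple[np.ndarray,
                                                                  np.ndarray]:
    """Single-sided squared amplitude spectrum of one (ch, n) segment."""
    n = seg.shape[1]
    if window == "hann":
        w = np.hanning(n)
    elif window == "rect":
        w = np.ones(n)
    else:
        raise ValueError(f"unknown window {window!r}")
    spec = np.fft.rfft(seg * w[None, :], axis=1)
    amp = 2.0 * np.abs(spec) / w.sum()   # coherent-gain normalization
    amp[:, 0] /= 2.0                     # DC is not doubled
    if n % 2 == 0:
        amp[:, -1] /= 2.0                # neither is Nyquist
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return freqs, amp ** 2


def fft_sq_amplitude(data, fs: float | None = None, fmax: float = 65.0,
                     window: str = "hann", seg_seconds: float = 2.0,
                     channels: list[str] | None = None) -> SpectralSummary:
    """Squared FFT amplitudes ``A²(f)`` up to ``fmax`` Hz.

    ``data`` may be an :class:`EEGRecording` or continuous (ch, n) array —
    averaged over tapered ``seg_seconds`` windows with 50% overlap — or an
    :class:`EpochedEEG`, in which case ``A²`` is computed per epoch and
    averaged over epochs.
    """
    if isinstance(data, EpochedEEG):
        fs = data.fs
        epochs = data.data
        labels = data.labels or [f"ch{i:02d}" for i in range(epochs.shape[1])]
        total = None
        for ep in epochs:
            freqs, a2 = _a2_segment(ep, fs, window)
            total = a2 if total is None else total + a2
        a2 = total / epochs.shape[0]
        n_seg = epochs.shape[0]
    else:
        if isinstance(data, EEGRecording):
            fs = data.fs
            labels = data.labels
            arr = data.data
        else:
            if fs is None:
                raise ValueError("fs is required for array input")
            arr = np.atleast_2d(np.asarray(data, float))
            labels = channels or [f"ch{i:02d}" for i in range(arr.shape[0])]
        nseg = int(round(seg_seconds * fs))
        if arr.shape[1] < nseg:
            raise ValueError(
                f"segment of {arr.shape[1]} samples is shorter than one "
                f"{seg_seconds} s window")
        step = nseg // 2
        starts = range(0, arr.shape[1] - nseg + 1, step)
        total, n_seg = None, 0
        for s in starts:
            freqs, a2 = _a2_segment(arr[:, s:s + nseg], fs, window)
            total = a2 if total is None else total + a2
            n_seg += 1
        a2 = total / n_seg
    keep = freqs <= fmax
    return SpectralSummary(channels=list(labels), freqs=freqs[keep],
                           a2=a2[:, keep], n_segments=n_seg)


def band_means(spec: SpectralSummary, centers=None) -> SpectralSummary:
    """Mean ``A²`` over a 2 Hz span around each integer center frequency.

    The span is half-open: center ``c`` averages bins with ``f in [c-1, c+1)``.
    """
    if spec.a2.size == 0:
        raise ValueError("a2 is not populated")
    centers = np.arange(1, 65) if centers is None else np.asarray(centers)
    means = np.empty((spec.a2.shape[0], centers.size))
    for j, c in enumerate(centers):
        sel = (spec.freqs >= c - 1) & (spec.freqs < c + 1)
        if not sel.any():
            raise ValueError(
                f"no frequency bins in band [{c - 1}, {c + 1}); "
                "frequency resolution too coarse")
        means[:, j] = spec.a2[:, sel].mean(axis=1)
    spec.band_centers = centers
    spec.band_means = means
    return spec


def band_mean_range(spec: SpectralSummary, lo: float = 15.0, hi: float = 25.0,
                    ) -> np.ndarray:
    """Per-channel mean of the band means over centers ``lo..hi`` inclusive."""
    if spec.band_means.size == 0:
        band_means(spec)
    sel = (spec.band_centers >= lo) & (spec.band_centers <= hi)
    if not sel.any():
        raise ValueError(f"band centers do not cover [{lo}, {hi}]")
    return spec.band_means[:, sel].mean(axis=1)


def index_of_dispersion(values: np.ndarray) -> float:
    """Across-electrode variance (n-1 denominator) divided by the mean."""
    values = np.asarray(values, float)
    mean = values.mean()
    if mean <= 0:
        raise ValueError("index of dispersion undefined for mean <= 0")
    if values.size < 2:
        raise ValueError("need at least 2 electrodes")
    return float(values.var(ddof=1) / mean)


def dispersion_curve(spec: SpectralSummary, condition_tag: str | None = None,
                     ) -> DispersionCurve:
    """Index of dispersion at every band center frequency."""
    if spec.band_means.size == 0:
        band_means(spec)
    disp = np.array([index_of_dispersion(spec.band_means[:, j])
                     for j in range(spec.band_centers.size)])
    return DispersionCurve(band_centers=spec.band_centers.copy(),
                           dispersion=disp, condition_tag=condition_tag)
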