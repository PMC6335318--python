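"""EEG preprocessing chain for simultaneous EEG-fMRI recordings.

The pipeline order is the conventional one for MR-contaminated EEG:

1. :func:`aas_correct` — average-artifact subtraction of the gradient
   artifact, using a sliding mean template over TR-locked epochs;
2. :func:`resample` — polyphase resampling (default 500 Hz);
3. :func:`bandpass` — zero-phase 2nd-order Butterworth, 0.5-30 Hz;
4. :func:`detect_qrs` — R-peak detection from an ECG channel or from an
   ICA component with maximal cardiac periodicity;
5. :func:`pulse_subtract` — Gaussian-weighted mean-template subtraction of
   the ballistocardiogram artifact;
6. :func:`interpolate_bad_channels`, :func:`rereference_average`,
   :func:`epoch_and_baseline`.

Stages whose artifact is absent (no ``tr_onset`` events, no detectable pulse)
simply do not apply; :func:`clean_pipeline` skips them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .recording import EEGRecording, EpochedEEG, Event

__all__ = [
    "aas_correct", "detect_qrs", "pulse_subtract", "resample", "bandpass",
    "interpolate_bad_channels", "rereference_average", "epoch_and_baseline",
    "clean_pipeline", "QRSDetection", "AlignmentError", "DetectionError",
]

log = logging.getLogger("eegfmriqc")

_MIN_RR_S = 60.0 / 110.0  # minimal credible RR interval (HR < 110 bpm)


class AlignmentError(ValueError):
    """TR onsets are not equidistant within the clock-sync tolerance."""


class DetectionError(RuntimeError):
    """QRS detection failed; supply an ECG channel or a manual threshold."""


# ---------------------------------------------------------------------------
# gradient artifact
# ---------------------------------------------------------------------------

def aas_correct(rec: EEGRecording, epochs_per_average: int = 25,
                ) -> EEGRecording:
    """Average-artifact subtraction of the TR-periodic gradient artifact.

    For every channel and TR epoch, the mean of the ``epochs_per_average``
    nearest TR epochs (a sliding window centered on the current epoch,
    truncated at the recording edges) is subtracted. Samples outside any TR
    epoch are left unchanged. Requires hardware clock synchronization: the
    inter-onset interval must be constant to within one sample.
    """
    onsets = rec.event_latencies("tr_onset")
    if onsets.size < 3:
        raise ValueError("need at least 3 tr_onset events for AAS")
    intervals = np.diff(onsets)
    d = int(np.median(intervals))
    if np.any(np.abs(intervals - d) > 1):
        raise AlignmentError(
            "tr_onset intervals vary by more than one sample; "
            "clock synchronization assumption violated")
    onsets = onsets[onsets + d <= rec.n_samples]
    n_ep = onsets.size
    if n_ep < epochs_per_average:
        warnings.warn(
            f"only {n_ep} TR epochs available; AAS window shrinks from "
            f"{epochs_per_average}", stacklevel=2)
        if n_ep < 3:
            raise ValueError("fewer than 3 TR epochs; cannot build a template")

    half = epochs_per_average // 2
    epochs = np.stack([rec.data[:, s:s + d] for s in onsets], axis=0)
    out = rec.data.copy()
    for i, s in enumerate(onsets):
        # sliding window over the epoch axis, truncated at the edges
        lo, hi = max(0, i - half), min(n_ep - 1, i + half)
        template = epochs[lo:hi + 1].mean(axis=0)
        out[:, s:s + d] = rec.data[:, s:s + d] - template
    return rec.copy_with(data=out)


# ---------------------------------------------------------------------------
# QRS detection
# ---------------------------------------------------------------------------

@dataclass
class QRSDetection:
    """Detected R-peak latencies plus the evidence behind them."""
    peak_latencies: np.ndarray          # samples, sorted
    component_scores: np.ndarray        # cardiac-periodicity score per IC
    min_distance_s: float = _MIN_RR_S
    prominence_threshold: float = 0.0
    source: str = "ecg"                 # "ecg" or "ica"

    def times(self, fs: float) -> np.ndarray:
        return self.peak_latencies / fs


def _cardiac_periodicity(x: np.ndarray, fs: float) -> float:
    """Max normalized autocorrelation over physiological RR lags."""
    x = x - x.mean()
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    if ac[0] <= 0:
        return 0.0
    ac = ac / ac[0]
    lo = int(_MIN_RR_S * fs)
    hi = min(int(1.5 * fs), n - 1)
    if hi <= lo:
        return 0.0
    return float(ac[lo:hi].max())


def _otsu_threshold(values: np.ndarray) -> float:
    """Valley of a two-class split of the value histogram (Otsu)."""
    from skimage.filters import threshold_otsu

    if values.size < 3 or np.ptp(values) == 0:
        return values.min() if values.size else 0.0
    return float(threshold_otsu(values, nbins=64))


def _find_r_peaks(sig_1d: np.ndarray, fs: float,
                  prominence: float | None) -> tuple[np.ndarray, float]:
    """Min-distance peak search plus automatic prominence split."""
    from scipy.stats import skew

    if skew(sig_1d) < 0:
        sig_1d = -sig_1d  # polarity so that R deflections point up
    distance = max(1, int(round(_MIN_RR_S * fs)))
    peaks, props = signal.find_peaks(sig_1d, distance=distance, prominence=0.0)
    if peaks.size == 0:
        return peaks, 0.0
    prom = props["prominences"]
    if prominence is None:
        # automatic replacement for a supervised histogram threshold:
        # two-class (Otsu) split of the log prominences, accepted only when
        # the classes are genuinely separated — with no low-prominence noise
        # candidates the split would otherwise halve the beat distribution
        logp = np.log(prom + 1e-12)
        thr = _otsu_threshold(logp)
        lo, hi = logp[logp < thr], logp[logp >= thr]
        # accept the split only when the classes sit far apart on the log
        # scale (noise vs QRS differ by orders of magnitude; beat-to-beat
        # amplitude jitter does not)
        if lo.size and hi.size and hi.mean() - lo.mean() >= 1.0:
            prominence = float(np.exp(thr))
        else:
            prominence = float(prom.min())
    keep = prom >= prominence
    return peaks[keep], float(prominence)


def detect_qrs(rec: EEGRecording, ecg: str | None = None,
               n_components: int = 20, prominence: float | None = None,
               seed: int = 0) -> QRSDetection:
    """Detect R-peak latencies from the ECG channel or via ICA.

    The recording should already be gradient-corrected and bandpass-filtered.
    Without an ECG channel, the EEG is decomposed with FastICA, each component
    is scored by its cardiac periodicity (max normalized autocorrelation over
    lags 60/110-1.5 s) and the top component provides the detection signal.
    Candidate peaks keep a minimal distance of 60/110 s; the prominence
    threshold is the two-class (Otsu) split of the log-prominence histogram
    unless given explicitly.
    """
    if ecg is not None:
        if ecg in rec.aux:
            det_sig = np.asarray(rec.aux[ecg], float)
        elif ecg in rec.labels:
            det_sig = rec.channel(ecg)
        else:
            raise KeyError(f"no ECG channel named {ecg!r}")
        scores = np.array([])
        source = "ecg"
    else:
        from sklearn.decomposition import FastICA

        n_comp = min(n_components, rec.n_channels)
        ica = FastICA(n_components=n_comp, random_state=seed, max_iter=500,
                      tol=1e-3, whiten="unit-variance")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sources = ica.fit_transform(rec.data.T).T
        scores = np.array([_cardiac_periodicity(s, rec.fs) for s in sources])
        if scores.max() < 0.1:
            raise DetectionError(
                "no independent component shows cardiac periodicity and no "
                "ECG channel was supplied; pass `prominence` and an explicit "
                "detection channel to override")
        det_sig = sources[int(np.argmax(scores))]
        source = "ica"

    peaks, thr = _find_r_peaks(det_sig, rec.fs, prominence)
    return QRSDetection(peak_latencies=peaks, component_scores=scores,
                        prominence_threshold=thr, source=source)


# ---------------------------------------------------------------------------
# pulse artifact
# ---------------------------------------------------------------------------

def pulse_subtract(rec: EEGRecording, peaks: QRSDetection | np.ndarray,
                   n_neighbors: int = 20, gaussian_sd_epochs: float = 5.0,
                   ) -> EEGRecording:
    """Subtract a Gaussian-weighted mean pulse-artifact template per beat.

    The artifact epoch around peak ``i`` spans ``[-0.25, +0.75] * median RR``.
    Its template is the weighted mean of the ``n_neighbors`` nearest epochs
    ``j`` with weights ``exp(-(i-j)^2 / (2 sd^2))``; overlapping epochs are
    resolved by processing peaks in order (each sample corrected once).
    """
    lat = peaks.peak_latencies if isinstance(peaks, QRSDetection) else \
        np.asarray(peaks, int)
    lat = np.sort(lat)
    if lat.size < 3:
        raise ValueError("need at least 3 R peaks for template subtraction")
    rr_med = float(np.median(np.diff(lat)))
    pre = int(round(0.25 * rr_med))
    post = int(round(0.75 * rr_med))
    length = pre + post

    valid, starts = [], []
    for i, p in enumerate(lat):
        s = p - pre
        if s < 0 or s + length > rec.n_samples:
            warnings.warn(f"pulse epoch at peak {p} exceeds recording bounds; "
                          "skipped", stacklevel=2)
            continue
        valid.append(i)
        starts.append(s)
    if len(valid) < 3:
        raise ValueError("fewer than 3 complete pulse epochs")
    starts = np.array(starts)
    epochs = np.stack([rec.data[:, s:s + length] for s in starts], axis=0)

    n_ep = len(valid)
    out = rec.data.copy()
    last_end = -1
    for k in range(n_ep):
        order = np.argsort(np.abs(np.arange(n_ep) - k), kind="stable")
        nbr = np.sort(order[:min(n_neighbors, n_ep)])
        w = np.exp(-((nbr - k) ** 2) / (2.0 * gaussian_sd_epochs ** 2))
        template = np.tensordot(w, epochs[nbr], axes=(0, 0)) / w.sum()
        s, e = starts[k], starts[k] + length
        lo = max(s, last_end)
        out[:, lo:e] -= template[:, lo - s:]
        last_end = e
    return rec.copy_with(data=out)


# ---------------------------------------------------------------------------
# resample / filter / reference / epoch
# ---------------------------------------------------------------------------

def resample(rec: EEGRecording, target_fs: float = 500.0) -> EEGRecording:
    """Polyphase anti-aliased resampling; event latencies are rescaled."""
    if target_fs > rec.fs:
        raise ValueError("upsampling is not supported")
    if target_fs == rec.fs:
        return rec.copy_with()
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    if abs(float(frac) - target_fs / rec.fs) > 1e-9:
        raise ValueError("sampling-rate ratio is not a usable rational number")
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(rec.data, up, down, axis=1)
    ratio = target_fs / rec.fs
    n_new = data.shape[1]
    events = [Event(min(int(round(e.latency * ratio)), n_new - 1), e.label)
              for e in rec.events]
    aux = {k: signal.resample_poly(v, up, down) for k, v in rec.aux.items()}
    return rec.copy_with(data=data, fs=target_fs, events=events, aux=aux)


def bandpass(rec: EEGRecording, low: float = 0.5, high: float = 30.0,
             order: int = 2) -> EEGRecording:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    if low >= high:
        raise ValueError("low cutoff must be below high cutoff")
    if high >= rec.fs / 2:
        raise ValueError("high cutoff must be below Nyquist")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs,
                        output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    # aux channels (ECG) are not EEG: left unfiltered so QRS spikes keep
    # their shape and timing for the detector
    return rec.copy_with(data=data)


def interpolate_bad_channels(rec: EEGRecording, bad: list[str]) -> EEGRecording:
    """Replace bad channels by inverse-distance-weighted means of good ones.

    Weights are ``1 / d^2`` with ``d`` the great-circle distance on the unit
    sphere; a bad channel coincident with a good electrode copies its signal.
    """
    labels = rec.labels
    unknown = [b for b in bad if b not in labels]
    if unknown:
        raise KeyError(f"bad channels not in montage: {unknown}")
    good = [l for l in labels if l not in set(bad)]
    if len(good) < 4:
        raise ValueError("need at least 4 good channels to interpolate")
    pos = rec.montage.positions
    out = rec.data.copy()
    good_idx = [labels.index(g) for g in good]
    for b in bad:
        bi = labels.index(b)
        cosang = np.clip(pos[good_idx] @ pos[bi], -1.0, 1.0)
        dist = np.arccos(cosang)
        if np.any(dist < 1e-9):
            out[bi] = rec.data[good_idx[int(np.argmin(dist))]]
            continue
        w = 1.0 / dist ** 2
        out[bi] = (w @ rec.data[good_idx]) / w.sum()
    return rec.copy_with(data=out)


def rereference_average(rec: EEGRecording, subset: list[str] | None = None,
                        ) -> EEGRecording:
    """Subtract the per-sample mean over ``subset`` (default: all channels)."""
    labels = rec.labels
    subset = subset or labels
    if not subset:
        raise ValueError("reference subset must be non-empty")
    idx = [labels.index(s) for s in subset]
    ref = rec.data[idx].mean(axis=0)
    return rec.copy_with(data=rec.data - ref, reference="average")


def epoch_and_baseline(rec: EEGRecording, event_label: str = "stimulus",
                       window: tuple[float, float] = (-0.8, 1.8),
                       baseline: tuple[float, float] = (-0.8, -0.6),
                       ) -> EpochedEEG:
    """Cut half-open ``[start, end)`` windows around events, baseline-correct.

    Epochs whose window exceeds the recording are dropped (count logged).
    """
    w0, w1 = window
    i0 = int(round(w0 * rec.fs))
    n_win = int(round((w1 - w0) * rec.fs))
    latencies = rec.event_latencies(event_label)
    kept, dropped = [], 0
    for lat in latencies:
        s = lat + i0
        if s < 0 or s + n_win > rec.n_samples:
            dropped += 1
            continue
        kept.append(rec.data[:, s:s + n_win])
    if dropped:
        log.info("epoch_and_baseline: dropped %d/%d epochs outside bounds",
                 dropped, latencies.size)
    if not kept:
        raise ValueError(f"no complete epochs for event {event_label!r}")
    data = np.stack(kept, axis=0)
    ep = EpochedEEG(data=data, window=window, baseline=baseline, fs=rec.fs,
                    labels=rec.labels)
    bl = ep.baseline_slice()
    ep.data = ep.data - ep.data[:, :, bl].mean(axis=2, keepdims=True)
    return ep


def clean_pipeline(rec: EEGRecording, epochs_per_average: int = 25,
                   target_fs: float = 500.0, band=(0.5, 30.0),
                   ecg: str | None = "ECG", bad: list[str] | None = None,
                   pulse: bool = True, seed: int = 0) -> EEGRecording:
    """Full cleaning chain; stages without their artifact are skipped."""
    if rec.event_latencies("tr_onset").size >= 3:
        rec = aas_correct(rec, epochs_per_average)
    rec = resample(rec, target_fs)
    rec = bandpass(rec, *band)
    if pulse and rec.condition_tag in (None, "pre_acquisition", "simultaneous"):
        try:
            ecg_name = ecg if (ecg in rec.aux or ecg in rec.labels) else None
            det = detect_qrs(rec, ecg=ecg_name, seed=seed)
            if det.peak_latencies.size >= 3:
                rec = pulse_subtract(rec, det)
        except DetectionError:
            log.warning("pulse stage skipped: no cardiac signal detected")
    if bad:
        rec = interpolate_bad_channels(rec, bad)
    rec = rereference_average(rec)
    return rec
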