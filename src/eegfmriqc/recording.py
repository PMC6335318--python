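"""Core in-memory containers: EEG recordings, epoched EEG, fMRI volume series.

Conventions used everywhere in the package:

* EEG amplitudes are in microvolts (μV); readers convert on load.
* Event latencies are 0-based sample indices.
* Time windows are half-open ``[start, end)`` in seconds relative to an event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Event", "EEGRecording", "EpochedEEG", "VolumeSeries", "MotionParams",
    "EVENT_LABELS",
]

#: canonical event labels; anything else is carried through as "custom"
EVENT_LABELS = ("tr_onset", "stimulus", "r_peak", "custom")


@dataclass(frozen=True)
class Event:
    latency: int          # 0-based sample index
    label: str

    def __iter__(self):
        return iter((self.latency, self.label))


@dataclass
class EEGRecording:
    """Multichannel EEG time series with events and montage.

    Parameters
    ----------
    data : (n_channels, n_samples) ndarray, μV
    fs : float, Hz
    events : list of Event
    montage : Montage
        Channel order of ``data`` follows ``montage.labels``.
    reference : str
        Electrode label or ``"average"``.
    condition_tag : str or None
        One of ``separate``, ``outside``, ``pre_acquisition``, ``simultaneous``.
    aux : dict
        Non-EEG channels by name (e.g. ``"ECG"``), each (n_samples,) μV.
    """

    data: np.ndarray
    fs: float
    events: list[Event] = field(default_factory=list)
    montage: object = None
    reference: str = "unknown"
    condition_tag: str | None = None
    aux: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = self.n_samples
        self.events = [Event(int(lat), str(lab)) for lat, lab in self.events]
        for ev in self.events:
            if not 0 <= ev.latency < n:
                raise ValueError(f"event latency {ev.latency} outside [0, {n})")
        if self.montage is not None and self.montage.n_channels != self.n_channels:
            raise ValueError("montage/channel count mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def labels(self) -> list[str]:
        if self.montage is not None:
            return list(self.montage.labels)
        return [f"ch{i:02d}" for i in range(self.n_channels)]

    def event_latencies(self, label: str) -> np.ndarray:
        """Sorted 0-based latencies of events with the given label."""
        lat = np.array([e.latency for e in self.events if e.label == label], int)
        return np.sort(lat)

    def copy_with(self, **kw) -> "EEGRecording":
        if "data" in kw:
            kw.setdefault("aux", dict(self.aux))
        return replace(self, **kw)

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]


@dataclass
class EpochedEEG:
    """Stimulus-locked epochs (epochs × channels × samples, μV)."""

    data: np.ndarray
    window: tuple[float, float]      # seconds relative to event, half-open
    baseline: tuple[float, float]    # ⊆ window
    fs: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        w0, w1 = self.window
        b0, b1 = self.baseline
        if not (w0 <= b0 and b1 <= w1):
            raise ValueError("baseline interval must lie inside the window")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def baseline_slice(self) -> slice:
        w0, _ = self.window
        b0, b1 = self.baseline
        i0 = int(round((b0 - w0) * self.fs))
        i1 = int(round((b1 - w0) * self.fs))
        return slice(i0, i1)


@dataclass
class VolumeSeries:
    """4D fMRI series (x × y × z × t, arbitrary MR units) with TR and affine."""

    data: np.ndarray
    tr: float
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected a 4D series, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 volumes")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape mismatch")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm from the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class MotionParams:
    """Per-volume rigid-body parameters: 3 translations (mm) + 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("params must be (n_volumes, 6)")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]
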