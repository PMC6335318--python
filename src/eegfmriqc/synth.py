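"""Synthetic EEG-fMRI sessions with known ground truth.

The generator emulates the four recording conditions of a combined EEG-fMRI
quality study:

* ``separate`` — EEG recorded outside the scanner room, no MR artifacts;
* ``outside`` — EEG with the MR-compatible system, still outside the bore;
* ``pre_acquisition`` — inside the bore, static field only: ballistocardiogram
  (pulse) artifact present, no gradient artifact;
* ``simultaneous`` — scanning: gradient artifact (TR-periodic, orders of
  magnitude above EEG) plus pulse artifact.

EEG = 1/f background + narrow-band rhythms + 50 Hz line noise + a 15-25 Hz
band-limited component whose per-channel gain carries the condition-dependent
left-right/amplifier inhomogeneity + optional gradient and pulse artifacts.
Everything injected is recorded in a :class:`SessionGroundTruth` so that every
downstream corrector and statistic can be scored without external data.

fMRI phantoms are concentric-ellipsoid tissue compartments (CSF core, WM,
GM shell) with linear drift and tissue/region-specific Gaussian noise, so the
true TSNR field (baseline / noise sd) is known exactly per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage, standard_montage
from .recording import EEGRecording, Event, MotionParams, VolumeSeries

__all__ = [
    "EEGSimParams", "GradientSpec", "PulseSpec", "SessionGroundTruth",
    "generate_eeg_session", "generate_fmri_session", "condition_params",
    "condition_band_gain", "CONDITIONS",
]

CONDITIONS = ("separate", "outside", "pre_acquisition", "simultaneous")

_MIN_RR = 60.0 / 110.0  # detector assumption: heart rate below 110 bpm


@dataclass
class GradientSpec:
    """MR gradient artifact: harmonics of the slice frequency, TR-periodic."""
    tr: float = 2.0                # s
    n_slices: int = 36
    amplitude: float = 1000.0      # RMS μV (order of magnitude above EEG)
    drift_per_minute: float = 0.01  # slow fractional amplitude drift


@dataclass
class PulseSpec:
    """Ballistocardiogram artifact locked to QRS complexes."""
    hr_bpm: float = 65.0
    hr_sd_bpm: float = 3.0
    scale_uv: float = 30.0         # peak template amplitude, μV
    jitter: float = 0.05           # epoch-to-epoch amplitude jitter fraction


@dataclass
class EEGSimParams:
    """Parameters of one synthetic EEG session."""
    montage: Montage = None
    fs: float = 5000.0             # Hz
    duration: float = 120.0        # s
    background_exponent: float = 1.0
    background_rms: float = 10.0   # μV
    rhythms: tuple = ((10.0, 2.0, 3.0), (20.0, 10.0, 1.5))  # (center, bw, RMS μV)
    line_noise_freq: float = 50.0
    line_noise_uv: float = 1.0
    gradient: GradientSpec | None = None
    pulse: PulseSpec | None = None
    condition_gain: np.ndarray | None = None  # per-channel gain on 15-25 Hz comp.
    condition_tag: str | None = None
    seed: int = 0
    keep_clean: bool = True

    def __post_init__(self):
        if self.montage is None:
            self.montage = standard_montage()
        if self.pulse is not None and self.pulse.hr_bpm >= 110:
            raise ValueError("mean heart rate must stay below 110 bpm")
        if self.gradient is not None:
            if self.gradient.amplitude < 10 * self.background_rms:
                raise ValueError("gradient amplitude must be >= 10x background RMS")
            if self.duration < 2 * self.gradient.tr:
                raise ValueError("duration too short for 2 TRs of gradient artifact")


@dataclass
class SessionGroundTruth:
    """Everything injected into a synthetic session, for recovery scoring."""
    r_peak_times: np.ndarray | None = None       # s
    tr_onset_samples: np.ndarray | None = None
    gradient_template: np.ndarray | None = None  # (n_ch, samples per TR)
    pulse_template: np.ndarray | None = None     # (n_ch, template samples)
    pulse_template_offset: int = 0               # samples before the R peak
    injected_band_gain: np.ndarray | None = None
    clean_data: np.ndarray | None = None         # neural-only signal, μV
    true_tsnr: np.ndarray | None = None          # voxelwise baseline/sd
    true_motion: MotionParams | None = None
    noise_sd: np.ndarray | None = None


# ---------------------------------------------------------------------------
# EEG pieces
# ---------------------------------------------------------------------------

def _one_over_f(rng, n, fs, exponent, rms):
    """Spectrally shaped Gaussian noise with power ~ 1/f**exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    shape = np.ones_like(f)
    nz = f >= 1.0  # flatten below 1 Hz to keep the variance finite
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _band_noise(rng, n, fs, center, bw, rms):
    """Band-limited Gaussian noise (hard band [center-bw/2, center+bw/2])."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    keep = (f >= center - bw / 2) & (f <= center + bw / 2)
    spec[~keep] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _pulse_template(fs, rr_s, scale_uv=1.0):
    """Three-Gaussian BCG template on [-0.2, +0.6] s, peak (=R) at tau 0."""
    offset = int(round(0.2 * fs))
    tau = (np.arange(-offset, int(round(0.6 * fs)) + 1)) / fs
    h = (np.exp(-0.5 * (tau / 0.02) ** 2)
         + 0.35 * np.exp(-0.5 * ((tau - 0.25) / 0.06) ** 2)
         - 0.25 * np.exp(-0.5 * ((tau - 0.10) / 0.04) ** 2))
    return scale_uv * h, offset


def _draw_r_peaks(rng, duration, pulse: PulseSpec):
    """R-peak times: RR ~ Normal(60/HR, sd) truncated at 60/110 s."""
    mean_rr = 60.0 / pulse.hr_bpm
    sd_rr = 60.0 * pulse.hr_sd_bpm / pulse.hr_bpm ** 2
    times = [0.35]  # first beat clear of the recording edge
    while times[-1] < duration:
        rr = mean_rr if sd_rr == 0 else max(_MIN_RR,
                                            rng.normal(mean_rr, sd_rr))
        times.append(times[-1] + rr)
    # beats virtually touching the recording edge are undetectable in
    # principle and excluded from the ground truth
    return np.array([t for t in times if t < duration - 0.05])


def condition_band_gain(montage: Montage, spread: float, asymmetry: float
                        ) -> np.ndarray:
    """Per-channel gain on the 15-25 Hz component for one recording condition.

    ``spread`` sets the overall inflation of the band component; ``asymmetry``
    the left-right alternating pattern: amplifier-1 channels gain more power on
    the right than the left, amplifier-2 channels the other way around, with a
    central-to-peripheral gradient (weight = polar angle from the vertex).
    """
    gains = np.ones(montage.n_channels)
    polar = np.degrees(np.arccos(np.clip(montage.positions[:, 2], -1, 1))) / 90.0
    for i, label in enumerate(montage.labels):
        g = spread
        if not montage.midline[label]:
            side = -1.0 if montage.positions[i, 0] < 0 else 1.0  # left / right
            amp_sign = 1.0 if montage.amplifier[label] == 1 else -1.0
            g += asymmetry * amp_sign * side * min(polar[i], 1.0)
        gains[i] = max(1.0 + g, 0.05)
    return gains


def condition_params(condition: str, seed: int = 0, fs: float = 5000.0,
                     duration: float = 120.0, montage: Montage | None = None,
                     ) -> EEGSimParams:
    """Preset simulation parameters for one of the four recording conditions."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    montage = montage or standard_montage()
    # (band spread, asymmetry, line noise μV, gradient?, pulse?)
    table = {
        "separate": (0.0, 0.0, 0.5, False, False),
        "outside": (0.3, 0.1, 1.0, False, False),
        "pre_acquisition": (1.0, 0.5, 2.0, False, True),
        "simultaneous": (2.5, 1.5, 2.0, True, True),
    }
    spread, asym, line_uv, grad, pulse = table[condition]
    return EEGSimParams(
        montage=montage, fs=fs, duration=duration,
        line_noise_uv=line_uv,
        gradient=GradientSpec() if grad else None,
        pulse=PulseSpec() if pulse else None,
        condition_gain=condition_band_gain(montage, spread, asym),
        condition_tag=condition, seed=seed,
    )


def generate_eeg_session(params: EEGSimParams
                         ) -> tuple[EEGRecording, SessionGroundTruth]:
    """Generate one synthetic EEG session plus its ground truth.

    The neural signal is background + rhythms + line noise + the gain-scaled
    15-25 Hz band component; the gradient and pulse artifacts are added on top
    and recorded separately in the ground truth. Same seed, same session.
    """
    rng = np.random.default_rng(params.seed)
    fs, n_ch = params.fs, params.montage.n_channels
    n = int(round(params.duration * fs))
    gt = SessionGroundTruth()
    gains = (np.ones(n_ch) if params.condition_gain is None
             else np.asarray(params.condition_gain, float))
    gt.injected_band_gain = gains.copy()

    data = np.empty((n_ch, n))
    line_phase = rng.uniform(0, 2 * np.pi, n_ch)
    t = np.arange(n) / fs
    # smooth, left-right symmetric rhythm topographies (alpha posterior,
    # beta central) so electrodes differ even without any artifact
    pos = params.montage.positions
    topo = {
        "posterior": 1.0 + 0.25 * -pos[:, 1],
        "central": 1.0 + 0.25 * pos[:, 2],
    }
    for c in range(n_ch):
        x = _one_over_f(rng, n, fs, params.background_exponent,
                        params.background_rms)
        for center, bw, rms in params.rhythms:
            w = topo["central"][c] if center >= 13 else topo["posterior"][c]
            comp = _band_noise(rng, n, fs, center, bw, rms * w)
            if 15.0 <= center <= 25.0:   # the condition-sensitive band
                comp = comp * gains[c]
            x += comp
        x += params.line_noise_uv * np.sin(
            2 * np.pi * params.line_noise_freq * t + line_phase[c])
        data[c] = x
    if params.keep_clean:
        gt.clean_data = data.copy()

    events: list[Event] = []

    if params.gradient is not None:
        g = params.gradient
        d = int(round(g.tr * fs))                 # samples per TR
        slice_period = d / g.n_slices             # samples
        n_harm = max(2, min(25, int(0.45 * slice_period)))
        k = np.arange(1, n_harm + 1)
        amps = 1.0 / k
        phases = rng.uniform(0, 2 * np.pi, n_harm)
        ch_gain = g.amplitude * (0.8 + 0.4 * rng.random(n_ch))
        idx = np.arange(n)
        base = np.zeros(n)
        for kk, a, ph in zip(k, amps, phases):
            base += a * np.cos(2 * np.pi * kk * idx / slice_period + ph)
        base /= base.std()
        drift = 1.0 + g.drift_per_minute * (idx / fs) / 60.0
        artifact = ch_gain[:, None] * (base * drift)[None, :]
        data += artifact
        onsets = np.arange(0, n - d + 1, d)
        gt.tr_onset_samples = onsets
        gt.gradient_template = ch_gain[:, None] * base[None, :d]
        events += [Event(int(s), "tr_onset") for s in onsets]
    else:
        gt.gradient_template = np.zeros((n_ch, 0))

    ecg = None
    if params.pulse is not None:
        p = params.pulse
        r_times = _draw_r_peaks(rng, params.duration, p)
        gt.r_peak_times = r_times
        h, offset = _pulse_template(fs, 60.0 / p.hr_bpm)
        # smooth spatial gain over the scalp (stronger low/posterior),
        # averaging ~1 so scale_uv stays the typical peak amplitude
        pos = params.montage.positions
        ch_scale = p.scale_uv * (0.75 + 0.5 * (1.0 - pos[:, 2]) / 2.0)
        gt.pulse_template = ch_scale[:, None] * h[None, :]
        gt.pulse_template_offset = offset
        amp_jit = 1.0 + p.jitter * rng.standard_normal(r_times.size)
        for t_r, a in zip(r_times, amp_jit):
            s0 = int(round(t_r * fs)) - offset
            lo, hi = max(s0, 0), min(s0 + h.size, n)
            if hi <= lo:
                continue
            data[:, lo:hi] += a * ch_scale[:, None] * h[None, lo - s0:hi - s0]
        # ECG aux channel: sharp synthetic QRS train, big amplitude
        he = (np.exp(-0.5 * ((np.arange(-offset, int(0.6 * fs) + 1) / fs)
                             / 0.012) ** 2)
              - 0.2 * np.exp(-0.5 * (((np.arange(-offset, int(0.6 * fs) + 1)
                                       / fs) - 0.05) / 0.03) ** 2))
        ecg = 20.0 * rng.standard_normal(n)
        for t_r, a in zip(r_times, amp_jit):
            s0 = int(round(t_r * fs)) - offset
            lo, hi = max(s0, 0), min(s0 + he.size, n)
            if hi <= lo:
                continue
            ecg[lo:hi] += a * 800.0 * he[lo - s0:hi - s0]
    else:
        gt.pulse_template = np.zeros((n_ch, 0))

    rec = EEGRecording(
        data=data, fs=fs, events=events, montage=params.montage,
        reference="FCz", condition_tag=params.condition_tag,
        aux={} if ecg is None else {"ECG": ecg},
    )
    return rec, gt


# ---------------------------------------------------------------------------
# fMRI phantom
# ---------------------------------------------------------------------------

DEFAULT_TISSUE = {          # baseline intensity, noise sd (MR units)
    "csf": (1500.0, 45.0),
    "wm": (800.0, 16.0),
    "gm": (1000.0, 25.0),
}


def _ellipsoid_radius(shape):
    """Normalized ellipsoidal radius per voxel (0 at center, 1 at FOV edge)."""
    grids = np.meshgrid(*[(np.arange(s) - (s - 1) / 2) / (s / 2) for s in shape],
                        indexing="ij")
    return np.sqrt(sum(g ** 2 for g in grids))


def phantom_masks(shape) -> dict[str, np.ndarray]:
    """Concentric tissue compartments: CSF core, WM between, GM shell."""
    r = _ellipsoid_radius(shape)
    masks = {
        "csf": r < 0.25,
        "wm": (r >= 0.25) & (r < 0.62),
        "gm": (r >= 0.62) & (r < 0.92),
    }
    masks["brain"] = r < 0.92
    return masks


def generate_fmri_session(shape=(24, 24, 12), n_volumes=100, tr=2.0,
                          tissue_spec=None, drift_total=0.01,
                          condition_effect=None, voxel_mm=3.0, seed=0,
                          motion_instantaneous_mm=0.08,
                          ) -> tuple[VolumeSeries, dict, SessionGroundTruth]:
    """Generate a 4D phantom series with a known TSNR field.

    Each voxel's series is ``baseline * (1 + drift) + N(0, sd)`` with tissue-
    specific baseline/sd and a mild anterior-posterior noise gradient.
    ``condition_effect=(factor, region_mask)`` multiplies the noise sd inside
    the region, emulating a regionally degraded condition; ``true_tsnr`` in the
    ground truth is baseline/sd including that effect. ``sd == 0`` voxels get
    a ``+inf`` TSNR sentinel.
    """
    if min(shape[:2]) < 8 or shape[2] < 4:
        raise ValueError("phantom shape must be at least 8x8x4")
    if n_volumes < 20:
        raise ValueError("need at least 20 volumes")
    rng = np.random.default_rng(seed)
    tissue_spec = tissue_spec or DEFAULT_TISSUE
    masks = phantom_masks(shape)
    for a in ("csf", "wm", "gm"):
        for b in ("csf", "wm", "gm"):
            if a < b and np.any(masks[a] & masks[b]):
                raise ValueError(f"overlapping tissue definitions: {a}/{b}")

    baseline = np.zeros(shape)
    sd = np.zeros(shape)
    for tissue, (b, s) in tissue_spec.items():
        baseline[masks[tissue]] = b
        sd[masks[tissue]] = s
    # regionally varying noise: mild gradient along y (anterior-posterior)
    ny = shape[1]
    grad = 1.0 + 0.2 * (np.arange(ny) - (ny - 1) / 2) / ny
    sd = sd * grad[None, :, None]
    if condition_effect is not None:
        factor, region = condition_effect
        sd = np.where(region, sd * factor, sd)

    tcourse = 1.0 + drift_total * np.linspace(0, 1, n_volumes)
    data = (baseline[..., None] * tcourse[None, None, None, :]
            + sd[..., None] * rng.standard_normal(shape + (n_volumes,)))

    with np.errstate(divide="ignore"):
        true_tsnr = np.where(sd > 0, baseline / np.where(sd > 0, sd, 1.0),
                             np.where(baseline > 0, np.inf, 0.0))

    step = motion_instantaneous_mm / 1.5958  # E||N(0, s I3)|| = 1.5958 s
    increments = np.vstack([
        np.zeros((1, 6)),
        np.hstack([step * rng.standard_normal((n_volumes - 1, 3)),
                   1e-3 * step * rng.standard_normal((n_volumes - 1, 3))]),
    ])
    motion = MotionParams(np.cumsum(increments, axis=0))

    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    vs = VolumeSeries(data=data, tr=tr, affine=affine, mask=masks["brain"])
    gt = SessionGroundTruth(true_tsnr=true_tsnr, true_motion=motion,
                            noise_sd=sd)
    return vs, masks, gt


def posterior_region(shape, fraction=0.3) -> np.ndarray:
    """Boolean mask of the posterior block (lowest-y slab) inside the brain."""
    masks = phantom_masks(shape)
    ny = shape[1]
    slab = np.zeros(shape, bool)
    slab[:, : int(round(fraction * ny)), :] = True
    return slab & masks["brain"]
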