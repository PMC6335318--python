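"""Readers and writers for the standard formats the pipeline touches.

EEG comes in as BrainVision (``.vhdr``/``.vmrk``/``.eeg``) or EDF and is read
through mne; amplitudes are converted to μV on load. Writers are implemented
here (BrainVision Core 1.0 binary; plain EDF with a sidecar events TSV, since
EDF itself carries no annotations). fMRI volume series use NIfTI-1 via nibabel
with the TR stored in ``pixdim[4]``.

Vendor marker strings are site-specific, so the mapping from marker
descriptions to canonical event labels (``tr_onset``, ``stimulus``, ``r_peak``)
is configuration-driven: pass a dict or a YAML file with a ``marker_map``
section.
"""

from __future__ import annotations

import logging
import os
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .recording import EEGRecording, Event, VolumeSeries
from .montage import Montage, derive_pairs

__all__ = [
    "read_eeg", "write_eeg", "read_volume_series", "write_volume",
    "read_events_tsv", "write_events_tsv", "load_marker_map", "FormatError",
]

log = logging.getLogger("eegfmriqc")


class FormatError(ValueError):
    """Malformed file or unsupported field in a standard format."""


#: default vendor-marker -> canonical label mapping
DEFAULT_MARKER_MAP = {
    "R128": "tr_onset",
    "tr_onset": "tr_onset",
    "stimulus": "stimulus",
    "r_peak": "r_peak",
}


def load_marker_map(config_path) -> dict:
    """Read ``marker_map`` from a YAML config file."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return dict(DEFAULT_MARKER_MAP, **cfg.get("marker_map", {}))


def _map_marker(desc: str, marker_map: dict) -> str:
    desc = desc.strip()
    if desc in marker_map:
        return marker_map[desc]
    # mne prefixes BrainVision descriptions with the marker type ("Stimulus/x")
    tail = desc.split("/")[-1].strip()
    return marker_map.get(tail, "custom")


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def read_eeg(path, format: str | None = None, montage: Montage | None = None,
             marker_map: dict | None = None) -> EEGRecording:
    """Read an EEG recording from BrainVision or EDF into μV.

    Parameters
    ----------
    path : str or Path
        ``.vhdr`` for BrainVision, ``.edf`` for EDF. ``format`` may override
        the extension-based guess.
    montage : Montage, optional
        Attached to the recording when its labels match the file's channels;
        channels are reordered to montage order. Non-montage channels (e.g. a
        dedicated ECG channel) become ``aux`` channels.
    marker_map : dict, optional
        Vendor marker description -> canonical event label.
    """
    import mne

    path = Path(path)
    fmt = format or ("brainvision" if path.suffix == ".vhdr" else "edf")
    marker_map = dict(DEFAULT_MARKER_MAP, **(marker_map or {}))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if fmt == "brainvision":
                raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
            elif fmt == "edf":
                raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
            else:
                raise FormatError(f"unknown EEG format {fmt!r}")
        except FormatError:
            raise
        except Exception as exc:  # mne raises assorted types on bad headers
            raise FormatError(f"cannot parse {path.name} as {fmt}: {exc}") from exc

    data_uv = raw.get_data() * 1e6  # mne is SI volts internally
    fs = float(raw.info["sfreq"])
    labels = list(raw.ch_names)

    events: list[Event] = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc.startswith("New Segment"):
            continue
        lat = int(round(onset * fs))
        if 0 <= lat < data_uv.shape[1]:
            events.append(Event(lat, _map_marker(desc, marker_map)))

    n_samples = data_uv.shape[1]
    if fmt == "edf":
        sidecar = path.with_suffix(".events.tsv")
        if sidecar.exists():
            ev, true_n = read_events_tsv(sidecar)
            events = ev
            if true_n is not None and true_n <= n_samples:
                data_uv = data_uv[:, :true_n]
                n_samples = true_n

    aux = {}
    if montage is not None:
        order = []
        for lab in montage.labels:
            if lab not in labels:
                raise FormatError(f"montage channel {lab} missing from {path.name}")
            order.append(labels.index(lab))
        montage_set = set(montage.labels)
        for i, lab in enumerate(labels):
            if lab not in montage_set:
                aux[lab] = data_uv[i]
        data_uv = data_uv[order]

    return EEGRecording(data=data_uv, fs=fs, events=events, montage=montage,
                        aux=aux)


def write_eeg(rec: EEGRecording, path, format: str = "brainvision",
              resolution_uv: float | None = None) -> None:
    """Write a recording to BrainVision (binary) or EDF.

    BrainVision stores IEEE float32 μV by default; pass ``resolution_uv``
    (e.g. ``0.1``) for 16-bit integer storage at that resolution. EDF always
    quantizes to 16 bits over the per-channel physical range and writes events
    to a sidecar ``.events.tsv`` (plain EDF has no annotation channel).
    """
    path = Path(path)
    if format == "brainvision":
        _write_brainvision(rec, path, resolution_uv)
    elif format == "edf":
        _write_edf(rec, path)
        write_events_tsv(rec.events, path.with_suffix(".events.tsv"),
                         n_samples=rec.n_samples)
    else:
        raise FormatError(f"unknown EEG format {format!r}")


def _write_brainvision(rec: EEGRecording, path: Path, resolution_uv=None) -> None:
    base = path.with_suffix("")
    vhdr, vmrk, eeg = base.with_suffix(".vhdr"), base.with_suffix(".vmrk"), \
        base.with_suffix(".eeg")
    labels = rec.labels + list(rec.aux)
    data = rec.data
    if rec.aux:
        data = np.vstack([data] + [rec.aux[k][None, :] for k in rec.aux])
    n_ch = data.shape[0]
    sampling_interval_us = 1e6 / rec.fs

    if resolution_uv is None:
        binfmt, res = "IEEE_FLOAT_32", 1.0
        payload = (data / res).astype("<f4").T.tobytes()
    else:
        binfmt, res = "INT_16", float(resolution_uv)
        q = np.clip(np.round(data / res), -32768, 32767)
        payload = q.astype("<i2").T.tobytes()

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; written by eegfmriqc",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={sampling_interval_us:.6f}".rstrip("0").rstrip("."),
        "",
        "[Binary Infos]",
        f"BinaryFormat={binfmt}",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(labels, start=1):
        lines.append(f"Ch{i}={lab},,{res:g},µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20000101000000000000",
    ]
    for k, ev in enumerate(sorted(rec.events, key=lambda e: e.latency), start=2):
        # positions are 1-based data points in BrainVision
        mlines.append(f"Mk{k}=Stimulus,{ev.label},{ev.latency + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    eeg.write_bytes(payload)


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: EEGRecording, path: Path) -> None:
    labels = rec.labels + list(rec.aux)
    data = rec.data
    if rec.aux:
        data = np.vstack([data] + [rec.aux[k][None, :] for k in rec.aux])
    n_ch, n = data.shape
    spr = int(round(rec.fs))  # one-second records
    if abs(rec.fs - spr) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    n_rec = int(np.ceil(n / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n] = data

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    span = np.maximum(pmax - pmin, 1e-6)
    pmin, pmax = pmin - 0.001 * span, pmax + 0.001 * span
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((padded - pmin[:, None]) / scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    hdr = b"".join([
        _edf_field(0, 8),
        _edf_field("eegfmriqc", 80),
        _edf_field("synthetic-session", 80),
        _edf_field("01.01.20", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + n_ch), 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(_edf_field(l, 16) for l in labels),
        b"".join(_edf_field("", 80) for _ in labels),
        b"".join(_edf_field("uV", 8) for _ in labels),
        b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in pmin),
        b"".join(_edf_field(f"{v:.6g}"[:8], 8) for v in pmax),
        b"".join(_edf_field(dmin, 8) for _ in labels),
        b"".join(_edf_field(dmax, 8) for _ in labels),
        b"".join(_edf_field("", 80) for _ in labels),
        b"".join(_edf_field(spr, 8) for _ in labels),
        b"".join(_edf_field("", 32) for _ in labels),
    ])
    body = bytearray()
    for r in range(n_rec):
        chunk = digital[:, r * spr:(r + 1) * spr]
        body += chunk.tobytes()  # channel-sequential within record
    with open(path, "wb") as fh:
        fh.write(hdr + sig + bytes(body))


# ---------------------------------------------------------------------------
# events TSV
# ---------------------------------------------------------------------------

def write_events_tsv(events, path, n_samples: int | None = None) -> None:
    """Write events as a two-column TSV (sample, label)."""
    with open(path, "w") as fh:
        if n_samples is not None:
            fh.write(f"# n_samples={n_samples}\n")
        fh.write("sample\tlabel\n")
        for ev in sorted(events, key=lambda e: e.latency):
            fh.write(f"{ev.latency}\t{ev.label}\n")


def read_events_tsv(path) -> tuple[list[Event], int | None]:
    """Read a (sample, label) TSV; returns (events, n_samples-or-None)."""
    events, n_samples = [], None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "n_samples=" in line:
                    n_samples = int(line.split("n_samples=")[1])
                continue
            if line.startswith("sample"):
                continue
            sample, label = line.split("\t")
            events.append(Event(int(sample), label))
    return events, n_samples


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_volume_series(path) -> VolumeSeries:
    """Read a 4D NIfTI-1 series; TR is taken from ``pixdim[4]``."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise FormatError(f"expected a 4D series, got {data.ndim}D in {path}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    return VolumeSeries(data=data, tr=tr, affine=img.affine)


def write_volume(vol, path, affine=None, tr: float | None = None) -> None:
    """Write a 3D or 4D array (or VolumeSeries) as NIfTI-1."""
    if isinstance(vol, VolumeSeries):
        data, affine, tr = vol.data, vol.affine, vol.tr
    else:
        data = np.asarray(vol, dtype=float)
        if affine is None:
            affine = np.eye(4)
    img = nib.Nifti1Image(data, affine)
    if tr is not None and data.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr
        img.header.set_zooms(zooms)
    nib.save(img, str(path))
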