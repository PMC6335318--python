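"""Electrode montage: 10-5 labels, unit-sphere positions, left-right pairs, amplifiers.

The montage used throughout the package is the 60-electrode subset common to
both recording systems of the study design this package supports: a WaveGuard
cap recorded outside the scanner and a BrainCap MR recorded inside, both laid
out on the 10-5 system. The 60 channels split into 26 symmetric left-right
pairs plus 8 midline electrodes, and into two 32-channel amplifiers whose
channel assignment is fixed by the recording hardware (symmetric pairs always
share an amplifier).

Positions are idealized: every electrode lies exactly on the unit sphere, the
head coordinate frame is +x right, +y nasion (front), +z vertex, and left-right
pairs are exact mirror images in x. Interior rows are placed by great-circle
interpolation between the midline electrode and the corresponding electrode on
the circumferential (Fpz-T7-Oz-T8) circle, which is the classical 10-20
construction extended to the 10-10 columns present here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Montage", "MontageError", "standard_montage", "load_montage", "save_montage"]


class MontageError(ValueError):
    """Raised for inconsistent montage definitions."""


#: channels wired to amplifier 1 (hardware layout; symmetric pairs share an amp)
AMP1 = {
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Cz", "Pz", "Oz",
    "FC1", "FC2", "CP1", "CP2", "FC5", "FC6", "CP5", "CP6", "FCz",
}

#: channels wired to amplifier 2
AMP2 = {
    "F1", "F2", "C1", "C2", "P1", "P2", "AF3", "AF4", "FC3", "FC4",
    "CP3", "CP4", "PO3", "PO4", "F5", "F6", "C5", "C6", "P5", "P6",
    "AF7", "AF8", "FT7", "FT8", "TP7", "TP8", "PO7", "PO8",
    "Fpz", "CPz", "POz",
}

#: the 60 electrodes shared between the two caps, alphabetically sorted
STANDARD_60 = sorted(
    [
        "AF3", "AF4", "AF7", "AF8", "C1", "C2", "C3", "C4", "C5", "C6",
        "CP1", "CP2", "CP3", "CP4", "CP5", "CP6", "CPz", "Cz",
        "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8",
        "FC1", "FC2", "FC3", "FC4", "FC5", "FC6", "FCz",
        "FT7", "FT8", "Fp1", "Fp2", "Fpz", "Fz",
        "O1", "O2", "Oz", "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8",
        "PO3", "PO4", "PO7", "PO8", "POz", "Pz", "T7", "T8", "TP7", "TP8",
    ]
)

_LABEL_RE = re.compile(r"^(Fp|AF|FC|FT|CP|TP|PO|F|C|T|P|O)(z|\d+)$")


def _parse_label(label: str) -> tuple[str, int]:
    """Split a 10-5 label into (row, column); column 0 encodes the midline 'z'."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise MontageError(f"cannot parse 10-5 label {label!r}")
    row, col = m.groups()
    return row, 0 if col == "z" else int(col)


def mirror_label(label: str) -> str | None:
    """Homotopic partner of a non-midline label (F3 -> F4, P8 -> P7); None for midline."""
    row, col = _parse_label(label)
    if col == 0:
        return None
    partner = col + 1 if col % 2 == 1 else col - 1
    return f"{row}{partner}"


@dataclass(frozen=True)
class Montage:
    """Electrode layout: labels, unit-sphere positions, pairs and amplifiers.

    Attributes
    ----------
    labels : list of str
        Unique electrode names, ordered (alphabetically for the standard set).
    positions : (n, 3) ndarray
        Unit-norm 3D coordinates per label (+x right, +y front, +z up).
    pair_map : dict
        left-label -> right-label for each symmetric non-midline pair.
    amplifier : dict
        label -> 1 | 2 hardware amplifier assignment.
    midline : dict
        label -> bool, True for z-line electrodes.
    """

    labels: list[str]
    positions: np.ndarray
    pair_map: dict[str, str]
    amplifier: dict[str, int]
    midline: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise MontageError("duplicate electrode labels")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise MontageError("positions must be (n_labels, 3)")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise MontageError("positions must have unit norm within 1e-6")
        object.__setattr__(self, "positions", pos)
        if not self.midline:
            object.__setattr__(
                self, "midline", {l: l.endswith("z") for l in self.labels}
            )
        paired = set(self.pair_map) | set(self.pair_map.values())
        for label in self.labels:
            if self.midline.get(label, False):
                continue
            if label not in paired:
                raise MontageError(f"unpaired non-midline electrode: {label}")
        for left, right in self.pair_map.items():
            if self.amplifier.get(left) != self.amplifier.get(right):
                raise MontageError(
                    f"pair {left}-{right} spans amplifiers "
                    f"{self.amplifier.get(left)}/{self.amplifier.get(right)}"
                )

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        """(left, right) tuples, ordered by left label."""
        return sorted(self.pair_map.items())

    @property
    def midline_labels(self) -> list[str]:
        return [l for l in self.labels if self.midline[l]]

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def position_of(self, label: str) -> np.ndarray:
        return self.positions[self.index(label)]

    def subset(self, labels: list[str]) -> "Montage":
        """Montage restricted to `labels` (pairs with a missing member dropped)."""
        keep = set(labels)
        pm = {l: r for l, r in self.pair_map.items() if l in keep and r in keep}
        # electrodes whose partner was dropped are treated as midline-like singletons
        midline = {
            l: self.midline[l] or (l not in pm and l not in set(pm.values()))
            for l in labels
        }
        return Montage(
            labels=list(labels),
            positions=np.array([self.position_of(l) for l in labels]),
            pair_map=pm,
            amplifier={l: self.amplifier[l] for l in labels},
            midline=midline,
        )


def _slerp(a: np.ndarray, b: np.ndarray, frac: float) -> np.ndarray:
    """Great-circle interpolation between unit vectors a and b."""
    omega = np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))
    if omega < 1e-12:
        return a
    return (np.sin((1 - frac) * omega) * a + np.sin(frac * omega) * b) / np.sin(omega)


def _ideal_positions(labels: list[str]) -> np.ndarray:
    """Idealized unit-sphere coordinates for the supported 10-5 labels."""
    # midline arc: angle from vertex along the sagittal midline, front positive
    mid_angle = {"Fp": 90, "AF": 72, "F": 54, "FC": 36, "C": 0,
                 "CP": -36, "P": -54, "PO": -72, "O": -90}

    def midline_point(row: str) -> np.ndarray:
        b = np.deg2rad(mid_angle[row])
        return np.array([0.0, np.sin(b), np.cos(b)])

    # circumferential circle (polar angle 90 deg): azimuth from the front
    circ_az = {"Fp": 18, "AF": 36, "F": 54, "FT": 72, "T": 90,
               "TP": 108, "P": 126, "PO": 144, "O": 162}
    # row of the circumferential endpoint for each interior row
    edge_row = {"AF": "AF", "F": "F", "FC": "FT", "C": "T",
                "CP": "TP", "P": "P", "PO": "PO"}

    def circumference_point(row: str, side: float) -> np.ndarray:
        psi = np.deg2rad(circ_az[row])
        return np.array([side * np.sin(psi), np.cos(psi), 0.0])

    out = np.empty((len(labels), 3))
    for i, label in enumerate(labels):
        row, col = _parse_label(label)
        if col == 0:
            out[i] = midline_point(row)
            continue
        side = -1.0 if col % 2 == 1 else 1.0  # odd = left
        lateral = (col + 1) // 2  # 1/2 -> 1, 3/4 -> 2, 5/6 -> 3, 7/8 -> 4
        if row in ("Fp", "O", "T", "FT", "TP") or lateral == 4:
            # on the circumferential circle
            edge = row if row in circ_az else edge_row[row]
            out[i] = circumference_point(edge, side)
        else:
            a = midline_point(row)
            b = circumference_point(edge_row[row], side)
            out[i] = _slerp(a, b, lateral / 4.0)
    # exact symmetry / unit norm by construction, but normalize defensively
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    out[np.abs(out) < 1e-12] = 0.0
    return out


def derive_pairs(labels: list[str], overrides: dict[str, str] | None = None
                 ) -> dict[str, str]:
    """Left->right pair map by the odd/even digit convention, plus overrides."""
    pm: dict[str, str] = {}
    labelset = set(labels)
    for label in labels:
        row, col = _parse_label(label)
        if col == 0 or col % 2 == 0:
            continue
        partner = mirror_label(label)
        if partner in labelset:
            pm[label] = partner
    if overrides:
        pm.update(overrides)
    return pm


def standard_montage() -> Montage:
    """The 60-channel montage shared by both recording systems."""
    labels = list(STANDARD_60)
    amp = {l: (1 if l in AMP1 else 2) for l in labels}
    return Montage(
        labels=labels,
        positions=_ideal_positions(labels),
        pair_map=derive_pairs(labels),
        amplifier=amp,
    )


def load_montage(path) -> Montage:
    """Load a montage from TSV with columns label, x, y, z, amplifier.

    Labels are sorted alphabetically; positions are normalized to unit length;
    pairs are derived from the odd/even digit convention. Raises
    :class:`MontageError` listing any non-midline electrode without a partner.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"label", "x", "y", "z", "amplifier"}
    if not required.issubset(df.columns):
        raise MontageError(f"montage TSV needs columns {sorted(required)}")
    df = df.sort_values("label").reset_index(drop=True)
    labels = df["label"].astype(str).tolist()
    pos = df[["x", "y", "z"]].to_numpy(float)
    norms = np.linalg.norm(pos, axis=1)
    if np.any(norms == 0):
        raise MontageError("zero-length electrode position")
    pos = pos / norms[:, None]
    pm = derive_pairs(labels)
    paired = set(pm) | set(pm.values())
    missing = [l for l in labels if not l.endswith("z") and l not in paired]
    if missing:
        raise MontageError(f"unpaired non-midline electrodes: {missing}")
    amp = dict(zip(labels, df["amplifier"].astype(int)))
    return Montage(labels=labels, positions=pos, pair_map=pm, amplifier=amp)


def save_montage(montage: Montage, path) -> None:
    """Write a montage to the TSV layout read by :func:`load_montage`."""
    df = pd.DataFrame(
        {
            "label": montage.labels,
            "x": montage.positions[:, 0],
            "y": montage.positions[:, 1],
            "z": montage.positions[:, 2],
            "amplifier": [montage.amplifier[l] for l in montage.labels],
        }
    )
    df.to_csv(path, sep="\t", index=False)
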