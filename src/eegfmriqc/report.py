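"""Topographic maps and multi-condition comparison reports.

The interactive exploration a recording site would do with a GUI is replaced
here by static, reproducible report generation: per frequency band and
recording condition a topographic map of (log10) band power, per-electrode
spectrum curves, and dispersion-versus-frequency curves, written as PNG plus a
machine-readable TSV containing every plotted number (round-trippable
bit-exactly) and a small standalone HTML index.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .montage import Montage
from .spectral import SpectralSummary, band_mean_range, dispersion_curve

__all__ = ["TopoMap", "project_montage", "topomap", "comparison_report"]


@dataclass
class TopoMap:
    """Interpolated scalp map on a 2D grid (NaN outside the electrode hull)."""
    grid_x: np.ndarray
    grid_y: np.ndarray
    grid_values: np.ndarray
    electrode_xy: np.ndarray
    electrode_values: np.ndarray
    scale: str = "linear"
    freq_range: tuple | None = None
    condition_tag: str | None = None


def project_montage(montage: Montage) -> np.ndarray:
    """Azimuthal equidistant projection: vertex at the origin, nasion up.

    A unit vector (x, y, z) maps to polar radius arccos(z) along azimuth
    atan2(y, x), so equal arc distances from the vertex map to equal radii and
    left-right mirrored electrodes are x-mirrored in the plane.
    """
    pos = montage.positions
    polar = np.arccos(np.clip(pos[:, 2], -1.0, 1.0))
    az = np.arctan2(pos[:, 1], pos[:, 0])
    return np.column_stack([polar * np.cos(az), polar * np.sin(az)])


def _idw(points: np.ndarray, values: np.ndarray, targets: np.ndarray,
         power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted interpolation, exact at the data points."""
    d = np.linalg.norm(targets[:, None, :] - points[None, :, :], axis=2)
    out = np.empty(targets.shape[0])
    exact = d < 1e-12
    has_exact = exact.any(axis=1)
    with np.errstate(divide="ignore"):
        w = 1.0 / d ** power
    w[~np.isfinite(w)] = 0.0
    out = (w @ values) / w.sum(axis=1)
    for i in np.flatnonzero(has_exact):
        out[i] = values[np.argmax(exact[i])]
    return out


def topomap(values: np.ndarray, montage: Montage, scale: str = "log10",
            resolution: int = 64, freq_range=None, condition_tag=None,
            ) -> TopoMap:
    """Inverse-distance interpolated scalp map of per-electrode values.

    With ``scale="log10"`` all values must be strictly positive; the offending
    electrode is named otherwise. The map is exact at electrode positions and
    masked (NaN) outside the convex hull of the electrodes.
    """
    values = np.asarray(values, float)
    if values.size != montage.n_channels:
        raise ValueError("one value per electrode required")
    if scale == "log10":
        bad = np.flatnonzero(values <= 0)
        if bad.size:
            raise ValueError(
                f"log10 scale needs positive values; offending electrode(s): "
                f"{[montage.labels[i] for i in bad]}")
        plot_values = np.log10(values)
    elif scale == "linear":
        plot_values = values
    else:
        raise ValueError(f"unknown scale {scale!r}")

    xy = project_montage(montage)
    lim = np.abs(xy).max() * 1.05
    gx, gy = np.meshgrid(np.linspace(-lim, lim, resolution),
                         np.linspace(-lim, lim, resolution))
    targets = np.column_stack([gx.ravel(), gy.ravel()])
    grid = _idw(xy, plot_values, targets)
    hull = Delaunay(xy)
    inside = hull.find_simplex(targets) >= 0
    grid[~inside] = np.nan
    return TopoMap(grid_x=gx, grid_y=gy, grid_values=grid.reshape(gx.shape),
                   electrode_xy=xy, electrode_values=plot_values, scale=scale,
                   freq_range=freq_range, condition_tag=condition_tag)


def _draw_topomap(ax, tm: TopoMap, montage: Montage, title: str = ""):
    im = ax.pcolormesh(tm.grid_x, tm.grid_y, tm.grid_values, cmap="viridis",
                       shading="auto")
    ax.scatter(tm.electrode_xy[:, 0], tm.electrode_xy[:, 1], s=4, c="k")
    ax.set_title(title, fontsize=8)
    ax.set_aspect("equal")
    ax.set_axis_off()
    return im


def comparison_report(spectra: dict[str, SpectralSummary], montage: Montage,
                      out_dir, bands=((15, 25),), electrodes=("F3", "F4",
                                                              "FC3", "FC4",
                                                              "C3", "C4"),
                      scale: str = "log10") -> dict[str, Path]:
    """Write a multi-condition comparison report.

    ``spectra`` maps condition name -> :class:`SpectralSummary` (band means are
    computed if absent). Emits, per band, a side-by-side topomap panel over
    conditions; per-electrode spectrum curves; a dispersion-vs-frequency
    figure; and one tidy TSV per figure holding every plotted number.
    """
    if not spectra:
        raise ValueError("need at least one condition")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    conditions = list(spectra)
    written: dict[str, Path] = {}
    tsv_rows = []

    for lo, hi in bands:
        fig, axes = plt.subplots(1, len(conditions),
                                 figsize=(3 * len(conditions), 3),
                                 squeeze=False)
        for ax, cond in zip(axes[0], conditions):
            vals = band_mean_range(spectra[cond], lo, hi)
            tm = topomap(vals, montage, scale=scale, freq_range=(lo, hi),
                         condition_tag=cond)
            _draw_topomap(ax, tm, montage, f"{cond} {lo}-{hi} Hz")
            for lab, v in zip(montage.labels, vals):
                tsv_rows.append({"figure": f"topomap_{lo}_{hi}",
                                 "condition": cond, "channel": lab,
                                 "band_lo": lo, "band_hi": hi,
                                 "value_uV2": v})
        name = f"topomap_{lo}_{hi}.png"
        fig.savefig(out_dir / name, dpi=110)
        plt.close(fig)
        written[name] = out_dir / name

    fig, axes = plt.subplots(1, len(electrodes),
                             figsize=(2.2 * len(electrodes), 2.5),
                             sharey=True, squeeze=False)
    for ax, el in zip(axes[0], electrodes):
        for cond in conditions:
            spec = spectra[cond]
            if el not in spec.channels:
                continue
            ci = spec.channels.index(el)
            ax.semilogy(spec.freqs, spec.a2[ci], lw=0.8, label=cond)
            for f, v in zip(spec.freqs, spec.a2[ci]):
                tsv_rows.append({"figure": "spectra", "condition": cond,
                                 "channel": el, "freq_hz": f, "value_uV2": v})
        ax.set_title(el, fontsize=8)
        ax.set_xlabel("Hz", fontsize=7)
    axes[0, 0].set_ylabel("A² (μV²)", fontsize=7)
    axes[0, -1].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out_dir / "spectra.png", dpi=110)
    plt.close(fig)
    written["spectra.png"] = out_dir / "spectra.png"

    fig, ax = plt.subplots(figsize=(5, 3))
    for cond in conditions:
        dc = dispersion_curve(spectra[cond], condition_tag=cond)
        ax.semilogy(dc.band_centers, np.maximum(dc.dispersion, 1e-12),
                    label=cond, lw=0.9)
        for c, v in zip(dc.band_centers, dc.dispersion):
            tsv_rows.append({"figure": "dispersion", "condition": cond,
                             "freq_hz": c, "value_uV2": v})
    ax.set_xlabel("center frequency (Hz)")
    ax.set_ylabel("index of dispersion (μV²)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_dir / "dispersion.png", dpi=110)
    plt.close(fig)
    written["dispersion.png"] = out_dir / "dispersion.png"

    tsv_path = out_dir / "report_values.tsv"
    # %.17g keeps every float bit-exact through the text round trip
    pd.DataFrame(tsv_rows).to_csv(tsv_path, sep="\t", index=False,
                                  float_format="%.17g")
    written["report_values.tsv"] = tsv_path

    html = out_dir / "report.html"
    imgs = "\n".join(f'<h2>{n}</h2><img src="{n}" style="max-width:100%">'
                     for n in written if n.endswith(".png"))
    html.write_text(
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>EEG-fMRI quality report</title></head><body>"
        f"<h1>EEG-fMRI quality report</h1>{imgs}"
        "<p>All plotted values: <a href='report_values.tsv'>"
        "report_values.tsv</a></p></body></html>")
    written["report.html"] = html
    return written
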