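"""Condition-comparison statistics for the EEG and fMRI quality metrics.

All group tests follow the conventions of a small balanced within-subject
quality study: subjects enter two-way ANOVAs as replicates (so a 2-condition ×
60-electrode × 5-subject analysis has dfs 1, 59, 59, 480), multiple testing is
controlled with Benjamini-Hochberg FDR at q = 0.05, and tissue-level fMRI
metrics are compared with a percentile bootstrap on paired differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .montage import Montage
from .recording import MotionParams

__all__ = [
    "FDRResult", "BootstrapResult", "paired_t_per_frequency", "fdr_bh",
    "anova2_balanced", "lr_abs_difference", "lr_signed_difference",
    "per_pair_anova", "lr_onesample_t", "percentile_bootstrap_diff",
    "movement_summary",
]


@dataclass
class FDRResult:
    """Benjamini-Hochberg decision over a family of p-values."""
    pvalues: np.ndarray
    rejected: np.ndarray
    q: float = 0.05
    method: str = "benjamini-hochberg"


@dataclass
class BootstrapResult:
    """Percentile bootstrap of a paired mean difference."""
    statistic: np.ndarray          # mean difference per resample
    percentile_of_zero: float      # %
    B: int = 10000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.percentile_of_zero <= 100.0:
            raise ValueError("percentile must be in [0, 100]")


def fdr_bh(p, q: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up procedure; NaN p-values are never rejected."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, float)
    rejected = np.zeros(p.shape, bool)
    ok = np.isfinite(p)
    if ok.any():
        rej, *_ = multipletests(p[ok], alpha=q, method="fdr_bh")
        rejected[ok] = rej
    return FDRResult(pvalues=p, rejected=rejected, q=q)


def paired_t_per_frequency(x: np.ndarray, y: np.ndarray, q: float = 0.05,
                           ) -> tuple[np.ndarray, np.ndarray, FDRResult]:
    """Two-sided paired t per center frequency, BH-FDR across frequencies.

    ``x`` and ``y`` are (n_subjects, n_frequencies) dispersion (or band power)
    matrices, paired by row. Frequencies whose subject differences have zero
    variance yield ``NaN`` t and p with a warning.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    if x.shape != y.shape:
        raise ValueError("x and y must have equal shape (paired design)")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    d = x - y
    sd = d.std(axis=0, ddof=1)
    mean = d.mean(axis=0)
    t = np.full(d.shape[1], np.nan)
    p = np.full(d.shape[1], np.nan)
    nz = sd > 0
    if (~nz).any():
        warnings.warn(f"{int((~nz).sum())} frequencies have zero-variance "
                      "differences; t undefined there", stacklevel=2)
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
    p[nz] = 2 * sps.t.sf(np.abs(t[nz]), df=n - 1)
    return t, p, fdr_bh(p, q)


def anova2_balanced(y, factor_a, factor_b) -> pd.DataFrame:
    """Classical balanced two-way crossed ANOVA with interaction.

    ``y`` is the response; ``factor_a`` and ``factor_b`` are level labels of
    the two crossed factors; every (a, b) cell must contain the same number of
    replicates. Returns a table with rows A, B, A:B, error and columns
    ``sum_sq``, ``df``, ``mean_sq``, ``F``, ``p``.
    """
    y = np.asarray(y, float).ravel()
    fa = np.asarray(factor_a).ravel()
    fb = np.asarray(factor_b).ravel()
    if not (y.size == fa.size == fb.size):
        raise ValueError("y, factor_a, factor_b must have equal length")
    levels_a, ia = np.unique(fa, return_inverse=True)
    levels_b, ib = np.unique(fb, return_inverse=True)
    a, b = levels_a.size, levels_b.size
    counts = np.zeros((a, b), int)
    np.add.at(counts, (ia, ib), 1)
    if counts.min() < 1 or counts.min() != counts.max():
        raise ValueError("unbalanced design: equal cell counts required")
    r = int(counts[0, 0])
    n = y.size

    grand = y.mean()
    cell = np.zeros((a, b))
    np.add.at(cell, (ia, ib), y)
    cell /= r
    mean_a = cell.mean(axis=1)
    mean_b = cell.mean(axis=0)

    ss_a = b * r * np.sum((mean_a - grand) ** 2)
    ss_b = a * r * np.sum((mean_b - grand) ** 2)
    ss_ab = r * np.sum((cell - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    ss_e = np.sum((y - cell[ia, ib]) ** 2)

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_e = n - a * b
    rows = []
    mse = ss_e / df_e if df_e > 0 else np.nan
    for name, ss, df in (("A", ss_a, df_a), ("B", ss_b, df_b),
                         ("A:B", ss_ab, df_ab)):
        ms = ss / df if df > 0 else np.nan
        if df_e > 0 and mse > 0:
            F = ms / mse
            p = sps.f.sf(F, df, df_e)
        elif df_e > 0 and mse == 0:
            F = np.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        else:
            F, p = np.nan, np.nan
        rows.append((name, ss, df, ms, F, p))
    rows.append(("error", ss_e, df_e, mse, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["effect", "sum_sq", "df", "mean_sq",
                                       "F", "p"]).set_index("effect")


def lr_abs_difference(values: np.ndarray, montage: Montage,
                      channels: list[str] | None = None) -> pd.Series:
    """|left - right| band power per symmetric electrode pair (μV²)."""
    return lr_signed_difference(values, montage, channels).abs()


def lr_signed_difference(values: np.ndarray, montage: Montage,
                         channels: list[str] | None = None) -> pd.Series:
    """Signed left - right band power per symmetric pair (μV²)."""
    channels = channels or montage.labels
    if not montage.pair_map:
        raise ValueError("montage has no symmetric pairs")
    values = np.asarray(values, float)
    lut = dict(zip(channels, values))
    out, idx = [], []
    for left, right in montage.pairs:
        if left not in lut or right not in lut:
            warnings.warn(f"pair {left}-{right} missing a member; skipped",
                          stacklevel=2)
            continue
        idx.append(f"{left}-{right}")
        out.append(lut[left] - lut[right])
    return pd.Series(out, index=idx, name="left_minus_right")


def per_pair_anova(band_values: np.ndarray, montage: Montage,
                   channels: list[str] | None = None, q: float = 0.05,
                   ) -> pd.DataFrame:
    """2 (condition) × 2 (hemisphere) ANOVA per symmetric pair, FDR over pairs.

    ``band_values`` is (n_conditions=2, n_subjects, n_channels). With 5
    subjects each pair's table has df (1, 1, 1, 16). Returns one row per pair
    with raw and FDR-corrected significance per effect.
    """
    band_values = np.asarray(band_values, float)
    if band_values.ndim != 3 or band_values.shape[0] != 2:
        raise ValueError("band_values must be (2 conditions, subjects, channels)")
    channels = channels or montage.labels
    n_subj = band_values.shape[1]
    records = []
    for left, right in montage.pairs:
        if left not in channels or right not in channels:
            continue
        li, ri = channels.index(left), channels.index(right)
        y, fc, fe = [], [], []
        for cond in range(2):
            for side, ci in (("left", li), ("right", ri)):
                y.extend(band_values[cond, :, ci])
                fc.extend([cond] * n_subj)
                fe.extend([side] * n_subj)
        tab = anova2_balanced(y, fc, fe)
        records.append({
            "pair": f"{left}-{right}",
            "amplifier": montage.amplifier[left],
            "F_condition": tab.loc["A", "F"], "p_condition": tab.loc["A", "p"],
            "F_electrode": tab.loc["B", "F"], "p_electrode": tab.loc["B", "p"],
            "F_interaction": tab.loc["A:B", "F"],
            "p_interaction": tab.loc["A:B", "p"],
            "df_effect": int(tab.loc["A", "df"]),
            "df_error": int(tab.loc["error", "df"]),
        })
    df = pd.DataFrame.from_records(records).set_index("pair")
    for effect in ("condition", "electrode", "interaction"):
        df[f"sig_{effect}"] = fdr_bh(df[f"p_{effect}"].to_numpy(), q).rejected
    return df


def lr_onesample_t(signed_diffs: np.ndarray, montage: Montage,
                   q: float = 0.05) -> pd.DataFrame:
    """One-sample t of the signed left-right difference per pair, by amplifier.

    ``signed_diffs`` is (n_subjects, n_pairs) ordered as ``montage.pairs``.
    FDR is applied within each amplifier group and the group mean difference
    is reported alongside.
    """
    signed = np.asarray(signed_diffs, float)
    pairs = montage.pairs
    if signed.ndim != 2 or signed.shape[1] != len(pairs):
        raise ValueError("signed_diffs must be (subjects, pairs)")
    if signed.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    mean = signed.mean(axis=0)
    sd = signed.std(axis=0, ddof=1)
    n = signed.shape[0]
    t = np.full(len(pairs), np.nan)
    p = np.full(len(pairs), np.nan)
    nz = sd > 0
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
    p[nz] = 2 * sps.t.sf(np.abs(t[nz]), df=n - 1)
    amp = np.array([montage.amplifier[l] for l, _ in pairs])
    rejected = np.zeros(len(pairs), bool)
    group_mean = {}
    for g in np.unique(amp):
        sel = amp == g
        rejected[sel] = fdr_bh(p[sel], q).rejected
        group_mean[int(g)] = float(mean[sel].mean())
    df = pd.DataFrame({
        "pair": [f"{l}-{r}" for l, r in pairs], "amplifier": amp,
        "mean_diff": mean, "t": t, "p": p, "significant": rejected,
    }).set_index("pair")
    df.attrs["group_mean_diff"] = group_mean
    return df


def percentile_bootstrap_diff(x: np.ndarray, y: np.ndarray, B: int = 10000,
                              seed: int = 0) -> BootstrapResult:
    """Percentile bootstrap of the paired mean difference x - y.

    Subjects are resampled with replacement; the reported statistic is the
    percentile of zero within the resampled mean differences, using a mid-rank
    convention for exact ties at zero (all-zero differences give 50%).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D (paired) arrays")
    if x.size < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    d = x - y
    idx = rng.integers(0, d.size, size=(B, d.size))
    stat = d[idx].mean(axis=1)
    below = np.count_nonzero(stat < 0)
    ties = np.count_nonzero(stat == 0)
    pct = 100.0 * (below + 0.5 * ties) / B
    return BootstrapResult(statistic=stat, percentile_of_zero=pct, B=B,
                           seed=seed)


def movement_summary(mp: MotionParams) -> float:
    """Mean instantaneous movement (mm): mean over volumes of the Euclidean
    norm of the volume-to-volume translation difference."""
    if mp.n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    step = np.diff(mp.translations, axis=0)
    return float(np.linalg.norm(step, axis=1).mean())
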