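"""Lifetime-window separation, autofluorescence exclusion, composites,
spectral+lifetime merging, and accuracy scoring against ground truth.

The fitting-based route to multiplexed unmixing: the per-pixel
intensity-weighted lifetime histogram of a multi-species sample shows one
peak per reporter, and cutting the histogram at the valleys between peaks
defines lifetime windows that assign each pixel to a species.  Short-lived
endogenous autofluorescence sits below every reporter window and is
excluded by thresholding.  Species resolved in other spectral channels are
merged in afterwards, treating detection windows as perfectly unmixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import argrelmax
from scipy.stats import gaussian_kde
from skimage.filters import threshold_otsu

from .core import LabelMask, SpeciesLabelMap
from .fitting import LifetimeMap

logger = logging.getLogger("flimplex.unmix")

#: Default composite palette: magenta / yellow / cyan, the conventional
#: pseudo-colors for short / mid / long lifetime species.
DEFAULT_PALETTE: dict[str, tuple[float, float, float]] = {
    "shortT550": (1.0, 0.0, 1.0),
    "midT550": (1.0, 1.0, 0.0),
    "longT550": (0.0, 1.0, 1.0),
    "EGFP": (0.0, 1.0, 0.0),
}


@dataclass(frozen=True)
class LifetimeWindows:
    """Ordered half-open [lower, upper) lifetime intervals, one per species.

    A value exactly on a shared boundary belongs to the upper window.
    """

    windows: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "windows", tuple(self.windows))
        labels = [w[0] for w in self.windows]
        if len(set(labels)) != len(labels):
            raise ValueError("window labels must be unique")
        prev_hi = -np.inf
        for label, lo, hi in self.windows:
            if hi <= lo:
                raise ValueError(f"window {label!r} has upper <= lower")
            if lo < prev_hi:
                raise ValueError("windows must be ascending and non-overlapping")
            prev_hi = hi

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(w[0] for w in self.windows)

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Window index (1-based) per value; 0 for NaN / outside all windows."""
        v = np.asarray(values, dtype=float)
        out = np.zeros(v.shape, dtype=np.int32)
        for i, (_, lo, hi) in enumerate(self.windows, start=1):
            out[(v >= lo) & (v < hi)] = i
        return out


def propose_windows(
    ti_values: np.ndarray,
    n_species: int,
    labels: list[str] | None = None,
    autofluorescence_cutoff_ns: float | None = None,
    grid_size: int = 1024,
) -> LifetimeWindows:
    """Cut the T_i distribution at density minima between its modes.

    A Gaussian kernel density (Silverman bandwidth) is evaluated on a dense
    grid; the ``n_species`` tallest local maxima define the species modes
    and the density minima between consecutive modes become the window
    boundaries.  With autofluorescence exclusion active, the lowest window
    starts at the cutoff instead of the data minimum.
    """
    v = np.asarray(ti_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 10 * n_species:
        raise ValueError(f"need at least {10 * n_species} finite values, have {v.size}")
    lo, hi = float(v.min()), float(v.max())
    if n_species == 1:
        lower = autofluorescence_cutoff_ns if autofluorescence_cutoff_ns is not None else lo
        name = labels[0] if labels else "species_1"
        return LifetimeWindows(((name, lower, hi + 1e-9),))
    kde = gaussian_kde(v, bw_method="silverman")
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    peaks = argrelmax(dens, order=3)[0]
    if len(peaks) < n_species:
        raise ValueError(
            f"only {len(peaks)} density modes detected but {n_species} species "
            "requested; populations may be unresolved at this photon budget"
        )
    top = np.sort(peaks[np.argsort(dens[peaks])[-n_species:]])
    bounds = []
    for a, b in zip(top[:-1], top[1:]):
        valley = a + int(np.argmin(dens[a:b]))
        bounds.append(float(grid[valley]))
    edges = [lo - 1e-9] + bounds + [hi + 1e-9]
    if autofluorescence_cutoff_ns is not None:
        if autofluorescence_cutoff_ns >= edges[1]:
            warnings.warn("autofluorescence cutoff reaches into a reporter window",
                          stacklevel=2)
        edges[0] = autofluorescence_cutoff_ns
    names = labels if labels else [f"species_{i + 1}" for i in range(n_species)]
    if len(names) != n_species:
        raise ValueError("need one label per species")
    return LifetimeWindows(
        tuple((names[i], edges[i], edges[i + 1]) for i in range(n_species))
    )


def assign_by_window(ti_map: LifetimeMap, windows: LifetimeWindows) -> SpeciesLabelMap:
    """Label each fitted pixel by the lifetime window containing its T_i."""
    labels = windows.assign(ti_map.ti)
    legend = {i + 1: name for i, name in enumerate(windows.labels)}
    return SpeciesLabelMap(labels, legend, provenance="window")


def exclude_autofluorescence(
    ti_map: LifetimeMap,
    threshold_ns: float,
    windows: LifetimeWindows | None = None,
) -> LifetimeMap:
    """Drop pixels whose lifetime falls below the autofluorescence cutoff.

    Endogenous autofluorescence decays faster than any reporter assembly,
    so selecting only lifetimes above a threshold retains the reporters.
    """
    if windows is not None and threshold_ns > windows.windows[0][1]:
        warnings.warn("autofluorescence threshold lies inside a reporter window",
                      stacklevel=2)
    ti = ti_map.ti.copy()
    chi2 = ti_map.chi2.copy()
    order = ti_map.model_order.copy()
    drop = np.isfinite(ti) & (ti < threshold_ns)
    ti[drop] = np.nan
    chi2[drop] = np.nan
    order[drop] = 0
    logger.info("excluded %d autofluorescent pixels (T_i < %.2f ns)",
                int(drop.sum()), threshold_ns)
    return LifetimeMap(ti, chi2, order, ti_map.photons, ti_map.min_photons)


def composite(
    intensity: np.ndarray,
    labels: SpeciesLabelMap,
    palette: dict[str, tuple[float, float, float]] | None = None,
    percentile: float = 99.0,
) -> np.ndarray:
    """Pseudo-color overlay: each species tints the intensity image.

    Unassigned pixels render as grayscale intensity.  Returns float RGB in
    [0, 1].
    """
    if intensity.shape != labels.labels.shape:
        raise ValueError("intensity and label shapes differ")
    palette = palette if palette is not None else DEFAULT_PALETTE
    missing = [name for name in labels.legend.values() if name not in palette]
    if missing:
        raise KeyError(f"palette missing colors for {missing}")
    scale = np.percentile(intensity[intensity > 0], percentile) if np.any(intensity > 0) else 1.0
    norm = np.clip(intensity / max(scale, 1e-12), 0.0, 1.0)
    rgb = np.repeat(norm[..., None], 3, axis=2)  # grayscale base
    for lab, name in labels.legend.items():
        m = labels.labels == lab
        rgb[m] = norm[m, None] * np.asarray(palette[name])
    return rgb


def decode_composite(
    rgb: np.ndarray,
    palette: dict[str, tuple[float, float, float]],
    legend: dict[int, str],
) -> np.ndarray:
    """Recover the label map from a noise-free composite (palette inverse)."""
    labels = np.zeros(rgb.shape[:2], dtype=np.int32)
    hue = rgb / np.clip(rgb.max(axis=2, keepdims=True), 1e-12, None)
    for lab, name in legend.items():
        target = np.asarray(palette[name])
        target = target / target.max()
        match = np.all(np.abs(hue - target) < 1e-6, axis=2) & (rgb.max(axis=2) > 0)
        labels[match] = lab
    return labels


def spectral_lifetime_merge(
    channel_intensities: dict[str, np.ndarray],
    lifetime_channel: str,
    lifetime_labels: SpeciesLabelMap | None,
    thresholds: dict[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """Combine spectrally separated channels with a lifetime-split channel.

    Each spectral channel contributes the pixels where it is the brightest
    channel above its (Otsu by default) threshold; the lifetime channel's
    pixels are then subdivided by the lifetime-based species labels.  With
    the lifetime split disabled (``lifetime_labels=None``) the lifetime
    channel counts as a single species.  Returns one boolean mask per
    species; masks are pairwise disjoint by construction.
    """
    shapes = {ch: im.shape for ch, im in channel_intensities.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"channel shapes differ: {shapes}")
    if lifetime_channel not in channel_intensities:
        raise ValueError(f"lifetime channel {lifetime_channel!r} not provided")
    channels = list(channel_intensities)
    stack = np.stack([channel_intensities[ch].astype(float) for ch in channels])
    thr = np.array(
        [
            (thresholds or {}).get(ch, _auto_threshold(channel_intensities[ch]))
            for ch in channels
        ]
    )
    thr = np.maximum(thr, 1e-12)
    above = stack >= thr[:, None, None]
    # a pixel positive in several channels goes to its brightest channel
    rel = np.where(above, stack / thr[:, None, None], -np.inf)
    winner = np.argmax(rel, axis=0)
    any_above = above.any(axis=0)
    masks: dict[str, np.ndarray] = {}
    for i, ch in enumerate(channels):
        ch_mask = any_above & (winner == i)
        if ch == lifetime_channel and lifetime_labels is not None:
            if lifetime_labels.labels.shape != ch_mask.shape:
                raise ValueError("lifetime label map shape mismatch")
            for lab, name in lifetime_labels.legend.items():
                masks[name] = ch_mask & (lifetime_labels.labels == lab)
        else:
            masks[ch] = ch_mask
    return masks


def _auto_threshold(intensity: np.ndarray) -> float:
    vals = np.asarray(intensity, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.max() <= vals.min():
        return float(vals.max()) + 1.0  # flat channel: nothing positive
    return max(float(threshold_otsu(vals)), 1e-6)


@dataclass
class SeparationScore:
    confusion: pd.DataFrame  # rows: truth species, cols: predicted (+unassigned)
    precision: pd.Series
    recall: pd.Series
    accuracy: float


def score_separation(pred: SpeciesLabelMap, truth: LabelMask) -> SeparationScore:
    """Pixelwise confusion of predicted vs ground-truth species.

    Scored over pixels with a nonzero truth label; unassigned predictions
    count as errors.  Raises if the predicted and true species sets are
    disjoint (nothing comparable).
    """
    if pred.labels.shape != truth.labels.shape:
        raise ValueError("prediction and truth shapes differ")
    true_species = sorted(set(truth.legend.values()))
    pred_species = sorted(set(pred.legend.values()))
    if not set(true_species) & set(pred_species):
        raise ValueError(
            f"no species in common between prediction {pred_species} "
            f"and truth {true_species}"
        )
    scored = truth.labels > 0
    truth_flat = truth.labels[scored]
    pred_flat = pred.labels[scored]
    t_names = np.vectorize(truth.legend.get)(truth_flat)
    p_legend = dict(pred.legend)
    p_legend[0] = "unassigned"
    p_names = np.vectorize(p_legend.get)(pred_flat)
    cols = pred_species + ["unassigned"]
    ct = pd.crosstab(pd.Series(t_names, name="truth"), pd.Series(p_names, name="pred"))
    confusion = ct.reindex(index=true_species, columns=cols, fill_value=0).astype(int)
    correct = sum(
        confusion.loc[sp, sp] for sp in true_species if sp in confusion.columns
    )
    accuracy = float(correct / max(confusion.values.sum(), 1))
    recall = pd.Series(
        {
            sp: (confusion.loc[sp, sp] / confusion.loc[sp].sum()
                 if sp in confusion.columns and confusion.loc[sp].sum() else np.nan)
            for sp in true_species
        }
    )
    precision = pd.Series(
        {
            sp: (confusion.loc[sp, sp] / confusion[sp].sum()
                 if sp in confusion.index and confusion[sp].sum() else np.nan)
            for sp in pred_species
        }
    )
    return SeparationScore(confusion, precision, recall, accuracy)
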