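"""Fit-free phasor analysis: transform, calibration, clustering, segmentation.

The phasor of a decay histogram is its first Fourier coefficient at the
laser modulation frequency, plotted as ``g = Re`` vs ``s = Im``.  All
monoexponential decays fall on the universal semicircle ``g**2 + s**2 = g``;
mixtures fall inside it, on the chord joining their pure components at the
position set by their intensity fractions.  Because the transform needs no
model of the decay, it complements reconvolution fitting: populations show
up as clusters that can be circled (manually or by a Gaussian-mixture fit)
and mapped back onto the image as a segmentation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from matplotlib.path import Path as MplPath
from sklearn.mixture import GaussianMixture

from .core import FLIMImage, SpeciesLabelMap, TimingConfig

logger = logging.getLogger("flimplex.phasor")

#: Phasor transform tolerates dimmer pixels than reconvolution fitting.
DEFAULT_MIN_PHOTONS = 50
#: Mahalanobis membership radius for auto-fitted elliptical clusters.
DEFAULT_N_SIGMA = 3.0


def angular_frequency(timing: TimingConfig, harmonic: int = 1) -> float:
    """omega = 2*pi*harmonic / period, in rad/ns."""
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    return 2.0 * np.pi * harmonic / timing.period_ns


def ideal_phasor(tau: float, omega: float) -> tuple[float, float]:
    """Phasor of an ideal monoexponential: on the universal semicircle."""
    wt = omega * tau
    d = 1.0 + wt * wt
    return 1.0 / d, wt / d


@dataclass(frozen=True)
class PhasorPoint:
    g: float
    s: float
    harmonic: int = 1
    omega: float = 0.0
    photons: float = 0.0

    @property
    def complex(self) -> complex:
        return complex(self.g, self.s)


def phasor_transform(
    hist: np.ndarray, timing: TimingConfig, harmonic: int = 1
) -> PhasorPoint:
    """Photon-weighted cosine/sine moments of one histogram (bin centers)."""
    c = np.asarray(hist, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("phasor undefined for an empty histogram")
    omega = angular_frequency(timing, harmonic)
    t = timing.bin_centers
    g = float(np.sum(c * np.cos(omega * t)) / total)
    s = float(np.sum(c * np.sin(omega * t)) / total)
    return PhasorPoint(g, s, harmonic=harmonic, omega=omega, photons=float(total))


def tau_from_phasor(point: PhasorPoint, omega: float | None = None) -> float:
    """Phase lifetime tau = s / (omega * g); undefined for g <= 0."""
    w = omega if omega is not None else point.omega
    if point.g <= 0:
        return float("nan")
    return float(point.s / (w * point.g))


@dataclass
class PhasorMap:
    """Per-pixel phasor coordinates with photon counts and calibration state."""

    g: np.ndarray
    s: np.ndarray
    photons: np.ndarray
    harmonic: int
    omega: float
    calibrated: bool = False
    reference_tau: float | None = None
    reference_point: PhasorPoint | None = None

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.g) & np.isfinite(self.s)

    def points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(g, s, photons) arrays of the valid pixels."""
        m = self.valid
        return self.g[m], self.s[m], self.photons[m]


def calibrate(
    raw: PhasorMap | PhasorPoint,
    reference_raw: PhasorPoint,
    reference_tau: float,
) -> PhasorMap | PhasorPoint:
    """Rotate/scale phasors so a known monoexponential reference lands on
    its ideal semicircle position (removes the IRF phase and modulation).
    """
    ref = reference_raw.complex
    if abs(ref) < 1e-9:
        raise ValueError("reference phasor is at the origin; cannot calibrate")
    omega = raw.omega
    ideal = complex(*ideal_phasor(reference_tau, omega))
    factor = ideal / ref
    if isinstance(raw, PhasorPoint):
        z = raw.complex * factor
        return replace(raw, g=z.real, s=z.imag)
    z = (raw.g + 1j * raw.s) * factor
    return replace(
        raw,
        g=z.real,
        s=z.imag,
        calibrated=True,
        reference_tau=reference_tau,
        reference_point=reference_raw,
    )


def _nanmedian_filter(arr: np.ndarray, radius: int) -> np.ndarray:
    """NaN-aware square median filter (vectorized via shifted stacks)."""
    if radius < 1:
        return arr
    size = 2 * radius + 1
    padded = np.pad(arr, radius, mode="constant", constant_values=np.nan)
    stack = np.empty(arr.shape + (size * size,))
    k = 0
    for dy in range(size):
        for dx in range(size):
            stack[..., k] = padded[dy : dy + arr.shape[0], dx : dx + arr.shape[1]]
            k += 1
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        out = np.nanmedian(stack, axis=-1)
    out[np.isnan(arr)] = np.nan
    return out


def phasor_image(
    img: FLIMImage,
    timing: TimingConfig | None = None,
    harmonic: int = 1,
    min_photons: int = DEFAULT_MIN_PHOTONS,
    median_filter_radius: int = 1,
    mask: np.ndarray | None = None,
) -> PhasorMap:
    """Per-pixel phasor transform with optional masking and median filtering.

    Sub-threshold or masked-out pixels are NaN and excluded downstream;
    the median filter (applied separately to g and s, NaN-aware) suppresses
    shot noise before clustering.
    """
    timing = timing or img.timing
    omega = angular_frequency(timing, harmonic)
    t = timing.bin_centers
    counts = img.counts.astype(float)
    total = counts.sum(axis=2)
    g = np.einsum("yxt,t->yx", counts, np.cos(omega * t))
    s = np.einsum("yxt,t->yx", counts, np.sin(omega * t))
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(total > 0, g / total, np.nan)
        s = np.where(total > 0, s / total, np.nan)
    exclude = total < min_photons
    if mask is not None:
        exclude |= ~np.asarray(mask, dtype=bool)
    g[exclude] = np.nan
    s[exclude] = np.nan
    if median_filter_radius >= 1:
        g = _nanmedian_filter(g, median_filter_radius)
        s = _nanmedian_filter(s, median_filter_radius)
    return PhasorMap(g, s, total, harmonic, omega)


@dataclass
class ClusterSpec:
    """A named region of phasor space used to pick out one species.

    Either an ellipse (mean/covariance at ``n_sigma`` Mahalanobis radius,
    as produced by the Gaussian-mixture fit) or a hand-drawn polygon.
    """

    label: str
    geometry: str  # "ellipse" | "polygon"
    mean: np.ndarray | None = None
    covariance: np.ndarray | None = None
    n_sigma: float = DEFAULT_N_SIGMA
    vertices: np.ndarray | None = None
    weight: float = float("nan")

    def __post_init__(self) -> None:
        if self.geometry == "ellipse":
            if self.mean is None or self.covariance is None:
                raise ValueError("ellipse cluster needs mean and covariance")
            self.mean = np.asarray(self.mean, dtype=float)
            self.covariance = np.asarray(self.covariance, dtype=float)
        elif self.geometry == "polygon":
            if self.vertices is None:
                raise ValueError("polygon cluster needs vertices")
            self.vertices = np.asarray(self.vertices, dtype=float)
        else:
            raise ValueError(f"unknown cluster geometry {self.geometry!r}")

    def mahalanobis(self, g: np.ndarray, s: np.ndarray) -> np.ndarray:
        if self.geometry != "ellipse":
            raise ValueError("Mahalanobis distance only defined for ellipses")
        d = np.stack([g - self.mean[0], s - self.mean[1]], axis=-1)
        inv = np.linalg.inv(self.covariance)
        return np.sqrt(np.einsum("...i,ij,...j->...", d, inv, d))

    def contains(self, g: np.ndarray, s: np.ndarray) -> np.ndarray:
        if self.geometry == "ellipse":
            return self.mahalanobis(g, s) <= self.n_sigma
        path = MplPath(self.vertices)
        pts = np.stack([np.ravel(g), np.ravel(s)], axis=-1)
        return path.contains_points(pts).reshape(np.shape(g))

    @property
    def phase_lifetime(self) -> float:
        """Implied monoexponential lifetime of the cluster center."""
        if self.geometry == "ellipse":
            gc, sc = self.mean
        else:
            gc, sc = self.vertices.mean(axis=0)
        return float("nan") if gc <= 0 else float(sc / gc)  # in units of 1/omega


def find_clusters(
    pmap: PhasorMap,
    k: int,
    method: str = "auto",
    manual_rois: list[ClusterSpec] | None = None,
    seed: int = 0,
    n_sigma: float = DEFAULT_N_SIGMA,
    labels: list[str] | None = None,
    n_resample: int = 20000,
) -> list[ClusterSpec]:
    """Locate k phasor clusters, one per species.

    ``auto``: photon-weighted Gaussian-mixture fit with full covariances
    (weighting via seeded resampling of points with probability
    proportional to photon count; 10 EM restarts, fixed seed).  Clusters
    are returned sorted by ascending phase lifetime so labels are stable
    under component permutation.  ``manual``: pass the user's ROIs through.
    """
    if method == "manual":
        if not manual_rois:
            raise ValueError("manual method requires ROIs")
        return list(manual_rois)
    if method != "auto":
        raise ValueError(f"unknown method {method!r}")
    g, s, w = pmap.points()
    if g.size < 50 * k:
        raise ValueError(f"need at least {50 * k} valid points, have {g.size}")
    pts = np.stack([g, s], axis=1)
    if np.allclose(pts.std(axis=0), 0.0):
        raise ValueError("degenerate phasor cloud: all points identical")
    rng = np.random.default_rng(seed)
    p = w / w.sum()
    idx = rng.choice(g.size, size=n_resample, replace=True, p=p)
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=10,
        random_state=int(seed) % (2**32),
        reg_covar=1e-9,
    ).fit(pts[idx])
    order = np.argsort([m[1] / m[0] if m[0] > 0 else np.inf for m in gm.means_])
    specs = []
    for rank, comp in enumerate(order):
        label = labels[rank] if labels else f"cluster_{rank + 1}"
        specs.append(
            ClusterSpec(
                label=label,
                geometry="ellipse",
                mean=gm.means_[comp],
                covariance=gm.covariances_[comp],
                n_sigma=n_sigma,
                weight=float(gm.weights_[comp]),
            )
        )
    return specs


def segment(pmap: PhasorMap, clusters: list[ClusterSpec]) -> SpeciesLabelMap:
    """Assign each valid pixel to the cluster containing its phasor.

    Overlaps between elliptical clusters resolve to the nearest Mahalanobis
    distance; polygon overlaps resolve by list order (logged).  Pixels in
    no cluster stay unassigned (0).
    """
    labels = np.zeros(pmap.g.shape, dtype=np.int32)
    legend = {i + 1: c.label for i, c in enumerate(clusters)}
    if not clusters:
        return SpeciesLabelMap(labels, legend, provenance="phasor")
    valid = pmap.valid
    g, s = pmap.g, pmap.s
    best_d = np.full(pmap.g.shape, np.inf)
    overlap_pixels = 0
    for i, cluster in enumerate(clusters, start=1):
        with np.errstate(invalid="ignore"):
            inside = np.zeros_like(valid)
            inside[valid] = cluster.contains(g[valid], s[valid])
        if cluster.geometry == "ellipse":
            d = np.full(pmap.g.shape, np.inf)
            d[valid] = cluster.mahalanobis(g[valid], s[valid])
            take = inside & (d < best_d)
            overlap_pixels += int(np.count_nonzero(inside & (labels > 0)))
            labels[take] = i
            best_d[take] = d[take]
        else:
            # polygon: first listed cluster wins
            take = inside & (labels == 0)
            overlap_pixels += int(np.count_nonzero(inside & (labels > 0)))
            labels[take] = i
    if overlap_pixels:
        logger.info("%d pixels fell in overlapping clusters; precedence applied",
                    overlap_pixels)
    return SpeciesLabelMap(labels, legend, provenance="phasor")
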