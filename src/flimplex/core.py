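"""Shared domain objects for TCSPC-FLIM simulation and analysis.

The central physical model: an emissive species excited by a pulsed laser
with repetition period ``T`` decays as a sum of exponentials
``f(t) = sum_i a_i exp(-t / tau_i)``.  The detected per-pixel arrival
histogram is the circular (periodic) convolution of that decay with the
instrument response function (IRF), because photons from earlier pulses
whose decay has not finished wrap into the current period.  Everything in
this module works with one laser period divided into ``n_bins`` equal time
bins and treats histograms as probability masses per bin.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

logger = logging.getLogger("flimplex")

#: FWHM of a Gaussian = FWHM_SIGMA_RATIO * sigma
FWHM_SIGMA_RATIO = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class TimingConfig:
    """Laser repetition period and TCSPC binning.

    Defaults correspond to a typical 80 MHz pulsed laser (12.5 ns period)
    histogrammed into 256 bins of ~48.8 ps.
    """

    period_ns: float = 12.5
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.period_ns <= 0:
            raise ValueError("period_ns must be positive")
        if self.n_bins < 32:
            raise ValueError("n_bins must be >= 32")

    @property
    def bin_width_ns(self) -> float:
        return self.period_ns / self.n_bins

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.period_ns, self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ns


@dataclass(frozen=True)
class IRFModel:
    """Instrument response: Gaussian, delta, or a measured histogram.

    ``center_t0`` is the arrival-time offset of the excitation pulse within
    the recorded period; ``fwhm`` the full width at half maximum of a
    Gaussian response (ignored for ``delta``).  A ``measured-histogram``
    kind carries its own per-bin histogram, which is normalized on use.
    """

    center_t0: float = 2.0
    fwhm: float = 0.2
    kind: str = "gaussian"
    histogram: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fwhm < 0:
            raise ValueError("IRF fwhm must be >= 0")
        if self.kind not in ("gaussian", "delta", "measured-histogram"):
            raise ValueError(f"unknown IRF kind {self.kind!r}")
        if self.kind == "measured-histogram" and self.histogram is None:
            raise ValueError("measured-histogram IRF requires a histogram")

    @property
    def sigma(self) -> float:
        return self.fwhm / FWHM_SIGMA_RATIO


def make_irf(irf: IRFModel, timing: TimingConfig) -> np.ndarray:
    """Materialize the IRF as a per-bin probability histogram (sums to 1).

    In the circular convolution a histogram bin ``m`` acts as a shift by
    ``m`` bins, so the delta kind splits its mass linearly between the two
    bins whose shifts bracket ``center_t0`` (a delta at t0 = 0 is exactly
    the identity).  The Gaussian kind integrates the density over each bin
    (via the error function) and wraps tails across the period boundary.
    """
    n = timing.n_bins
    dt = timing.bin_width_ns
    t0 = irf.center_t0 % timing.period_ns

    if irf.kind == "measured-histogram":
        h = np.asarray(irf.histogram, dtype=float)
        if h.shape != (n,):
            raise ValueError("measured IRF histogram length must equal n_bins")
        if np.any(h < 0):
            raise ValueError("measured IRF histogram must be non-negative")
        s = h.sum()
        if s <= 0:
            raise ValueError("measured IRF histogram must have positive mass")
        return h / s

    if irf.kind == "delta" or irf.sigma == 0.0:
        h = np.zeros(n)
        pos = t0 / dt
        k = int(np.floor(pos)) % n
        frac = pos - np.floor(pos)
        h[k] += 1.0 - frac
        h[(k + 1) % n] += frac
        return h

    edges = timing.bin_edges
    h = np.zeros(n)
    sig = irf.sigma
    for wrap in (-1, 0, 1):
        mu = t0 + wrap * timing.period_ns
        z = (edges - mu) / (sig * math.sqrt(2.0))
        cdf = 0.5 * (1.0 + erf(z))
        h += np.diff(cdf)
    total = h.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        # tails further than one period away are negligible for any sane fwhm
        logger.debug("IRF mass after wrapping = %.9f; renormalizing", total)
    return h / total


@dataclass(frozen=True)
class DecayParams:
    """Multi-exponential decay: amplitudes (photon-rate scale) and lifetimes.

    Lifetimes are stored sorted ascending with their amplitudes carried
    along.  The *intensity fraction* of component ``i`` is
    ``a_i * tau_i / sum_j a_j * tau_j`` — the share of detected photons it
    contributes — and is the natural weight for the intensity-weighted
    average lifetime.
    """

    amplitudes: tuple[float, ...]
    lifetimes: tuple[float, ...]

    def __post_init__(self) -> None:
        a = tuple(float(x) for x in self.amplitudes)
        tau = tuple(float(x) for x in self.lifetimes)
        if len(a) != len(tau):
            raise ValueError("amplitudes and lifetimes must have equal length")
        if not 1 <= len(tau) <= 3:
            raise ValueError("1 to 3 decay components supported")
        if any(t <= 0 for t in tau):
            raise ValueError("all lifetimes must be positive")
        if any(x < 0 for x in a):
            raise ValueError("amplitudes must be non-negative")
        if not any(x > 0 for x in a):
            raise ValueError("at least one amplitude must be positive")
        order = np.argsort(tau)
        object.__setattr__(self, "amplitudes", tuple(a[i] for i in order))
        object.__setattr__(self, "lifetimes", tuple(tau[i] for i in order))

    @property
    def n_components(self) -> int:
        return len(self.lifetimes)

    @property
    def intensity_fractions(self) -> tuple[float, ...]:
        w = np.array(self.amplitudes) * np.array(self.lifetimes)
        w = w / w.sum()
        return tuple(w)

    @classmethod
    def monoexp(cls, tau: float, amplitude: float = 1.0) -> "DecayParams":
        return cls((amplitude,), (tau,))

    @classmethod
    def from_intensity_fractions(
        cls, fractions: tuple[float, ...], lifetimes: tuple[float, ...]
    ) -> "DecayParams":
        """Build params whose photon shares equal ``fractions``."""
        f = np.asarray(fractions, dtype=float)
        tau = np.asarray(lifetimes, dtype=float)
        if np.any(f < 0) or f.sum() <= 0:
            raise ValueError("fractions must be non-negative with positive sum")
        f = f / f.sum()
        a = f / tau
        return cls(tuple(a), tuple(tau))


def _periodic_exp_bin_mass(tau: float, timing: TimingConfig) -> np.ndarray:
    """Exact per-bin integral of the periodic exponential decay.

    For a decay ``exp(-t/tau)`` excited every period ``T``, the steady-state
    intensity at ``t in [0, T)`` is ``exp(-t/tau) / (1 - exp(-T/tau))``;
    integrating over each bin gives the per-bin photon mass (unnormalized).
    """
    edges = timing.bin_edges
    q = np.exp(-edges / tau)
    seg = tau * (q[:-1] - q[1:])
    return seg / -np.expm1(-timing.period_ns / tau)


def expected_decay(
    params: DecayParams,
    irf: IRFModel | np.ndarray,
    timing: TimingConfig,
) -> np.ndarray:
    """Expected per-bin photon probabilities for a multi-exponential decay.

    Circularly convolves the periodic (wraparound-corrected) decay with the
    IRF histogram and normalizes to unit total, so multiplying by an
    expected photon count gives per-bin Poisson means.
    """
    for tau in params.lifetimes:
        if tau >= 10 * timing.period_ns:
            warnings.warn(
                f"lifetime {tau} ns >= 10x period {timing.period_ns} ns: "
                "histogram is wraparound-dominated and nearly uniform",
                stacklevel=2,
            )
    irf_hist = irf if isinstance(irf, np.ndarray) else make_irf(irf, timing)
    a = np.asarray(params.amplitudes)
    shape = np.zeros(timing.n_bins)
    for ai, tau in zip(a, params.lifetimes):
        if ai > 0:
            shape += ai * _periodic_exp_bin_mass(tau, timing)
    out = np.fft.irfft(np.fft.rfft(shape) * np.fft.rfft(irf_hist), n=timing.n_bins)
    np.clip(out, 0.0, None, out=out)
    return out / out.sum()


@dataclass
class FLIMImage:
    """A TCSPC-FLIM acquisition: per-pixel photon-count histograms.

    ``counts`` has axes (y, x, time-bin); integers, non-negative.
    """

    counts: np.ndarray
    timing: TimingConfig
    channel: str = "green"
    irf: IRFModel | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValueError("counts must be a 3-D (y, x, t) array")
        if c.shape[2] != self.timing.n_bins:
            raise ValueError(
                f"third axis length {c.shape[2]} != n_bins {self.timing.n_bins}"
            )
        if not np.issubdtype(c.dtype, np.integer):
            if np.any(c != np.round(c)):
                raise ValueError("counts must be integer-valued")
            c = c.astype(np.uint32)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        self.counts = c

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def intensity(self) -> np.ndarray:
        """Total photons per pixel (the intensity image)."""
        return self.counts.sum(axis=2)


@dataclass
class LabelMask:
    """Ground-truth per-pixel species labels (0 = background)."""

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2-D")
        present = set(np.unique(lab).tolist()) - {0}
        unknown = present - set(self.legend)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from legend")
        self.labels = lab.astype(np.int32)

    def mask_for(self, species: str) -> np.ndarray:
        ids = [k for k, v in self.legend.items() if v == species]
        if not ids:
            raise KeyError(f"species {species!r} not in legend")
        return np.isin(self.labels, ids)


@dataclass
class SpeciesLabelMap:
    """Predicted per-pixel species assignment (0 = unassigned/excluded)."""

    labels: np.ndarray
    legend: dict[int, str]
    provenance: str = "window"

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2-D")
        present = set(np.unique(lab).tolist()) - {0}
        unknown = present - set(self.legend)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from legend")
        self.labels = lab.astype(np.int32)
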