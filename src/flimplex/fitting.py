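"""Mono/biexponential reconvolution fitting of TCSPC histograms.

Per-pixel photon counts are low, so fits maximize the Poisson likelihood
(minimize the deviance ``2*sum(E - O + O*ln(O/E))``) rather than least
squares.  The reduced chi-square is computed post hoc with Pearson
weighting for reporting and model selection.  The headline summary of a
fit is the intensity-weighted average lifetime

    T_i = sum(a_i * tau_i**2) / sum(a_i * tau_i),

which is comparable across mono- and biexponentially decaying reporters
and is the quantity used for lifetime-window unmixing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize

from .core import DecayParams, FLIMImage, IRFModel, TimingConfig, make_irf, _periodic_exp_bin_mass

logger = logging.getLogger("flimplex.fitting")

#: Pixels with fewer photons than this are refused / NaN in maps.
DEFAULT_MIN_PHOTONS = 100
#: Reduced chi-square improvement required to prefer the biexponential model.
DEFAULT_DELTA_CHI2 = 0.1
#: Minor-component intensity fraction below which a biexponential fit is
#: treated as effectively monoexponential during model selection.
MIN_MINOR_FRACTION = 0.01

_TAU_LO = 0.05  # ns, lower lifetime bound


def intensity_weighted_lifetime(params: DecayParams) -> float:
    """T_i = sum(a_i tau_i^2) / sum(a_i tau_i); invariant to amplitude scaling."""
    a = np.asarray(params.amplitudes)
    tau = np.asarray(params.lifetimes)
    denom = float(np.sum(a * tau))
    if denom <= 0:
        raise ValueError("intensity-weighted lifetime undefined: all amplitudes zero")
    return float(np.sum(a * tau**2) / denom)


def amplitude_weighted_lifetime(params: DecayParams) -> float:
    """T_a = sum(a_i tau_i) / sum(a_i); never exceeds T_i (Cauchy-Schwarz)."""
    a = np.asarray(params.amplitudes)
    s = float(np.sum(a))
    if s <= 0:
        raise ValueError("amplitude-weighted lifetime undefined: all amplitudes zero")
    return float(np.sum(a * np.asarray(params.lifetimes)) / s)


def mean_arrival_time(
    hist: np.ndarray,
    timing: TimingConfig,
    t0: float = 0.0,
    background_per_bin: float = 0.0,
) -> float:
    """First moment of the (background-subtracted) histogram relative to t0.

    Arrival times are taken at bin centers, wrapped modulo the period so
    photons detected before ``t0`` (from the tail of the previous pulse)
    contribute at their true delay.  NaN when no photons remain.
    """
    c = np.asarray(hist, dtype=float) - background_per_bin
    np.clip(c, 0.0, None, out=c)
    total = c.sum()
    if total <= 0:
        return float("nan")
    t = (timing.bin_centers - t0) % timing.period_ns
    return float(np.sum(c * t) / total)


def wraparound_corrected_lifetime(mean_t: float, period_ns: float) -> float:
    """Invert the periodic-decay first moment to a monoexponential lifetime.

    For a periodic exponential observed over one period, the mean delay is
    ``tau - T / (exp(T/tau) - 1)`` < tau; this solves that relation for tau.
    """
    if not np.isfinite(mean_t) or mean_t <= 0:
        return float("nan")
    if mean_t >= period_ns / 2:
        # mean of a uniform histogram; lifetime unidentifiable
        return float("inf")

    def f(tau: float) -> float:
        with np.errstate(over="ignore"):
            return tau - period_ns / np.expm1(period_ns / tau) - mean_t

    return brentq(f, 1e-4, 100.0 * period_ns)


def reduced_chi2(
    observed: np.ndarray,
    fitted: np.ndarray,
    n_free_params: int,
    expected_floor: float = 1.0,
) -> float:
    """Pearson reduced chi-square over bins with fitted counts >= floor."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(fitted, dtype=float)
    use = e >= expected_floor
    dof = int(np.count_nonzero(use)) - n_free_params
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom ({dof})")
    return float(np.sum((o[use] - e[use]) ** 2 / e[use]) / dof)


@dataclass
class FitResult:
    """Outcome of a per-pixel/per-region reconvolution fit."""

    params: DecayParams
    t0: float
    background: float  # total background counts over the period
    reduced_chi2: float
    n_photons: float
    model_order: int
    ti: float
    ta: float
    converged: bool
    fitted_curve: np.ndarray | None = None
    deviance: float = float("nan")


class _CurveFactory:
    """Precomputed machinery to evaluate expected histograms quickly."""

    def __init__(self, irf: IRFModel | np.ndarray, timing: TimingConfig):
        self.timing = timing
        self.n_bins = timing.n_bins
        self.edges = timing.bin_edges
        hist = irf if isinstance(irf, np.ndarray) else make_irf(irf, timing)
        self.irf_rfft = np.fft.rfft(hist)

    def shape(self, taus: np.ndarray, int_fracs: np.ndarray) -> np.ndarray:
        """Unit-sum expected histogram for given lifetimes/photon shares."""
        out = np.zeros(self.n_bins)
        for tau, f in zip(taus, int_fracs):
            seg = _periodic_exp_bin_mass(tau, self.timing)
            out += f * (seg / seg.sum())
        curve = np.fft.irfft(np.fft.rfft(out) * self.irf_rfft, n=self.n_bins)
        np.clip(curve, 1e-300, None, out=curve)
        return curve / curve.sum()


def _deviance(obs: np.ndarray, exp: np.ndarray) -> float:
    pos = obs > 0
    dev = 2.0 * (exp.sum() - obs.sum())
    dev += 2.0 * float(np.sum(obs[pos] * np.log(obs[pos] / exp[pos])))
    return dev


def fit_decay(
    hist: np.ndarray,
    irf: IRFModel | np.ndarray,
    timing: TimingConfig,
    n_components: int = 2,
    init: DecayParams | None = None,
    min_photons: int = DEFAULT_MIN_PHOTONS,
    t0: float | None = None,
    _factory: _CurveFactory | None = None,
) -> FitResult:
    """Poisson-MLE reconvolution fit of one histogram.

    The model is ``E_k = N * p_k(tau, f) + B / n_bins`` with ``p`` the
    IRF-convolved periodic decay shape, ``N`` signal photons and ``B`` a
    uniform background.  Mono fits seed from the wraparound-corrected first
    moment; biexponential fits seed at (0.5x, 1.5x) the moment lifetime
    with equal photon shares — deterministic, no random restarts.
    Non-convergence is flagged on the result, not raised.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    obs = np.asarray(hist, dtype=float)
    total = obs.sum()
    if total < min_photons:
        raise ValueError(
            f"histogram has {total:.0f} photons, below the minimum of {min_photons}"
        )
    fac = _factory or _CurveFactory(irf, timing)
    n_bins = timing.n_bins
    if t0 is None:
        t0 = irf.center_t0 if isinstance(irf, IRFModel) else 0.0

    # deterministic initialization from the first moment
    if init is not None:
        taus0 = np.asarray(init.lifetimes, dtype=float)
        fracs0 = np.asarray(init.intensity_fractions, dtype=float)
        if len(taus0) != n_components:
            raise ValueError("init has wrong number of components")
    else:
        m = mean_arrival_time(obs, timing, t0=t0)
        tau_m = wraparound_corrected_lifetime(m, timing.period_ns)
        if not np.isfinite(tau_m):
            tau_m = 0.25 * timing.period_ns
        tau_m = float(np.clip(tau_m, 2 * _TAU_LO, 0.8 * timing.period_ns))
        if n_components == 1:
            taus0 = np.array([tau_m])
            fracs0 = np.array([1.0])
        else:
            taus0 = np.array([0.5 * tau_m, 1.5 * tau_m])
            fracs0 = np.array([0.5, 0.5])

    bg0 = max(1e-3 * total, float(n_bins * max(np.percentile(obs, 2), 1e-6)) * 0.5)
    bg0 = min(bg0, 0.5 * total)
    sig0 = max(total - bg0, 1.0)

    log_tau_bounds = (np.log(_TAU_LO), np.log(timing.period_ns))
    if n_components == 1:
        x0 = np.array([np.log(taus0[0]), np.log(sig0), np.log(bg0)])
        bounds = [log_tau_bounds, (None, None), (np.log(1e-6), np.log(total + 1.0))]
    else:
        f1 = float(np.clip(fracs0[0], 1e-4, 1 - 1e-4))
        x0 = np.array(
            [np.log(taus0[0]), np.log(taus0[1]), np.log(f1 / (1 - f1)),
             np.log(sig0), np.log(bg0)]
        )
        bounds = [log_tau_bounds, log_tau_bounds, (-12.0, 12.0),
                  (None, None), (np.log(1e-6), np.log(total + 1.0))]

    def unpack(x):
        if n_components == 1:
            taus = np.exp(x[:1])
            fracs = np.array([1.0])
            n_sig, bg = np.exp(x[1]), np.exp(x[2])
        else:
            taus = np.exp(x[:2])
            f1 = 1.0 / (1.0 + np.exp(-x[2]))
            fracs = np.array([f1, 1.0 - f1])
            n_sig, bg = np.exp(x[3]), np.exp(x[4])
        return taus, fracs, n_sig, bg

    def objective(x):
        taus, fracs, n_sig, bg = unpack(x)
        exp_counts = n_sig * fac.shape(taus, fracs) + bg / n_bins
        return _deviance(obs, exp_counts)

    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 200, "ftol": 1e-10})
    taus, fracs, n_sig, bg = unpack(res.x)
    order = np.argsort(taus)
    taus, fracs = taus[order], fracs[order]
    params = DecayParams.from_intensity_fractions(tuple(fracs), tuple(taus))
    curve = n_sig * fac.shape(taus, fracs) + bg / n_bins
    n_free = 3 if n_components == 1 else 5
    chi2 = reduced_chi2(obs, curve, n_free)
    if not res.success:
        logger.debug("fit did not converge: %s", res.message)
    return FitResult(
        params=params,
        t0=float(t0),
        background=float(bg),
        reduced_chi2=chi2,
        n_photons=float(total),
        model_order=n_components,
        ti=intensity_weighted_lifetime(params),
        ta=amplitude_weighted_lifetime(params),
        converged=bool(res.success),
        fitted_curve=curve,
        deviance=float(res.fun),
    )


def select_model(
    fit_mono: FitResult,
    fit_bi: FitResult,
    delta_threshold: float = DEFAULT_DELTA_CHI2,
) -> FitResult:
    """Pick mono vs biexponential by reduced chi-square improvement.

    The biexponential wins only if it improves the reduced chi-square by
    more than ``delta_threshold`` *and* its minor component carries at
    least 1 % of the photons; ties and marginal gains go to the simpler
    model.  An unconverged fit defers to the other.
    """
    if fit_mono.model_order != 1 or fit_bi.model_order != 2:
        raise ValueError("arguments must be (mono fit, bi fit)")
    if not fit_bi.converged and fit_mono.converged:
        logger.info("biexponential fit unconverged; keeping monoexponential")
        return fit_mono
    if not fit_mono.converged and fit_bi.converged:
        logger.info("monoexponential fit unconverged; keeping biexponential")
        return fit_bi
    minor = min(fit_bi.params.intensity_fractions)
    improved = (fit_mono.reduced_chi2 - fit_bi.reduced_chi2) > delta_threshold
    chosen = fit_bi if (improved and minor >= MIN_MINOR_FRACTION) else fit_mono
    logger.debug(
        "model selection: chi2 mono=%.3f bi=%.3f minor=%.3f -> order %d",
        fit_mono.reduced_chi2, fit_bi.reduced_chi2, minor, chosen.model_order,
    )
    return chosen


@dataclass
class LifetimeMap:
    """Per-pixel fit summaries: T_i, reduced chi-square, model order, photons."""

    ti: np.ndarray
    chi2: np.ndarray
    model_order: np.ndarray
    photons: np.ndarray
    min_photons: int = DEFAULT_MIN_PHOTONS

    def __post_init__(self) -> None:
        below = self.photons < self.min_photons
        if np.any(np.isfinite(self.ti) & below):
            raise ValueError("finite T_i present below the photon threshold")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.ti)


def _block_bin(counts: np.ndarray, k: int) -> np.ndarray:
    """Sum k x k pixel blocks of histograms, replicated back to full size."""
    y, x, t = counts.shape
    ky, kx = (y + k - 1) // k, (x + k - 1) // k
    padded = np.zeros((ky * k, kx * k, t), dtype=counts.dtype)
    padded[:y, :x] = counts
    pooled = padded.reshape(ky, k, kx, k, t).sum(axis=(1, 3))
    return np.repeat(np.repeat(pooled, k, axis=0), k, axis=1)[:y, :x]


def fit_image(
    img: FLIMImage,
    irf: IRFModel | np.ndarray | None = None,
    timing: TimingConfig | None = None,
    binning: int = 1,
    min_photons: int = DEFAULT_MIN_PHOTONS,
    n_components: int = 2,
    select_order: bool = False,
    delta_threshold: float = DEFAULT_DELTA_CHI2,
) -> LifetimeMap:
    """Fit every sufficiently bright pixel; NaN elsewhere.

    With ``binning=k`` each pixel is fitted on the pooled histogram of its
    k x k block (the map keeps full resolution; block pixels share one
    fit).  A 3x3 binning is suggested in the log when the median labeled
    pixel falls below ``min_photons``.
    """
    timing = timing or img.timing
    irf = irf if irf is not None else (img.irf or IRFModel())
    counts = img.counts
    if counts.size == 0:
        empty = np.empty(img.shape)
        return LifetimeMap(empty * np.nan, empty * np.nan, np.zeros(img.shape, int),
                           np.zeros(img.shape), min_photons)
    if binning > 1:
        counts = _block_bin(counts, binning)
    photons = counts.sum(axis=2).astype(float)
    nonzero = photons[photons > 0]
    if binning == 1 and nonzero.size and np.median(nonzero) < min_photons:
        logger.info(
            "median occupied pixel has %.0f photons (< %d); consider 3x3 binning",
            np.median(nonzero), min_photons,
        )

    fac = _CurveFactory(irf, timing)
    t0 = irf.center_t0 if isinstance(irf, IRFModel) else 0.0
    ti = np.full(img.shape, np.nan)
    chi2 = np.full(img.shape, np.nan)
    order_map = np.zeros(img.shape, dtype=np.int8)

    # fit each distinct binned histogram once (blocks share fits)
    cache: dict[tuple[int, int], FitResult] = {}
    ys, xs = np.nonzero(photons >= min_photons)
    for yy, xx in zip(ys, xs):
        key = (yy // binning, xx // binning) if binning > 1 else (yy, xx)
        fit = cache.get(key)
        if fit is None:
            hist = counts[yy, xx]
            if select_order:
                f1 = fit_decay(hist, irf, timing, 1, min_photons=min_photons,
                               t0=t0, _factory=fac)
                f2 = fit_decay(hist, irf, timing, 2, min_photons=min_photons,
                               t0=t0, _factory=fac)
                fit = select_model(f1, f2, delta_threshold)
            else:
                fit = fit_decay(hist, irf, timing, n_components,
                                min_photons=min_photons, t0=t0, _factory=fac)
            fit.fitted_curve = None  # keep the cache light
            cache[key] = fit
        ti[yy, xx] = fit.ti
        chi2[yy, xx] = fit.reduced_chi2
        order_map[yy, xx] = fit.model_order

    return LifetimeMap(ti, chi2, order_map, photons, min_photons)
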