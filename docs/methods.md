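# Methods

## Signal model

A pulsed laser with repetition period `T` excites the sample every
period; the TCSPC electronics histogram each detected photon's delay into
`n_bins` equal bins. A species with decay `f(t) = Σᵢ aᵢ exp(−t/τᵢ)`
reaches a periodic steady state in which the intensity at delay
`t ∈ [0, T)` is `exp(−t/τ)/(1 − exp(−T/τ))` per component — the geometric
sum over all earlier pulses whose decay has not finished ("incomplete
decay" or wraparound). `expected_decay` integrates this periodic decay
exactly over each bin, circularly convolves it with the binned instrument
response, and normalizes to unit mass; multiplying by a photon budget
gives per-bin Poisson means. Sampling is Poisson per bin, which is
distributionally identical to drawing a Poisson total and splitting it
multinomially over the curve, and is exactly reproducible from a seed.

Discretization convention: a histogram bin used as a convolution kernel
acts as a shift by its index, so a delta IRF at `t0 = 0` is exactly the
identity and moment-based oracles (below) carry no half-bin offset. Bin
centers are used wherever a bin must stand for a single time (moments,
phasor transform).

Timing defaults are 12.5 ns / 256 bins (an 80 MHz laser); the IRF
defaults to a Gaussian with 0.2 ns FWHM centered at 2.0 ns, typical of a
confocal TCSPC response, with the rising edge safely inside the window.
Acquisition timing is instrument configuration, not a property of the
reporters, so these are package defaults, stated here as such.

## Lifetime summaries and their oracles

For fitted parameters the intensity-weighted average lifetime is
`T_i = Σ aᵢτᵢ²/Σ aᵢτᵢ` and the amplitude-weighted one
`T_a = Σ aᵢτᵢ/Σ aᵢ`; `T_i ≥ T_a` always (Cauchy–Schwarz), with equality
only for a single effective component. Two fit-free identities anchor
the test suite:

* the first moment of the expected histogram (delta IRF, negligible
  wraparound) equals `T_i` — the mean photon arrival time estimates
  `T_i` without any model;
* over one period the mean delay of a periodic monoexponential is
  `τ − T/(exp(T/τ) − 1)`; `wraparound_corrected_lifetime` inverts this,
  so moment estimates remain unbiased at 12.5 ns periods where the raw
  moment is ~0.02 ns low for τ ≈ 2 ns.

## Fitting

Per-pixel counts are low (hundreds to thousands of photons over 256
bins), so fits maximize the Poisson likelihood — minimizing the deviance
`2 Σ [E_k − O_k + O_k ln(O_k/E_k)]` — rather than least squares. The
model is `E_k = N·p_k(τ, f) + B/n_bins` with `p` the IRF-convolved
periodic decay shape, `N` signal photons and `B` a uniform background.
Parameters are optimized in log (lifetimes, N, B) and logit (photon-share
fraction) space with L-BFGS-B; lifetimes are bounded to
[0.05 ns, period]. Initialization is deterministic: the mono fit seeds
from the wraparound-corrected first moment, the biexponential fit at
(0.5×, 1.5×) that lifetime with equal photon shares — no random
restarts, so refits are bit-reproducible and permuting the initial
component order changes nothing beyond convergence tolerance.

The reduced χ² is computed post hoc with Pearson weighting
(`Σ (O−E)²/E`) over bins with at least one expected count, divided by
(bins used − free parameters). On well-specified simulations it averages
1.00 (the acceptance suite checks ±0.1). Model selection keeps the
monoexponential unless the biexponential improves reduced χ² by more
than 0.1 *and* its minor component carries ≥1 % of the photons; ties go
to the simpler model. The 0.1 threshold is a package decision calibrated
so that decays whose mono and bi fits are statistically equivalent
resolve to monoexponential while a genuine two-component decay
(0.8/2.4 ns, equal photon shares, 10⁴ photons) is detected in ≥90 % of
replicates.

`fit_image` fits the biexponential model per pixel by default — a single
model order keeps `T_i` comparable across reporters regardless of their
true decay shape — with per-pixel selection available behind
`select_order=True`. Pixels below `min_photons` (default 100) are NaN.
`binning=k` pools k×k blocks of histograms before fitting and shares the
fit across the block.

### Why the three-species analyses use 3×3 binning

At 10³ photons per pixel the shot-noise floor of any per-pixel lifetime
estimate is ≈0.08 ns (measured: moment-estimator SD 0.080–0.084 ns;
biexponential-fit `T_i` SD 0.05–0.10 ns). The closest reporter pair
(1.89 vs 2.10 ns) is then only ~2σ apart per pixel and their histogram
modes merge. Pooling 3×3 blocks (9×10³ photons per fit) brings the SD to
≈0.03 ns, cleanly trimodal, at a 3-pixel resolution cost that is
negligible for nucleus-sized structures. This mirrors standard FLIM
practice and the phasor route's 3×3 median filter. Two-region scenes
with larger gaps are analyzed unbinned.

## Phasor analysis

The transform takes photon-weighted cosine/sine moments at
`ω = 2π·harmonic/T` (first harmonic by default — a single modulation
separates all species here). Calibration multiplies every phasor by
`ideal(τ_ref)/measured(reference)` as complex numbers, which removes the
IRF phase/modulation; the suite uses a simulated monoexponential
reference recorded with the same IRF and timing, standing in for the
dye/fluorophore standard used on a real instrument. After calibration
monoexponentials satisfy `|g² + s² − g| < 0.01` at 10⁵ photons, mixtures
lie on chords at their intensity fractions (exactly, in expectation —
the transform is linear in the histogram), and the phase lifetime
`τ = s/(ωg)` inverts the semicircle. A biexponential with `T_i = x`
does *not* share the phasor of a monoexponential `τ = x`; the suite
asserts the inequality to keep the two summaries distinct.

Per-pixel maps apply a NaN-aware 3×3 median filter to g and s before
clustering (radius configurable) and exclude pixels below 50 photons —
more tolerant than the fitting threshold, since no model is inverted.
Automatic clustering fits a k-component full-covariance Gaussian mixture.
Scikit-learn's EM has no per-sample weights, so photon weighting is
implemented by seeded resampling of 20 000 points with probability
proportional to photon count before the fit (10 EM restarts, fixed
seed). Components are returned sorted by phase lifetime, making labels
invariant to EM component permutation. Manual ROIs (ellipses or
polygons) are first-class, mirroring how clusters are circled by hand in
practice.

Cluster membership uses a Mahalanobis radius of 3σ for fitted ellipses;
overlaps resolve to the nearest Mahalanobis distance, polygon overlaps
to list order. A 2σ radius was considered and rejected: in two
dimensions it covers only 86.5 % of a Gaussian cluster, so ~13 % of
pixels of a perfectly separated population would land outside every
ellipse and count as unassigned. 3σ covers 98.9 %.

## Separation and merging

Window unmixing smooths the `T_i` distribution with a Gaussian kernel
density (Silverman bandwidth), takes the `n` tallest modes, and cuts at
the density minima between them; windows are half-open `[lower, upper)`,
so a value exactly on a boundary belongs to the upper window. Manual
windows always override. Autofluorescence — modeled as a 0.6 ns
monoexponential, faster than every reporter — is excluded by dropping
pixels with `T_i` below a threshold placed under the lowest reporter
window.

The spectral+lifetime merge treats detection channels as perfectly
unmixed (distinct detection windows; spectral bleed-through is out of
scope): each channel claims pixels above its Otsu threshold, conflicts
go to the brightest channel, and the lifetime channel's pixels are
subdivided by the lifetime labels — six disjoint species masks for the
four-channel, green-split-three-ways scenario. Scoring against ground
truth counts unassigned predictions as errors and reports a full
confusion matrix with per-species precision/recall.

## The scene simulator

Scenes emulate the cellular geometries used to validate lifetime
multiplexing: nuclei as filled ellipses (H2B fusions), mitochondria as
scattered small blobs, microtubules as dilated persistent random walks
(MAP4 fusions), cytosol as a cell ellipse minus its nucleus. Regions are
placed without overlap where possible; genuine overlaps resolve to the
later region, logged. Per-species photon budgets are independent knobs,
reflecting how expression levels are balanced experimentally to equalize
signals.

Reporter decays default to a mild biexponential — a fast component at
0.6× the slow lifetime carrying 15 % of the photons, slow lifetime
solved so `T_i` matches the published value (1.45/1.89/2.10 ns for
shortT550/midT550/longT550; EGFP 2.6 ns and autofluorescence 0.6 ns are
monoexponential). Published characterizations report bi- or
near-mono-exponential decays without printing component values, so the
15 %/0.6× shape is this package's realistic stand-in.

What the simulator deliberately omits: optics/PSF blur, detector
afterpulsing and pile-up, spectral bleed-through, cell-to-cell lifetime
variability, and motion. Passing tests therefore demonstrate the
correctness and statistical calibration of the analysis under ideal
acquisition, not robustness to instrument artifacts — on real data the
same pipeline would additionally face IRF drift and background structure
that these tests do not probe.

## Problem sizes and numerical choices

Test and acceptance runs use 64–128 px scenes at 600–1000 photons per
pixel, 200-replicate recovery/selection studies at 10⁴ photons and
30 replicates at 10⁵ — sizes chosen to give stable Monte-Carlo estimates
on a single CPU. Histogram peak detection uses 0.02 ns bins, σ = 2 bins
Gaussian smoothing, a 5 % relative height floor, and quadratic
interpolation of the maximum, which resolves the closest published peak
pair (1.89/2.10 ns). All randomness flows through
`numpy.random.default_rng` seeds carried in scene configs; equal
configs produce bit-identical images, and the pipeline manifest records
SHA-256 checksums of the canonical arrays so reproducibility is checked
independently of file-format metadata.

## Known limitations

Per-pixel fitting assumes one species per pixel; fractional unmixing of
co-localized species along phasor chords is not implemented. No
triexponential fits, no global multi-pixel fitting, no IRF estimation
from data (the IRF is taken as known or calibrated away), and no vendor
raw formats (HDF5 and TIFF+JSON only). The ± values reported by
`per_cell_stats` are SDs across biological-replicate means — cell-to-cell
and fit-error spreads are reported separately and should not be
conflated.
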