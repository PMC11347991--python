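# flimplex

Fluorescence-lifetime multiplexing for TCSPC-FLIM: simulate images of
spectrally identical reporters that differ only in their excited-state
lifetime, then separate them by decay fitting and by fit-free phasor
clustering.

## The problem

Multicolor microscopy runs out of spectral channels at four or five
fluorophores. Fluorescence lifetime imaging (FLIM) adds an orthogonal
axis: reporters with identical excitation/emission spectra can still be
distinguished if their decays differ. Fluorogen-activating protein tags
(FAST variants binding HBR-family chromophores) provide exactly such a
set — shortT, midT and longT variants whose assemblies emit in the same
green window with intensity-weighted average lifetimes spanning roughly
1.2–2.6 ns. `flimplex` implements the complete analysis that makes this
multiplexing work, for people developing or validating lifetime-based
unmixing protocols: a TCSPC scene simulator with ground truth, per-pixel
decay fitting, phasor analysis, lifetime-window unmixing, and the
photophysics/replicate statistics around them.

## The model

Each pixel records a photon-arrival histogram over one laser period `T`
(default 12.5 ns, 256 bins). A species decays as
`f(t) = Σᵢ aᵢ exp(−t/τᵢ)` (1–2 components); the expected histogram is the
circular convolution of the periodic (wraparound-corrected) decay with
the instrument response function (IRF), scaled by the photon budget, with
Poisson counting noise per bin. Fits maximize the Poisson likelihood;
model order (mono vs biexponential) is chosen by a reduced-χ² test. The
headline per-pixel summary is the intensity-weighted average lifetime

```
T_i = Σ aᵢ τᵢ² / Σ aᵢ τᵢ
```

which is comparable across mono- and biexponential reporters. Its
histogram over a multi-species sample shows one mode per reporter;
cutting at the valleys defines lifetime windows that label each pixel.
The fit-free alternative is the phasor transform
`g = ⟨cos ωt⟩, s = ⟨sin ωt⟩` at the laser frequency `ω = 2π/T`:
monoexponential decays fall on the universal semicircle `g² + s² = g`,
species form clusters, and a Gaussian-mixture fit (or hand-drawn ROIs)
segments the image. Quantum yields Φ decompose the decay rate into
radiative and non-radiative constants, `k_r = Φ/T_i`,
`k_nr = (1−Φ)/T_i`.

## Worked example

Simulate the three-population co-culture (nuclei labeled with shortT550,
midT550 or longT550; generative T_i 1.45/1.89/2.10 ns; 10³ photons per
pixel), fit every nucleus pixel with the biexponential reconvolution
model (3×3 binning), and unmix by lifetime windows:

```python
from flimplex import simulate_scene, three_population_scene, fit_image, lifetime_histogram
from flimplex.unmix import propose_windows, assign_by_window, score_separation

scene = three_population_scene(seed=20240620)   # 128x128, T_i 1.45/1.89/2.10 ns
images, truth = simulate_scene(scene)
ti_map = fit_image(images["green"], irf=scene.irf, timing=scene.timing, binning=3)

hist = lifetime_histogram(ti_map.ti)
print("T_i peaks (ns):", [round(p, 3) for p in hist.peak_positions_ns])

windows = propose_windows(ti_map.ti, 3, labels=["shortT550", "midT550", "longT550"])
for label, lo, hi in windows.windows:
    print(f"  {label}: [{lo:.3f}, {hi:.3f}) ns")

labels = assign_by_window(ti_map, windows)
print(f"pixel accuracy vs ground truth: {score_separation(labels, truth).accuracy:.3f}")
```

Output:

```
T_i peaks (ns): [1.446, 1.887, 2.093]
  shortT550: [1.371, 1.656) ns
  midT550: [1.656, 1.996) ns
  longT550: [1.996, 2.310) ns
pixel accuracy vs ground truth: 0.998
```

The three histogram modes recover the generative lifetimes to a few
hundredths of a nanosecond, the kernel-density valleys place the window
boundaries between them, and window assignment labels 99.8 % of the
ground-truth pixels correctly. The same scene segmented through the
phasor route (`flimplex.phasor`) agrees with the window labels on >99 %
of co-assigned pixels.

The whole workflow is also available from the shell:

```sh
flimplex run --seed 7 --out demo/        # simulate -> fit -> phasor -> unmix -> stats -> report
flimplex simulate --config scene.yaml --out sample/ --seed 7
flimplex fit --in sample/sample_green.h5 --min-photons 100 --out fits/
```

`run` writes a manifest with per-stage checksums; rerunning with the same
seed reproduces them bit-for-bit.

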