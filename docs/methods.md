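# Methods

This note documents the models, parameter choices and numerical decisions
behind `chromoquant`, and what the synthetic-data validation does and does
not demonstrate.

## 1. Widefield scene model

A scene is a two-channel float image (channel 0 DAPI, channel 1 Arc) of a
field of cultured neurons. Per nucleus:

* **Geometry.** An ellipse with semi-axes drawn uniformly from
  `nucleus_radius_range` (default 170–200 px) and random orientation,
  placed by rejection sampling so nuclei are pairwise disjoint with a
  margin. The silhouette is softened by a Gaussian of `edge_sigma = 2` px
  to mimic optical blur at the nuclear envelope. Placement failure after
  bounded retries raises an error rather than degrading silently.
* **Chromatin texture.** A low-frequency multiplicative field
  (Gaussian-filtered white noise, correlation length 0.2× the minor axis,
  relative SD 8%) on the in-nucleus DAPI base level (`dapi_background`,
  default 1000 intensity units) — "relatively homogenous" chromatin with
  gentle spatial variation.
* **Arc level.** Class label Bernoulli(`arc_positive_fraction`); the
  per-nucleus Arc level is the class mean (100 negative / 1200 positive)
  plus N(0, 15) between-nucleus variation, constant across the nucleus.
* **Puncta.** Count ~ Poisson(class mean; defaults 11.1 / 15.9) — the
  minimal-assumption count model given only reported group means; planted
  areas ~ Normal(class mean; defaults 431 / 488 px², SD 80) clipped to
  ±3.5 SD.
* **Read noise.** Additive Gaussian, SD 1% of the DAPI base level, both
  channels.

Identical config + seed reproduces scenes bit-exactly. RNG sub-streams
(geometry / classes / counts / puncta / noise) are derived as
`default_rng([seed, tag])` with documented draw order, so any stream can be
re-executed independently (used by the re-draw oracle test).

### 1.1 Punctum profile and area calibration

Planted puncta must be recoverable by the *detector's* rule (components
above mean + k·SD of in-nucleus pixels) with their planted areas. Two
design decisions follow:

* **Flat-top profile.** Chromocenters are extended chromatin domains much
  larger than the PSF, so puncta are rendered as super-Gaussian blobs
  `A·exp(−(r²/2ρ²)³)` rather than diffraction-shaped Gaussians. A steep
  edge makes the enclosed area insensitive to the exact threshold (for a
  pure Gaussian profile, d ln A / d ln h = 1/ln(peak/h), which translates a
  few-percent threshold shift into tens of percent of area; with the cubic
  exponent the sensitivity drops threefold and the boundary sits on a steep
  flank).
* **Per-nucleus calibration.** For each nucleus the noiseless patch is
  composed, the default detection threshold (mean + 2·SD over the ellipse)
  is computed, and every blob's ρ is solved from its planted area at that
  threshold elevation; three fixed-point iterations converge. The planted
  "area" ground truth is therefore *defined* as the area enclosed at the
  default batch threshold — exactly what the detector measures.

Peak amplitude is `(puncta_peak_contrast − 1)` × the local background
(default contrast 2.6, i.e. puncta ~2.6× brighter than surrounding
chromatin). The contrast leaves the calibrated threshold at roughly half
the blob amplitude, with headroom for puncta sitting on dim texture spots.
Planted puncta keep a center separation of at least 1.45× the sum of their
boundary radii; closer pairs would merge into one connected component at
high realized thresholds in crowded nuclei.

### 1.2 Scale

The source measurements report punctum areas of ~431–488 px² and ~11–16
puncta per nucleus, but not the pixel size or nucleus pixel area. Nucleus
semi-axes default to 170–200 px so that the puncta occupy only ~6% of the
nuclear area. This is a feasibility constraint of the adaptive threshold:
as the puncta fraction φ grows, the in-mask SD grows with the puncta
themselves and mean + 2·SD approaches the blob peaks (at φ ≳ 20% it
exceeds them and detection collapses). The chosen scale corresponds to
fine sampling (~0.05 µm/px) of a ~10 µm nucleus, consistent with deconvolved
high-NA imaging.

### 1.3 The control preset and why the mean-of-controls cutoff works

The vehicle (control) preset plants 10% spontaneously Arc-expressing
nuclei (`arc_positive_fraction = 0.10`); the stimulated preset plants 49%.
Spontaneous network activity in mature cultures induces Arc in a small
fraction of unstimulated neurons, and this has a crucial statistical role:
the control intensity distribution becomes right-skewed, so its *mean* sits
well above the negative mode. Without any bright control cells the cutoff
would sit in the middle of the negative distribution and, by symmetry,
about half of all truly negative nuclei would fall above it — classification
at chance, and a measured "positive fraction" near 75% rather than 49%.
With the skewed control distribution the cutoff separates the modes and
≥99% of planted labels are recovered (tested). The spontaneous fraction is
a modelling choice, stated here openly; it is the generator's counterpart
of the real-world fact that mean-based cutoffs are only meaningful for
skewed intensity distributions.

## 2. Widefield analysis chain

* **Background subtraction** (`subtract_background`): grayscale opening
  with a disk (rolling-ball contract), computed on a block-averaged copy
  (block = radius/12) for speed, lightly smoothed, upsampled, subtracted,
  clamped at 0. The radius must exceed the nucleus half-width; the
  pipeline default is 1.3× the largest configured nucleus radius. A
  constant image maps exactly to zero.
* **Segmentation**: Otsu threshold by default (the original interactive
  ROI marking is not reproducible; an absolute-threshold override exists),
  hole filling, border-object removal (their intensity statistics are
  biased), area window 10,000–300,000 px² at the default scale.
  Deterministic ordering by centroid. No watershed splitting: the
  generator (like the sparse cultures it emulates) produces disjoint
  nuclei.
* **Arc measurement**: mean of the Arc channel over the nucleus mask
  pixels only (no dilated ring).
* **Cutoff / classification**: T = arithmetic mean of that experiment's
  control nuclei; strictly-greater comparison, ties classified negative (a
  value equal to the control mean is not evidence of induction).
* **Puncta detection**: per-nucleus crop (bounding box + 8 px pad),
  threshold mean + k·SD over mask pixels (k = 2), 8-connected components,
  size window [50, 2000] px² bracketing the reported mean areas. The
  same parameters apply to every nucleus of a batch. Nuclei with zero
  detected puncta get a *missing* mean area, never zero, and are excluded
  from area comparisons.

## 3. SMLM chain

* **Movie model.** Fixed emitters blink independently per frame
  (Bernoulli `blink_rate`); each event renders the shared Gaussian PSF
  (sampled at pixel centers — simulator and fitter use the same function,
  so there is no integration-model mismatch) with expected `photons_per_blink`
  photons; pixel values are Poisson(signal + background). Default
  acquisition length 10,000 frames.
* **Presets.** Far-red ("647"): s = 94 nm (0.21·λ/NA at λ = 670 nm,
  NA = 1.49), a = 100 nm/px, N = 1500 photons/event, b = 10 photons/px/frame,
  40 emitters at blink rate 0.003 → ~1200 events/movie. Green ("488"):
  s = 73 nm, N = 1000.
* **Detection**: difference-of-Gaussians band-pass (σ and 2σ matched to
  the PSF), local maxima with non-maximum suppression at one PSF diameter,
  threshold 5 robust SDs (MAD) of the filtered frame unless given
  absolutely. False-positive rate on background-only frames is far below
  0.1/frame (tested).
* **Fitting**: least squares on a (2·ceil(3 s/a)+1)² patch (Poisson MLE
  optional); moment-based initialisation; fits that fail to converge, leave
  the patch, or return fewer than 100 photons (the usual intensity
  acceptance filter — sub-100-photon "localizations" are background noise
  fits) are dropped and counted.
* **Precision**: Thompson expression with b = rms background noise =
  sqrt(fitted background level), since the simulated background is Poisson.
  At the far-red preset the predicted and estimated precision is ~2.7 nm
  median and the Monte-Carlo RMSE of the least-squares fitter is within
  1.25× of it; both satisfy the ≤30 nm specification of the emulated
  instrument with a wide margin. (The quoted "typically 30 nm" of real
  acquisitions includes labelling and drift contributions that this
  simulation deliberately omits.)
* **Rendering**: unit-integral Gaussian per localization (fixed 20 nm by
  default, or per-localization precision), 10 nm output pixels, 647→red,
  488→green; rendering is linear and shift-equivariant (tested).
  Out-of-field localizations are skipped and counted.
* **Apposition**: `nn_distances(A, B)` gives each A-point's Euclidean
  distance to the nearest B-point (k-d tree; equals brute force, tested) —
  the quantitative handle on two-channel "close apposition".

## 4. Statistics

Mean ± SEM with sample SD (n−1). Student's pooled-variance unpaired
t-test by default (matching the historical default of the graphing software
that the emulated analysis used), Welch via flag; two-sided p; stars at
0.05/0.01/0.001/0.0001. Per-nucleus comparisons use SEM across nuclei;
prevalence uses SEM across experiments. Under the null the test's type-I
error at α = 0.05 is 0.05 ± 0.01 over 2000 simulations (tested).

## 5. Validation scale and runtime

The acceptance run simulates 3 experiments × (9 control + 8 stimulated)
fields × 7 nuclei — 168 stimulated nuclei, matching the ~167-nucleus /
3-experiment scale of the emulated dataset — plus one 10,000-frame blink
movie; it completes in a few minutes on one CPU. Unit tests run on
miniaturized scenes (50–62 px nuclei, ~100 px² puncta) chosen purely for
speed; all distributional checks use the documented generator laws.

## 6. Known limitations

* The generator is 2D; z-stacks, deconvolution artefacts and
  depth-dependent blur are not modelled (max-projection input is accepted).
* Arc levels are spatially constant per nucleus; real nuclear Arc is
  textured.
* Dye photophysics is a per-frame Bernoulli blink without dark-state
  kinetics, bleaching, or multi-frame on-times; drift is absent, so no
  drift correction is implemented.
* Passing parameter recovery on these synthetics demonstrates the
  pipeline's correctness and internal consistency, not robustness to the
  full variability of real micrographs (focus drift, debris, clumped
  nuclei, heterogeneous staining).
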