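# chromoquant

Quantification pipeline for nuclear chromocenter puncta, activity-induced
Arc-responder classification, and single-molecule localization microscopy
(SMLM), exercised end-to-end on a synthetic-image generator with full
ground truth.

## The scientific problem

Network activity induces the immediate-early gene **Arc** in a subset of
cultured neurons; in nuclei that express Arc, chromatin reorganises into
more numerous DAPI-bright chromocenter puncta. Quantifying this requires a
chain of image-analysis steps that are individually standard but must be
wired together reproducibly:

1. **Nucleus segmentation** — smooth-background subtraction, then marking
   nuclei on the DAPI channel (Otsu threshold by default), with size window
   and border filtering.
2. **Responder classification** — each nucleus's mean Arc
   immunofluorescence is compared against a **cutoff T = the arithmetic mean
   of all control (unstimulated) nuclei of the same experiment**; a nucleus
   is Arc-positive iff its mean intensity strictly exceeds T. Cutoffs are
   never pooled across experiments.
3. **Puncta counting** — each nucleus is cropped and its chromocenter
   puncta are the 8-connected components above an adaptive intensity
   threshold (mean + k·SD of in-nucleus pixels, k = 2 by default), filtered
   to a size window [50, 2000] px²; batch-constant parameters.
4. **SMLM localization** — blinking single molecules are detected per frame
   and fitted with an isotropic 2D Gaussian

   I(x, y) = b + A·exp(−((x−x₀)² + (y−y₀)²) / 2s²),

   giving sub-pixel positions with Thompson lateral precision
   σ²_loc = (s² + a²/12)/N + 8π·s⁴·b²/(a²·N²), where N is the fitted photon
   count, a the pixel size and b the rms background noise per pixel.
   Dual-color super-resolution images are rendered by superimposing a unit-
   integral Gaussian per localization (green = 488 nm, red = 647 nm), and
   channel apposition is quantified with nearest-neighbour distances.
5. **Statistics** — per-group mean ± SEM, unpaired t-tests (Student default,
   Welch optional) with the usual star convention, and Arc-positive
   prevalence as mean ± SEM of per-experiment fractions.

Because no raw micrographs are available, the package ships a first-class
**synthetic scene generator** whose defaults plant the study conditions
(49% Arc-positive nuclei; Poisson puncta counts with class means 11.1 and
15.9; punctum areas around 431 and 488 px²; 10,000-frame blink movies at
~1500 photons/event) and record every planted object as ground truth, so
the pipeline can be validated by parameter recovery. See `docs/methods.md`
for the generator model and its limitations.

## Worked example

```python
from chromoquant import (
    stimulated_preset, vehicle_preset, generate_widefield_scene,
    compute_arc_cutoff, classify_arc, unpaired_t_test,
)
from chromoquant.pipeline import analyze_scene, default_background_radius

control_ms, stim_ms = [], []
for i in range(4):
    cfg = vehicle_preset(seed=100 + i)
    image, _ = generate_widefield_scene(cfg)
    res = analyze_scene(image, "exp1", "control",
                        background_radius=default_background_radius(cfg))
    control_ms += res.measurements
for i in range(4):
    cfg = stimulated_preset(seed=200 + i)
    image, _ = generate_widefield_scene(cfg)
    res = analyze_scene(image, "exp1", "stimulated",
                        background_radius=default_background_radius(cfg))
    stim_ms += res.measurements

cutoff = compute_arc_cutoff(control_ms, "exp1")
classified = classify_arc(stim_ms, cutoff)
print(f"cutoff = {cutoff.threshold:.1f} from {cutoff.n_control_nuclei} control nuclei")
neg = [m.puncta_count for m in classified if m.arc_class == "negative"]
pos = [m.puncta_count for m in classified if m.arc_class == "positive"]
print(unpaired_t_test(neg, pos, name_a="Arc-negative", name_b="Arc-positive").summary())
```

prints

```
cutoff = 128.6 from 28 control nuclei
Arc-negative: 10.3 +/- 1 (n=10)
Arc-positive: 16.6 +/- 0.84 (n=18)
Student unpaired t test: t(26) = -4.602, p = 9.62e-05 [****]
```

i.e. the control cultures set an Arc cutoff of 128.6 intensity units, the
stimulated nuclei split into 10 Arc-negative and 18 Arc-positive, and the
Arc-positive class carries significantly more chromocenter puncta per
nucleus (16.6 vs 10.3, **** tier) — the planted class difference, recovered
from pixels. At the full acceptance scale (3 experiments, ≥150 nuclei) the
recovered class means land on the planted 11.1 / 15.9.

A command-line interface mirrors the library
(`chromoquant simulate widefield`, `chromoquant analyze`,
`chromoquant classify`, `chromoquant smlm fit`, `chromoquant smlm render`,
`chromoquant stats compare`); run `chromoquant --help`.

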