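# omdiff

Quantitative analysis of lateral mobility in the bacterial outer membrane,
for microscopists studying how lipopolysaccharide (LPS) and outer-membrane
proteins move — or fail to move — in the outer leaflet of Gram-negative
bacteria. The package turns three kinds of raw measurement into numbers:

* **FRAP** (fluorescence recovery after photobleaching) image sequences →
  double-normalized recovery curves and **mobile fractions**;
* **SPT** (single-particle tracking) trajectory tables → mean-squared
  displacement (MSD) curves, confined/free classification, lateral
  diffusion coefficients **D₂D** and confinement (corral) diameters;
* **two-color super-resolution maps** → thresholded Pearson co-localization
  (PCC) and patch ("island") morphometry.

A seeded synthetic-data generator produces ground-truth-labeled inputs for
all three modalities, so every stage of the pipeline is verifiable at desk
scale.

## The statistics at the core

**FRAP.** With B_t, T_t, BG_t the mean intensities of the bleached region,
the whole cell, and a cell-free background region, the double-normalized
recovery curve is

    Î_t = (T̂_0 · B̂_t) / (T̂_t · B̂_0),   B̂_t = B_t − BG_t,  T̂_t = T_t − BG_t,

referenced to the last pre-bleach frame (Î_0 = 1). Dividing by the
whole-cell trace cancels acquisition photobleaching exactly. The end-point
statistic is

    mobile fraction = (I_end − I_postbleach) / (1 − I_postbleach),

with I_postbleach the first post-bleach Î and I_end the Î at 300 s.
Distributions over cells are compared with a two-sided Mann–Whitney U test.

**SPT.** Per track, the time-averaged MSD over all overlapping pairs is
computed; tracks shorter than 0.9 s are excluded, tracks whose
end-of-trajectory MSD is ≤ 0.008 µm² are discarded as surface-immobilized,
and intensity traces must show a single-step photobleach (single
fluorophore). Each MSD curve is classified confined vs free Brownian by a
plateau ratio (measured late MSD over the origin-anchored short-lag linear
extrapolation, threshold 0.6). D₂D = slope/4 of an ordinary least-squares
line over the first 4 (confined) or 13 (free) lags. For confined molecules
the corral diameter follows from the mean MSD over the 0.5–0.8 s lag
window:

    MSD_average = (d_confine / 2)² / 6.

**Co-localization.** Both channels are Gaussian-blurred (σ = 1 px), a
minimal ISODATA threshold on the lower-signal channel masks out
extracellular/dark pixels, and the Pearson correlation coefficient of the
masked intensities is reported (+1 co-localized … −1 mutually exclusive).
Islands are segmented by ISODATA thresholding; height (caliper extent along
the principal axis) and width (perpendicular extent) are reported for
patches larger than 50 nm.

## Worked example

```python
import numpy as np
from omdiff import synthetic as syn, frap as fr, spt

# a synthetic FRAP experiment: 3 µm cell, 50 % mobile molecules, D = 0.02 µm²/s
seq, truth = syn.simulate_frap_sequence(syn.FrapSimParams(mobile_fraction=0.5, seed=42))
curve, res = fr.analyze_sequence(seq)
print(f"I_postbleach = {res.i_postbleach:.3f}")
print(f"I_end        = {res.i_end:.3f}")
print(f"mobile fraction = {res.mobile_fraction:.3f}")

# 200 freely diffusing molecules at 30 Hz, 1.5 s tracks, 25 nm noise
tracks = [syn.simulate_track(syn.TrajectoryParams(d_um2_s=0.055, n_frames=45, seed=s))
          for s in range(200)]
fit = spt.fit_diffusion(spt.ensemble_msd(tracks), "brownian")
print(f"D_2D = {fit.d2d:.4f} um2/s")

# 200 corral-confined molecules (0.22 µm disc, D = 0.018 µm²/s)
conf = [syn.simulate_track(syn.TrajectoryParams(
            d_um2_s=0.018, corral_diameter_um=0.22, n_frames=45, seed=1000 + s))
        for s in range(200)]
est = spt.confinement_diameter(spt.ensemble_msd(conf))
print(f"MSD_average = {est.msd_average:.4f} um2 -> d_confine = {est.d_confine:.3f} um")
```

Output:

```
I_postbleach = 0.263
I_end        = 0.606
mobile fraction = 0.465
D_2D = 0.0538 um2/s
MSD_average = 0.0138 um2 -> d_confine = 0.576 um
```

The recovered mobile fraction (0.465 vs the generator's 0.5) and diffusion
coefficient (0.0538 vs 0.055 µm²/s) sit within single-experiment noise.
The confinement diameter from the printed relation (0.576 µm) exceeds the
0.22 µm geometric corral because the factor-6 convention differs from the
stationary disc plateau — see `docs/methods.md` for the two conventions.

A CLI wraps the same functions: `omdiff simulate-frap`, `omdiff
analyze-frap`, `omdiff compare-frap`, `omdiff simulate-tracks`, `omdiff
analyze-tracks`, `omdiff simulate-patches`, `omdiff coloc`, `omdiff
islands`, and a config-driven `omdiff run`.

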