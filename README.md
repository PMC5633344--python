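# pexflux

Quantitative machinery for studying clearance of tail-anchored (TA)
membrane proteins — such as the peroxisomal protein Pex15 extracted by the
AAA ATPase Msp1 — from live-cell confocal microscopy. The package is aimed
at cell biologists running fluorescence pulse-chase experiments who need
to go from Z-stacks to per-organelle turnover kinetics, and at modelers
probing whether a substrate decays exponentially or in two kinetic states.

It provides five stages, usable as a library or a CLI:

1. **synthetic** — ground-truthed 3D stacks (spherical peroxisomes,
   tubular mitochondria, log-normal densities, Gaussian camera background)
   and density time courses, so every stage is testable without raw images.
2. **segmentation** — 3D organelle objects from marker channels: Gaussian
   smoothing, per-slice Canny edges, contour filling, distance-transform
   watershed, mitochondrial merging, and peroxisome-overlap exclusion.
3. **quantitation** — per-object fluorescence density (total intensity /
   volume in voxels), empirical background subtraction, log-scale
   population summaries, and mCherry/sfYFP tandem-timer ratios.
4. **kinetics** — 1-state vs 2-state decay model fits and the
   time-normalized area-between-fits statistic.
5. **simulation** — Gillespie simulation of a molecule population with
   import, maturation, and state-dependent degradation, read out through
   tandem fluorescent timer (tFT) maturation.

## The models

**1-state decay.** Every molecule has the same degradation probability, so
the normalized signal is F(t) = e^(−k_decay·t); log-transformed data are
fit by linear least squares, and half-life = ln 2 / k_decay.

**2-state decay.** Molecules arrive nascent, decay at k_decay,1, and
mature at rate k_mat into a state decaying at k_decay,2. With nascent
fraction f₀ at t = 0, a = k_mat + k_decay,1 and c = k_mat/(a − k_decay,2):

    F(t) = f₀(1 − c) e^(−a·t) + (1 − f₀ + f₀c) e^(−k_decay,2·t)

Non-exponentiality is scored as ∫|F₁ − F₂|dt over the measured interval,
divided by the interval length.

**Age readout.** A tandem fluorescent timer (fast-maturing sfYFP +
slow-maturing mCherry) converts the age a of each molecule into expected
fluorescence 1 − 2^(−a/t½) per fluorophore; the population mCherry/sfYFP
ratio is a monotone function of population age.

## Worked example

Fit both models to a noiseless 13-point, 3-hour two-state time course
(nascent decay 3.45 hr⁻¹, mature decay 0.87 hr⁻¹, maturation 1 hr⁻¹,
pure pulse):

```python
import numpy as np
from pexflux import kinetics as K

t = np.linspace(0, 3, 13)
y = K.two_state_curve(t, k_mat=1.0, k_decay1=3.45, k_decay2=0.87, f0=1.0)
tc = K.NormalizedTimeCourse(t, y)
one = K.fit_one_state(tc)
two = K.fit_two_state(tc, fix_f0=1.0)
area = K.area_between_fits(one, two, (0, 3))
print(f"1-state: k_decay = {one.params.k_decay:.3f} /hr  "
      f"(half-life {K.half_life_minutes(one.params.k_decay):.1f} min)")
print(f"2-state: k_mat = {two.params.k_mat:.3f} /hr, "
      f"k_decay1 = {two.params.k_decay1:.3f} /hr, k_decay2 = {two.params.k_decay2:.3f} /hr")
print(f"nascent/mature rate ratio = {two.params.k_decay1/two.params.k_decay2:.2f}")
print(f"area between fits = {area:.4f} per hr")
```

prints

```
1-state: k_decay = 1.163 /hr  (half-life 35.8 min)
2-state: k_mat = 1.000 /hr, k_decay1 = 3.450 /hr, k_decay2 = 0.870 /hr
nascent/mature rate ratio = 3.97
area between fits = 0.0356 per hr
```

The 2-state fit recovers the generating constants exactly; the forced
single exponential compromises between fast early and slow late decay, and
the non-zero area score flags the time course as non-exponential. The
nascent state turns over ~4-fold faster than the mature state.

From the shell, the same stages are available as subcommands:

```sh
pexflux simulate --seed 1 --out sim_out        # Gillespie ensemble CSV
pexflux synth --seed 7 --out synth_out         # ground-truthed stack
pexflux segment --stack synth_out/stack_marker.tif --camera-background 100 \
    --out labels.tif
pexflux quantify --labels labels.tif --stack synth_out/stack_substrate.tif \
    --background 100 --out measurements.csv
pexflux fit --summary summary.csv --out fit_report.json
```

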