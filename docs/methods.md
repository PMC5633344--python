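# Methods

## Scope and data model

The pipeline quantifies turnover of a fluorescently tagged tail-anchored
protein at organelles in live yeast cells. Raw input is a multi-channel 3D
confocal Z-stack per timepoint: one organelle-marker channel (e.g. a
mitochondrial Tom70 fusion or a peroxisomal PTS1 reporter) and one or two
substrate channels, plus a per-channel camera-background reference.
Stacks are (Z, Y, X) voxel volumes; the 0.2 µm Z step of typical
acquisitions is carried as metadata only — all geometry (distance
transforms, volumes, densities) is computed on the raw voxel grid, since
quantities of interest are densities per voxel and ratios thereof. An
anisotropy-aware distance transform exists behind
`SegmentationParams.anisotropic_distance` but is off by default.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not the optics of a microscope. It produces:

* **Peroxisomes** as voxelized spheres, radii uniform in a configured
  range (default 3–5 voxels), rejection-placed with a minimum
  surface-to-surface separation (default 6 voxels).
* **Mitochondria** as isotropic 3D random walks with unit step length
  (default 60 steps) dilated by a spherical structuring element (default
  radius 2). Any elongated connected shape suffices to exercise the
  merge logic; no claim of biological realism is made.
* **Densities** per organelle drawn log-normally (default location
  ln 250, scale 0.25 on the log scale), matching the approximately
  log-normal fluorescence-density distributions seen in such data.
  Against the default camera noise (Gaussian, mean 100 AU, sd 8 AU) this
  puts essentially all objects at SNR ≳ 10.
* **Camera background** added voxelwise as Gaussian noise and clipped at
  zero (cameras cannot record negative ADU); the clipped-voxel count is
  recorded in the stack metadata.
* **Density time courses**: organelle *i* at time *t* has density
  baseline_i · F(t) · ε with log-normal baselines, F the 1- or 2-state
  decay curve, and ε multiplicative log-normal measurement noise (default
  log-sd 0.05). Multiplicative rather than additive noise is used
  because the analysis works on log-transformed densities; additive noise
  would break that structure.

The default steady-state kinetic configuration is single-exponential
decay at a 58-minute half-life (k = ln 2·60/58 ≈ 0.717 hr⁻¹), the
turnover measured microscopically for peroxisomal Pex15 without induced
extraction.

Not emulated: point-spread-function blur, photobleaching, stage drift,
cell boundaries, and object tracking across timepoints. Passing tests on
synthetic stacks therefore demonstrate correctness of the measurement and
inference chain under the stated noise model, not robustness to every
optical artifact of real data.

## Segmentation

Marker stacks are background-subtracted, Gaussian-smoothed in 3D
(σ = 1 voxel), and each Z slice is processed with a Canny edge detector
(σ = 1, hysteresis thresholds as gradient-magnitude quantiles 0.90/0.98).
Closed contours are filled per slice — edges are per-slice, so filling is
too — and the slices are stacked into a 3D mask. Because the filled
contours include the edge band, which sits on or just outside the true
boundary, each 3D connected component is then trimmed to voxels whose
smoothed intensity exceeds 0.35 of the component's peak above the stack
median (a fractional-maximum boundary criterion). On synthetic spheres
this recenters recovered volumes on truth (within ±25%) where the raw
filled mask overshoots by ~50% and a one-pixel erosion undershoots by
~25%.

Objects are separated by watershed on the negated 3D Euclidean distance
transform, seeded at distance-transform maxima under minimum-distance
suppression (default 4 voxels), with seed ids ordered by (z, y, x) so tie
breaking is deterministic. Mask components that receive no seed are kept
as their own objects, so the split conserves mask voxels exactly.
Mitochondrion mode then merges touching labels (26-connectivity by
default, so diagonal contact counts as one mitochondrion) and deletes
mitochondrial voxels overlapping any peroxisome label; peroxisome mode is
the identity.

Two object filters guard the pipeline against spurious responses to pure
camera noise, to which quantile-threshold Canny is otherwise susceptible:
a minimum object size (20 voxels) and a minimum object SNR (mean object
intensity at least 3 robust noise sigmas above the stack median, with the
noise sigma estimated by MAD). Real marker signals at SNR ≥ 10 are
unaffected; an all-noise stack yields zero objects.

All numeric defaults in this stage are engineering choices tuned on the
synthetic fixtures (the segmentation literature for this assay does not
fix them) and are recorded in each label map's provenance.

## Quantitation

Per object and channel: total intensity is the sum over the object's
voxels; fluorescence density is total intensity divided by object volume
in voxels. Background density is the mean density measured at organelles
of control cells lacking the labeled substrate, and is subtracted from
every object's density; corrected densities may legitimately be negative
(background is normally distributed around its mean) and are preserved.

Population summaries (mean, SEM) are computed on log-transformed
corrected densities. Non-positive corrected densities cannot enter the
log and are excluded, with the exclusion count reported alongside the
summary — a deliberate policy choice, since negatives carry no usable
log-scale information. Timepoint normalization (dividing a series by its
t = 0 mean) lives in the kinetics stage so that raw summaries remain
unit-bearing.

The population tandem-timer ratio divides summed corrected mCherry
intensity by summed corrected sfYFP intensity over matched objects,
rather than averaging per-object ratios, because per-object ratios are
unstable at small sfYFP denominators; per-object ratios are still emitted
for inspection.

## Kinetic model fitting

The 1-state fit is ordinary least squares of log mean density against
time; k_decay is the negated slope, and the intercept is reported but not
constrained to zero. The 2-state curve is the closed-form solution of the
two-compartment linear system (see README); the degenerate case
a = k_decay,2 switches to the analytic limit e^(−a·t)(1 + f₀k_mat·t) when
|a − k_decay,2| < 1e-8.

The 2-state fit minimizes squared residuals of log F(t) against log data
with `scipy.optimize.least_squares`. The Trust-Region-Reflective method
is used rather than classical Levenberg–Marquardt because the fit honors
bounds (non-negative rates, f₀ ∈ [0, 1]) that plain LM cannot; it solves
the same damped-least-squares subproblem within the feasible region.
Because the objective is non-convex, ten multiplicatively perturbed
starts (log-normal, σ = 0.5, fixed seed) are tried and the best-RSS
solution wins; parameter standard errors come from the Jacobian at the
optimum (Gauss–Newton covariance, pseudo-inverse for rank-deficient
cases). Fits are unweighted on the log scale by default; 1/SEM²
weighting is intentionally not a default because the upstream SEMs are
themselves log-scale estimates.

f₀ is free in [0, 1] by default — a pre-loaded substrate pool is of mixed
age — but can be fixed (`fix_f0=1` for pure-pulse designs). Note an
identifiability limit: from a single curve only a = k_mat + k_decay,1,
k_decay,2, and the fast-component amplitude are determined, so with f₀
free the triple (k_mat, k_decay,1, f₀) is not individually identifiable;
recovering the nascent decay constant requires the pure-pulse constraint.

The area-between-fits statistic integrates the *absolute* difference of
the two fitted curves (adaptive quadrature) over the measured interval
and divides by the interval length. The absolute value matters: fitted
curves can cross, and a signed integral could cancel to zero and mask
genuine non-exponentiality. The statistic is zero iff the fits coincide
on the interval.

## Gillespie simulation

The stochastic model tracks one peroxisome's worth of molecules (default
1000 — deliberately generous, which improves statistical robustness
without shifting means) with three event channels: import at constant
rate N₀·k_ss, maturation of a nascent molecule at k_mat each, and
degradation at a state-dependent per-molecule rate. Waiting times are
exponential in the summed rate; the event is chosen by a rate-weighted
draw; ages advance by exact event-driven time (molecules store birth
times, so aging is O(1) per event). Per-minute records carry the state
at the last event before each minute mark, with ages evaluated exactly at
the mark.

Starting conditions are steady state: ages exponential with mean
half-life/ln 2 (default half-life 58 min; literature values up to
143 min are accepted via configuration). In the 2-state regime, 60% of
molecules start nascent, selected by age-weighted draws without
replacement with weight e^(−k_mat·age) (implemented via the Gumbel top-k
trick, which degrades gracefully to "the youngest molecules" as
k_mat → ∞). The default k_mat is chosen for self-consistency with that
steady state: balancing import against nascent outflow gives
f_u = k_ss/(k_mat + k_ss), so f_u = 0.6 implies k_mat = ⅔·k_ss
(≈ 0.478 hr⁻¹ at a 58-min half-life). Both the fraction and k_mat are
configurable.

At t = 0 the activated decay constant replaces the steady-state one:
2.82 hr⁻¹ for every molecule in the 1-state regime, or 3.45 hr⁻¹ for
nascent molecules only in the 2-state regime, where the mature state
keeps decaying at k_ss (the mature decay constant equals the steady-state
constant by construction). Imported molecules enter the nascent state in
the 2-state regime (configurable), the biologically coherent reading of
maturation. An unperturbed mode keeps all constants at steady state and
is used to validate that the starting conditions are conserved.

Fluorophore maturation is single-step exponential per fluorophore with
configurable half-times; the defaults (sfYFP 15 min, mCherry 40 min) are
literature-typical configuration values, not measured constants of this
pipeline. Each molecule contributes 1 − 2^(−age/t½) expected
fluorescence; the replicate's population ratio is the ratio of totals,
and the ensemble ratio is the mean over replicates of that population
ratio (mean-of-population-ratios), normalized to its starting value.
Ensembles run replicate-per-substream from a master seed
(`numpy.random.SeedSequence.spawn`), so output is bit-reproducible.

Default ensemble size is 100 replicates of 4 simulated hours at 1-minute
records. Under these conditions the unperturbed ensemble holds its mean
abundance within 3 SEM of N₀ at every minute; 1-state activation drives
the normalized timer ratio down ~25% over two hours while 2-state
activation leaves it within a few percent of 1 — the qualitative
signature that distinguishes age-independent from age-selective
clearance. The test suite checks the 1-state decline on 15-minute block
means rather than per-minute differences: the ratio approaches its new
plateau with a ~21-minute relaxation time, so by two hours Monte-Carlo
jitter dominates minute-to-minute differences and strict per-minute
monotonicity would test the noise, not the direction.

## Numerical and policy notes

* Fractions remaining and half-life conversions are exact closed forms:
  half-life (min) = ln 2/k·60 for k in hr⁻¹; fraction = 2^(−t/t½).
* Degenerate inputs: empty label maps, empty masks, zero-object specs,
  zero-duration simulations, and empty populations all return well-formed
  empty results; impossible geometry placement and all-negative
  log-summary inputs raise errors naming the offender.
* Determinism: every stochastic entry point takes an explicit seed; the
  pipeline runner requires a master seed whenever a stochastic stage is
  configured and records it in the run manifest together with a hash of
  all parameters.

## Known limitations

* Segmentation accuracy is validated on the synthetic geometry only;
  densely packed or strongly anisotropic organelles may require retuning
  the Canny quantiles, seed distance, and refinement fraction.
* The per-slice Canny step can miss the polar caps of small spheres;
  recovered volumes are unbiased only down to radii ≈ 3 voxels.
* The 2-state fitter's standard errors are asymptotic Gauss–Newton
  estimates and understate uncertainty near the identifiability boundary
  discussed above.
* The simulation models a single well-mixed compartment; organelle-to-
  organelle heterogeneity and exchange are out of scope.
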