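# Methods

`strobetrack` re-implements, as a tested library, the analysis chain used
for single-molecule tracking (SMT) of fluorophore-labelled proteins in
live rod-shaped bacteria, together with a synthetic-movie generator that
provides ground truth for every stage.  This note records the models, the
parameter choices and their rationale, the numerical decisions, and what
the synthetic studies do and do not demonstrate about real data.

## The synthetic study conditions

The generator emulates the acquisition regime of stroboscopic live-cell
SMT in *E. coli* micro-colonies:

* **Cells** are 3D spherocylinders lying flat in the imaging plane,
  length 2.8–3.8 µm, radius 0.45–0.55 µm (drawn uniformly per cell),
  placed without overlap in colonies of a few cells.  Real cells are
  slightly curved and vary more; the straight capsule is sufficient for
  the coordinate conventions and confinement statistics used here.
* **Pixel size** is 65.7 nm: the analysis convention that 20 px = 1314 nm,
  consistent with a 100×/1.45 objective plus a 0.7× adapter on a 4.6 µm
  camera pixel.
* **Timing**: 3 ms excitation pulses inside 5 ms camera exposures (20 ms
  variant available for slow membrane transporters), zero dead time.
* **Molecules** carry one of K ≤ 3 diffusion coefficients; with a
  transition matrix A they switch states between frames (Markov), without
  one each molecule keeps its initial state drawn from the weights —
  the static-mixture regime used for the step-histogram studies.
* **Motion** is Brownian with per-substep standard deviation
  √(2·D·δt) per axis, specularly reflected at the cell surface (10
  substeps per pulse for motion blur; the dark interval is covered by
  coarser substeps).  Specular reflection preserves the uniform
  stationary density of a closed domain, which rejection schemes distort.
* **Photophysics**: Poisson photons (500 per pulse by default) emitted
  uniformly over the pulse window at the molecule's instantaneous
  position, geometric photobleaching with per-frame survival
  exp(−k·t_pulse) (k = 11 s⁻¹, mean ≈ 30 lit frames), and optional 1–2
  frame blinking dark states (p = 0.05 per frame) to exercise gap
  closing.  Molecules activate at uniformly random frames so occupancy
  stays at ~1–2 visible emitters per cell per frame, the sparsity regime
  SMT labelling is tuned for.
* **Camera**: ADU = offset + gain·(photon counts) + Gaussian read noise,
  i.e. an sCMOS-like model without EM excess noise.  The per-photon
  binning of the rendered signal already realizes the Poisson statistics
  (thinning), so with unit gain and no noise the image integral equals
  the emitted photon count exactly — a conservation law the tests check.
* **Backgrounds**: a uniform 5 photons/px/frame plus 3 photons/px/frame
  of cellular autofluorescence inside the masks.  The
  dim-cell filter (below) is only meaningful when cells are brighter
  than the surrounding field, as real autofluorescent cells are.

Photons per pulse and background levels are not reported for the original
movies; 500 and 5 (+3) are plausible for bright rhodamine-family dyes at
these pulse energies and give localization errors (~0.1 px core) in the
regime where the 250-photon acceptance filter is the binding constraint.

## Segmentation and normalized cell coordinates

Segmentation accepts a label mask directly (the path used for synthetic
data, where masks are ground truth); otherwise a convenience baseline
finds cells as ellipse-like objects by Otsu thresholding, hole filling
and connected components with area/aspect sanity bounds.  Each region
carries a straight principal-axis backbone (sufficient for near-straight
cells; a curved-backbone replacement can be slotted in at
`segment._fit_region`) and a local half-width profile estimated from the
per-slab mask *area* rather than the maximum extent — the area estimator
is unbiased to sub-pixel level, which matters because the short-axis
coordinate s divides by it.

Normalized coordinates: l is the normalized backbone projection (0 and 1
at the poles), s the signed perpendicular offset over the local
half-width.  Which pole is l = 0 is arbitrary, so every downstream
statistic is invariant under l → 1−l (tested).  Points up to 3 px outside
the mask are accepted, matching the localization filter.

Filters applied before detection, with their published settings:

* colonies with more than 8 cells are removed whole (inclusive
  threshold: a colony of exactly 8 is kept);
* cells whose mean fluorescence over the first 10 frames is ≤ 1.1× the
  background mean are removed.  "Background" is the field of view outside
  all masks dilated by 5 px; intensities are camera-inverted to photons
  first so the ratio does not depend on the camera offset.

## Detection and localization

Candidates are difference-of-Gaussians local maxima (σ and 2σ, σ = 1.3 px
≈ the diffraction-limited PSF at this pixel size).  Two choices differ
from naive practice and were driven by measurement on synthetic movies:

* Non-maximum suppression runs at 5 px, much finer than the 11 px fit
  ROI, and any candidate with a neighbour within 10 px is vetoed before
  fitting.  With coarse NMS, nearby emitters merge into a single
  candidate whose single-emitter fit is silently pulled toward the
  neighbour — measured as a heavy error tail (q99 ≈ 2 px) that inflates
  slow-state step variances several-fold.  Vetoing overlapping ROIs
  restores ~0.16 px rms at a 0.8% risk of discarding one motion-blurred
  spot split into two candidates.  Multi-emitter fitting is deliberately
  out of scope.
* The candidate acceptance threshold (150 photons, below the 250-photon
  analysis filter so that the published filter stays binding) is applied
  to the background-subtracted ROI photon sum, not the band-pass peak
  height: fast molecules blur over several pixels during the 3 ms pulse
  and their peak response drops even though the photon budget is intact.

Sub-pixel positions come from the radial-symmetry centre (closed-form
least squares on the 2×2-cell diagonal gradient field, weights =
gradient²/distance-to-centroid), then maximum a posteriori refinement of
a pixel-integrated symmetric Gaussian μ = b + N·G(x, y, σ) under Poisson
noise.  The pixel-integrated form (erf differences) is exact at small σ
where a sampled Gaussian is not.  Priors are weak log-normals centred on
the candidate-stage estimates (scale 1.0 in log units for N and b, 0.4
for σ) — they make MAP ≈ MLE away from degenerate fits while keeping
blurred spots (fitted σ up to ~3 px) inside the model class.  The
position uncertainty is curvature-based (numeric 2×2 Hessian at the
optimum); it is well calibrated in the core of the error distribution
(median reported ≈ median realized ≈ 0.1 px at 500 photons).

Localization filters, as published: amplitude ≥ 250 photons (a fit of
exactly 250 passes, "lower than 250" being the exclusion), and position
within 3 px of a cell boundary, implemented as 3× binary dilation of the
mask (Chebyshev distance); survivors are assigned the nearest cell.

## Tracking

Linking is strictly per cell, in two linear-assignment stages with
search radius 20 px (1314 nm): consecutive-frame links with cost =
squared distance and a non-link alternative cost radius², then gap
closing of 1–2 missing frames between segment ends and starts under the
same radius (a single radius for all gap lengths, as published).  The
assignment objective — Σ d² over links + radius²·(unmatched on either
side) — is checked exactly against brute-force enumeration on small
instances.  Before linking, any (cell, frame) holding more than 3 dots
is dropped whole; this conservative reading of the density rule (rather
than keeping the 3 brightest) avoids mis-links in crowded frames, and a
`keep-brightest` alternative would be a one-line change in
`enforce_density`.  Trajectories with fewer than 5 *observed* frames are
excluded (gap frames carry no data, so counting spanned frames would be
more permissive than the rule's intent).

## Step-length mixtures

Steps are frame-to-frame displacements of consecutive observed frames;
pairs spanning bridged gaps are excluded by default.  The theoretical
2D Brownian step-length density is the Rayleigh mixture

p(r) = Σ_k w_k · r/(2 D_k Δt) · exp(−r²/(4 D_k Δt)),

optionally with 2σ_loc² added to each 2 D_k Δt.  Fitting minimizes the
summed per-bin absolute error between the observed histogram (50 equal
bins from 0 to the 99.5th percentile, overflow pooled into the last bin;
binning is not specified in the source analyses) and bin-integrated
expected counts, over (log D, softmax weights) — Nelder–Mead from
Latin-hypercube starts plus deterministic warm starts (step-quantile
coefficients; the free-space solution when a confined basis is in use),
with a final polish pass from the incumbent.  States are reported sorted
by D.  The L1 objective is non-smooth, which rules out gradient methods;
with ≤ 5 free parameters the restarted simplex is reliable.

**Confinement-aware expected model.**  For fast states the free-space
Rayleigh form is measurably wrong in bacteria: at D = 5 µm²/s and
Δt = 5 ms the apparent coefficient in a 1 µm-wide cell is ~4 µm²/s
(transverse motion is range-limited) even after the standard motion-blur
correction Δt_eff = Δt − t_pulse/3.  The pipeline therefore fits, by the
same L1 criterion, expected histograms built from single-state
simulations in the *segmented* cell geometries: for each D on a 28-point
log grid (0.005–25 µm²/s), confined trajectories are simulated with the
acquisition's stroboscopic timing in cells drawn per molecule from the
segmented region population, pulse-window-averaged positions yield
step-length samples, and the typical localization error (median fit
uncertainty of unblurred spots) is folded in.  Distributions at arbitrary
D interpolate the log-quantile curves linearly in log D — exact for a
scale family, smooth under confinement; naive per-bin CDF interpolation
would instead produce a two-component mixture and a few-percent shape
error.  This is simulation-calibrated inference from measured geometry
only; no ground-truth information enters.  The analytic Rayleigh fit
remains the default of `fit_mixture` and the right choice for sampled or
unconfined data.

**Spurious-link decoy.**  At the published 20 px search radius a few
percent of steps join localizations of *different* molecules (bleaching
of one molecule near the activation of another, or path crossings);
their lengths spread over the whole radius and masquerade as an
intermediate diffusive state.  The pipeline fit therefore includes one
fixed-shape background component whose step-length distribution is
estimated from the population the mis-links are drawn from —
localization pairs of *different* trajectories in the same cell,
at least 25 frames apart (so the positions are decorrelated),
conditioned on lying within the search radius — with its weight
(capped at 0.2) fitted alongside the states and reported separately
(`background_weight`); the diffusive weights are renormalized over the
K states.  On synthetic data the fitted background weight reproduces
the independently measured mis-link rate (0.037 vs 0.038) without
touching the published linking rules.  This decoy construction is the
tracking analogue of randomized controls in colocalization analysis.

Localization error enters the confined basis as a single per-axis
value: the median curvature-based uncertainty of unblurred spots.
Curvature estimates are a Cramér–Rao-style lower bound and somewhat
under-report the realized error of real spots (motion blur, neighbour
photons); the covariance-based self-calibration from one- versus
two-frame displacement moments
(`pipeline.estimate_localization_error_msd`) removes that bias in
principle, but needs a few dozen long, slowly-diffusing trajectories
and is therefore offered as a utility rather than wired in by default —
at a 6% slow fraction a typical dataset does not feed it.  The residual
under-estimate leaves a small unmodelled broadening of the slow and
middle states, discussed under limitations.

Known estimator behaviour, measured on data sampled from the model
itself: the middle state of a 3-state fit is the ill-conditioned
direction (its mass trades against the fast state's lower tail), with
~±20% sampling spread on D_mid at 2×10⁴ steps; the slow and fast
coefficients and all weights are much tighter.  Tests therefore assert
median accuracy over replicate datasets, and pipeline-level recovery is
validated at the full study size (~3×10⁴ steps).

## Hidden-Markov state inference

Displacement sequences (dx, dy) per trajectory are modelled by a hidden
chain whose state-k emission is the isotropic 2D Gaussian with per-axis
variance 2 D_k Δt (the displacement vector is the sufficient statistic;
scalar step lengths discard the sign structure for no gain).  Parameters
are estimated by maximum-likelihood EM with scaled forward–backward,
vectorized across trajectories; the cited variational treatment is
replaced by ML-EM plus BIC (p = (K−1) + K(K−1) + K parameters), which is
fully specifiable and equivalent at these data sizes.  Initialization: D
from quantiles of r²/(4Δt), sticky A (0.9 diagonal), 10 seeded restarts.
Bridged gaps contribute no emission; the chain is propagated across a
gap by powering A.  Expected transition counts for the A update are
accumulated over unit-frame transitions only — the exact E-step for
compound transitions would require within-gap decompositions that do not
pay for themselves at the ≤ few-percent gap rates this pipeline
produces.  EM monotonicity holds exactly on gapless data (tested).
Occupancies are posterior means over steps (γ-average); the stationary
distribution of Â is also available, and the two agree for stationary
chains.

## Spatial statistics

Localizations are mapped to (l, s); the short-axis distribution excludes
the poles (l ≤ 0.15 or ≥ 0.85, where the hemispherical caps make s
ill-defined) and mid-cell (0.35 ≤ l ≤ 0.65, where septation in dividing
cells distorts the profile), then histograms |s| on [0, 1.2] in 20 bins
(the 1.2 ceiling admits the 3-px-outside tolerance).  Subsampling to a
fixed count (default 22 207) is uniform without replacement, datasets at
or below the target passing through unchanged.

"Membrane enrichment" — the fraction of retained localizations with
|s| > 0.5 — is this package's operationalization of qualitative membrane
localization and is labelled as such.  Its analytic anchors: uniform
surface points project to |s| = |cos θ| (median √2/2 ≈ 0.71, enrichment
2/3), uniform cytosolic points follow the chord-projection density
(4/π)√(1−s²) (enrichment 2/3 − √3/(2π) ≈ 0.391).  The two scores are
separated by ≈ 0.28 with sampling noise of ~0.01 at 10⁴ points, so the
conditions never overlap in practice.

## Plate-reader computations

Doubling time: blank-subtract, take the first 10 consecutive readings
from the first point with OD₆₀₀ ≥ 0.015 (ties qualify), least-squares
line on ln OD vs time, doubling time = ln 2/slope.  The log-linear fit
is standard for plate readers and exact on clean exponentials; a
nonlinear exponential fit is provided as a cross-check and agrees on
clean data.  Slopes at or below round-off raise (a flat culture has no
doubling time).  Reporter normalization (F/OD) and fluorogenic turn-on
ratios (F⁺/F⁻) are guarded ratios.

## Problem sizes and determinism

The validation studies use 20 simulated movies of 3 cells × 500 frames
(≈3×10⁴ steps) for end-to-end recovery, 500×30-step chains for HMM
recovery, 50 replicates for BIC selection rates, and 10⁴-point datasets
for the spatial scores — sizes at which every asserted tolerance has
comfortable statistical margin while the whole suite stays fast on a
single core.  All stochastic stages take explicit seeds or Generators;
identical seeds give bit-identical movies, truth tables and fits.

## Known limitations

* The simulator's phase-contrast channel is a label mask, not an image;
  the built-in Otsu segmenter is a baseline, not a reproduction of the
  boundary-finding algorithm used on real phase-contrast data, and the
  original study's manual colony curation cannot be reproduced.
* Detection censors the hardest cases (strongly blurred fast molecules,
  overlapping emitters), so step samples are not a perfectly unbiased
  draw from the motion model; at the default sparsity this shifts the
  recovered fast-state parameters by a few percent at most.
* The confined basis assumes straight spherocylinders of the segmented
  sizes; curved or constricted cells would need a richer geometry model.
* Localization error is folded into the fits as a single typical value,
  not per-localization; state-dependent error (blur) is ignored beyond
  the basis's blur simulation itself.
* The HMM assumes state changes only at frame boundaries and ignores
  confinement entirely; its D estimates inherit the confinement bias the
  mixture pipeline corrects for, which is acceptable for the state-count
  and occupancy questions it answers.
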