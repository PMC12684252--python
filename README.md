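# strobetrack

Single-molecule tracking (SMT) analysis for fluorophore-labelled
proteins in live rod-shaped bacteria, together with a synthetic-movie
generator that makes every stage testable against ground truth.

In live-cell SMT, individual labelled proteins are imaged with short
laser pulses inside each camera exposure (stroboscopic illumination),
localized to sub-pixel precision frame by frame, and linked into
diffusion trajectories.  The step-length statistics of those
trajectories reveal how many mobility states a protein population
occupies — e.g. freely diffusing versus complex-bound versus aggregated
— their diffusion coefficients D_k and their fractions w_k.  This
package implements the whole chain for *E. coli*-like micro-colonies:

* **simulate** — spherocylindrical cells, molecules switching among up
  to three diffusive states by a Markov process, reflecting-boundary
  confinement, stroboscopic excitation with motion blur, Gaussian PSF,
  Poisson photons with bleaching/blinking, and a photon-calibrated
  camera model; ground-truth localization tables come with every movie.
* **segment** — cells as ellipse-like objects (or supplied label
  masks), colony-size and dim-cell filters, and normalized cell
  coordinates (l along the axis, s across it).
* **detect** — radial-symmetry sub-pixel centring plus maximum a
  posteriori fitting of a pixel-integrated Gaussian under Poisson
  noise, photon-calibrated amplitudes, and the published acceptance
  filters (≥ 250 photons, ≤ 3 px outside a cell).
* **track** — two-stage linear-assignment linking (20 px search
  radius, 2-frame gap closing, ≤ 3 dots per cell, ≥ 5-frame
  trajectories).
* **diffuse** — step-length histograms fitted to K-state 2D Brownian
  (Rayleigh) mixtures by per-bin absolute error,

  p(r) = Σ_k w_k · r/(2 D_k Δt) · exp(−r² / (4 D_k Δt)),

  with an optional confinement-aware expected model simulated in the
  segmented cell geometry (fast molecules in 1 µm-wide cells otherwise
  read out ~20% slow).
* **hmm** — hidden-Markov diffusion-state inference on displacement
  sequences (EM with scaled forward–backward, BIC state-count
  selection, posterior occupancies).
* **spatial** — localization distributions in normalized coordinates
  with the standard pole (0–0.15, 0.85–1) and mid-cell (0.35–0.65)
  exclusions, subsampling, and a membrane-enrichment score.
* **assay** — plate-reader computations: doubling time from OD₆₀₀
  curves, reporter normalization, fluorogenic turn-on ratios.

The package is a library: import it from Python, or start from the
short scripts in `examples/` (one per capability).  File formats are
plain: 16-bit TIFF movies and masks with JSON metadata sidecars, CSV
tables.

## Worked example

Fit 1/2/3-state mixtures to 2×10⁴ steps drawn from a known 3-state
model (`examples/step_length_fit.py`):

```
$ python examples/step_length_fit.py
K=1: D = [4.34] um^2/s, w = [1.00], L1 residual = 5276
K=2: D = [0.319, 4.89] um^2/s, w = [0.17, 0.83], L1 residual = 1612
K=3: D = [0.0411, 0.491, 4.95] um^2/s, w = [0.06, 0.14, 0.80], L1 residual = 597
true   D = [0.05, 0.5, 5] um^2/s, w = [0.06, 0.14, 0.80]
```

The three-state fit recovers the simulated coefficients (0.05, 0.5,
5 µm²/s) and weights (6%, 14%, 80%), and the residual drop from K=1 to
K=3 is how the state count is judged from experimental histograms.  The
HMM example prints the matching state-count selection by BIC, and
`examples/spatial_profile.py` separates membrane from cytosolic
proteins by their short-axis distributions:

```
membrane : 7891 retained, median |s| = 0.71, enrichment (|s| > 0.5) = 0.66
cytosolic: 8693 retained, median |s| = 0.40, enrichment (|s| > 0.5) = 0.39
```

(0.71 = √2/2 and 0.39 = 2/3 − √3/2π are the analytic values for surface
and volume distributions.)

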