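# Methods

## The measurement model

A still exposure records each reflection h on image c only partially. The
package takes as input, per measurement: the partial intensity I^P_hj and its
counting sigma σ^P_hj (photons), the partiality P_hj ∈ (0, 1], and the
resolution term sin²θ/λ² (Å⁻²); and per image: the post-refined scale G_c,
Wilson factor B_c (Å²) and wavelength λ_c (Å). Partiality, G and B are inputs
— the package does not re-derive them, and it treats the combined correction

    K_hj = [ G_c · exp(−2 B_c sin²θ/λ²) · P_hj ]⁻¹

as an exact constant when propagating the sigma (no uncertainty in K is
carried; see Limitations). Dividing by scale, Wilson falloff and partiality
yields the full-intensity equivalent, so K ≥ 1 whenever P < 1 at G = 1,
B = 0, and per-measurement I/σ is preserved exactly.

Intensities are in photon units throughout. Conversion from detector units is
an explicit gain division, never auto-detected; when counting sigmas are
recomputed from photon counts a gain g shrinks I/σ by √g, which is why the
per-image filter threshold must be rescaled by 1/√g (0.5 → 0.1 at g = 25).

## Grouping and merging

Miller indices are mapped to a canonical asymmetric-unit representative with
gemmi's reciprocal-space ASU; with `anomalous=True` (default) an index
reached through the Friedel flip is negated, keeping Bijvoet mates in
separate groups. A configurable partiality floor can reject near-zero
partials before merging; the default keeps everything.

Three merge protocols operate on the corrected measurements of each group:

* **unweighted** — I_h = mean, σ_h = SD(n−1)/√n. For n = 1 the spread is
  undefined (0/0); the measurement's own counting sigma is emitted and
  flagged. Spread-based errors are generally unreliable below a multiplicity
  of about 5.
* **counting-weighted** — w = 1/σ², I_h = Σ wI/Σ w, σ_h = (Σ w)^(−1/2).
  The propagated form is deliberate: counting sigmas know nothing about the
  partiality-correction scatter, so these merged errors can sit orders of
  magnitude below the spread-based ones. A weighted-spread alternative
  (weighted SD about the weighted mean over (n−1)Σw) is available behind
  `MergePolicy(weighted_sem="spread")` for sensitivity analysis.
* **Ev11** — identical to counting-weighted but with weights 1/σ_Ev11².
  With (s_fac, s_B, s_add) = (1, 0, 0) it reproduces protocol 2 bit for bit.

Negative merged intensities are retained; no outlier rejection is applied at
the merge step.

## The Ev11 error model

    σ_Ev11 = s_fac · [ σ_hj² + s_B·⟨I_h⟩ + (s_add·⟨I_h⟩)² ]^(1/2)

with ⟨I_h⟩ the plain mean of the corrected measurements of h. s_fac absorbs
multiplicative sigma errors (a wrong gain mis-scales every counting sigma by
√gain, and the fitted s_fac² ratio between a mis-gained and a corrected run
recovers the gain ratio); s_add absorbs errors proportional to intensity
(instrument instability); s_B is an empirical intermediate term with no
assigned physical meaning. All three are kept non-negative. If a parameter
excursion ever drives the radicand non-positive the sigma is clamped to
s_fac·σ_hj and counted.

Calibration is judged through leave-one-out normalized deviations
δ = [(n−1)/n]^(1/2)(I_hj − ⟨I′_hj⟩)/σ. The (n−1)/n prefactor is exactly the
equal-sigma variance correction for the leave-one-out difference, so the
denominator is the single measurement's sigma only (counting sigma during
initialization, σ_Ev11 during refinement). Groups with n = 1 have δ ≡ 0 and
are excluded from both the probability plot and the binned target.

**Initialization.** All δ (counting-sigma denominator) are sorted against
rankits z_i = Φ⁻¹[(i−a)/(m+1−2a)], a = 3/8 for m ≤ 10 and 0.5 otherwise. An
ordinary least-squares line through the points with rankit in [−0.5, 0.5]
(configurable) gives s_fac = slope, s_add = max(offset, 0), s_B = √s_add. A
negative offset clamps s_add and s_B to 0, both being non-negative scale
terms.

**Target.** ⟨I_h⟩ values are binned into 100 equal-width bins spanning
[min⟨I_h⟩, max⟨I_h⟩] (top edge inclusive; a degenerate range falls back to a
single bin with a warning); every measurement of h lands in the bin of
⟨I_h⟩. With rmsd_b the root-mean-square of δ about zero in bin b and
w_b = √m_b,

    f = Σ_b w_b (rmsd_b − 1)² .

⟨I_h⟩, the bin assignment and the leave-one-out numerators are computed once
from the corrected intensities and held fixed, so f is smooth in the three
parameters; only the sigma model moves during refinement. The analytic
gradient follows the chain rule f → rmsd_b → Σδ² → σ_Ev11²
(∂δ²/∂θ = −δ²·∂σ_E²/∂θ/σ_E²) and is verified against central finite
differences at 1e−5 relative as part of the test suite.

**Refinement.** scipy's L-BFGS-B minimizes f with bounds s_fac ≥ 1e−12,
s_B ≥ 0, s_add ≥ 0 (defaults: 200 iterations, gtol 1e−8, ftol 1e−10). Two
structural traps are handled deterministically:

* because s_add enters squared, ∂f/∂s_add vanishes identically on the
  s_add = 0 plane, which is therefore a spurious stationary set a purely
  local descent can never leave. If the first run converges with s_add = 0, a
  short probe along s_add (0.01…3) is evaluated and, if it lowers f, a second
  run starts there;
* the target is nearly flat along a ridge where s_fac²(σ² + s_B·⟨I⟩) trades
  off against the other terms (counting variance is itself roughly linear in
  intensity), so after the first run a coarse (s_fac, s_add) scan is
  evaluated and a restart is taken only if it undercuts the converged target.

The bound on s_B is a modelling choice: leaving it free lets the fit discard
the counting-sigma term entirely (s_fac → 0, s_B → 10⁴) in favor of a smooth
linear variance, which fits marginally better on binned statistics but is
physically meaningless; the term legitimately pins at 0.00 instead. The
reported trace holds the target at the winning run's start point and at each
accepted iterate, and is non-increasing by construction of the line search.
The parameters of the model are weakly identifiable by design of the
quadrature — on strong data only the products s_fac·s_add and
s_fac²(const + s_B) are well determined; raw values are pinned only when the
dataset contains a counting-noise-dominated (weak) population, which real
still data possess in abundance and the synthetic presets emulate.

## Per-image resolution filter

Within each image, measurements are binned into 10 equal-volume resolution
shells (uniform in 1/d³). Scanning from low to high resolution, the cutoff is
the low-resolution edge of the first shell whose mean I/σ falls below the
threshold (default 0.1, the photon-unit value); everything beyond is removed.
The filter uses partial (pre-correction) intensities by default, since it
runs per image during merging; a switch applies it to corrected values
instead.

## Synthetic data

The generator emulates, term by term, the error structure the model
explains: true intensities J_h ~ Exp(wilson_mean) (acentric Wilson
statistics, simulated space group P1; centric statistics are not modelled);
per-image G ~ U(g_range), B ~ U(b_range), fixed wavelength; partiality either
≡ 1 or 0.05 + 0.95·Beta(2, 1.5) (left-skewed, zero-tending); Poisson photon
counting on μ = G·e^(−2B·stol2)·P·J; optional Gaussian background with
variance `background_var` photons² entering both the noise and the reported
sigma (σ² = counts + background_var), as background-subtracting integration
software produces; gain misestimation as I = (g_true/g_assumed)·N with
σ = √I — i.e. the sigma is wrong by √(gain ratio) exactly when the gain is;
and optional instability noise N(0, s_add_true·μ) added to the intensity but
not the sigma. Sigmas are floored at one photon-equivalent. Everything is
reproducible from a single seed.

Named presets fix the study conditions:

| preset | images × refl | key settings | exercises |
| --- | --- | --- | --- |
| clean-poisson | 2000 × 60 | P ≡ 1, G = 1, B = 0, wilson_mean 1000 | pure counting-noise calibration (120 000 measurements) |
| gain25 | 5000 × 20 | gain 25 reported as 1, wilson_mean 2000 | s_fac ≈ √25 |
| gain25-corrected | 5000 × 20 | same, gain divided out | s_fac ≈ 1; squared ratio ≈ 25 |
| instability | 5000 × 20 | s_add_true 0.5, wilson_mean 200, background 25 | raw s_add recovery |
| partiality-heavy | 1000 × 30 | wide G/B/P spread | diagnostics, CC1/2 |
| mini | 60 × 12 | — | fast CLI/smoke tests |

The instability preset's weak-signal choice (wilson_mean 200 photons with
background variance 25) is what makes the *raw* s_fac/s_add values — not just
their product — identifiable, mirroring the weak-measurement population of
real datasets. The gain presets use strong, background-free signal so the
sigma mis-scaling is the only error present.

What the simulator does **not** emulate: spot shape, mosaicity physics,
spectral bandpass, partiality-estimation error (P is known exactly, so the
dominant real-data error source is absent), detector non-uniformity, centric
reflections, and anomalous differences beyond an optional fixed Bijvoet
offset. Passing tests therefore demonstrate correctness of the estimator
machinery under the stated noise models, not end-to-end performance on real
XFEL data.

## Diagnostics

CC1/2 splits each group's measurements randomly into two halves (odd
measurement to a random half, seeded), merges each half under the active
protocol, and Pearson-correlates the two half-dataset intensities; fewer than
3 usable groups returns NaN with a warning. Resolution-binned I/σ tables use
equal-volume shells. The 2-D (I, I/σ) histogram clips out-of-range values
into edge cells so counts are conserved. All diagnostics emit
machine-readable tables; plotting is left to the caller.

## Numerical choices and conventions

* Problem sizes: the shipped presets (≤ 120 000 measurements) refine in
  about a second each; the full test suite and the acceptance script each
  finish in well under a minute on one CPU.
* Leave-one-out means are computed by the algebraic identity
  (n·mean − I_j)/(n − 1), vectorized per group.
* Ties in the sorted deviations are broken by a stable sort; they cannot
  affect the line fit.
* Table I/O is tab-separated text with `#` comments and 12-significant-digit
  floats (round-trip safe); merged data can be exported to MTZ
  (IMEAN/SIGIMEAN, or I(+)/I(−) when anomalous) via gemmi.
* The merge step drops groups below `min_multiplicity` (default 1 — merge
  everything).

## Limitations

* Uncertainty in K_hj (partiality, scale, Wilson B) is not propagated into
  σ_hj; the correction is treated as exact.
* The binned target makes individual Ev11 parameters weakly identifiable on
  strong-signal data (see above); compare parameter *products* across runs
  when in doubt.
* The per-image filter's binning scheme (10 equal-volume shells) is a
  convention; data with very few measurements per image make the shell means
  noisy.
* No image processing of any kind: indexing, integration, post-refinement
  and phasing all live upstream or downstream of this package.
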