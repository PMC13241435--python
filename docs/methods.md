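# Methods

## The prior

`pogmdm` implements an explicit, score-exact diffusion prior for images: a
product-of-experts density over filter responses,

```
p(x, t)  ∝  ∏_{l=1}^{d} ∏_{k=1}^{o}  ψ_k((K_k x)_l, w_k, t),
```

where the `K_k` are circular (periodic) convolutions with small kernels or
full-grid shearlet spectra, and each expert `ψ_k` is a one-dimensional
Gaussian mixture with `L` components on a shared, equally spaced grid of
means over `[v_min, v_max]`, a per-expert symmetric simplex weight vector
`w_k`, and a time-dependent variance `σ_k²(t)` shared across components.
The base variance is tied to the grid, `σ₀² = (v_max − v_min)/(L − 1)`,
so neighbouring components overlap by construction.  Because the density is
explicit, the score `∇ log p` is available in closed form and is exactly the
gradient of the log density — a conservative field, unlike a free-form
score network.

### Time conditioning

Under the variance-exploding diffusion `dX_t = √2 dW_t` the marginal at time
`t` is the data density convolved with `N(0, 2tI)`.  For ideal filters
(flat spectra with disjoint supports) this convolution is implemented
*exactly* by inflating each expert's variance,

```
σ_k²(t) = σ₀² + ν_k² · 2t ,
```

with `ν_k` the filter's spectral magnitude.  Practical filters are not
ideal, so `ν_k²` is set heuristically to the maximum of the magnitude
spectrum (the mean is available behind a flag; the two behave almost
identically).  Two learned alternatives are provided: a small MLP
`√(2t) → softplus(L₃ ∘ ELU ∘ L₂ ∘ ELU ∘ L₁)` with hidden widths 64/64, and a
three-parameter-per-filter parametric form
`σ₀² + θ₁ softplus(θ₂ √(2t) + θ₃)`, `θ₁ > 0`.  The hidden widths are not
externally fixed and were chosen as the unique three-layer configuration consistent
with the reference learnable-parameter total (7348 for 20 filters); the
same applies to the shearlet generator sizes below.

### Parameter bookkeeping

The learnable values are the filter parameters (20 × 5 × 5 for the fully
learned configuration; 9 + 17 × 17 = 298 for the shearlet generators h₁ and
P), one weight vector of `⌈L/2⌉` free values per distinct sharing group
(mirror symmetry makes the rest redundant: 63 for L = 125), and the time
conditioning (0 spectral / 5588 MLP / 3o parametric).  The five preset
configurations reproduce the reference totals 1760, 7348, 1820, 1558 and
676 exactly; these are checked in the test suite and recomputed by
`scripts/acceptance.py`.

### Shearlet bank

The shearlet system is generated from a 1D low pass `h₁` (length 9, unit DC
gain) and a 2D directional generator `P` (17 × 17, unit Frobenius energy).
Scale bands telescope the squared low-pass spectrum (`√(1 − G²)` at the
finest scale, `G·√(1 − G(2ω)²)` one scale down, with `G` the DTFT magnitude
of `h₁`), and directions are carved by shearing the generator's transfer
function, evaluated at arbitrary frequencies through its DTFT; the vertical
cone transposes the horizontal one.  With two scales, shears `|k| ≤ 2` and
both cones this yields the default `o = 2 × 5 × 2 = 20` filters whose
squared spectra sum to a strictly positive function away from DC (checked
numerically on a 64 × 64 grid).  The construction follows the cone-adapted
digital recipe in spirit but is this package's own; per-scale shear
conventions for systems other than the two-scale default are a package
convention, not an external standard.

## Training by denoising score matching

The DSM objective is the ancestral-sampling form

```
E  || x₀ − x_t − 2t ∇ log p(x_t, t) ||²,     x_t = x₀ + √(2t) z,  t ~ U(0, T),
```

minimized with Adam (any adaptive-moment method serves; the projection
steps after every update are what matter), followed by projection of every
weight group onto the symmetric simplex and of every kernel onto zero mean,
with an exponential moving average (momentum 0.999) of the weights whose
final value is returned.  Times are drawn from `U(t_eps, T)` with
`t_eps = 10⁻⁴` to avoid the `1/(2t)` blow-up in the implied score target.

The trainable surface of this implementation is the mixture weights; the
gradient of the loss in the weights is analytic (via the unweighted
component responsibilities `φ_i/ψ`), so no automatic differentiation is
needed.  Filters and time-conditioning parameters are held fixed during
training — parameter counts still report them as learnable values of the
model family.

A note on conditioning: with a single weight vector serving all `t ∈ (0,T]`
the large-`t` terms of the objective dominate numerically and push the
weights toward flat profiles, while reconstruction quality is decided by
the small-`t` behaviour of the score.  The weight-recovery experiment (see
below) is immune because the identity-filter model is well specified at
every `t`; for misspecified convolutional models the recommended desk-scale
recipe fits the `t = 0` factors directly (next section).

## The desk prior

`presets.desk_prior` is the prior the reconstruction examples and the
end-to-end tests use: four fixed unit-gain difference kernels (first and
second differences, horizontal and vertical), `L = 125` components on
`[−0.5, 0.5]`, spectral time conditioning, and weights obtained by a
maximum-likelihood (EM) fit of each filter's response marginal over a batch
of 16 synthetic phantoms.  Fitting the clean-image factors and letting the
variance adaptation supply the time dependence is exactly the model
family's design premise, keeps the score near zero on typical clean images
(so the prior does not bias the data term), and takes a few seconds on one
CPU.  A DSM-trained variant is available as `presets.dsm_prior`.  Unit gain
matters: the max-spectrum heuristic `ν_k²` scales linearly in the kernel
while the true response-noise variance scales quadratically, and the two
agree for the unit-gain difference kernels.

## Joint reconstruction

The acquisition model is nonlinear SENSE: per coil, `y_i = M F(s_i ⊙ x) + n`
with a binary sampling mask `M`, the unitary 2D DFT `F`, and complex
Gaussian noise whose `σ_n` is the per-component standard deviation.  Both
the image and the coil sensitivities are unknown; the model carries the
well-known per-pixel scaling ambiguity `(x ⊙ b, s ⊘ b)`.  Likelihood
gradients follow the Wirtinger convention (full real gradients
`∂/∂Re + i ∂/∂Im`), which makes them exact ascent directions — in the coil
gradient this puts a conjugate on the image factor, verified against finite
differences.

The coil prior is the quadratic smoothness penalty
`γ(s) = ½ Σ_i ‖D Re s_i‖² + ‖D Im s_i‖²` with forward differences under
Dirichlet boundaries (sensitivities vanish outside the field of view).  Its
smoothing map `Q_μ = μ(DᵀD + μI)⁻¹` is closed-form via the orthonormal
DST-I, which diagonalizes the Dirichlet Laplacian with eigenvalues
`4 sin²(aπ/(2(h+1))) + 4 sin²(bπ/(2(w+1)))`.  As written, `Q_μ` is the
proximal map of `γ` at weight `1/μ` rather than `μ`; the formula is
implemented verbatim and `μ` is simply the smoothing trade-off knob
(larger `μ`, weaker smoothing).

One iteration of the sampler runs, at noise level `ζ_i` on the geometric
schedule `ζ(t) = ζ_max (ζ_min/ζ_max)^{(1−t/T)^p}` (defaults
`ζ_min = 0.001`, `ζ_max = 10`, `p = 5`, `T = 1`, `N = 1000` grid steps):

1. **predictor** — Euler–Maruyama step of the reverse variance-exploding
   SDE; the prior score is evaluated at the diffusion time `τ = ζ²/2`
   (whose marginal perturbation std equals `ζ`) separately on the real and
   imaginary channels;
2. **data consistency** — one `λ`-weighted likelihood ascent step in the
   image (`λ = 1`);
3. **corrector** — `M = 1` annealed-Langevin step with the norm-matched
   step `ε = 2r‖ξ‖²/‖∇ log p‖²`, capped at `eps_max` because the rule
   diverges when the score is much weaker than it presumes;
4. **coil update** — one likelihood ascent step on the sensitivities
   followed by the DST smoothing map with `μ`.

Reconstruction starts from the reduced time `t₀ = 0.2 T` (so 200 of the
1000 grid steps run) with the zero-filled coil-combined image plus
`ζ(t₀)`-scaled noise, and coils initialized as smoothed zero-filled coil
images divided by their stabilized RSS.  Measurements are normalized by
`‖x_ZF‖_∞` beforehand and the final magnitude is rescaled back and
multiplied by the RSS of the estimated sensitivities (the intensity
correction, which also cancels the per-pixel scaling ambiguity).  After the
final iteration the expected clean image is returned (a Tweedie step at the
terminal noise level followed by one data-consistency step) — without it
the last corrector's injected noise remains in the estimate.  The MMSE
estimate averages independent reconstructions (default 25; the desk-scale
experiments use 4) and the per-pixel sample variance serves as an
uncertainty map.

`r` and `μ` are the tunable trade-offs and were fixed once by grid search
on a held-out synthetic validation phantom (`r = 0.005`, `μ = 1.0`,
exposed as defaults and revisitable via the `gridsearch` CLI command).
Smaller `r` lowers the corrector's noise floor (equilibrium error scales
like `r^{1/4}` when data consistency is strong) but slows the annealing
mixing; the plateau between `0.0025` and `0.01` is flat.

A smoothed isotropic (Charbonnier) total-variation penalty with analytic
gradient is included as the classical variational baseline.

## Synthetic data

The generators emulate the structure of the multi-coil experiments at desk
scale.  Phantoms are piecewise-smooth ellipse composites with lightly
smoothed boundaries, normalized to `[0, 1]` — the reconstruction algorithms
care about edges and smooth regions, not anatomical fidelity.  Coil maps
are smooth complex fields (Gaussian magnitude bumps centred outside the
field of view, low-order random phase), normalized to unit RSS and tapered
toward the border with a floor of 0.15 so that every pixel remains weakly
observable; `γ(coils)` is under 5% of a white-noise field of equal energy.
Masks cover Cartesian (equispaced phase-encode columns plus a contiguous
ACL block centred on DC, with a transposed "rotated" variant), pseudo-radial
and pseudo-spiral rasterizations, and center-peaked 2D-Gaussian Bernoulli
sampling — all realized as binary masks on the Cartesian grid (no
gridding), hitting the target acceleration within ~10%.  Acquisition noise
is complex Gaussian on the sampled locations only (the single-coil
simulation convention uses `σ = 0.02`; the multi-coil desk experiment
`σ_n = 0.01`).  GMM random fields with known symmetric weights provide
ground truth for the weight-recovery experiment; the recovery setting uses
five components on `[−2, 2]` (spacing equal to `σ₀`), where the weights are
well identified — the reference 125-component grid overlaps so heavily that
weight vectors are only weakly identified from finite data, which is a
property of the parameterization, not of the estimator.

What passing these tests does *not* show: anatomical realism, robustness to
contrast or anatomy shifts, behaviour at clinical matrix sizes or coil
counts, or the performance of fully learned filters trained at scale.  The
desk experiments are property checks of the algorithms, not benchmark
reproductions.

## Numerical choices and degenerate inputs

- Circular boundary conditions throughout the prior (consistent with the
  exact-diffusion theory); Dirichlet boundaries in the coil penalty.
- Mixture evaluations use log-sum-exp; responsibilities are computed in
  log space, so zero weights after projection are harmless.
- The symmetric-simplex projection averages mirrored pairs and then
  projects onto the simplex (sort-based); the simplex projection preserves
  mirror symmetry, so the composite is idempotent.
- Degenerate inputs raise: nonpositive variances, `t < 0`, `μ ≤ 0`,
  all-zero images in normalization, all-zero shearlet generators,
  infeasible mask rates, off-mask nonzeros in k-space containers.
- Non-finite iterates or losses abort with the iteration index.
- PSNR uses the maximum of the reference as peak and a +200 dB sentinel for
  exact matches; SSIM uses the standard 7 × 7 window with K₁ = 0.01,
  K₂ = 0.03; NMSE is reported ×100 only at print time.
- The null-space residual of estimated coils is judged against fully
  sampled coil images; against zero-filled coil images the comparison is
  structurally biased toward the initialization, which is itself derived
  from them.

## Problem sizes

The test-suite and acceptance-script experiments run at 64 × 64 with four
coils, four MMSE samples, 2000 DSM iterations for weight recovery, and 200
sampler steps per reconstruction (the `N = 1000` grid entered at
`t₀ = 0.2T`) — sizes at which the full suite completes in a few minutes on
one CPU while every property under test is already informative.

## Known limitations

- Training updates mixture weights only; learning filters or
  time-conditioning parameters end to end is out of the numerical scope of
  this implementation (no autodiff), though the model family, projections
  and parameter bookkeeping cover them.
- Single-coil undersampled reconstruction does not beat the zero-filled
  baseline with the desk prior: for `c = 1` the unsampled frequencies are a
  pure null space that only a far stronger prior can fill.  With four
  coils the same pipeline gains 3–4 dB over zero filling.
- The partition function of the prior is never computed; all uses
  (score, DSM, sampling) need only the unnormalized density.
- Non-Cartesian trajectories are binary masks on the grid; there is no
  NUFFT/gridding path.
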