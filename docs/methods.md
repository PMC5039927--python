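# Methods

## Model

Expression is modelled on the log scale.  With G genes, C cells and
capture times k_c drawn from T levels κ_1 < … < κ_T, the generative
process is

- log ψ_g ~ N(μ_ψ, σ_ψ), log ω_g ~ N(μ_ω, σ_ω)   (gene variances)
- τ_c ~ N(k_c, σ_τ)                               (pseudotimes)
- y_g ~ GP(φ_g, ψ_g K + ω_g δ)                    (profiles)
- x_{g,c} = y_g(τ_c)                              (data link)

K is Matern 3/2 on the scaled separation r = d/l.  The Kronecker delta is
on **cell index**: two cells at numerically equal pseudotimes share signal
but not noise.  The alternative (delta on pseudotime value) would make the
likelihood discontinuous in τ and is not used.  φ_g is fixed at the gene's
mean expression rather than sampled; it enters the GP mean only, and with
log-scale data the per-gene mean is estimated far more precisely than the
quantities of interest.

### Periodic kernel

For cyclic processes the raw separation d = |τ_i − τ_j| is folded as
d_Ω = (Ω/2)·|sin(π d / Ω)| before dividing by l.  Every profile is then
exactly Ω-periodic, and the covariance is invariant under shifting any
subset of cells by whole periods.  The Ω/2 prefactor is a convention
(it makes the maximal folded separation Ω/2); a different constant would
be absorbed by rescaling l.  The fold is applied to the raw separation so
that Ω is a period in pseudotime units — the same units as the capture
times — which is what the capture-time prior requires.  The fold lives in
one function (`periodic_distance`) and is swappable.

### Sparse likelihood

The deterministic-training-conditional (projected-process) approximation
replaces each gene's covariance ψK + βI (β = ω + jitter) with
Q + βI, Q = K_fu K_uu⁻¹ K_uf, through M inducing pseudotimes placed evenly
over [κ_1 − 3σ_τ, κ_T + 3σ_τ].  Likelihood and analytic gradients are
computed by Woodbury/determinant-lemma identities in O(C·M²) per gene; no
C×C matrix is ever formed, so the implementation is usable at thousands of
cells.  At u = τ (distinct) the approximation is exact, which the test
suite uses as its oracle.  The finite-M behaviour of other sparse schemes
(FITC, variational) differs; DTC was chosen as the simplest scheme with
the stated cost and an exactness oracle.

## Inference

The unconstrained parameter vector is (τ, log ψ, log ω); on this scale
the variance priors are exactly normal, so no Jacobian bookkeeping leaks
into the samplers.  Gradients of the GP marginals with respect to τ,
log ψ, log ω are computed analytically (via tr(E·∂Σ/∂θ) with
E = ααᵀ − Σ⁻¹, batched over genes) and are property-tested against central
finite differences for the exact, sparse and periodic variants.

- **NUTS**: the efficient slice-based no-U-turn sampler with
  dual-averaging step-size adaptation (target acceptance 0.8), one
  diagonal mass-matrix adaptation window in mid-warmup, and a divergence
  threshold of 1000 on the Hamiltonian error.  Default tree depth is
  capped at 8 (7 in the bundled studies; typical trajectories are much
  shorter).
- **ADVI**: a fully factorized Gaussian on the unconstrained scale,
  optimized with reparameterized gradients (2 Monte Carlo samples per
  step) and Adam (lr 0.05), stopping when a smoothed ELBO changes by less
  than a relative tolerance (1e-4) between windows.

Reported log joints are on the constrained scale (log-normal densities for
ψ, ω), so the "best sample" — the draw maximizing the log joint, ties to
the first occurrence — is comparable across methods.

### Initialization

Chain 1 starts at τ = k plus N(0, σ_τ/4) jitter.  Subsequent chains order
cells within each capture time by their projection on the leading
principal axis of the expression matrix (sign-aligned with capture time)
and spread them evenly over [k − σ_τ, k + σ_τ].  This gives order-diverse
chains cheaply and respects the prior.  Variances start at their prior
medians.  All initialization is deterministic given the seed.

### Empirical Bayes

Per gene, ω̂_g is the mean within-capture-time variance and ψ̂_g the
variance of the capture-time group means (both floored at 1e-6); the
log-normal priors are moment-matched to the log estimates across genes.
Two known biases, accepted rather than patched: (i) with few capture
levels, the log-scale sampling noise of a variance estimate biases μ̂_ψ
downward (≈ digamma((T−1)/2) − log((T−1)/2), about −0.27 at T = 5);
(ii) when a capture group spans substantial temporal variation (coarse
group labels, or T = 3 over a full cycle), within-group variance inflates
ω̂.  Both shrink the likelihood's influence somewhat; the posterior still
recovers orderings well in the bundled studies, but users with very coarse
designs should consider supplying μ_ω, σ_ω directly.  l and σ_τ are always
user choices, in capture-time units.

### Choosing NUTS vs ADVI

ADVI is 20–50× faster and works well when the initialization is close to
a dominant mode (the capture-anchored, non-periodic studies).  Mean-field
ADVI cannot move cells past each other — reordering requires traversing a
low-ELBO region — so it inherits its initial within-group ordering, and on
cyclic data or outlier cells it reproduces the known failure mode of
pushing hard-to-place cells to the extremes of pseudotime.  The periodic
and precocious-cell studies therefore use NUTS, which crosses those
barriers reliably at these problem sizes.

## Validation statistic

Roughness of a held-out gene under an ordering z is

    R_g(z) = (1/σ_g) · sqrt( (1/(C−1)) Σ_c (x_{g,z_c} − x_{g,z_{c+1}})² )

— scale-free (affine-invariant) and reversal-symmetric; the square root
makes R the sd-normalized RMS of consecutive differences (the un-rooted
variant is available via `sqrt=False` for sensitivity checks).  The null
model draws orderings sorted by capture time and uniformly shuffled within
each capture time.  The test statistic treats the fitted mean-over-genes R
as a single draw against the null sample:

    t = (mean(null) − R_fit) / (sd(null) · sqrt(1 + 1/n_null)),  df = n_null − 1.

This construction is calibrated: an ordering drawn from the null gives t
centred on 0, and pure-noise held-out genes give approximately uniform
p-values.  Normalizing instead by the standard error of the null mean
(sd/√n_null) would reject for essentially any fixed ordering and is not
calibrated for a single fitted value.  A Welch two-sample variant across
posterior draws (`posterior_mean_roughness`) is available when a full
posterior, rather than a point ordering, is being tested.

## Profiles and peak times

Profile prediction is the standard GP conditional given a posterior draw,
on a grid spanning the fitted pseudotime range ± one length-scale (or one
full period).  Pointwise variance is the noise-free signal variance
(ψ reverting far from data).  Peak times are the grid argmax of the
posterior-mean curve (earliest grid point on ties; profiles whose range is
below 1e-8 are flagged undefined), compared on the circle by the RMSE of
wrapped differences.  Per-draw argmaxes are noisier and are not used.

## Synthetic data

The generator runs the generative process above exactly: round-robin
assignment of cells to T evenly spaced capture times, GP profile draws at
the true pseudotimes (jointly with an optional evaluation grid, so the
noise-free truth is recorded), Gaussian noise.  Misspecification knobs,
off by default: Student-t noise (`noise_df`) and single-peaked sinusoid
profiles at known phases (`profile="sinusoid"`, amplitude √(2ψ) so the
temporal variance over a period equals ψ).  The sinusoid variant exists
because a raw periodic GP draw can have two near-equal maxima, making
"the" peak ill-defined: even predictions computed with the generating
parameters mislocate such peaks by ~10% of the period, so phase-recovery
studies use profiles whose peak is unambiguous.  The precocious variant
displaces chosen first-capture cells' true pseudotimes by a fixed amount
while keeping their labels.

What the generator does not emulate: count noise and dropout, cell-size
artefacts (inputs are assumed pre-adjusted; an optional per-cell
mean-centering is provided), batch effects, branching trajectories, and
genes whose profiles violate the shared-length-scale assumption.  Passing
studies on this generator demonstrate correct inference under the model's
own assumptions — not robustness to everything real data does.

## Study sizes and numerical choices

The bundled studies run at desk scale on one CPU: recovery G=20(+20
held-out)×C=50 with 2 NUTS chains × 500 draws (~4 min); coarsened-capture
G=20×C=48 by ADVI (~15 s); periodic G=20×C=40 with three order-diverse
chains (~4 min; cyclic orderings have a reflected mode, so chain
initializations alternate the principal-axis direction); precocious
G=20×C=40 with the sparse likelihood and two chains (~20 s; the truth uses
cohort scatter σ_τ = 0.25 so the one-interval displacement is unambiguous,
while the fit uses the softer σ_τ = 0.5).  Covariance
diagonals carry a relative jitter of 1e-6·(ψ+ω), escalated ×10 up to three
times on factorization failure (then an error naming the gene); the
inducing-point correlation uses 1e-12 with the same escalation.  The
variance floor for empirical Bayes is 1e-6 on the log-expression scale.
Serialization stores arrays as JSON text; Python float repr round-trips
bit-exactly on load.

## Known limitations

- Chains may mix poorly across ordering modes; R̂ flags this, and the
  best-sample point estimate is the supported fallback, mirroring standard
  practice for multimodal latent-ordering models.
- Outlying cells can be best fit by pushing them to the extremes of
  pseudotime, where the GP reverts to its prior and any expression value
  is cheap; occasionally this mode genuinely dominates the posterior (by a
  nat or so) and a displaced cell lands at the wrong extreme.  Inspecting
  cells fitted at the edge of the pseudotime range is advisable.
- The empirical-Bayes biases above, and the ADVI limitations above.
- One-dimensional trajectories only: no branching, no multiple lineages,
  no time warping; no missing-data mechanism (missing values are rejected
  at load).
- The exact likelihood is O(GC³) per gradient; beyond a few hundred cells
  use the sparse likelihood.
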