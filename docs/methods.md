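# Methods

## Model

One experiment is a compound × cell-line assay: wells seeded with a known
number of cells `n0_i`, treated at log10-molar concentration `z_i`, and
measured once after a fixed follow-up, plus `q ≥ 2` compound-free
background wells `e_1..e_q`.

Cell growth in each well is a linear birth–death (Kendall) process: each
cell divides at rate λ(z) and dies at rate μ(z), both constant over the
follow-up and absorbed over its duration (t ≡ 1), so the rates are
per-experiment-duration quantities.  The exact transition probability of
the process is a combinatorial sum over surviving founder lineages; it is
implemented (in log space, in the all-positive binomial-thinning ×
negative-binomial form that avoids the catastrophic cancellation of the
direct alternating sum) as a validation oracle, together with an exact
event-driven Gillespie simulator.  Inference does not use the exact
likelihood — at assay scale it is numerically infeasible — but a Gaussian
with the process's matched mean and variance,

    m(n0, z) = n0 e^{λ−μ},
    v(n0, z) = n0 (λ+μ)/(λ−μ) e^{λ−μ}(e^{λ−μ} − 1),   v → n0(λ+μ) as λ→μ.

The acceptance suite quantifies this approximation directly: the
Kolmogorov distance between 10⁵ simulated trajectories and the matched
Gaussian is below 0.05 for n0 ∈ {100, 1000}.  Measured counts (assay
intensities, treated as real-valued) add Gaussian noise with mean θ and
variance σ², so a well contributes `Normal(x | m + θ, v + σ²)` and each
background well `Normal(e | θ, σ²)`.

λ−μ is pinned by the well means; λ+μ is informed only by count variances.
This separation is the model's mechanistic payoff and also its numerical
crux: with triplicate wells the per-dose variance estimates are χ²₂-noisy,
and when the rate curves are flat the process variance is dose-constant and
nearly confounded with σ² (only the background wells separate them).  The
posterior is then genuinely bimodal — a "quiescence" basin (small rates,
inflated σ²) and a "turnover" basin — and credible intervals are wide.
This is a property of the design, not the implementation; more replicates
or more background wells shrink it.

## Priors

GP priors on φ_λ = log λ(z) and φ_μ = log μ(z), independent, with constant
means α and squared-exponential kernels K(z,z′) = τ² exp(−(z−z′)²/l²).
Hyperpriors: α ~ Normal(0, s_a²), τ² ~ Inverse-Gamma(a₁, b₁),
l² ~ Gamma(a₂, b₂), p(θ) ∝ 1, p(σ²) ∝ 1/σ².  The improper noise priors are
proper a posteriori because ≥ 2 background wells are required at input
validation.

Defaults (all config-exposed): s_a² = 4, τ² ~ IG(2, 1), l² ~ Gamma(2, 0.5).
These are weakly informative *on the physical scale*: per-cell rates over
one assay duration live within a few e-folds of 1, so a prior sd of 2 on
the log-rate level is generous, τ² has prior mean 1, and l² has prior mean
4 (a correlation length of ~2 decades on a 5-decade dose axis).  We found
arbitrarily diffuse choices (prior sd 10 on log rates, mean-free IG(1,1)
kernels) actively harmful: they let the latent curves wander to physically
impossible rate scales and concentrate posterior mass in the spurious
quiescence boundary mode whenever replicates are few, costing both
calibration and interpretability.  Jitter of 1e−6·τ² is added to kernel
diagonals — large enough that Cholesky factorisation essentially never
needs data-dependent escalation, which would make Metropolis density
evaluations asymmetric between current and proposed length-scales.

## Posterior computation

Latents are sampled only at the distinct tested doses.  Dense prediction
grids (default: 100 points spanning the tested range, union the doses) are
filled in per retained draw by exact GP conditional *sampling* given that
draw's latents and hyperparameters — distributionally identical to carrying
the dense grid through the chain, at a fraction of the cost, and the bands
it yields are full posterior bands rather than plug-in interpolations.

One sweep of the Metropolis-within-Gibbs sampler:

1. **φ_λ, φ_μ** — preconditioned Crank–Nicolson proposals
   `φ′ = α + ρ(φ−α) + √(1−ρ²) L ε` with L the kernel Cholesky factor.  The
   proposal preserves the GP prior exactly, so acceptance reduces to the
   likelihood ratio while detailed balance w.r.t. the full posterior holds.
2. **Rate-shift moves** — (λ, μ) → (λ+c, μ+c), once across all doses and
   once at a single random dose; c ~ Normal(0, s²) with a 10% mixture
   component at 5× scale.  These moves hold the mean curve fixed while
   travelling the variance-identified λ+μ direction, including jumps
   between the quiescence and turnover basins that pCN crosses only slowly.
   They are deterministic-map Metropolis steps with the explicit φ-space
   Jacobian Π λ/(λ+c) · Π μ/(μ+c).
3. **α, τ²** — exact conjugate draws (Normal; Inverse-Gamma with the
   quadratic form taken in the unit-variance kernel).
4. **l²** — random-walk Metropolis on log l².
5. **θ** — conjugate Normal draw (flat prior, precision-weighted residuals
   of wells and background); **σ²** — random-walk Metropolis on log σ²
   (the 1/σ² prior cancels the log-scale Jacobian, leaving the likelihood
   ratio).

Proposal scales adapt toward acceptance 0.23 (vector blocks) / 0.44
(scalars) during burn-in only, then freeze, preserving the stationary
distribution.  The default configuration runs **three independent chains**
(seeds derived deterministically from the user seed) of 8,000 iterations
each and pools the retained halves; with few replicates single chains can
sit in one posterior basin for long stretches, and pooled dispersed-start
chains represent both basins far more reliably.  A fixed seed yields
bit-identical output.  Initialisation is per-dose method-of-moments (growth
rate from the mean count ratio, turnover from the replicate variance);
its χ²-noise usefully disperses the chains across basins.

Correctness was established two ways: prior-recovery (likelihood disabled;
marginal draws match every proper hyperprior by KS tests on
effective-sample-size subsamples — raw KS on thinned chains rejects
spuriously from residual autocorrelation) and a Geweke-style
joint-distribution check comparing forward prior simulation with
successive-conditional simulation.  The Geweke check runs under a
tightened hyperprior configuration keeping rates within a few e-folds of
0.5: with wide priors the successive chain enters regions where each
freshly resimulated dataset pins the latents (likelihood curvature grows
with the rates) and the check becomes non-ergodic on any practical time
scale.  Kernel correctness is configuration-independent, so nothing is
lost.  θ and σ² are held fixed in both halves of the check — improper
priors cannot be forward-simulated.

Diagnostics (effective sample size and split-R̂ per hyperparameter and a
subsample of grid points, via arviz) are computed on request and attached
to the run manifest; R̂ > 1.05 produces warnings.

## Summaries

With net growth g(z) = m(n0, z) − n0 and control growth g_c at a reference
dose: GI50 is the smallest z with g(z) = g_c/2, TGI the smallest z with
m(z) = n0, LC50 the smallest z with m(z) = n0/2.  The default control is
the smallest tested concentration ("min_dose") — the only reference always
available from modelled data; a "zero_dose" policy accepts dedicated
untreated wells.  Crossings are solved per posterior draw on the dense grid
by linear interpolation, taking the smallest crossing (GP curves may be
non-monotone; the fraction of draws with multiple crossings is reported).
Draws whose curve never reaches the threshold inside the tested range —
including GI50 draws whose control population shrinks — are censored,
excluded from the interval, and reported as a censored fraction rather
than extrapolated.  The point estimate is the crossing of the
posterior-mean curve; the 95% interval is the 2.5/97.5 percentile of
per-draw crossings.  Percent rate changes are
100·(r̄(z_max) − r̄(z_min))/r̄(z_min) on posterior-mean rates at the extreme
tested doses.

The Gompertz and logistic baselines are nonlinear least-squares fits with
≥ 12 data-driven multi-starts (asymptotes from the data range, midpoints
from dose quantiles, both slope signs) and an honest convergence flag;
their summary concentrations are point estimates only, by construction.

## Synthetic data

The generator emulates the screening design the method targets: 9
log-spaced doses on z ∈ [−9, −4], triplicate wells, n0 = 1000 per well,
θ = 30 and σ² = 400 (sd 20 counts) background noise measured in q = 6
background wells.  Final counts come from the exact Gillespie simulator —
not from the Gaussian approximation — so end-to-end tests exercise the
approximation as well as the inference.  Scenario shapes: constant rates;
sigmoidal birth inhibition; sigmoidal death induction; both (λ halves, μ
triples across the range); a two-step "plateau" response no single sigmoid
can track; and a quiescence/turnover pair (λ = μ = 0.02 vs 1.0) with
identical mean counts and ≥ 10× different process variances.  Ground-truth
GI50/TGI/LC50 are solved analytically on the noiseless true mean curve
under the min-dose control policy, keeping generator and estimator
conventions aligned.

What the generator does not emulate: plate/edge effects, luminescence
calibration nonlinearity, pipetting drift in n0, or density-dependent
rates λ(k, z).  Passing tests therefore demonstrate correctness of the
inference under the model's own assumptions plus exact birth–death
dynamics, not robustness to those real-data artefacts.

## Test problem sizes

The validation suite runs at desk scale: 10⁶ Gillespie trajectories per
transition-probability comparison (three representative rate/start
configurations), 10⁵ trajectories for moment and normality checks, 5,000
retained draws for prior recovery, 5,000 forward vs 5,000
successive-conditional draws for the Geweke comparison, and 50 replicated
9-dose triplicate experiments (3 chains × 8,000 iterations each) for the
coverage study, where pointwise 95% intervals are required to cover the
generating rate curves at ≥ 80% of dose points — deliberately looser than
nominal in acknowledgement of the triplicate-design identifiability limits
discussed above.

## Known limitations

* Per-dose death-rate point estimates remain noisy at realistic replicate
  counts; only λ−μ is sharply identified.  Interval summaries are the
  honest output, which is the method's point.
* The quiescence/turnover bimodality means posterior summaries can depend
  visibly on chain pooling at small n_iter; raise iterations or chains for
  publication-grade runs.
* Rates are time-homogeneous and density-independent by assumption; each
  experiment is analysed independently (no sharing across compounds or
  cell lines).
* The exact transition probability is exposed for validation, not
  inference; its cost grows with min(a, b).
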