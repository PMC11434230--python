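# Methods

This note documents the models, estimators, default parameters and design
choices in `evoqg`, and what the synthetic-data tests do and do not
demonstrate.

## Movement model and rate estimation

Locomotion is a three-state process (still, forward, backward; fixed index
order S=0, F=1, B=2) modeled as a time-homogeneous continuous-time Markov
chain. The six free parameters are the off-diagonal rates θ = (q_SF, q_SB,
q_FS, q_FB, q_BS, q_BF) in 1/s; diagonals are the negative row sums.
Transition probabilities use `scipy.linalg.expm` (Padé scaling-and-squaring);
the stationary distribution is the normalized null space of Qᵀ, with an
explicit reachability check that rejects reducible chains rather than
returning a boundary distribution.

Tracks are compressed to count matrices indexed by observation lag Δt.
Lags within a merge tolerance (default 1e-6 s) are pooled and represented
by their mean; this supports the mixture of lags produced by dropped
frames. The compressed log-likelihood is algebraically identical to the
per-pair sum; the test suite verifies agreement to 1e-10 against an
independently coded per-pair oracle with exactly-rounded summation.

Priors are independent log-normal, ln q ~ N(ln 2, 0.6²); the 0.6 is read as
the standard deviation on the log scale. Default estimation is MAP
(Nelder–Mead then BFGS on log-rates) with a Laplace approximation whose
Hessian is computed by central finite differences; posterior draws are
sampled from the resulting Gaussian on the log scale. A full MCMC
alternative uses the affine-invariant ensemble sampler (`emcee`),
initialized at the MAP and checked by autocorrelation-time/ESS diagnostics;
both routes must agree on synthetic data (tested at 5% on posterior means).
At the data sizes of interest (hundreds of tracks), interval calibration of
the Laplace route is verified directly: pooled 95% coverage across
replicate synthetic datasets is consistent with 0.95.

The state-frequency diagnostic compares observed time-in-state fractions
per plate with the stationary frequencies of a fitted Q. Note its
robustness: even strongly non-exponential (gamma shape 8–50) dwell times
leave the stationary-vs-occupancy relation within ~1% of the identity line,
because the fitted rates absorb the misspecification. The diagnostic
therefore detects a *mismatched* rate matrix, not semi-Markov dwell
structure per se.

## G-matrix estimation

Model: y = μ + T\*H\*D + L + B + e for the six log rates jointly, with
intercept, the three standardized covariates and all interactions (8 fixed
columns; an optional two-level assay-year flag adds one) and unstructured
6×6 line, block and residual covariances. G = L/2: for fully inbred lines
derived without selection, the between-line variance is twice the additive
variance of the source population.

The sampler is Gibbs with conjugate updates: matrix-normal draws for fixed
effects (flat prior), multivariate-normal conditionals for line and block
effects (batched over groups sharing a replicate count), inverse-Wishart
conditionals for the three covariance components. Priors are weak
inverse-Wishart with ν = 7 (traits + 1) and scale diag(phenotypic
variance)/2 split across components. Defaults: 3000 iterations, 1000
burn-in, thinning 10 (the pipeline uses 2500/500/10); production-scale
settings are reachable through `GibbsConfig`.

Convergence is flagged (never silently ignored) when the lag-1
autocorrelation of retained variance chains exceeds max(0.05, 2.5/√n):
with a few hundred retained draws, the max over six chains of a
white-noise autocorrelation regularly exceeds a fixed 0.05, so the bar
adapts to the retained sample size.

An independent MANOVA moment estimator ((MS_between − MS_within)/r₀, halved,
on covariate-residualized traits) cross-checks the Gibbs posterior mean;
the two routes agree within a few percent on synthetic panels.

Expected accuracy: with 150 lines the posterior mean G carries an
irreducible relative Frobenius error of roughly 10–20% driven by sampling
of the line effects themselves (of order √(2/n_lines) for an elliptical G,
worse for round ones); more replicates per line do not reduce it. This is
why panel comparisons rely on permutation and subsampling nulls rather
than raw point estimates.

Permutation nulls shuffle line and block labels independently and retain
the posterior mean per refit; line subsampling refits on random subsets
(e.g. 60 of 150+ lines) to mimic smaller panels.

## Divergence statistics

Spectral analysis uses descending eigenvalues with a deterministic sign
convention (largest-magnitude loading positive). Angles between directions
are folded to [0°, 90°] since v and −v span the same axis. The
"no alignment" null is the angle between pairs of vectors with i.i.d.
Uniform(−1, 1) coordinates (median ≈ 72° in six dimensions).

The covariance tensor of a set of G-matrices is built on scaled
half-vectorizations: 21-vectors with off-diagonals multiplied by √2, so
Euclidean geometry equals Frobenius geometry and eigentensor orthonormality
is testable exactly. The covariance across populations uses denominator
m − 1, giving at most m − 1 nonzero eigenvalues (asserted exactly).
Posterior uncertainty propagates by computing the tensor per posterior draw
with draws paired by index across populations, then summarizing. The
finite-sampling null for the tensor eigenvalues α_i draws line-effect
samples of the study's line count from a single pooled G per replicate,
re-estimates each population's G as half the sample covariance, and
rebuilds the tensor; resampling from a pooled matrix (rather than each
population's own posterior) is the implemented choice, exposed in the API.
The angle null and the α null are distinct and never interchanged.

## Selection surface

Relative fitness is exp(log-fertility) normalized to mean 1. Traits are
centered before building the quadratic design; variance standardization is
off by default (traits stay on the log-rate scale). The ½ factor sits in
the diagonal design columns so the coefficients are γ directly. Linear
(directional) terms are excluded by default — after adaptation no
directional selection is expected — with a flag to include them.

The regression posterior is exact (flat prior on coefficients, Jeffreys on
σ²: scaled-inverse-χ² for σ², conditional normal for coefficients), so
posterior draws are sampled analytically; residual normality and
scale-trend diagnostics are reported. Canonical analysis eigendecomposes
the point estimate for the reported U and rotates per-draw spectra for
intervals. The permutation null shuffles fitness across lines, refits, and
rotates each permuted γ by the *fixed* observed U, keeping the diagonal.
Alignment between divergence directions (eigentensor eigenvectors e_11,
e_12) and canonical axes uses Pearson correlations across the six loadings,
with intervals from re-deriving the axes on γ posterior draws. Note the
caveat: sorted eigenvalue posteriors are biased outward where the true
spectrum is nearly degenerate; interval statements are reliable for
well-separated axes (the strong stabilizing ones).

## Drift

Closed form V(t) = V₀(1 − 1/(2Ne))ᵗ. The individual-based check simulates
Ne diploid parents with 6-variate breeding values; offspring are midparent
plus a segregation deviation with covariance half the current realized G —
this recursion reproduces the closed-form mean decay exactly in
expectation (verified against the simulator across replicates).

The envelope comparison rotates G posteriors into the canonical frame and
compares each axis at each generation against the drift expectation
anchored at the ancestral posterior mode (configurable to the mean). Two
sources of spread enter the envelope: ancestral posterior uncertainty, and
the dispersion of *realized* drift, modeled per generation as a χ²(Ne−1)
variance-sampling factor. The latter dominates whenever t ≪ Ne (relative
sd ≈ √(2t/Ne) ≈ 45% at Ne = 1000, t = 100, versus a mean decay of only
4.9%), so omitting it would flag nearly every single drift realization as
selection. Consequently only variance losses well beyond that dispersion
(e.g. an axis losing ~90%+ of its variance) are detectable as
selection-like at these scales; the flag uses non-overlap of 83% intervals,
the convention for declaring two posteriors different.

## Synthetic data: what it does and does not emulate

Tracks: exact Gillespie paths observed at regular 4 Hz frames with i.i.d.
frame drops (`gap_probability`) to create mixed lags; initial states from
the stationary distribution; exponential track durations (mean 60 s); a
burn-in interval (default 300 s) yields no observations. Real tracker data
differ: variable native frame rates, track fragmentation from collisions,
male/hermaphrodite mixtures and density effects are not modeled, so
passing recovery tests demonstrates estimator correctness under the model,
not robustness to acquisition artifacts.

Panels: line effects drawn from N(0, 2G_true); shared block effects
(per-trait sd, default 0.1); plate-level covariates standardized with
configurable fixed effects; Gaussian residuals (default 0.05·I). Each line
appears in ≥2 of ≥4 blocks. The default planted G is strongly elliptical
(leading axis with positive loadings on all rates, largest for the
still-exit rates, carrying ~80% of the variance) — matching an ancestral
population whose variation concentrates along one g_max-like axis — with
trace ≈ 1.12.

Fitness: w = α + ½Σγ_kk z² + Σγ_k1k2 z_k1 z_k2 + ε on centered line means;
the default planted surface is diagonal with mixed signs,
diag(0.08, 0.05, 0.02, −0.04, −0.15, −0.35): weak disruptive curvature on
three axes and stabilizing selection strongest on the last axis.

Pipeline demonstration defaults (desk scale, chosen so the full run takes
seconds to low minutes on one CPU): 150 tracks × 3 plates, 100 ancestral /
60 derived lines × 3 blocks, derived populations at generations 50 and 100
of drift at Ne = 1000, 200 fitness permutations, 300 tensor-null
replicates, 1000 angle-null pairs. Replicate counts in the test suite and
acceptance script are similarly desk-scaled (e.g. 25–100 permutations,
200 drift replicates).

## Numerical conventions

- Trait order everywhere: (SF, SB, FS, FB, BS, BF); trait columns `lnq_*`.
- 83%/95% intervals are equal-tailed quantiles; posterior modes via a
  Freedman–Diaconis histogram peak.
- expm output clipped to [0, 1] (guards Padé round-off); likelihood returns
  −∞ if a positive count meets a zero probability, and zero-count cells
  contribute zero regardless of probability.
- Eigen sign convention: largest-magnitude loading positive; ties broken by
  the first differing loading.
- All generators and samplers take integer seeds and are bit-reproducible;
  the pipeline derives stage seeds from one root seed via `SeedSequence`
  and records them in the manifest, which contains no timestamps so reruns
  are byte-identical.

## Known limitations

- Broad-sense G from inbred lines equals the additive G only absent
  directional non-additive gene action; the package does not attempt
  narrow-sense decomposition.
- The Laplace posterior for transition rates is Gaussian on the log scale;
  for very sparse states (a state never visited) the MAP is
  prior-influenced but multi-jump paths still inform it — such fits are
  flagged with a warning rather than treated as pure prior.
- Permutation refits at reduced Gibbs settings trade some Monte-Carlo error
  in each null draw for runtime; null summaries average over permutations,
  which damps that error.
- The drift envelope treats axes independently; correlated variance changes
  across axes are summarized only through the full-matrix trace check.
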