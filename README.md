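# evoqg

Quantitative genetics of locomotion behavior under experimental evolution:
an end-to-end, fully synthetic-testable pipeline for studying **phenotypic
stasis with genetic divergence** in *Caenorhabditis elegans*-style
evolution experiments.

Worm locomotion is summarized by six transition rates between three
movement states — still (S), forward (F), backward (B). The package
estimates those rates from tracking data, estimates the genetic
(co)variance structure of the rates from inbred-line panels, quantifies how
that structure diverges among populations, estimates the selection surface
acting on the rates, and asks whether the observed loss of genetic variance
is compatible with drift alone.

## The models

**Movement as a continuous-time Markov chain.** The state sequence follows
a time-homogeneous CTMC with rate matrix *Q* (off-diagonals *q*<sub>ij</sub> ≥ 0,
rows summing to zero), so the transition probability over a lag Δt is
*P*(Δt) = exp(Δt·*Q*). Observed tracks are compressed to transition counts
ñ(i, j, Δt) and the log-likelihood is
ℒ = Σ<sub>k</sub> **1**ᵀ(Ñ<sub>k</sub> ⊙ ln *P*(Δt<sub>k</sub>))**1**,
identical to the per-pair sum but far cheaper. Rates get independent
log-normal priors ln *q*<sub>ij</sub> ~ 𝒩(ln 2, 0.6²); estimation is MAP with a
Laplace approximation (optional full ensemble MCMC).

**Broad-sense G-matrix.** The six log rates are a multivariate response in

y = μ + T\*H\*D + L + B + e

with standardized environmental covariates (temperature, humidity, density;
all interactions) as fixed effects and unstructured line (L), block (B) and
residual covariances, fitted by a conjugate Gibbs sampler. **G** is half
the between-line covariance. Permutation nulls (shuffled line/block labels)
and random line subsampling quantify sampling expectations.

**Divergence and differentiation.** Matrix size is the trace; shape is
compared via eigenvectors (g<sub>max</sub>), angles folded to [0°, 90°] against a
uniform-random-vector null, and the fourth-order genetic covariance tensor
**Σ**, whose orthonormal eigentensors **E**<sub>i</sub> (eigenvalues α<sub>i</sub>) give the
phenotypic directions that maximally separate a set of G-matrices.

**Selection surface.** Relative fitness per line is regressed on squared
and cross-product trait deviations, w = α + ½Σγ<sub>kk</sub>z²<sub>k</sub> + Σγ<sub>k1k2</sub>z<sub>k1</sub>z<sub>k2</sub> + ε;
canonical analysis Λ = **U**ᵀγ**U** rotates the surface onto axes of pure
disruptive (λ > 0) or stabilizing (λ < 0) selection, and G-matrices are
rotated into the same frame as **G**′ = **U**ᵀ**G****U**.

**Drift.** Under the infinitesimal model the genetic variance decays as
V(t) = V₀(1 − 1/(2N<sub>e</sub>))ᵗ. An individual-based simulator provides the
stochastic counterpart, and observed per-axis variances are compared
against a drift envelope that includes both ancestral posterior uncertainty
and the realized-drift dispersion.

Every input has a synthetic generator with known ground truth
(`evoqg.synthetic`), so the whole pipeline is testable by parameter
recovery without any external data.

## Worked example

Simulate plates of tracks from known rates and re-estimate them:

```sh
evoqg simulate-tracks --rates 2,0.5,0.5,0.5,0.5,0.5 --n-tracks 200 --seed 1 --out tracks.tsv
evoqg estimate-rates --tracks tracks.tsv --out rates/
```

```
rate     mode     mean     q2.5     q8.5    q91.5    q97.5
  SF 2.015880 2.016907 1.934936 1.962703 2.072095 2.098887
  SB 0.478991 0.479888 0.440718 0.451419 0.509946 0.524551
  FS 0.502386 0.502756 0.478302 0.486416 0.519796 0.526779
  FB 0.494407 0.494094 0.472575 0.479470 0.509211 0.515403
  BS 0.514869 0.514984 0.486839 0.495187 0.534639 0.543978
  BF 0.482511 0.483022 0.456504 0.463726 0.502653 0.510899
```

Each row is one transition rate (per second): the posterior mode and mean,
with 95% (`q2.5`–`q97.5`) and 83% (`q8.5`–`q91.5`) equal-tailed credible
intervals. All six true rates (2.0 for S→F, 0.5 elsewhere) are recovered
inside their 95% intervals.

The full synthetic demonstration — tracks → rates → G-matrices for an
ancestral and two drift-derived populations → tensor comparison →
selection surface → drift envelope — runs with

```sh
evoqg run-all --out demo_run --seed 0
```

and writes CSV reports (`rate_posterior.csv`, `G_summary_*.csv`,
`eigentensor_alphas.csv`, `canonical_analysis.csv`, `drift_envelope.csv`,
…) plus a `manifest.json` recording the config hash and all derived seeds;
rerunning with the same config reproduces every artifact byte for byte.

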