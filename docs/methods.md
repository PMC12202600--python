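# Methods

## Model

`burstfish` infers the kinetics of transcriptional bursting from dual-color
single-molecule FISH (smFISH) snapshots. The underlying model is the random
telegraph model: a promoter switches between an inactive (OFF) and an active
(ON) state with activation rate λ and deactivation rate γ (both 1/h);
while ON, mRNA is produced at rate μ (RNA/h); every mRNA is degraded at rate
δ (1/h). The stationary probability of the ON state is the active fraction

    f = λ / (λ + γ),

which is the principal regulated quantity in bursting analyses. A fifth
parameter β is the variance of the exon-fluorescence intensity at an active
transcription site (TS), in squared mature-RNA equivalents; it absorbs the
overdispersion of measured TS intensities relative to the mechanistic
prediction and is phenomenological, not mechanistic.

### Single-allele stationary law

With a = λ/δ, b = (λ+γ)/δ and ρ = μ/δ, the joint stationary law of
(promoter state X, copy number Y) for one allele is available in closed form
through Kummer's confluent hypergeometric function M(·,·,·):

    p(m) = P(X=ON,  Y=m) = [Γ(b)Γ(m+a+1) / (Γ(a)Γ(m+b+1))] · M(m+a+1, m+b+1, −ρ) · ρ^m/m!
    q(m) = P(X=OFF, Y=m) = (b−a) · [Γ(b)Γ(m+a) / (Γ(a)Γ(m+b+1))] · M(m+a, m+b+1, −ρ) · ρ^m/m!

The q form follows from the contiguous relation
G₀ = M(a,b,ρs) − (a/b)·M(a+1,b+1,ρs) = ((b−a)/b)·M(a,b+1,ρs) applied to the
generating-function solution, and is enforced mechanically: the test-suite
requires both partial mass functions to agree with a brute-force stationary
solution of the truncated chemical master equation (CME) to max-abs 1e-8
across a parameter grid. The marginal p+q is the familiar beta-Poisson
count distribution, cross-checked against the independent closed form
(a)_m/(b)_m · ρ^m/m! · M(a+m, b+m, −ρ).

All pmf evaluations assemble linear-space values from log-gamma differences.
Every in-model Kummer call has a negative argument −ρ, where the direct
series alternates and cancels catastrophically; the Kummer transformation
M(a,b,−ρ) = e^(−ρ)·M(b−a, b, ρ) is therefore applied everywhere, leaving an
all-positive series that scipy evaluates stably. For ρ beyond scipy's
overflow range (≈700) a log-domain series summation takes over; arguments
beyond 1e4 are rejected outright (they exceed the truncation budget anyway).

### Polyploid convolution (count likelihood, L1)

The study system is a polyploid cell line: each cell carries K statistically
identical, independent alleles (K known per cell from prior DNA FISH, an
input here). The probability of observing k active alleles and a *total*
count m is

    L1(θ; k, m) = C(K,k) · (p^{*k} ⊛ q^{*(K−k)})(m),

where ^{*k} is k-fold self-convolution (0-fold = unit mass at m=0).
Convolutions are computed by direct summation on the truncated arrays; the
truncation m_max is chosen adaptively as the smallest power-of-two-grown
length with joint tail mass below `tail_tol` (default 1e-10, cap 2000).
A cell whose observed count exceeds the single-allele truncation indexes the
full convolved support rather than being clipped. "Active" in the data means
intron-probe signal detected; the likelihood equates detection with the ON
state, an approximation the mechanistic simulator can quantify (below).

The independent oracle for all of this is `cme_stationary_oracle`: for K
exchangeable alleles the aggregated pair (number ON, total RNA) is itself a
Markov chain (activation (K−k)λ, deactivation kγ, birth kμ, death mδ), so
the oracle builds that generator on a truncated lattice and solves the
balance equations as a dense linear system (relative residual < 1e-10).
This is exact up to truncation and shares no code with the closed forms.

### Nascent-intensity model (intensity likelihood, L2)

The measured exon fluorescence z at a *detected* active TS is modelled as
Gamma with mean ν and variance β (shape ν²/β, scale β/ν). The mean ν is
predicted mechanistically from (λ, γ, μ) by rejection sampling:

1. a stationary promoter trajectory is drawn over an observation window equal
   to the gene traversal time L/v (earlier initiations cannot still occupy
   the gene, so no warm-up is needed; initial state ON with probability f);
2. initiation events form a Poisson process at rate μ on ON segments; an
   event at time t sits at position v·(t_obs − t) at observation time;
3. the sample is accepted only if some polymerase sits inside an intron at or
   past an intron-probe target in that intron — the detection condition under
   the fast-splicing assumption (completed introns vanish instantly);
4. z = Σ_polymerases (#exon probes transcribed)/(total exon probes), so a
   complete nascent transcript contributes exactly 1.0 (mature-RNA-equivalent
   units, matching normalization by the average mature-spot intensity).

ν is the mean of accepted z values. The elongation rate v defaults to
50 bp/s (mammalian Pol II, ~2-3 kb/min) and is a configurable hyperparameter.
The sampler is vectorized and is validated against closed forms: always-ON
polymerase occupancy is Poisson(μL/v), and for a single whole-gene intron
probed at its start the acceptance probability is 1 − e^(−μL/v) with an
analytic conditional mean.

Because ν is re-estimated by Monte Carlo at every parameter proposal, the
posterior is pseudo-marginal in flavour. The package mitigates the noise
with common random numbers: each chain fixes one intensity-model seed, so the
log-posterior is a deterministic function of the parameters within a chain
(`n_intensity_samples`, default 1000 accepted draws, controls the residual
bias/smoothness trade-off). An acceptance-rate floor (1e-4 after 1e6
proposals) converts vanishing-μ pathologies into an explicit infeasibility,
which the posterior maps to zero mass.

### Posterior

Cells and detected TSs are independent given θ, so
log L = Σ_c log L1,c + Σ_t log L2,t. The prior is improper uniform on the
positive linear scale; sampling runs in natural-log coordinates, so the
Jacobian Σ_i log θ_i is added (a flag switches to uniform-in-log for
sensitivity checks). L1 alone leaves the parameters scale-ambiguous — only
a, b, ρ enter it — and the L2 factor, whose ν depends on absolute time via
the elongation rate, resolves the scale of δ. This is reproduced
quantitatively: an L1-only fit widens the relative credible interval of δ by
well over 5× compared to that of f. The L1-only ablation is run under the
uniform-in-log prior: under the linear-uniform prior the Jacobian makes the
unidentified scale direction drift systematically toward large scales until
it meets the log-parameter bound, whereas under the log-uniform prior the
flat direction diffuses freely and the δ marginal honestly reflects the
non-identifiability.

## Sampling

Adaptive random-walk Metropolis in the 5-dimensional log domain. The
proposal is multivariate normal, initial covariance I, scaled by 2.38²/5.
During burn-in only, two adaptations run:

* covariance shape: Σ ← Σ + η_i (S_window − Σ) with η_i = (i+1)^(−0.6), a
  Robbins–Monro recursion on the empirical covariance of a moving window of
  500 samples (jitter 1e-10·I);
* global scale: log s ← log s + η_i·(acc_window − 0.234)/(0.234·0.766),
  steering windowed acceptance toward the 0.234 optimum.

Both freeze at the end of burn-in, so the recorded phase is a valid
Metropolis chain. Window length, exponent, target rate and jitter are this
package's choices (they are tuning constants by nature); defaults are
10,000 burn-in + 30,000 recorded samples, single chain. Initialization is a
method-of-moments heuristic (f₀ from mean k/K; ρ₀ from mean counts; δ₀ =
1/h; promoter timescale λ₀+γ₀ = 2δ₀; β₀ = sample variance of intensities),
overridable. Summaries are posterior means with 2.5%/97.5% empirical
quantiles (linear interpolation of the empirical CDF) on the linear scale,
including f computed per draw. Convergence is assessed from traces, backed
by numeric aids: autocorrelation-based effective sample size (Geyer initial
positive sequence) and windowed acceptance.

## Synthetic data

The generator defines the package's reference study conditions:

* truth λ=0.4, γ=0.6, μ=8, δ=0.4 (1/h) → a=1, b=2.5, ρ=20, f=0.4 — a
  clearly overdispersed, identifiable bursting regime with switching on the
  degradation timescale, typical of stress-responsive genes; β=0.15;
* ploidy K=3 (polyploid line), n_cells=400 per condition — the scale of a
  well-powered smFISH time-point;
* gene fixture: 10 kb, 30 exon probes, 10 intron probes in 2 introns,
  unevenly placed (seeded), elongation 50 bp/s.

`idealized` mode draws each allele exactly from the stationary joint law
(inverse CDF), sets k = #ON alleles, m = Σ counts, and gives each active TS a
Gamma(ν*, β) intensity with ν* computed at the truth — data that satisfy the
inference model exactly, so fits test parameter recovery with no mismatch.
`mechanistic` mode simulates trajectories and polymerase positions per
allele; "active" means the intron signal would actually be detected, and
intensities are simulated exon fluorescence with multiplicative Gamma noise
whose variance is calibrated so the total matches β (no noise added when the
mechanistic variance already exceeds β). Mechanistic fits quantify the
detection≈ON approximation as a bias report, not an assertion. Neither mode
simulates segmentation errors, spot-detection errors or extrinsic noise, so
passing recovery tests demonstrates correctness of the inference machinery,
not robustness to microscopy artefacts.

Cells with zero detected TSs are kept (and counted in the ground-truth
record); the fit includes every cell with known ploidy.

## Numerical choices and degenerate inputs

* λ, γ < 1e-12 rejected (both promoter states must be reachable); limits are
  explored with small-but-positive rates.
* pmf truncation failure, non-SPD proposal covariance, ill-conditioned oracle
  solves, and infeasible rejection sampling all raise distinct exceptions;
  within the posterior the first and last map to −∞ (zero mass) because the
  sampler must keep moving.
* log-parameters beyond ±40 get zero posterior mass outright: e^40/h rates
  are beyond physical meaning and protect the special-function budget.
* UPGMA clustering ties follow scipy's deterministic lower-index-first
  convention; quantiles use linear CDF interpolation — both stated so the
  worked examples are exact.
* Mann–Whitney U: exact null for n ≤ 20 without ties, normal approximation
  with tie correction otherwise; Bonferroni family is per (gene, condition)
  by default, with a global-family option.

## Problem sizes used in validation

The validation suite uses deliberately scaled problem sizes chosen for a
single-CPU workstation run: oracle comparisons on a 27-point parameter grid
with truncations of a few hundred states; rejection-sampler checks at 10,000
draws; the Gaussian-target MCMC check at 5,000+15,000 iterations; and the
end-to-end recovery study at n_cells=400, K=3 with 10,000+10,000 iterations
(the headline analyses in production use 10,000+30,000). Recovery is scored
on the δ-normalized parameters (within 20% relative error at these sizes)
and on 95% credible-interval coverage of f.

## Known limitations

* Single-chain MCMC can miss distant posterior modes; no tempering or
  multi-chain R-hat is provided (traces + ESS are).
* The pseudo-marginal ν estimate introduces a small bias that decreases with
  `n_intensity_samples`; an exact-marginal method is not available.
* The detection≈ON identification in L1 is an approximation; its size is
  measurable with the mechanistic generator but not corrected for.
* No splicing kinetics, polymerase pausing, probe-specific brightness or
  optics modelling; intensity units assume the exon probe set is the unit of
  brightness.
* Time-dependent (non-stationary) telegraph solutions and >2-state promoters
  are out of scope.
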