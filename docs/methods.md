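# Methods

## Models

All estimators address the same dimensionality-reduction problem: find a
filter matrix K (D × p, orthonormal columns) such that the response
distribution depends on the stimulus only through x = K^⊤s. Three
conditional response families are implemented:

* **LNP** (Poisson): r | s ~ Poisson(λΔ) with rate λ = f(x) in spikes/s and
  bin width Δ in seconds.
* **LNB** (Bernoulli): r ∈ {0,1} with spike probability λ = f(x) ∈ [0,1].
* **LNC** (count/categorical): r ∈ {0..r_max} with per-count probability
  functions f^(j)(x) summing to 1 at every x. LNB is the r_max = 1 special
  case; LNP is the limit in which the count distribution is Poisson.

With a piecewise-constant nonlinearity over a histogram partition
{B_1..B_m} of the projection, the maximum-likelihood nonlinearity has closed
form (bin spike rate, or per-count bin frequencies), and the profiled
log-likelihood equals the corresponding plug-in information estimator times
n_sp·ln 2, plus a filter-independent constant:

* Poisson: n_sp·Î_ss·ln2 = ℒ_lnp(θ̂) − ℒ_lnp(θ₀), θ₀ the constant-rate model;
* Bernoulli: n_sp·Î_Ber·ln2 = ℒ_lnb(θ̂) + N·Ĥ[r];
* Count: n_sp·Î_count·ln2 = ℒ_lnc(θ̂) + N·Ĥ[r],

where Ĥ[r] is the plug-in marginal response entropy (−N·Ĥ[r] is exactly the
null model's log-likelihood). These identities are exact at machine
precision for any data, bin width, and binning, and the test suite asserts
them to 1e-9 nats on random datasets in all three regimes. They are the
reason information-maximizing and likelihood-maximizing subspaces coincide.

Two sign/typography points were resolved by requiring the identities to
hold: the Bernoulli log-likelihood is Σ r ln λ + (1−r) ln(1−λ) (the form for
which the Bernoulli identity is exact), and the second-derivative term of
the Poisson log-likelihood in λ is −r/λ² (the curvature term of the CBF
Hessian enters with a minus sign). Finite-difference tests pin both.

## Information estimators and conventions

Internal computations use natural logs; every public value is reported in
bits (per spike unless stated), with `InfoReport` carrying an explicit unit
tag and a lossless bits↔nats converter. 0·log 0 ≡ 0 throughout. Support
nesting (a spike-triggered stimulus is a stimulus) guarantees finite plug-in
values on training data. A dataset with no spikes returns 0 with a warning —
a pipeline convenience convention, not a substantive claim. The per-count
conditionals q̂^(j) are kept distinct from the spike-weighted q̂: I_1 (the
one-spike term of the count information) is *not* the single-spike
information, which weights each stimulus by its full spike count.

The PSTH-based estimator for frozen-noise repeat data uses the
trial-averaged rate λ̂(t) as the plug-in inhomogeneous rate; the same
Poisson-likelihood identity holds and is tested. Its cross-validated
variant evaluates a training-set rate on held-out responses and may be
negative for poor models; bins with zero training rate but held-out spikes
receive a pseudocount floor of 0.5 spikes (held-out evaluation only — raw
plug-in estimates are never smoothed).

## Histogram machinery

Partitions are products of per-axis partitions with half-open cells
[b_{i−1}, b_i) and unbounded outer cells; a value exactly at an interior
edge goes right. Edge placement is either equal-width over the data range
or equal-occupancy (quantile edges). Equal-occupancy is the default for
data-driven estimation because it stabilizes the density-ratio denominator
in sparsely-sampled tails, exactly where log-ratio objectives are most
noise-sensitive. Multi-axis histograms cost m^p bins and are practical only
for p ≤ 3; the CBF route exists for everything beyond.

The bin count m is the capacity of the implied nonlinearity and is the one
parameter a user must own: small-sample fits overestimate information with
large m (overfitting) and underestimate the asymptotic value with small m
under a steep nonlinearity (underfitting). `cross_validate_bins` sweeps m
and reports held-out information on an 80/20 split.

## Subspace optimization

The histogram objectives are piecewise-constant in K, so derivative-free
search is used: an exhaustive angle grid (default 1°, ties resolved to the
smallest angle) for one filter in two stimulus dimensions — the setting of
the analytic toys, and fully reproducible — and multi-restart Nelder-Mead
over unconstrained filter coordinates with per-evaluation orthonormalization
(QR, sign fixed so each column's largest-magnitude entry is positive)
otherwise. The first restart starts at the spike-triggered average plus
leading spike-triggered-covariance axes; the rest are seeded random
orthonormal frames. Histograms are rebuilt at every candidate K. A flat
objective (range below tolerance) is flagged "no informative direction"
rather than returning an arbitrary axis silently. Recovery is always scored
by the largest principal angle between subspaces — only the column space of
K is identifiable.

## Population (infinite-data) curves

For toy neurons with analytic stimulus laws and conditional response
probabilities, information-versus-angle curves are computed by quadrature:
midpoint rule on the half-circle (20001 nodes), equal-area polar grids on
the unit disk, tensor Gauss-Hermite nodes for Gaussian stimuli. Exact
conditionals replace observed counts in the histogram tallies, removing all
sampling noise and isolating estimator bias.

The histogram partition is part of the objective being analyzed: a
histogram estimator with m bins converges, as data grow, to the argmax of
the *binned* information, which is why a mismatched objective can remain
biased "with infinite data". The package's canonical resolution for these
curves is 20 equal-width bins. For the half-circle neuron this yields a
clockwise displacement of the spikes-only argmax of 15.75° (Bernoulli
argmax exactly 90° at every resolution tested); the displacement grows at
coarser resolution (≈20° at 5 bins) and shrinks toward zero in the
infinitely-fine-bin limit, where both binned curves approach the continuous
KL curves. Equal-width edges are used on these compact projections; for the
Gaussian-stimulus toy, equal-occupancy edges are used instead (unbounded
projections), with edges placed only between distinct atoms of the discrete
quadrature distribution — splitting a tied group would let numerically
leaked orthogonal components order the tie and manufacture spurious
information.

## Silence-information bound

For binary responses the mutual information decomposes exactly as
I = ρ·KL(Q₁‖P) + (1−ρ)·KL(Q₀‖P) with Q₁/Q₀ the spike/silence-conditioned
stimulus distributions and P = ρQ₁ + (1−ρ)Q₀. Small-ρ expansion gives
(1−ρ)KL(Q₀‖P) = ½ρ²V(Q₁,Q₀) + O(ρ³) and I = ρKL(Q₁‖Q₀) − ½ρ²V + O(ρ³),
with V = ΣQ₁(Q₁/Q₀ − 1) ≥ KL(Q₁‖Q₀); hence silence fraction ≥ ρ/2 as ρ→0.
The numerical minimum over binary-stimulus channels — prior q and both
conditional spike probabilities constrained to the marginal ρ, on a
400 × 400 grid, excluding channels with < 1e-12 bits of total information —
stays above the bound at every ρ tested (0.104 at ρ = 0.2, against the
bound's 0.100). The search includes the conditional probabilities as free
parameters, the conservative reading of the binary-channel minimum. The
ρ = ½ case (a Jensen–Shannon statement, conjectured fraction ≥ ¼) is probed
by randomized Dirichlet search, which reports — never asserts — the minimum
found.

The Taylor-remainder scaling study uses a fixed channel with a strongly
suppressed stimulus symbol (Q₁ = (0.001, 0.4995, 0.4995) against
Q₀ = (0.3, 0.35, 0.35)) — the silence-dominated regime the bound concerns,
where a stimulus symbol almost never elicits a spike. The exact cubic
coefficient of the silence remainder is −Σd²(Q₀+2Q₁)/(6Q₀²) (d = Q₁−Q₀),
strictly negative; the finite-range log-log slope fitted over
ρ ∈ [10⁻⁴, 10⁻¹] therefore sits within ~0.05 of 3 for any valid pair, with
the side of 3 set by the sign of the quartic coefficient (negative for
suppressed-symbol channels such as the fixture). Random-pair property tests
assert |slope − 3| ≤ 0.1.

## CBF-LNP model

The many-filter nonlinearity is λ = g(Σ α_i φ_i(K^⊤s)) with first-order
atoms exp(−(x_a−μ)²/(2σ²)) (Gaussian in one projected axis, constant in the
rest) or second-order atoms on axis pairs; d atoms per axis cost p·d weights
(first order) versus d^p for a full radial-basis grid — the two coincide at
p = 1. Centers sit at per-axis quantiles of the projected training values
and σ equals the center spacing, making the basis invariant to projection
scale. g is softplus by default (exp is provided; with a first-order basis
it makes f multiplicatively separable across axes).

Fitting maximizes ℒ = r^⊤log λ − Δ·1^⊤λ (the parameter-free Σ log r! is
omitted) jointly over {K, α} by trust-region Newton with the analytic
gradient and Hessian (trust-ncg, gradient tolerance 1e-5, trust-krylov
fallback); joint optimization converges far faster here than alternating
updates. The α-subproblem is concave for convex log-concave g and is solved
by damped Newton both for initialization and for the weights-only refit
after the final orthonormalization of K. Initialization is STA plus leading
STC eigenvectors by default, with random-restart and incremental
(one-filter-at-a-time warm start) modes. Per-filter informativeness is
measured by dropping a filter, refitting the weights only on training data,
and scoring the held-out log-likelihood drop in bits; filters are labelled
excitatory or suppressive by whether the fitted marginal nonlinearity at
the 90th percentile of projections exceeds its median value — a documented
convention, flagged when the marginal is non-monotone.

## Synthetic data

Every generator is seeded through `numpy.random.default_rng` and attaches
its ground truth for principal-angle scoring. The study conditions:

* **Half-circle Bernoulli neuron** — stimuli uniform on the right unit
  half-circle, spike probability θ/π + 1/2 (the linear-in-angle law; mean
  spike fraction ½).
* **Sigmoid LNB neuron** — 2-D Gaussian stimuli, one filter (default 45°),
  logistic nonlinearity with slope 4 and offset −2 (≈20% spiking, the regime
  where bin-count over/underfitting is visible). The published version of
  this toy does not print its sigmoid parameters; only orderings are tested,
  not values.
* **Excitatory/suppressive neuron** — λ = σ(g_e·s₁)·exp(−g_s·s₂²) with
  gains (2, 1): a synthetic stand-in (the published nonlinearity is not
  recoverable), chosen so each cardinal axis is a local maximum of the
  Bernoulli information with a dip between, and either axis's information
  vanishes when its gain is zeroed. The published global-argmax reversal and
  its 13% margin are not reproduced by this stand-in.
* **Count toys on the unit disk** — deterministic variant: count ∈ {0,1,2}
  piecewise-constant in the horizontal projection with breakpoints at its
  terciles (breakpoints are not printed in the source analysis; terciles
  make all three counts common); variance-coded variant: probability
  σ(4x) of emitting {0 or 2, fair coin} and otherwise exactly 1 spike, so
  the conditional mean count is 1 everywhere and only the variance carries
  the signal — the spikes-only objective is provably blind to it.
* **Two-stimulus worked example** — deterministic raster for sequences AB
  and BA (A → 3 spikes, B → 1, Δ = 1 s): single-spike information 0.19
  bits/spike (equivalently prior entropy 1 bit minus posterior 0.81 bits),
  count information 0.5 bits/spike, Bernoulli information undefined (counts
  exceed 1; the estimator raises rather than truncating).
* **Frozen-noise repeats** — Poisson draws around a fixed rate profile.

What these generators emulate is the *conditional response structure* of
the corresponding models; they do not emulate natural-stimulus
correlations, spike-history dependence (refractoriness, bursting,
adaptation), or nonstationarity. Passing recovery tests therefore show
estimator correctness under matched or controlled-mismatched model
families, not performance on real recordings.

## Problem sizes and numerical choices

Default problem sizes are chosen to make the statistical claims decisive at
desk scale: N = 10⁴ for 1-filter recovery (< 5° principal angle), N = 2×10⁴
for 2-filter CBF-LNP recovery (< 10°), N = 10⁵ for the variance-coded
failure-mode comparison (count objective < 5°; spikes-only objective median
error > 10° at both 10⁴ and 10⁵, i.e. non-convergent), 20001 quadrature
nodes and a 0.25° angle grid for the asymptotic curves. Optimizer
tie-breaks, the 1e-12-bit zero-information guard, the 0.5-spike held-out
floor, and the sign convention for filters are all stated above and fixed
by tests.

## Known limitations

Histogram objectives do not scale past p ≈ 3; use the CBF route. The
Nelder-Mead search offers no global guarantee (mitigated by restarts and by
exhaustive grids in 2-D). Plug-in information is upward-biased on training
data at small N (no jackknife/bias correction is implemented — out of
scope). The CBF σ/center placement is a heuristic; no basis-size selection
is automated beyond the cross-validation helpers. Spike-history and
continuous-time representations are out of scope. The ρ/2 bound above the
small-ρ regime, and its binary-stimulus minimum, rest on numerical search,
not proof.
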