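# Methods

## Model

`ergmee` fits exponential random graph models (ERGMs) to a single observed
directed network. An ERGM assigns a sparse digraph `x` on `N` nodes the
probability

    Pr(X = x) = (1/kappa) * exp( sum_A theta_A * z_A(x) )

where each *configuration* `A` is a small subgraph pattern, `z_A(x)` its
statistic, `theta_A` the corresponding parameter and `kappa` an intractable
normalizer. Dependence between ties follows the social-circuit assumption:
two potential ties are conditionally dependent exactly when they would
close a 4-cycle, which licenses the "alternating" statistics below.

### Effects

Structural effects (`lambda >= 1` is a geometric damping constant,
default 2):

| Effect | Statistic |
|---|---|
| Arc | number of arcs (density intercept; always first in a model) |
| Reciprocity | number of mutual dyads |
| AinS / AoutS | alternating k-in/out-stars: `sum_k (-1)^k S_k / lambda^(k-2)` over in/out-star counts `S_k` (degree spread) |
| AT-T | `lambda * sum_ij x_ij [1 - (1-1/lambda)^L2(i,j)]` with `L2(i,j)` the directed two-path count i->h->j (path closure) |
| AT-C | as AT-T but on `x_ji` (cyclic closure) |
| A2P-T | `lambda * sum_{i<j} [1 - (1-1/lambda)^L2(i,j)]` (multiple connectivity) |
| A2P-D / A2P-U | same form on shared-predecessor counts `L2D` / shared-successor counts `L2U` (shared popularity / activity) |
| A2P-TD | `z_A2P-T + z_A2P-D / 2` (combined, D term halved against double counting) |
| AKT-D / AKT-U | closure of A2P-D / A2P-U paths: `lambda * sum_ij x_ij [1 - (1-1/lambda)^L2D/L2U(i,j)]` |
| Isolates | count of nodes with zero in- and out-degree |

Attribute effects: binary Sender / Receiver / Interaction; categorical
Matching / Mismatching and their reciprocity variants (mutual dyads
counted once, matching the Reciprocity convention); continuous Sender /
Receiver / absolute-difference (Diff) homophily. Any term touching a
missing attribute value contributes zero.

Every effect has a *change statistic* — the difference in `z_A` caused by
toggling one arc — with a closed form using only the endpoints'
neighbourhoods and incrementally maintained two-path count tables. The
full statistics exist in the package as reference definitions and test
oracles; samplers and the estimator touch only change statistics. The
equivalence of the two (to 1e-9 over thousands of random toggles) is the
core correctness property of the test suite, checked independently for
the pure-Python reference and the compiled kernels.

## Data structures

The graph store keeps out- and in-adjacency lists, a flat arc list
(swap-with-last deletion, so uniform arc sampling is O(1)), and three
hash tables keyed by node pairs: ordered directed-two-path counts
(`mix2`), and unordered common-predecessor (`in2`) / common-successor
(`out2`) counts. Arc toggles update all tables in O(deg(i)+deg(j));
entries reaching zero are deleted so table size tracks the number of
nonzero pairs. The compiled kernels mirror this layout on numba typed
containers; deletion change statistics are evaluated directly on the
pre-deletion graph (two-path counts corrected for paths through the arc
itself), so rejected deletion proposals mutate nothing.

## Samplers

*Basic*: toggle a uniformly random ordered dyad, accept with probability
`min(1, exp(theta . delta_z))`. Exactness is verified against full
enumeration of all 64 digraphs on three nodes (total variation < 0.01).

*Improved fixed density (IFD)*: insertion of a uniform absent dyad and
deletion of a uniform arc, with an auxiliary parameter `v` entering the
log-acceptance as `+v` for insertions and `-v` for deletions. The
proposal type is state-driven — insertion at the observed arc count L0,
deletion at L0+1 — so the count never leaves {L0, L0+1}; at block
boundaries deletion proposals continue until the count is exactly L0.
`v` absorbs the density intercept and the insertion/deletion proposal
asymmetry; because every move changes the arc count, the value of `v`
affects only the mixing between the two count levels, not the
conditional distribution at fixed density, which is the distribution of
interest. `v` is adapted during burn-in (an accepted insertion lowers
it, a rejected one raises it, symmetrically for deletions, by
`ifd_adapt_rate` = 0.01) and frozen afterwards.

## Estimation

**Equilibrium expectation (EE).** The chain starts at the observed
network with divergence `dz = z(x_t) - z(x_obs) = 0`, runs
`steps_per_update` proposals, then updates each parameter against the
sign of its divergence:

    theta_A <- theta_A - sign(dz_A) * a * max(|theta_A|, theta_min)

with `a` = `learning_rate` = 0.01 and `theta_min` = 0.01, exploiting the
exponential-family monotonicity of `E[z_A]` in `theta_A`. After a
transient the divergences oscillate around zero and the parameters
around the MLE; the point estimate is the mean of the second half of the
parameter trace. An additive variant `theta_A <- theta_A - a * dz_A` is
available (`update_rule="simple"`).

**Contrastive divergence initialization** applies the same signed update
(at the coarser `cd_learning_rate` = 0.1) to divergences accumulated
over short bursts (`cd_steps` = 500) that revert to the observed network
before every update, starting from theta = 0. 200 updates are the
default: the multiplicative rule needs roughly `ln(|theta|/theta_min) /
ln(1.1) ~ 60` sign-consistent updates to reach a magnitude of 4, plus
headroom for effects whose divergence changes sign during the climb
(observed for reciprocity-like effects, which first track the density
drift).

**Standard errors.** Per run, the Monte Carlo covariance of the
parameter-trace mean is estimated by multivariate batch means
(floor(sqrt(T)) batches over the averaging window) and added to the
inverse of the covariance of the simulated statistics (the Fisher
information); the standard error is the square root of the diagonal.
Statistics held fixed by the sampler (the arc count under IFD) carry no
information and get an infinite standard error. Estimates from
independent runs (sequential, separately seeded) are pooled by
inverse-variance weighting.

**Convergence.** A run converges when every divergence t-ratio
(mean/sd over the second half of the dz trace) is at most 0.3 in
magnitude, the parameter trace is finite and below 1e10, and the
simulated-statistic covariance is not numerically singular (reciprocal
condition number >= 1e-12). Failures are verdicts, not exceptions.
Low per-run convergence rates are expected and handled by pooling only
converged runs; this mirrors the reference validation protocol, where a
minority of runs per network converged.

### Sampler choice for estimation

With the basic sampler at N = 2000 the slowest-mixing statistic is the
arc count itself, and its relaxation time (millions of proposals)
exceeds desk-scale run lengths, so runs rarely pass the t-ratio test.
The IFD sampler removes that mode entirely; contrastive divergence then
initializes within a few percent of the generating values and most runs
converge. The bundled validation studies therefore estimate with the
IFD sampler; the density intercept (Arc) is not estimated there and is
reported as NaN. The basic sampler remains the default for
`EEConfig` and is exercised by the closed-form Bernoulli tests.

## Validation studies (synthetic data)

The generator draws networks from the two reference designs on N = 2000
nodes with the basic sampler:

* binary design: theta = (Arc -1.00, Reciprocity 4.25, AinS -2.00,
  AoutS -1.50, AT-T 0.60, A2P-TD -0.15, Interaction 2.00, Sender 1.50,
  Receiver 1.00), lambda = 2, with exactly 2.5% of nodes (50) True;
* categorical design: theta = (Arc -1.00, Reciprocity 4.25, AinS -2.00,
  AoutS -1.50, AT-T 1.00, A2P-TD -0.15, Matching 1.50,
  MatchingReciprocity 2.00), attribute uniform over three levels.

Type I designs zero one effect; when a categorical star/two-path effect
is zeroed the Arc parameter is lowered to -4.0 to keep the network
sparse. Generator chains run 4e7 burn-in proposals with 1e6-proposal
sample gaps, a desk-scale choice (the reference protocol used ~1e9 /
1e8). The burn-in length matters beyond mean degree: density
equilibrates within ~1e6 proposals, but attribute-level statistics such
as the matched-arc count relax over ~1e7, and networks sampled before
that point carry systematically shifted matching structure that
estimation then faithfully reports as parameter bias; 4e7 leaves a
margin (verified by the collapse of the Matching bias in the zero-truth
design from ~+0.05 to ~+0.003 when moving from 1e7 to 4e7). Consecutive
samples remain mildly correlated through the 1e6 gaps, which widens
(never shrinks) the spread of the simulated networks. Slowest of all
are the reciprocity-type statistics, whose estimates retain visible
upward bias at this scale; they are reported but not headline
quantities. Simulated mean degree and density land within a few percent
of the reference values.

`run_study` estimates every simulated network (8 runs pooled), excludes
networks with no converged run, and reports per effect: bias, RMSE,
coverage of the nominal 95% CI, and Type II (CI contains zero;
nonzero-truth effects) or Type I (CI excludes zero; zero-truth effect)
rates, each with a Wilson score interval. The studies run at 20
networks rather than 100, so rate estimates carry ~5-percentage-point
granularity; the Wilson intervals make that uncertainty explicit.

What the synthetic data does *not* emulate: real networks' unobserved
heterogeneity, degree hubs, missing data, or model misspecification
beyond the single zeroed effect. Passing studies demonstrate that the
estimator recovers parameters of data generated by its own model family
at this scale — a necessary, not sufficient, condition for empirical
adequacy.

## Numerical and design choices

* Eq-level ambiguity in the combined two-path statistic is resolved as
  `z_A2P-TD = z_A2P-T + z_A2P-D/2`, with `z_A2P-T` summed over ordered
  pairs i < j; all internal consistency checks use this one rule.
* Reciprocity-style statistics count each mutual dyad once (the common
  software convention); the corresponding change statistic is `x_ji`.
* The Isolates change statistic for adding (i, j) is
  `-[i isolated] - [j isolated]`.
* Batch count floor(sqrt(T)) in batch means; t-ratio uses the sample
  standard deviation over the second-half window.
* Significance stars use |estimate| > 1.96 * SE (two-sided p < 0.05).
* Node ids are dense and 0-based in memory; Pajek files are 1-based on
  disk. Self-loops are dropped and duplicate arcs deduplicated on read.
* Graph capacity for the compiled state is preallocated (the full dyad
  space for N <= 300, a sparse headroom above); exceeding it raises.
* Per-run and per-network seeds are spawned from the master seed via
  `numpy.random.SeedSequence`, so every result is reproducible from one
  integer.

## Known limitations

* The damping lambda is fixed, never estimated (no curved-ERGM support):
  the estimation algorithm requires a change statistic per parameter.
* Under IFD estimation the Arc parameter is not estimated; recovering it
  from the auxiliary parameter is possible in principle but the adapted
  `v` targets balanced acceptance, not the exact proposal-asymmetry
  correction, so no Arc estimate is reported.
* Single-process execution; independent runs are sequential.
* The hash-table two-path store assumes the two-path matrices are
  sparse; dense two-path structure (very high degrees) defeats it.
* Very large descriptive computations (geodesics, shared partners) are
  not provided; the triad census skips nothing but costs ~sum of squared
  degrees.
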