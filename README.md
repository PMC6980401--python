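# ergmee

Equilibrium-expectation estimation of exponential random graph models
(ERGMs) for large sparse **directed** networks.

ERGMs model a directed network `x` on `N` nodes as

    Pr(X = x) = (1/kappa) exp( sum_A theta_A z_A(x) )

where each statistic `z_A` counts a configuration — arcs, mutual dyads,
alternating in/out-stars, alternating transitive/cyclic triangles,
alternating two-paths, and node-attribute patterns (sender/receiver,
matching, homophily). Classical Monte Carlo maximum likelihood requires
repeated equilibrium simulation of the model and is impractical beyond a
few thousand nodes. The **Equilibrium Expectation (EE)** algorithm
instead starts the chain *at the observed network*, takes short
Metropolis-Hastings bursts, and nudges each parameter against the sign
of the divergence `dz_A = z_A(x_t) - z_A(x_obs)`:

    theta_A <- theta_A - sign(dz_A) * a * max(|theta_A|, theta_min)

until the divergences oscillate around zero; the parameters then
oscillate around the maximum-likelihood estimate. Everything runs on
change statistics — the O(local) difference a single arc toggle makes —
backed by incrementally maintained two-path hash tables, so cost per
proposal is proportional to the endpoints' degrees, not to N.

The package provides:

* `ergmee.graph` — sparse mutable digraph with incremental two-path
  count tables; typed node attributes with missing values;
* `ergmee.effects` — 23 directed ERGM effects, each with a reference
  full statistic and an O(local) change statistic;
* `ergmee.sampler` — basic dyad-toggle and improved fixed-density (IFD)
  Metropolis-Hastings samplers (numba-compiled kernels) and long-run
  simulation from a model;
* `ergmee.estimator` — contrastive-divergence initialization, the EE
  loop, and independent multi-run estimation;
* `ergmee.inference` — batch-means + Fisher-information standard errors,
  inverse-variance pooling across runs, t-ratio convergence verdicts;
* `ergmee.study` — a validation harness measuring bias, RMSE, coverage
  and Type I/II error rates with Wilson intervals on simulated data;
* `ergmee.netstats` / `ergmee.io` / a small `ergmee` CLI — descriptive
  statistics (triad census, reciprocity, components, clustering), hub
  filtering, Pajek/edge-list/attribute-table readers and writers, and a
  key=value configuration format.

## Worked example

Simulate a network from a known model, then recover the parameters:

```python
import numpy as np
from ergmee import ModelSpec, simulate, EEConfig, run_parallel, combine_runs

model = ModelSpec(["Arc", "Reciprocity"])
truth = np.array([-2.0, 1.5])
g = simulate(model, truth, n_nodes=60, burn_in=300_000, n_samples=1,
             seed=30)[0]
print(f"observed: {g.n_arcs} arcs, density {g.density():.3f}")

cfg = EEConfig(ee_steps=300, steps_per_update=400, cd_steps=400,
               cd_updates=250, n_runs=4, seed=31)
runs = run_parallel(g, model, None, cfg)
est = combine_runs([r for r in runs if r.converged])
for label, th, se in zip(model.labels, est.theta_hat, est.se):
    star = "*" if abs(th) > 1.96 * se else " "
    print(f"{label:12s} {th:7.3f} ({se:.3f}) {star}")
```

prints

```
observed: 566 arcs, density 0.160
Arc           -1.946 (0.032) *
Reciprocity    1.282 (0.073) *
```

Both estimates land close to the generating values (-2.0, 1.5) — within
a few standard errors on a single 60-node draw; both effects are
significant at p < 0.05 (starred). The Arc estimate is the density
intercept and Reciprocity the log-odds boost for an arc whose reverse
exists.

The same pipeline from the shell, via a configuration file naming the
network, the effect list (e.g. `Arc, Reciprocity, AinS(lambda=2),
Matching(attr=region)`) and the algorithm constants:

```sh
ergmee estimate run.cfg --out estimates.txt
ergmee stats network.net --max-degree 1000
ergmee study --design categorical --n-networks 20 --seed 1
```

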