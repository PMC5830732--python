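# hillgrn

Hill-kinetics ODE modelling and parameter estimation for gene regulatory
networks (GRNs).

A GRN is a signed directed graph over genes.  Each gene's product
concentration `x_i` follows

```
dx_i/dt = P_i * prod_{j in inhibitors(i)} Q_ij^R_ij / (x_j^R_ij + Q_ij^R_ij)
              * prod_{k in activators(i)} (1 + x_k^R_ik / (x_k^R_ik + Q_ik^R_ik))
          - S_i * x_i
```

with synthesis rates `P`, degradation rates `S`, per-edge thresholds `Q`
and cooperativity exponents `R` — `2*(M+N)` positive parameters for `N`
genes and `M` edges.

The estimator is a profiled (cascaded) spline-collocation method:

* **inner problem** — for fixed parameters, fit per-gene B-spline
  coefficients minimizing data misfit plus a quadrature-discretized
  penalty on the mismatch between the spline derivative and the ODE
  right-hand side (Gauss–Newton with an analytic Jacobian);
* **outer problem** — minimize the pure data misfit of the profiled fit
  over the parameters, on the **log scale** (`P = e^p`, …) so positivity
  needs no constrained solver; gradients come from the implicit-function
  (parameter-cascading) Jacobian, with finite differences as a fallback;
* **alternating loop** — the log-parameters split into the cooperativity
  exponents (one per edge) and everything else; the two blocks are
  estimated alternately until all parameters converge, which keeps each
  subproblem small when data are sparse.

The 9-gene / 43-edge *E. coli* SOS-response case study ships as an
executable fixture (`hillgrn.sos`), including the published parameter
estimates and the measured steady-state column used for validation; see
`docs/sos_edge_parameters.tsv` for the full edge ↔ (Q, R) cross-reference.

## Library quick start

```python
import numpy as np
from hillgrn import (GeneNetwork, ParameterSet, GPMConfig,
                     simulate, steady_state, alternate_estimate, TimeSeriesData)

net = GeneNetwork(("g1", "g2"), [(0, 1, +1), (1, 0, -1)])
truth = ParameterSet(P=[5, 4], S=[0.3, 0.25], Q=[6, 8], R=[2, 2])
traj = simulate(net, truth, np.array([1.0, 1.0]), (0, 60),
                grid=np.linspace(0, 60, 25))
data = TimeSeriesData(traj.times, traj.states, gene_names=net.gene_names)
result = alternate_estimate(net, data, config=GPMConfig(lam=150, n_knots=100))
print(result.params_hat.P, result.converged)
```

The SOS steady-state validation:

```python
from hillgrn import reproduce_table2
frame, sse = reproduce_table2()   # per-gene steady states + SSE vs measured
```

## Command line

```sh
hillgrn synth --genes 3 --edges 4 --seed 1 --out demo/      # synthetic bundle
hillgrn estimate demo/network.tsv demo/data.csv --out demo/fit/
hillgrn simulate demo/network.tsv demo/truth_params.json --x0 1,1,1 --out traj.csv
hillgrn steady-state --fixture sos                          # SOS validation table
hillgrn fixture --out sos_files/                            # dump the case study
```

File formats: networks are TSV edge lists (`regulator  target  +|-`, with
an optional `# genes:` ordering directive), time series are CSV with a
`time` column, parameters are JSON (`P/S/Q/R` or `log_*` dialects), and
run configuration is YAML (see `hillgrn.io.RunConfig`).

## Notes

* The bundled SOS fixture defaults to the parameter attribution under
  which the published parameter table and steady-state column are
  mutually consistent (the published equation listing orders three
  inhibitor blocks differently; `load_sos(attribution="literal")` gives
  the verbatim reading).  See the `hillgrn.sos` docstring.
* B-spline conventions: "order" is degree + 1; `n_knots` counts
  breakpoints including both endpoints, so the basis dimension is
  `n_knots + order - 2` with clamped uniform knots.
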