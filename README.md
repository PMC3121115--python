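# ssimod

Modeling and multistationarity analysis of single-substrate single-product
metabolic modules with inhibition (SSI modules).

An SSI module is a small reaction network in which every reaction converts
one substrate into one product, and at least one reaction is inhibited by
another metabolite. `ssimod`:

* represents such modules as typed reaction graphs, derives node roles
  (input / output / state) from edge directions, and validates the module
  definition clauses (nonempty state set, relevance, SS-ness, nonempty
  inhibition relation, input→output path coverage, state-graph
  connectivity);
* builds the Hill-kinetics ODE model `dC/dt = R(C;P)` with exact analytic
  Jacobian, using the mixed-inhibition rate law
  `v = V_max·C_A^n / (K·(1 + C_I/K_C) + C_A^n·(1 + C_I/K_U))`, `K = K_M^n`;
* decides absence of multiple equilibria by a **structural determinant-sign
  certificate**: `det J = det(S·G)` is expanded by Cauchy–Binet over
  reaction subsets and each subset determinant over permutations; every
  rate partial has a fixed strict sign on the positive orthant (+ for the
  substrate, − for an inhibitor), so a one-signed expansion proves the
  Jacobian is nonsingular for *all* positive states and parameters, ruling
  out multistationarity;
* when the certificate is inconclusive, searches for equilibria with a
  multistart damped-Newton solver, classifies their stability from the
  Jacobian spectrum, and locates singular-Jacobian witnesses by bisection;
* simulates time courses (stiff-capable, analytic Jacobian) and labels the
  attractor each trajectory settles on.

The built-in `fig4` fixture is a branched pathway with mutual inhibition
between its two branches. With the bundled parameter set it has exactly
three positive equilibria; the package reproduces their coordinates, the
Jacobian spectra, and the initial-condition sensitivity of the trajectories.

## CLI

```sh
ssimod fixture fig4 --out fig4.json      # write a built-in module file
ssimod validate fig4.json                # check the module clauses
ssimod certify fig4.json                 # determinant-sign certificate
ssimod equilibria fig4.json --seed 1     # CSV of positive equilibria
ssimod simulate fig4.json --init 0.2,0.728,2.519 --t-end 2000
ssimod graph fig4.json                   # Graphviz DOT export
```

Exit codes: 0 success, 1 validation failure, 2 configuration/schema/usage
error.

Module files are JSON (canonical) or YAML, validated against the strict
schema in `src/ssimod/io_cli/module.schema.json` (unknown keys are
rejected). A reaction block gives `k_m` by default; the saturation constant
can be supplied instead under the explicit key `k`.

## Library

```python
from ssimod import build_rate_model, determinant_sign_certificate, find_equilibria
from ssimod.io_cli import fixture

module, params = fixture("fig4")
print(determinant_sign_certificate(module).status)  # inconclusive_mixed_signs

model = build_rate_model(module, params)
for rec in find_equilibria(model, seed=1):          # sorted by C_2
    print(rec)  # coordinates, residual, stability label
```

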