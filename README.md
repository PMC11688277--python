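# eldersim

Simulation and optimization toolkit for smart elder-care service models. It
implements, as composable and testable components:

- **dynamics** — a scalar health index `H(t)` integrated under two ODE
  variants: a *linear-driver* model (`dH/dt = a1*S + a2*P + a3*E - b*C`,
  deliberately independent of `H`) and an *environment-suppressed resource*
  model (`dH/dt = a*R_h/(1 + k*E) - b*C`), the latter optionally closed-loop
  with the logistic allocation rule and the social-capital cost model.
  Includes equilibrium analysis and least-squares parameter recovery from
  observed trajectories.
- **allocation** — saturating utility `U(R) = a*R^theta / (1 + b*R^delta)`,
  a numerical diminishing-returns check, a numerically stable logistic
  feedback rule `R_h = lam * sigmoid(gamma*H)`, and budget-constrained utility
  maximization solved by bisection on the shared Lagrange multiplier (concave
  case) or a flagged multi-start local search (non-concave case).
- **economics** — social-capital behavior cost
  `C = C0*(1 - delta*Sc/(1 + eta*Rm))` with admissibility checks, weighted
  benefit/cost totals, cost-benefit ratios, and scenario ranking.
- **monitoring** — Gaussian-process imputation of short sensor gaps (fixed
  squared-exponential kernel; long gaps stay masked) and a rule-based
  emergency detector that flags windows with a simultaneous significant
  activity drop and heart-rate rise.
- **synthetic** — reproducible driver-signal generators (constant, sinusoid,
  mean-reverting), six scenario cohort contrasts (urban/rural, income,
  lifestyle, diet, social activity, pollution) with configurable directional
  priors and the published per-arm sample sizes (500/500, 500/500, 500/500,
  3x300, 3x400, 500/500), missingness injection, and bundled market-research
  tables with checksum-verified loaders.
- **cli / io** — a `eldersim` command-line front end with deterministic run
  manifests, plus CSV/JSON/YAML round-trip readers and writers.

A note on the allocation sign convention: the logistic rule as written grants
*more* resources at *higher* `H` when `gamma > 0`. The narrative behavior —
more support when health is poor — corresponds to `gamma < 0`, which is the
default in the shipped scenario configurations.

## Command line

```bash
eldersim simulate  --config cfg.yaml --out traj.csv
eldersim calibrate --traj traj.csv --drivers drv.csv --out params.json
eldersim allocate  --config problem.yaml --out alloc.csv
eldersim cbr       --config scenarios.yaml --out report.csv
eldersim impute    --in hr.csv --policy policy.yaml --out hr_filled.csv
eldersim detect    --activity act.csv --hr hr.csv --rule rule.yaml --out alerts.jsonl
eldersim genpop    --scenario urban_rural --seed 7 --out cohort/
eldersim report    --out gaps.csv
```

Every command validates its configuration (unknown keys are rejected, exit
code 2), writes its artifacts plus a `*.manifest.json` run manifest with
resolved config and input/output checksums, and exits 1 on computation
errors. Manifests contain no timestamps or absolute paths, so identical runs
produce byte-identical manifests.

Example `simulate` config:

```yaml
model: linear          # linear | env | closed_loop
params: {alpha1: 0.5, alpha2: 0.3, alpha3: 0.2, beta: 0.1}
drivers:
  S:     {process: sinusoid, mean: 1.0, amplitude: 0.5, period: 6.0}
  P:     {process: constant, value: 0.5}
  E_env: {process: mean_reverting, rate: 0.5, mean: 0.0, sd: 0.2}
  C_exo: {process: constant, value: 2.0}
grid: {start: 0.0, stop: 10.0, num: 101}
H0: 0.0
seed: 1
```

## Conventions

- `H` is a dimensionless standardized health index; a working range of about
  [-3, 3] is recommended but not enforced, and the linear-driver model can
  drift without bound (no clamping).
- Dense driver tables are linearly interpolated between grid points; no
  extrapolation outside the tabulated range.
- The health-benefit-from-trajectory helper (`mean(H) - H0`) is a repo
  convention, not part of the underlying model.
- All randomness flows from explicit seeds; one global seed is split into
  per-stream generators through a fixed stream-id registry, so adding a new
  generator never perturbs existing streams.
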