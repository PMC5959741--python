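# mcrelease

Monte Carlo simulation of drug release from a cylindrical matrix dosage
form, with pluggable micro-step time models, release-curve fitting, and
genetic-algorithm inference of the release mechanism from observed curves.

The simulation clock advances by a *Monte Carlo Micro-Step* (MCS) whose
functional form encodes the physics of release:

| mode | micro-step | typical release curve |
| --- | --- | --- |
| `diffusion` | `1/N(t)` | Weibull (stretched exponential) |
| `erosion` | `\|ln u\| / lambda` | linear |
| `hybrid` | `A(k)/(lambda1 * N^nu) + B(k) * \|ln u\| / lambda2` | mixed |

Two kernels are provided: the `shell` kernel (remove every molecule in the
unit-thickness leak shell, shrink the radius by one, repeat) and the `walk`
kernel (single-occupancy random walk on the integer lattice with escape at
the leak shell).

## Layout

- `mcrelease.lattice` — cylinder geometry, site classification
  (interior / leak / restricted), point sampling with optional minimum
  inter-distance thinning.
- `mcrelease.kernel` — MCS models, the two simulation kernels,
  `ReleaseCurve`, fractional-release conversion.
- `mcrelease.fitting` — Weibull / linear / Higuchi regressions with
  R-style diagnostics, replicate ensembles, synthetic-curve generator.
- `mcrelease.inference` — sum-of-squares objective against ensemble-mean
  curves and a seeded genetic algorithm recovering hybrid-MCS parameters;
  `stochastic_time_share` quantifies the noise-term share of simulated
  time (the mechanism-identification statistic).
- `mcrelease.io` / `mcrelease.cli` — CSV/YAML/JSON interchange, run
  manifests, and the `mcrelease` command.

## CLI

```sh
# one simulation from a YAML config
mcrelease simulate --config sim.yaml --out curve.csv --seed 7

# replicate ensemble + fitted-parameter distributions
mcrelease ensemble --config sim.yaml --n-runs 50 --model weibull \
    --seed 1 --out-params params.csv --out-summary summary.json

# fit a model to a curve (R-style coefficient table; optional JSON report)
mcrelease fit --model weibull --curve curve.csv --out report.json

# synthetic noisy curves for fitting experiments
mcrelease synth --model weibull --params a=1000,b=2,c=0.7 \
    --noise-sd 5 --seed 3 --out synth.csv

# genetic-algorithm inference of hybrid micro-step parameters
mcrelease infer --curve observed.csv --ga-config ga.yaml \
    --sim-config sim.yaml --out inference.json --best-curve best.csv
```

A simulation config YAML mirrors `SimulationConfig` one-to-one (unknown
keys are rejected):

```yaml
n0: 1745
R0: 32
H: 64
d: 3.0
sampler_mode: paper   # or volume_uniform
kernel: shell         # or walk
seed: 1
mcs:
  mode: diffusion     # or erosion / hybrid
```

Every CLI run writes a `<output>.manifest.json` provenance record (config
snapshot, seed, package version, timestamps) from which the outputs can be
regenerated bit-identically.

## Notes

- All randomness flows through `numpy.random.default_rng` seeds; identical
  configs (including seed) produce bit-identical outputs.
- The `paper` sampler draws the radius uniformly (density concentrated
  near the axis, matching the published generator); `volume_uniform` is
  the corrected volume-uniform sampler.
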