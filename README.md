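# mikana

ODE-regression inference of gene regulatory networks from steady-state
(siRNA knockdown) expression data, time-series expression data, or — the
point of the package — both at once.

## The problem

A gene regulatory network (GRN) is a directed, signed graph of
transcriptional influences: an edge *j → i* means the product of gene *j*
activates (+) or inhibits (−) the transcription of gene *i*.  Two kinds of
expression experiments carry information about this graph:

- **steady-state data** — expression of all genes measured after a
  single-gene perturbation (e.g. an siRNA knockdown) has settled to a new
  equilibrium, one experiment per targeted gene;
- **time-series data** — expression sampled at successive times after a
  broad stimulus (e.g. a cytokine) displaces the whole system from its
  reference state.

This package implements the MIKANA family of regression methods, which pose
per-gene ordinary-differential-equation models

    dx_i/dt = Σ_j w_ij f(x_j) − λ_i x_i,      f(x) = xⁿ / (Kⁿ + xⁿ),

with Hill basis functions *f* of candidate regulators, a structural basal
transcription term, and first-order degradation λ_i.  Each data regime maps
onto a linear regression with the same right-hand side:

- **ssMIKANA** — at steady state `0 = Σ_j w_ij f(x_j) − λ_i x_i` per
  knockdown equilibrium (the sample perturbing gene *i* itself is dropped,
  since the perturbation strength is unknown);
- **tsMIKANA** — `(x_i(t_{k+1}) − x_i(t_k)) / Δt = Σ_j w_ij f(x_j(t_k)) − λ_i x_i(t_k)`
  over consecutive time pairs within each replicate;
- **cMIKANA** — the row-wise stack of both, fitted simultaneously.

Which regulators enter each gene's model is decided by iterative
forward–backward subset selection under a description-length cost
(extended-BIC), and every selected Hill term becomes a directed, signed,
weighted edge.  The package also ships the simulation machinery used to
benchmark the three modes — a preferential-attachment generator of
scale-free signed networks, a saturating-kinetics expression simulator
(knockdowns, time courses, signal-proportional noise), edge-wise scoring
(sensitivity, FDR, directionality), and runners for the standard
simulation studies (noise sweep, matched-budget comparison, directionality
analysis).

## Worked example

```python
import mikana as mk

# ground truth: 10-gene scale-free network, average total degree 3
truth = mk.generate_scale_free(mk.TopologyConfig(n_genes=10, k_av=3, seed=42))

# kinetic simulator bound to that network
model = mk.sample_parameters(truth, seed=1)
mk.find_reference_state(model, seed=2)

# one siRNA knockdown per gene + a 10-point, 3-replicate time course, 5% noise
ss = mk.simulate_steady_state_dataset(model, list(range(10)), seed=3)
ts = mk.simulate_timeseries(model, n_timepoints=10, n_replicates=3, seed=4)
ss = mk.add_noise(ss, 0.05, seed=5)
ts = mk.add_noise(ts, 0.05, seed=6)

results = mk.MIKANA(steady_state=ss, time_series=ts, mode="combined").fit()
print(results.summary())
print(results.score(truth))
```

prints

```
MIKANA network inference results
================================================
mode:            combined
genes:           10
inferred edges:  5
Hill exponent:   2.0
half-saturation: median

gene             #regulators      lambda          cost
------------------------------------------------------
G000                       2       0.553     -109.8222
G001                       2      0.3246     -111.6426
G002                       0      0.4311     -114.1223
...
```

and scores `sensitivity = 0.333, FDR = 0.000` against the generating
network: at 5% measurement noise the selection recovers a third of the true
edges (the strongest ones — most simulated regulatory effects are small
relative to the noise) without a single false positive.  Every inferred
edge carries its regulator, target, interaction coefficient w_ij and sign;
`results.to_edge_frame()` returns them as a DataFrame and
`mikana.io.write_edges` / `write_sif` export them.

The command line mirrors the library:

```sh
mikana simulate-network --genes 100 --kav 3 --seed 1 --out truth.tsv
mikana simulate-data --network truth.tsv --noise 0.1 \
       --out-matrix expr.tsv --out-meta meta.tsv
mikana infer --mode combined --expr expr.tsv --meta meta.tsv --out edges.tsv
mikana evaluate --inferred edges.tsv --truth truth.tsv --out report.tsv
mikana experiment --design noise_sweep --scale desk --out sweep/
```

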