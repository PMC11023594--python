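# madmix

Mixture-model clustering of mixed categorical/numeric tables with
collapsed conjugate priors, fully Bayesian selection of the number of
clusters, and cluster-wise synthetic tabular data generation.

Clinical and epidemiological tables mix data types — lab values, diagnoses,
demographic categories — and often hide row structure: subpopulations from
different sites, genotypes or socioeconomic strata in which the outcome
variable behaves differently.  `madmix` is for analysts who want to (a)
find such latent row clusters without inventing a distance metric for
heterogeneous columns, (b) decide *how many* clusters the data actually
support, and (c) release a synthetic copy of a sensitive table that trains
downstream models nearly as well as the original.

## The model in brief

Rows belong to one of K clusters; within a cluster, columns are
independent, categorical columns follow a categorical distribution with a
Dirichlet prior and numeric columns a Gaussian with a normal-gamma prior.
Distribution parameters θ are integrated out analytically, so a clustering
is scored by its collapsed likelihood

    P(D | A, K) = ∏_j ∏_l ∫ P(d_j | θ_lj) P(θ_lj) dθ_lj ,

a product of closed-form Dirichlet-multinomial and Student-t marginals.
A hard-assignment EM loop moves each row to the cluster that maximizes its
leave-one-out posterior predictive, growing K incrementally by splitting
off the worst-fitting rows.  The number of clusters is chosen by the
evidence `ML_K = Σ_A P(D|A,K) P(A|K)`, estimated by thermodynamic
integration (TI) or by a tempered harmonic-mean estimator, HMβ, that
interpolates between the arithmetic-mean (β=0) and harmonic-mean (β=1)
estimators; β=0.5 is the default and tracks exact enumeration closely on
tables small enough to sum directly.  The generator, MMMSynth-style,
pre-clusters a table, fits per-cluster column distributions plus a noisy
linear output model, and samples synthetic clusters of the original sizes.

See `docs/methods.md` for the complete model, estimator derivations,
defaults and limitations.

## Worked example

Simulate a mixed table (5 numeric + 5 four-valued categorical columns,
300 rows) with three planted clusters, then recover both the cluster
number and the partition:

```python
from madmix import simulate, fit, adjusted_rand_index

spec = simulate.SynthSpec(n_rows=300, n_binary=0, n_clusters=3,
                          delta=4.0, seed=7)
table, truth = simulate.make_mixed(spec)

sel = fit(table, k_max=5, selection="hmbeta", seed=0)
for k, est in sel.evidences.items():
    print(f"K={k}: log ML = {est.log_ml:9.1f}  "
          f"(method {est.method}, mc error {est.mc_error:.2f})")
print("selected K:", sel.best_k)
ari = adjusted_rand_index(sel.assignments[sel.best_k], truth)
print(f"ARI vs planted labels: {ari:.3f}")
```

prints

```
K=1: log ML =   -5080.4  (method HMbeta, mc error 0.00)
K=2: log ML =   -4333.7  (method HMbeta, mc error 2.18)
K=3: log ML =   -3962.7  (method HMbeta, mc error 2.61)
K=4: log ML =   -3995.1  (method HMbeta, mc error 2.91)
K=5: log ML =   -4045.2  (method HMbeta, mc error 9.32)
selected K: 3
ARI vs planted labels: 1.000
```

The estimated log evidence rises steeply while real structure remains,
peaks at the planted K=3, and then falls as extra clusters cost more prior
mass than they gain in fit (the Bayesian Occam razor); the selected
partition matches the planted labels exactly (adjusted Rand index 1.0).

The same workflow is available from the shell:

```sh
madmix simulate --kind mixed --delta 4.0 --rows 300 --seed 7 --out-prefix bench
madmix select-k bench.csv --schema bench.schema.json --k-max 5 \
       --method hmbeta --labels-out pred.csv
madmix evaluate ari --pred pred.csv --truth bench.labels.csv
```

and `madmix synth --input real.csv --schema schema.json --output synth.csv`
generates a synthetic copy of a table whose schema declares an output
column (`madmix infer-schema` drafts a schema for review).

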