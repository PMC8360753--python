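# bnetreg — Bayesian gene selection with network-constrained regularization

`bnetreg` identifies disease-associated genes from expression data by
fitting a hierarchical Bayesian shrinkage regression whose prior is
shaped by a gene-interaction network.  It is aimed at analysts working
with microarray/RNA expression matrices (samples × genes), a response
per sample (continuous, e.g. log survival time, or a 0/1 disease label),
and a pathway database exported as an edge list.  Because the posterior
is explored by Gibbs sampling, every regression coefficient comes with a
credible interval, and the penalty strengths are estimated alongside the
coefficients — no cross-validation grid.

## The model

For standardized expression `X` (n × p) and response `y`,

```
y | X, β, σ²          ~  N(Xβ, σ² Iₙ)
β | σ², τ², r         ~  N_p(0, (σ²/r) Λ⁻¹),   Λ = diag(1/τ₁², …, 1/τ_p²) + L
τ_j² | λ²             ~  (λ²/2) exp(−λ² τ_j²/2)   (scale mixture, j = 1..p)
σ² ~ InvGamma(a, b),   r ~ Gamma(c, d),   λ² ~ Gamma(e, f)
```

where `L` is the normalized Laplacian of the gene network
(`L[u,u] = 1` for connected genes, `L[u,v] = −w(u,v)/√(d_u d_v)` for
edges).  Integrating out the latent scales τ² shows that the posterior
mode of β minimizes

```
‖y − Xβ‖² + rλ‖β‖₁ + r βᵀLβ ,
```

an ℓ1 penalty for sparsity plus a Laplacian quadratic form that pulls
the degree-scaled coefficients β_u/√d_u of interacting genes toward each
other.  With `L = 0` the model reduces to a Bayesian lasso; with `L = I`
to a Bayesian elastic net.  All full conditionals are conjugate
(Gaussian, inverse-gamma, generalized-inverse-Gaussian, gamma), so the
Gibbs sampler is exact.  Binary responses use probit data augmentation:
`y_i = 1` iff a latent `z_i = X_i β + ε_i` is positive, and `z` is
refreshed from truncated normals each sweep.

Genes are ranked by |posterior mean coefficient|, following the
convention of selecting the top k (default 50) genes.

## Worked example

```python
import numpy as np
from bnetreg import NetworkBayesRegressor, SimulationScenario, simulate

ds = simulate(SimulationScenario(seed=0))          # 10 star pathways × 5 genes,
est = NetworkBayesRegressor(network=ds.network,    # 3 pathways carry signal
                            random_state=0)
est.fit(ds.data.X, ds.data.y, feature_names=ds.data.gene_ids)

print(est.top_genes(5))
print(np.round(np.corrcoef(est.coef_, ds.true_beta)[0, 1], 3))
print(est.ranking_.table.head(3).to_string(index=False))
```

prints

```
['pw02_hub', 'pw00_hub', 'pw01_hub', 'pw02_s1', 'pw02_s3']
0.997
 gene_id  rank  post_mean  post_sd  ci_lower  ci_upper
pw02_hub     1   0.997443 0.054005  0.889702  1.103990
pw00_hub     2   0.966931 0.053126  0.863195  1.070285
pw01_hub     3   0.949737 0.052172  0.842520  1.047650
```

The three signal-carrying pathway hubs head the ranking, the posterior
means track the simulated truth (Pearson r = 0.997), and each
coefficient carries a 95% equal-tailed credible interval.  The
matching probit classifier is `NetworkBayesProbitClassifier` (same API,
plus `predict_proba`).

The same workflow is available from the shell:

```sh
bnetreg simulate --seed 0 --out sim/
bnetreg fit --expression sim/expression.tsv --response sim/response.txt \
            --network sim/network.tsv --out run/ --seed 0
bnetreg rank --chain-summary run/ranking.tsv --top-k 10
```

`fit` / `classify` write a ranking table, log-joint trace, selected-gene
list, metrics and a JSON manifest; identical seeds give byte-identical
outputs.

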