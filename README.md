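# gpsc — Gaussian Process Spatial Clustering

`gpsc` clusters *supervised spatial data*: observations
(sᵢ, xᵢ, yᵢ) of a planar location, a covariate vector, and a scalar
response, under the model

    yᵢ = Σⱼ 1(lᵢ = j) · fⱼ(xᵢ) + εᵢ

where each latent cluster j occupies a region of the spatial domain and
carries its own unknown response function fⱼ. Two locations belong to the
same cluster because they share a covariate–response relationship — not
because their coordinates or covariates look similar marginally, which is
precisely the regime where classical clustering (K-means, hierarchical,
DBSCAN, …) fails. The motivating application is grouping census tracts by
the relationship between socioeconomic/environmental indicators and a
health-related latent-class response.

Each fⱼ is approximated by Gaussian-process regression with the RBF kernel
K(x, x′) = σ²·exp(−‖x−x′‖²/(2b)) and a nugget τ², hyperparameters fitted by
bounded maximum marginal likelihood. The algorithm alternates per-cluster
GP fits with an error-minimizing reassignment

    l̂ᵢ = argminⱼ ( f̂ⱼ(xᵢ) − yᵢ )² + λ·‖sᵢ − Cⱼ‖

(Cⱼ the cluster's spatial center; λ ≥ 0 an optional contiguity penalty),
until the labels stabilize. Reliability from random starts comes from an
annealed-bounds schedule plus likelihood-ranked restarts; see
`docs/methods.md` for the full model, schedule, and design rationale.

The package also ships three synthetic study designs with known ground
truth (`linear_ball`, `nonlinear_ring`, `sun_moon`) and hand-implemented,
oracle-tested clustering agreement metrics (adjusted Rand index, adjusted
mutual information), so the whole method is testable end to end with no
external data.

## Worked example

```python
import numpy as np
from gpsc import (SimulationSpec, simulate_dataset, GPSCConfig, gpsc_fit,
                  adjusted_rand_index)

# 800 points: a central disc and the background, each with its own linear
# response function of the covariates; no marginal separation in s, x or y.
ds = simulate_dataset(SimulationSpec(design="linear_ball", n=800, seed=1))

state = gpsc_fit(ds, GPSCConfig(L=2, seed=8))
print("iterations:", state.iteration, "converged:", state.converged)
print("cluster sizes:", np.bincount(state.labels)[1:])
print("ARI vs truth:", round(adjusted_rand_index(state.labels, ds.true_labels), 3))
```

Output:

```
iterations: 9 converged: True
cluster sizes: [641 159]
ARI vs truth: 1.0
```

The recovered partition matches the generating one exactly (ARI = 1.0):
159 points fall in the disc (the disc covers π·0.25² ≈ 19.6% of the unit
square) and the other 641 in the background. K-means on the coordinates alone
scores ARI ≈ 0 on the same data — the clusters are invisible without the
response relationship.

The same workflow is available from the shell:

```sh
gpsc simulate --design linear_ball --n 800 --seed 1 --out data.csv
gpsc fit --input data.csv --L 2 --seed 8 --true-label true_label --out result.csv
gpsc score --pred result.csv --truth data.csv
```

`fit` writes the labeled data plus a JSON sidecar (config, iteration
history, per-cluster kernel parameters, ARI/AMI when truth is present).
Arbitrary CSVs are supported via `--spatial/--covariates/--response`
column mappings; rows with missing values are dropped, never imputed.

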