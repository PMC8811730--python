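# phenoclust

Unsupervised phenotype analysis of fermentation time series.

Anaerobes like *Clostridium pasteurianum* shift between strikingly
different metabolic states — solventogenic (butanol, ethanol,
1,3-propanediol) and acidogenic (acetate, butyrate, lactate, formate) —
within and across cultivations.  Sorting hundreds of noisy concentration
time courses into "which phenotype was the culture expressing here?" by
hand is slow and subjective.  `phenoclust` automates it:

1. **Rates** — each sampling point of each cultivation becomes a phenotype
   vector `a = (μ, r_2, …, r_m)'` of biomass-specific rates,
   `r_D = (1/c_1)·dc_D/dt` [mmol g⁻¹ h⁻¹], via shape-preserving PCHIP
   interpolation, centered differencing and an exponential fit for μ, with
   percentile trimming of low-biomass blow-ups.
2. **Clustering** — vectors are z-scored and clustered with k-means
   (squared-Euclidean or cosine distance, k-means++ seeding, spherical
   updates under cosine) or DBSCAN; k is screened with silhouette, Gap,
   Davies–Bouldin and Calinski–Harabasz.  Each cluster's *reference
   phenotype* ζ is the per-dimension median of its raw vectors.
3. **Analysis of the references** —
   conditionality `δ = log10[(n_CL,cond/n_CL)/(n_cond/n)]` screens tags
   and concentration ranges for over/under-representation; carbon recovery
   `R_C` (including theoretical CO₂ from pyruvate decarboxylation) and the
   substrate-level-phosphorylation balance
   `Σ s_ATP/D·ζ_D = (1/Y_BM/ATP)·μ + q_ATP^m` check each reference against
   stoichiometry; and non-negative least squares re-describes any
   phenotype or whole time course as percentages of the references.
4. **Synthetic data** — a forward simulator plants known archetypes in
   realistic multi-experiment batch campaigns so the entire chain is
   testable closed-loop, without any external download.

Intended users: bioprocess engineers and systems biologists with
multi-experiment cultivation panels (time, biomass, HPLC metabolite
concentrations) who want reference phenotypes for monitoring, comparison
or balancing.

## Worked example

```python
import phenoclust as pc

# 1. simulate a campaign of 20 batch fermentations with 5 planted phenotypes
experiments, truth = pc.generate_dataset(20, seed=7, noise_sigma=0.02)

# 2. concentration series -> biomass-specific rate vectors, trimmed at 3/97
vectors = pc.compute_all_rate_vectors(experiments)
kept, removed = pc.remove_outliers(vectors)
print(f"{len(vectors)} phenotype vectors, {len(kept)} kept after trimming")

# 3. z-score and cluster with cosine-distance k-means at k = 5
X = pc.vectors_to_matrix(kept)
Z = pc.zscore_apply(pc.zscore_fit(X), X)
model = pc.kmeans_cluster(Z, kept, k=5, metric="cd", replicates=20, seed=1)
for cl in range(1, model.k + 1):
    c = model.centroid(cl)
    top = max((d for d in c if d not in ("mu", "Glc", "Gly")), key=lambda d: c[d])
    print(f"cluster {cl}: mu = {c['mu']:.3f} 1/h, main product {top} "
          f"at {c[top]:.2f} mmol/g/h")
```

prints

```
151 phenotype vectors, 93 kept after trimming
cluster 1: mu = 0.221 1/h, main product AcAc at 3.66 mmol/g/h
cluster 2: mu = 0.018 1/h, main product PDO at 0.50 mmol/g/h
cluster 3: mu = 0.123 1/h, main product EtOH at 2.80 mmol/g/h
cluster 4: mu = 0.099 1/h, main product PDO at 5.97 mmol/g/h
cluster 5: mu = 0.173 1/h, main product BuOH at 5.10 mmol/g/h
```

— the five planted archetypes (fast acidogenic, near-dormant, glucose-fed
mixed-acid, 1,3-PDO/acetate, butanol solventogenic), each read off by its
growth rate and dominant product.  `pc.carbon_recovery(model.centroid(cl))`
and `pc.atp_rate(...)` then balance each reference;
`pc.fit_atp_regression([...])` estimates the ATP-specific biomass yield
and maintenance demand across references, and
`pc.decompose_timecourse(...)` tracks, for one experiment, how the culture
moves between references over time.

The same pipeline is available from the shell:

```
phenoclust simulate -n 20 --seed 7 --out synth/
phenoclust rates --samples synth/samples.csv --tags synth/tags.csv --out rates.csv
phenoclust cluster --rates rates.csv -k 5 --metric cd --seed 1 --out model/
phenoclust evaluate-k --rates rates.csv --criterion silhouette --metric cd --kmax 10 --out k.csv
phenoclust conditionality --model model/ --rates rates.csv --tags synth/tags.csv --tag BES --out delta.csv
phenoclust balance --model model/ --out balance.csv
phenoclust superpose --model model/ --rates rates.csv --experiment synth_004 --out proportions.csv
```

Every command writes its outputs as delimited text plus a YAML manifest
(parameters, seed, input digests) for bit-for-bit re-runs.  Real data
enter through the same `samples.csv`/`tags.csv` wide format (header
`experiment_id, time_h, biomass_gL, <abbrev>_mM, …`; see
`phenoclust.io.load_experiments`).

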