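# meadowmrr

Mark–release–recapture (MRR) analysis of a patchy butterfly metapopulation
under different meadow mowing regimes, with a synthetic MRR generator for
parameter-recovery experiments.

The package is aimed at movement ecologists working with individually
marked insects on a network of habitat patches. It takes capture records
(individual, date, sex, patch, GPS point) plus patch polygons (GeoJSON with
locality and mowing information) and produces the complete analysis chain a
study of this kind needs:

- **Movement classification.** Each pair of consecutive captures of an
  individual is a *dispersal* (the patch changed) or a *displacement*
  (within-patch move); distances are WGS84 geodesics between capture points.
  Per-patch **emigration probability** is the fraction of recaptured
  individuals, first captured in the patch, ever recaptured elsewhere.
- **Connectivity.** The standard neighbourhood index
  S_j = Σ_{k≠j, d_jk ≤ 3 km} exp(−α d_jk) · A_k^ξ with d in km, A in m²,
  ξ = 0.5 and α = 1 / mean dispersal distance (km).
- **Cormack–Jolly–Seber (CJS) estimation.** Maximum-likelihood daily
  apparent survival ϕ and capture probability p from the multinomial
  m-array likelihood, with unequal occasion intervals handled as ϕ^l.
  Candidate models {ϕ(.)p(.), ϕ(sex)p(.), ϕ(.)p(sex), ϕ(sex)p(sex)} are
  compared by AIC (with the "simpler model within 2 AIC units" rule).
- **Population size.** Occasion abundance N_i = n_i / p̂, recruitment
  B_i = N_{i+1} − ϕ^{l_i} N_i corrected for individuals that emerge and die
  within a multi-day gap (factor l(1−ϕ)/(1−ϕ^l)), and the seasonal total
  N_total = N_1 + Σ B*_i.
- **Mixed models.** In-repo GLM (IRLS) and GLMM (Laplace approximation over
  a scalar locality random intercept) for the binomial (emigration), gamma
  (distances), Poisson (population size) and Gaussian families, with
  z-scaled covariates, Wald tables, response-scale predictions and AIC
  selection.
- **Synthetic data.** An individual-based simulator (46 patches in 5
  localities, a six-week near-daily calendar, ~4000 marked individuals)
  whose defaults are the study conditions the analysis targets, with the
  full generating truth recorded for recovery tests.

## Worked example

Simulate a season at the default study conditions and run the full
analysis:

```python
from meadowmrr.pipeline import run_all

report = run_all({"simulate": {"seed": 1}, "out": "runs/demo"})
print(report.emigration_by_regime.round(3))
```

```
   regime  n_recaptured  n_emigrants  emigration_probability
     mown           224           46                   0.205
recovered           318           56                   0.176
   unmown          1038           87                   0.084
```

Mown meadows lose about a fifth of their recaptured residents to other
patches, unmown meadows less than a tenth — the emigration gradient the
generator encodes (0.22 / 0.16 / 0.09). The per-patch CJS fits average
ϕ̂ = 0.789 and p̂ = 0.318 (generating values 0.79 and 0.32), and the gamma
mixed model for dispersal distances,

```
                    term  estimate    se   stat  p_value
             (Intercept)     4.707 0.122 38.637    0.000
origin_regime[recovered]     0.589 0.146  4.035    0.000
   origin_regime[unmown]     0.784 0.136  5.775    0.000
                  sex[M]    -0.162 0.108 -1.501    0.135
                    area     0.041 0.055  0.750    0.454
```

puts the mown-origin mean at exp(4.707) ≈ 111 m with unmown origins
exp(0.784) ≈ 2.2× farther — matching the generating kernels (102 m vs
246 m). `runs/demo/` holds every table as CSV plus a Markdown summary; the
same analysis runs on real inputs via
`{"input": {"records": "records.csv", "patches": "patches.geojson"}}`.

The same workflow is available from the shell:

```bash
meadowmrr simulate --seed 1 --out data/
meadowmrr report --seed 1 --out runs/demo
meadowmrr recover --seed 1
```

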