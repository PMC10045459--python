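# Methods

This note documents the statistical models, the synthetic-data generator
and the numerical choices behind `meadowmrr`, in the spirit of the model
documentation that simulation and statistics packages ship alongside their
code. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study system and data model

The package models a season-long mark–release–recapture (MRR) campaign on
a specialist meadow butterfly occupying a network of discrete habitat
patches. Patches are polygons (WGS84) grouped into *localities* — the
geographic sampling blocks that also serve as the random-effect grouping
factor — and each carries a mowing *regime*:

- **unmown** — no cut, full nectar and host-plant resources;
- **recovered** — mown at least 15 days before the flight period starts,
  long enough for the vegetation to reflower;
- **mown** — cut within 15 days of (or during) the flight period.

The 15-day threshold is configurable (`threshold_days`). When both an
explicit regime label and a mowing date are present, the label wins and a
warning records the conflict. Capture sessions form an ordered calendar;
`l_i` denotes the number of days between occasions i and i+1 (1 on a daily
schedule, up to 3 after bad-weather gaps).

Records whose GPS point lies farther than a tolerance (default 25 m,
roughly consumer-GPS error) outside the declared patch are flagged by the
validator and excluded from patch-level summaries but retained for
distances; points are taken as authoritative for locations, polygons for
patch membership. The study this emulates released every butterfly at its
capture point, so the records define where animals were, while digitised
polygons define what counts as "the patch".

### Geodesy without a projection library

Point-to-point distances use Vincenty's inverse solution on the WGS84
ellipsoid (sub-millimetre agreement with Karney's algorithm at
study-system scales; the test suite pins four reference distances frozen
from an independent implementation). Areas and the simulator's coordinate
frame use a local tangent-plane projection — an equirectangular map scaled
by the meridional and prime-vertical radii of curvature at the reference
latitude. Within ~20 km of the origin this keeps distance and area
distortion well below 0.1%, comfortably inside the 0.5% accuracy the area
invariant demands. A UTM projection would do the same job; the local
tangent frame avoids any dependency beyond numpy and is exact enough at
this extent.

## Movement definitions

For each individual captured at least twice, every pair of consecutive
captures yields one movement event: a **dispersal** if the patch id
changed, otherwise a **displacement**. The event distance is the geodesic
between the two capture points (not between patch centroids); the origin
patch and regime are those of the earlier capture, and sex is the sex
recorded at first capture. **Emigration probability** of a patch is
`n_emigrants / n_recaptured`, where the denominator counts individuals
first captured in the patch and recaptured *anywhere* (stay-at-homes
included) and the numerator those ever recaptured elsewhere. An individual
that leaves and returns contributes two dispersal events but counts once
as an emigrant. A patch with no recaptured individuals has an undefined
(NaN) probability, not zero.

Whether distances should connect consecutive captures or the natal to the
final capture is a genuine design fork; consecutive pairs are the default
here because they are what capture coordinates directly measure.

## Connectivity

S_j = Σ_{k≠j, d_jk ≤ buffer} exp(−α d_jk) · A_k^ξ, with d_jk in km, A_k in
m², ξ = 0.5 and a 3-km buffer by default. α is the inverse of the mean
dispersal distance in km; when not supplied, the pipeline recomputes it
from the dataset's own observed dispersal events. Distances between
patches use polygon centroids by default; an edge-to-edge mode (minimum
boundary distance, 0 with a warning for touching patches) is available as
a sensitivity knob, since the index's literature uses both conventions.
The implementation is vectorized; tests compare it against a naive double
loop to 1e-10 and verify the exact 2^ξ response to doubling all areas.

## Cormack–Jolly–Seber estimation

Survival is parameterised as a **daily** apparent survival probability ϕ;
an interval of l days contributes ϕ^l, which makes unequally spaced
occasions commensurable and yields a single interpretable daily rate.
Capture probability p is per occasion. Both may differ between the sexes
(four candidate models); neither varies over time, which also avoids the
classic terminal-interval confounding of time-varying CJS models.

Fitting maximises the multinomial m-array likelihood: animals released at
occasion i are distributed over "first recaptured at j" cells with
probability ϕ^{Σl} (1−p)^{j−i−1} p and a never-seen-again remainder. An
independent per-history likelihood (with the χ "never seen after t"
recursion) is kept as a testing oracle; the two routes agree to 1e-8 on
random fixtures, as they must (they are algebraically identical).
Optimisation is quasi-Newton (BFGS) on the logit scale from five random
starts (seeded); standard errors come from the inverse numerical observed
information, delta-transformed to the probability scale. Convergence
accepts either the optimizer's own success flag or a relative gradient
below 1e-4·(1+|loglik|), since BFGS reports precision loss on large
samples long after the optimum is located to far better than a standard
error. With two occasions only the product ϕ^l p is identifiable; a grid
search over that product serves as the test oracle.

A patch qualifies for its own fit with ≥20 marked individuals and ≥5
recapture transitions (configurable); the threshold stands in for the
source study's unquantified "large enough sample".

## Abundance and seasonal population size

N_i = n_i / p̂ (per sex when the selected model separates p by sex, then
summed), with delta-method SEs. Raw recruitment B_i = N_{i+1} − ϕ^{l_i}
N_i is truncated at zero (recruitment is non-negative; truncation events
are logged). Because an individual can emerge *and* die inside a multi-day
gap without ever being capturable, raw recruitment undercounts. Under
uniform daily emergence within the interval and daily survival ϕ, the
expected fraction of an interval's recruits still alive at its end is
(1 − ϕ^l) / (l (1 − ϕ)), so the correction

B*_i = B_i · l_i (1 − ϕ) / (1 − ϕ^{l_i})

restores the total. The factor is 1 at l = 1 and in the ϕ→1 limit, always
≥1, decreasing in ϕ and increasing in l. The literature this follows cites
a correction of this kind without printing a formula; the uniform-emergence
derivation above is adopted as the default and the correction is a
pluggable function, so an alternative can be swapped in without touching
the rest of the chain. The seasonal total is N_total = N_1 + Σ B*_i.

**Small-sample caveat.** Truncating negative B_i rectifies sampling noise
upward, so N_total overestimates when per-occasion abundances are noisy:
simulations show ~+17% mean bias at ~400 recruits/season, +4% at ~1000 and
<1% at 3000 (the regime where the <5% recovery invariant is tested).
Patch-level totals of a few hundred animals therefore carry a known
upward bias; regime comparisons, which share it, are affected far less.

## GLM and GLMM machinery

The mixed-model layer is written in-repo so that every link, likelihood
and approximation is inspectable and testable; an established GLM
implementation serves as a cross-check oracle in the tests, never as the
fitting route.

Families: binomial (logit), Poisson (log), gamma (log link, mean/shape
parameterisation) and Gaussian (identity). GLMs are fitted by IRLS
(relative log-likelihood change < 1e-9 or 200 iterations; the likelihood
trace is monotone on every fixture). The gamma shape is profiled by
maximum likelihood (Brent solve of the digamma score). Wald tables use z
statistics for binomial/Poisson and t with residual degrees of freedom for
gamma/Gaussian. AIC counts fixed effects plus variance/dispersion
parameters.

The GLMM integrates a single scalar random intercept per group out of the
likelihood by a Laplace approximation: for each group the joint mode b̂_g
is found by damped Newton steps, and the marginal contribution is
ℓ_g(b̂) − b̂²/(2σ²) − ½ log(σ² W_g + 1) with W_g the curvature at the mode.
The outer optimisation (L-BFGS-B) runs over fixed effects, σ ≥ 0 and any
log-dispersion; at σ = 0 the expression reduces *exactly* to the GLM
likelihood, so the boundary case is clean (returned with a `boundary`
flag, fixed effects re-polished at σ = 0). An adaptive Gauss–Hermite
route (nodes recentred at b̂_g and rescaled by the mode curvature, 25
nodes) validates the Laplace log-likelihood to |Δ| < 0.05 on five-group
problems; in-session checks against an independent mixed-model
implementation agreed to four decimals on coefficients, σ and
log-likelihood.

Model formulas are explicit term lists (`"a"`, `"a:b:c"`), so
non-hierarchical specifications — such as a three-way interaction without
all two-way margins, which the emigration analysis uses — are
representable verbatim. Continuous covariates are z-scaled before fitting
and the scaling record rides along with the fit, so `predict_response`
accepts new data on the original scale; predictions are at random effect
zero with delta-method SEs. Model selection takes the lowest AIC unless a
simpler model (fewer parameters) lies within 2 AIC units, in which case
the simplest such model wins; exact ties break by parameter count, then
label order. The Poisson population-size response is the per-patch N_total
rounded to the nearest integer.

## The synthetic-data generator

`SimConfig` defaults *are* the study conditions; they are not tuned per
experiment. Defaults: 46 patches in 5 localities; log-uniform patch areas
on [800 m², 10 ha] (median ≈ 0.9 ha); regime composition 45% unmown / 30%
recovered / 25% mown, assigned as fixed counts (a mowing mosaic is a fixed
landscape design, not an iid draw); a 41-day season starting 19 July with
~15% of days skipped but never more than a 3-day gap; daily survival
ϕ = 0.79; capture probability p = 0.32; lifetime emigration probabilities
0.22 / 0.16 / 0.09 (mown / recovered / unmown); dispersal-step means
102 / 198 / 246 m by origin regime; displacement-step means 57 m (F) /
43 m (M); gamma steps with shape 2 (positive, right-skewed, and consistent
with the gamma GLMM the analysis fits); even sex ratio; expected recruits
per patch 150 / 75 / 70 (unmown / recovered / mown), which yields roughly
4000 marked individuals per season, unmown populations about twice the
size of managed ones, and local totals inside the low-hundreds range
typical of such systems. `total_recruits` rescales the per-patch
expectations when an experiment needs a specific sample size.

The simulation is daily and individual-based. Emergence days follow a
triangular curve peaking at 40% of the season. Each individual survives
each day with probability ϕ (geometric lifespan, mean 1/(1−ϕ) ≈ 4.8 days).
Each day it may emigrate with a regime-specific hazard; the destination is
a neighbouring patch within 3 km drawn with weight exp(−α d) · A^ξ — the
same kernel the connectivity index assumes — with α = 1/mean dispersal
distance. On capture occasions every living individual is recorded with
probability p.

**Hazard calibration.** The lifetime emigration targets are converted to
per-day hazards exactly: with L ~ Geometric(1−ϕ) days of life and constant
daily hazard h, the lifetime emigration probability is
1 − (1−h)(1−ϕ)/(1 − ϕ(1−h)), and solving for h at target P gives
1 − h = (1 − P)/(1 − ϕP). (The simpler plug-in 1−(1−P)^{(1−ϕ)} that uses
the mean lifespan is Jensen-biased — it realises ≈0.203 instead of 0.22 —
so the closed-form inversion is used.)

**Movement realisation.** Movement steps are realised at capture and
emigration events rather than as independent daily jitter: between two
consecutive captures in the same patch the new point sits a
gamma-distributed step (sex-specific mean) from the old one, in a uniform
direction that keeps the point inside the patch (resampled up to 40 times,
then relocated uniformly — relevant only when the drawn step exceeds the
patch); after a patch change the point sits a gamma step with the *origin
regime's* mean from the previous capture point, headed toward the
destination centroid with angular noise. This makes the recorded
between-capture distances genuine draws from the configured kernels — the
quantity the gamma GLMMs estimate — at the cost of not modelling
within-day micro-movement. Post-dispersal points may fall outside the
destination polygon (the declared patch id is authoritative), emulating
GPS/digitisation mismatch in real data.

**What passing recovery tests does and does not show.** The generator
matches the analysis' structural assumptions (constant ϕ and p,
gamma-distributed distances, regime-constant emigration hazards, no
transience or trap response, closed localities). Recovery therefore
demonstrates the estimation chain is correct and internally consistent —
not that those assumptions hold in any field system. Known divergences
from real data: no behavioural heterogeneity in capture probability, no
weather-driven daily variation, rectangular patches, and emigration
observed only between first and last capture — the last means observed
emigration proportions run a few percent below the lifetime targets
(exposure after the last capture is invisible), a conditioning property
shared by the field estimator itself.

## Sizes used by the recovery experiments

The acceptance experiments use 20 replicates of 500 recruits × 30 daily
occasions for the CJS means; one season-scale simulation per regime, sized
so that at least 600 recaptured individuals originate from that regime
(≈3000–16000 recruits depending on the regime's share); and 500 dispersal
events per regime / 1000 displacement events per sex for the distance
models. These sizes put Monte-Carlo error comfortably inside the stated
tolerances (±0.03 for ϕ and p, ±3 binomial SEs for emigration, ±10% for
distance means) while a full run stays in the low tens of seconds.

## Known limitations

- Apparent survival confounds death and permanent emigration off the
  mapped network; ϕ is a lower bound on true survival.
- The N_total truncation bias at small samples (above).
- The Laplace approximation can understate random-intercept variance with
  very few groups (five localities is near the practical minimum); the AGQ
  route exists precisely to check this on a given fit.
- Edge-mode connectivity treats touching polygons as distance 0.
- The emigration estimator is conditional on recapture; its small
  downward bias relative to lifetime probabilities is inherent to MRR
  observation, not to the implementation.
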