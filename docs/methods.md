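# Methods

This note documents the models and numerical conventions behind `nsikit`,
the choices that were genuinely open, and what the test suite does and does
not demonstrate.

## Data model

The pipeline consumes two tables. The **town table** carries five
climate/terrain factors per town: annual accumulated temperature (°C·day,
the yearly sum of daily mean temperatures above 0 °C), annual precipitation
(mm), relative humidity (%), mean annual temperature (°C) and mean altitude
(m). The **plot table** (long format) carries one row per (plot, census
year) with the observed seral stage and four per-plot eligibility flags:
started as grassland, early grazing/cutting disturbance later disappeared,
no significant natural disaster, under patrol protection. The default
census grid is 1987–2017 at 5-year intervals; any evenly spaced grid is
accepted. The stage vocabulary is closed — grassland, shrub, forest — and
unknown codes are parse errors rather than silent drops; the pre-forest
bare-ground phase never occurs in series that begin on grassland and is not
modeled. Nested sub-plot geometry of the monitoring design (28.28 m forest
square, 4 m shrub squares, 1 m herb squares) is metadata only and plays no
computational role.

## Climate zonation

Towns are regionalized in two stages: a primary split on accumulated
temperature alone (the dominant control on vegetation growth once rainfall
is adequate), then a within-region split on the remaining four factors.
The clustering algorithm is agglomerative hierarchical clustering with Ward
linkage on Euclidean distance, factors z-scored within region — the
standard recipe for environmental zonation; the linkage is configurable.
Cluster counts are fixed by configuration (defaults 4 primary regions and
2/3/4/4 sub-areas for C/M/W/H); no automatic model selection is attempted
because none is defined for this design.

Two conventions make the output deterministic. Regions are labeled C, M,
W, H in ascending order of cluster-mean accumulated temperature. Sub-area
numerals are assigned by descending cluster size, ties broken by ascending
mean precipitation, then ascending minimum town id. Input row order never
affects the result (rows are canonically sorted before linkage). These
labels are *our* convention: published sub-area labelings cannot be
reconstructed from cluster output in general, so cross-study comparisons
should be done on partitions, not labels.

**Threshold mode** assigns regions from the fixed published
accumulated-temperature intervals (C 1489–3215, M 3280–4344, W 4348–6281,
H 6302–8287 °C·day). It provides a bit-exact, clustering-free regression
surface; values falling in a gap between intervals snap to the nearest
interval with a logged warning.

## Outcome classification and durations

An eligible plot's succession outcome is determined solely by its final
census: grassland → non-succession, shrub → hard succession, forest →
accessible succession. The chain is one-directional, so a series that
regresses (e.g. shrub back to grassland) is rejected by default; a lenient
mode (`on_nonmonotone="final"`) warns and uses the final stage, which is
sufficient for outcome tallies.

Transition times are interval-censored by the census grid: a transition is
known only to lie in (last year observed in the old stage, first year
observed in the new stage]. The point estimator is configurable:

* `midpoint` (default) — bracket midpoint; unbiased when the transition
  time is uniform within the 5-year interval, and never pretends to
  sub-interval knowledge (the bracket is always reported alongside);
* `first_observation` / `last_previous` — upper/lower bracket endpoints,
  giving conservative bounds in either direction.

Durations whose end was never observed are right-censored (upper bound
+inf) and excluded from sub-area means; no survival-likelihood machinery
(e.g. Turnbull estimation) is applied, as stratum means of uncensored
points are what the downstream trend comparison uses. A plot observed to
jump grassland → forest between censuses passed through shrub latently; its
shrub residence gets a zero point estimate with a bracket reflecting the
full uncertainty. Per sub-area the pipeline reports mean time-to-forest,
mean forest tenure (years in forest by the final census) and log10 of the
mean tenure — the log of the mean, not the mean of logs, matching how the
index-versus-time trend is displayed on a log axis. The association between
sub-area NSI and log forest tenure is summarized by Spearman rank
correlation with the sub-area as the unit, because the claim of interest is
an ordering, not a linear fit.

## The index

Habitat quality is the exact reciprocal of landscape resistance. Default
resistances 30 (grassland), 5 (shrub), 1 (forest) come from the
circuit-theory resistance literature and are configuration, so alternative
resistance sets can be supplied. Exactness matters: using the 4-decimal
display value 0.0333 instead of 1/30 changes the fourth decimal of real
strata (e.g. a 15-plot stratum with counts 4/2/9 gives 0.6356 exactly but
0.6355 with the rounded weight). The index of a stratum is the
quality-weighted mean `P = (Σ Q·n)/N`, computed in double precision;
rounding is applied only at display, 4 decimals, round-half-up (decimal,
not banker's). Percentages are `100·n/N` at 2 decimals half-up. `P` is
undefined for an empty stratum and raises rather than returning 0 (0 is
below the attainable minimum `1/30`).

Key identities, enforced as property tests: bounds `1/30 ≤ P ≤ 1`;
strict increase under promotion of any sample to a later stage; pooling
`P(pooled) = Σ N_i P_i / Σ N_i` over disjoint strata; invariance under
scaling all counts. Region rows in the bundled regression fixture are kept
verbatim as printed in the source tables even where they are not the sums
of their sub-area rows; the pooling identity is asserted only on
self-consistent data.

## Budget reallocation

With `K` the unweighted arithmetic mean of exact sub-area indices (the
plain reading of "mean across all sub-areas" — no sample-size weighting),
each baseline budget is adjusted to `I = In·(1 + (K − Px)/K)`. Sub-areas
with `Px > K` are surplus (funding reduced), `Px < K` deficit (funding
increased). Since `Σ(K − Px) = 0`, equal baselines conserve the total
budget exactly (asserted to 1e-9 relative). A sub-area with `Px > 2K`
receives a negative allocation; the plan reports it with a warning instead
of clamping, because clamping would silently break the conservation
identity users check first. A switch allows computing `K` from 4-dp
rounded indices to mimic hand calculation from a published table.

## Synthetic data generator

The generator emulates the study conditions, not an arbitrary benchmark:

* **Towns** draw their five factors uniformly within each sub-area's
  published factor box. Uniform (not normal) sampling guarantees the
  generated towns respect the printed ranges exactly, and since the
  accumulated-temperature boxes are disjoint across regions, threshold-mode
  zonation recovers every generating region — a closed-loop test.
* **Plots** follow a latent annual two-step absorbing chain: each year
  grassland → shrub with probability `p₁` and shrub → forest with `p₂`,
  recorded only at the 5-yearly censuses. Waiting times are drawn as
  geometric variates, which is exactly the annual-Bernoulli chain. This
  reproduces the interval-censoring structure the duration estimators must
  handle. The closed-form outcome distribution after `T` years
  (`P(grassland) = (1−p₁)^T`, `P(shrub) = Σ_k p₁(1−p₁)^{k−1}(1−p₂)^{T−k}`)
  is implemented independently and checked against both a matrix-power
  oracle and Monte-Carlo fractions (3 standard errors at n = 10,000).

No per-year transition rates are published for the real system, so each
scenario's rates are free parameters set through a favorability θ ∈ (0,1):
`p₁ = 0.02 + 0.23·θ`, `p₂ = 0.02 + 0.18·θ`, chosen once so the default θ
grid spans mostly-grassland (θ ≈ 0.07: about half the plots never leave
grassland in 30 years) to mostly-forest (θ ≈ 0.93) outcomes. The 13
default scenarios assign θ = rank/14 with ranks matching the published
index ordering, 500 plots per sub-area and 5 towns per sub-area. Parameter
recovery is asserted statistically: over 20 seeds, Spearman correlation
between recovered sub-area indices and θ is ≥ 0.9 in at least 95 % of
seeds. Individual adjacent ranks can still swap in one realization — at
high θ the expected index saturates near 1 and ordering among the top
scenarios is noise-dominated — which is the same saturation a real
monitoring panel would show.

What the generator does *not* emulate: spatial autocorrelation of climate
within a sub-area, observation error in stage calls, plot attrition, and
ineligible plots (all flags are generated true). Passing closed-loop tests
therefore demonstrates correctness of the pipeline's arithmetic and
plumbing under the stated stochastic model, not robustness to messy field
data.

## Reproducibility and problem sizes

A single integer seed drives every random draw through split seed
sequences (towns and plots get independent streams, scenarios independent
substreams), so any run is bit-reproducible; pipeline runs write a JSON
manifest with the configuration snapshot, SHA-256 input digests, seed,
per-stage timings and output list, and deterministic stages are
byte-identical across reruns. The default test suite runs in seconds: the
published-table checks are desk-scale arithmetic, and the stochastic
acceptance checks use 13 × 500 plots × 20 seeds plus one 10,000-plot
scenario, sizes at which the binomial standard errors are already far
smaller than the effects being asserted.

## Known limitations

* Sub-grid duration claims (e.g. "about 3 years" for a stage) cannot be
  produced from 5-yearly censuses; the package only ever reports brackets
  and bracket-based point estimates.
* Cluster-mode sub-area labels are a package convention and not comparable
  across implementations; use threshold mode or partition comparisons for
  regression surfaces.
* The index treats stage counts as exchangeable within a stratum — no
  within-stratum covariates, no uncertainty interval on `P` (none is
  defined for the published method).
* Reallocation is a single-period rule; it does not model multi-year
  dynamics or cost-effectiveness.
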