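# icepulse

Analysis pipeline for a question in polar movement ecology: how does the
annual sea-ice break-out, and the near-surface phytoplankton bloom it
releases, reshape the vertical foraging behaviour of an air-breathing top
predator?  The package implements the full analysis chain for Weddell seal
(*Leptonychotes weddellii*) biologging data from an Antarctic fast-ice
system — dive-record signal processing, prey-capture detection from jaw
accelerometry, sea-ice break-out phenology and advection timing, seasonal
dive-depth phenology statistics, and a Bayesian stable-isotope diet mixing
model — together with a ground-truthed synthetic-data generator, so that
every stage is testable end to end without access to tag or satellite data.

It is written for ecologists who want to run, audit or extend this style of
analysis: the library is the primary interface, `examples/` holds one short
narrative script per capability, and a thin `icepulse` command line drives
the same stages on file inputs.

## The analyses

**Dive processing.** A time-depth record (6 s sampling, 0.5 m resolution) is
zero-offset corrected, segmented into dives (excursions beyond 2 m reaching
≥ 10 m for ≥ 30 s), and summarized per dive: maximum depth, duration, the
*bottom phase* (first to last sample at ≥ 80 % of maximum depth), and the
number of *wiggles* — vertical reversals toward the surface within the
bottom phase with ≥ 1 m limbs, a feeding proxy.  Dives are classified
benthic (flat-bottomed, at the seal's rolling 7-day depth ceiling) or
pelagic; benthic dives are excluded from the seasonal analyses.  Per
seal-day summaries carry mean maximum depth, the wiggle rate (wiggles per
minute of bottom time) and diving efficiency (bottom share of dive time).

**Prey captures.** The surge axis of a 20 Hz jaw accelerometer is zero-phase
high-pass filtered (1 Hz) and thresholded at 0.3 g; super-threshold
excursions closer than 1 s merge into one capture attempt, timed at peak.

**Ice phenology and advection.** Break-out at a grid cell is the first date
whose trailing 7-day mean ice concentration drops below 50 % cover.  Travel
times of advected phytoplankton from five source areas around Ross Island to
the Erebus Bay study site (77.6° S 167.0° E) are along-coast great-circle
path distances divided by published current velocities (6.5, 10.3,
12 km d⁻¹), rounded to whole days; the *resource pulse* is the 35-day bloom
window opening on the arrival date.

**Phenology statistics.** Seal-day depth is modelled by a generalized
additive mixed model — a penalized cubic spline over time with a Gaussian
random intercept per seal, estimated by marginal ML (the spline is the
classical mixed-model representation, with the smoothing parameter a
variance ratio).  The *shallowing period* is the longest span of the fitted
curve at or below 140 m.  The same smooth refitted with time measured as
days-since-arrival gives ΔAIC = AIC(calendar) − AIC(arrival); positive
values mean foraging depth tracks the resource pulse better than the
calendar.  OLS utilities cover the cross-year shallowest-point regression,
the wiggle-rate-on-depth regression and period contrasts of feeding rate
and efficiency.

**Diet mixing.** Consumer isotope values x (δ¹³C, δ¹⁵N per seal) mix source
groups s with proportions p:

    x_k ~ Normal( Σ_s p_s (μ_sk + λ_sk),  Σ_s p_s² (ω_sk² + τ_sk²) + σ_k² )

with source means/SDs μ, ω, trophic enrichment factors λ, τ, a Dirichlet(1)
prior on p and half-normal σ.  The posterior is sampled by an ensemble MCMC
on a log-ratio transform of the simplex, with split-chain R-hat < 1.05 as
the convergence contract.  The shipped prey-source table is **synthetic**
(clearly labelled), not published prey data.

## A worked example

```bash
python examples/01_advection_timing.py
```

prints

```
source       direct km coastal km  days @6.5 @10.3 @12
Northeast         64.7      161.0        25   16  13
North             51.7      135.8        21   13  11
Northwest         59.8       85.1        13    8   7
West              41.9       59.9         9    6   5
Southwest         34.6       34.6         5    3   3
```

i.e. the closest source (Southwest, 34.6 km along-coast) delivers the bloom
in 5 days at the slow current and 3 days at the intermediate and fast
currents, while the farthest (Northeast, 161 km) takes 25/16/13 days — the
full span of possible lags between a local break-out and the resource pulse
at the colony.  `examples/05_seasonal_phenology.py` runs the depth-phenology
stack on the default synthetic scenario and prints the planted vs fitted
shallowing period, the wiggle-depth regression and the covariate ΔAIC;
`examples/06_diet_mixing.py` prints posterior diet proportions with 95 %
credible intervals.

The full pipeline on synthetic inputs:

```bash
icepulse run --config config.yaml --seed 11 --out run/
```

where `config.yaml` can be as small as

```yaml
simulate:
  scenario: {n_seals: 2, days: 12}
```

Outputs are plain CSV/JSON plus a manifest with content hashes; identical
config and seed reproduce byte-identical files.

## Layout

- `src/icepulse/` — the library (`synthetic`, `dive_processing`,
  `prey_capture`, `ice_phenology`, `phenology_stats`, `isotope_mixing`,
  `pipeline`, `params`, `cli`)
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, assumptions, parameter choices, limitations
- `tests/` — pytest suite with independent brute-force oracles
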