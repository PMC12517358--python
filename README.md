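# crowdprofile

Visual crowding is the breakdown of peripheral object recognition caused by
nearby clutter: a Landolt-C whose gap orientation is easy to report in
isolation becomes hard to report when two flanking Landolt-Cs sit close to it.
`crowdprofile` is a Python package for quantifying **the spatial profile of
crowding** from continuous orientation-report experiments: how the mix of
target- and flanker-driven responses changes as target-flanker spacing grows,
at different target eccentricities and levels of target-flanker similarity
(relative orientation difference Δ).

It is aimed at visual psychophysicists who collect trial-level continuous
report data (or want to simulate such experiments) and want a tested,
reproducible implementation of the two-stage model-fitting analysis.

## The model

**Stage 1 — pooling model.** Signed report errors θ (re-signed so that
errors toward the flanker orientation are positive) are tallied into 72
five-degree bins and fitted, by minimising the sum of squared errors between
observed and model bin probabilities, with a mixture of a uniform lapse
component and two von Mises components:

    P(θ) = wR·f(θ | 0, 0) + (1 − wR)·[ wT·f(θ | θT, kT) + (1 − wT)·f(θ | Δ, kF) ]

with weights wR (random responses) and wT; a target-centered component with
free mean θT ∈ [−10°, 10°] and concentration kT; and a flanker-centered
component fixed at the orientation difference Δ with concentration kF. Both
concentrations are bounded between 8 and the concentration fitted to the same
observer's unflanked (target-alone) data. The fitted wT is **p(Target)**, the
proportion of non-random responses centered on the target.

**Stage 2 — spatial profile.** For each (eccentricity E, Δ), p(Target) as a
function of spacing S is fitted with a logistic,

    p(S) = 1 / (1 + exp(−(S − L)/G)),      0 < L ≤ E,  G > 0,

weighted by 1/SSE of each point's pooling fit. The **midpoint L** is the
spacing where responses balance between target- and flanker-centered; the
**span** of the transition zone is the spacing difference between
p = 0.4 and p = 0.6, equal to 2·G·ln 1.5. Both are also reported in Bouma
units (divided by E), and each profile carries an unweighted
R² = 1 − SSE/SST.

A synthetic observer with exactly this generative structure (uniform lapse +
spacing-dependent target/flanker mixture, midpoint at 0.33·E by default)
simulates the full study design — 3 eccentricities (4.24°, 12.72°, 21.2°),
Δ ∈ {22.5°, 45°, 90°, 180°}, five tangential spacings from "just touching"
outward plus an unflanked condition, 80–150 trials per condition — so every
stage of the analysis can be validated by parameter recovery.

## Worked example

```python
import crowdprofile as cp

result = cp.run_pipeline(cp.RunConfig(seed=7))
cols = ["eccentricity_deg", "orientation_diff_deg", "location_deg",
        "span_deg", "midpoint_bouma", "span_bouma", "r_squared"]
print(result.profile_fits[cols].round(3).to_string(index=False))
```

```
 eccentricity_deg  orientation_diff_deg  location_deg  span_deg  midpoint_bouma  span_bouma  r_squared
             4.24                  22.5         0.000     3.495           0.000       0.824      0.007
             4.24                  45.0         1.277     2.719           0.301       0.641      0.621
             4.24                  90.0         1.670     1.138           0.394       0.268      0.976
             4.24                 180.0         1.424     0.604           0.336       0.142      0.929
            12.72                  22.5         0.000     5.199           0.000       0.409     -1.362
            12.72                  45.0         4.325     5.726           0.340       0.450      0.972
            12.72                  90.0         4.340     2.994           0.341       0.235      0.964
            12.72                 180.0         4.058     2.251           0.319       0.177      0.999
            21.20                  22.5         4.308     9.803           0.203       0.462      0.851
            21.20                  45.0         5.395     7.711           0.254       0.364      0.979
            21.20                  90.0         6.632     4.511           0.313       0.213      0.996
            21.20                 180.0         7.362     2.512           0.347       0.118      0.973
```

Reading the table: fitted midpoints sit near a third of the eccentricity
(`midpoint_bouma` ≈ 0.3, the Bouma-law regularity the simulator generates),
while the span shrinks as the orientation difference grows — dissimilar
flankers produce a steeper, more step-like transition out of crowding. The
shallow Δ = 22.5° profiles are the hardest to pin down with five spacings:
at 12.72° this run yields a negative R², meaning that profile fit describes
its p(Target) points worse than a flat line through their mean — exactly the
failure mode the R² diagnostic exists to flag.

The same pipeline runs from a shell:

```bash
crowdprofile run --seed 7 --out results/run7          # simulate + fit
crowdprofile simulate --seed 7 --out results/sim7     # trial table only
crowdprofile fit --trials results/sim7/trials.csv --out results/fits7
```

Outputs are plain CSV tables (trials, binned distributions, pooling fits,
profile fits) plus a JSON metadata record of the resolved configuration and
seed; reruns with the same configuration and seed are byte-identical.

To analyse real data instead, write your trials to the same seven-column CSV
schema (participant, eccentricity_deg, orientation_diff_deg — empty when
unflanked —, spacing_deg, flanker_sign, target_orientation_deg,
response_orientation_deg) and point `crowdprofile fit` (or
`RunConfig(trials_path=...)`) at it.

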