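# Methods

This note documents the models, numerical choices, and limitations of
`crowdprofile`. It is the place where genuinely open design decisions are
recorded; the README gives the user-facing overview.

## Signed errors and binning

A report error is the circular difference between response and target gap
orientation, wrapped into the half-open interval (−180°, 180°]. On flanked
trials the error is multiplied by the flanker direction (+1 clockwise,
−1 anticlockwise) so that positive errors always point toward the flanker
orientation; if that flip lands exactly on −180° it is mapped to +180°,
keeping the convention that 180° is representable and −180° is not. This
matches the bin-center list, which contains +180 but not −180.

Errors are tallied into 72 five-degree bins centered at −175°, −170°, …,
180°. Continuous errors are assigned to the **nearest** bin center under
circular distance; half-way values (odd multiples of 2.5°) round **away from
zero**. How exactly continuous dial settings map onto 5° steps is not
uniquely determined by the analysis they feed; nearest-center assignment
with away-from-zero ties is this package's convention, and the test suite
pins it against an exhaustive nearest-center search so it cannot drift
silently.

## Pooling model

The flanked model for the 72 bin probabilities is

P(θ) = wR·U + (1 − wR)·[wT·VM(θ | θT, kT) + (1 − wT)·VM(θ | Δ, kF)]

with the uniform lapse U = 1/72 per bin and VM a von Mises distribution with
a 360° period (the Landolt-C gap is a full-circle variable). Free
parameters and bounds:

| parameter | meaning | bounds | default start values |
|---|---|---|---|
| wR | lapse weight | [0, 1] | 0.05, 0.25 |
| wT | target weight within non-random responses | [0, 1] | 0.1, 0.5, 0.9 |
| θT | target-component mean (deg) | [−10, 10] | 0 |
| kT, kF | concentrations | [k_lo, k_hi] | k_lo, √(k_lo·k_hi), k_hi |

k_lo = min(8, κ_unflanked) and k_hi = max(8, κ_unflanked), where
κ_unflanked is the concentration of the same observer/eccentricity's
unflanked fit. The nominal rule "8 ≤ k ≤ unflanked concentration" is
ill-posed when the unflanked concentration falls below 8; reordering via
min/max keeps the optimizer feasible and such fits carry a
`kappa_bounds_reordered` flag.

**p(Target) is wT**, the target weight *within* the non-random mixture, not
(1 − wR)·wT. The alternative reading conflates lapses with flanker capture
and was rejected: the quantity the spatial profile tracks is the balance of
target- versus flanker-centered responses among non-random reports.

Continuous densities are converted to bin masses by Simpson's rule with five
nodes per 5° bin, after which the 72 masses are renormalized to sum exactly
to one (the renormalization also cancels the Bessel normalizer, keeping the
objective cheap and overflow-free at large κ). The Simpson error per bin is
below 1e-6 even at κ = 30, verified against 0.001°-grid integration.

Fitting minimises the unweighted sum of squared errors between observed and
model bin probabilities (whether the residuals should be weighted is an open
question for this analysis; raw probabilities are used here). Optimization
is bounded trust-region least squares (`scipy.optimize.least_squares`,
ftol = xtol = gtol = 1e-12) from a deterministic 2×3×1×3×3 start lattice
(54 points). The SSE is first evaluated at every lattice point and the
best `n_polish = 6` (stable order on ties) are polished; the lowest final
SSE wins, ties broken by start order. Polishing all 54 starts changes no
reported quantity in the recovery experiments but costs ~9× the runtime of
the study-scale fits, so the screened start set is the default; `n_polish`
is a constructor parameter for anyone who wants the exhaustive behaviour.

The unflanked fit is a single von Mises with free mean in [−10°, 10°] and
concentration in [1e−3, 500]. The upper cap prevents divergence on
degenerate single-bin histograms (flagged `kappa_at_upper_bound`); uniform
histograms pin the concentration at the lower bound and are flagged too.
The mean is left free within the same ±10° band used for θT: the unflanked
distribution is nominally centered at 0°, but small response biases (the
kind the mean-error diagnostic exists to catch) should be absorbed by the
mean rather than distorting the concentration.

## Spatial profile

p(Target) versus spacing S is fitted with p(S) = 1/(1 + exp(−(S − L)/G)),
G > 0, so p increases with spacing as crowding releases. (Written with the
opposite sign in the exponent, the same curve has a negative gradient; the
increasing convention is used throughout this package, so a fitted G here
corresponds to minus the gradient of the decreasing-convention form.)

- L ∈ (0, E]: the midpoint cannot exceed the target eccentricity.
- G ∈ (0, 2E]: no upper bound is implied by the model, but unbounded G
  admits degenerate, perfectly flat fits; 2E is far shallower than any
  profile five spacings can support, and fits pinned there are flagged.
- Weights: each point enters as 1/SSE of its pooling fit, with the SSE
  floored at 1e−8 so a numerically perfect pooling fit cannot acquire
  infinite weight.
- Span = 2·G·ln 1.5, the closed form of the spacing difference between
  p = 0.4 and p = 0.6; midpoint and span divided by E give Bouma units.
- R² = 1 − SSE/SST is computed **unweighted** (recorded in the fit flags
  convention rather than silently mixing weighted and unweighted sums). It
  can be negative — a profile flatter or more inverted than its mean line —
  and is NaN (flagged `zero_sst`) when all points are identical.
- Data with all points on one side of 0.5, or with a decreasing trend, are
  fitted anyway and flagged (`one_sided_data`, `inverted_trend`) rather than
  forced or rejected.

Optimization mirrors the pooling stage: bounded least squares from a
deterministic 4×3 start grid over (L, G) fractions of E. Fits require at
least three distinct spacings; fewer raise an underdetermined-fit error.

## Synthetic observer

The simulator draws, per trial: a uniform target orientation in [0°, 360°);
a fair ±1 flanker direction (flanked trials); and an error in
flanker-positive sign space from the generative mixture — uniform with
probability w_random, otherwise target-centered von Mises with probability
w_target(S) or flanker-centered von Mises at Δ. The flanker sign is undone
when the response is placed on the circle, so the analysis-side sign
convention recovers the drawn error exactly. w_target follows a ground-truth
logistic per (E, Δ). Sampling uses numpy's von Mises generator (the standard
Best–Fisher rejection sampler) on the full 360° period. One seed drives a
single sequential stream in condition-then-trial order; the assembled
session is then shuffled with the same stream, so a session is reproducible
from (design, parameters, seed).

Simulator defaults (all overridable) emulate the study conditions:
three eccentricities 4.24°, 12.72°, 21.2°; Δ ∈ {22.5°, 45°, 90°, 180°};
five spacings per eccentricity linearly spaced from the just-touching
separation (one stimulus diameter, itself (E + 1.77)·1.5/14.49 deg) to
0.8·E; 150 trials per condition at 12.72° and 80 at the outer two; plus an
unflanked condition. Ground truth: midpoint L = 0.33·E; spans 0.45·E,
0.35·E, 0.22·E, 0.15·E for the four Δ levels (G = span / (2 ln 1.5));
w_random = 0.05; κ_target = κ_flanker = 20; κ_unflanked = 30; θT = 0. The
exact five spacing values used in the original experiments are not public;
the linear grid spanning the crowding zone is this package's documented
stand-in. The number of spacings (five) is implied by the 21-condition,
3150-trial bookkeeping of the design.

What the simulator deliberately does **not** model: reaction times, learning
or fatigue across blocks, spacing-dependent lapse rates (w_random is constant
per observer, though the fitting stage estimates wR per condition
regardless), response-dial dynamics, and any stimulus rendering. Passing
recovery tests therefore demonstrate that the analysis inverts its own
generative assumptions at realistic trial counts — not that human data obey
those assumptions.

## Recovery experiments and problem sizes

The heaviest validation simulates the full 63-condition design at 150
trials/condition for 100 seeded replicates and checks: fitted wT near 0.5 at
the condition closest to the true midpoint; median fitted L within 15% of
0.33·E at every eccentricity (Δ = 180° profiles, where the two mixture
components are fully separable); and strict monotonicity of median fitted
span in the generating gradient across the four Δ levels. Only the pooling
fits those summaries need are computed (all Δ at 12.72°, Δ = 180° elsewhere),
keeping the experiment around three minutes on one CPU. Optimizer quality is
checked separately by dominance over brute-force parameter grids (a
3267-point lattice for the pooling model, 50×50 for the profile).

## Known limitations

- SSE fitting over binned probabilities follows the analysis being
  implemented; it is not maximum likelihood, and no standard errors are
  attached to fitted parameters. Downstream inference is expected to happen
  on the exported tidy tables (e.g. mixed-effects models in R), which is out
  of scope here.
- With overlapping components (Δ = 22.5°, κ ≈ 20) wT, θT, and the
  concentrations trade off; recovery of wT is noticeably noisier there than
  at Δ ≥ 90°. The ±10° bound on θT is what keeps the problem identifiable.
- Shallow profiles (span comparable to the sampled spacing range) can pin L
  at 0 or G at its cap; such fits are flagged, not suppressed, and can carry
  negative R².
- Trial-level classification of individual responses as target- or
  flanker-centered is intentionally unsupported: the mixture's overlapping
  components make per-trial assignment ill-defined.
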