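# Methods

`choicerep` implements, end to end and without any human data, a value-based
choice-repetition experiment: the adaptive construction of the decision game's
trials, a mechanistic synthetic participant, and the preregistered statistical
analysis. This note records the models, the parameter choices, and the design
decisions made where the procedure was genuinely open.

## The task and its adaptive design

Every trial offers a small coin near the avatar (SN) against a larger coin
further away (LF). The LF value is uniform on 65–85 credits; what varies
meaningfully is the value **ratio** r = SN/LF and the **distance** d (how many
fields further the LF coin lies, 1–12; the SN coin is 2 or 3 fields away).

A *measurement block* samples r uniformly on [0.20, 0.95] at distances
d ∈ {1, 4, 8, 12}. For each of those anchor distances we fit a logistic
psychometric function by maximum likelihood,

    P(choose LF) = expit(a + b·r),   b < 0,

and define the indifference point r*(d) = −a/b, the ratio at which both coins
are chosen equally often. Values at the remaining distances are linear
interpolants in d; all r*(d) are clipped to [0.05, 0.95]. Degenerate choice
data (all-LF, all-SN, or perfectly separated, detected as |b| > 150) yields a
clipped midpoint with a flag rather than an error, because the experiment's
own screening rule handles extreme behaviour: a participant is *eligible*
only if at least two distances satisfy r*(d) < 0.7 (room for an SN-bias
trial) **and** at least two satisfy r*(d) > 0.3 (room for an LF-bias trial).

Experimental blocks consist of *triplets*: two bias trials of one type
followed by a neutral target. Bias trials set the ratio to r*(d) ± 0.30 —
read additively, since the 0.7/0.3 feasibility bounds are exactly the
additive bounds that keep the shifted ratio inside (0, 1) — at a distance
drawn from the feasible set of that type; targets sit at r*(d) with d uniform
on 1–12. The inter-trial interval before the target is always 500 ms (the
repetition effect is strongest at short ITIs); the triplet's other two ITIs
are {500, 1500} ms in randomised order, masking the triplet structure. Both
bias trials of a triplet share one type because the analysis conditions each
target on a single preceding bias type.

Two-session stimulation plans are counterbalanced over four scenarios: real
stimulation (anodal in one session, cathodal in the other) occupies either
the first (2–3) or last (4–5) pair of experimental blocks, flipping between
sessions, with the remaining pair sham. Scenarios are assigned cyclically, so
any multiple-of-four cohort is exactly balanced.

Grid placement (used by the `design` CLI and available for rendering layers)
puts coins at the required Manhattan distances — movement is restricted to
orthogonally adjacent fields, so path length equals Manhattan distance — with
the two avatar→coin vectors subtending at least 90° (dot product ≤ 0), so
approaching one coin recedes from the other.

## The synthetic participant

The agent is a two-unit rate reduction of an attractor network: each option
has one population with self-excitation, mutual inhibition, and background
noise,

    dx_i = [−λ·x_i + w_s·g(x_i) − w_i·g(x_j) + γ·V_i + π] dt + σ·√dt·η,

with rectified transfer g(x) = max(x, 0). The first population whose
rectified activity crosses the threshold wins (winner-takes-all); decision
time is the crossing time plus a fixed non-decision component t₀, which in
this mouse-driven game also absorbs movement initiation. Ties within one
integration step go to the larger activity, then to a coin flip. Timeouts
(beyond `max_time`) are resolved by the larger current activity and flagged,
because the human task has no no-response trials.

Option inputs are hyperbolically discounted values, V = value/(1 + k·d_total)
— distance is a time proxy here, and hyperbolic discounting is the field
default. This gives a closed-form indifference ratio
r*(d) = (1 + k·d_SN)/(1 + k·(d_SN + d)) used as the ground truth in recovery
tests.

Between trials the activities decay exponentially with time constant τ. A
residual head start for the previous winner is the repetition mechanism: it
is strong after 500 ms and nearly gone after 1500 ms. Stimulation enters
twice, each with its own constant so either can be zeroed: a polarization
offset π added to both populations' drive (anodal positive, cathodal
negative, sham zero), and a decay-time scaling τ_eff = τ·(1 + c·π), so
depolarization slows the return to rest and thereby strengthens repetition
while speeding decisions; hyperpolarization does the opposite.

### Committed default parameters ("default-2021")

| parameter | symbol | default | units | rationale |
|---|---|---|---|---|
| leak | λ | 4.0 | 1/s | stable sub-threshold dynamics |
| self-excitation | w_s | 5.0 | – | net positive feedback (w_s > λ) for winner-takes-all |
| inhibition | w_i | 7.0 | – | suppresses the loser; symmetric fixed point below threshold |
| noise SD | σ | 0.8 | units/√s | sets psychometric steepness and choice stochasticity |
| threshold | – | 1.0 | units | activity scale anchor |
| time step | dt | 0.001 | s | Euler–Maruyama resolution |
| non-decision time | t₀ | 500 | ms | motor/encoding floor for a mouse response |
| decay constant | τ | 250 | ms | clear 500-vs-1500 ms ITI contrast |
| value gain | γ | 0.30 | 1/value | psychometric slope ≈ 10 per ratio unit |
| polarization | π | ±0.3 | units | applied per real-stimulation block |
| decay gain | c | 1.5 | 1/unit | τ_eff ≈ 360/110 ms under anodal/cathodal |
| discount rate | k | 0.15 | 1/field | population mean; SD 0.05 across agents |
| timeout | – | 4.0 | s | flagged, resolved by larger activity |

The polarization sensitivity floor: with 6,000 triplets per condition the
repetition-index and decision-time orderings are reliably resolved for
|π| ≥ 0.1; the default ±0.3 sits well above it. Cohorts emulating a
stimulation-insensitive population set `stim_polarization = 0`.

Cohort simulation draws per-agent k and τ from truncated normal population
distributions (k: 0.15 ± 0.05 on [0.02, 1]; τ: 250 ± 50 ms on [50, 1500]),
runs measurement → profile estimation → eligibility screen → four
experimental blocks per session under the counterbalanced plan, and excludes
ineligible agents the way the lab excluded participants after the
measurement block. Near-zero discounting (r* → 1 everywhere, clipped at
0.95) empties the SN-feasible set and is the screened-out extreme; very
strong discounting, by the additive ±0.30 rule, retains feasible distances
for both types and so remains eligible.

## The analysis pipeline

All percentages are computed per participant and then averaged (the reported
SDs are between-participant). The stages run in the preregistered order:

1. **Sham pooling gate** — paired t on per-participant sham-target LF%
   across the two sessions. Pooling is unconditional, with a flag when the
   gate is significant (the preregistration's conditional phrasing).
2. **Bias-success filter** — a target counts only if its bias trial was
   chosen bias-consistently; the default `preceding` mode conditions on the
   second bias trial (the one immediately before the target), `both` on
   both.
3. **H1.1** — one-tailed paired t of LF% after LF bias vs after SN bias
   (sham only); the difference is the *repetition index* in percentage
   points.
4. **H1.2** — targets classed as repetition or switch; per-participant mean
   log decision times enter a one-tailed paired t (switches slower). The
   Hedges g reported for this contrast uses the raw millisecond means/SDs.
5. **H2.1 / H2.2** — one-way repeated-measures ANOVAs of the repetition
   index and of mean log decision time (all targets) over
   anodal/cathodal/sham, with Holm-corrected one-tailed post hocs
   (H2.1.1/H2.1.2, H2.2.1/H2.2.2).
6. **Exploratory block** — sham-first vs sham-second overall LF%; stimulation
   ANOVAs on overall LF% and on bias success; stimulation × trial-type ANOVA
   on log decision times.

Effect sizes: paired contrasts report Hedges g with the averaged-SD
standardizer, g = (m₁ − m₂)/√((s₁² + s₂²)/2) · J with J = 1 − 3/(4(n−1) − 1)
— the estimator that reproduces both published values (0.95 and 0.39) from
the published means and SDs. ANOVAs report partial eta squared, recovered
exactly from F·df₁/(F·df₁ + df₂); the underlying decomposition is pingouin's
repeated-measures ANOVA with subject as the blocking factor, and it is
checked in the tests against an independent brute-force sums-of-squares
oracle. Holm correction is statsmodels' step-down implementation. The
required-sample-size routine inverts the noncentral t distribution
(noncentrality d·√n, df n−1), searching n upward from 3.

Degenerate inputs: paired differences that are all exactly zero return
t = 0, p = 1 (a legitimate null), while a constant nonzero difference raises
a degenerate-test error; repeated-measures designs with missing cells raise
rather than impute; an ANOVA whose effect and error sums of squares are both
zero reports F = 0.

## Reproducibility

All randomness flows from one master seed through named
`numpy.random.SeedSequence` substreams (participant, session, stage), so a
fixed configuration reproduces byte-identical choice logs and reports. The
integration inner loop is numba-compiled with a per-decision seed drawn from
the participant stream.

## What the generator does and does not emulate

The synthetic cohort reproduces the *mechanisms* the experiment was designed
around: hyperbolic discounting with interindividual variance, repetition
that decays with ITI, faster repeats than switches, bias-trial compliance
well below ceiling, and (optionally) polarization-dependent modulation of
all three. It does **not** attempt a quantitative match to the human data:

- The default agent is more value-sensitive than the human cohort
  (bias-success ≈ 93% vs ≈ 80%); this steepness is what lets a 1000-trial
  measurement block recover indifference points to MAE < 0.03, the
  calibration precision the design assumes.
- Its sham repetition index (≈ 20–40 points depending on cohort size and
  triplet counts) exceeds the human ≈ 16 points.
- Indifference-point estimation treats measurement trials as independent,
  but a hysteretic agent (like a human) makes serially dependent choices at
  the 500 ms measurement ITI; under the default agent this roughly doubles
  the recovery error. The recovery calibration therefore uses a known-k
  agent with instant residual decay, isolating the estimator itself.
- No generative claim is made about human LF rates or the published test
  statistics (t(51) = 7.76 etc.), which require the raw data; Bayesian
  ANOVAs, current-flow modelling, and questionnaire measures are out of
  scope.

Passing tests therefore certify the machinery — design construction,
estimation, simulation mechanisms, and the statistical pipeline — not any
claim about human cortex.

## Problem sizes used in the test suite

The suite exercises the pipeline at desk scale by choice: cohorts of 4–8
agents at 12–20 triplets per block for end-to-end checks, 10,000
bias→target pairs per seed for the ITI-monotonicity probe, 6,000 per
condition for the polarization orderings, five replicate 1000-trial
measurement blocks for recovery calibration, and 200 cohorts of 20 null
agents (instant decay) for the false-positive-rate check of H1.1, whose
rejection count is required to fall inside the central 95% band of
Binomial(200, 0.05).
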