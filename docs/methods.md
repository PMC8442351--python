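# Methods

## Model

One business day of a diagnostic-imaging unit is modelled as a
finite-horizon Markov decision process with `N` regular and `K`
overtime decision stages, each one service period long. States count
waiting patients by class: `(w_ip, w_op, w_ep)` in regular periods,
`(w_ip, w_op)` in overtime. The day starts empty; emergencies arriving
between days are handled by dedicated equipment.

Assumptions, in the package's own terms:

- At most one inpatient and one emergency request arrive per regular
  period, independently, with probabilities `p_ip` and `p_ep`; both are
  stored per period but constant across periods in every shipped
  preset.
- Outpatients are booked to specific periods; each booked slot `h` of
  period `i` shows independently with probability `p_i,h`. The number
  of shows among the `Ag_{i+1}` slots booked for the next period is
  therefore Poisson-binomial. Shown patients are punctual.
- Emergencies must be served in the period after arrival, so every
  feasible action seats all waiting EPs; an EP count exceeding capacity
  raises an error rather than being silently queued.
- Exactly `min(capacity, waiting)` patients are served per period — no
  voluntary idling.
- Service takes one period on a fast scanner. The (at most one) slow
  scanner takes two periods, so it can only start exams on alternating
  periods; this is encoded purely as the 2-periodic capacity profile
  (3, 2, 3, … for the default 2 + 1 fleet), both in the solver and in
  the simulator. The slow scanner's phase is a config field; the
  default starts its first exam in period 1. Overtime uses fast
  scanners only (1 or 2 resources).
- No arrivals occur in overtime, so overtime transitions are
  deterministic, and the crossing from regular period `N` into overtime
  drops the EP component (after-hours emergencies go to dedicated
  equipment).
- Costs are linear and undiscounted: per-period waiting costs for IPs
  and OPs, per-patient overtime costs, and a terminal penalty per
  unserved patient.

## State enumeration

Two modes are defined. *Unrestricted* enumeration applies only box
bounds: `w_ip ≤ i`, `w_op ≤` cumulative bookings, `w_ep ∈ {0, 1}` in
regular period `i`; `w_ip ≤ N`, `w_op ≤` total bookings in overtime.
*Restricted* enumeration adds the joint bound

```
w_ip + w_op ≤ Σ_{l≤i} Ag_l + i − Σ_{l<i} (C_l − 1),
```

i.e. every past period is guaranteed to have dedicated at least
`C_l − 1` service slots to IPs/OPs — the worst case of one emergency
arrival in every past period. For overtime period `k` the bound
additionally shrinks by the overtime capacity already offered,
`Σ_{y<k} C_{N+y}`; a negative bound collapses the set to the empty
state, as does cumulative capacity exceeding cumulative potential
arrivals in a regular period (fallback to the day-start box). On the
baseline instance these rules give 93,534 (unrestricted) and 52,680
(restricted) states; the restricted sets are forward-closed under the
transition kernel, which the solver re-verifies at every sweep by
refusing to extrapolate missing successors.

## Solver

Plain backward induction over the restricted sets: terminal penalties,
then overtime sweeps (deterministic successors), then regular sweeps.
Within a regular period the expected continuation value depends on the
action only through the post-service residual `(w − a)`, so it is
memoised per period; this makes the baseline solve (52,680 states)
take ~0.3 s on one core. Argmin ties are broken by the fixed
IP-descending action order with a 1e-12 comparison margin, so the
stored policy is identical across runs and platforms. Transition
distributions are exact (no probability pruning); each is checked to
sum to 1 within 1e-12 in the tests. The expected day cost is the
initial-state distribution (pre-day arrivals applied to the empty
state) averaged over `V_1`; `V_1` itself is also exposed.

## Poisson-binomial kernel

The show-count pmf is computed by iterative convolution over slots,
left to right: starting from a point mass at zero, slot `h` convolves
the pmf with `(1 − p_h, p_h)`. This is exact and O(Q²); tests verify it
against explicit 2^Q subset enumeration for Q ≤ 12 to 1e-12, the mean
identity `Σ p_h`, and collapse to the binomial for equal slots. A slot
probability of 0 is allowed (it simply contributes no mass), although
the configuration validator requires probabilities in (0, 1] so that
booked slots are meaningful.

## Benchmark policies and simulator

P1–P5 share the mandatory action structure (EPs seated, no idling) and
differ only in how leftover capacity is split: P1 draws uniformly
without replacement from the pooled waiting lists (hypergeometric IP
count), P2/P3 give static priority to OPs/IPs, P4 prioritises IPs for
the first `ceil(N/2)` periods (19 of 37) then OPs, with OPs first in
overtime; P5 mirrors P4 and gives IPs priority in overtime.

The simulator replays the exact model dynamics with sampled arrivals
and verifies feasibility of every policy action (an infeasible action
is a hard failure, not a correction). Per day it returns the full cost
decomposition, served/unserved counts per class, and arrival counts,
so the tests can assert per-class patient conservation and that the
decomposition sums to the total. Occupancy is served patient-slots
divided by all offered slots — the full regular capacity profile plus
the configured overtime capacity, whether used or not.

Policy comparisons use common random numbers by default: each policy
receives the same per-day child seeds, and in-policy randomness (P1)
draws from a separate stream split off the day's seed so the arrival
sequence is identical across policies. Independent streams are
available via `common_random_numbers=False`. Significance against the
reference policy uses Welch's unequal-variance two-sample t-test at
5%; Welch was chosen because cost variances differ visibly across
policies. Identical samples (a policy compared against itself under
common random numbers) are reported as t = 0, not significant.

## Synthetic no-show probabilities

The source unit predicted individual no-show risk with a penalized
logistic regression on private patient records. The `noshow` module
emulates that model's *output*: per booked slot it draws a covariate
vector (three generic standard-normal covariates by default, stand-ins
for lead time, period of day and a patient score), applies the
inverse-logit of a linear predictor, and clips the result to
`[1e-6, 1 − 1e-6]`. The intercept can be calibrated by bisection on a
100,000-draw Monte-Carlo sample to hit a target mean show probability
within 0.005; the default target used throughout the examples and
tests is **0.80**, a typical imaging-clinic attendance level chosen
once as the package's default study condition. The generator
reproduces the *heterogeneity structure* of patient-level risk, not
any real population: it has no covariate correlations, no schedule
effects, and no claim of matching the source unit's probabilities, so
simulation results on synthetic probabilities demonstrate the
machinery and qualitative orderings, not the unit's dollar figures.

## Problem sizes in the shipped tests

The acceptance-style checks use: the full baseline instance for the
exact state counts; an N=2/K=1 unit-capacity instance (256
deterministic Markov policies) for exhaustive-optimality
cross-checking; an N=8/K=2 double-overbooked instance for
solver-vs-simulator consistency (20,000 days) and the
optimal-vs-heuristic comparison (10,000 days); and an N=12/K=2
instance with 3 overbooked slots for the overbooking/overtime
orderings (5,000 days per cell). These sizes were chosen so each
property is tested where its effect is clearly expressed while the
whole suite stays quick to run.

## Known limitations

- Exactly one slow scanner is supported, and it never runs in
  overtime; stochastic service times are out of scope.
- Periods are abstract slots; no calendar or intra-period timing.
- The unrestricted counting mode exists for diagnostics and
  comparison; the solver always uses restricted sets.
- The scenario grid re-solves the MDP once per scenario when the
  optimal policy is included; at full published scale (36 scenarios ×
  10,000 days) this is minutes of compute, dominated by day simulation.
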