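# Methods

## Task model

The apparatus is modelled as a strict chain of states, each named after the
lock that currently blocks progress:

```
WHEEL_LOCKED → BAR_LOCKED → DOOR_LOCKED → SOLVED
```

Exactly one component is *functional* per state (wheel, bar, door
respectively).  An event stream is annotated by walking this chain: each
contact is tagged with the state in force when it began, and the state
advances immediately after a contact that opens the functional component.
An `opens_lock` flag on any other component is a mechanical impossibility
and rejected with the offending event.  This gives state-conditioned counts
without needing a fine-grained action ethogram (push/pull/bite variants are
deliberately collapsed into "contact").

### Episodes across sessions

A solution episode runs from the start of the first session after the
previous solution to the door-opening contact.  Design choices:

* **Episode start is session start, not first contact.**  Δ = T/n_a divides
  session time including idle time; idle time is part of (dis)engagement,
  so it belongs to the episode.
* **Only in-session time counts.**  T sums full durations of intervening
  unsolved sessions plus the elapsed time within the boundary session; the
  time between sessions contributes nothing.
* **State carry-over.**  Within an episode that spans sessions, the state
  carries over (a removed wheel stays removed).  The per-session
  `initial_state` column is authoritative: a continuation session must
  declare the carried state, and the only sanctioned disagreement is a full
  experimenter reset to `wheel_locked` (wheel re-attached), which is
  accepted with a logged warning.  Any forward jump is a validation error
  naming both sessions.
* **Post-solution events** (contacts after the door opened, within the same
  session) belong to no episode and are reported as a warning count.
  Protocols normally end a session at solution, so this is rare.
* At most one trailing **incomplete episode** is kept, flagged, and
  excluded from all metrics: with locks unopened, n_c is censored and M
  would be misleading.

## Decomposition

For a complete episode, per state `s ∈ {wheel, bar, door}` we count
`n_all_s` (every contact in state `s`, including contacts on non-lock
surfaces, "other") and `n_correct_s` (contacts on `s` itself).  Then

```
n_a = Σ_s n_all_s      n_c = Σ_s n_correct_s
M = n_a / n_c          E = n_c          Δ = T / n_a
```

and `T = M · E · Δ` holds identically.  Numerical notes:

* M is a single ratio of pooled sums, not a mean of per-state ratios.
* Δ is `T/n_a` exactly (not T over the n_a − 1 inter-event gaps); with the
  episode anchored at session start there are n_a waiting intervals.
* The identity is exact in rational arithmetic; in floats the pipeline
  reproduces T to ~1e-16 relative error (tested at 1e-9 tolerance).
* "Other" contacts count toward n_a only — mistargeting is about contact
  with non-functional locations, wherever they are.

### Trend fit

Slow strategy adaptation is summarised by OLS of `ln M` on solution index,
using the centred closed form (slope = Sxy/Sxx), which recovers exactly
log-linear input to machine precision.  The first solution is excluded by
default — the drop into the first success is a distinct, fast process — but
can be included via an option.  Natural log is used throughout; the base
only rescales the slope.  The fit requires at least two usable episodes and
refuses otherwise.

## Synthetic agents

The generator exists to make every estimator in the pipeline testable with
known ground truth.  It commits to the simplest distributions consistent
with the metric definitions, not to any cognitive mechanism:

* inter-contact intervals are i.i.d. exponential with rate λ_e (so Δ
  estimates 1/λ),
* each contact hits the functional component with probability p_{s,e} (so
  pooled M estimates 1/p̄),
* each correct contact opens its lock with probability q_{s,e} (so per-lock
  effort is geometric with mean 1/q).

Learning trajectories are episode-indexed.  Targeting follows a
jump-plus-exponential form: `p_{s,1} = p0`, then immediately after the
first success a fraction `jump` of the gap to the asymptote closes, and the
remainder decays exponentially at rate κ.  Skill and engagement use the
plain exponential approach `x_e = x∞ − (x∞ − x0)·exp(−κ(e−1))`; their fast
adaptation is expressed through large rates.  Three further behavioural
features are generative options:

* **Regression** (probability ρ per episode after the first): wheel
  targeting reverts to its naive value for that episode only, producing
  non-monotone M series.
* **Old-strategy bias** b: in episode 1, before the agent has touched the
  wheel at all, mistargeted contacts are directed to bar/door with
  probability b — the components that solved the training box without a
  wheel.
* **Mistarget weights** distribute remaining mistargets over non-functional
  components (default weights 1:1:1:3 favouring "other" surfaces).

The continuous timeline is sliced into sessions of at most 900 s; a session
ends early exactly when the door opens, and the next episode starts a fresh
session with the box re-locked.  Exponential memorylessness makes slicing
equivalent to simulating per-session.  Each subject gets an independent RNG
stream seeded from `(seed, crc32(subject_id))`, so multi-subject runs are
reproducible subject by subject.  Parameters whose expected episode length
exceeds a hard contact cap (default 100,000) abort with a stall error, as
does any episode that actually reaches the cap.

### The "birdlike" preset

Defaults chosen once to match the qualitative shape of the study
conditions: a first episode of roughly 1500–4000 s (measured mean ≈ 3850 s)
followed by episodes of tens of seconds, a steep post-first-success drop in
T, a slow negative log-linear trend in M over solutions 2–12, non-monotone
per-lock effort, and one regression episode in five (ρ = 0.2).

| parameter | wheel | bar | door |
|---|---|---|---|
| targeting p0 → p∞ (rate, jump) | 0.40 → 0.95 (0.20, 0.05) | 0.40 → 0.95 (0.20, 0.05) | 0.50 → 0.97 (0.20, 0.05) |
| skill q0 → q∞ (rate) | 0.015 → 0.35 (1.4) | 0.20 → 0.45 (1.2) | 0.40 → 0.55 (1.2) |

Engagement: λ 0.05 → 0.17 contacts/s (rate 2.0); old-strategy bias 0.8.

The naive deficit is placed in wheel *skill* (the rotate-and-displace
manoeuvre almost never succeeds, q0 = 0.015) rather than wheel *targeting*
(p0 = 0.40: the new wheel is salient and touched often).  This matters
because regression reverts targeting to p0: a low naive p0 would make every
regression episode an extreme mistargeting spike, whereas the observed
regressions are temporary, moderate resurgences.

### What the generator does not emulate

Real coded data have structure the generator omits: bout structure in
contacts (intervals are not exponential in reality), within-session
fatigue, day-to-day motivational drift, multi-stage locks (the wheel's
rotation and displacement are separate sub-goals), and any actual learning
mechanism.  Passing parameter-recovery tests therefore shows the pipeline's
estimators are consistent for data of this generic statistical shape — not
that real birds follow these distributions.

## Recovery harness

`recovery_report` compares, with tolerances of k Monte-Carlo standard
errors (default k = 4):

* mean late-episode Δ̂ vs the mean of 1/λ_e over the same episodes,
* pooled M̂ = Σn_a/Σn_c vs 1/p̄ with p̄ the contact-weighted mean targeting
  probability (binomial standard error mapped through d(1/p)/dp),
* mean Ê vs the mean of Σ_s 1/q_{s,e},
* the fitted log-M slope vs the OLS slope of the log of the analytically
  expected M series (standard error from fit residuals; needs ≥ 3 usable
  episodes).

Because which episodes regress is random, the simulator returns the
realised per-episode truth table; without it the harness recomputes
trajectories deterministically and warns when ρ > 0.

## Problem sizes

The validation suite uses: 50 randomised agents × 20 episodes for the
identity sweep (1000 episodes), 200 random logs for the counting
cross-check, 400-episode constant agents for parameter recovery, and 100
seeds × 12 episodes of the birdlike preset for the constraint-shape suite.
At these sizes the whole test suite runs in a few seconds on one CPU.

## Known limitations

* The event-log reader trusts the `opens_lock` coding; it validates
  mechanical possibility but cannot detect a missed opening (which would
  shift all subsequent state attributions).
* Only single-chain, three-lock apparatuses are supported; no arbitrary
  lock dependency graphs.
* No statistical inference on trend slopes (standard errors, p-values) and
  no cross-subject models — the fit is descriptive.
* Incomplete episodes contribute observed time to nothing; an analysis of
  censored episodes would need a different estimand.
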