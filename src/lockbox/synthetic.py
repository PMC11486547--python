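"""Generative agent simulator for lockbox event logs.

The simulator produces multi-session contact logs from a parameterised
stochastic agent, providing ground truth for parameter-recovery tests of the
whole analysis pipeline.  Its design mirrors the behavioural phenomenology
the analysis is meant to expose:

* **Fast and slow adaptation.**  Each per-state targeting probability ``p``
  follows the agent's first success with a one-off jump that closes a
  fraction ``jump`` of the gap to its asymptote, then approaches the
  asymptote exponentially over further solutions.  Opening skill ``q`` and
  the contact rate ``lambda`` adapt exponentially from their initial values.
* **Regression to earlier behaviour.**  With probability ``regression_prob``
  an episode's *wheel* targeting reverts to its naive initial value,
  producing a temporary resurgence of mistargeting and a non-monotone M
  series.
* **Old strategy on the new task.**  In the very first episode, before the
  agent has touched the wheel at all, mistargeted contacts are biased (weight
  ``old_strategy_bias``) toward bar and door -- the components that solved
  the pre-training box that lacked the wheel.
* **Inter-individual differences.**  Each subject carries its own parameter
  set and an independent RNG stream derived from ``(seed, subject_id)``.

Mechanics: within an episode the agent iterates the task states in order;
inter-contact intervals are i.i.d. exponential with the episode's contact
rate, each contact lands on the functional component with probability
``p``, and each correct contact opens its lock with probability ``q``
(geometric number of correct contacts per lock).  The continuous timeline is
sliced into sessions of at most ``session_cap_s`` seconds; a session ends
early exactly when the door opens.  None of this commits to a cognitive
mechanism -- the distributions are the simplest ones consistent with the
definitions of the Delta and E metrics.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .decomposition import DecompositionRecord, fit_log_linear
from .errors import StallError, ValidationError
from .io_ethogram import COMPONENTS, LOCKS, ContactEvent, SessionRecord
from .task_model import LockboxState

logger = logging.getLogger(__name__)

DEFAULT_SESSION_CAP_S = 900.0
DEFAULT_CONTACT_CAP = 100_000


@dataclass(frozen=True)
class Adaptation:
    """An episode-indexed learning trajectory.

    With ``jump=None`` the value approaches the asymptote exponentially::

        x(e) = asymptote - (asymptote - initial) * exp(-rate * (e - 1))

    With a ``jump`` fraction (used for targeting probabilities), episode 1
    returns ``initial``; immediately after the first success the value jumps
    by ``jump * (asymptote - initial)`` and from there approaches the
    asymptote exponentially::

        x(1) = initial
        x(2) = initial + jump * (asymptote - initial)
        x(e) = asymptote - (asymptote - x(2)) * exp(-rate * (e - 2))
    """

    initial: float
    asymptote: float
    rate: float = 0.0
    jump: float | None = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValidationError(f"adaptation rate must be >= 0, got {self.rate}")
        if self.jump is not None and not (0.0 <= self.jump <= 1.0):
            raise ValidationError(f"jump must be in [0, 1], got {self.jump}")

    def value(self, episode: int) -> float:
        if episode < 1:
            raise ValidationError(f"episode index must be >= 1, got {episode}")
        if self.jump is None:
            return self.asymptote - (self.asymptote - self.initial) * math.exp(
                -self.rate * (episode - 1)
            )
        if episode == 1:
            return self.initial
        v2 = self.initial + self.jump * (self.asymptote - self.initial)
        return self.asymptote - (self.asymptote - v2) * math.exp(
            -self.rate * (episode - 2)
        )


def _check_prob(name: str, x: float, *, open_zero: bool = True) -> None:
    lo_ok = x > 0 if open_zero else x >= 0
    if not (lo_ok and x <= 1):
        raise ValidationError(f"{name} must be a probability in (0, 1], got {x}")


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters for one simulated subject.

    ``targeting[s]`` gives the probability that a contact made in state ``s``
    lands on the functional component (an :class:`Adaptation` with a
    post-first-success ``jump``); ``skill[s]`` the probability that a correct
    contact opens lock ``s``; ``engagement`` the contact rate in contacts per
    second.  ``mistarget_weights`` distributes mistargeted contacts over the
    non-functional components (including ``other``).
    """

    subject_id: str
    n_episodes: int
    targeting: Mapping[str, Adaptation]
    skill: Mapping[str, Adaptation]
    engagement: Adaptation
    regression_prob: float = 0.0
    old_strategy_bias: float = 0.0
    mistarget_weights: Mapping[str, float] = field(
        default_factory=lambda: {"wheel": 1.0, "bar": 1.0, "door": 1.0, "other": 3.0}
    )
    session_cap_s: float = DEFAULT_SESSION_CAP_S
    max_contacts_per_episode: int = DEFAULT_CONTACT_CAP
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValidationError("subject_id must be non-empty")
        if self.n_episodes < 1:
            raise ValidationError(f"n_episodes must be >= 1, got {self.n_episodes}")
        for group, name in ((self.targeting, "targeting"), (self.skill, "skill")):
            for lock in LOCKS:
                if lock not in group:
                    raise ValidationError(f"{name} is missing lock {lock!r}")
                traj = group[lock]
                _check_prob(f"{name}[{lock}].initial", traj.initial)
                _check_prob(f"{name}[{lock}].asymptote", traj.asymptote)
        if self.engagement.initial <= 0 or self.engagement.asymptote <= 0:
            raise ValidationError("engagement (contact rate) must be positive")
        if not (0.0 <= self.regression_prob < 1.0):
            raise ValidationError(
                f"regression_prob must be in [0, 1), got {self.regression_prob}"
            )
        if not (0.0 <= self.old_strategy_bias <= 1.0):
            raise ValidationError(
                f"old_strategy_bias must be in [0, 1], got {self.old_strategy_bias}"
            )
        for comp, w in self.mistarget_weights.items():
            if comp not in COMPONENTS:
                raise ValidationError(f"mistarget_weights has unknown component {comp!r}")
            if w < 0:
                raise ValidationError(f"mistarget_weights[{comp!r}] must be >= 0")
        if self.session_cap_s <= 0:
            raise ValidationError("session_cap_s must be positive")
        if self.max_contacts_per_episode < 3:
            raise ValidationError("max_contacts_per_episode must be >= 3")


def targeting_trajectory(
    params: AgentParams, state: str, episode: int, regressed: bool = False
) -> float:
    """Probability of contacting the functional component in ``state`` during
    the given episode.

    ``regressed`` marks an episode whose wheel targeting reverted to its
    naive initial value; the draw itself is made by the simulator (Bernoulli
    ``regression_prob`` per episode after the first success).
    """
    if state not in LOCKS:
        raise ValidationError(f"state must be one of {LOCKS}, got {state!r}")
    if regressed and state == "wheel":
        return params.targeting["wheel"].initial
    return params.targeting[state].value(episode)


def opening_trajectory(params: AgentParams, state: str, episode: int) -> float:
    """Probability that a correct contact opens lock ``state`` in ``episode``."""
    if state not in LOCKS:
        raise ValidationError(f"state must be one of {LOCKS}, got {state!r}")
    return params.skill[state].value(episode)


def contact_rate(params: AgentParams, episode: int) -> float:
    """Contact rate (contacts per second) in ``episode``."""
    return params.engagement.value(episode)


@dataclass
class SimulationResult:
    """Simulated sessions plus the per-episode ground truth that generated
    them (columns: episode, regressed, lambda, p_<lock>, q_<lock>)."""

    params: AgentParams
    sessions: list[SessionRecord]
    truth: pd.DataFrame


def _subject_rng(params: AgentParams) -> np.random.Generator:
    # one independent, reproducible stream per (seed, subject) pair
    entropy = [params.seed % 2**32, zlib.crc32(params.subject_id.encode("utf-8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _expected_contacts(params: AgentParams, episode: int, regressed: bool) -> float:
    total = 0.0
    for lock in LOCKS:
        p = targeting_trajectory(params, lock, episode, regressed)
        q = opening_trajectory(params, lock, episode)
        total += 1.0 / (p * q)
    return total


def run_simulation(params: AgentParams) -> SimulationResult:
    """Simulate one subject and return sessions together with ground truth."""
    rng = _subject_rng(params)
    cap = params.session_cap_s
    sessions: list[SessionRecord] = []
    truth_rows: list[dict] = []

    session_index = 0
    session_events: list[ContactEvent] = []
    session_entry = LockboxState.WHEEL_LOCKED
    session_elapsed = 0.0

    def close_session(duration: float, entry_next: LockboxState) -> None:
        nonlocal session_index, session_events, session_entry, session_elapsed
        session_index += 1
        sessions.append(
            SessionRecord(
                subject_id=params.subject_id,
                session_index=session_index,
                duration_s=duration,
                initial_state=session_entry.value,
                events=session_events,
            )
        )
        session_events = []
        session_entry = entry_next
        session_elapsed = 0.0

    for episode in range(1, params.n_episodes + 1):
        regressed = bool(episode >= 2 and rng.random() < params.regression_prob)
        lam = contact_rate(params, episode)
        p = {s: targeting_trajectory(params, s, episode, regressed) for s in LOCKS}
        q = {s: opening_trajectory(params, s, episode) for s in LOCKS}
        truth_rows.append(
            {
                "subject_id": params.subject_id,
                "episode": episode,
                "regressed": regressed,
                "lambda": lam,
                **{f"p_{s}": p[s] for s in LOCKS},
                **{f"q_{s}": q[s] for s in LOCKS},
            }
        )
        if _expected_contacts(params, episode, regressed) > params.max_contacts_per_episode:
            raise StallError(
                f"episode {episode} of subject {params.subject_id!r} expects more "
                f"than {params.max_contacts_per_episode} contacts; parameters stall"
            )

        state = LockboxState.WHEEL_LOCKED
        contacts_this_episode = 0
        touched_wheel = False
        while state is not LockboxState.SOLVED:
            contacts_this_episode += 1
            if contacts_this_episode > params.max_contacts_per_episode:
                raise StallError(
                    f"episode {episode} of subject {params.subject_id!r} exceeded "
                    f"the hard cap of {params.max_contacts_per_episode} contacts"
                )
            dt = 0.0
            while dt <= 0.0:
                dt = rng.exponential(1.0 / lam)
            t = session_elapsed + dt
            while t >= cap:
                # session expires before the next contact; carry the residual
                # waiting time into a fresh session (exponential memorylessness
                # makes this equivalent to slicing a continuous timeline)
                close_session(cap, state)
                t -= cap
            # guard against a degenerate float collision with the previous event
            if session_events and t <= session_events[-1].time_s:
                t = math.nextafter(session_events[-1].time_s, math.inf)
            session_elapsed = t

            lock = state.functional_component
            on_target = rng.random() < p[lock]
            if on_target:
                component = lock
            else:
                component = _draw_mistarget(
                    rng,
                    params,
                    lock,
                    old_strategy=(episode == 1 and not touched_wheel),
                )
            if component == "wheel":
                touched_wheel = True
            opens = bool(on_target and rng.random() < q[lock])
            session_events.append(
                ContactEvent(time_s=t, component=component, opens_lock=opens)
            )
            if opens:
                state = state.advance()

        # door opened: the session ends at the solving contact
        close_session(session_elapsed, LockboxState.WHEEL_LOCKED)

    truth = pd.DataFrame(truth_rows)
    result = SimulationResult(params=params, sessions=sessions, truth=truth)
    return result


def _draw_mistarget(
    rng: np.random.Generator,
    params: AgentParams,
    functional: str,
    old_strategy: bool,
) -> str:
    """Pick the component of a mistargeted contact."""
    if old_strategy and params.old_strategy_bias > 0:
        # pre-first-wheel-contact in episode 1: fall back on the strategy that
        # solved the training box without a wheel (act on bar/door)
        if rng.random() < params.old_strategy_bias:
            choices = [c for c in ("bar", "door") if c != functional]
            return choices[int(rng.integers(len(choices)))]
    comps = [c for c in COMPONENTS if c != functional]
    weights = np.array([params.mistarget_weights.get(c, 0.0) for c in comps])
    if weights.sum() <= 0:
        weights = np.ones(len(comps))
    weights = weights / weights.sum()
    return comps[int(rng.choice(len(comps), p=weights))]


def simulate_subject(params: AgentParams) -> list[SessionRecord]:
    """Simulate one subject's full event log (see :func:`run_simulation`)."""
    return run_simulation(params).sessions


def deterministic_truth(params: AgentParams) -> pd.DataFrame:
    """The truth table implied by the trajectories with no regression draws.

    Valid as recovery ground truth only when ``regression_prob == 0``; with
    regression the realised table from :func:`run_simulation` must be used.
    """
    if params.regression_prob > 0:
        logger.warning(
            "deterministic_truth ignores regression episodes "
            "(regression_prob=%.3f > 0); prefer the realised truth table",
            params.regression_prob,
        )
    rows = []
    for episode in range(1, params.n_episodes + 1):
        rows.append(
            {
                "subject_id": params.subject_id,
                "episode": episode,
                "regressed": False,
                "lambda": contact_rate(params, episode),
                **{f"p_{s}": targeting_trajectory(params, s, episode) for s in LOCKS},
                **{f"q_{s}": opening_trajectory(params, s, episode) for s in LOCKS},
            }
        )
    return pd.DataFrame(rows)


def recovery_report(
    params: AgentParams,
    records: Sequence[DecompositionRecord],
    truth: pd.DataFrame | None = None,
    k: float = 4.0,
) -> pd.DataFrame:
    """Compare pipeline estimates against the generative ground truth.

    Rows (columns ``quantity, truth, estimate, tolerance, passed``):

    * ``delta_late_s`` -- mean per-episode inter-contact interval over the
      late half of episodes vs the mean of ``1/lambda`` there;
    * ``pooled_M`` -- ratio of total to correct contacts vs the reciprocal of
      the contact-weighted mean targeting probability;
    * ``mean_E`` -- mean effort per episode vs the mean of
      ``sum_s 1/q_s`` (the geometric expectation per lock);
    * ``logM_slope`` -- fitted slope of ``ln M`` (episodes >= 2) vs the OLS
      slope of the log of the analytically expected M series (only when at
      least 3 episodes enter the fit).

    Tolerances are ``k`` Monte-Carlo standard errors (default 4).
    """
    if not records:
        raise ValidationError("recovery_report needs at least one decomposition record")
    for r in records:
        if r.subject_id != params.subject_id:
            raise ValidationError(
                f"record subject {r.subject_id!r} does not match params subject "
                f"{params.subject_id!r}"
            )
    if truth is None:
        truth = deterministic_truth(params)
    truth = truth.set_index("episode", drop=False)

    recs = sorted(records, key=lambda r: r.solution_index)
    episodes = [r.solution_index for r in recs]
    rows = []

    # --- engagement: late-episode inter-contact interval ------------------
    n = len(recs)
    late = [r for r in recs if r.solution_index > n / 2]
    if len(late) >= 2:
        deltas = np.array([r.delta_s for r in late])
        truth_delta = float(
            np.mean([1.0 / truth.loc[r.solution_index, "lambda"] for r in late])
        )
        est = float(deltas.mean())
        se = float(deltas.std(ddof=1) / math.sqrt(len(deltas)))
        rows.append(("delta_late_s", truth_delta, est, k * se))

    # --- targeting: pooled mistargeting ------------------------------------
    tot_a = sum(r.n_a for r in recs)
    tot_c = sum(r.n_c for r in recs)
    weighted_p = 0.0
    for r in recs:
        for lock in LOCKS:
            weighted_p += r.counts.n_all[lock] * float(
                truth.loc[r.solution_index, f"p_{lock}"]
            )
    weighted_p /= tot_a
    est_M = tot_a / tot_c
    p_hat = tot_c / tot_a
    se_p = math.sqrt(max(p_hat * (1 - p_hat), 0.0) / tot_a)
    tol_M = k * se_p / p_hat**2
    rows.append(("pooled_M", 1.0 / weighted_p, est_M, tol_M))

    # --- skill: mean effort -------------------------------------------------
    eff = np.array([float(r.E) for r in recs])
    truth_E = float(
        np.mean(
            [
                sum(1.0 / float(truth.loc[e, f"q_{lock}"]) for lock in LOCKS)
                for e in episodes
            ]
        )
    )
    se_E = float(eff.std(ddof=1) / math.sqrt(len(eff))) if len(eff) > 1 else 0.0
    rows.append(("mean_E", truth_E, float(eff.mean()), k * se_E))

    # --- slow adaptation: log-M slope --------------------------------------
    usable = [r for r in recs if r.solution_index >= 2]
    if len(usable) >= 3:
        fit = fit_log_linear(recs)
        xs = np.array([float(r.solution_index) for r in usable])
        expected_m = []
        for r in usable:
            e = r.solution_index
            na = sum(
                1.0
                / (float(truth.loc[e, f"p_{s}"]) * float(truth.loc[e, f"q_{s}"]))
                for s in LOCKS
            )
            nc = sum(1.0 / float(truth.loc[e, f"q_{s}"]) for s in LOCKS)
            expected_m.append(na / nc)
        ys = np.log(expected_m)
        xbar, ybar = xs.mean(), ys.mean()
        sxx = float(((xs - xbar) ** 2).sum())
        truth_slope = float(((xs - xbar) * (ys - ybar)).sum() / sxx)
        se_slope = math.sqrt(fit.residual_ss / (fit.n_points - 2) / sxx)
        rows.append(("logM_slope", truth_slope, fit.slope, k * se_slope))

    report = pd.DataFrame(rows, columns=["quantity", "truth", "estimate", "tolerance"])
    report["passed"] = (report["estimate"] - report["truth"]).abs() <= report["tolerance"]
    return report


# ---------------------------------------------------------------------------
# presets and parameter files


def birdlike(subject_id: str = "sim_bird", n_episodes: int = 12, seed: int = 0) -> AgentParams:
    """Default preset qualitatively matching the study animals.

    The first episode takes roughly 1500-4000 simulated seconds: the naive
    agent contacts the salient new wheel often (40% of contacts) but almost
    never manages the rotate-and-displace manoeuvre that removes it
    (opening probability 1.5% per wheel contact).  After the first success,
    targeting jumps and then keeps improving slowly (the slow log-linear
    decline in M), skill and engagement ramp up over a few episodes, and
    later episodes take tens of seconds.  One episode in five regresses to
    naive wheel targeting, producing temporary resurgences of mistargeting.
    """
    return AgentParams(
        subject_id=subject_id,
        n_episodes=n_episodes,
        targeting={
            "wheel": Adaptation(initial=0.40, asymptote=0.95, rate=0.20, jump=0.05),
            "bar": Adaptation(initial=0.40, asymptote=0.95, rate=0.20, jump=0.05),
            "door": Adaptation(initial=0.50, asymptote=0.97, rate=0.20, jump=0.05),
        },
        skill={
            "wheel": Adaptation(initial=0.015, asymptote=0.35, rate=1.40),
            "bar": Adaptation(initial=0.20, asymptote=0.45, rate=1.20),
            "door": Adaptation(initial=0.40, asymptote=0.55, rate=1.20),
        },
        engagement=Adaptation(initial=0.05, asymptote=0.17, rate=2.00),
        regression_prob=0.20,
        old_strategy_bias=0.80,
        mistarget_weights={"wheel": 1.0, "bar": 1.0, "door": 1.0, "other": 3.0},
        seed=seed,
    )


def constant_agent(
    subject_id: str,
    n_episodes: int,
    p: float = 0.5,
    q: float = 1.0,
    rate: float = 0.1,
    seed: int = 0,
) -> AgentParams:
    """An agent with episode-independent parameters (no learning); the
    workhorse of parameter-recovery checks."""
    flat = lambda x: Adaptation(initial=x, asymptote=x, rate=0.0, jump=0.0)
    return AgentParams(
        subject_id=subject_id,
        n_episodes=n_episodes,
        targeting={s: flat(p) for s in LOCKS},
        skill={s: Adaptation(initial=q, asymptote=q, rate=0.0) for s in LOCKS},
        engagement=Adaptation(initial=rate, asymptote=rate, rate=0.0),
        regression_prob=0.0,
        old_strategy_bias=0.0,
        seed=seed,
    )


def _adaptation_to_dict(a: Adaptation) -> dict:
    d = {"initial": a.initial, "asymptote": a.asymptote, "rate": a.rate}
    if a.jump is not None:
        d["jump"] = a.jump
    return d


def params_to_dict(params: AgentParams) -> dict:
    return {
        "subject_id": params.subject_id,
        "n_episodes": params.n_episodes,
        "seed": params.seed,
        "session_cap_s": params.session_cap_s,
        "max_contacts_per_episode": params.max_contacts_per_episode,
        "regression_prob": params.regression_prob,
        "old_strategy_bias": params.old_strategy_bias,
        "mistarget_weights": dict(params.mistarget_weights),
        "targeting": {s: _adaptation_to_dict(params.targeting[s]) for s in LOCKS},
        "skill": {s: _adaptation_to_dict(params.skill[s]) for s in LOCKS},
        "engagement": _adaptation_to_dict(params.engagement),
    }


def _adaptation_from_dict(d: Mapping, where: str) -> Adaptation:
    try:
        return Adaptation(
            initial=float(d["initial"]),
            asymptote=float(d["asymptote"]),
            rate=float(d.get("rate", 0.0)),
            jump=(float(d["jump"]) if "jump" in d and d["jump"] is not None else None),
        )
    except KeyError as exc:
        raise ValidationError(f"{where}: missing field {exc.args[0]!r}") from None


def params_from_dict(d: Mapping) -> AgentParams:
    for req in ("subject_id", "n_episodes", "targeting", "skill", "engagement"):
        if req not in d:
            raise ValidationError(f"agent parameters: missing field {req!r}")
    targeting = {
        s: _adaptation_from_dict(d["targeting"][s], f"targeting[{s}]")
        for s in d["targeting"]
    }
    skill = {s: _adaptation_from_dict(d["skill"][s], f"skill[{s}]") for s in d["skill"]}
    return AgentParams(
        subject_id=str(d["subject_id"]),
        n_episodes=int(d["n_episodes"]),
        targeting=targeting,
        skill=skill,
        engagement=_adaptation_from_dict(d["engagement"], "engagement"),
        regression_prob=float(d.get("regression_prob", 0.0)),
        old_strategy_bias=float(d.get("old_strategy_bias", 0.0)),
        mistarget_weights=dict(
            d.get(
                "mistarget_weights",
                {"wheel": 1.0, "bar": 1.0, "door": 1.0, "other": 3.0},
            )
        ),
        session_cap_s=float(d.get("session_cap_s", DEFAULT_SESSION_CAP_S)),
        max_contacts_per_episode=int(
            d.get("max_contacts_per_episode", DEFAULT_CONTACT_CAP)
        ),
        seed=int(d.get("seed", 0)),
    )


def load_agent_params(path: str | Path) -> list[AgentParams]:
    """Load one or more agent parameter sets from a YAML file.

    The file may contain a single mapping, a list of mappings, or a mapping
    with a top-level ``subjects`` list.
    """
    with Path(path).open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        raise ValidationError(f"{path}: empty parameter file")
    if isinstance(doc, Mapping) and "subjects" in doc:
        doc = doc["subjects"]
    if isinstance(doc, Mapping):
        doc = [doc]
    if not isinstance(doc, list):
        raise ValidationError(f"{path}: expected a mapping or list of mappings")
    return [params_from_dict(entry) for entry in doc]


def save_agent_params(params: Sequence[AgentParams] | AgentParams, path: str | Path) -> None:
    """Write agent parameter sets to YAML (inverse of :func:`load_agent_params`)."""
    if isinstance(params, AgentParams):
        doc: object = params_to_dict(params)
    else:
        doc = [params_to_dict(p) for p in params]
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
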