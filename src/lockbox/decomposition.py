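"""Exact multiplicative decomposition of time-to-solution.

For a complete solution episode with ``n_a`` contacts in total and ``n_c``
contacts on the currently functional component ("correct" contacts), the
time-to-solution factors exactly as::

    T = (n_a / n_c) * n_c * (T / n_a) = M * E * Delta

where

* ``M = n_a / n_c`` is *mistargeting of actions* -- how many contacts were
  made per functionally useful contact.  ``M = 1`` means every contact was on
  the component that could advance the task; its reciprocal ``p = 1/M`` is
  the empirical probability of touching a functionally relevant part.
* ``E = n_c`` is *effort* -- the number of correctly targeted contacts needed
  to open all locks, a proxy for sensorimotor skill.
* ``Delta = T / n_a`` is the *inter-contact interval* -- seconds per contact,
  operationalising engagement (lower Delta = higher engagement).

The identity holds by construction, so it is a consistency check on any
pipeline that computes the three factors from the same event stream.

Correct contacts are counted per state: ``n_w`` is the number of wheel
contacts made while the wheel still blocked the task, and so on; contacts on
non-lock surfaces ("other") count toward ``n_a`` only.  Slow adaptation is
summarised by an ordinary least-squares fit of ``ln M`` against solution
index, by default excluding the first solution, where the steep initial drop
would dominate the trend.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Sequence

from .errors import IncompleteEpisodeError, InsufficientDataError, LockboxError
from .io_ethogram import LOCKS
from .task_model import LockboxState, SolutionEpisode

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StateContactCounts:
    """Per-state contact tallies for one episode.

    ``n_all[s]`` counts every contact made while lock ``s`` was the
    functional component (any component, including ``other``);
    ``n_correct[s]`` counts only the contacts on ``s`` itself.
    """

    n_all: Mapping[str, int]
    n_correct: Mapping[str, int]

    def __post_init__(self) -> None:
        for s in LOCKS:
            if not 0 <= self.n_correct[s] <= self.n_all[s]:
                raise LockboxError(
                    f"inconsistent counts for state {s!r}: "
                    f"correct={self.n_correct[s]}, all={self.n_all[s]}"
                )

    @property
    def n_a(self) -> int:
        """Total contacts across all states."""
        return sum(self.n_all[s] for s in LOCKS)

    @property
    def n_c(self) -> int:
        """Total correctly targeted contacts across all states."""
        return sum(self.n_correct[s] for s in LOCKS)


@dataclass(frozen=True)
class DecompositionRecord:
    """Per-episode quantities of the multiplicative decomposition."""

    subject_id: str
    solution_index: int
    T_s: float
    n_a: int
    n_c: int
    M: float
    E: int
    delta_s: float
    p: float
    counts: StateContactCounts
    complete: bool = True


@dataclass(frozen=True)
class TrendFit:
    """Ordinary least-squares fit of ``ln M`` on solution index.

    ``slope`` is the per-solution change of ``ln M``; ``intercept`` the
    fitted ``ln M`` at solution index 0.
    """

    slope: float
    intercept: float
    n_points: int
    residual_ss: float


def count_contacts(episode: SolutionEpisode) -> StateContactCounts:
    """Partition an episode's state-annotated events into per-state tallies."""
    n_all = {s: 0 for s in LOCKS}
    n_correct = {s: 0 for s in LOCKS}
    for aev in episode.events:
        if aev.state is LockboxState.SOLVED:
            raise LockboxError(
                f"episode {episode.episode_index} of subject "
                f"{episode.subject_id!r} contains a post-solution event; "
                "segmentation should have excluded it"
            )
        lock = aev.state.functional_component
        n_all[lock] += 1
        if aev.event.component == lock:
            n_correct[lock] += 1
    return StateContactCounts(
        n_all=MappingProxyType(n_all), n_correct=MappingProxyType(n_correct)
    )


def compute_decomposition(episode: SolutionEpisode) -> DecompositionRecord:
    """Compute ``T``, ``n_a``, ``n_c``, ``M``, ``E`` and ``Delta`` for one
    complete episode.

    Raises
    ------
    IncompleteEpisodeError
        If the episode never opened the door; ``M`` is undefined when locks
        remain unopened.
    """
    if not episode.complete:
        raise IncompleteEpisodeError(
            f"episode {episode.episode_index} of subject {episode.subject_id!r} "
            "is incomplete; M/E/Delta are undefined"
        )
    counts = count_contacts(episode)
    n_a, n_c = counts.n_a, counts.n_c
    if n_a < 3 or any(counts.n_correct[s] < 1 for s in LOCKS):
        raise LockboxError(
            f"complete episode {episode.episode_index} of subject "
            f"{episode.subject_id!r} must contain at least one correct contact "
            f"per lock (got {dict(counts.n_correct)})"
        )
    M = n_a / n_c
    delta = episode.T_s / n_a
    return DecompositionRecord(
        subject_id=episode.subject_id,
        solution_index=episode.episode_index,
        T_s=episode.T_s,
        n_a=n_a,
        n_c=n_c,
        M=M,
        E=n_c,
        delta_s=delta,
        p=n_c / n_a,
        counts=counts,
        complete=True,
    )


def decomposition_table(episodes: Sequence[SolutionEpisode]) -> list[DecompositionRecord]:
    """Decompose every complete episode of one subject, in solution order.

    Incomplete trailing episodes are omitted (and reported via the module
    logger): their metrics are undefined.
    """
    records: list[DecompositionRecord] = []
    omitted = 0
    for ep in sorted(episodes, key=lambda e: e.episode_index):
        if ep.complete:
            records.append(compute_decomposition(ep))
        else:
            omitted += 1
    if omitted:
        logger.warning(
            "omitted %d incomplete episode(s) for subject %r",
            omitted,
            episodes[0].subject_id if episodes else "?",
        )
    return records


def fit_log_linear(
    records: Sequence[DecompositionRecord], include_first: bool = False
) -> TrendFit:
    """Fit ``ln M = intercept + slope * solution_index`` by ordinary least
    squares.

    By default only solutions with index >= 2 enter the fit; the steep drop
    into the first solution is a separate (fast) adaptation process.  The
    closed-form centred OLS solution is used, so exactly log-linear input is
    recovered to machine precision.
    """
    first = 1 if include_first else 2
    usable = [r for r in records if r.solution_index >= first]
    if len(usable) < 2:
        raise InsufficientDataError(
            f"log-linear trend fit needs at least 2 usable episodes, got {len(usable)}"
        )
    xs = [float(r.solution_index) for r in usable]
    ys = [math.log(r.M) for r in usable]
    n = len(xs)
    xbar = sum(xs) / n
    ybar = sum(ys) / n
    sxx = sum((x - xbar) ** 2 for x in xs)
    sxy = sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys))
    if sxx == 0:
        raise InsufficientDataError("all usable episodes share one solution index")
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    residual_ss = sum((y - (intercept + slope * x)) ** 2 for x, y in zip(xs, ys))
    return TrendFit(slope=slope, intercept=intercept, n_points=n, residual_ss=residual_ss)
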