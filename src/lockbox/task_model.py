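"""Lockbox state machine, state annotation and solution-episode segmentation.

The apparatus is a strictly sequential chain of three locks: a wheel that
must be rotated and pulled off its axle, a bar that must be shifted aside,
and finally the door to the reward.  At any moment exactly one component is
*functional* -- the only one whose manipulation can advance the task.  The
state machine is therefore a simple chain::

    WHEEL_LOCKED -> BAR_LOCKED -> DOOR_LOCKED -> SOLVED

with no skips and no reversals within an episode.

A *solution episode* is everything a subject did between two consecutive
openings of the door.  Episodes routinely span several 15-minute sessions
before the first solution; time between sessions does not count, so the
episode's time-to-solution ``T`` sums full durations of intervening unsolved
sessions plus the elapsed time within the session where the door finally
opened.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Sequence

from .errors import MechanicalImpossibilityError, ValidationError
from .io_ethogram import ContactEvent, SessionRecord

logger = logging.getLogger(__name__)


class LockboxState(enum.Enum):
    """State of the sequential lockbox, named after the lock that currently
    blocks progress."""

    WHEEL_LOCKED = "wheel_locked"
    BAR_LOCKED = "bar_locked"
    DOOR_LOCKED = "door_locked"
    SOLVED = "solved"

    @property
    def functional_component(self) -> str | None:
        """The single component whose manipulation advances the task
        (``None`` once solved)."""
        return _FUNCTIONAL[self]

    @property
    def order(self) -> int:
        return _ORDER[self]

    def advance(self) -> "LockboxState":
        """The state after the current functional lock opens."""
        if self is LockboxState.SOLVED:
            raise ValidationError("cannot advance past SOLVED")
        return _CHAIN[_ORDER[self] + 1]


_CHAIN = [
    LockboxState.WHEEL_LOCKED,
    LockboxState.BAR_LOCKED,
    LockboxState.DOOR_LOCKED,
    LockboxState.SOLVED,
]
_ORDER = {s: i for i, s in enumerate(_CHAIN)}
_FUNCTIONAL = {
    LockboxState.WHEEL_LOCKED: "wheel",
    LockboxState.BAR_LOCKED: "bar",
    LockboxState.DOOR_LOCKED: "door",
    LockboxState.SOLVED: None,
}


@dataclass(frozen=True)
class AnnotatedEvent:
    """A contact event tagged with the task state in force when it began."""

    event: ContactEvent
    state: LockboxState


@dataclass
class SolutionEpisode:
    """All annotated events between consecutive door openings.

    ``segments`` holds ``(session_index, annotated events)`` pairs in session
    order; an episode that spans sessions has several segments.  ``T_s`` is
    the cumulative in-session time from the start of the episode's first
    session to the door-opening event (for incomplete trailing episodes, all
    observed time so far).
    """

    subject_id: str
    episode_index: int
    segments: list[tuple[int, list[AnnotatedEvent]]] = field(default_factory=list)
    T_s: float = 0.0
    complete: bool = False

    @property
    def events(self) -> list[AnnotatedEvent]:
        """All annotated events of the episode, flattened in time order."""
        return [ev for _, seg in self.segments for ev in seg]

    @property
    def n_events(self) -> int:
        return sum(len(seg) for _, seg in self.segments)


def annotate_states(
    session: SessionRecord, entry_state: LockboxState
) -> tuple[list[AnnotatedEvent], LockboxState]:
    """Tag each event of a session with the state it occurred in.

    The state advances immediately *after* an event with ``opens_lock=True``
    on the currently functional component, so the opening contact itself is
    attributed to the state it resolved.  Returns the annotated events and
    the exit state of the session.

    Raises
    ------
    MechanicalImpossibilityError
        If an event claims to open a component that is not functional in the
        current state (e.g. the bar opening while the wheel is attached).
    ValidationError
        If an event claims to open component ``other``.
    """
    session.validate()
    state = entry_state
    annotated: list[AnnotatedEvent] = []
    for ev in session.events:
        if ev.opens_lock:
            if ev.component == "other":
                raise ValidationError(
                    f"opens_lock=true on component 'other' at t={ev.time_s!r} "
                    f"(subject {session.subject_id!r}, session {session.session_index})"
                )
            if ev.component != state.functional_component:
                raise MechanicalImpossibilityError(
                    f"component {ev.component!r} cannot open in state {state.value!r} "
                    f"at t={ev.time_s!r} (subject {session.subject_id!r}, "
                    f"session {session.session_index})"
                )
        annotated.append(AnnotatedEvent(event=ev, state=state))
        if ev.opens_lock:
            state = state.advance()
    return annotated, state


def segment_episodes(sessions: Sequence[SessionRecord]) -> list[SolutionEpisode]:
    """Split one subject's ordered sessions into solution episodes.

    Episode ``k`` begins at the start of the first session after solution
    ``k-1`` (or the first session overall) and ends at the ``k``-th
    door-opening event.  ``T_s`` accumulates full durations of intervening
    unsolved sessions plus the elapsed in-session time of boundary sessions;
    the gaps between sessions contribute nothing.

    Mid-episode the lockbox state must carry over from one session to the
    next: the declared ``initial_state`` of a continuation session has to
    equal the previous session's exit state, with one sanctioned override --
    a full experimenter reset back to ``wheel_locked`` (the wheel
    re-attached), which the ``initial_state`` column records.  Any other
    discontinuity raises :class:`ValidationError` naming both sessions.

    Events occurring after the door opened within a session belong to no
    episode; they are counted and reported through a logger warning.

    At most one trailing incomplete episode is returned, with
    ``complete=False``; downstream metrics exclude it.
    """
    if not sessions:
        return []
    subject = sessions[0].subject_id
    for rec in sessions:
        if rec.subject_id != subject:
            raise ValidationError(
                f"segment_episodes expects one subject, got {subject!r} and "
                f"{rec.subject_id!r}"
            )
    ordered = sorted(sessions, key=lambda r: r.session_index)
    for a, b in zip(ordered, ordered[1:]):
        if b.session_index == a.session_index:
            raise ValidationError(
                f"duplicate session_index {a.session_index} for subject {subject!r}"
            )

    episodes: list[SolutionEpisode] = []
    current = SolutionEpisode(subject_id=subject, episode_index=1)
    in_progress = False  # current episode has accumulated any observed time
    carry_state: LockboxState | None = None  # exit state of the previous session
    prev_index: int | None = None
    post_solution_events = 0

    for rec in ordered:
        declared = LockboxState(rec.initial_state)
        if in_progress and carry_state is not None and declared is not carry_state:
            if declared is not LockboxState.WHEEL_LOCKED:
                raise ValidationError(
                    f"state continuity broken for subject {subject!r}: session "
                    f"{prev_index} ended in {carry_state.value!r} but session "
                    f"{rec.session_index} declares initial_state {declared.value!r} "
                    f"(only a full reset to 'wheel_locked' is a valid override)"
                )
            logger.warning(
                "subject %r session %d: initial_state reset to wheel_locked "
                "overriding carried state %s",
                subject,
                rec.session_index,
                carry_state.value,
            )
        annotated, exit_state = annotate_states(rec, declared)

        solved_at = None
        for i, aev in enumerate(annotated):
            if aev.state is LockboxState.DOOR_LOCKED and aev.event.opens_lock:
                solved_at = i
                break
        if solved_at is not None:
            current.segments.append((rec.session_index, annotated[: solved_at + 1]))
            current.T_s += annotated[solved_at].event.time_s
            current.complete = True
            episodes.append(current)
            post_solution_events += len(annotated) - (solved_at + 1)
            current = SolutionEpisode(subject_id=subject, episode_index=len(episodes) + 1)
            in_progress = False
            carry_state = None
        else:
            current.T_s += rec.duration_s
            if annotated:
                current.segments.append((rec.session_index, annotated))
            in_progress = True
            carry_state = exit_state
        prev_index = rec.session_index

    if in_progress:
        episodes.append(current)

    if post_solution_events:
        logger.warning(
            "subject %r: %d event(s) after a door opening were assigned to no episode",
            subject,
            post_solution_events,
        )
    return episodes
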