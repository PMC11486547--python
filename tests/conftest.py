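"""Shared fixtures: hand-built event logs with known decompositions."""

from __future__ import annotations

import pytest

from lockbox import ContactEvent, SessionRecord


@pytest.fixture
def worked_session() -> SessionRecord:
    """Single 50 s session solving the box in 5 contacts.

    States run [wheel, wheel, wheel, bar, door]; three wheel-state contacts
    (two on the wheel, one stray on the bar), then one bar and one door
    contact, each opening.  Hand enumeration gives n_a=5, n_c=4, M=1.25,
    E=4, Delta=10 s, T=50 s.
    """
    return SessionRecord(
        subject_id="bird1",
        session_index=1,
        duration_s=50.0,
        initial_state="wheel_locked",
        events=[
            ContactEvent(10.0, "wheel"),
            ContactEvent(20.0, "bar"),
            ContactEvent(30.0, "wheel", opens_lock=True),
            ContactEvent(40.0, "bar", opens_lock=True),
            ContactEvent(50.0, "door", opens_lock=True),
        ],
    )


@pytest.fixture
def spanning_sessions() -> list[SessionRecord]:
    """One episode spanning two sessions: a full unsolved 900 s session with
    two contacts, then a solution 70 s into the next session.

    Hand sum: T = 900 + 70 = 970 s over n_a=5 contacts, so Delta = 194 s;
    the counts match the worked session (n_c=4, M=1.25, E=4).
    """
    return [
        SessionRecord(
            subject_id="bird1",
            session_index=1,
            duration_s=900.0,
            initial_state="wheel_locked",
            events=[ContactEvent(100.0, "wheel"), ContactEvent(500.0, "bar")],
        ),
        SessionRecord(
            subject_id="bird1",
            session_index=2,
            duration_s=70.0,
            initial_state="wheel_locked",
            events=[
                ContactEvent(30.0, "wheel", opens_lock=True),
                ContactEvent(50.0, "bar", opens_lock=True),
                ContactEvent(70.0, "door", opens_lock=True),
            ],
        ),
    ]


@pytest.fixture
def perfect_session() -> SessionRecord:
    """Perfectly efficient 30 s episode: three contacts, each correct and
    opening, so M=1, E=3, Delta=10 s."""
    return SessionRecord(
        subject_id="bird2",
        session_index=1,
        duration_s=30.0,
        initial_state="wheel_locked",
        events=[
            ContactEvent(10.0, "wheel", opens_lock=True),
            ContactEvent(20.0, "bar", opens_lock=True),
            ContactEvent(30.0, "door", opens_lock=True),
        ],
    )
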