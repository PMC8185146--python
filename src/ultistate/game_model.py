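"""Field geometry, zones and the possession state machine.

A possession is modeled as a walk through team-relative field zones
(the four transient states) that begins in a starting state (a pull
received or an earned turnover) and ends in an absorbing state (a
point, a forced or unforced turnover, or a period end).  Every throw
is a transition; the model is length-only, with no lateral coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Tuple


class Zone(str, Enum):
    """Team-relative field segment occupied by the disc.

    ``END``/``REAR``/``MID``/``FRONT`` are the four transient states of
    the model, ordered from the attacking team's own end zone toward the
    opponent's.  ``OPP_END`` is the pseudo-destination used only for
    scoring catches (and as the nominal start zone of a Callahan).
    """

    END = "END"
    REAR = "REAR"
    MID = "MID"
    FRONT = "FRONT"
    OPP_END = "OPP_END"


#: The four transient states, in downfield order for the attacking team.
TRANSIENT_ZONES: Tuple[Zone, ...] = (Zone.END, Zone.REAR, Zone.MID, Zone.FRONT)


class StateLabel(str, Enum):
    """All states of the possession state machine."""

    START_PULL = "START_PULL"
    START_EARNED_TO = "START_EARNED_TO"
    END = "END"
    REAR = "REAR"
    MID = "MID"
    FRONT = "FRONT"
    POINT = "POINT"
    TO_FORCED = "TO_FORCED"
    TO_UNFORCED = "TO_UNFORCED"
    PERIOD_END = "PERIOD_END"


STARTING_STATES = (StateLabel.START_PULL, StateLabel.START_EARNED_TO)
TRANSIENT_STATES = (StateLabel.END, StateLabel.REAR, StateLabel.MID, StateLabel.FRONT)
ABSORBING_STATES = (
    StateLabel.POINT,
    StateLabel.TO_FORCED,
    StateLabel.TO_UNFORCED,
    StateLabel.PERIOD_END,
)


class Outcome(str, Enum):
    """Result of a single throw."""

    COMPLETED = "COMPLETED"
    SCORE = "SCORE"
    TO_FORCED = "TO_FORCED"
    TO_UNFORCED = "TO_UNFORCED"


_OUTCOME_TO_ABSORBING = {
    Outcome.SCORE: StateLabel.POINT,
    Outcome.TO_FORCED: StateLabel.TO_FORCED,
    Outcome.TO_UNFORCED: StateLabel.TO_UNFORCED,
}


def state_of_zone(zone: Zone) -> StateLabel:
    """Map a transient zone to its state label."""
    if zone not in TRANSIENT_ZONES:
        raise ValueError(f"{zone} is not a transient zone")
    return StateLabel(zone.value)


class OutOfBoundsError(ValueError):
    """A field position outside [0, total_length]."""


@dataclass(frozen=True)
class FieldGeometry:
    """Yard-line layout of the field along its length.

    ``boundary_yardlines`` are the absolute positions delimiting, in
    order, the attacking team's own end zone, the rear zone, the mid
    zone, the front zone and the attacked end zone.  The defaults
    follow the American-football yard lines used in AUDL play: end
    zones 20 yards deep, rear and front zones 25 yards, mid zone 30
    yards, 120 yards in total.
    """

    total_length: float = 120.0
    boundary_yardlines: Tuple[float, ...] = (0.0, 20.0, 45.0, 75.0, 100.0, 120.0)

    def __post_init__(self) -> None:
        b = self.boundary_yardlines
        if len(b) != 6:
            raise ValueError("expected 6 boundary yard lines (5 segments)")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundary yard lines must be strictly increasing")
        if b[0] != 0:
            raise ValueError("first boundary must be 0")
        if b[-1] != self.total_length:
            raise ValueError("last boundary must equal total_length")

    @property
    def segment_depths(self) -> Tuple[float, ...]:
        """Depths of the five segments (own end, rear, mid, front, opp end)."""
        b = self.boundary_yardlines
        return tuple(b[i + 1] - b[i] for i in range(len(b) - 1))


#: Segment index -> team-relative zone, attacking direction +1.
_SEGMENT_ZONES = (Zone.END, Zone.REAR, Zone.MID, Zone.FRONT, Zone.OPP_END)


def classify_zone(
    absolute_yard: float,
    attacking_direction: int = 1,
    geometry: FieldGeometry = FieldGeometry(),
) -> Zone:
    """Team-relative zone containing an absolute field position.

    Intervals are half-open in the attacking direction: a shared
    boundary yard line belongs to the downfield zone.  For a team
    attacking in the -1 direction the position is mirrored about the
    field midpoint, so ``classify_zone(y, -1)`` equals
    ``classify_zone(total_length - y, +1)``.
    """
    if attacking_direction not in (1, -1):
        raise ValueError("attacking_direction must be +1 or -1")
    if not (0 <= absolute_yard <= geometry.total_length):
        raise OutOfBoundsError(
            f"position {absolute_yard} outside field [0, {geometry.total_length}]"
        )
    y = absolute_yard if attacking_direction == 1 else geometry.total_length - absolute_yard
    b = geometry.boundary_yardlines
    for i in range(5):
        if b[i] <= y < b[i + 1]:
            return _SEGMENT_ZONES[i]
    return Zone.OPP_END  # y == total_length


def allowed_transition(
    from_state: StateLabel, to_state: StateLabel, callahan_flag: bool = False
) -> bool:
    """Whether the transition appears in the model's transition matrix.

    Forbidden: pull -> point, pull -> turnover, earned turnover ->
    turnover, earned turnover -> point (unless it is a Callahan), any
    transition out of an absorbing state, and any transition into a
    starting state.
    """
    from_state = StateLabel(from_state)
    to_state = StateLabel(to_state)
    if from_state in ABSORBING_STATES:
        return False
    if to_state in STARTING_STATES:
        return False
    if from_state is StateLabel.START_PULL:
        return to_state in TRANSIENT_STATES
    if from_state is StateLabel.START_EARNED_TO:
        if to_state is StateLabel.POINT:
            return callahan_flag
        return to_state in TRANSIENT_STATES
    # transient origin: passes anywhere (same zone, adjacent, cross-zone),
    # scores, turnovers, or period-end censoring
    return True


@dataclass(frozen=True)
class ThrowEvent:
    """One throw by the team in possession.

    For a completed pass ``destination`` is the transient zone of the
    catch; for a score it is ``OPP_END``; for a turnover it is the zone
    where the disc was last held (the origin).  ``callahan_flag`` marks
    the pseudo-event of a Callahan score, the only event whose origin
    is ``OPP_END``.
    """

    origin_zone: Zone
    destination: Zone
    outcome: Outcome
    absolute_yard: Optional[float] = None
    callahan_flag: bool = False

    def __post_init__(self) -> None:
        if (self.outcome is Outcome.SCORE) != (self.destination is Zone.OPP_END):
            raise ValueError("outcome is SCORE iff destination is OPP_END")
        if self.callahan_flag:
            if self.outcome is not Outcome.SCORE:
                raise ValueError("a Callahan event must be a score")
        elif self.origin_zone not in TRANSIENT_ZONES:
            raise ValueError("throw origin must be a transient zone")


@dataclass(frozen=True)
class PossessionRecord:
    """One uninterrupted spell of disc control by one team."""

    point_index: int
    possession_index: int
    team: str
    start_state: StateLabel
    start_zone: Zone
    events: Tuple[ThrowEvent, ...]
    end_state: StateLabel
    quarter: int = 1
    pull_timestamp_s: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "start_state", StateLabel(self.start_state))
        object.__setattr__(self, "end_state", StateLabel(self.end_state))
        object.__setattr__(self, "start_zone", Zone(self.start_zone))

    @property
    def is_callahan(self) -> bool:
        return any(e.callahan_flag for e in self.events)

    @property
    def completed_passes(self) -> int:
        """Completed passes, counting the scoring catch, excluding Callahans."""
        return sum(
            1
            for e in self.events
            if e.outcome in (Outcome.COMPLETED, Outcome.SCORE) and not e.callahan_flag
        )


@dataclass(frozen=True)
class Violation:
    """One state-machine or bookkeeping violation found in a possession."""

    code: str
    message: str
    event_index: Optional[int] = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f" (event {self.event_index})" if self.event_index is not None else ""
        return f"[{self.code}]{where} {self.message}"


def validate_possession(p: PossessionRecord) -> list:
    """Check a possession against the state machine.

    Returns a list of :class:`Violation` (empty iff the possession is
    legal): the start state must be a starting state and the end state
    absorbing; consecutive states must be allowed transitions; each
    throw's origin must equal the previous throw's destination (zone
    continuity); no events may follow an absorbing outcome.
    """
    violations = []

    if p.start_state not in STARTING_STATES:
        violations.append(
            Violation("bad_start", f"start_state {p.start_state.value} is not a starting state")
        )
    if p.end_state not in ABSORBING_STATES:
        violations.append(
            Violation("bad_end", f"end_state {p.end_state.value} is not an absorbing state")
        )

    callahan = p.is_callahan
    if callahan:
        if p.start_state is not StateLabel.START_EARNED_TO:
            violations.append(
                Violation("callahan_start", "a Callahan possession must start from an earned turnover")
            )
        if len(p.events) != 1 or p.end_state is not StateLabel.POINT:
            violations.append(
                Violation(
                    "callahan_events",
                    "a Callahan possession has no events other than the score",
                )
            )
        if not allowed_transition(p.start_state, StateLabel.POINT, callahan_flag=True):
            violations.append(
                Violation("forbidden", f"{p.start_state.value} -> POINT is forbidden")
            )
        return violations

    if not p.events:
        # only a period-end truncation may leave a possession throwless
        if p.end_state is not StateLabel.PERIOD_END:
            violations.append(
                Violation(
                    "empty",
                    f"possession with no throws cannot end in {p.end_state.value}",
                )
            )
        return violations

    if p.start_zone not in TRANSIENT_ZONES:
        violations.append(
            Violation("bad_start_zone", f"start zone {p.start_zone.value} is not transient")
        )
        return violations

    # starting state -> first zone
    first_zone_state = state_of_zone(p.events[0].origin_zone)
    if not allowed_transition(p.start_state, first_zone_state):
        violations.append(
            Violation(
                "forbidden",
                f"{p.start_state.value} -> {first_zone_state.value} is forbidden",
                event_index=0,
            )
        )
    if p.events[0].origin_zone is not p.start_zone:
        violations.append(
            Violation(
                "continuity",
                f"first throw origin {p.events[0].origin_zone.value} differs from "
                f"start zone {p.start_zone.value}",
                event_index=0,
            )
        )

    for i, ev in enumerate(p.events):
        if i > 0:
            prev = p.events[i - 1]
            if prev.outcome is not Outcome.COMPLETED:
                violations.append(
                    Violation(
                        "after_absorbing",
                        f"event follows absorbing outcome {prev.outcome.value}",
                        event_index=i,
                    )
                )
                continue
            if ev.origin_zone is not prev.destination:
                violations.append(
                    Violation(
                        "continuity",
                        f"throw origin {ev.origin_zone.value} differs from previous "
                        f"destination {prev.destination.value}",
                        event_index=i,
                    )
                )
        origin_state = state_of_zone(ev.origin_zone) if ev.origin_zone in TRANSIENT_ZONES else None
        if origin_state is not None:
            if ev.outcome is Outcome.COMPLETED:
                to_state = state_of_zone(ev.destination)
            else:
                to_state = _OUTCOME_TO_ABSORBING[ev.outcome]
            if not allowed_transition(origin_state, to_state):
                violations.append(
                    Violation(
                        "forbidden",
                        f"{origin_state.value} -> {to_state.value} is forbidden",
                        event_index=i,
                    )
                )

    last = p.events[-1]
    if last.outcome is Outcome.COMPLETED:
        if p.end_state is not StateLabel.PERIOD_END:
            violations.append(
                Violation(
                    "dangling",
                    "last throw completed but possession does not end in PERIOD_END",
                )
            )
    else:
        expected_end = _OUTCOME_TO_ABSORBING[last.outcome]
        if p.end_state is not expected_end:
            violations.append(
                Violation(
                    "end_mismatch",
                    f"last outcome {last.outcome.value} implies end state "
                    f"{expected_end.value}, got {p.end_state.value}",
                )
            )

    return violations


#: Perspective flip between the two teams' zone labels (Fig-2-style
#: mirror): the thrower's mid zone is the opponent's mid zone, the
#: thrower's front is the opponent's rear, and so on.
MIRROR_ZONE = {
    Zone.END: Zone.OPP_END,
    Zone.REAR: Zone.FRONT,
    Zone.MID: Zone.MID,
    Zone.FRONT: Zone.REAR,
    Zone.OPP_END: Zone.END,
}


def mirror_start_zone(occurrence_zone: Zone) -> Zone:
    """Zone where the earning team's possession begins after a turnover.

    The turnover's occurrence zone (thrower's perspective) is mirrored
    into the earner's perspective.  A turnover occurring inside the
    thrower's own end zone would mirror to the earner's attacking end
    zone; play restarts at the goal line, so it is clamped to FRONT.
    """
    z = MIRROR_ZONE[Zone(occurrence_zone)]
    return Zone.FRONT if z is Zone.OPP_END else z
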