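"""Geometry, zone classification and the possession state machine."""

import pytest
from hypothesis import given, settings, strategies as st

from ultistate import (
    FieldGeometry,
    Outcome,
    StateLabel,
    ThrowEvent,
    TRANSIENT_ZONES,
    Zone,
    allowed_transition,
    classify_zone,
    mirror_start_zone,
    validate_possession,
)
from ultistate.game_model import (
    ABSORBING_STATES,
    OutOfBoundsError,
    STARTING_STATES,
    TRANSIENT_STATES,
    PossessionRecord,
)


class TestFieldGeometry:
    def test_default_depths_match_yardline_definitions(self):
        # end zones 20 yd, rear/front 25 yd, mid 30 yd
        assert FieldGeometry().segment_depths == (20, 25, 30, 25, 20)

    def test_depths_sum_to_field_length(self):
        geom = FieldGeometry()
        assert sum(geom.segment_depths) == geom.total_length == 120

    @pytest.mark.parametrize(
        "boundaries",
        [
            (0, 20, 45, 75, 100),  # too few
            (0, 45, 20, 75, 100, 120),  # not increasing
            (5, 20, 45, 75, 100, 120),  # first not 0
            (0, 20, 45, 75, 100, 110),  # last not total_length
        ],
    )
    def test_bad_boundaries_rejected(self, boundaries):
        with pytest.raises(ValueError):
            FieldGeometry(boundary_yardlines=boundaries)


class TestClassifyZone:
    @pytest.mark.parametrize(
        "yard, direction, expected",
        [
            (50, 1, Zone.MID),  # between the two 35-yard lines
            (45, 1, Zone.MID),  # shared boundary belongs downfield
            (15, 1, Zone.END),  # behind the attacking team's 10-yard line
            (15, -1, Zone.OPP_END),  # same spot, mirrored perspective
            (0, 1, Zone.END),
            (120, 1, Zone.OPP_END),
            (99.9, 1, Zone.FRONT),
            (100, 1, Zone.OPP_END),
        ],
    )
    def test_examples(self, yard, direction, expected):
        assert classify_zone(yard, direction) is expected

    def test_out_of_bounds(self):
        with pytest.raises(OutOfBoundsError):
            classify_zone(-1, 1)
        with pytest.raises(OutOfBoundsError):
            classify_zone(121, 1)

    def test_bad_direction(self):
        with pytest.raises(ValueError):
            classify_zone(50, 2)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=0, max_value=120, allow_nan=False))
    def test_mirror_property(self, yard):
        geom = FieldGeometry()
        assert classify_zone(yard, -1, geom) is classify_zone(
            geom.total_length - yard, 1, geom
        )


class TestAllowedTransition:
    def test_pull_cannot_reach_point_or_turnover(self):
        assert not allowed_transition(StateLabel.START_PULL, StateLabel.POINT)
        assert not allowed_transition(StateLabel.START_PULL, StateLabel.TO_FORCED)
        assert not allowed_transition(StateLabel.START_PULL, StateLabel.TO_UNFORCED)

    def test_earned_turnover_cannot_reach_turnover(self):
        assert not allowed_transition(StateLabel.START_EARNED_TO, StateLabel.TO_FORCED)
        assert not allowed_transition(StateLabel.START_EARNED_TO, StateLabel.TO_UNFORCED)

    def test_callahan_is_the_only_earned_to_point_transition(self):
        assert not allowed_transition(StateLabel.START_EARNED_TO, StateLabel.POINT)
        assert allowed_transition(
            StateLabel.START_EARNED_TO, StateLabel.POINT, callahan_flag=True
        )

    def test_zone_transitions_allowed(self):
        assert allowed_transition(StateLabel.MID, StateLabel.FRONT)
        assert allowed_transition(StateLabel.MID, StateLabel.MID)  # within-zone
        assert allowed_transition(StateLabel.REAR, StateLabel.FRONT)  # cross-zone huck
        assert allowed_transition(StateLabel.FRONT, StateLabel.POINT)

    def test_no_transitions_out_of_absorbing_states(self):
        for absorbing in ABSORBING_STATES:
            for to_state in StateLabel:
                assert not allowed_transition(absorbing, to_state)

    def test_no_transitions_into_starting_states(self):
        for from_state in StateLabel:
            for start in STARTING_STATES:
                assert not allowed_transition(from_state, start)

    def test_starts_reach_only_transient_zones(self):
        for start in STARTING_STATES:
            for zone_state in TRANSIENT_STATES:
                assert allowed_transition(start, zone_state)


def _record(start_state, start_zone, events, end_state):
    return PossessionRecord(1, 1, "A", start_state, start_zone, tuple(events), end_state)


class TestValidatePossession:
    def test_legal_sequence(self, mini_log):
        assert validate_possession(mini_log.possessions[0]) == []

    def test_forbidden_pull_to_point(self):
        # a possession claiming a score with no throws is a pull->point pair
        rec = _record(StateLabel.START_PULL, Zone.REAR, [], StateLabel.POINT)
        violations = validate_possession(rec)
        assert violations and any(v.code == "empty" for v in violations)

    def test_continuity_violation(self):
        rec = _record(
            StateLabel.START_PULL,
            Zone.REAR,
            [
                ThrowEvent(Zone.REAR, Zone.MID, Outcome.COMPLETED),
                ThrowEvent(Zone.FRONT, Zone.OPP_END, Outcome.SCORE),  # origin != MID
            ],
            StateLabel.POINT,
        )
        assert any(v.code == "continuity" for v in validate_possession(rec))

    def test_end_state_must_match_last_outcome(self):
        rec = _record(
            StateLabel.START_PULL,
            Zone.REAR,
            [ThrowEvent(Zone.REAR, Zone.REAR, Outcome.TO_FORCED)],
            StateLabel.TO_UNFORCED,
        )
        assert any(v.code == "end_mismatch" for v in validate_possession(rec))

    def test_events_after_absorbing_outcome(self):
        rec = _record(
            StateLabel.START_PULL,
            Zone.REAR,
            [
                ThrowEvent(Zone.REAR, Zone.REAR, Outcome.TO_FORCED),
                ThrowEvent(Zone.REAR, Zone.MID, Outcome.COMPLETED),
            ],
            StateLabel.TO_FORCED,
        )
        assert any(v.code == "after_absorbing" for v in validate_possession(rec))

    def test_callahan_possession_is_legal(self):
        rec = _record(
            StateLabel.START_EARNED_TO,
            Zone.OPP_END,
            [ThrowEvent(Zone.OPP_END, Zone.OPP_END, Outcome.SCORE, callahan_flag=True)],
            StateLabel.POINT,
        )
        assert validate_possession(rec) == []

    def test_callahan_requires_earned_start(self):
        rec = _record(
            StateLabel.START_PULL,
            Zone.OPP_END,
            [ThrowEvent(Zone.OPP_END, Zone.OPP_END, Outcome.SCORE, callahan_flag=True)],
            StateLabel.POINT,
        )
        assert any(v.code == "callahan_start" for v in validate_possession(rec))

    def test_censored_possession_without_throws_is_legal(self):
        rec = _record(StateLabel.START_PULL, Zone.REAR, [], StateLabel.PERIOD_END)
        assert validate_possession(rec) == []


class TestThrowEvent:
    def test_score_iff_opp_end(self):
        with pytest.raises(ValueError):
            ThrowEvent(Zone.MID, Zone.OPP_END, Outcome.COMPLETED)
        with pytest.raises(ValueError):
            ThrowEvent(Zone.MID, Zone.FRONT, Outcome.SCORE)

    def test_origin_must_be_transient_unless_callahan(self):
        with pytest.raises(ValueError):
            ThrowEvent(Zone.OPP_END, Zone.OPP_END, Outcome.SCORE)


class TestMirror:
    def test_mirror_is_involution_on_transient_interior(self):
        # REAR<->FRONT, MID<->MID under the perspective flip
        from ultistate.game_model import MIRROR_ZONE

        for z in Zone:
            assert MIRROR_ZONE[MIRROR_ZONE[z]] is z

    def test_own_end_occurrence_clamped_to_front(self):
        assert mirror_start_zone(Zone.END) is Zone.FRONT
        assert mirror_start_zone(Zone.OPP_END) is Zone.END
        assert mirror_start_zone(Zone.MID) is Zone.MID
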