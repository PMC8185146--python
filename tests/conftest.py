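"""Shared fixtures: hand-built match logs with known statistics."""

import pytest

from ultistate import (
    MatchLog,
    Outcome,
    PossessionRecord,
    StateLabel,
    ThrowEvent,
    Zone,
)

E, R, M, F, OPP = Zone.END, Zone.REAR, Zone.MID, Zone.FRONT, Zone.OPP_END


def _pass(a, b):
    return ThrowEvent(a, b, Outcome.COMPLETED)


def _score(a):
    return ThrowEvent(a, OPP, Outcome.SCORE)


def _to(a, forced):
    return ThrowEvent(a, a, Outcome.TO_FORCED if forced else Outcome.TO_UNFORCED)


def _poss(point, idx, team, start_state, start_zone, events, end_state, quarter=1):
    return PossessionRecord(
        point_index=point,
        possession_index=idx,
        team=team,
        start_state=start_state,
        start_zone=start_zone,
        events=tuple(events),
        end_state=end_state,
        quarter=quarter,
    )


PULL = StateLabel.START_PULL
EARN = StateLabel.START_EARNED_TO
PT = StateLabel.POINT
TOF = StateLabel.TO_FORCED
TOU = StateLabel.TO_UNFORCED


@pytest.fixture
def mini_log():
    """One-point game: B pulls, A holds with the four-throw possession
    pull->REAR, REAR->REAR, REAR->MID, MID->FRONT, FRONT->score."""
    p = _poss(1, 1, "A", PULL, R,
              [_pass(R, R), _pass(R, M), _pass(M, F), _score(F)], PT)
    return MatchLog(game_id="mini", home_team="A", away_team="B", possessions=[p])


@pytest.fixture
def toy_log():
    """Five-point game between A (home) and B with hand-counted stats.

    Final score A 3 - B 2.  Hand counts:
      A: PPG 3, BPG 1, CPG 9, possessions 6 (PPP 1.5), UTPG 2, FTPG 1,
         TTPCE 2/3 of B's 3 turnovers, pulls received 3 of 5 (PO 60%).
      B: PPG 2, BPG 1, CPG 7, possessions 5 (PPP 1.4), UTPG 1, FTPG 2,
         TTPCE 2/3, PO 40%.
    """
    poss = [
        # point 1: B pulls, A holds
        _poss(1, 1, "A", PULL, R, [_pass(R, R), _pass(R, M), _pass(M, F), _score(F)], PT),
        # point 2: A pulls; B turns over, A converts (break + earned point)
        _poss(2, 1, "B", PULL, E, [_pass(E, R), _to(R, forced=False)], TOU),
        _poss(2, 2, "A", EARN, F, [_score(F)], PT),
        # point 3: A pulls; B TO, A TO, B converts
        _poss(3, 1, "B", PULL, R, [_pass(R, M), _to(M, forced=True)], TOF),
        _poss(3, 2, "A", EARN, M, [_pass(M, M), _to(M, forced=False)], TOU),
        _poss(3, 3, "B", EARN, M, [_pass(M, F), _score(F)], PT),
        # point 4: B pulls; A turns over immediately, B converts (break for B)
        _poss(4, 1, "A", PULL, E, [_to(E, forced=True)], TOF),
        _poss(4, 2, "B", EARN, F, [_score(F)], PT),
        # point 5: B pulls; A TO, B TO, A converts
        _poss(5, 1, "A", PULL, M, [_pass(M, F), _to(F, forced=False)], TOU),
        _poss(5, 2, "B", EARN, R, [_pass(R, M), _pass(M, F), _to(F, forced=True)], TOF),
        _poss(5, 3, "A", EARN, R, [_pass(R, M), _score(M)], PT),
    ]
    return MatchLog(game_id="toy", home_team="A", away_team="B", possessions=poss)
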