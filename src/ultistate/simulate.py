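"""Rule-compliant synthetic match generator.

The generator runs the possession state machine forward: pulls land in
a zone drawn from a landing distribution, every throw draws an outcome
(a completed pass to some zone, a score, or a forced/unforced
turnover) from a zone-conditional multinomial, turnovers hand the disc
to the opponent in the mirrored zone, and the scoring team pulls the
next point.  All randomness flows through a single seeded
``numpy.random.Generator``, so a seed fully determines a match log.

The default parameters emulate elite AUDL-style play: per-zone scoring
and turnover rates and the pull landing distribution are set to
league-level observed means, matches run 4 quarters of 12 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation_io import MatchLog
from .game_model import (
    Outcome,
    PossessionRecord,
    StateLabel,
    ThrowEvent,
    TRANSIENT_ZONES,
    Zone,
    mirror_start_zone,
)

ZONES = TRANSIENT_ZONES  # (END, REAR, MID, FRONT)
_ZONE_INDEX = {z: i for i, z in enumerate(ZONES)}

#: Column order of the per-origin outcome matrix: pass destination
#: END/REAR/MID/FRONT, then SCORE, TO_FORCED, TO_UNFORCED.
OUTCOME_COLUMNS: Tuple[str, ...] = (
    "pass_END",
    "pass_REAR",
    "pass_MID",
    "pass_FRONT",
    "SCORE",
    "TO_FORCED",
    "TO_UNFORCED",
)

_SCORE_COL = 4
_TOF_COL = 5
_TOU_COL = 6

# Per-zone absorbing rates from league-level observed means; the pass
# mass is the remainder, split over destinations with flow-toward-goal
# weights (within-zone resets and short advances dominate, cross-zone
# hucks are rare).
_DEFAULT_SCORE = np.array([0.0, 0.0164, 0.0704, 0.3320])
_DEFAULT_TOF = np.array([0.0404, 0.0366, 0.0409, 0.0372])
_DEFAULT_TOU = np.array([0.0402, 0.0358, 0.0468, 0.0563])
_DEFAULT_DEST_WEIGHTS = np.array(
    [
        [0.22, 0.60, 0.16, 0.02],  # from END
        [0.06, 0.40, 0.50, 0.04],  # from REAR
        [0.01, 0.17, 0.44, 0.38],  # from MID
        [0.00, 0.03, 0.32, 0.65],  # from FRONT
    ]
)
_DEFAULT_PULL = np.array([0.2657, 0.6375, 0.0939, 0.0036])


def _default_outcome_matrix() -> np.ndarray:
    m = np.zeros((4, 7))
    m[:, _SCORE_COL] = _DEFAULT_SCORE
    m[:, _TOF_COL] = _DEFAULT_TOF
    m[:, _TOU_COL] = _DEFAULT_TOU
    pass_mass = 1.0 - m.sum(axis=1)
    m[:, :4] = _DEFAULT_DEST_WEIGHTS * pass_mass[:, None]
    return m


class InvalidParamsError(ValueError):
    """Simulation parameters violate a distribution or structural rule."""


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the forward possession model.

    ``outcome_given_origin`` is a 4x7 row-stochastic matrix (rows:
    origin zone END/REAR/MID/FRONT; columns: :data:`OUTCOME_COLUMNS`).
    ``pull_landing_dist`` is the 4-vector of pull landing zones.
    Scoring mass from the thrower's own end zone is a structural zero
    unless ``allow_own_end_score`` is set (a full-field huck).

    ``turnover_downfield_prob`` is the probability that a turnover
    occurs one zone downfield of the throw's origin (a failed downfield
    throw) rather than in the origin zone itself; the occurrence zone,
    mirrored into the opponent's perspective, locates the earned
    possession.  ``period_end_prob`` censors a possession into
    PERIOD_END (quarter/half/game clock expiring) and ends the point
    unscored.  ``callahan_prob`` applies to forced turnovers occurring
    in the thrower's own end zone.
    """

    pull_landing_dist: np.ndarray = field(default_factory=lambda: _DEFAULT_PULL / _DEFAULT_PULL.sum())
    outcome_given_origin: np.ndarray = field(default_factory=_default_outcome_matrix)
    quarters: int = 4
    points_per_quarter: int = 12
    turnover_downfield_prob: float = 0.5
    period_end_prob: float = 0.0
    callahan_prob: float = 0.0
    allow_own_end_score: bool = False
    home_team: str = "HOME"
    away_team: str = "AWAY"
    home_receives_first: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        pull = np.asarray(self.pull_landing_dist, dtype=float)
        m = np.asarray(self.outcome_given_origin, dtype=float)
        object.__setattr__(self, "pull_landing_dist", pull)
        object.__setattr__(self, "outcome_given_origin", m)
        if pull.shape != (4,):
            raise InvalidParamsError("pull_landing_dist must have 4 entries")
        if m.shape != (4, 7):
            raise InvalidParamsError("outcome_given_origin must be 4x7")
        if (pull < 0).any() or (m < 0).any():
            raise InvalidParamsError("probabilities must be non-negative")
        if abs(pull.sum() - 1.0) > 1e-9:
            raise InvalidParamsError("pull_landing_dist must sum to 1")
        bad = np.abs(m.sum(axis=1) - 1.0) > 1e-9
        if bad.any():
            zones = [ZONES[i].value for i in np.flatnonzero(bad)]
            raise InvalidParamsError(f"outcome rows must sum to 1 (zones {zones})")
        if not self.allow_own_end_score and m[0, _SCORE_COL] > 0:
            raise InvalidParamsError(
                "scoring mass from the own end zone is a structural zero "
                "(set allow_own_end_score to permit full-field hucks)"
            )
        for p_name in ("turnover_downfield_prob", "period_end_prob", "callahan_prob"):
            v = getattr(self, p_name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParamsError(f"{p_name} must be in [0, 1]")
        if self.quarters < 1 or self.points_per_quarter < 1:
            raise InvalidParamsError("quarters and points_per_quarter must be >= 1")

    @classmethod
    def homogeneous(
        cls,
        p_turnover: float = 1.0 / 12.0,
        p_score: float = 1.0 / 12.0,
        **kwargs,
    ) -> "SimulationParams":
        """Zone-homogeneous model: every throw turns over with
        probability ``p_turnover`` (split evenly forced/unforced),
        scores with ``p_score`` (from any zone), and otherwise
        completes to a uniformly chosen zone.  Mean completed passes
        per possession has the closed form
        ``(1 - p_turnover) / (p_turnover + p_score)``.
        """
        if p_turnover + p_score > 1.0:
            raise InvalidParamsError("p_turnover + p_score must be <= 1")
        row = np.empty(7)
        row[:4] = (1.0 - p_turnover - p_score) / 4.0
        row[_SCORE_COL] = p_score
        row[_TOF_COL] = p_turnover / 2.0
        row[_TOU_COL] = p_turnover / 2.0
        m = np.tile(row, (4, 1))
        kwargs.setdefault("allow_own_end_score", p_score > 0)
        kwargs.setdefault("pull_landing_dist", np.full(4, 0.25))
        return cls(outcome_given_origin=m, **kwargs)

    def replace(self, **changes) -> "SimulationParams":
        return replace(self, **changes)


_DOWNFIELD = {Zone.END: Zone.REAR, Zone.REAR: Zone.MID, Zone.MID: Zone.FRONT, Zone.FRONT: Zone.OPP_END}


def _sample_index(rng: np.random.Generator, cumulative: np.ndarray) -> int:
    return int(np.searchsorted(cumulative, rng.random(), side="right"))


def simulate_possession(
    params: SimulationParams,
    start_state: StateLabel,
    start_zone: Zone,
    rng: np.random.Generator,
    *,
    team: str = "HOME",
    point_index: int = 1,
    possession_index: int = 1,
    quarter: int = 1,
    censor: bool = False,
) -> Tuple[PossessionRecord, Optional[Zone]]:
    """Sample one possession.

    Returns the record and, when it ended in a turnover, the zone in
    which the opponent's earned possession begins (``None`` otherwise).
    With ``censor=True`` the absorbing throw is dropped and the
    possession ends in PERIOD_END.
    """
    m = params.outcome_given_origin
    cum = np.cumsum(m, axis=1)
    zone = Zone(start_zone)
    events: List[ThrowEvent] = []
    end_state: Optional[StateLabel] = None
    opp_start: Optional[Zone] = None

    while end_state is None:
        o = _ZONE_INDEX[zone]
        k = _sample_index(rng, cum[o])
        if k < 4:
            dest = ZONES[k]
            events.append(ThrowEvent(zone, dest, Outcome.COMPLETED))
            zone = dest
        elif k == _SCORE_COL:
            events.append(ThrowEvent(zone, Zone.OPP_END, Outcome.SCORE))
            end_state = StateLabel.POINT
        else:
            outcome = Outcome.TO_FORCED if k == _TOF_COL else Outcome.TO_UNFORCED
            events.append(ThrowEvent(zone, zone, outcome))
            end_state = StateLabel(outcome.value)
            occurrence = zone
            if rng.random() < params.turnover_downfield_prob:
                occurrence = _DOWNFIELD[zone]
            opp_start = mirror_start_zone(occurrence)

    if censor:
        events.pop()
        end_state = StateLabel.PERIOD_END
        opp_start = None

    record = PossessionRecord(
        point_index=point_index,
        possession_index=possession_index,
        team=team,
        start_state=StateLabel(start_state),
        start_zone=Zone(start_zone),
        events=tuple(events),
        end_state=end_state,
        quarter=quarter,
    )
    return record, opp_start


def _callahan_possession(
    team: str, point_index: int, possession_index: int, quarter: int
) -> PossessionRecord:
    return PossessionRecord(
        point_index=point_index,
        possession_index=possession_index,
        team=team,
        start_state=StateLabel.START_EARNED_TO,
        start_zone=Zone.OPP_END,
        events=(ThrowEvent(Zone.OPP_END, Zone.OPP_END, Outcome.SCORE, callahan_flag=True),),
        end_state=StateLabel.POINT,
        quarter=quarter,
    )


#: Safety cap on possessions within one point (degenerate parameter
#: sets with no scoring mass would otherwise never absorb).
_MAX_POSSESSIONS_PER_POINT = 2000
_MAX_OVERTIME_POINTS = 200


def simulate_match(params: SimulationParams, game_id: str = "sim") -> MatchLog:
    """Simulate a full match under AUDL bookkeeping rules.

    Points are grouped into quarters; the team that scores a point
    pulls the next one; the opening pull assignment of the second half
    flips relative to the first.  A point truncated by PERIOD_END
    censoring is unscored and the pull assignment carries over.  A
    game tied after regulation continues with sudden-death overtime
    points (recorded with quarter = quarters + 1) so every match log
    has a winner.
    """
    rng = np.random.default_rng(params.seed)
    pull_cum = np.cumsum(params.pull_landing_dist)
    possessions: List[PossessionRecord] = []
    score = {params.home_team: 0, params.away_team: 0}
    first_receiver = params.home_team if params.home_receives_first else params.away_team

    def other(team: str) -> str:
        return params.away_team if team == params.home_team else params.home_team

    receiver = first_receiver
    point_index = 0

    def play_point(quarter: int) -> None:
        nonlocal point_index, receiver
        point_index += 1
        offense = receiver
        start_state = StateLabel.START_PULL
        start_zone = ZONES[_sample_index(rng, pull_cum)]
        possession_index = 0
        while True:
            possession_index += 1
            if possession_index > _MAX_POSSESSIONS_PER_POINT:
                raise InvalidParamsError(
                    "point did not terminate; parameters have (near-)zero scoring mass"
                )
            censor = (
                params.period_end_prob > 0.0 and rng.random() < params.period_end_prob
            )
            record, opp_start = simulate_possession(
                params,
                start_state,
                start_zone,
                rng,
                team=offense,
                point_index=point_index,
                possession_index=possession_index,
                quarter=quarter,
                censor=censor,
            )
            possessions.append(record)
            if record.end_state is StateLabel.PERIOD_END:
                return  # point unscored; same team receives next point
            if record.end_state is StateLabel.POINT:
                score[offense] += 1
                receiver = other(offense)  # scorer pulls next
                return
            # turnover: Callahan chance on forced turnovers in the
            # thrower's own end zone, otherwise play continues
            if (
                record.end_state is StateLabel.TO_FORCED
                and record.events[-1].origin_zone is Zone.END
                and params.callahan_prob > 0.0
                and rng.random() < params.callahan_prob
            ):
                possession_index += 1
                possessions.append(
                    _callahan_possession(other(offense), point_index, possession_index, quarter)
                )
                score[other(offense)] += 1
                receiver = other(other(offense))  # scorer pulls next
                return
            offense = other(offense)
            start_state = StateLabel.START_EARNED_TO
            start_zone = opp_start

    for quarter in range(1, params.quarters + 1):
        if quarter == 1 + params.quarters // 2 and params.quarters >= 2:
            receiver = other(first_receiver)  # second-half assignment flip
        for _ in range(params.points_per_quarter):
            play_point(quarter)

    overtime = 0
    while score[params.home_team] == score[params.away_team]:
        overtime += 1
        if overtime > _MAX_OVERTIME_POINTS:
            raise InvalidParamsError("overtime did not resolve the tie")
        play_point(params.quarters + 1)

    return MatchLog(
        game_id=game_id,
        home_team=params.home_team,
        away_team=params.away_team,
        possessions=possessions,
    )


def simulate_matches(params: SimulationParams, n_matches: int) -> List[MatchLog]:
    """Simulate ``n_matches`` independent games, seeds derived from
    ``params.seed`` via SeedSequence spawning."""
    seeds = np.random.SeedSequence(params.seed).generate_state(n_matches) % (2**31)
    return [
        simulate_match(params.replace(seed=int(s)), game_id=f"sim{i:04d}")
        for i, s in enumerate(seeds)
    ]


def simulate_possessions(
    params: SimulationParams, n_possessions: int, seed: Optional[int] = None
) -> List[PossessionRecord]:
    """Sample independent possessions, each started by a pull whose
    landing zone is drawn from the pull landing distribution."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    pull_cum = np.cumsum(params.pull_landing_dist)
    out = []
    for i in range(n_possessions):
        zone = ZONES[_sample_index(rng, pull_cum)]
        rec, _ = simulate_possession(
            params, StateLabel.START_PULL, zone, rng, point_index=i + 1
        )
        out.append(rec)
    return out


def calibrate_from_table(table, **kwargs) -> SimulationParams:
    """Build generator parameters from an estimated transition table.

    The estimated pull landing distribution and zone-conditional
    outcome probabilities become the generator's parameters, so that
    re-estimating from a large simulation recovers the table.  Rows
    with no observed throws (undefined probabilities) are an error.
    """
    undefined = [
        ZONES[i].value for i in range(4) if not table.row_defined[i]
    ]
    if not table.pull_defined:
        undefined.append("pull")
    if undefined:
        raise InvalidParamsError(
            f"cannot calibrate from undefined rows: {', '.join(undefined)}"
        )
    m = table.outcome_given_origin.copy()
    if m[0, _SCORE_COL] > 0:
        kwargs.setdefault("allow_own_end_score", True)
    return SimulationParams(
        pull_landing_dist=table.pull_dist.copy(),
        outcome_given_origin=m,
        **kwargs,
    )
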