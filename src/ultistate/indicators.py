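"""The nine team-game performance indicators.

General match indicators: points per game (PPG), break points per game
(BPG; points scored by the pulling team), possession opportunity
(PO%).  Technical: total/unforced/forced turnovers per game (TTPG,
UTPG, FTPG).  Tactical: completed passes per game (CPG), mean passes
per possession (PPP), turnover-to-point conversion efficiency
(TTPCE%).

Conventions: a scoring catch counts as a completed pass (a goal is
caught); a Callahan counts toward the intercepting team's PPG/BPG and
TTPCE numerator but not its CPG (no completed pass is thrown by its
offense).  PO% defaults to pulls received over total pulls, under
which the two teams of a match sum to exactly 100%; the literal
total-possessions denominator is available via ``po_denominator``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import pandas as pd

from .annotation_io import MatchLog
from .game_model import StateLabel

INDICATOR_NAMES = (
    "PPG",
    "BPG",
    "CPG",
    "PPP",
    "TTPG",
    "UTPG",
    "FTPG",
    "TTPCE_pct",
    "PO_pct",
)


@dataclass(frozen=True)
class IndicatorSet:
    """The nine indicators for one team-game.

    ``TTPCE_pct`` is ``None`` when the opponent committed no turnovers
    (undefined quotient).
    """

    team: str
    game_id: str
    PPG: int
    BPG: int
    CPG: int
    PPP: float
    TTPG: int
    UTPG: int
    FTPG: int
    TTPCE_pct: Optional[float]
    PO_pct: float

    def to_series(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in INDICATOR_NAMES}, dtype=float)


def compute_indicators(
    log: MatchLog, team: str, po_denominator: str = "pulls"
) -> IndicatorSet:
    """Compute the indicator set for one team in one game.

    ``po_denominator`` selects the PO% quotient: ``"pulls"`` (pulls
    received / total pulls, the default) or ``"possessions"`` (pulls
    received / total possessions by both teams).
    """
    if po_denominator not in ("pulls", "possessions"):
        raise ValueError("po_denominator must be 'pulls' or 'possessions'")
    opponent = log.other_team(team)

    points = 0
    break_points = 0
    completed = 0
    n_possessions = 0
    unforced = 0
    forced = 0
    pulls_received = 0
    earned_points = 0

    by_point = log.points()
    for plist in by_point.values():
        puller = log.puller_of_point(plist)
        for p in plist:
            if p.team != team:
                continue
            n_possessions += 1
            completed += p.completed_passes
            if p.start_state is StateLabel.START_PULL:
                pulls_received += 1
            if p.end_state is StateLabel.POINT:
                points += 1
                if puller == team:
                    break_points += 1
                if p.start_state is StateLabel.START_EARNED_TO:
                    earned_points += 1
            elif p.end_state is StateLabel.TO_UNFORCED:
                unforced += 1
            elif p.end_state is StateLabel.TO_FORCED:
                forced += 1

    opp_turnovers = sum(
        1
        for p in log.possessions_of(opponent)
        if p.end_state in (StateLabel.TO_FORCED, StateLabel.TO_UNFORCED)
    )
    total_pulls = len(by_point)  # every point opens with exactly one pull
    if po_denominator == "pulls":
        po = 100.0 * pulls_received / total_pulls if total_pulls else 0.0
    else:
        po = 100.0 * pulls_received / len(log.possessions) if log.possessions else 0.0

    ttpce = 100.0 * earned_points / opp_turnovers if opp_turnovers > 0 else None
    ppp = completed / n_possessions if n_possessions else 0.0

    return IndicatorSet(
        team=team,
        game_id=log.game_id,
        PPG=points,
        BPG=break_points,
        CPG=completed,
        PPP=ppp,
        TTPG=unforced + forced,
        UTPG=unforced,
        FTPG=forced,
        TTPCE_pct=ttpce,
        PO_pct=po,
    )


def label_winner(log: MatchLog) -> Tuple[str, str]:
    """(winner, loser) by final score; ties are an error (league games
    are decided in overtime, so a drawn log is malformed)."""
    score = log.final_score()
    (team_a, pts_a), (team_b, pts_b) = score.items()
    if pts_a == pts_b:
        raise ValueError(f"game {log.game_id} is tied {pts_a}-{pts_b}; no winner")
    return (team_a, team_b) if pts_a > pts_b else (team_b, team_a)


def indicator_table(
    logs, po_denominator: str = "pulls"
) -> pd.DataFrame:
    """One row per team-game, columns = the nine indicators plus
    ``game_id``, ``team`` and ``result`` (winner/loser)."""
    rows = []
    for log in logs:
        winner, _ = label_winner(log)
        for team in log.teams:
            ind = compute_indicators(log, team, po_denominator=po_denominator)
            row = {"game_id": log.game_id, "team": team,
                   "result": "winner" if team == winner else "loser"}
            row.update(ind.to_series().to_dict())
            rows.append(row)
    return pd.DataFrame(rows)
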