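"""Estimation and aggregation of the model's transition probabilities.

All probabilities are maximum-likelihood multinomial proportions of
raw event counts — no smoothing or priors.  Per team-game the table
holds the pull landing distribution, the earned-turnover start
distribution, the zone-conditional throw outcome probabilities
(passing to each zone, scoring, forced/unforced turnover) and the
attempted-pass origin marginal.  Undefined rows (zero denominators)
are flagged and excluded pairwise from aggregation rather than being
propagated as errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation_io import MatchLog
from .game_model import Outcome, StateLabel, TRANSIENT_ZONES, Zone

ZONES = TRANSIENT_ZONES
_ZONE_INDEX = {z: i for i, z in enumerate(ZONES)}

#: Outcome columns of the per-origin count matrix (matches the
#: simulator's convention): pass destinations, score, turnovers.
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

#: The six adjacent passing transitions reported by default, in field
#: order: forward END->REAR->MID->FRONT and backward FRONT->MID->REAR->END.
ADJACENT_PASSES: Tuple[Tuple[Zone, Zone], ...] = (
    (Zone.END, Zone.REAR),
    (Zone.REAR, Zone.MID),
    (Zone.MID, Zone.FRONT),
    (Zone.FRONT, Zone.MID),
    (Zone.MID, Zone.REAR),
    (Zone.REAR, Zone.END),
)

NON_ADJACENT_PASSES: Tuple[Tuple[Zone, Zone], ...] = (
    (Zone.END, Zone.MID),
    (Zone.END, Zone.FRONT),
    (Zone.REAR, Zone.FRONT),
    (Zone.MID, Zone.END),
    (Zone.FRONT, Zone.REAR),
    (Zone.FRONT, Zone.END),
)


@dataclass(frozen=True)
class ReportGrouping:
    """How the estimated probabilities are grouped for reporting.

    The default grouping counts 4 pull + 4 earned-turnover + 4
    within-zone passing + 6 adjacent passing + 8 turnover + 4 scoring
    probabilities = 30 distinct reported parameters.  ``passing`` may
    be ``"adjacent"`` (the six between-adjacent-zone transitions,
    optionally plus the four within-zone ones) or ``"full"`` (the
    complete 4x4 origin-destination matrix).
    """

    passing: str = "adjacent"
    within_zone: bool = True

    def __post_init__(self) -> None:
        if self.passing not in ("adjacent", "full"):
            raise ValueError("passing must be 'adjacent' or 'full'")


def count_model_parameters(grouping: ReportGrouping = ReportGrouping()) -> int:
    """Number of distinct transition probabilities under a grouping."""
    if grouping.passing == "full":
        n_pass = 16
    else:
        n_pass = 6 + (4 if grouping.within_zone else 0)
    return 4 + 4 + n_pass + 8 + 4


@dataclass
class TransitionTable:
    """Event counts and derived transition probabilities for one team-game."""

    team: str
    game_id: str
    pull_counts: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=int))
    earned_counts: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=int))
    throw_counts: np.ndarray = field(default_factory=lambda: np.zeros((4, 7), dtype=int))
    n_callahans: int = 0
    n_possessions: int = 0
    n_censored: int = 0

    # -- derived quantities -------------------------------------------------

    @property
    def pull_defined(self) -> bool:
        return int(self.pull_counts.sum()) > 0

    @property
    def earned_defined(self) -> bool:
        return int(self.earned_counts.sum()) > 0

    @property
    def row_defined(self) -> np.ndarray:
        """Boolean mask: origin zones with at least one observed throw."""
        return self.throw_counts.sum(axis=1) > 0

    @staticmethod
    def _proportions(counts: np.ndarray) -> np.ndarray:
        total = counts.sum()
        if total == 0:
            return np.full(counts.shape, np.nan)
        return counts / total

    @property
    def pull_dist(self) -> np.ndarray:
        return self._proportions(self.pull_counts)

    @property
    def earned_to_dist(self) -> np.ndarray:
        return self._proportions(self.earned_counts)

    @property
    def outcome_given_origin(self) -> np.ndarray:
        """4x7 row-stochastic matrix; undefined rows are NaN."""
        totals = self.throw_counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(totals > 0, self.throw_counts / np.maximum(totals, 1), np.nan)
        return probs

    @property
    def attempted_pass_marginal(self) -> np.ndarray:
        """Share of all throws attempted from each origin zone."""
        return self._proportions(self.throw_counts.sum(axis=1))

    def to_series(self) -> pd.Series:
        """Flatten every probability to a labeled series.

        Labels: ``pull_<Z>``, ``earned_to_<Z>``, ``pass_<A>_<B>``
        (conditional on origin A), ``to_forced_<Z>``,
        ``to_unforced_<Z>``, ``score_<Z>``, ``attempted_<Z>``.
        """
        out: Dict[str, float] = {}
        pull = self.pull_dist
        earned = self.earned_to_dist
        probs = self.outcome_given_origin
        attempted = self.attempted_pass_marginal
        for i, z in enumerate(ZONES):
            out[f"pull_{z.value}"] = pull[i]
            out[f"earned_to_{z.value}"] = earned[i]
        for i, a in enumerate(ZONES):
            for j, b in enumerate(ZONES):
                out[f"pass_{a.value}_{b.value}"] = probs[i, j]
            out[f"score_{a.value}"] = probs[i, _SCORE_COL]
            out[f"to_forced_{a.value}"] = probs[i, _TOF_COL]
            out[f"to_unforced_{a.value}"] = probs[i, _TOU_COL]
        for i, z in enumerate(ZONES):
            out[f"attempted_{z.value}"] = attempted[i]
        return pd.Series(out, dtype=float)

    def __add__(self, other: "TransitionTable") -> "TransitionTable":
        """Pool counts of two tables (e.g. both teams, or many games)."""
        return TransitionTable(
            team=self.team if self.team == other.team else "pooled",
            game_id=self.game_id if self.game_id == other.game_id else "pooled",
            pull_counts=self.pull_counts + other.pull_counts,
            earned_counts=self.earned_counts + other.earned_counts,
            throw_counts=self.throw_counts + other.throw_counts,
            n_callahans=self.n_callahans + other.n_callahans,
            n_possessions=self.n_possessions + other.n_possessions,
            n_censored=self.n_censored + other.n_censored,
        )


def estimate_transition_table(log: MatchLog, team: str) -> TransitionTable:
    """Maximum-likelihood transition table for one team in one game.

    Pull landings come from the team's pull-received possessions;
    earned-turnover locations from the start zones of its earned
    possessions (Callahans excluded — their start zone is the attacked
    end zone, outside the four transient states); throw outcomes from
    every non-Callahan throw.  Possessions censored by a period end
    contribute their completed throws but no absorbing event.
    """
    log.other_team(team)  # raises KeyError if the team is absent
    table = TransitionTable(team=team, game_id=log.game_id)
    for p in log.possessions_of(team):
        table.n_possessions += 1
        if p.end_state is StateLabel.PERIOD_END:
            table.n_censored += 1
        if p.is_callahan:
            table.n_callahans += 1
        elif p.start_state is StateLabel.START_PULL:
            table.pull_counts[_ZONE_INDEX[p.start_zone]] += 1
        else:
            table.earned_counts[_ZONE_INDEX[p.start_zone]] += 1
        for ev in p.events:
            if ev.callahan_flag:
                continue
            o = _ZONE_INDEX[ev.origin_zone]
            if ev.outcome is Outcome.COMPLETED:
                table.throw_counts[o, _ZONE_INDEX[ev.destination]] += 1
            elif ev.outcome is Outcome.SCORE:
                table.throw_counts[o, _SCORE_COL] += 1
            elif ev.outcome is Outcome.TO_FORCED:
                table.throw_counts[o, _TOF_COL] += 1
            else:
                table.throw_counts[o, _TOU_COL] += 1
    return table


def pool_tables(tables: Iterable[TransitionTable]) -> TransitionTable:
    """Sum the counts of many tables into one pooled table."""
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to pool")
    pooled = tables[0]
    for t in tables[1:]:
        pooled = pooled + t
    return pooled


def aggregate_tables(tables: Sequence[TransitionTable]) -> pd.DataFrame:
    """Per-probability mean and sample SD over team-games.

    Undefined entries (NaN) are excluded pairwise; the returned frame
    has columns ``mean``, ``sd`` (n-1 denominator) and ``n`` (the
    number of team-games contributing to each entry).
    """
    if len(tables) == 0:
        raise ValueError("need at least one table")
    frame = pd.DataFrame([t.to_series() for t in tables])
    return pd.DataFrame(
        {
            "mean": frame.mean(axis=0, skipna=True),
            "sd": frame.std(axis=0, ddof=1, skipna=True),
            "n": frame.notna().sum(axis=0).astype(int),
        }
    )


def grouped_probability_labels(grouping: ReportGrouping = ReportGrouping()) -> List[str]:
    """Flattened labels of the reported probabilities under a grouping,
    in report order (pulls, earned turnovers, passing, turnovers,
    scoring).  Length equals :func:`count_model_parameters`."""
    labels = [f"pull_{z.value}" for z in ZONES]
    labels += [f"earned_to_{z.value}" for z in ZONES]
    if grouping.passing == "full":
        labels += [f"pass_{a.value}_{b.value}" for a in ZONES for b in ZONES]
    else:
        if grouping.within_zone:
            labels += [f"pass_{z.value}_{z.value}" for z in ZONES]
        labels += [f"pass_{a.value}_{b.value}" for a, b in ADJACENT_PASSES]
    labels += [f"to_forced_{z.value}" for z in ZONES]
    labels += [f"to_unforced_{z.value}" for z in ZONES]
    labels += [f"score_{z.value}" for z in ZONES]
    return labels


def conservation_check(log: MatchLog, team: str) -> Tuple[int, int]:
    """(#points + #turnovers + #censored, #possessions) for a team-game;
    the two are equal for any valid log."""
    n_abs = 0
    n_poss = 0
    for p in log.possessions_of(team):
        n_poss += 1
        if p.end_state in (
            StateLabel.POINT,
            StateLabel.TO_FORCED,
            StateLabel.TO_UNFORCED,
            StateLabel.PERIOD_END,
        ):
            n_abs += 1
    return n_abs, n_poss
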