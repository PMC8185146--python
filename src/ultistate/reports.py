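"""Pipeline orchestration and rendered report tables.

``run_pipeline`` executes ingest -> validate -> transition estimation
-> indicators -> winner/loser comparison over a set of match logs
(read from disk or simulated), returning a :class:`ReportBundle` of
tidy tables: per-team-game indicator and transition-probability
values, all/winners/losers summaries (mean +/- SD), and the paired
comparison battery for every indicator and reported transition
probability.  Probabilities are stored as raw proportions; rendered
summary tables show percentages with two decimals.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotation_io import MatchLog, read_match_log, write_match_log
from .config import RunConfig, load_config
from .indicators import INDICATOR_NAMES, indicator_table, label_winner
from .inferential import ComparisonResult, compare_winners_losers, significance_marker
from .simulate import simulate_matches
from .transition_stats import (
    ReportGrouping,
    TransitionTable,
    aggregate_tables,
    estimate_transition_table,
    grouped_probability_labels,
)


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run."""

    indicators_by_teamgame: pd.DataFrame
    transitions_by_teamgame: pd.DataFrame
    indicators_summary: pd.DataFrame
    transitions_summary: pd.DataFrame
    comparisons: pd.DataFrame
    provenance: Dict[str, object] = field(default_factory=dict)

    def write(self, out_dir) -> List[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        tables = {
            "indicators_by_teamgame.csv": self.indicators_by_teamgame,
            "transitions_by_teamgame.csv": self.transitions_by_teamgame,
            "indicators_summary.csv": self.indicators_summary,
            "transitions_summary.csv": self.transitions_summary,
            "comparisons.csv": self.comparisons,
        }
        for name, frame in tables.items():
            path = out_dir / name
            labeled = not isinstance(frame.index, pd.RangeIndex)
            frame.to_csv(path, index=labeled, index_label="variable" if labeled else None)
            written.append(path)
        log_path = out_dir / "run.log"
        log_path.write_text(
            "".join(f"{k}: {v}\n" for k, v in self.provenance.items()), encoding="utf-8"
        )
        written.append(log_path)
        return written


def _summary_by_group(frame: pd.DataFrame, value_cols: Sequence[str]) -> pd.DataFrame:
    """Mean +/- SD over all team-games and split by winner/loser."""
    out = {}
    for label, sub in (
        ("all", frame),
        ("winners", frame[frame["result"] == "winner"]),
        ("losers", frame[frame["result"] == "loser"]),
    ):
        vals = sub[list(value_cols)].apply(pd.to_numeric, errors="coerce")
        out[f"{label}_mean"] = vals.mean(skipna=True)
        out[f"{label}_sd"] = vals.std(ddof=1, skipna=True)
    return pd.DataFrame(out)


def transition_probability_table(
    logs: Sequence[MatchLog], grouping: ReportGrouping = ReportGrouping()
) -> pd.DataFrame:
    """One row per team-game holding every flattened transition
    probability, with winner/loser labels."""
    rows = []
    for log in logs:
        winner, _ = label_winner(log)
        for team in log.teams:
            table = estimate_transition_table(log, team)
            row = {"game_id": log.game_id, "team": team,
                   "result": "winner" if team == winner else "loser"}
            row.update(table.to_series().to_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def comparison_report(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tidy comparison table with significance markers."""
    rows = []
    for r in results:
        row = r.to_dict()
        row["marker"] = significance_marker(r.p_two_tailed, r.test_used == "wilcoxon")
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config, seed: Optional[int] = None, grouping: ReportGrouping = ReportGrouping()
) -> ReportBundle:
    """Execute the full analysis pipeline.

    ``config`` is a :class:`RunConfig` or a path to a YAML/JSON config
    file.  With a simulation block, ``n_matches`` seeded games are
    generated; otherwise the listed input logs are read and validated.
    """
    if not isinstance(config, RunConfig):
        config = load_config(config)

    if config.inputs:
        logs = [read_match_log(p, validate=True) for p in config.inputs]
        source = f"{len(logs)} input log(s)"
    else:
        params = config.simulation_params(seed=seed)
        logs = simulate_matches(params, config.n_matches)
        source = f"simulation of {len(logs)} matches (seed {params.seed})"

    ind = indicator_table(logs, po_denominator=config.po_denominator)
    trans = transition_probability_table(logs, grouping=grouping)

    ind_summary = _summary_by_group(ind, INDICATOR_NAMES)
    labels = grouped_probability_labels(grouping) + [
        c for c in trans.columns if c.startswith("attempted_")
    ]
    trans_summary = _summary_by_group(trans, labels)

    def _paired(frame: pd.DataFrame, cols: Sequence[str]) -> List[ComparisonResult]:
        winners = frame[frame["result"] == "winner"].sort_values("game_id")
        losers = frame[frame["result"] == "loser"].sort_values("game_id")
        return compare_winners_losers(
            winners[list(cols)].reset_index(drop=True),
            losers[list(cols)].reset_index(drop=True),
            alpha=config.alpha,
        )

    comparisons = comparison_report(
        _paired(ind, INDICATOR_NAMES) + _paired(trans, labels)
    )

    provenance = {
        "tool": f"ultistate {__version__}",
        "python": sys.version.split()[0],
        "source": source,
        "seed": seed,
        "po_denominator": config.po_denominator,
        "alpha": config.alpha,
        "n_team_games": len(ind),
    }
    return ReportBundle(
        indicators_by_teamgame=ind,
        transitions_by_teamgame=trans,
        indicators_summary=ind_summary,
        transitions_summary=trans_summary,
        comparisons=comparisons,
        provenance=provenance,
    )


def render_percent(frame: pd.DataFrame) -> pd.DataFrame:
    """Render a proportions summary as percentages with two decimals."""
    return (frame * 100.0).round(2)
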