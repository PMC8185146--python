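"""Reading, writing and validating match annotation logs.

The on-disk formats are a flat CSV event log (one row per pull, pass,
turnover, score, Callahan or period-end marker) and an equivalent
nested JSON document.  Both round-trip losslessly: reading a written
log reproduces the in-memory :class:`MatchLog` exactly, and a second
write is byte-identical.

CSV schema (UTF-8, comma-separated, header row)::

    game_id, quarter, point_index, possession_index, team, event_index,
    event_type, origin_zone, dest_zone, absolute_yard, timestamp_s

``event_type`` is one of ``pull``, ``pass``, ``forced_turnover``,
``unforced_turnover``, ``score``, ``callahan``, ``period_end``.  Pull
rows carry the landing zone in ``dest_zone`` (origin blank); score and
Callahan rows use the ``SCORE`` destination token.  Zone labels are
serialized team-relative (``END``/``REAR``/``MID``/``FRONT``); the
perspective is resolved via the ``team`` column.  Two leading
``#``-comment lines carry match metadata (home/away team, division,
week, quarter length) that is not recoverable from event rows.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .game_model import (
    Outcome,
    PossessionRecord,
    StateLabel,
    ThrowEvent,
    Zone,
    validate_possession,
)

CSV_COLUMNS = (
    "game_id",
    "quarter",
    "point_index",
    "possession_index",
    "team",
    "event_index",
    "event_type",
    "origin_zone",
    "dest_zone",
    "absolute_yard",
    "timestamp_s",
)

_SCORE_TOKEN = "SCORE"

_TURNOVER_TYPES = {"forced_turnover": Outcome.TO_FORCED, "unforced_turnover": Outcome.TO_UNFORCED}


class MatchLogParseError(ValueError):
    """Malformed log file; message names the offending row/column."""


class MatchLogValidationError(ValueError):
    """Structurally parseable log that violates the state machine."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__(
            "match log failed validation:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )


@dataclass
class MatchLog:
    """A full game: metadata plus the ordered list of possessions."""

    game_id: str
    home_team: str
    away_team: str
    possessions: List[PossessionRecord] = field(default_factory=list)
    division: Optional[str] = None
    week: Optional[str] = None
    quarter_length_min: float = 12.0

    @property
    def teams(self) -> Tuple[str, str]:
        return (self.home_team, self.away_team)

    def other_team(self, team: str) -> str:
        if team == self.home_team:
            return self.away_team
        if team == self.away_team:
            return self.home_team
        raise KeyError(f"team {team!r} does not play in game {self.game_id}")

    def possessions_of(self, team: str) -> List[PossessionRecord]:
        self.other_team(team)  # membership check
        return [p for p in self.possessions if p.team == team]

    def points(self) -> Dict[int, List[PossessionRecord]]:
        """Possessions grouped by point, in order."""
        by_point: Dict[int, List[PossessionRecord]] = {}
        for p in self.possessions:
            by_point.setdefault(p.point_index, []).append(p)
        return by_point

    def puller_of_point(self, point_possessions: Sequence[PossessionRecord]) -> str:
        """The pulling team of a point = opponent of the pull receiver."""
        first = point_possessions[0]
        return self.other_team(first.team)

    def scorer_of_point(self, point_possessions: Sequence[PossessionRecord]) -> Optional[str]:
        for p in point_possessions:
            if p.end_state is StateLabel.POINT:
                return p.team
        return None

    def final_score(self) -> Dict[str, int]:
        score = {self.home_team: 0, self.away_team: 0}
        for p in self.possessions:
            if p.end_state is StateLabel.POINT:
                score[p.team] += 1
        return score


def validate_match_log(log: MatchLog) -> List[str]:
    """Match-level validation; returns human-readable violation strings.

    Checks every possession against the state machine, the alternation
    of possession within a point, that every point opens with a pull,
    and the rule that the scoring team pulls the next point (not
    enforced across the half-time boundary, where the opening pull
    assignment resets).
    """
    problems: List[str] = []
    for p in log.possessions:
        for v in validate_possession(p):
            problems.append(f"point {p.point_index} possession {p.possession_index}: {v}")
        if p.team not in log.teams:
            problems.append(
                f"point {p.point_index} possession {p.possession_index}: unknown team {p.team!r}"
            )

    points = log.points()
    prev_index = None
    for idx in points:
        if prev_index is not None and idx <= prev_index:
            problems.append(f"point indices out of order at point {idx}")
        prev_index = idx

    ordered = sorted(points.items())
    for idx, plist in ordered:
        if plist[0].start_state is not StateLabel.START_PULL:
            problems.append(f"point {idx}: first possession does not start with a pull")
        for k, p in enumerate(plist):
            if p.possession_index != k + 1:
                problems.append(
                    f"point {idx}: possession indices not consecutive at position {k + 1}"
                )
            if k > 0:
                if p.team == plist[k - 1].team:
                    problems.append(f"point {idx}: possession does not alternate teams")
                if p.start_state is not StateLabel.START_EARNED_TO:
                    problems.append(
                        f"point {idx}: non-initial possession must start from an earned turnover"
                    )

    for (idx_a, plist_a), (idx_b, plist_b) in zip(ordered, ordered[1:]):
        scorer = None
        try:
            scorer = log.scorer_of_point(plist_a)
        except KeyError:  # pragma: no cover - unknown team already reported
            continue
        crosses_half = plist_a[-1].quarter <= 2 < plist_b[0].quarter
        if scorer is not None and not crosses_half and plist_b[0].team not in log.teams:
            continue
        if scorer is not None and not crosses_half:
            puller_next = log.other_team(plist_b[0].team)
            if puller_next != scorer:
                problems.append(
                    f"point {idx_b}: pulled by {puller_next}, but {scorer} scored point {idx_a}"
                )
    return problems


# ---------------------------------------------------------------------------
# serialization helpers


def _fmt_num(x: Optional[float]) -> str:
    if x is None:
        return ""
    return repr(float(x))


def _event_rows(log: MatchLog, p: PossessionRecord) -> List[List[str]]:
    rows: List[List[str]] = []
    base = [
        log.game_id,
        str(p.quarter),
        str(p.point_index),
        str(p.possession_index),
        p.team,
    ]
    idx = 0
    if p.start_state is StateLabel.START_PULL:
        rows.append(
            base
            + [str(idx), "pull", "", p.start_zone.value, "", _fmt_num(p.pull_timestamp_s)]
        )
        idx += 1
    for ev in p.events:
        if ev.callahan_flag:
            etype, origin, dest = "callahan", "", _SCORE_TOKEN
        elif ev.outcome is Outcome.SCORE:
            etype, origin, dest = "score", ev.origin_zone.value, _SCORE_TOKEN
        elif ev.outcome is Outcome.COMPLETED:
            etype, origin, dest = "pass", ev.origin_zone.value, ev.destination.value
        else:
            etype = "forced_turnover" if ev.outcome is Outcome.TO_FORCED else "unforced_turnover"
            origin, dest = ev.origin_zone.value, ev.destination.value
        rows.append(base + [str(idx), etype, origin, dest, _fmt_num(ev.absolute_yard), ""])
        idx += 1
    if p.end_state is StateLabel.PERIOD_END:
        current = p.events[-1].destination.value if p.events else p.start_zone.value
        rows.append(base + [str(idx), "period_end", current, "", "", ""])
    return rows


def _to_csv_text(log: MatchLog) -> str:
    buf = io.StringIO()
    meta = {
        "home_team": log.home_team,
        "away_team": log.away_team,
        "quarter_length_min": repr(float(log.quarter_length_min)),
    }
    opt = {"division": log.division, "week": log.week}
    meta.update({k: v for k, v in opt.items() if v is not None})
    buf.write("# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for p in log.possessions:
        writer.writerows(_event_rows(log, p))
    return buf.getvalue()


def _possession_from_rows(rows: List[dict], row_numbers: List[int]) -> PossessionRecord:
    first = rows[0]
    team = first["team"]
    quarter = int(first["quarter"])
    point_index = int(first["point_index"])
    possession_index = int(first["possession_index"])
    pull_timestamp = None

    if first["event_type"] == "pull":
        start_state = StateLabel.START_PULL
        start_zone = _parse_zone(first["dest_zone"], row_numbers[0], "dest_zone")
        if first["timestamp_s"]:
            pull_timestamp = float(first["timestamp_s"])
        throw_rows = rows[1:]
        throw_numbers = row_numbers[1:]
    else:
        start_state = StateLabel.START_EARNED_TO
        throw_rows = rows
        throw_numbers = row_numbers
        if throw_rows and throw_rows[0]["event_type"] == "callahan":
            start_zone = Zone.OPP_END
        elif throw_rows:
            col = "origin_zone"
            start_zone = _parse_zone(throw_rows[0][col], throw_numbers[0], col)
        else:
            raise MatchLogParseError(
                f"row {row_numbers[0]}: possession has no events and no pull"
            )

    events: List[ThrowEvent] = []
    end_state: Optional[StateLabel] = None
    for row, rownum in zip(throw_rows, throw_numbers):
        etype = row["event_type"]
        if end_state is not None:
            raise MatchLogParseError(f"row {rownum}: event after possession ended")
        yard = float(row["absolute_yard"]) if row["absolute_yard"] else None
        if etype == "pass":
            origin = _parse_zone(row["origin_zone"], rownum, "origin_zone")
            if not row["dest_zone"]:
                raise MatchLogParseError(f"row {rownum}: pass missing dest_zone")
            dest = _parse_zone(row["dest_zone"], rownum, "dest_zone")
            events.append(ThrowEvent(origin, dest, Outcome.COMPLETED, yard))
        elif etype == "score":
            origin = _parse_zone(row["origin_zone"], rownum, "origin_zone")
            if row["dest_zone"] != _SCORE_TOKEN:
                raise MatchLogParseError(f"row {rownum}: score rows need dest_zone={_SCORE_TOKEN}")
            events.append(ThrowEvent(origin, Zone.OPP_END, Outcome.SCORE, yard))
            end_state = StateLabel.POINT
        elif etype == "callahan":
            events.append(
                ThrowEvent(Zone.OPP_END, Zone.OPP_END, Outcome.SCORE, yard, callahan_flag=True)
            )
            end_state = StateLabel.POINT
        elif etype in _TURNOVER_TYPES:
            origin = _parse_zone(row["origin_zone"], rownum, "origin_zone")
            dest = _parse_zone(row["dest_zone"] or row["origin_zone"], rownum, "dest_zone")
            events.append(ThrowEvent(origin, dest, _TURNOVER_TYPES[etype], yard))
            end_state = StateLabel(_TURNOVER_TYPES[etype].value)
        elif etype == "period_end":
            end_state = StateLabel.PERIOD_END
        elif etype == "pull":
            raise MatchLogParseError(f"row {rownum}: pull row not at possession start")
        else:
            raise MatchLogParseError(f"row {rownum}: unknown event_type {etype!r}")

    if end_state is None:
        raise MatchLogParseError(
            f"row {row_numbers[-1]}: possession (point {point_index}, "
            f"possession {possession_index}) has no terminating event"
        )

    return PossessionRecord(
        point_index=point_index,
        possession_index=possession_index,
        team=team,
        start_state=start_state,
        start_zone=start_zone,
        events=tuple(events),
        end_state=end_state,
        quarter=quarter,
        pull_timestamp_s=pull_timestamp,
    )


def _parse_zone(token: str, rownum: int, column: str) -> Zone:
    try:
        return Zone(token)
    except ValueError:
        raise MatchLogParseError(
            f"row {rownum}: column {column}: unknown zone label {token!r}"
        ) from None


def _parse_meta_line(line: str) -> Dict[str, str]:
    meta: Dict[str, str] = {}
    for chunk in line.lstrip("#").strip().split():
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            meta[k] = v
    return meta


def _from_csv_text(text: str) -> MatchLog:
    meta: Dict[str, str] = {}
    lines = text.splitlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            meta.update(_parse_meta_line(line))
            body_start += 1
        else:
            break
    reader = csv.DictReader(lines[body_start:])
    if reader.fieldnames is None or tuple(reader.fieldnames) != CSV_COLUMNS:
        raise MatchLogParseError(
            f"bad header: expected {','.join(CSV_COLUMNS)}, got "
            f"{','.join(reader.fieldnames or ())}"
        )

    game_id = None
    groups: List[Tuple[Tuple[int, int], List[dict], List[int]]] = []
    for rownum, row in enumerate(reader, start=body_start + 2):
        missing = [c for c in ("quarter", "point_index", "possession_index", "team", "event_type") if not row.get(c)]
        if missing:
            raise MatchLogParseError(f"row {rownum}: missing value for {missing[0]}")
        if game_id is None:
            game_id = row["game_id"]
        try:
            key = (int(row["point_index"]), int(row["possession_index"]))
        except ValueError as exc:
            raise MatchLogParseError(f"row {rownum}: non-integer index ({exc})") from None
        if groups and groups[-1][0] == key:
            groups[-1][1].append(row)
            groups[-1][2].append(rownum)
        else:
            groups.append((key, [row], [rownum]))

    possessions = [_possession_from_rows(rows, nums) for _, rows, nums in groups]
    teams_seen = {p.team for p in possessions}
    home = meta.get("home_team")
    away = meta.get("away_team")
    if home is None or away is None:
        ordered = sorted(teams_seen)
        home = home or (ordered[0] if ordered else "HOME")
        away = away or (ordered[1] if len(ordered) > 1 else "AWAY")
    return MatchLog(
        game_id=game_id or "",
        home_team=home,
        away_team=away,
        possessions=possessions,
        division=meta.get("division"),
        week=meta.get("week"),
        quarter_length_min=float(meta.get("quarter_length_min", 12.0)),
    )


# ---------------------------------------------------------------------------
# JSON


def _log_to_jsonable(log: MatchLog) -> dict:
    return {
        "game_id": log.game_id,
        "home_team": log.home_team,
        "away_team": log.away_team,
        "division": log.division,
        "week": log.week,
        "quarter_length_min": log.quarter_length_min,
        "possessions": [
            {
                "quarter": p.quarter,
                "point_index": p.point_index,
                "possession_index": p.possession_index,
                "team": p.team,
                "start_state": p.start_state.value,
                "start_zone": p.start_zone.value,
                "pull_timestamp_s": p.pull_timestamp_s,
                "end_state": p.end_state.value,
                "events": [
                    {
                        "origin_zone": e.origin_zone.value,
                        "destination": e.destination.value,
                        "outcome": e.outcome.value,
                        "absolute_yard": e.absolute_yard,
                        "callahan": e.callahan_flag,
                    }
                    for e in p.events
                ],
            }
            for p in log.possessions
        ],
    }


def _log_from_jsonable(doc: dict) -> MatchLog:
    try:
        possessions = [
            PossessionRecord(
                point_index=p["point_index"],
                possession_index=p["possession_index"],
                team=p["team"],
                start_state=StateLabel(p["start_state"]),
                start_zone=Zone(p["start_zone"]),
                events=tuple(
                    ThrowEvent(
                        Zone(e["origin_zone"]),
                        Zone(e["destination"]),
                        Outcome(e["outcome"]),
                        e.get("absolute_yard"),
                        bool(e.get("callahan", False)),
                    )
                    for e in p["events"]
                ),
                end_state=StateLabel(p["end_state"]),
                quarter=p.get("quarter", 1),
                pull_timestamp_s=p.get("pull_timestamp_s"),
            )
            for p in doc["possessions"]
        ]
    except (KeyError, ValueError) as exc:
        raise MatchLogParseError(f"malformed JSON match log: {exc}") from None
    return MatchLog(
        game_id=doc.get("game_id", ""),
        home_team=doc["home_team"],
        away_team=doc["away_team"],
        possessions=possessions,
        division=doc.get("division"),
        week=doc.get("week"),
        quarter_length_min=doc.get("quarter_length_min", 12.0),
    )


# ---------------------------------------------------------------------------
# public API


def _infer_format(path: Union[str, Path], fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValueError("format must be 'csv' or 'json'")
        return fmt
    suffix = Path(path).suffix.lower()
    return "json" if suffix == ".json" else "csv"


def read_match_log(
    path: Union[str, Path], format: Optional[str] = None, validate: bool = True
) -> MatchLog:
    """Read a match log from a CSV or JSON file.

    The format is inferred from the file extension unless given.  With
    ``validate=True`` (the default) the log is checked against the
    state machine and match bookkeeping rules; violations raise
    :class:`MatchLogValidationError` listing every problem.
    """
    fmt = _infer_format(path, format)
    text = Path(path).read_text(encoding="utf-8")
    if fmt == "json":
        log = _log_from_jsonable(json.loads(text))
    else:
        log = _from_csv_text(text)
    if validate:
        problems = validate_match_log(log)
        if problems:
            raise MatchLogValidationError(problems)
    return log


def write_match_log(log: MatchLog, path: Union[str, Path], format: Optional[str] = None) -> Path:
    """Write a match log; deterministic output (round-trip/byte identity)."""
    fmt = _infer_format(path, format)
    path = Path(path)
    if fmt == "json":
        text = json.dumps(_log_to_jsonable(log), indent=1, sort_keys=False) + "\n"
    else:
        text = _to_csv_text(log)
    path.write_text(text, encoding="utf-8", newline="")
    return path
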