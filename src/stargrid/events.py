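"""Turn game logs into the observation/decision streams the learning model
consumes, plus aggregate behavioral measures (zap rates, time-binned rates,
cross-path rates).

Definitions used throughout:

* A player *could zap* another player on a turn iff the two shared a row or
  a column (a zap ray travels in a straight line).
* An observed action is classified as an **avoidance** when the player
  moved while able to zap at least one other active player *and* was not
  the strictly closest player to any star — mirroring the bot algorithm's
  first check.  A move while closest to a star, or with nobody in line,
  carries no information about willingness to zap and is classified
  ``none`` (no belief update).
* Covariates entering the decision rule are Manhattan distances divided by
  ``divisor`` (default 10, the grid side): ``star_dist`` to the nearest
  star and ``target_dist`` to the candidate target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .game import GameLog, TurnRecord, Position, manhattan, NEUTRAL_REL

ZAP, AVOID, NONE = "zap", "avoid", "none"

DEFAULT_DIVISOR = 10.0
#: maximum L1 distance on a g×g grid, used for star_dist on a bare board
def _max_dist(grid_size: int) -> int:
    return 2 * (grid_size - 1)


def shared_line(pos_a: Position, pos_b: Position) -> bool:
    """True iff the two cells share a row or a column."""
    return pos_a[0] == pos_b[0] or pos_a[1] == pos_b[1]


def _is_unique_closest_to_any_star(positions: dict[int, Position],
                                   stars: list[Position], pid: int) -> bool:
    pos = positions[pid]
    for star in stars:
        d = manhattan(pos, star)
        if all(manhattan(q, star) > d for qid, q in positions.items() if qid != pid):
            return True
    return False


def classify_record(record: TurnRecord) -> str:
    """Classify one logged action as ``zap``, ``avoid`` or ``none``."""
    if record.action.kind == "zap":
        return ZAP
    pos = record.positions[record.actor_id]
    in_line = any(shared_line(pos, q) for qid, q in record.positions.items()
                  if qid != record.actor_id)
    if not in_line:
        return NONE
    if _is_unique_closest_to_any_star(record.positions, record.stars,
                                      record.actor_id):
        return NONE
    return AVOID


def classify_observed_action(log: GameLog, turn: int, actor: int) -> str:
    """Classification of ``actor``'s action at round ``turn`` (``none`` if
    the actor emitted no record, e.g. was in time-out)."""
    for r in log.records:
        if r.turn_index == turn and r.actor_id == actor:
            return classify_record(r)
    return NONE


# ---------------------------------------------------------------------------
# Model-facing event stream
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpportunityEvent:
    """One (observer turn, candidate target) zap opportunity."""

    seq: int
    turn: int
    observer: int
    target: int
    relation: str  # relation of target to observer
    could_zap: bool
    observed_action: str  # zap / avoid / none — what the observer did
    chose_zap: bool       # whether the observer's zap ray included target
    star_dist: float      # scaled
    target_dist: float    # scaled
    divisor: float


def _relations(log: GameLog) -> dict[int, str]:
    return {p.player_id: p.relation_to_participant for p in log.config.players}


def _teams(log: GameLog) -> dict[int, str]:
    return {p.player_id: p.team for p in log.config.players}


def _participant(log: GameLog, participant_id: int | None) -> int:
    if participant_id is not None:
        return participant_id
    pid = log.config.participant_id
    if pid is None:
        raise ValueError("log has no participant seat; pass participant_id")
    return pid


def _covariates(record: TurnRecord, observer: int, target: int,
                divisor: float, grid_size: int) -> tuple[float, float]:
    pos = record.positions[observer]
    if record.stars:
        sd = min(manhattan(pos, s) for s in record.stars)
    else:
        sd = _max_dist(grid_size)
    td = manhattan(pos, record.positions[target])
    return sd / divisor, td / divisor


def extract_participant_decisions(log: GameLog, participant_id: int | None = None,
                                  divisor: float = DEFAULT_DIVISOR
                                  ) -> list[OpportunityEvent]:
    """All (turn, target) zap opportunities of the participant, in turn
    order then target-id order, with covariates from the pre-move state."""
    pid = _participant(log, participant_id)
    rels = _relations(log)
    out: list[OpportunityEvent] = []
    seq = 0
    g = log.config.grid_size
    for r in log.records:
        seq += 1
        if r.actor_id != pid:
            continue
        pos = r.positions[pid]
        cls = classify_record(r)
        for target in sorted(r.positions):
            if target == pid or not shared_line(pos, r.positions[target]):
                continue
            sd, td = _covariates(r, pid, target, divisor, g)
            hit = target in r.zapped_ids
            out.append(OpportunityEvent(
                seq=seq, turn=r.turn_index, observer=pid, target=target,
                relation=rels[target], could_zap=True,
                observed_action=ZAP if hit else (cls if cls == AVOID else NONE),
                chose_zap=hit, star_dist=sd, target_dist=td, divisor=divisor))
    return out


def build_event_stream(log: GameLog, participant_id: int | None = None,
                       divisor: float = DEFAULT_DIVISOR):
    """Chronological (observation | decision) stream for the learning model.

    Observations cover every *other* player's classified zap/avoid act
    (bot-vs-bot acts included); the participant's own records become
    decision events, one candidate entry per in-line target.  Returns a list
    of ``stargrid.model`` ``Observation``/``Decision`` events.
    """
    from .model import Observation, Decision, DecisionTarget

    pid = _participant(log, participant_id)
    rels = _relations(log)
    teams = _teams(log)
    g = log.config.grid_size
    events = []
    for seq, r in enumerate(log.records, start=1):
        if r.actor_id == pid:
            pos = r.positions[pid]
            targets = []
            for target in sorted(r.positions):
                if target == pid or not shared_line(pos, r.positions[target]):
                    continue
                sd, td = _covariates(r, pid, target, divisor, g)
                targets.append(DecisionTarget(
                    target=target, relation=rels[target], star_dist=sd,
                    target_dist=td, chose_zap=target in r.zapped_ids))
            if targets:
                events.append(Decision(seq=seq, turn=r.turn_index, targets=tuple(targets)))
        else:
            cls = classify_record(r)
            if cls == NONE:
                continue
            mates = tuple(
                (qid, rels[qid]) for qid in sorted(teams)
                if qid not in (r.actor_id, pid) and teams[qid] == teams[r.actor_id]
                and rels[r.actor_id] != NEUTRAL_REL)
            events.append(Observation(
                seq=seq, turn=r.turn_index, actor=r.actor_id,
                relation=rels[r.actor_id], action=cls, teammates=mates))
    return events


def events_to_frame(events: Iterable[OpportunityEvent]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in events])


# ---------------------------------------------------------------------------
# Aggregate behavioral measures
# ---------------------------------------------------------------------------

def _target_labels(log: GameLog, pid: int) -> pd.DataFrame:
    rows = []
    for p in log.config.players:
        if p.player_id == pid:
            continue
        rows.append({"target": p.player_id,
                     "relation": p.relation_to_participant,
                     "behavior": p.policy})
    return pd.DataFrame(rows)


def zap_rate(log: GameLog, participant_id: int | None = None,
             group_by: tuple[str, ...] = ("relation", "behavior"),
             denominator: str = "pairs",
             turn_range: tuple[int, int] | None = None) -> pd.DataFrame:
    """Zaps divided by zap opportunities, per target group.

    ``denominator="pairs"`` counts each (turn, target) opportunity;
    ``"turns"`` counts turns with at least one in-line target (a zap of any
    target counts as a zap that turn).  Cells with zero opportunities are
    reported as missing (NaN), never as 0.
    """
    pid = _participant(log, participant_id)
    ops = extract_participant_decisions(log, pid)
    if turn_range is not None:
        lo, hi = turn_range
        ops = [e for e in ops if lo <= e.turn < hi]
    labels = _target_labels(log, pid)
    if denominator == "pairs":
        df = events_to_frame(ops) if ops else pd.DataFrame(
            columns=["target", "chose_zap"])
        agg = (df.groupby("target")["chose_zap"].agg(["sum", "count"])
               .rename(columns={"sum": "zaps", "count": "opportunities"})
               .reset_index()) if len(df) else pd.DataFrame(
                   columns=["target", "zaps", "opportunities"])
    elif denominator == "turns":
        rows: dict[int, list[int]] = {}
        for e in ops:
            rows.setdefault(e.target, [0, 0])
        per_turn: dict[tuple[int, int], list] = {}
        for e in ops:
            per_turn.setdefault((e.turn, e.target), []).append(e.chose_zap)
        counts: dict[int, list[int]] = {}
        for (turn, target), zs in per_turn.items():
            c = counts.setdefault(target, [0, 0])
            c[0] += int(any(zs))
            c[1] += 1
        agg = pd.DataFrame(
            [{"target": t, "zaps": c[0], "opportunities": c[1]}
             for t, c in counts.items()])
    else:
        raise ValueError("denominator must be 'pairs' or 'turns'")
    out = labels.merge(agg, on="target", how="left")
    out[["zaps", "opportunities"]] = (out[["zaps", "opportunities"]]
                                      .astype(float).fillna(0).astype(int))
    out["rate"] = np.where(out["opportunities"] > 0,
                           out["zaps"] / out["opportunities"].replace(0, 1), np.nan)
    if group_by:
        grouped = (out.groupby(list(group_by))[["zaps", "opportunities"]]
                   .sum().reset_index())
        grouped["rate"] = np.where(grouped["opportunities"] > 0,
                                   grouped["zaps"] / grouped["opportunities"].replace(0, 1),
                                   np.nan)
        return grouped
    return out


def time_binned_rates(log: GameLog, participant_id: int | None = None,
                      bin_size: int = 25,
                      group_by: tuple[str, ...] = ("relation", "behavior")
                      ) -> pd.DataFrame:
    """`zap_rate` restricted to consecutive ``bin_size``-turn bins."""
    n = log.config.n_turns
    frames = []
    truncated = n % bin_size != 0
    for b, lo in enumerate(range(0, n, bin_size)):
        hi = min(lo + bin_size, n)
        df = zap_rate(log, participant_id, group_by, turn_range=(lo, hi))
        df.insert(0, "bin", b)
        df.insert(1, "turns", f"{lo}-{hi - 1}")
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["truncated_last_bin"] = truncated
    return out


def cross_path_rate(log: GameLog, participant_id: int | None = None,
                    group_by: tuple[str, ...] = ("relation", "behavior")
                    ) -> pd.DataFrame:
    """Fraction of participant moves landing in line with each other player,
    out of the moves where some legal step would have crossed that player."""
    from .game import landing_cell, DIRECTIONS

    pid = _participant(log, participant_id)
    g = log.config.grid_size
    counts: dict[int, list[int]] = {}
    for r in log.records:
        if r.actor_id != pid or r.action.kind != "move":
            continue
        pos = r.positions[pid]
        occupied = set(r.positions.values())
        dest = landing_cell(pos, r.action.direction, g)
        if dest is None or dest in occupied:
            dest = pos  # blocked move: no displacement
        reachable = [pos]
        for d in DIRECTIONS:
            cell = landing_cell(pos, d, g)
            if cell is not None and cell not in occupied:
                reachable.append(cell)
        for qid, q in r.positions.items():
            if qid == pid:
                continue
            c = counts.setdefault(qid, [0, 0])
            if any(shared_line(cell, q) for cell in reachable):
                c[1] += 1
                if shared_line(dest, q):
                    c[0] += 1
    labels = _target_labels(log, pid)
    agg = pd.DataFrame([{"target": t, "crossings": c[0], "possible": c[1]}
                        for t, c in counts.items()])
    if len(agg) == 0:
        agg = pd.DataFrame(columns=["target", "crossings", "possible"])
    out = labels.merge(agg, on="target", how="left")
    out[["crossings", "possible"]] = (out[["crossings", "possible"]]
                                      .astype(float).fillna(0).astype(int))
    if group_by:
        out = (out.groupby(list(group_by))[["crossings", "possible"]]
               .sum().reset_index())
    out["rate"] = np.where(out["possible"] > 0,
                           out["crossings"] / out["possible"].replace(0, 1), np.nan)
    return out
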