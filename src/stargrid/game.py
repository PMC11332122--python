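"""Star-harvest grid-world engine.

Five players move on a square grid collecting stars; instead of moving a
player may "zap": emit a ray in one of the four cardinal directions that
sends every player caught in it to a time-out zone for a fixed number of
turns.  Two scripted bot policies are provided: *zappers* zap a competitor
who blocks their path to a star, *avoiders* never zap and reroute instead.

Coordinates are 0-based ``(row, col)`` with the origin at the top-left;
``up`` decreases the row index.  All distances are Manhattan (L1) — the
natural path metric of a 4-connected grid.

Determinism: a single seeded ``numpy.random.Generator`` drives each game,
with a fixed draw order per round (star spawn, star expiry, time-out
re-entry, then any policy randomness in turn order).  Identical
(config, policies, seed) yield byte-identical logs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

Position = tuple[int, int]

UP, DOWN, LEFT, RIGHT = "up", "down", "left", "right"
DIRECTIONS = (UP, DOWN, LEFT, RIGHT)
DELTAS: dict[str, tuple[int, int]] = {
    UP: (-1, 0),
    DOWN: (1, 0),
    LEFT: (0, -1),
    RIGHT: (0, 1),
}

GROUPS, NEUTRAL = "groups", "neutral"
ALL_ZAPPERS, ALL_AVOIDERS, MIXED = "all_zappers", "all_avoiders", "mixed"

PARTICIPANT, BOT = "participant", "bot"
ZAPPER, AVOIDER, MODEL_AGENT, EXTERNAL = "zapper", "avoider", "model_agent", "external"
INGROUP, OUTGROUP, NEUTRAL_REL, SELF = "ingroup", "outgroup", "neutral", "self"


def manhattan(a: Position, b: Position) -> int:
    return abs(a[0] - b[0]) + abs(a[1] - b[1])


@dataclass(frozen=True)
class PlayerSpec:
    """One seat at the table: the human participant slot or a bot."""

    player_id: int
    role: str = BOT
    policy: str = AVOIDER
    team: str = ""
    relation_to_participant: str = NEUTRAL_REL

    def __post_init__(self):
        if self.role not in (PARTICIPANT, BOT):
            raise ValueError(f"unknown role {self.role!r}")
        if self.policy not in (ZAPPER, AVOIDER, MODEL_AGENT, EXTERNAL):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.relation_to_participant not in (INGROUP, OUTGROUP, NEUTRAL_REL, SELF):
            raise ValueError(f"unknown relation {self.relation_to_participant!r}")


def make_players(grouping: str = GROUPS, behavior: str = MIXED) -> tuple[PlayerSpec, ...]:
    """Standard 5-seat layout: participant (id 0) plus four bots.

    In the grouped conditions bots 1–2 share the participant's team color
    and bots 3–4 belong to the other team; in the mixed condition each team
    contributes one zapper and one avoider.  In the neutral condition every
    player has a distinct color.
    """
    if behavior == ALL_ZAPPERS:
        policies = [ZAPPER] * 4
    elif behavior == ALL_AVOIDERS:
        policies = [AVOIDER] * 4
    elif behavior == MIXED:
        policies = [ZAPPER, AVOIDER, ZAPPER, AVOIDER]
    else:
        raise ValueError(f"unknown behavior condition {behavior!r}")
    players = [PlayerSpec(0, PARTICIPANT, MODEL_AGENT, "blue", SELF)]
    if grouping == GROUPS:
        teams = ["blue", "blue", "orange", "orange"]
        rels = [INGROUP, INGROUP, OUTGROUP, OUTGROUP]
    elif grouping == NEUTRAL:
        teams = ["green", "red", "purple", "yellow"]
        rels = [NEUTRAL_REL] * 4
    else:
        raise ValueError(f"unknown grouping condition {grouping!r}")
    for i in range(4):
        players.append(PlayerSpec(i + 1, BOT, policies[i], teams[i], rels[i]))
    return tuple(players)


@dataclass(frozen=True)
class GameConfig:
    grid_size: int = 10
    n_players: int = 5
    n_turns: int = 100
    star_spawn_prob: float = 0.75
    # The original description says uncollected stars "can disappear" but
    # never gives the probability; 0.05/star/round is this package's default.
    star_expire_prob: float = 0.05
    timeout_turns: int = 3
    n_initial_stars: int = 5
    ray_stops_at_first: bool = False
    grouping: str = GROUPS
    behavior: str = MIXED
    players: tuple[PlayerSpec, ...] = ()
    turn_order: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.grid_size < 4:
            raise ValueError("grid_size must be >= 4")
        if self.n_players < 2:
            raise ValueError("n_players must be >= 2")
        for p in (self.star_spawn_prob, self.star_expire_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("star probabilities must lie in [0, 1]")
        if self.timeout_turns < 1:
            raise ValueError("timeout_turns must be >= 1")
        if not self.players:
            object.__setattr__(self, "players", make_players(self.grouping, self.behavior))
        if len(self.players) != self.n_players:
            raise ValueError("players list does not match n_players")
        ids = [p.player_id for p in self.players]
        if not self.turn_order:
            object.__setattr__(self, "turn_order", tuple(ids))
        if sorted(self.turn_order) != sorted(ids):
            raise ValueError("turn_order must be a permutation of player ids")

    @property
    def participant_id(self) -> int | None:
        for p in self.players:
            if p.role == PARTICIPANT:
                return p.player_id
        return None

    def spec(self, player_id: int) -> PlayerSpec:
        for p in self.players:
            if p.player_id == player_id:
                return p
        raise KeyError(player_id)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["players"] = [dataclasses.asdict(p) for p in self.players]
        d["turn_order"] = list(self.turn_order)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GameConfig":
        d = dict(d)
        d["players"] = tuple(PlayerSpec(**p) for p in d.get("players", ()))
        d["turn_order"] = tuple(d.get("turn_order", ()))
        return cls(**d)


@dataclass(frozen=True)
class Action:
    kind: str  # "move" | "zap"
    direction: str

    def __post_init__(self):
        if self.kind not in ("move", "zap"):
            raise ValueError(f"unknown action kind {self.kind!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class GridState:
    """Evolving board: positions, time-outs, scores and star cells.

    ``stars`` is kept in spawn order so "lowest star index" tie-breaks are
    reproducible.  Players inside the time-out zone are absent from
    ``positions``.
    """

    turn_index: int
    positions: dict[int, Position]
    timeout: dict[int, int]
    scores: dict[int, int]
    stars: list[Position]
    just_zapped: set[int] = field(default_factory=set)

    def copy(self) -> "GridState":
        return GridState(
            self.turn_index,
            dict(self.positions),
            dict(self.timeout),
            dict(self.scores),
            list(self.stars),
            set(self.just_zapped),
        )

    def active_players(self) -> list[int]:
        return sorted(self.positions)

    def check_invariants(self, config: GameConfig) -> None:
        occupied = list(self.positions.values())
        if len(occupied) != len(set(occupied)):
            raise AssertionError("two active players share a cell")
        g = config.grid_size
        for pos in occupied:
            if not (0 <= pos[0] < g and 0 <= pos[1] < g):
                raise AssertionError("player off-grid")
        for c in self.timeout.values():
            if not 0 <= c <= config.timeout_turns:
                raise AssertionError("timeout counter out of range")


@dataclass(frozen=True)
class TurnRecord:
    """One player's action with the pre-move board snapshot."""

    turn_index: int
    actor_id: int
    positions: dict[int, Position]
    stars: list[Position]
    action: Action
    zapped_ids: tuple[int, ...]
    star_collected: bool

    def to_dict(self) -> dict:
        return {
            "turn": self.turn_index,
            "actor": self.actor_id,
            "positions": {str(k): list(v) for k, v in self.positions.items()},
            "stars": [list(s) for s in self.stars],
            "action": {"kind": self.action.kind, "direction": self.action.direction},
            "zapped": list(self.zapped_ids),
            "star_collected": self.star_collected,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TurnRecord":
        return cls(
            turn_index=d["turn"],
            actor_id=d["actor"],
            positions={int(k): tuple(v) for k, v in d["positions"].items()},
            stars=[tuple(s) for s in d["stars"]],
            action=Action(**d["action"]),
            zapped_ids=tuple(d["zapped"]),
            star_collected=d["star_collected"],
        )


@dataclass
class GameLog:
    config: GameConfig
    records: list[TurnRecord]

    def to_jsonl(self) -> str:
        lines = [json.dumps({"type": "config", **self.config.to_dict()}, sort_keys=True)]
        for r in self.records:
            lines.append(json.dumps({"type": "turn", **r.to_dict()}, sort_keys=True))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str) -> "GameLog":
        config = None
        records = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            kind = d.pop("type")
            if kind == "config":
                config = GameConfig.from_dict(d)
            elif kind == "turn":
                records.append(TurnRecord.from_dict(d))
            else:
                raise ValueError(f"unknown record type {kind!r}")
        if config is None:
            raise ValueError("log has no config header line")
        return cls(config, records)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_jsonl())

    @classmethod
    def load(cls, path) -> "GameLog":
        with open(path) as fh:
            return cls.from_jsonl(fh.read())

    def zap_count(self) -> int:
        return sum(1 for r in self.records if r.action.kind == "zap")


# ---------------------------------------------------------------------------
# Core transitions
# ---------------------------------------------------------------------------

def landing_cell(pos: Position, direction: str, grid_size: int) -> Position | None:
    """Cell a move lands on, or None if it leaves the grid."""
    dr, dc = DELTAS[direction]
    r, c = pos[0] + dr, pos[1] + dc
    if not (0 <= r < grid_size and 0 <= c < grid_size):
        return None
    return (r, c)


def ray_targets(state: GridState, actor: int, direction: str,
                stop_at_first: bool = False) -> list[int]:
    """Active players hit by a zap ray, ordered by distance from the actor."""
    ar, ac = state.positions[actor]
    dr, dc = DELTAS[direction]
    hits = []
    for pid, (r, c) in state.positions.items():
        if pid == actor:
            continue
        if dr != 0 and c == ac and (r - ar) * dr > 0:
            hits.append((abs(r - ar), pid))
        elif dc != 0 and r == ar and (c - ac) * dc > 0:
            hits.append((abs(c - ac), pid))
    hits.sort()
    pids = [pid for _, pid in hits]
    return pids[:1] if (stop_at_first and pids) else pids


def apply_action(state: GridState, actor: int, action: Action,
                 config: GameConfig) -> tuple[GridState, tuple[int, ...], bool]:
    """Apply one action; returns (new state, zapped ids, star collected).

    Moves blocked by the grid edge or an occupied cell leave the position
    unchanged.  A zap removes every active player on the ray from the grid
    and starts their time-out counter; the actor does not move.
    """
    if actor not in state.positions:
        raise ValueError(f"player {actor} is in time-out and cannot act")
    new = state.copy()
    zapped: tuple[int, ...] = ()
    collected = False
    if action.kind == "move":
        dest = landing_cell(new.positions[actor], action.direction, config.grid_size)
        if dest is not None and dest not in new.positions.values():
            new.positions[actor] = dest
            if dest in new.stars:
                new.stars.remove(dest)
                new.scores[actor] = new.scores.get(actor, 0) + 1
                collected = True
    else:
        zapped = tuple(ray_targets(new, actor, action.direction, config.ray_stops_at_first))
        for pid in zapped:
            del new.positions[pid]
            new.timeout[pid] = config.timeout_turns
            new.just_zapped.add(pid)
    return new, zapped, collected


def _free_cells(state: GridState, grid_size: int) -> list[Position]:
    occupied = set(state.positions.values()) | set(state.stars)
    return [(r, c) for r in range(grid_size) for c in range(grid_size)
            if (r, c) not in occupied]


def advance_round(state: GridState, rng: np.random.Generator,
                  config: GameConfig) -> GridState:
    """End-of-round bookkeeping after all active players have acted.

    Draw order is fixed: (1) star spawn — with probability
    ``star_spawn_prob`` one star appears at a uniformly random cell free of
    players and stars; (2) star expiry — each pre-existing star is removed
    independently with probability ``star_expire_prob``; (3) time-out
    re-entry — counters of players zapped in *earlier* rounds tick down and
    players reaching 0 re-enter at a uniformly random free cell.  Players
    zapped during this round keep their full counter so that they sit out
    exactly ``timeout_turns`` subsequent rounds.
    """
    new = state.copy()
    # 1. spawn
    spawned: Position | None = None
    if config.star_spawn_prob > 0 and rng.random() < config.star_spawn_prob:
        free = _free_cells(new, config.grid_size)
        if free:
            spawned = free[rng.integers(len(free))]
    # 2. expiry of pre-existing stars
    if config.star_expire_prob > 0:
        new.stars = [s for s in new.stars if rng.random() >= config.star_expire_prob]
    if spawned is not None:
        new.stars.append(spawned)
    # 3. re-entry
    for pid in sorted(new.timeout):
        if pid in new.just_zapped:
            continue  # zapped this round: full wait starts next round
        new.timeout[pid] -= 1
        if new.timeout[pid] <= 0:
            occupied = set(new.positions.values()) | set(new.stars)
            g = config.grid_size
            free = [(r, c) for r in range(g) for c in range(g) if (r, c) not in occupied]
            if free:
                new.positions[pid] = free[rng.integers(len(free))]
                del new.timeout[pid]
            else:
                new.timeout[pid] = 0  # retry next round
    new.just_zapped.clear()
    new.turn_index += 1
    return new


# ---------------------------------------------------------------------------
# Bot policies
# ---------------------------------------------------------------------------

def _nearest_star(state: GridState, pid: int) -> tuple[Position, int] | None:
    """Nearest star by (distance, spawn index); None if the board is bare."""
    pos = state.positions[pid]
    best = None
    for idx, star in enumerate(state.stars):
        key = (manhattan(pos, star), idx)
        if best is None or key < best[0]:
            best = (key, star)
    return (best[1], best[0][0]) if best else None


def _unique_closest_stars(state: GridState, pid: int) -> list[tuple[int, int]]:
    """(distance, star index) for stars this player is strictly closest to."""
    pos = state.positions[pid]
    out = []
    for idx, star in enumerate(state.stars):
        d = manhattan(pos, star)
        if all(manhattan(q, star) > d
               for qid, q in state.positions.items() if qid != pid):
            out.append((d, idx))
    out.sort()
    return out


def _weakly_closest_stars(state: GridState, pid: int) -> list[tuple[int, int]]:
    pos = state.positions[pid]
    out = []
    for idx, star in enumerate(state.stars):
        d = manhattan(pos, star)
        if all(manhattan(q, star) >= d
               for qid, q in state.positions.items() if qid != pid):
            out.append((d, idx))
    out.sort()
    return out


def _move_toward(state: GridState, pid: int, goal: Position,
                 config: GameConfig) -> Action:
    """Step reducing L1 distance to goal; row axis preferred, and a blocked
    preferred step falls back to the other reducing axis, then to any legal
    direction, before accepting a no-op."""
    pos = state.positions[pid]
    candidates: list[str] = []
    if goal[0] != pos[0]:
        candidates.append(UP if goal[0] < pos[0] else DOWN)
    if goal[1] != pos[1]:
        candidates.append(LEFT if goal[1] < pos[1] else RIGHT)
    occupied = set(state.positions.values())
    for d in candidates + [d for d in DIRECTIONS if d not in candidates]:
        dest = landing_cell(pos, d, config.grid_size)
        if dest is not None and dest not in occupied:
            return Action("move", d)
    return Action("move", candidates[0] if candidates else UP)  # fully boxed in


def _direction_to(src: Position, dst: Position) -> str:
    if src[0] == dst[0]:
        return LEFT if dst[1] < src[1] else RIGHT
    return UP if dst[0] < src[0] else DOWN


def _random_legal_move(state: GridState, pid: int, rng: np.random.Generator,
                       config: GameConfig) -> Action:
    pos = state.positions[pid]
    occupied = set(state.positions.values())
    legal = [d for d in DIRECTIONS
             if (dest := landing_cell(pos, d, config.grid_size)) is not None
             and dest not in occupied]
    if not legal:
        return Action("move", UP)
    return Action("move", legal[rng.integers(len(legal))])


def _competitors(state: GridState, pid: int, star: Position, dist: int) -> list[int]:
    """Active players strictly closer than pid to pid's nearest star."""
    return sorted(qid for qid, q in state.positions.items()
                  if qid != pid and manhattan(q, star) < dist)


def zapper_policy(state: GridState, self_id: int, rng: np.random.Generator,
                  config: GameConfig) -> Action:
    """Star-seeking bot that zaps a competitor blocking its path.

    Cascade: (i) strictly closest to some star → step toward the nearest
    such star; (ii) in competition (another player strictly closer to own
    nearest star) and a competitor shares the row or column → zap toward the
    lowest-id such competitor; (iii) otherwise step toward the nearest star;
    (iv) bare board → uniformly random legal move.  Zaps thus happen only in
    competition over a star, never opportunistically.
    """
    if not state.stars:
        return _random_legal_move(state, self_id, rng, config)
    mine = _unique_closest_stars(state, self_id)
    if mine:
        return _move_toward(state, self_id, state.stars[mine[0][1]], config)
    star, dist = _nearest_star(state, self_id)
    rivals = _competitors(state, self_id, star, dist)
    pos = state.positions[self_id]
    for qid in rivals:
        q = state.positions[qid]
        if q[0] == pos[0] or q[1] == pos[1]:
            return Action("zap", _direction_to(pos, q))
    return _move_toward(state, self_id, star, config)


def avoider_policy(state: GridState, self_id: int, rng: np.random.Generator,
                   config: GameConfig) -> Action:
    """Star-seeking bot that never zaps: under competition it reroutes to a
    star it can win (weakly closest), else retreats from the rival."""
    if not state.stars:
        return _random_legal_move(state, self_id, rng, config)
    mine = _unique_closest_stars(state, self_id)
    if mine:
        return _move_toward(state, self_id, state.stars[mine[0][1]], config)
    star, dist = _nearest_star(state, self_id)
    rivals = _competitors(state, self_id, star, dist)
    if not rivals:
        return _move_toward(state, self_id, star, config)
    winnable = _weakly_closest_stars(state, self_id)
    if winnable:
        return _move_toward(state, self_id, state.stars[winnable[0][1]], config)
    # retreat: maximize distance from the lowest-id rival; ties row-then-column
    rival = state.positions[rivals[0]]
    pos = state.positions[self_id]
    occupied = set(state.positions.values())
    best: tuple[int, int, str] | None = None
    for rank, d in enumerate((UP, DOWN, LEFT, RIGHT)):
        dest = landing_cell(pos, d, config.grid_size)
        if dest is None or dest in occupied:
            continue
        key = (-manhattan(dest, rival), rank, d)
        if best is None or key < best:
            best = key
    if best is None:
        return Action("move", UP)
    return Action("move", best[2])


POLICIES: dict[str, Callable] = {ZAPPER: zapper_policy, AVOIDER: avoider_policy}


# ---------------------------------------------------------------------------
# Game loop
# ---------------------------------------------------------------------------

def initial_state(config: GameConfig, rng: np.random.Generator) -> GridState:
    """Players at distinct random cells; ``n_initial_stars`` on free cells."""
    g = config.grid_size
    cells = [(r, c) for r in range(g) for c in range(g)]
    idx = rng.choice(len(cells), size=config.n_players + config.n_initial_stars,
                     replace=False)
    chosen = [cells[i] for i in idx]
    positions = {p.player_id: chosen[i] for i, p in enumerate(config.players)}
    stars = chosen[config.n_players:]
    return GridState(0, positions, {}, {p.player_id: 0 for p in config.players},
                     list(stars))


def run_game(config: GameConfig,
             policies: Mapping[int, Callable] | None = None,
             seed: int | None = None,
             observers: Sequence[Callable] | None = None,
             check: bool = False) -> GameLog:
    """Play ``n_turns`` rounds in fixed turn order and return the log.

    ``policies`` maps player id to a callable ``(state, pid, rng) -> Action``
    and overrides the scripted policy named in the player spec.  Players in
    time-out emit no record.  ``observers`` are called as
    ``observer(record, pre_state)`` after every action — the hook the
    model-driven agent uses to watch other players.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    resolved: dict[int, Callable] = {}
    for p in config.players:
        if policies and p.player_id in policies:
            resolved[p.player_id] = policies[p.player_id]
        elif p.policy in POLICIES:
            resolved[p.player_id] = (
                lambda state, pid, r, _f=POLICIES[p.policy]: _f(state, pid, r, config))
        else:
            raise ValueError(
                f"player {p.player_id} has policy {p.policy!r} but no callable was supplied")
    state = initial_state(config, rng)
    records: list[TurnRecord] = []
    for _ in range(config.n_turns):
        for pid in config.turn_order:
            if pid not in state.positions:
                continue  # in time-out: no record
            action = resolved[pid](state, pid, rng)
            if not isinstance(action, Action):
                raise ValueError(f"policy for player {pid} returned {action!r}")
            pre = state
            state, zapped, collected = apply_action(state, pid, action, config)
            record = TurnRecord(
                turn_index=pre.turn_index,
                actor_id=pid,
                positions=dict(pre.positions),
                stars=list(pre.stars),
                action=action,
                zapped_ids=zapped,
                star_collected=collected,
            )
            records.append(record)
            if observers:
                for obs in observers:
                    obs(record, pre)
        state = advance_round(state, rng, config)
        if check:
            state.check_invariants(config)
    return GameLog(config, records)
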