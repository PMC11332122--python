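"""Synthetic studies: bot-only games, replay-based model predictions, and
closed-loop model-driven participants with known parameters.

Three layers, mirroring how the method is validated:

* :func:`simulate_bot_game` — a game where every seat runs a scripted
  policy; the participant slot follows the avoider policy as a stand-in so
  its positions (and hence decision covariates) are well defined.
* :func:`replay_predict` — runs the learning model *against* a recorded
  game: the bots' logged behavior forms the observation stream, and at each
  of the participant slot's zap opportunities the model emits a choice
  probability and a sampled decision, without altering the log.
* :func:`simulate_participant` / :func:`simulate_study` — closed-loop games
  where the participant seat is driven by the model itself (learning
  online), with per-participant parameters sampled from group-level
  distributions.  The ground truth is stored for recovery scoring.

Generative decision scheme: on the agent's turn the in-line candidate
targets are visited in random order; each gets an independent Bernoulli
draw at its model probability, and the first success produces a zap toward
that target (otherwise the agent moves by the avoider policy).  This keeps
the per-opportunity Bernoulli likelihood and the generative process
consistent, at the cost that at most one zap can occur per turn.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .game import (Action, GameConfig, GameLog, GridState, TurnRecord,
                   avoider_policy, run_game, GROUPS, MIXED, NEUTRAL_REL)
from .events import build_event_stream, classify_record, shared_line
from .model import (ModelParams, PLA, forward_pass, update_actor_belief,
                    update_teammate_belief, zap_probability,
                    RATE_NAMES, PARAM_NAMES)
from scipy.special import expit, logit


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

#: Default group-level means (natural scale).  Decision weights follow the
#: scaled-covariate convention (distances divided by 10).
DEFAULT_GROUP_MEANS = {
    "bias": -1.01, "prior_in": -0.87, "prior_out": -0.12,
    "w_star_dist": 0.26, "w_target_dist": -1.84, "w_target_zap": 0.89,
    "lr_zap_in": 0.71, "lr_zap_out": 0.84,
    "lr_avoid_in": 0.08, "lr_avoid_out": 0.13,
    "at_zap_in": 0.19, "at_zap_out": 0.22,
    "at_avoid_in": 0.14, "at_avoid_out": 0.02,
}

#: Between-participant sd on the sampling scale (linear directly, rates on
#: the logit scale): moderate heterogeneity without drowning group signal.
DEFAULT_GROUP_SD = 0.5

RATE_SET = set(RATE_NAMES)


@dataclass
class TrueParams:
    """Generating group-level distribution and per-participant samples."""

    group_means: dict[str, float]            # natural scale
    group_sds: dict[str, float]              # sampling scale
    participants: dict[int, ModelParams] = field(default_factory=dict)
    seed: int = 0

    def sampling_scale_mean(self, name: str) -> float:
        v = self.group_means[name]
        return float(logit(np.clip(v, 1e-6, 1 - 1e-6))) if name in RATE_SET else v


def sample_participant_params(true: TrueParams, rng: np.random.Generator
                              ) -> ModelParams:
    vals = {}
    for name in PARAM_NAMES:
        mu = true.sampling_scale_mean(name)
        sd = true.group_sds.get(name, DEFAULT_GROUP_SD)
        draw = rng.normal(mu, sd)
        vals[name] = float(expit(draw)) if name in RATE_SET else float(draw)
    return ModelParams(**vals)


def default_true_params(seed: int = 0,
                        group_means: dict[str, float] | None = None,
                        group_sd: float = DEFAULT_GROUP_SD) -> TrueParams:
    means = dict(DEFAULT_GROUP_MEANS)
    if group_means:
        means.update(group_means)
    return TrueParams(group_means=means,
                      group_sds={n: group_sd for n in PARAM_NAMES}, seed=seed)


# ---------------------------------------------------------------------------
# Bot-only games and replay prediction
# ---------------------------------------------------------------------------

def simulate_bot_game(config: GameConfig | None = None, seed: int = 0,
                      grouping: str = GROUPS, behavior: str = MIXED
                      ) -> GameLog:
    """A full game with scripted bots; the participant slot plays as an
    avoider placeholder so replay covariates are always defined."""
    if config is None:
        config = GameConfig(grouping=grouping, behavior=behavior, seed=seed)
    pid = config.participant_id
    policies = {}
    if pid is not None:
        policies[pid] = lambda state, p, rng: avoider_policy(state, p, rng, config)
    return run_game(config, policies=policies, seed=seed)


@dataclass
class ReplayResult:
    """Model predictions replayed against a recorded game."""

    probabilities: np.ndarray          # per (turn, target) opportunity
    opportunities: list[tuple[int, int]]
    sampled_zaps: np.ndarray           # Bernoulli decisions, one per opportunity
    target_relation: dict[int, str]
    target_policy: dict[int, str]
    trajectories: dict[int, np.ndarray]

    def zap_rate_by(self, attr: str = "policy") -> pd.DataFrame:
        lab = self.target_policy if attr == "policy" else self.target_relation
        df = pd.DataFrame({
            "target": [t for _, t in self.opportunities],
            "p": self.probabilities,
            "zap": self.sampled_zaps.astype(int),
        })
        df["label"] = df["target"].map(lab)
        return (df.groupby("label")[["p", "zap"]].mean()
                .rename(columns={"p": "mean_prob", "zap": "zap_rate"}))


def replay_predict(bot_log: GameLog, params: ModelParams, variant: str = PLA,
                   seed: int = 0, participant_id: int | None = None
                   ) -> ReplayResult:
    """Discard the participant slot's recorded choices and generate the
    model's predicted zapping behavior from the bots' logged acts.

    The participant slot's logged *positions* anchor the decision
    covariates; its logged actions never enter the observation stream, and
    the bots' recorded behavior is read, never modified.  Sampling follows
    the generative scheme described in the module docstring (candidates in
    random order, first Bernoulli success zaps) so sampled zap rates are
    directly comparable to the closed-loop simulator.
    """
    pid = participant_id if participant_id is not None else bot_log.config.participant_id
    if pid is None:
        raise ValueError("log has no participant seat; pass participant_id")
    events = build_event_stream(bot_log, pid)
    res = forward_pass(events, params, variant)
    rng = np.random.default_rng(seed)
    # group opportunities by decision turn, then sample in random order
    sampled = np.zeros(len(res.opportunities), dtype=bool)
    by_seq: dict[int, list[int]] = {}
    for i, (seq, _t) in enumerate(res.opportunities):
        by_seq.setdefault(seq, []).append(i)
    for seq in sorted(by_seq):
        idxs = by_seq[seq]
        order = rng.permutation(len(idxs))
        for j in order:
            i = idxs[j]
            if rng.random() < res.probabilities[i]:
                sampled[i] = True
                break
    spec = {p.player_id: p for p in bot_log.config.players}
    rels = {t: spec[t].relation_to_participant for t in res.targets if t in spec}
    pols = {t: spec[t].policy for t in res.targets if t in spec}
    return ReplayResult(
        probabilities=res.probabilities, opportunities=res.opportunities,
        sampled_zaps=sampled, target_relation=rels, target_policy=pols,
        trajectories=res.trajectories)


# ---------------------------------------------------------------------------
# Closed-loop model-driven participant
# ---------------------------------------------------------------------------

class ModelAgent:
    """Stateful policy: observes other players, keeps beliefs, and decides
    to zap by the model's decision rule.  Plug into ``run_game`` via the
    policies map plus the observer hook."""

    def __init__(self, config: GameConfig, params: ModelParams,
                 variant: str = PLA, divisor: float = 10.0):
        self.config = config
        self.params = params.with_variant(variant)
        self.pid = config.participant_id
        self.divisor = divisor
        self.beliefs: dict[int, float] = {
            p.player_id: 0.0 for p in config.players if p.player_id != self.pid}
        self._rels = {p.player_id: p.relation_to_participant
                      for p in config.players}
        self._teams = {p.player_id: p.team for p in config.players}

    # -- observer hook -----------------------------------------------------
    def observe(self, record: TurnRecord, pre_state: GridState) -> None:
        if record.actor_id == self.pid:
            return
        cls = classify_record(record)
        if cls == "none":
            return
        actor = record.actor_id
        rel = self._rels[actor]
        self.beliefs[actor] = update_actor_belief(self.beliefs[actor], cls,
                                                  rel, self.params)
        if rel != NEUTRAL_REL:
            for mate, team in self._teams.items():
                if mate in (actor, self.pid):
                    continue
                if team == self._teams[actor]:
                    self.beliefs[mate] = update_teammate_belief(
                        self.beliefs[mate], cls, self._rels[mate], self.params)

    # -- policy ------------------------------------------------------------
    def __call__(self, state: GridState, pid: int,
                 rng: np.random.Generator) -> Action:
        pos = state.positions[pid]
        candidates = [t for t in sorted(state.positions)
                      if t != pid and shared_line(pos, state.positions[t])]
        if candidates:
            order = rng.permutation(len(candidates))
            if state.stars:
                star_d = min(self._dist(pos, s) for s in state.stars)
            else:
                star_d = 2 * (self.config.grid_size - 1)
            for j in order:
                t = candidates[j]
                td = self._dist(pos, state.positions[t])
                p = zap_probability(self.params, self._rels[t],
                                    star_d / self.divisor, td / self.divisor,
                                    self.beliefs[t])
                if rng.random() < p:
                    return Action("zap", self._direction(pos, state.positions[t]))
        return avoider_policy(state, pid, rng, self.config)

    @staticmethod
    def _dist(a, b):
        return abs(a[0] - b[0]) + abs(a[1] - b[1])

    @staticmethod
    def _direction(src, dst):
        if src[0] == dst[0]:
            return "left" if dst[1] < src[1] else "right"
        return "up" if dst[0] < src[0] else "down"


def simulate_participant(config: GameConfig, params: ModelParams,
                         variant: str = PLA, seed: int = 0) -> GameLog:
    """One closed-loop game: bots by their scripted policies, the
    participant seat by the model agent with the given parameters."""
    agent = ModelAgent(config, params, variant)
    if agent.pid is None:
        raise ValueError("config has no participant seat")
    return run_game(config, policies={agent.pid: agent}, seed=seed,
                    observers=[agent.observe])


# ---------------------------------------------------------------------------
# Whole-study generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    logs: list[GameLog]
    true_params: TrueParams
    manifest: dict

    def event_streams(self, divisor: float = 10.0) -> dict[int, list]:
        return {i: build_event_stream(log, divisor=divisor)
                for i, log in enumerate(self.logs)}


def simulate_study(n_participants: int = 60,
                   true_params: TrueParams | None = None,
                   seed: int = 0,
                   grouping: str = GROUPS,
                   behavior: str = MIXED,
                   variant: str = PLA,
                   n_turns: int = 100) -> SyntheticDataset:
    """Generate a cohort of closed-loop games with known ground truth.

    Per-participant parameters are sampled from the group-level
    distributions (rates on the logit scale, then transformed); each game
    gets its own derived seed so the dataset is reproducible bit-exact from
    the manifest.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    true = true_params if true_params is not None else default_true_params(seed)
    master = np.random.default_rng(seed)
    logs = []
    for i in range(n_participants):
        p = sample_participant_params(true, master)
        game_seed = int(master.integers(2 ** 31 - 1))
        config = GameConfig(grouping=grouping, behavior=behavior,
                            n_turns=n_turns, seed=game_seed)
        logs.append(simulate_participant(config, p, variant, seed=game_seed))
        true.participants[i] = p
    manifest = {
        "seed": seed, "n_participants": n_participants, "variant": variant,
        "grouping": grouping, "behavior": behavior, "n_turns": n_turns,
        "group_means": true.group_means, "group_sds": true.group_sds,
        "config_hash": hashlib.sha256(
            json.dumps(logs[0].config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
    }
    return SyntheticDataset(logs=logs, true_params=true, manifest=manifest)
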