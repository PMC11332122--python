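"""Trial-by-trial social-learning models of the decision to zap.

The decision rule is a logistic choice model over one candidate target at a
time::

    p(zap) = logistic(Bias + Prior(relation)
                      + w_star_dist * star_dist
                      + w_target_dist * target_dist
                      + w_target_zap * belief)

where ``belief`` is the learner's running estimate in [0, 1] of that
target's likelihood to zap.  Beliefs start at 0 (prior inclinations live in
the Prior terms) and evolve by a delta rule driven by the prediction error
between the observed act (zap = 1, avoid = 0) and the current belief:

* direct learning — the acting player's own belief moves by a learning
  rate ``lr_{zap,avoid}_{in,out}``;
* group-level attribution — beliefs about the actor's *teammates* move by
  an attribution rate ``at_{zap,avoid}_{in,out}`` on the same prediction
  error.

Three nested variants: ``P`` (priors only; all lr and at forced to 0),
``PL`` (priors + direct learning; at forced to 0) and ``PLA`` (all three
mechanisms).  Neutral-condition targets get a Prior term of 0 and one
shared learning-rate pair (no teams, so attribution never applies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .game import INGROUP, OUTGROUP, NEUTRAL_REL

P, PL, PLA = "P", "PL", "PLA"
VARIANTS = (P, PL, PLA)

RATE_NAMES = ("lr_zap_in", "lr_zap_out", "lr_avoid_in", "lr_avoid_out",
              "at_zap_in", "at_zap_out", "at_avoid_in", "at_avoid_out")
LINEAR_NAMES = ("bias", "prior_in", "prior_out",
                "w_star_dist", "w_target_dist", "w_target_zap")
PARAM_NAMES = LINEAR_NAMES + RATE_NAMES

#: parameters active (free) under each variant
ACTIVE = {
    P: LINEAR_NAMES,
    PL: LINEAR_NAMES + RATE_NAMES[:4],
    PLA: PARAM_NAMES,
}

PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Every free parameter of the decision rule and both update rules.

    Rates are on the probability scale, in [0, 1].  ``lr_zap_neutral`` /
    ``lr_avoid_neutral`` cover neutral-condition targets and default to the
    in/out average; they only matter for simulation (fits use grouped
    data).
    """

    bias: float = 0.0
    prior_in: float = 0.0
    prior_out: float = 0.0
    w_star_dist: float = 0.0
    w_target_dist: float = 0.0
    w_target_zap: float = 0.0
    lr_zap_in: float = 0.0
    lr_zap_out: float = 0.0
    lr_avoid_in: float = 0.0
    lr_avoid_out: float = 0.0
    at_zap_in: float = 0.0
    at_zap_out: float = 0.0
    at_avoid_in: float = 0.0
    at_avoid_out: float = 0.0
    lr_zap_neutral: float | None = None
    lr_avoid_neutral: float | None = None

    def __post_init__(self):
        for name in RATE_NAMES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in LINEAR_NAMES:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.lr_zap_neutral is None:
            object.__setattr__(self, "lr_zap_neutral",
                               0.5 * (self.lr_zap_in + self.lr_zap_out))
        if self.lr_avoid_neutral is None:
            object.__setattr__(self, "lr_avoid_neutral",
                               0.5 * (self.lr_avoid_in + self.lr_avoid_out))

    def prior(self, relation: str) -> float:
        if relation == INGROUP:
            return self.prior_in
        if relation == OUTGROUP:
            return self.prior_out
        return 0.0

    def learning_rate(self, action: str, relation: str) -> float:
        if relation == NEUTRAL_REL:
            return self.lr_zap_neutral if action == "zap" else self.lr_avoid_neutral
        suffix = "in" if relation == INGROUP else "out"
        return getattr(self, f"lr_{'zap' if action == 'zap' else 'avoid'}_{suffix}")

    def attribution_rate(self, action: str, relation: str) -> float:
        if relation == NEUTRAL_REL:
            return 0.0
        suffix = "in" if relation == INGROUP else "out"
        return getattr(self, f"at_{'zap' if action == 'zap' else 'avoid'}_{suffix}")

    def with_variant(self, variant: str) -> "ModelParams":
        """Coerce to a variant by zeroing the mechanisms it excludes."""
        if variant == PLA:
            return self
        if variant == PL:
            return replace(self, at_zap_in=0.0, at_zap_out=0.0,
                           at_avoid_in=0.0, at_avoid_out=0.0)
        if variant == P:
            return replace(self, lr_zap_in=0.0, lr_zap_out=0.0,
                           lr_avoid_in=0.0, lr_avoid_out=0.0,
                           at_zap_in=0.0, at_zap_out=0.0,
                           at_avoid_in=0.0, at_avoid_out=0.0,
                           lr_zap_neutral=0.0, lr_avoid_neutral=0.0)
        raise ValueError(f"unknown variant {variant!r}")

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in PARAM_NAMES}


@dataclass(frozen=True)
class Observation:
    """Another player's classified act, as seen by the learner."""

    seq: int
    turn: int
    actor: int
    relation: str            # actor's relation to the learner
    action: str              # "zap" | "avoid"
    teammates: tuple[tuple[int, str], ...] = ()  # (player_id, relation)


@dataclass(frozen=True)
class DecisionTarget:
    target: int
    relation: str
    star_dist: float
    target_dist: float
    chose_zap: bool


@dataclass(frozen=True)
class Decision:
    """The learner's own turn: one candidate entry per in-line target."""

    seq: int
    turn: int
    targets: tuple[DecisionTarget, ...]


Event = Observation | Decision


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def zap_probability(params: ModelParams, relation: str, star_dist: float,
                    target_dist: float, target_belief: float) -> float:
    """Logistic choice probability for one candidate target."""
    if not (math.isfinite(star_dist) and math.isfinite(target_dist)):
        raise ValueError("covariates must be finite")
    eta = (params.bias + params.prior(relation)
           + params.w_star_dist * star_dist
           + params.w_target_dist * target_dist
           + params.w_target_zap * target_belief)
    return float(expit(eta))


def update_actor_belief(belief: float, observed: str, relation: str,
                        params: ModelParams) -> float:
    """Delta-rule update of the belief about the player who just acted."""
    lr = params.learning_rate(observed, relation)
    outcome = 1.0 if observed == "zap" else 0.0
    return belief + lr * (outcome - belief)


def update_teammate_belief(belief_other: float, observed: str, relation: str,
                           params: ModelParams) -> float:
    """Group-level attribution: same delta rule with the attribution rate."""
    at = params.attribution_rate(observed, relation)
    outcome = 1.0 if observed == "zap" else 0.0
    return belief_other + at * (outcome - belief_other)


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

@dataclass
class ForwardResult:
    """Belief trajectories and per-opportunity choice probabilities.

    ``trajectories[target]`` has one entry per event (belief *after* that
    event), prefixed by the initial value 0.  ``probabilities`` aligns with
    ``opportunities`` — the flattened (decision, target) pairs in stream
    order.
    """

    targets: list[int]
    trajectories: dict[int, np.ndarray]
    opportunities: list[tuple[int, int]]  # (seq, target)
    probabilities: np.ndarray
    chose_zap: np.ndarray


def _check_order(events: Sequence[Event]) -> None:
    last = -1
    for e in events:
        if e.seq <= last:
            raise ValueError("event stream is not in increasing seq order")
        last = e.seq


def forward_pass(events: Sequence[Event], params: ModelParams,
                 variant: str = PLA) -> ForwardResult:
    """Run the learner over a chronological event stream.

    Observations update the acting player's belief (and, under PLA, each
    same-team partner's belief); decisions emit one choice probability per
    candidate using the beliefs current at that moment.  Pure: identical
    inputs give bit-identical outputs.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    _check_order(events)
    p = params.with_variant(variant)
    beliefs: dict[int, float] = {}
    traj: dict[int, list[float]] = {}

    def ensure(target: int) -> None:
        if target not in beliefs:
            beliefs[target] = 0.0
            traj[target] = [0.0] * (len(done) + 1)

    done: list[Event] = []
    opportunities: list[tuple[int, int]] = []
    probs: list[float] = []
    chosen: list[bool] = []
    for e in events:
        if isinstance(e, Observation):
            ensure(e.actor)
            beliefs[e.actor] = update_actor_belief(beliefs[e.actor], e.action,
                                                   e.relation, p)
            for mate, mate_rel in e.teammates:
                ensure(mate)
                beliefs[mate] = update_teammate_belief(beliefs[mate], e.action,
                                                       mate_rel, p)
        else:
            for t in e.targets:
                ensure(t.target)
                opportunities.append((e.seq, t.target))
                probs.append(zap_probability(p, t.relation, t.star_dist,
                                             t.target_dist, beliefs[t.target]))
                chosen.append(t.chose_zap)
        done.append(e)
        for target in beliefs:
            traj[target].append(beliefs[target])
    return ForwardResult(
        targets=sorted(beliefs),
        trajectories={t: np.asarray(v) for t, v in traj.items()},
        opportunities=opportunities,
        probabilities=np.asarray(probs, dtype=float),
        chose_zap=np.asarray(chosen, dtype=bool),
    )


def pointwise_loglik(events: Sequence[Event], params: ModelParams,
                     variant: str = PLA) -> np.ndarray:
    """One Bernoulli log-likelihood term per (decision, target) opportunity."""
    res = forward_pass(events, params, variant)
    p = np.clip(res.probabilities, PROB_FLOOR, 1.0 - PROB_FLOOR)
    return np.where(res.chose_zap, np.log(p), np.log1p(-p))


# ---------------------------------------------------------------------------
# Flat encoding + fast likelihood kernel (used by fitting)
# ---------------------------------------------------------------------------

REL_CODE = {INGROUP: 0, OUTGROUP: 1, NEUTRAL_REL: 2}
MAX_MATES = 3


@dataclass
class EncodedStream:
    """Event stream flattened to numpy arrays for the likelihood kernel.

    Rows are events in order; decision events contribute one row per
    candidate target (consecutive rows sharing ``seq``; no updates occur
    between them, so per-row processing is exact).
    """

    ev_type: np.ndarray     # int8: 0 observation, 1 decision-target
    player: np.ndarray      # int32 index of actor (obs) / target (decision)
    rel: np.ndarray         # int8 relation code of that player
    act: np.ndarray         # int8: obs zap=1/avoid=0; decision chose_zap
    mates: np.ndarray       # int32 (n, MAX_MATES), -1 padded
    mate_rel: np.ndarray    # int8  (n, MAX_MATES)
    star_dist: np.ndarray   # float64
    target_dist: np.ndarray  # float64
    player_ids: list[int]
    n_decisions: int


def encode_stream(events: Sequence[Event]) -> EncodedStream:
    _check_order(events)
    ids: list[int] = []

    def idx(pid: int) -> int:
        if pid not in ids:
            ids.append(pid)
        return ids.index(pid)

    rows = []
    for e in events:
        if isinstance(e, Observation):
            mates = [(idx(m), REL_CODE[r]) for m, r in e.teammates]
            rows.append((0, idx(e.actor), REL_CODE[e.relation],
                         1 if e.action == "zap" else 0, mates, 0.0, 0.0))
        else:
            for t in e.targets:
                rows.append((1, idx(t.target), REL_CODE[t.relation],
                             int(t.chose_zap), [], t.star_dist, t.target_dist))
    n = len(rows)
    enc = EncodedStream(
        ev_type=np.zeros(n, dtype=np.int8),
        player=np.zeros(n, dtype=np.int32),
        rel=np.zeros(n, dtype=np.int8),
        act=np.zeros(n, dtype=np.int8),
        mates=np.full((n, MAX_MATES), -1, dtype=np.int32),
        mate_rel=np.zeros((n, MAX_MATES), dtype=np.int8),
        star_dist=np.zeros(n, dtype=np.float64),
        target_dist=np.zeros(n, dtype=np.float64),
        player_ids=ids,
        n_decisions=0,
    )
    for i, (et, pl, rl, ac, mates, sd, td) in enumerate(rows):
        enc.ev_type[i] = et
        enc.player[i] = pl
        enc.rel[i] = rl
        enc.act[i] = ac
        for j, (m, mr) in enumerate(mates[:MAX_MATES]):
            enc.mates[i, j] = m
            enc.mate_rel[i, j] = mr
        enc.star_dist[i] = sd
        enc.target_dist[i] = td
    enc.n_decisions = int((enc.ev_type == 1).sum())
    return enc


def _kernel_py(ev_type, player, rel, act, mates, mate_rel, star_dist,
               target_dist, theta, n_players, out_prob):
    """Natural-scale parameter vector ``theta`` layout:

    [bias, prior_in, prior_out, w_star, w_target, w_zap,
     lr_zap_in, lr_zap_out, lr_zap_neu, lr_avoid_in, lr_avoid_out,
     lr_avoid_neu, at_zap_in, at_zap_out, at_avoid_in, at_avoid_out]
    """
    beliefs = np.zeros(n_players)
    priors = np.array([theta[1], theta[2], 0.0])
    k = 0
    for i in range(ev_type.shape[0]):
        if ev_type[i] == 0:
            r = rel[i]
            if act[i] == 1:
                lr = theta[6 + r]
                beliefs[player[i]] += lr * (1.0 - beliefs[player[i]])
            else:
                lr = theta[9 + r]
                beliefs[player[i]] += lr * (0.0 - beliefs[player[i]])
            for j in range(mates.shape[1]):
                m = mates[i, j]
                if m < 0:
                    break
                mr = mate_rel[i, j]
                if mr > 1:
                    continue
                if act[i] == 1:
                    at = theta[12 + mr]
                    beliefs[m] += at * (1.0 - beliefs[m])
                else:
                    at = theta[14 + mr]
                    beliefs[m] += at * (0.0 - beliefs[m])
        else:
            eta = (theta[0] + priors[rel[i]] + theta[3] * star_dist[i]
                   + theta[4] * target_dist[i] + theta[5] * beliefs[player[i]])
            if eta > 0:
                pz = 1.0 / (1.0 + math.exp(-eta))
            else:
                ex = math.exp(eta)
                pz = ex / (1.0 + ex)
            out_prob[k] = pz
            k += 1
    return k


def _kernel_sum_py(ev_type, player, rel, act, mates, mate_rel, star_dist,
                   target_dist, theta, n_players):
    """Fused variant of the kernel returning the summed Bernoulli
    log-likelihood of the decision rows (floor-clamped)."""
    beliefs = np.zeros(n_players)
    p_in, p_out = theta[1], theta[2]
    total = 0.0
    floor_log = math.log(PROB_FLOOR)
    for i in range(ev_type.shape[0]):
        if ev_type[i] == 0:
            r = rel[i]
            if act[i] == 1:
                beliefs[player[i]] += theta[6 + r] * (1.0 - beliefs[player[i]])
            else:
                beliefs[player[i]] += theta[9 + r] * (0.0 - beliefs[player[i]])
            for j in range(mates.shape[1]):
                m = mates[i, j]
                if m < 0:
                    break
                mr = mate_rel[i, j]
                if mr > 1:
                    continue
                if act[i] == 1:
                    beliefs[m] += theta[12 + mr] * (1.0 - beliefs[m])
                else:
                    beliefs[m] += theta[14 + mr] * (0.0 - beliefs[m])
        else:
            prior = p_in if rel[i] == 0 else (p_out if rel[i] == 1 else 0.0)
            eta = (theta[0] + prior + theta[3] * star_dist[i]
                   + theta[4] * target_dist[i] + theta[5] * beliefs[player[i]])
            # log p or log(1-p) directly from eta, clamped at the floor
            if act[i] == 1:
                t = -eta
            else:
                t = eta
            if t > 0:
                term = -t - math.log1p(math.exp(-t))
            else:
                term = -math.log1p(math.exp(t))
            if term < floor_log:
                term = floor_log
            total += term
    return total


try:  # JIT-compile the hot loops when numba is available
    from numba import njit

    _kernel = njit(cache=True)(_kernel_py)
    _kernel_sum = njit(cache=True)(_kernel_sum_py)
except ImportError:  # pragma: no cover - numba is a standard install here
    _kernel = _kernel_py
    _kernel_sum = _kernel_sum_py


def stream_loglik_sum(enc: EncodedStream, theta_nat: np.ndarray) -> float:
    """Summed Bernoulli log-likelihood via the fused kernel (fast path)."""
    return float(_kernel_sum(enc.ev_type, enc.player, enc.rel, enc.act,
                             enc.mates, enc.mate_rel, enc.star_dist,
                             enc.target_dist, theta_nat, len(enc.player_ids)))


def stream_loglik(enc: EncodedStream, theta_nat: np.ndarray) -> np.ndarray:
    """Pointwise Bernoulli log-likelihood terms via the fast kernel."""
    probs = np.empty(enc.n_decisions)
    _kernel(enc.ev_type, enc.player, enc.rel, enc.act, enc.mates, enc.mate_rel,
            enc.star_dist, enc.target_dist, theta_nat, len(enc.player_ids),
            probs)
    probs = np.clip(probs, PROB_FLOOR, 1.0 - PROB_FLOOR)
    chose = enc.act[enc.ev_type == 1].astype(bool)
    return np.where(chose, np.log(probs), np.log1p(-probs))


def params_to_theta(params: ModelParams) -> np.ndarray:
    """Natural-scale kernel vector from a ModelParams."""
    return np.array([
        params.bias, params.prior_in, params.prior_out,
        params.w_star_dist, params.w_target_dist, params.w_target_zap,
        params.lr_zap_in, params.lr_zap_out, params.lr_zap_neutral,
        params.lr_avoid_in, params.lr_avoid_out, params.lr_avoid_neutral,
        params.at_zap_in, params.at_zap_out,
        params.at_avoid_in, params.at_avoid_out,
    ])
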