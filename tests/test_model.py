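"""Decision rule, belief updates, forward pass and its invariants."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from stargrid.model import (Decision, DecisionTarget, ModelParams,
                            Observation, encode_stream, forward_pass,
                            params_to_theta, pointwise_loglik,
                            stream_loglik, stream_loglik_sum,
                            update_actor_belief, update_teammate_belief,
                            zap_probability)

TABLE_PARAMS = dict(bias=-1.01, prior_in=-0.87, prior_out=-0.12,
                    w_star_dist=0.26, w_target_dist=-1.84, w_target_zap=0.89,
                    lr_zap_in=0.71, lr_zap_out=0.84,
                    lr_avoid_in=0.08, lr_avoid_out=0.13,
                    at_zap_in=0.19, at_zap_out=0.22,
                    at_avoid_in=0.14, at_avoid_out=0.02)


class TestZapProbability:
    def test_all_zero_gives_half(self):
        p = ModelParams()
        assert zap_probability(p, "ingroup", 0, 0, 0) == 0.5

    def test_fitted_outgroup_intercepts(self):
        # published decision weights with zero covariates and belief:
        # eta = bias + prior_out = -1.01 - 0.12 = -1.13
        p = ModelParams(bias=-1.01, prior_out=-0.12, w_star_dist=0.03,
                        w_target_dist=-0.18, w_target_zap=0.89)
        assert zap_probability(p, "outgroup", 0, 0, 0) == pytest.approx(
            expit(-1.13), abs=1e-12)

    def test_neutral_relation_has_no_prior(self):
        p = ModelParams(prior_in=2.0, prior_out=-2.0)
        assert zap_probability(p, "neutral", 0, 0, 0) == 0.5

    def test_monotone_in_belief_when_weight_positive(self):
        p = ModelParams(w_target_zap=0.89)
        probs = [zap_probability(p, "ingroup", 0.3, 0.4, b)
                 for b in np.linspace(0, 1, 7)]
        assert all(a < b for a, b in zip(probs, probs[1:]))

    def test_nonfinite_covariates_rejected(self):
        with pytest.raises(ValueError):
            zap_probability(ModelParams(), "ingroup", float("nan"), 0, 0)


class TestBeliefUpdates:
    def test_zap_from_zero(self):
        p = ModelParams(lr_zap_in=0.9)
        assert update_actor_belief(0.0, "zap", "ingroup", p) == 0.9

    def test_avoid_decays(self):
        p = ModelParams(lr_avoid_out=0.25)
        assert update_actor_belief(0.5, "avoid", "outgroup", p) == 0.375

    def test_repeated_zaps_follow_geometric_closed_form(self):
        p = ModelParams(lr_zap_in=0.2)
        b = 0.0
        seen = []
        for _ in range(50):
            b = update_actor_belief(b, "zap", "ingroup", p)
            seen.append(b)
        assert b == pytest.approx(1 - 0.8 ** 50, abs=1e-12)
        assert all(x < y for x, y in zip(seen, seen[1:]))

    def test_zero_attribution_leaves_teammate_unchanged(self):
        p = ModelParams()
        assert update_teammate_belief(0.37, "zap", "outgroup", p) == 0.37

    def test_fitted_attribution_step(self):
        p = ModelParams(at_zap_out=0.22)
        assert update_teammate_belief(0.4, "zap", "outgroup", p) == pytest.approx(
            0.532, abs=1e-12)

    def test_full_attribution_tracks_actor(self):
        # equal rates and equal starting beliefs -> identical updates
        p = ModelParams(lr_zap_in=0.55, at_zap_in=0.55)
        a = update_actor_belief(0.3, "zap", "ingroup", p)
        b = update_teammate_belief(0.3, "zap", "ingroup", p)
        assert a == b


def toy_stream():
    return [
        Observation(seq=1, turn=0, actor=1, relation="ingroup", action="zap",
                    teammates=((2, "ingroup"),)),
        Observation(seq=2, turn=0, actor=3, relation="outgroup",
                    action="avoid", teammates=((4, "outgroup"),)),
        Decision(seq=3, turn=1, targets=(
            DecisionTarget(1, "ingroup", 0.3, 0.2, False),
            DecisionTarget(3, "outgroup", 0.3, 0.5, True),
        )),
        Observation(seq=4, turn=1, actor=1, relation="ingroup", action="zap",
                    teammates=((2, "ingroup"),)),
        Decision(seq=5, turn=2, targets=(
            DecisionTarget(2, "ingroup", 0.1, 0.4, False),
        )),
    ]


def random_stream(rng, n_events=40, n_players=4):
    events = []
    teams = {1: "a", 2: "a", 3: "b", 4: "b"}
    rels = {1: "ingroup", 2: "ingroup", 3: "outgroup", 4: "outgroup"}
    for seq in range(1, n_events + 1):
        if rng.random() < 0.7:
            actor = int(rng.integers(1, n_players + 1))
            mates = tuple((m, rels[m]) for m in teams
                          if m != actor and teams[m] == teams[actor])
            events.append(Observation(
                seq=seq, turn=seq, actor=actor, relation=rels[actor],
                action="zap" if rng.random() < 0.4 else "avoid",
                teammates=mates))
        else:
            k = int(rng.integers(1, 4))
            targets = tuple(
                DecisionTarget(int(t), rels[int(t)],
                               float(rng.uniform(0, 1.8)),
                               float(rng.uniform(0.1, 1.0)),
                               bool(rng.random() < 0.2))
                for t in rng.choice(range(1, 5), size=k, replace=False))
            events.append(Decision(seq=seq, turn=seq, targets=targets))
    return events


class TestForwardPass:
    def test_three_observation_stream_matches_hand_computation(self):
        p = ModelParams(**TABLE_PARAMS)
        res = forward_pass(toy_stream(), p, "PLA")
        # hand-rolled sequential oracle
        b1 = 0.71 * 1.0                      # zap by 1 (lr_zap_in)
        b2 = 0.19 * 1.0                      # attribution to teammate 2
        b3 = 0.0 + 0.13 * (0.0 - 0.0)        # avoid by 3 from 0 stays 0
        b4 = 0.0
        p1 = expit(-1.01 - 0.87 + 0.26 * 0.3 - 1.84 * 0.2 + 0.89 * b1)
        p3 = expit(-1.01 - 0.12 + 0.26 * 0.3 - 1.84 * 0.5 + 0.89 * b3)
        b1 += 0.71 * (1 - b1)
        b2 += 0.19 * (1 - b2)
        p2 = expit(-1.01 - 0.87 + 0.26 * 0.1 - 1.84 * 0.4 + 0.89 * b2)
        assert res.probabilities == pytest.approx([p1, p3, p2], abs=1e-12)
        assert res.trajectories[1][-1] == pytest.approx(b1, abs=1e-12)
        assert res.trajectories[2][-1] == pytest.approx(b2, abs=1e-12)
        assert res.trajectories[3][-1] == pytest.approx(b3, abs=1e-12)
        assert res.trajectories[4][-1] == pytest.approx(b4, abs=1e-12)

    def test_variant_p_freezes_beliefs(self):
        p = ModelParams(**TABLE_PARAMS)
        res = forward_pass(toy_stream(), p, "P")
        for traj in res.trajectories.values():
            assert np.all(traj == 0.0)

    def test_pla_with_zero_attribution_equals_pl(self, rng):
        p = dataclasses.replace(ModelParams(**TABLE_PARAMS),
                                at_zap_in=0.0, at_zap_out=0.0,
                                at_avoid_in=0.0, at_avoid_out=0.0)
        ev = random_stream(rng)
        a = forward_pass(ev, p, "PLA")
        b = forward_pass(ev, p, "PL")
        assert np.array_equal(a.probabilities, b.probabilities)

    def test_pure_and_deterministic(self, rng):
        p = ModelParams(**TABLE_PARAMS)
        ev = random_stream(rng)
        a = forward_pass(ev, p, "PLA")
        b = forward_pass(ev, p, "PLA")
        assert np.array_equal(a.probabilities, b.probabilities)
        for t in a.trajectories:
            assert np.array_equal(a.trajectories[t], b.trajectories[t])

    def test_out_of_order_stream_rejected(self):
        ev = toy_stream()
        ev[1], ev[3] = ev[3], ev[1]
        with pytest.raises(ValueError):
            forward_pass(ev, ModelParams(), "PLA")

    def test_only_zap_observations_drive_belief_monotonically_to_one(self):
        p = ModelParams(lr_zap_in=0.3)
        ev = [Observation(seq=s, turn=s, actor=1, relation="ingroup",
                          action="zap") for s in range(1, 30)]
        res = forward_pass(ev, p, "PL")
        traj = res.trajectories[1]
        assert np.all(np.diff(traj[:-1]) >= 0)
        assert traj[-1] > 0.99

    def test_ingroup_outgroup_symmetry(self, rng):
        """Swapping group labels together with the paired parameters leaves
        the likelihood unchanged."""
        p = ModelParams(**TABLE_PARAMS)
        swapped = ModelParams(
            bias=p.bias, prior_in=p.prior_out, prior_out=p.prior_in,
            w_star_dist=p.w_star_dist, w_target_dist=p.w_target_dist,
            w_target_zap=p.w_target_zap,
            lr_zap_in=p.lr_zap_out, lr_zap_out=p.lr_zap_in,
            lr_avoid_in=p.lr_avoid_out, lr_avoid_out=p.lr_avoid_in,
            at_zap_in=p.at_zap_out, at_zap_out=p.at_zap_in,
            at_avoid_in=p.at_avoid_out, at_avoid_out=p.at_avoid_in)
        flip = {"ingroup": "outgroup", "outgroup": "ingroup"}
        ev = random_stream(rng)
        mirrored = []
        for e in ev:
            if isinstance(e, Observation):
                mirrored.append(dataclasses.replace(
                    e, relation=flip[e.relation],
                    teammates=tuple((m, flip[r]) for m, r in e.teammates)))
            else:
                mirrored.append(dataclasses.replace(e, targets=tuple(
                    dataclasses.replace(t, relation=flip[t.relation])
                    for t in e.targets)))
        assert pointwise_loglik(ev, p, "PLA").sum() == pytest.approx(
            pointwise_loglik(mirrored, swapped, "PLA").sum(), abs=1e-12)


class TestPointwiseLoglik:
    def test_half_probability_gives_k_log_two(self):
        ev = [Decision(seq=1, turn=0, targets=tuple(
            DecisionTarget(t, "neutral", 0, 0, False) for t in (1, 2, 3)))]
        ll = pointwise_loglik(ev, ModelParams(), "P")
        assert ll.sum() == pytest.approx(-3 * math.log(2), abs=1e-12)

    def test_empty_stream_gives_empty_vector(self):
        assert pointwise_loglik([], ModelParams(), "PLA").size == 0

    def test_length_equals_could_zap_opportunities(self, rng):
        ev = random_stream(rng)
        n = sum(len(e.targets) for e in ev if isinstance(e, Decision))
        assert pointwise_loglik(ev, ModelParams(**TABLE_PARAMS), "PLA").size == n


class TestKernelAgreement:
    """The fast encoded kernel is an independent path from forward_pass."""

    def test_kernel_matches_forward_pass_on_random_streams(self):
        master = np.random.default_rng(99)
        p = ModelParams(**TABLE_PARAMS)
        theta = params_to_theta(p)
        for _ in range(25):
            ev = random_stream(master)
            ll_ref = pointwise_loglik(ev, p, "PLA")
            enc = encode_stream(ev)
            assert stream_loglik(enc, theta) == pytest.approx(ll_ref, abs=1e-12)
            assert stream_loglik_sum(enc, theta) == pytest.approx(
                ll_ref.sum(), abs=1e-10)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000),
       lr=st.floats(0, 1), at=st.floats(0, 1))
def test_beliefs_always_stay_in_unit_interval(seed, lr, at):
    """Convex-combination updates can never leave [0, 1]."""
    rng = np.random.default_rng(seed)
    p = ModelParams(lr_zap_in=lr, lr_zap_out=lr, lr_avoid_in=lr,
                    lr_avoid_out=lr, at_zap_in=at, at_zap_out=at,
                    at_avoid_in=at, at_avoid_out=at)
    ev = random_stream(rng, n_events=60)
    res = forward_pass(ev, p, "PLA")
    for traj in res.trajectories.values():
        assert np.all(traj >= 0.0) and np.all(traj <= 1.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_pl_with_zero_learning_equals_p(seed):
    rng = np.random.default_rng(seed)
    p = ModelParams(**{**TABLE_PARAMS, "lr_zap_in": 0.0, "lr_zap_out": 0.0,
                       "lr_avoid_in": 0.0, "lr_avoid_out": 0.0})
    ev = random_stream(rng)
    a = forward_pass(ev, p, "PL")
    b = forward_pass(ev, p, "P")
    assert np.array_equal(a.probabilities, b.probabilities)
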