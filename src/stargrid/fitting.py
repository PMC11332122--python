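"""Hierarchical estimation of the learning-model parameters and WAIC model
comparison.

The estimator is a penalized-likelihood (empirical-Bayes) EM scheme with a
Laplace approximation for uncertainty.  Participant parameters live on a
sampling scale (linear parameters directly; rate parameters through a
logit link so they stay in (0, 1)) and are modelled as
``theta_i ~ Normal(mu, diag(sigma^2))`` around group-level means:

1. **E-step / per-participant MAP**: each participant's parameters are fit
   by penalized likelihood under the current group prior Normal(mu, sigma),
   and the local posterior is approximated as Gaussian via the inverse
   Hessian (Laplace).
2. **M-step**: ``mu_j = mean_i theta_ij`` (with a weakly informative
   Normal(0, prior_scale) hyperprior) and
   ``sigma_j^2 = mean_i[(theta_ij - mu_j)^2 + var_ij]`` — the Laplace
   E-step variance enters so weakly identified participants do not
   collapse the population sd.
3. Iterate to convergence, then sample posterior draws for every quantity
   (group means, participant parameters, pointwise log-likelihoods) from
   the Gaussian approximations; ``SE(mu_j) = sqrt(mean_i[(theta_ij -
   mu_j)^2 + var_ij] / n)``.

Because participants shrink toward the *estimated* group mean rather than
toward 0, the fixed point is free of the centering bias a single
weak-prior pass would inherit.

``method="mcmc"`` instead samples the joint hierarchical posterior with a
Metropolis-within-Gibbs scheme: per-participant parameter blocks move by
Metropolis proposals preconditioned with the Laplace covariances from an
EM warm start, group means are drawn from their conjugate normal
conditionals (Normal(0, prior_scale) hyperprior), and each population sd
takes a random-walk step on the log scale against a half-Normal(1) prior.
This is the reference method: several model parameters (notably the
learning rates and the belief weight) are only jointly weakly identified
per participant, and posterior averaging over that ridge is what the
Laplace point approximation cannot do.  ``method="map"`` (the EM fitter)
remains the fast fallback for repeated model-recovery sweeps.

Both methods are deterministic given (config, seed); parameters are
modelled as independent at the group level.

WAIC follows the standard pointwise definition on the deviance scale::

    lppd   = sum_i log mean_s exp(ll_si)
    pWAIC  = sum_i var_s(ll_si)
    WAIC   = -2 (lppd - pWAIC)
    SE     = sqrt(n * var_i(waic_i)),  waic_i = -2 (lppd_i - pwaic_i)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp

from .model import (ACTIVE, RATE_NAMES, PLA, VARIANTS, EncodedStream,
                    encode_stream, stream_loglik, stream_loglik_sum)

RATE_SET = set(RATE_NAMES)

#: kernel theta index for each free parameter (see model.stream_loglik)
_KERNEL_INDEX = {
    "bias": 0, "prior_in": 1, "prior_out": 2,
    "w_star_dist": 3, "w_target_dist": 4, "w_target_zap": 5,
    "lr_zap_in": 6, "lr_zap_out": 7,
    "lr_avoid_in": 9, "lr_avoid_out": 10,
    "at_zap_in": 12, "at_zap_out": 13,
    "at_avoid_in": 14, "at_avoid_out": 15,
}
_THETA_LEN = 16


@dataclass(frozen=True)
class FitConfig:
    variant: str = PLA
    method: str = "map"          # "map" = EB-MAP + Laplace draws
    chains: int = 4              # pseudo-chains for split-rhat on draws
    n_draws: int = 400           # total posterior draws
    seed: int = 0
    prior_scale: float = 2.5     # hyperprior sd on group means (sampling scale)
    sd_floor: float = 0.05       # lower bound for the population sd
    covariate_divisor: float = 10.0
    min_zaps: int = 1
    max_iter: int = 300
    em_iter: int = 25            # maximum EM sweeps
    em_tol: float = 1e-3         # stop when max |delta mu| falls below
    n_starts: int = 8            # multi-start count for the pooled anchor
    warmup: int = 1000           # MCMC warmup sweeps per chain
    thin: int = 10               # MCMC thinning interval

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.chains < 2:
            raise ValueError("chains must be >= 2 for rhat")
        if self.n_draws < self.chains:
            raise ValueError("n_draws must be positive and >= chains")


@dataclass
class PosteriorDraws:
    """Posterior draws and summaries from ``fit_hierarchical``.

    Sampling scale: linear parameters as-is, rates on the logit scale.
    ``group_mean_nat`` maps rate draws through the inverse logit.
    """

    variant: str
    param_names: list[str]
    participants: list
    group_mean: np.ndarray       # (S, P) sampling scale
    group_mean_nat: np.ndarray   # (S, P) natural scale
    group_sd: np.ndarray         # (P,) population sd point estimates
    participant_draws: np.ndarray  # (n, S, P) sampling scale
    pointwise_ll: np.ndarray     # (S, N_obs)
    obs_participant: np.ndarray  # (N_obs,) participant index per observation
    rhat: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.group_mean.shape[0]

    def group_mean_natural(self) -> pd.DataFrame:
        return pd.DataFrame(self.group_mean_nat, columns=self.param_names)


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

def apply_fitting_exclusions(datasets: Mapping, min_zaps: int = 1
                             ) -> tuple[dict, pd.DataFrame]:
    """Drop participants who zapped fewer than ``min_zaps`` times.

    ``datasets`` maps participant key -> event stream (model events).
    Returns the filtered mapping and a per-participant report.
    """
    from .model import Decision

    kept: dict = {}
    rows = []
    for key, events in datasets.items():
        zaps = sum(t.chose_zap for e in events if isinstance(e, Decision)
                   for t in e.targets)
        opportunities = sum(len(e.targets) for e in events
                            if isinstance(e, Decision))
        excluded = zaps < min_zaps
        rows.append({"participant": key, "zaps": int(zaps),
                     "opportunities": int(opportunities), "excluded": excluded})
        if not excluded:
            kept[key] = events
    report = pd.DataFrame(rows)
    if not kept:
        raise ValueError("all participants excluded: nothing left to fit")
    return kept, report


# ---------------------------------------------------------------------------
# Per-participant MAP machinery
# ---------------------------------------------------------------------------

_EXPANDERS: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _expand_theta(x: np.ndarray, names: Sequence[str]) -> np.ndarray:
    """Sampling-scale vector -> natural-scale kernel theta (rates via
    inverse logit, inactive entries 0)."""
    key = tuple(names)
    cached = _EXPANDERS.get(key)
    if cached is None:
        idx = np.array([_KERNEL_INDEX[n] for n in names], dtype=np.intp)
        is_rate = np.array([n in RATE_SET for n in names])
        _EXPANDERS[key] = cached = (idx, is_rate)
    idx, is_rate = cached
    v = np.asarray(x, dtype=float).copy()
    v[is_rate] = 1.0 / (1.0 + np.exp(-v[is_rate]))
    theta = np.zeros(_THETA_LEN)
    theta[idx] = v
    return theta


def _neg_log_post(x, enc, names, prior_mean, prior_sd):
    ll = stream_loglik_sum(enc, _expand_theta(x, names))
    pen = 0.5 * np.sum(((x - prior_mean) / prior_sd) ** 2)
    return -ll + pen


def _map_fit(enc: EncodedStream, names: Sequence[str], prior_mean: np.ndarray,
             prior_sd: np.ndarray, x0: np.ndarray | None = None,
             max_iter: int = 300, cov: str = "full"
             ) -> tuple[np.ndarray, np.ndarray]:
    """MAP estimate and Laplace covariance on the sampling scale.

    ``cov="diag"`` returns only marginal variances (diagonal curvature, much
    cheaper — used during EM sweeps); ``"full"`` inverts the full Hessian.
    """
    k = len(names)
    if x0 is None:
        x0 = prior_mean.astype(float).copy()
    res = minimize(_neg_log_post, x0, args=(enc, names, prior_mean, prior_sd),
                   method="L-BFGS-B", options={"maxiter": max_iter})
    xhat = res.x
    f = lambda x: _neg_log_post(x, enc, names, prior_mean, prior_sd)
    if cov == "diag":
        h = 1e-4
        f0 = f(xhat)
        d2 = np.empty(k)
        for i in range(k):
            e = np.zeros(k); e[i] = h
            d2[i] = (f(xhat + e) - 2 * f0 + f(xhat - e)) / h ** 2
        prior_prec = 1.0 / prior_sd ** 2
        d2 = np.maximum(d2, prior_prec)  # curvature at least the prior's
        return xhat, np.diag(1.0 / d2)
    hess = _numerical_hessian(f, xhat)
    return xhat, _safe_inverse(hess, k)


def _numerical_hessian(f, x, h: float = 1e-4) -> np.ndarray:
    k = x.size
    hess = np.empty((k, k))
    f0 = f(x)
    fp = np.empty(k)
    fm = np.empty(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = h
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            fpp = f(x + ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm) / (2 * h ** 2)
    return hess


def _safe_inverse(hess: np.ndarray, k: int) -> np.ndarray:
    """Invert a Hessian, jittering toward PD when curvature is degenerate."""
    jitter = 0.0
    for _ in range(8):
        try:
            h = hess + jitter * np.eye(k)
            eigvals = np.linalg.eigvalsh(h)
            if eigvals.min() > 1e-8:
                return np.linalg.inv(h)
        except np.linalg.LinAlgError:
            pass
        jitter = max(jitter * 10, 1e-6)
    # fall back to a diagonal approximation
    diag = np.clip(np.diag(hess), 1e-6, None)
    return np.diag(1.0 / diag)


# ---------------------------------------------------------------------------
# Hierarchical fit
# ---------------------------------------------------------------------------

def _pooled_fit(encs: list, names: list, config: FitConfig,
                anchor: np.ndarray | None = None) -> np.ndarray:
    """Common-parameter MAP over the whole cohort (one theta for everyone).

    The pooled likelihood is well identified even where single participants
    are not; it anchors the EM start so the hierarchical fit does not drift
    into a spurious joint mode.  ``anchor`` adds an extra start (used to
    chain nested variants so a richer model never fits worse than the model
    it nests).
    """
    k = len(names)
    prior_mean = np.zeros(k)
    prior_sd = np.full(k, config.prior_scale)

    def nll(x):
        theta = _expand_theta(x, names)
        ll = sum(stream_loglik_sum(e, theta) for e in encs)
        return -ll + 0.5 * np.sum(((x - prior_mean) / prior_sd) ** 2)

    # the surface is multimodal (learning rates trade off against the
    # belief weight): take the best of several scattered starts, plus
    # "nested corner" starts with rate blocks switched off (logit -4)
    rng = np.random.default_rng(config.seed + 104729)
    starts = [prior_mean]
    for block in ("at_", "lr_"):
        corner = prior_mean.copy()
        for j, name in enumerate(names):
            if name.startswith("at_") or (block == "lr_"
                                          and name.startswith("lr_")):
                corner[j] = -4.0
        starts.append(corner)
    if anchor is not None:
        starts.append(np.asarray(anchor, dtype=float))
    starts += [rng.normal(0.0, 1.0, size=k)
               for _ in range(max(0, config.n_starts - len(starts)))]
    best = None
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B",
                       options={"maxiter": config.max_iter})
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def _fit_em(encs: list, names: list, config: FitConfig,
            anchor: np.ndarray | None = None):
    """EM loop: returns (mu, sigma, theta, cov, var, se_mu)."""
    n, k = len(encs), len(names)
    mu = _pooled_fit(encs, names, config, anchor=anchor)
    sigma = np.full(k, 1.0)
    theta = np.tile(mu, (n, 1))
    cov = np.empty((n, k, k))
    var = np.empty((n, k))
    hyper_prec = 1.0 / config.prior_scale ** 2

    def sweep_fits(full: bool) -> None:
        for i, enc in enumerate(encs):
            xhat, c = _map_fit(enc, names, mu, sigma, x0=theta[i],
                               max_iter=config.max_iter,
                               cov="full" if full else "diag")
            theta[i] = xhat
            cov[i] = c
            var[i] = np.clip(np.diag(c), 1e-8, None)

    for sweep in range(config.em_iter):
        sweep_fits(full=False)
        new_mu = (theta.sum(axis=0) / sigma ** 2) / (
            n / sigma ** 2 + hyper_prec)
        sigma = np.sqrt(np.clip(
            ((theta - new_mu) ** 2 + var).mean(axis=0),
            config.sd_floor ** 2, None))
        delta = np.abs(new_mu - mu).max()
        mu = new_mu
        if delta < config.em_tol:
            break
    sweep_fits(full=True)
    se_mu = np.sqrt(((theta - mu) ** 2 + var).mean(axis=0) / n)
    return mu, sigma, theta, cov, var, se_mu


def _sample_gibbs(encs: list, names: list, config: FitConfig,
                  mu0, sigma0, theta0, cov0):
    """Metropolis-within-Gibbs on the joint hierarchical posterior.

    Participant blocks take preconditioned Metropolis steps; group means
    are conjugate; population sds take log-scale random-walk steps against
    a half-Normal(1) prior.  Group-level *translation* moves — shifting one
    coordinate of mu together with every participant's matching coordinate
    — let the chain traverse the weakly identified group-level ridges that
    per-participant steps cannot cross.  Returns stacked (group draws,
    participant draws) across ``config.chains`` chains.
    """
    warmup, thin = config.warmup, config.thin
    n, k = len(encs), len(names)
    kept_per_chain = config.n_draws // config.chains
    hyper_prec = 1.0 / config.prior_scale ** 2
    chol = np.empty((n, k, k))
    for i in range(n):
        chol[i] = np.linalg.cholesky(cov0[i] + 1e-9 * np.eye(k))
    ridge = None
    if {"bias", "prior_in", "prior_out"} <= set(names):
        ridge = np.zeros(k)
        ridge[names.index("bias")] = 1.0
        ridge[names.index("prior_in")] = -1.0
        ridge[names.index("prior_out")] = -1.0
    group_chains = []
    part_chains = []
    for chain in range(config.chains):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 7919, chain]))
        theta = theta0.copy()
        mu = mu0 + 0.05 * rng.standard_normal(k)
        sigma = sigma0.copy()
        scale = np.full(n, 2.38 / np.sqrt(k))
        tr_scale = np.full(k, 0.1)
        tr_acc = np.zeros(k)
        tr_tries = np.zeros(k)
        cur_ll = np.array([stream_loglik_sum(e, _expand_theta(theta[i], names))
                           for i, e in enumerate(encs)])
        acc = np.zeros(n)
        since = 0
        g_draws = np.empty((kept_per_chain, k))
        p_draws = np.empty((kept_per_chain, n, k))
        kept = 0
        total = warmup + kept_per_chain * thin
        for sweep in range(total):
            # participant blocks
            z = rng.standard_normal((n, k))
            logu = np.log(rng.random(n))
            for i in range(n):
                prop = theta[i] + scale[i] * (chol[i] @ z[i])
                ll = stream_loglik_sum(encs[i], _expand_theta(prop, names))
                d_prior = -0.5 * (((prop - mu) / sigma) ** 2
                                  - ((theta[i] - mu) / sigma) ** 2).sum()
                if ll - cur_ll[i] + d_prior > logu[i]:
                    theta[i] = prop
                    cur_ll[i] = ll
                    acc[i] += 1
            since += 1
            # adapt proposal scales during warmup
            if sweep < warmup and since == 40:
                rate = acc / since
                scale *= np.exp(np.clip(rate - 0.25, -0.5, 0.5))
                acc[:] = 0
                since = 0
            # group means: conjugate normal
            prec = n / sigma ** 2 + hyper_prec
            mean = (theta.sum(axis=0) / sigma ** 2) / prec
            mu = mean + rng.standard_normal(k) / np.sqrt(prec)
            # translation moves along group-level ridges
            for j in rng.choice(k, size=min(4, k), replace=False):
                delta = tr_scale[j] * rng.standard_normal()
                prop_theta = theta.copy()
                prop_theta[:, j] += delta
                new_ll = np.array([
                    stream_loglik_sum(encs[i], _expand_theta(prop_theta[i], names))
                    for i in range(n)])
                d_hyper = -0.5 * hyper_prec * ((mu[j] + delta) ** 2 - mu[j] ** 2)
                tr_tries[j] += 1
                if (new_ll.sum() - cur_ll.sum() + d_hyper
                        > np.log(rng.random())):
                    theta = prop_theta
                    cur_ll = new_ll
                    mu[j] += delta
                    tr_acc[j] += 1
            # bias/prior ridge: with only in/out targets the likelihood sees
            # just (bias+prior_in, bias+prior_out), so shifting everyone
            # along (+1, -1, -1) leaves it invariant; mix by prior alone
            if ridge is not None:
                delta = 0.5 * rng.standard_normal()
                mu_prop = mu + delta * ridge
                d_hyper = -0.5 * hyper_prec * (
                    (mu_prop ** 2).sum() - (mu ** 2).sum())
                if d_hyper > np.log(rng.random()):
                    mu = mu_prop
                    theta = theta + delta * ridge
            if sweep < warmup and sweep % 50 == 49:
                rate_tr = tr_acc / np.maximum(tr_tries, 1)
                tr_scale *= np.exp(np.clip(rate_tr - 0.25, -0.5, 0.5))
                tr_acc[:] = 0
                tr_tries[:] = 0
            # population sds: log-scale random walk vs half-Normal(1)
            prop_s = sigma * np.exp(0.15 * rng.standard_normal(k))
            dev2 = ((theta - mu) ** 2).sum(axis=0)
            def logp_sigma(s):
                return (-n * np.log(s) - 0.5 * dev2 / s ** 2
                        - 0.5 * s ** 2 + np.log(s))  # last terms: prior+Jacobian
            accept = logp_sigma(prop_s) - logp_sigma(sigma) > np.log(rng.random(k))
            sigma = np.where(accept & (prop_s > config.sd_floor), prop_s, sigma)
            if sweep >= warmup and (sweep - warmup) % thin == thin - 1:
                g_draws[kept] = mu
                p_draws[kept] = theta
                kept += 1
        group_chains.append(g_draws[:kept])
        part_chains.append(p_draws[:kept])
    group = np.concatenate(group_chains, axis=0)
    part = np.concatenate(part_chains, axis=0).transpose(1, 0, 2)
    return group, part, sigma


def fit_hierarchical(datasets: Mapping, config: FitConfig,
                     anchor: Mapping[str, float] | None = None
                     ) -> PosteriorDraws:
    """Fit one model variant to a cohort of event streams.

    ``datasets`` maps participant key -> chronological model-event list
    (already past :func:`apply_fitting_exclusions`).  ``anchor`` optionally
    supplies sampling-scale group means from a nested variant's fit as an
    extra optimization start (parameters absent there start switched off).
    """
    names = list(ACTIVE[config.variant])
    keys = list(datasets.keys())
    if not keys:
        raise ValueError("empty dataset")
    encs = []
    for key in keys:
        v = datasets[key]
        encs.append(v if isinstance(v, EncodedStream) else encode_stream(v))
    n = len(keys)
    k = len(names)

    anchor_vec = None
    if anchor is not None:
        anchor_vec = np.array([
            anchor.get(name, -4.0 if name in RATE_SET else 0.0)
            for name in names])
    mu, sigma, theta2, cov2, var2, se_mu = _fit_em(encs, names, config,
                                                   anchor=anchor_vec)

    rng = np.random.default_rng(config.seed)
    S = config.n_draws
    if config.method == "mcmc":
        group_draws, part_draws, sigma = _sample_gibbs(
            encs, names, config, mu, sigma, theta2, cov2)
        S = group_draws.shape[0]
    elif config.method == "map":
        group_draws = mu + rng.standard_normal((S, k)) * se_mu
        part_draws = np.empty((n, S, k))
        for i in range(n):
            L = np.linalg.cholesky(cov2[i] + 1e-10 * np.eye(k))
            part_draws[i] = theta2[i] + rng.standard_normal((S, k)) @ L.T
    else:
        raise ValueError(f"unknown method {config.method!r}")

    # pointwise log-likelihood matrix across all observations
    n_obs = sum(e.n_decisions for e in encs)
    pointwise = np.empty((S, n_obs))
    obs_part = np.empty(n_obs, dtype=np.int32)
    offset = 0
    for i, enc in enumerate(encs):
        m = enc.n_decisions
        obs_part[offset:offset + m] = i
        for s in range(S):
            pointwise[s, offset:offset + m] = stream_loglik(
                enc, _expand_theta(part_draws[i, s], names))
        offset += m

    nat = group_draws.copy()
    for j, name in enumerate(names):
        if name in RATE_SET:
            nat[:, j] = expit(nat[:, j])

    rhat = {name: split_rhat(group_draws[:, j], config.chains)
            for j, name in enumerate(names)}
    flags = [f"rhat>1.05 for {p}" for p, v in rhat.items() if v > 1.05]
    return PosteriorDraws(
        variant=config.variant, param_names=names, participants=keys,
        group_mean=group_draws, group_mean_nat=nat, group_sd=sigma,
        participant_draws=part_draws, pointwise_ll=pointwise,
        obs_participant=obs_part, rhat=rhat, flags=flags)


def split_rhat(draws: np.ndarray, chains: int = 4) -> float:
    """Rank-normalized split-rhat of a flat draw vector.

    Draws are split into ``2 * chains`` consecutive segments; iid draws give
    values very close to 1.
    """
    from scipy.stats import norm

    x = np.asarray(draws, dtype=float)
    ranks = np.argsort(np.argsort(x)) + 1
    z = norm.ppf((ranks - 0.375) / (x.size + 0.25))
    m = 2 * chains
    seg = x.size // m
    if seg < 2:
        return float("nan")
    z = z[:seg * m].reshape(m, seg)
    within = z.var(axis=1, ddof=1).mean()
    between = seg * z.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    return float(np.sqrt((seg - 1) / seg + between / (seg * within)))


# ---------------------------------------------------------------------------
# WAIC and model comparison
# ---------------------------------------------------------------------------

def compute_waic(pointwise_ll: np.ndarray) -> dict[str, float | np.ndarray]:
    """WAIC on the deviance scale from a (draws x observations) ll matrix."""
    ll = np.asarray(pointwise_ll, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws >= 2, observations) matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite log-likelihood values")
    S, n = ll.shape
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    pwaic_i = ll.var(axis=0, ddof=1)
    waic_i = -2.0 * (lppd_i - pwaic_i)
    waic = float(waic_i.sum())
    se = float(np.sqrt(n * waic_i.var(ddof=1)))
    return {"WAIC": waic, "SE": se, "pWAIC": float(pwaic_i.sum()),
            "lppd": float(lppd_i.sum()), "pointwise": waic_i}


def akaike_weights(dwaic: np.ndarray) -> np.ndarray:
    rel = np.exp(-0.5 * np.asarray(dwaic, dtype=float))
    return rel / rel.sum()


def compare_models(results: Mapping[str, Mapping]) -> pd.DataFrame:
    """Build the WAIC comparison table from per-variant `compute_waic` output.

    All models must have been scored on the identical observation set; rows
    are sorted best (smallest WAIC) first, with dWAIC relative to the best
    model, dSE the standard error of the pointwise WAIC differences, and
    Akaike weights over the compared set.
    """
    names = list(results.keys())
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    lengths = {len(np.asarray(results[m]["pointwise"])) for m in names}
    if len(lengths) != 1:
        raise ValueError("models were scored on different observation sets")
    order = sorted(names, key=lambda m: results[m]["WAIC"])
    best = order[0]
    best_pw = np.asarray(results[best]["pointwise"])
    rows = []
    dwaics = np.array([results[m]["WAIC"] - results[best]["WAIC"]
                       for m in order])
    weights = akaike_weights(dwaics)
    for m, dw, w in zip(order, dwaics, weights):
        pw = np.asarray(results[m]["pointwise"])
        diff = pw - best_pw
        n = diff.size
        dse = float(np.sqrt(n * diff.var(ddof=1))) if m != best else float("nan")
        rows.append({"model": m, "WAIC": results[m]["WAIC"],
                     "SE": results[m]["SE"], "dWAIC": float(dw), "dSE": dse,
                     "pWAIC": results[m]["pWAIC"], "weight": float(w)})
    return pd.DataFrame(rows)


def hdi(draws: np.ndarray, mass: float = 0.89) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws")
    m = max(1, int(np.ceil(mass * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[:n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])
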