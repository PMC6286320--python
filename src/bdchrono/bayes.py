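"""Bayesian estimation of (lam, mu, lam*, mu*) and posterior model checks.

The samplers target the joint likelihood of a phylogeny and a set of
stratigraphic ranges (treated as independent data sets) times gamma
priors on every birth-death rate (shape and rate 1.1 by default).
Proposals are log-scale random walks (multipliers), one parameter at a
time, with proposal scales tuned during burn-in towards an acceptance
rate of about 0.3.

Under the unconstrained (incompatible) model the four rates move
freely; the equal model samples the shared pair (lam, mu); the
compatible model samples (lam, mu, c >= 0) with lam* = lam + c and
mu* = mu + c.  Unlike maximum-likelihood estimation, the samplers do
not hard-enforce lam > mu: the reconstructed-process density remains
valid on the whole positive quadrant and the priors keep the chain
proper, which also makes prior-only runs exactly Gamma distributed.

The posterior model check mirrors the credible-interval rules used for
empirical data: equal rates are preferred when 0 falls inside the
credible intervals of lam* - lam and mu* - mu; otherwise compatible
rates when 0 falls inside the credible interval of
(lam* - lam) - (mu* - mu) and P(lam* >= lam) exceeds 1 - level;
otherwise the rates are declared incompatible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chronospecies import RangeSet, range_bin_statistics
from .likelihoods import (
    SkylineRates,
    phylo_loglik,
    range_loglik,
    skyline_phylo_loglik,
    skyline_range_loglik,
)
from .treesim import PhyloData

__all__ = [
    "PosteriorSample",
    "mcmc_sample",
    "posterior_model_check",
    "skyline_mcmc",
]


@dataclass
class PosteriorSample:
    """Post-burn-in draws of the rate quadruple (or per-bin quadruples)."""

    draws: pd.DataFrame  # columns lambda, mu, lambda_star, mu_star (per bin)
    logpost: np.ndarray
    model: str
    burnin: int
    acceptance: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.draws)


def _gamma_logpdf(x, shape, rate):
    return (shape - 1.0) * np.log(x) - rate * x


class _AdaptiveMH:
    """One-parameter-at-a-time multiplier Metropolis with burn-in tuning."""

    def __init__(self, rng, names, n_params):
        self.rng = rng
        self.names = names
        self.scale = np.full(n_params, 0.3)
        self.n_prop = np.zeros(n_params)
        self.n_acc = np.zeros(n_params)

    def step(self, x, logpost, lp_cur, tuning):
        for j in range(len(x)):
            u = np.exp(self.rng.uniform(-self.scale[j], self.scale[j]))
            xp = x.copy()
            xp[j] *= u
            lp_new = logpost(xp)
            self.n_prop[j] += 1
            # multiplier proposal: Hastings ratio contributes log(u)
            if np.log(self.rng.random()) < lp_new - lp_cur + np.log(u):
                x, lp_cur = xp, lp_new
                self.n_acc[j] += 1
            if tuning and self.n_prop[j] % 50 == 0:
                rate = self.n_acc[j] / self.n_prop[j]
                self.scale[j] *= np.exp(0.5 * (rate - 0.3))
                self.scale[j] = float(np.clip(self.scale[j], 0.01, 3.0))
        return x, lp_cur

    def rates(self):
        with np.errstate(invalid="ignore"):
            return {n: float(a / max(p, 1)) for n, a, p in
                    zip(self.names, self.n_acc, self.n_prop)}


def mcmc_sample(
    phylo: PhyloData | None,
    stats,
    model: str = "incompatible",
    prior_shape: float = 1.1,
    prior_rate: float = 1.1,
    iterations: int = 50000,
    burnin: float = 0.25,
    seed=None,
    condition: str = "origin",
    use_likelihood: bool = True,
) -> PosteriorSample:
    """Metropolis-Hastings sampling of the rate quadruple.

    ``stats`` is the (B, D, S) triple; ``use_likelihood=False`` runs
    the chain against the prior alone (a sampler validity check).
    """
    if model not in ("equal", "compatible", "incompatible"):
        raise ValueError(f"unknown model {model!r}")
    if iterations < 10**4:
        raise ValueError("use at least 1e4 iterations")
    rng = np.random.default_rng(seed)

    def quadruple(x):
        if model == "equal":
            lam, mu = x
            return lam, mu, lam, mu
        if model == "compatible":
            lam, mu, c = x
            return lam, mu, lam + c, mu + c
        return tuple(x)

    def logpost(x):
        lam, mu, lam_s, mu_s = quadruple(x)
        if min(lam, mu, lam_s, mu_s) <= 0:
            return -np.inf
        lp = 0.0
        for v in (x if model != "incompatible" else (lam, mu, lam_s, mu_s)):
            lp += _gamma_logpdf(v, prior_shape, prior_rate)
        if use_likelihood:
            try:
                lp += phylo_loglik(phylo, lam, mu, condition=condition,
                                   check_rates=False)
            except (ValueError, FloatingPointError):
                return -np.inf
            lp += range_loglik(stats, lam_s, mu_s)
        if not np.isfinite(lp):
            return -np.inf
        return float(lp)

    names = {"equal": ["lambda", "mu"],
             "compatible": ["lambda", "mu", "c"],
             "incompatible": ["lambda", "mu", "lambda_star", "mu_star"]}[model]
    x = rng.gamma(prior_shape, 1.0 / prior_rate, size=len(names)) + 1e-3
    lp = logpost(x)
    while not np.isfinite(lp):  # nudge an unlucky start into the support
        x = rng.gamma(prior_shape, 1.0 / prior_rate, size=len(names)) + 1e-3
        lp = logpost(x)
    mh = _AdaptiveMH(rng, names, len(names))
    n_burn = int(iterations * burnin)
    kept = np.empty((iterations - n_burn, 4))
    lp_tr = np.empty(iterations - n_burn)
    for it in range(iterations):
        x, lp = mh.step(x, logpost, lp, tuning=it < n_burn)
        if it >= n_burn:
            kept[it - n_burn] = quadruple(x)
            lp_tr[it - n_burn] = lp
    if np.isnan(lp_tr).any():
        raise RuntimeError("NaN log-posterior encountered during sampling")
    acc = mh.rates()
    overall = float(np.mean(list(acc.values())))
    if not 0.1 <= overall <= 0.6:
        warnings.warn(
            f"MCMC acceptance rate {overall:.2f} outside [0.1, 0.6]",
            RuntimeWarning,
        )
    draws = pd.DataFrame(kept, columns=["lambda", "mu", "lambda_star", "mu_star"])
    return PosteriorSample(draws, lp_tr, model, n_burn, acc)


def posterior_model_check(sample: PosteriorSample, level: float = 0.95) -> str:
    """Credible-interval model check on an unconstrained posterior.

    Rules, applied in order: *equal* if 0 lies in the ``level``
    credible intervals of both lam* - lam and mu* - mu; *compatible*
    if 0 lies in the credible interval of (lam* - lam) - (mu* - mu)
    and P(lam* >= lam) > 1 - level; else *incompatible*.
    """
    if level not in (0.95, 0.99):
        raise ValueError("level must be 0.95 or 0.99")
    if len(sample) < 1000:
        raise ValueError("need at least 1000 post-burn-in draws")
    d = sample.draws
    a = (1.0 - level) / 2.0

    def contains_zero(v) -> bool:
        lo, hi = np.quantile(v, [a, 1.0 - a])
        return lo <= 0.0 <= hi

    dl = d["lambda_star"] - d["lambda"]
    dm = d["mu_star"] - d["mu"]
    if contains_zero(dl) and contains_zero(dm):
        return "equal"
    if contains_zero(dl - dm) and float(np.mean(dl >= 0)) > 1.0 - level:
        return "compatible"
    return "incompatible"


def skyline_mcmc(
    phylo: PhyloData,
    ranges: RangeSet,
    boundaries,
    model: str = "incompatible",
    prior_shape: float = 1.1,
    prior_rate: float = 1.1,
    iterations: int = 50000,
    burnin: float = 0.25,
    seed=None,
    condition: str = "origin",
) -> PosteriorSample:
    """Per-bin rate sampling under the skyline likelihoods.

    ``boundaries`` are the younger bin edges starting at 0.  Under the
    compatible model the BDC constraint lam*_b = lam_b + c_b (c_b >= 0)
    is applied within every bin.  Bins containing no range events are
    flagged: their stratigraphic rates are prior-dominated.
    """
    if model not in ("compatible", "incompatible"):
        raise ValueError("skyline model must be 'compatible' or 'incompatible'")
    rng = np.random.default_rng(seed)
    b = tuple(float(v) for v in boundaries)
    k = len(b)
    bin_stats = range_bin_statistics(ranges, b)
    empty = [j for j in range(k) if bin_stats[j, :2].sum() == 0]
    if empty:
        warnings.warn(
            f"bins {empty} contain no range events; their fossil rates are "
            "prior-dominated", RuntimeWarning,
        )

    n_per = 3 if model == "compatible" else 4

    def split(x):
        lam = x[0:k]
        mu = x[k:2 * k]
        if model == "compatible":
            c = x[2 * k:3 * k]
            return lam, mu, lam + c, mu + c
        return lam, mu, x[2 * k:3 * k], x[3 * k:4 * k]

    def logpost(x):
        if np.any(x <= 0):
            return -np.inf
        lam, mu, lam_s, mu_s = split(x)
        lp = float(np.sum(_gamma_logpdf(np.concatenate([lam, mu, lam_s, mu_s]),
                                        prior_shape, prior_rate)))
        try:
            lp += skyline_phylo_loglik(
                phylo, SkylineRates(b, tuple(lam), tuple(mu)), condition=condition
            )
        except (ValueError, FloatingPointError):
            return -np.inf
        lp += skyline_range_loglik(bin_stats, lam_s, mu_s)
        return lp if np.isfinite(lp) else -np.inf

    names = [f"{p}_{j}" for p in
             (["lambda", "mu", "c"] if model == "compatible"
              else ["lambda", "mu", "lambda_star", "mu_star"])
             for j in range(k)]
    x = rng.gamma(prior_shape, 1.0 / prior_rate, size=n_per * k) + 1e-3
    lp = logpost(x)
    while not np.isfinite(lp):
        x = rng.gamma(prior_shape, 1.0 / prior_rate, size=n_per * k) + 1e-3
        lp = logpost(x)
    mh = _AdaptiveMH(rng, names, len(x))
    n_burn = int(iterations * burnin)
    cols = [f"{p}_{j}" for p in ("lambda", "mu", "lambda_star", "mu_star")
            for j in range(k)]
    kept = np.empty((iterations - n_burn, 4 * k))
    lp_tr = np.empty(iterations - n_burn)
    for it in range(iterations):
        x, lp = mh.step(x, logpost, lp, tuning=it < n_burn)
        if it >= n_burn:
            kept[it - n_burn] = np.concatenate(split(x))
            lp_tr[it - n_burn] = lp
    draws = pd.DataFrame(kept, columns=cols)
    return PosteriorSample(draws, lp_tr, f"skyline-{model}", n_burn, mh.rates())
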