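"""Exact log-likelihoods for extant phylogenies and stratigraphic ranges.

Phylogeny side (reconstructed birth-death process, sampling fraction
``rho``): the density of the branching ages ``t_1 >= ... >= t_{n-1}``
given the origin age ``t_0`` is

    f = p1(t0) / (1 - p0(t0)) * prod_i lam * p1(t_i),

with ``p0``/``p1`` the no-descendant / one-descendant probabilities.
Crown conditioning replaces the origin factor by conditioning both
crown lineages on survival:
``[p1(t1) / (1 - p0(t1))]^2 * prod_{i>=2} lam p1(t_i)``.

Range side: given the number of origination events ``B``, extinction
events ``D`` and the summed range durations ``S``,

    P(R | lam*, mu*) \\propto lam*^B mu*^D exp(-(lam* + mu*) S),

whose maximiser is the closed form ``(B/S, D/S)``.

Proportionality constants are dropped consistently everywhere; only
log-likelihood differences are meaningful, which is all the
likelihood-ratio machinery uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._bdprob import PiecewiseBD
from .bdcmath import FossilRates
from .treesim import PhyloData

__all__ = [
    "FossilRates",
    "SkylineRates",
    "phylo_loglik",
    "range_loglik",
    "range_mle",
    "skyline_phylo_loglik",
    "skyline_range_loglik",
]


@dataclass(frozen=True)
class SkylineRates:
    """Per-bin rates on a partition of [0, origin] into age bins.

    ``boundaries`` are the younger edges of the bins (starting at 0);
    bin ``j`` covers ``[boundaries[j], boundaries[j+1])`` and the last
    bin extends beyond the origin.
    """

    boundaries: tuple[float, ...]
    lams: tuple[float, ...]
    mus: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries)
        if b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ValueError("bin boundaries must increase from 0")
        if len(self.lams) != len(b) or len(self.mus) != len(b):
            raise ValueError("need one (lam, mu) pair per bin")
        if any(l <= 0 for l in self.lams) or any(m < 0 for m in self.mus):
            raise ValueError("require lam > 0 and mu >= 0 per bin")

    @property
    def n_bins(self) -> int:
        return len(self.boundaries)


def _conditioned_loglik(kernel: PiecewiseBD, lam_at, phylo: PhyloData,
                        condition: str) -> float:
    ages = phylo.branching_ages
    if condition == "origin":
        if phylo.origin_age is None:
            raise ValueError("origin conditioning requires a known origin age")
        p0, logp1 = kernel.p0_logp1(np.array([phylo.origin_age]))
        if p0[0] >= 1.0:  # survival probability underflowed (mu >> lam)
            return -np.inf
        ll = float(logp1[0] - np.log1p(-p0[0]))
        rest = ages
    elif condition == "crown":
        if phylo.n < 2:
            raise ValueError("crown conditioning requires n >= 2")
        p0, logp1 = kernel.p0_logp1(np.array([phylo.crown_age]))
        if p0[0] >= 1.0:
            return -np.inf
        ll = 2.0 * float(logp1[0] - np.log1p(-p0[0]))
        rest = ages[1:]
    else:
        raise ValueError("condition must be 'origin' or 'crown'")
    if len(rest):
        p0r, logp1r = kernel.p0_logp1(rest)
        ll += float(np.sum(np.log(lam_at(rest)) + logp1r))
    return ll


def phylo_loglik(
    phylo: PhyloData,
    lam: float,
    mu: float,
    condition: str = "origin",
    check_rates: bool = True,
) -> float:
    """Log-likelihood of an extant phylogeny under constant rates.

    ``check_rates=True`` enforces the estimation constraint
    ``lam > mu >= 0``; samplers that place priors over the whole
    positive quadrant may disable it (the density remains valid).
    """
    if lam <= 0 or mu < 0:
        raise ValueError("require lam > 0 and mu >= 0")
    if check_rates and lam <= mu:
        raise ValueError("estimation requires positive net diversification, lam > mu")
    kernel = PiecewiseBD([0.0], [lam], [mu], rho=phylo.rho)
    return _conditioned_loglik(kernel, lambda t: np.full_like(t, lam), phylo, condition)


def skyline_phylo_loglik(
    phylo: PhyloData, rates: SkylineRates, condition: str = "origin"
) -> float:
    """Extant-phylogeny log-likelihood under piecewise-constant rates.

    ``p0``/``p1`` are propagated across bin boundaries from the present
    backwards; each branching event contributes ``lam_b(t_i) p1(t_i)``.
    With a single bin this equals :func:`phylo_loglik` exactly.
    """
    kernel = PiecewiseBD(rates.boundaries, rates.lams, rates.mus, rho=phylo.rho)
    b = np.asarray(rates.boundaries)
    lams = np.asarray(rates.lams)

    def lam_at(t):
        j = np.clip(np.searchsorted(b, t, side="right") - 1, 0, len(b) - 1)
        return lams[j]

    return _conditioned_loglik(kernel, lam_at, phylo, condition)


def range_loglik(stats, lam_star: float, mu_star: float) -> float:
    """Log-likelihood of range data summarised by ``(B, D, S)``.

    Returns ``B log lam* + D log mu* - (lam* + mu*) S`` (constant
    dropped).  ``mu* = 0`` with ``D > 0`` yields ``-inf`` by contract.
    """
    B, D, S = stats
    if S <= 0:
        raise ValueError("summed range duration S must be positive")
    if lam_star <= 0:
        raise ValueError("lam_star must be positive")
    if mu_star < 0:
        raise ValueError("mu_star must be non-negative")
    if D > 0 and mu_star == 0.0:
        return -np.inf
    ll = B * np.log(lam_star) - (lam_star + mu_star) * S
    if D > 0:
        ll += D * np.log(mu_star)
    return float(ll)


def range_mle(stats) -> tuple[FossilRates, bool]:
    """Closed-form maximiser (B/S, D/S) of the range likelihood.

    Returns the estimates and a flag marking boundary solutions
    (``B = 0`` gives a zero origination-rate estimate, which violates
    the interior constraint ``lam* > 0``).
    """
    B, D, S = stats
    if S <= 0:
        raise ValueError("summed range duration S must be positive")
    rates = FossilRates(B / S, D / S)
    return rates, B == 0


def skyline_range_loglik(bin_stats, lam_stars, mu_stars) -> float:
    """Range log-likelihood with per-bin rates.

    ``bin_stats`` is a sequence of ``(B_b, D_b, S_b)`` per bin
    (origination events, extinction events and lineage-time accrued in
    bin ``b``); see ``chronospecies.range_bin_statistics``.
    """
    lam_stars = np.asarray(lam_stars, dtype=float)
    mu_stars = np.asarray(mu_stars, dtype=float)
    stats = np.asarray(bin_stats, dtype=float)
    if stats.shape != (len(lam_stars), 3):
        raise ValueError("need one (B, D, S) triple per bin")
    if np.any(lam_stars <= 0) or np.any(mu_stars < 0):
        raise ValueError("require lam* > 0 and mu* >= 0 per bin")
    B, D, S = stats[:, 0], stats[:, 1], stats[:, 2]
    if np.any((D > 0) & (mu_stars == 0.0)):
        return -np.inf
    ll = np.sum(B * np.log(lam_stars) - (lam_stars + mu_stars) * S)
    dd = D > 0
    ll += np.sum(D[dd] * np.log(mu_stars[dd]))
    return float(ll)
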