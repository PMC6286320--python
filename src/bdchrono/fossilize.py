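"""From true stratigraphic ranges to realistic fossil data.

Three degradation steps are modelled:

* incomplete species sampling -- each range is dropped independently
  with probability ``x`` (uniformly, or restricted to extinct-only /
  extant-only ranges);
* fossil occurrence sampling -- occurrences fall within each range as a
  Poisson process with preservation rate ``psi`` per lineage-time, so
  short ranges are more likely to go entirely unobserved;
* range truncation -- observed ranges run from first to last
  appearance and therefore underestimate the true durations.

:func:`estimate_ranges_hpp` partially undoes the truncation: a
Metropolis-within-Gibbs sampler jointly infers each species' true
origination/extinction times, the preservation rate and the
origination/extinction rates of the range birth-death prior, under a
homogeneous-Poisson preservation model with each sampled taxon
conditioned on having at least one occurrence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chronospecies import MODE_OBSERVED, RangeSet, SpeciesRange

__all__ = [
    "SamplingConfig",
    "OccurrenceTable",
    "subsample_ranges",
    "sample_occurrences",
    "ranges_from_occurrences",
    "estimate_ranges_hpp",
    "HPPPosterior",
]


@dataclass(frozen=True)
class SamplingConfig:
    """Which degradation scheme to apply and with what intensity."""

    scheme: str = "uniform"  # uniform | extinct_only | extant_only | poisson
    removal_prob: float = 0.0
    psi: float = 0.5
    include_extant_at_present: bool = True

    def __post_init__(self) -> None:
        if self.scheme not in {"uniform", "extinct_only", "extant_only", "poisson"}:
            raise ValueError(f"unknown sampling scheme {self.scheme!r}")
        if not 0.0 <= self.removal_prob < 1.0:
            raise ValueError("removal probability must lie in [0, 1)")
        if self.psi <= 0:
            raise ValueError("psi must be positive")


@dataclass
class OccurrenceTable:
    """Fossil occurrences: one row per (species, age)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"species_id", "age"} - set(self.data.columns)
        if missing:
            raise ValueError(f"occurrence table lacks columns {sorted(missing)}")
        if (self.data["age"] < 0).any():
            raise ValueError("occurrence ages must be non-negative")
        if len(self.data) == 0:
            raise ValueError("empty occurrence table")

    def counts(self) -> pd.Series:
        return self.data.groupby("species_id")["age"].size()

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species_id"].unique())


def subsample_ranges(
    ranges: RangeSet, config: SamplingConfig, seed=None
) -> RangeSet:
    """Drop each eligible range independently with probability ``x``."""
    if config.scheme == "poisson":
        raise ValueError("use sample_occurrences for the poisson scheme")
    rng = np.random.default_rng(seed)
    x = config.removal_prob
    kept = []
    for r in ranges:
        eligible = (
            config.scheme == "uniform"
            or (config.scheme == "extinct_only" and not r.extant)
            or (config.scheme == "extant_only" and r.extant)
        )
        if eligible and rng.random() < x:
            continue
        kept.append(r)
    if not kept:
        raise ValueError("subsampling removed every range")
    return RangeSet(kept)


def sample_occurrences(
    ranges: RangeSet,
    psi: float,
    seed=None,
    include_extant_at_present: bool = True,
) -> OccurrenceTable:
    """Poisson(psi * duration) occurrences per range, uniform in age.

    Ranges with no occurrences are simply absent from the output.  If
    ``include_extant_at_present`` is set, every extant species receives
    a present-day (age 0) record, reflecting that its living status is
    known.
    """
    if psi <= 0:
        raise ValueError("psi must be positive")
    rng = np.random.default_rng(seed)
    sp, ages = [], []
    for r in ranges:
        k = rng.poisson(psi * r.duration)
        if k:
            occ = rng.uniform(r.t_extinction, r.t_origination, size=k)
            sp.extend([r.species_id] * k)
            ages.extend(occ.tolist())
        if r.extant and include_extant_at_present:
            sp.append(r.species_id)
            ages.append(0.0)
    if not sp:
        raise ValueError("no range produced any occurrence; psi too small?")
    return OccurrenceTable(pd.DataFrame({"species_id": sp, "age": ages}))


def ranges_from_occurrences(
    occ: OccurrenceTable, extant_ids: set[str] | None = None
) -> RangeSet:
    """Naive observed ranges: first and last appearances per species.

    Species listed in ``extant_ids`` extend to the present (age 0)
    regardless of their last appearance.  Single-occurrence extinct
    species yield degenerate zero-duration ranges, which are kept.
    """
    extant_ids = extant_ids or set()
    out = []
    for sid, grp in occ.data.groupby("species_id"):
        t_o = float(grp["age"].max())
        extant = sid in extant_ids
        t_e = 0.0 if extant else float(grp["age"].min())
        out.append(
            SpeciesRange(str(sid), t_o, t_e, extant=extant, mode=MODE_OBSERVED)
        )
    return RangeSet(out)


@dataclass
class HPPPosterior:
    """Posterior summaries of the range-time sampler."""

    species: list[str]
    ts_mean: np.ndarray
    te_mean: np.ndarray
    extant: np.ndarray
    psi_trace: np.ndarray
    lambda_star_trace: np.ndarray
    mu_star_trace: np.ndarray
    logpost_trace: np.ndarray
    ess: dict[str, float] = field(default_factory=dict)

    def to_ranges(self) -> RangeSet:
        out = []
        for i, sid in enumerate(self.species):
            out.append(
                SpeciesRange(
                    sid,
                    float(self.ts_mean[i]),
                    float(self.te_mean[i]),
                    extant=bool(self.extant[i]),
                    mode=MODE_OBSERVED,
                )
            )
        return RangeSet(out)

    def psi_interval(self, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        return tuple(np.quantile(self.psi_trace, [a, 1.0 - a]))


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial positive sequence estimator."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 1.0
    for k in range(1, min(n // 2, 1000)):
        if acf[k] <= 0:
            break
        s += 2.0 * acf[k]
    return float(n / max(s, 1.0))


def estimate_ranges_hpp(
    occ: OccurrenceTable,
    extant_ids: set[str] | None = None,
    iterations: int = 20000,
    burnin: float = 0.25,
    seed=None,
    prior_shape: float = 1.1,
    prior_rate: float = 1.1,
) -> HPPPosterior:
    """Bayesian estimation of true range times from fossil occurrences.

    Sampler: sliding-window Metropolis updates of the per-species
    origination (``ts``) and extinction (``te``) times, a multiplier
    update of ``psi``, and Gibbs updates of the range birth-death rates
    (conjugate under gamma priors given the current B, D, S).
    """
    extant_ids = extant_ids or set()
    rng = np.random.default_rng(seed)
    grp = occ.data.groupby("species_id")["age"]
    species = sorted(grp.groups)
    m = len(species)
    extant = np.array([s in extant_ids for s in species])
    fa = grp.max().loc[species].to_numpy(float)   # first appearances (oldest)
    la = grp.min().loc[species].to_numpy(float)   # last appearances (youngest)
    # a present-day (age 0) record of an extant species marks its living
    # status; it is not a fossil preservation event and does not enter k
    pos = occ.data[occ.data["age"] > 0].groupby("species_id")["age"]
    k = np.zeros(m)
    k_pos = pos.size()
    for i, s in enumerate(species):
        k[i] = k_pos.get(s, 0) if extant[i] else float(grp.size().loc[s])
    la = np.where(extant, 0.0, la)
    if np.any((k == 0) & ~extant):
        raise ValueError("every extinct species needs at least one occurrence")

    ts = fa + 0.1 * (fa - la + 0.5)
    te = np.where(extant, 0.0, np.maximum(la - 0.1 * (fa - la + 0.5), 0.0))
    psi = max(float(k.sum() / np.maximum((ts - te).sum(), 1e-6)), 1e-3)
    B = m - 1
    D = int((~extant).sum())

    def log_pres(ts_, te_, psi_):
        # plain HPP likelihood psi^k exp(-psi d); only taxa with k >= 1
        # (or known living status) enter the data, and the per-taxon
        # conditioning constant is omitted: dividing by 1 - exp(-psi d)
        # diverges for single-occurrence taxa (d -> 0) and collapses the
        # duration posterior onto the observed span
        d = ts_ - te_
        return float(np.sum(k * np.log(psi_) - psi_ * d))

    win = 0.5 * max(np.mean(fa - la), 0.1)
    keep_from = int(iterations * burnin)
    n_keep = iterations - keep_from
    psi_tr = np.empty(n_keep)
    lam_tr = np.empty(n_keep)
    mu_tr = np.empty(n_keep)
    lp_tr = np.empty(n_keep)
    ts_sum = np.zeros(m)
    te_sum = np.zeros(m)

    lam_star, mu_star = 0.1, 0.1
    lp_pres = log_pres(ts, te, psi)
    for it in range(iterations):
        # Gibbs: conjugate gamma updates of the range BD rates given S
        S = float((ts - te).sum())
        lam_star = rng.gamma(prior_shape + B, 1.0 / (prior_rate + S))
        mu_star = rng.gamma(prior_shape + D, 1.0 / (prior_rate + S)) if D else 0.0

        # Metropolis: per-species time updates (a random third each sweep)
        idx = rng.choice(m, size=max(1, m // 3), replace=False)
        for i in idx:
            def _dlp(d_old, d_new):
                return -(psi + lam_star + mu_star) * (d_new - d_old)

            prop = ts[i] + rng.uniform(-win, win)
            if prop >= fa[i]:
                if np.log(rng.random()) < _dlp(ts[i] - te[i], prop - te[i]):
                    ts[i] = prop
            if not extant[i]:
                prop = te[i] + rng.uniform(-win, win)
                if 0.0 <= prop <= la[i]:
                    if np.log(rng.random()) < _dlp(ts[i] - te[i], ts[i] - prop):
                        te[i] = prop

        # multiplier update of psi
        u = np.exp(rng.uniform(-0.3, 0.3))
        psi_new = psi * u
        lp_old = log_pres(ts, te, psi)
        lp_new = log_pres(ts, te, psi_new)
        prior = (prior_shape - 1) * (np.log(psi_new) - np.log(psi)) - prior_rate * (
            psi_new - psi
        )
        if np.log(rng.random()) < lp_new - lp_old + prior + np.log(u):
            psi = psi_new
            lp_pres = lp_new
        else:
            lp_pres = lp_old

        if it >= keep_from:
            j = it - keep_from
            psi_tr[j] = psi
            lam_tr[j] = lam_star
            mu_tr[j] = mu_star
            S = float((ts - te).sum())
            lp_tr[j] = lp_pres + B * np.log(lam_star) - (lam_star + mu_star) * S
            ts_sum += ts
            te_sum += te

    ess = {
        "psi": _ess(psi_tr),
        "lambda_star": _ess(lam_tr),
        "mu_star": _ess(mu_tr),
    }
    if min(ess.values()) < 100:
        warnings.warn(
            f"low effective sample size in range-time MCMC: {ess}", RuntimeWarning
        )
    return HPPPosterior(
        species=species,
        ts_mean=ts_sum / n_keep,
        te_mean=te_sum / n_keep,
        extant=extant,
        psi_trace=psi_tr,
        lambda_star_trace=lam_tr,
        mu_star_trace=mu_tr,
        logpost_trace=lp_tr,
        ess=ess,
    )
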