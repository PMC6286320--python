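"""Model testing: are fossil and phylogenetic diversification rates
reconcilable?

Three nested models constrain the quadruple (lam, mu, lam*, mu*):

* equal rates       -- lam* = lam, mu* = mu (pure budding; 2 free);
* compatible rates  -- lam* = lam + c, mu* = mu + c with c >= 0 (the
  BDC relations; 3 free);
* incompatible      -- no cross-data constraints (4 free).

The joint log-likelihood treats the two data sets as independent:
phylogeny term (branching ages) plus range term (B, D, S).  Fits use
bounded quasi-Newton optimisation on log-transformed parameters with
the positive-net-diversification constraint lam > mu built in
(lam = mu + d, d > 0); each fit is restarted from several initial
values and from warm starts at the nested models' optima.

The likelihood-ratio cascade follows the boundary-aware null
distributions: equal-vs-compatible relaxes a boundary constraint, so
its LR is a 50:50 mixture of a point mass at 0 and chi2(1) -- the
equal model is rejected at level alpha when the chi2(1) tail
probability falls below 2 alpha (threshold 2.71 at alpha = 0.05);
compatible-vs-incompatible uses chi2(1) and equal-vs-incompatible
chi2(2).  The selected model is the simplest one not rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .bdcmath import RateQuadruple, lambda_a_interval, mode_prevalence
from .chronospecies import BDCParams, assign_chronospecies, range_statistics
from .fossilize import SamplingConfig, subsample_ranges
from .likelihoods import phylo_loglik, range_loglik, range_mle
from .treesim import PhyloData, RateSchedule, prune_extinct, simulate_tree

__all__ = [
    "MODEL_NAMES",
    "FitResult",
    "ModelFitReport",
    "joint_ml_fit",
    "lrt_cascade",
    "model_test",
    "ExperimentConfig",
    "selection_experiment",
]

MODEL_NAMES = ("equal", "compatible", "incompatible")
_N_FREE = {"equal": 2, "compatible": 3, "incompatible": 4}

_LOG_LO, _LOG_HI = -15.0, 3.0
_LOG_C_LO = -20.0


@dataclass
class FitResult:
    model: str
    rates: RateQuadruple
    loglik: float
    n_restarts: int
    best_restart: int

    @property
    def n_free(self) -> int:
        return _N_FREE[self.model]


def _joint_ll(phylo, stats, lam, mu, lam_star, mu_star, condition) -> float:
    ll = phylo_loglik(phylo, lam, mu, condition=condition)
    return ll + range_loglik(stats, lam_star, mu_star)


def _fit(objective, inits, bounds):
    best, best_i = None, -1
    for i, x0 in enumerate(inits):
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best, best_i = res, i
    if best is None:
        raise RuntimeError("all optimiser restarts failed")
    return best, best_i


def _random_inits(rng, ndim, restarts):
    # initial rates drawn log-uniform in [0.01, 2]
    return [
        np.log(np.exp(rng.uniform(np.log(0.01), np.log(2.0), size=ndim)))
        for _ in range(restarts)
    ]


def joint_ml_fit(
    phylo: PhyloData,
    stats,
    model: str,
    restarts: int = 5,
    seed=None,
    condition: str = "origin",
    warm_starts: list[np.ndarray] | None = None,
) -> FitResult:
    """Constrained maximum-likelihood fit of one of the three models.

    ``stats`` is the (B, D, S) triple of the range data.  The range
    component of the incompatible model is the closed form (B/S, D/S).
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    B, D, S = stats

    if model == "incompatible":
        fossil, _ = range_mle(stats)
        lam_star = max(fossil.lambda_star, 1e-10)
        mu_star = fossil.mu_star
        ll_range = range_loglik(stats, lam_star, mu_star)

        def obj(x):
            d, mu = np.exp(x)
            try:
                return -phylo_loglik(phylo, mu + d, mu, condition=condition)
            except (ValueError, FloatingPointError):
                return np.inf

        inits = _random_inits(rng, 2, restarts) + (warm_starts or [])
        best, best_i = _fit(obj, inits, [(_LOG_LO, _LOG_HI)] * 2)
        d, mu = np.exp(best.x)
        rates = RateQuadruple(mu + d, mu, lam_star, mu_star)
        return FitResult(model, rates, -best.fun + ll_range, len(inits), best_i)

    if model == "equal":

        def obj(x):
            d, mu = np.exp(x)
            try:
                return -_joint_ll(phylo, stats, mu + d, mu, mu + d, mu, condition)
            except (ValueError, FloatingPointError):
                return np.inf

        inits = _random_inits(rng, 2, restarts) + (warm_starts or [])
        best, best_i = _fit(obj, inits, [(_LOG_LO, _LOG_HI)] * 2)
        d, mu = np.exp(best.x)
        rates = RateQuadruple(mu + d, mu, mu + d, mu)
        return FitResult(model, rates, -best.fun, len(inits), best_i)

    # compatible: lam* = lam + c, mu* = mu + c, c >= 0
    def obj(x):
        d, mu, c = np.exp(x)
        lam = mu + d
        try:
            return -_joint_ll(phylo, stats, lam, mu, lam + c, mu + c, condition)
        except (ValueError, FloatingPointError):
            return np.inf

    inits = _random_inits(rng, 3, restarts) + (warm_starts or [])
    bounds = [(_LOG_LO, _LOG_HI), (_LOG_LO, _LOG_HI), (_LOG_C_LO, _LOG_HI)]
    best, best_i = _fit(obj, inits, bounds)
    d, mu, c = np.exp(best.x)
    rates = RateQuadruple(mu + d, mu, mu + d + c, mu + c)
    return FitResult(model, rates, -best.fun, len(inits), best_i)


def lrt_cascade(ll_equal: float, ll_compatible: float, ll_incompatible: float,
                alpha: float = 0.05) -> dict:
    """Likelihood-ratio cascade selecting the simplest surviving model.

    Equal-vs-compatible tests a boundary parameter, so the null LR is a
    mixture of chi2(1) and a point mass at zero: rejection when the
    chi2(1) tail probability of LR is below ``2 alpha`` (equivalently
    LR > 2.71 at alpha = 0.05).  Compatible-vs-incompatible uses
    chi2(1), equal-vs-incompatible chi2(2).  Ties at the threshold go
    to the simpler model.
    """
    lr_ec = max(0.0, 2.0 * (ll_compatible - ll_equal))
    lr_ci = max(0.0, 2.0 * (ll_incompatible - ll_compatible))
    lr_ei = max(0.0, 2.0 * (ll_incompatible - ll_equal))
    p_ec = float(chi2.sf(lr_ec, 1))
    p_ci = float(chi2.sf(lr_ci, 1))
    p_ei = float(chi2.sf(lr_ei, 2))
    reject_ec = p_ec < 2.0 * alpha
    reject_ci = p_ci < alpha
    reject_ei = p_ei < alpha
    if not reject_ec and not reject_ei:
        selected = "equal"
    elif not reject_ci:
        selected = "compatible"
    else:
        selected = "incompatible"
    return {
        "LR": {"equal_vs_compatible": lr_ec,
               "compatible_vs_incompatible": lr_ci,
               "equal_vs_incompatible": lr_ei},
        "p": {"equal_vs_compatible": p_ec,
              "compatible_vs_incompatible": p_ci,
              "equal_vs_incompatible": p_ei},
        "rejected": {"equal_vs_compatible": reject_ec,
                     "compatible_vs_incompatible": reject_ci,
                     "equal_vs_incompatible": reject_ei},
        "alpha": alpha,
        "selected": selected,
    }


@dataclass
class ModelFitReport:
    """All three fits plus the cascade decisions and BDC summaries."""

    fits: dict[str, FitResult]
    cascades: dict[float, dict]
    lambda_a_interval: tuple[tuple[float, float], tuple[float, float]] | None
    mode_prevalence: dict | None

    def selected(self, level: float = 0.95) -> str:
        return self.cascades[level]["selected"]

    def to_dict(self) -> dict:
        out = {"schema_version": 1, "models": {}, "selection": {}}
        for name, fit in self.fits.items():
            r = fit.rates
            out["models"][name] = {
                "lambda": r.lambda_,
                "mu": r.mu,
                "lambda_star": r.lambda_star,
                "mu_star": r.mu_star,
                "loglik": fit.loglik,
                "n_free": fit.n_free,
                "n_restarts": fit.n_restarts,
                "best_restart": fit.best_restart,
            }
        for level, casc in self.cascades.items():
            out["selection"][str(level)] = casc
        if self.lambda_a_interval is not None:
            (la_lo, la_hi), (b_lo, b_hi) = self.lambda_a_interval
            out["lambda_a_interval"] = [la_lo, la_hi]
            out["beta_interval"] = [b_lo, b_hi]
        if self.mode_prevalence is not None:
            out["mode_prevalence"] = self.mode_prevalence
        return out


def model_test(
    phylo: PhyloData,
    stats,
    levels: tuple[float, ...] = (0.95, 0.99),
    restarts: int = 5,
    seed=None,
    condition: str = "origin",
) -> ModelFitReport:
    """Fit all three models and run the LRT cascade at each level."""
    rng = np.random.default_rng(seed)
    fit_eq = joint_ml_fit(phylo, stats, "equal", restarts, rng, condition)
    warm_in = [np.log([max(fit_eq.rates.lambda_ - fit_eq.rates.mu, 1e-6),
                       max(fit_eq.rates.mu, 1e-6)])]
    fit_in = joint_ml_fit(phylo, stats, "incompatible", restarts, rng, condition,
                          warm_starts=warm_in)
    # warm starts for the compatible fit from both neighbours
    d_eq = max(fit_eq.rates.lambda_ - fit_eq.rates.mu, 1e-6)
    warm_co = [
        np.array([np.log(d_eq), np.log(max(fit_eq.rates.mu, 1e-6)), _LOG_C_LO]),
        np.log([
            max(fit_in.rates.lambda_ - fit_in.rates.mu, 1e-6),
            max(fit_in.rates.mu, 1e-6),
            max(fit_in.rates.lambda_star - fit_in.rates.lambda_, 1e-6),
        ]),
    ]
    fit_co = joint_ml_fit(phylo, stats, "compatible", restarts, rng, condition,
                          warm_starts=warm_co)
    cascades = {
        level: lrt_cascade(fit_eq.loglik, fit_co.loglik, fit_in.loglik,
                           alpha=1.0 - level)
        for level in levels
    }
    r = fit_co.rates
    interval = None
    if r.lambda_star >= r.lambda_:
        interval = lambda_a_interval(r.lambda_, r.lambda_star)
    prevalence = mode_prevalence(r.lambda_, r.lambda_star)
    return ModelFitReport(
        fits={"equal": fit_eq, "compatible": fit_co, "incompatible": fit_in},
        cascades=cascades,
        lambda_a_interval=interval,
        mode_prevalence=prevalence,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Generating conditions of one model-selection experiment."""

    schedule: RateSchedule
    n_extant: int = 200
    beta: float = 0.0
    lambda_a: float = 0.0
    kappa: float = 0.0
    range_sampling: SamplingConfig | None = None
    independent: bool = False  # incompatible generator: two separate trees
    method: str = "auto"
    condition: str = "origin"

    def bdc_params(self) -> BDCParams:
        lam, mu = self.schedule.intervals[0][2], self.schedule.intervals[0][3]
        return BDCParams(lam, mu, beta=self.beta, lambda_a=self.lambda_a,
                         kappa=self.kappa)


def _one_dataset(config: ExperimentConfig, rng) -> tuple[PhyloData, tuple]:
    """Simulate one (phylogeny, range-statistics) replicate."""
    if config.independent:
        # fossil and phylogenetic data from two unrelated clades with
        # rates drawn U(0.1, 1.5) for lam and U(0, lam) for mu
        lam1 = rng.uniform(0.1, 1.5)
        mu1 = rng.uniform(0.0, lam1)
        lam2 = rng.uniform(0.1, 1.5)
        mu2 = rng.uniform(0.0, lam2)
        t1 = simulate_tree(RateSchedule.constant(lam1, mu1), config.n_extant,
                           rng, method=config.method)
        t2 = simulate_tree(RateSchedule.constant(lam2, mu2), config.n_extant,
                           rng, method=config.method)
        phylo, _ = prune_extinct(t1)
        ranges = assign_chronospecies(t2, BDCParams(lam2, mu2), rng)
    else:
        tree = simulate_tree(config.schedule, config.n_extant, rng,
                             method=config.method)
        phylo, _ = prune_extinct(tree)
        ranges = assign_chronospecies(tree, config.bdc_params(), rng)
    if config.range_sampling is not None:
        ranges = subsample_ranges(ranges, config.range_sampling, rng)
    return phylo, range_statistics(ranges)


def selection_experiment(
    config: ExperimentConfig,
    n_reps: int = 100,
    levels: tuple[float, ...] = (0.95, 0.99),
    restarts: int = 5,
    seed=None,
) -> pd.DataFrame:
    """Frequencies with which each model is selected over replicates.

    Returns a table indexed by confidence level with one column per
    model (percent of successful replicates), plus the replicate
    counts.  Failed replicates are excluded and counted.
    """
    rng = np.random.default_rng(seed)
    counts = {level: {m: 0 for m in MODEL_NAMES} for level in levels}
    n_ok, n_fail = 0, 0
    for _ in range(n_reps):
        try:
            phylo, stats = _one_dataset(config, rng)
            report = model_test(phylo, stats, levels=levels, restarts=restarts,
                                seed=rng, condition=config.condition)
        except Exception:
            n_fail += 1
            continue
        n_ok += 1
        for level in levels:
            counts[level][report.selected(level)] += 1
    rows = []
    for level in levels:
        row = {"level": level, "n_ok": n_ok, "n_failed": n_fail}
        for m in MODEL_NAMES:
            row[m] = 100.0 * counts[level][m] / max(n_ok, 1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("level")
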