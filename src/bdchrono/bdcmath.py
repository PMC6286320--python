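"""Algebra of the birth-death chronospecies (BDC) process.

The BDC process extends the constant-rate birth-death process (branching
rate ``lambda_``, lineage-extinction rate ``mu``) with two extra
parameters controlling the mode of speciation:

* ``beta`` -- probability that a branching event is a *bifurcation*
  (the ancestor goes pseudo-extinct and two new morphospecies arise);
  with probability ``1 - beta`` the event is a *budding* (the ancestor
  survives and one new morphospecies arises);
* ``lambda_a`` -- rate of *anagenetic* replacement along each lineage
  (the ancestor is replaced by one new morphospecies without branching).

Rates measurable from stratigraphic ranges count every morphospecies
origination/termination, regardless of branching::

    lambda* = lambda (1 - beta) + 2 lambda beta + lambda_a
    mu*     = lambda beta + lambda_a + mu

This module evaluates these relations, classifies observed rate
quadruples into the equal / compatible / incompatible scenarios, and
computes the identifiable intervals for (beta, lambda_a) together with
the speciation-mode prevalence statistic ``lambda* - 2 lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FossilRates:
    """Morphospecies origination and extinction rates (per lineage per time)."""

    lambda_star: float
    mu_star: float

    def __post_init__(self) -> None:
        if self.lambda_star < 0:
            raise ValueError("lambda_star must be non-negative")
        if self.mu_star < 0:
            raise ValueError("mu_star must be non-negative")


@dataclass(frozen=True)
class RateQuadruple:
    """The four rates (lambda, mu, lambda*, mu*) entering model comparison."""

    lambda_: float
    mu: float
    lambda_star: float
    mu_star: float

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.lambda_star <= 0:
            raise ValueError("speciation rates must be positive")
        if self.mu < 0 or self.mu_star < 0:
            raise ValueError("extinction rates must be non-negative")


#: Scenario labels: A = equal rates, B = compatible (BDC) rates,
#: C = incompatible rates.
SCENARIO_EQUAL = "A"
SCENARIO_COMPATIBLE = "B"
SCENARIO_INCOMPATIBLE = "C"


def fossil_rates_from_bdc(
    lambda_: float, mu: float, beta: float, lambda_a: float
) -> FossilRates:
    """Map BDC parameters to the stratigraphic rates (lambda*, mu*).

    Parameters
    ----------
    lambda_ : branching rate (> 0).
    mu : lineage-extinction rate (>= 0).
    beta : probability of bifurcation at a branching event, in [0, 1].
    lambda_a : anagenesis rate per lineage-time (>= 0).
    """
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if not 0 <= beta <= 1:
        raise ValueError("beta must lie in [0, 1]")
    if lambda_a < 0:
        raise ValueError("lambda_a must be non-negative")
    lambda_star = lambda_ * (1.0 - beta) + 2.0 * lambda_ * beta + lambda_a
    mu_star = lambda_ * beta + lambda_a + mu
    return FossilRates(lambda_star, mu_star)


def classify_scenario(q: RateQuadruple, tol: float = 1e-8) -> str:
    """Classify an exact rate quadruple into scenario A, B or C.

    A: lambda* = lambda and mu* = mu (pure budding is the only solution).
    B: lambda* - lambda = mu* - mu > 0 (infinitely many (beta, lambda_a)).
    C: no BDC parameters reproduce the quadruple.

    ``tol`` is an algebraic tolerance for exact quadruples; statistical
    classification of noisy estimates belongs to the model tests.
    """
    d_lambda = q.lambda_star - q.lambda_
    d_mu = q.mu_star - q.mu
    if abs(d_lambda) <= tol and abs(d_mu) <= tol:
        return SCENARIO_EQUAL
    if abs(d_lambda - d_mu) <= tol and d_lambda > tol:
        return SCENARIO_COMPATIBLE
    return SCENARIO_INCOMPATIBLE


def lambda_a_interval(
    lambda_: float, lambda_star: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Identifiable intervals for (lambda_a, beta) under compatible rates.

    Given estimates with ``lambda* >= lambda``, every
    ``beta in [0, min(1, lambda*/lambda - 1)]`` with
    ``lambda_a = lambda* - (1 + beta) lambda`` is a solution, hence

    ``lambda_a in [max(0, lambda* - 2 lambda), lambda* - lambda]``.

    Returns ``((lambda_a_lo, lambda_a_hi), (beta_lo, beta_hi))``.
    """
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    if lambda_star < lambda_:
        raise ValueError(
            "lambda_star < lambda: incompatible rates (scenario C), "
            "no admissible (beta, lambda_a) exists"
        )
    la_lo = max(0.0, lambda_star - 2.0 * lambda_)
    la_hi = lambda_star - lambda_
    beta_hi = min(1.0, lambda_star / lambda_ - 1.0)
    return (la_lo, la_hi), (0.0, beta_hi)


MODE_ANAGENESIS = "anagenesis-dominant"
MODE_BUDDING = "budding-dominant"
MODE_BALANCED = "balanced"


def mode_prevalence(
    lambda_: float, lambda_star: float, tol: float = 1e-8
) -> dict[str, float | str]:
    """Speciation-mode prevalence statistic lambda* - 2 lambda.

    Since ``lambda* - 2 lambda = lambda_a - lambda (1 - beta)``, a
    positive value means anagenesis outpaces budding cladogenesis, a
    negative value the reverse.  Also reports ``lambda* - lambda``,
    which equals the summed rate of anagenetic plus bifurcating
    speciation (``lambda_a + lambda beta``).
    """
    stat = lambda_star - 2.0 * lambda_
    if stat > tol:
        label = MODE_ANAGENESIS
    elif stat < -tol:
        label = MODE_BUDDING
    else:
        label = MODE_BALANCED
    return {
        "statistic": stat,
        "label": label,
        "extra_speciation_rate": lambda_star - lambda_,
    }
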