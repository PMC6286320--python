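"""Core birth-death probability kernels.

For a single lineage alive at age ``t`` (time before present), under a
birth-death process with branching rate ``lam`` and extinction rate
``mu`` and with each extant lineage sampled at the present with
probability ``rho``:

* ``p0(t)`` -- probability the lineage leaves no sampled descendant at
  the present;
* ``p1(t)`` -- probability it leaves exactly one sampled descendant.

With constant rates these are the classic closed forms::

    p0(t) = 1 - rho (lam - mu) / (rho lam + (lam (1 - rho) - mu) e^{-(lam-mu) t})
    p1(t) = rho (lam - mu)^2 e^{-(lam-mu) t}
            / (rho lam + (lam (1 - rho) - mu) e^{-(lam-mu) t})^2

For piecewise-constant rates the population-size generating function is
a composition of Moebius transforms, so ``p0``/``p1`` propagate across
bin boundaries: the value at a boundary becomes the initial condition
of the next (older) bin.  The same structure yields the geometric law
of the population size, ``P(N(t) = n) = p1(t) u(t)^{n-1}`` with
``u = 1 - p1 / (1 - p0)``, and the identity ``d u / d t = lam(t) p1(t)``
(for rho = 1), both of which the tree sampler relies on.

Everything here is vectorised over ``t`` and computed in log space
where underflow is possible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["p0_const", "log_p1_const", "PiecewiseBD"]


def _transform(s, lam: float, mu: float, d):
    """Moebius update of the no-sampled-descendant probability.

    Given probability ``s`` at the younger end of an interval of
    duration ``d`` with constant rates, returns ``(F, logFp)`` where
    ``F`` is the probability at the older end and ``logFp`` the log of
    the derivative dF/ds (the multiplier propagating p1).
    """
    s = np.asarray(s, dtype=float)
    d = np.asarray(d, dtype=float)
    if lam == mu:
        g = 1.0 + lam * d * (1.0 - s)
        F = 1.0 - (1.0 - s) / g
        logFp = -2.0 * np.log(g)
        return F, logFp
    r = lam - mu
    E = np.exp(-r * d)
    denom = lam * (1.0 - s) - (mu - lam * s) * E
    F = (mu * (1.0 - s) - (mu - lam * s) * E) / denom
    logFp = 2.0 * np.log(abs(r)) - r * d - 2.0 * np.log(np.abs(denom))
    return F, logFp


def p0_const(t, lam: float, mu: float, rho: float = 1.0):
    """Extinction/non-sampling probability, constant rates."""
    F, _ = _transform(1.0 - rho, lam, mu, t)
    return F


def log_p1_const(t, lam: float, mu: float, rho: float = 1.0):
    """log p1(t), constant rates."""
    _, logFp = _transform(1.0 - rho, lam, mu, t)
    return logFp + np.log(rho)


class PiecewiseBD:
    """p0 / p1 evaluation under piecewise-constant rates.

    Parameters
    ----------
    boundaries : increasing ages starting at 0.0; bin ``j`` covers
        ``[boundaries[j], boundaries[j+1])``, the last bin extends to
        infinity.
    lams, mus : per-bin branching and extinction rates.
    rho : sampling probability of an extant lineage at the present.
    """

    def __init__(self, boundaries, lams, mus, rho: float = 1.0):
        self.b = np.asarray(boundaries, dtype=float)
        self.lam = np.asarray(lams, dtype=float)
        self.mu = np.asarray(mus, dtype=float)
        if not 0.0 < rho <= 1.0:
            raise ValueError("rho must lie in (0, 1]")
        if self.b[0] != 0.0 or np.any(np.diff(self.b) <= 0):
            raise ValueError("boundaries must be increasing and start at 0")
        if len(self.b) != len(self.lam) or len(self.lam) != len(self.mu):
            raise ValueError("boundaries, lams and mus must have equal length")
        if np.any(self.lam <= 0) or np.any(self.mu < 0):
            raise ValueError("require lam > 0 and mu >= 0 in every bin")
        self.rho = float(rho)
        # propagate base values to every bin boundary, youngest first
        k = len(self.b)
        self._q0 = np.empty(k)
        self._logq1 = np.empty(k)
        self._q0[0] = 1.0 - rho
        self._logq1[0] = np.log(rho)
        for j in range(1, k):
            d = self.b[j] - self.b[j - 1]
            F, logFp = _transform(self._q0[j - 1], self.lam[j - 1], self.mu[j - 1], d)
            self._q0[j] = float(F)
            self._logq1[j] = self._logq1[j - 1] + float(logFp)

    def _bin_index(self, t):
        return np.clip(np.searchsorted(self.b, t, side="right") - 1, 0, len(self.b) - 1)

    def p0_logp1(self, t):
        """Return ``(p0(t), log p1(t))``; scalar in, scalar out."""
        scalar = np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        j = self._bin_index(t)
        p0 = np.empty_like(t)
        logp1 = np.empty_like(t)
        for jj in np.unique(j):
            m = j == jj
            F, logFp = _transform(
                self._q0[jj], self.lam[jj], self.mu[jj], t[m] - self.b[jj]
            )
            p0[m] = F
            logp1[m] = logFp + self._logq1[jj]
        if scalar:
            return float(p0[0]), float(logp1[0])
        return p0, logp1

    def p0(self, t):
        return self.p0_logp1(t)[0]

    def log_p1(self, t):
        return self.p0_logp1(t)[1]

    def log_u(self, t):
        """log of u(t) = 1 - p1/(1 - p0), the geometric parameter of N(t).

        For rho = 1, ``u(t)`` is also the CDF mass ``int_0^t lam p1``.
        """
        p0, logp1 = self.p0_logp1(np.atleast_1d(t))
        ratio = np.exp(logp1) / (1.0 - p0)
        out = np.log1p(-np.clip(ratio, 0.0, 1.0 - 1e-300))
        return float(out[0]) if np.ndim(t) == 0 else out

    def u(self, t):
        p0, logp1 = self.p0_logp1(t)
        return 1.0 - np.exp(logp1) / (1.0 - p0)

    def log_pn(self, t, n: int):
        """log P(N(t) = n) for a process started from one lineage at age t."""
        if n < 1:
            raise ValueError("n must be >= 1 (use p0 for n = 0)")
        _, logp1 = self.p0_logp1(t)
        return logp1 + (n - 1) * self.log_u(t)
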