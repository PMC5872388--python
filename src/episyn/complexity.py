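"""Sample-complexity bound for plug-in synergy estimation.

For a subset ``S``, estimation error tolerance ``delta`` and confidence
level ``1 - epsilon`` (both in (0, 1)), the bound prescribes

.. math::

    \\widetilde N(\\varepsilon, \\delta)
        = \\frac{2^{2|S|+3}}{\\delta^2}
          \\log \\frac{\\max\\{2^{|S|+1}, 6\\}}{\\varepsilon},
    \\qquad
    N \\ge \\frac{e^2}{(e-2)^2}\\,\\widetilde N\\,[\\log \\widetilde N]^2,

with natural logarithms throughout, after which
``Pr(|plug-in Syn - Syn| > delta) <= epsilon``.  The bound grows as
``2^{2|S|}``: sample complexity is exponential in the interaction order.

:func:`empirical_error_curve` verifies the concentration claim by Monte
Carlo against the exact population synergy of a small model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import xlogy

from .measures import synergy
from .model import InteractionModel, canonical_subset

__all__ = ["ComplexityQuery", "EmpiricalErrorCurve", "empirical_error_curve",
           "n_bound", "n_tilde"]

_E = float(np.e)
#: Leading constant e^2/(e-2)^2 of the bound, ~14.31.
BOUND_CONSTANT = _E ** 2 / (_E - 2.0) ** 2


def _check(subset_size: int, epsilon: float, delta: float):
    if subset_size < 1:
        raise ValueError("subset_size must be >= 1")
    if not 0 < epsilon < 1:
        raise ValueError(f"epsilon={epsilon} must lie in (0, 1)")
    if not 0 < delta < 1:
        raise ValueError(f"delta={delta} must lie in (0, 1)")


def n_tilde(subset_size: int, epsilon: float, delta: float) -> float:
    """Inner sample-size quantity ``2^{2|S|+3}/delta^2 * log(max{2^{|S|+1},6}/epsilon)``."""
    _check(subset_size, epsilon, delta)
    return (2.0 ** (2 * subset_size + 3) / delta ** 2
            * np.log(max(2.0 ** (subset_size + 1), 6.0) / epsilon))


def n_bound(subset_size: int, epsilon: float, delta: float) -> float:
    """Prescribed sample size ``(e^2/(e-2)^2) * Ntilde * (log Ntilde)^2``."""
    nt = n_tilde(subset_size, epsilon, delta)
    if nt <= 1.0:
        raise ValueError(f"n_tilde={nt} <= 1: the log factor is not positive")
    return BOUND_CONSTANT * nt * np.log(nt) ** 2


@dataclass(frozen=True)
class ComplexityQuery:
    """(|S|, epsilon, delta) triple for the sample-complexity bound."""

    subset_size: int
    epsilon: float
    delta: float

    def __post_init__(self):
        _check(self.subset_size, self.epsilon, self.delta)

    def n_tilde(self) -> float:
        return n_tilde(self.subset_size, self.epsilon, self.delta)

    def n_bound(self) -> float:
        return n_bound(self.subset_size, self.epsilon, self.delta)


def _synergy_stack(P: np.ndarray, k: int) -> np.ndarray:
    """Plug-in synergy for a stack of (reps, 2,...,2) tables over (S, Y).

    Alternating sum of mutual informations over nonempty sub-subsets,
    vectorized over the leading replicate axis.
    """
    axes = list(range(1, k + 2))  # table axes: 1..k covariates, k+1 outcome
    def H(keep):
        drop = tuple(a for a in axes if a not in keep)
        m = P.sum(axis=drop) if drop else P
        return -xlogy(m, m).sum(axis=tuple(range(1, m.ndim)))
    h_y = H([axes[-1]])
    total = np.zeros(P.shape[0])
    for r in range(1, k + 1):
        sign = (-1.0) ** (k - r)
        for t_axes in itertools.combinations(axes[:-1], r):
            mi = H(list(t_axes)) + h_y - H(list(t_axes) + [axes[-1]])
            total += sign * np.maximum(mi, 0.0)  # plug-in MI is >= 0 exactly
    return total


@dataclass
class EmpiricalErrorCurve:
    """Monte-Carlo deviations of the plug-in synergy from its population value."""

    subset: tuple[int, ...]
    population_synergy: float
    sample_sizes: tuple[int, ...]
    #: N -> array of |plug-in - population| over replicates
    deviations: dict[int, np.ndarray]

    def quantile(self, level: float) -> dict[int, float]:
        """The given quantile of the absolute deviation, per sample size."""
        return {n: float(np.quantile(dev, level))
                for n, dev in self.deviations.items()}

    def exceed_fraction(self, delta: float) -> dict[int, float]:
        """Fraction of replicates with deviation exceeding ``delta``, per N."""
        return {n: float((dev > delta).mean())
                for n, dev in self.deviations.items()}

    def loglog_slope(self) -> float:
        """Slope of log(mean deviation) against log(N) (expected near -1/2)."""
        ns = np.array(self.sample_sizes, dtype=float)
        means = np.array([self.deviations[int(n)].mean() for n in ns])
        return float(stats.linregress(np.log(ns), np.log(means)).slope)


def empirical_error_curve(model: InteractionModel, subset, N_list,
                          reps: int = 200, seed=None) -> EmpiricalErrorCurve:
    """Monte-Carlo distribution of the plug-in synergy estimation error.

    The population synergy is computed from the exact joint table of
    ``(X_S, Y)``; each replicate's empirical table is drawn directly as a
    multinomial sample of its ``2^{|S|+1}`` cell counts from that exact
    joint, which is distributionally identical to drawing ``N`` iid
    observations and tabulating them (the plug-in synergy depends on the
    data only through these cell counts).
    """
    sub = canonical_subset(subset, model.d)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if reps == 1:
        warnings.warn("reps=1 gives a single deviation; quantiles are degenerate")
    table = model.exact_joint(sub, include_outcome=True)
    pop = synergy(table, sub).value
    flat = table.probs.ravel()
    k = len(sub)
    rng = np.random.default_rng(seed)
    deviations = {}
    for n in N_list:
        n = int(n)
        counts = rng.multinomial(n, flat, size=reps)
        P = counts.reshape((reps,) + (2,) * (k + 1)) / n
        est = _synergy_stack(P, k)
        deviations[n] = np.abs(est - pop)
    return EmpiricalErrorCurve(sub, pop, tuple(int(n) for n in N_list), deviations)
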