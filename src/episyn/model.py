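"""Full logistic interaction model over binary covariates.

The model: ``d`` covariates :math:`X_1,\\dots,X_d` taking values in
:math:`\\{+1,-1\\}` with :math:`\\Pr(X_i=+1)=p_i`, and a binary outcome
:math:`Y` with

.. math::

    \\Pr(Y=1\\mid X_1,\\dots,X_d)
        = \\sigma\\Big(\\beta_\\emptyset
          + \\sum_{\\emptyset \\subset S \\subseteq \\{1..d\\}}
            \\beta_S \\prod_{i\\in S} X_i\\Big),

where :math:`\\sigma(x)=1/(1+e^{-x})`.  A coefficient :math:`\\beta_S`
attached to a subset ``S`` of two or more covariates is a multiplicative
(epistatic) interaction; singleton coefficients are main effects.

Covariate indices are 0-based everywhere in this package's API; report
writers add 1 when emitting human-readable tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.special import expit, xlogy

__all__ = [
    "EnumerationLimitError",
    "InteractionModel",
    "JointTable",
    "MAX_ENUM_D",
    "random_model",
]

#: Largest d for which exact 2^d enumeration is permitted.
MAX_ENUM_D = 20

#: The simulation study's grid of marginal probabilities.
DEFAULT_P_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)

Subset = tuple[int, ...]


class EnumerationLimitError(RuntimeError):
    """Raised when exact enumeration is requested for a model too large for 2^d state iteration."""


def canonical_subset(subset: Iterable[int], d: int | None = None,
                     allow_empty: bool = False) -> Subset:
    """Normalize a covariate subset to a sorted tuple of distinct 0-based indices."""
    s = tuple(sorted(int(i) for i in subset))
    if not allow_empty and len(s) == 0:
        raise ValueError("subset must be nonempty")
    if len(set(s)) != len(s):
        raise ValueError(f"subset has duplicate indices: {s}")
    if s and s[0] < 0:
        raise ValueError(f"negative covariate index in subset {s}")
    if d is not None and s and s[-1] >= d:
        raise ValueError(f"subset {s} out of range for d={d}")
    return s


@dataclass(frozen=True)
class JointTable:
    """Exact or empirical probability table over a small set of +/-1 variables.

    Parameters
    ----------
    variables
        Ordered tuple of 0-based covariate indices covered by the table.
    probs
        Array of shape ``(2,) * t`` where ``t = len(variables) + has_outcome``.
        Axis order follows ``variables``, with the outcome axis last when
        present.  Index 1 on an axis means the variable equals +1, index 0
        means -1.
    has_outcome
        Whether the final axis is the outcome Y.
    """

    variables: Subset
    probs: np.ndarray
    has_outcome: bool = True

    def __post_init__(self):
        t = len(self.variables) + int(self.has_outcome)
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (2,) * t:
            raise ValueError(f"probs shape {p.shape} incompatible with {t} variables")
        if np.any(p < -1e-15):
            raise ValueError("negative probability in table")
        if abs(float(p.sum()) - 1.0) > 1e-12:
            raise ValueError(f"table sums to {p.sum()!r}, not 1")
        object.__setattr__(self, "probs", np.clip(p, 0.0, None))
        object.__setattr__(self, "variables",
                           canonical_subset(self.variables, allow_empty=True))

    @property
    def n_vars(self) -> int:
        return len(self.variables) + int(self.has_outcome)

    def _axis(self, i: int) -> int:
        return self.variables.index(i)

    def marginal(self, subset: Iterable[int], include_outcome: bool = True) -> "JointTable":
        """Marginalize onto ``subset`` (and optionally the outcome axis)."""
        sub = canonical_subset(subset, allow_empty=True)
        missing = [i for i in sub if i not in self.variables]
        if missing:
            raise ValueError(f"variables {missing} not in table {self.variables}")
        if include_outcome and not self.has_outcome:
            raise ValueError("table has no outcome axis")
        keep = [self._axis(i) for i in sub]
        if include_outcome:
            keep.append(self.probs.ndim - 1)
        drop = tuple(a for a in range(self.probs.ndim) if a not in keep)
        p = self.probs.sum(axis=drop)
        # axes already ordered: variables sorted, outcome last
        return JointTable(sub, p, has_outcome=include_outcome)

    def p_plus(self, i: int) -> float:
        """Marginal probability that covariate ``i`` equals +1."""
        m = self.marginal((i,), include_outcome=False)
        return float(m.probs[1])

    def entropy(self) -> float:
        """Plug-in Shannon entropy of the full table, in nats (0 log 0 := 0)."""
        p = self.probs
        return float(-xlogy(p, p).sum())


def _validate_pm1(x: np.ndarray, d: int) -> np.ndarray:
    x = np.asarray(x)
    if x.shape[-1] != d:
        raise ValueError(f"assignment length {x.shape[-1]} != d={d}")
    if not np.isin(x, (-1, 1)).all():
        raise ValueError("assignment entries must be +1 or -1")
    return x.astype(np.float64)


@dataclass
class InteractionModel:
    """A full logistic interaction model.

    Parameters
    ----------
    d
        Number of covariates.
    beta
        Mapping from covariate subsets (iterables of 0-based indices; the
        empty tuple holds the intercept) to real coefficients.  Subsets not
        listed have coefficient exactly 0.
    p
        Length-``d`` vector of marginal probabilities ``Pr(X_i = +1)``,
        each strictly inside (0, 1).
    C
        Optional strict bound on coefficient magnitudes: ``|beta_S| < C``
        is enforced at construction when given.
    """

    d: int
    beta: dict[Subset, float] = field(default_factory=dict)
    p: np.ndarray = None
    C: float | None = None

    def __post_init__(self):
        if self.d < 1:
            raise ValueError("d must be a positive integer")
        clean: dict[Subset, float] = {}
        for s, b in dict(self.beta).items():
            key = canonical_subset(s, self.d, allow_empty=True)
            if key in clean:
                raise ValueError(f"duplicate subset {key}")
            clean[key] = float(b)
        self.beta = clean
        if self.p is None:
            self.p = np.full(self.d, 0.5)
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.d,):
            raise ValueError(f"p has shape {self.p.shape}, expected ({self.d},)")
        if np.any(self.p <= 0) or np.any(self.p >= 1):
            raise ValueError("all p_i must lie strictly in (0, 1)")
        if self.C is not None:
            if self.C <= 0:
                raise ValueError("C must be positive")
            bad = {s: b for s, b in self.beta.items() if abs(b) >= self.C}
            if bad:
                raise ValueError(f"|beta_S| >= C={self.C} for subsets {sorted(bad)}")

    # -- basic accessors -------------------------------------------------

    @property
    def q(self) -> np.ndarray:
        """Complement marginals ``q_i = 1 - p_i``."""
        return 1.0 - self.p

    @property
    def intercept(self) -> float:
        return self.beta.get((), 0.0)

    def coefficient(self, subset: Iterable[int]) -> float:
        return self.beta.get(canonical_subset(subset, self.d, allow_empty=True), 0.0)

    def interaction_subsets(self) -> list[Subset]:
        """Nonempty subsets carrying a (possibly zero) stored coefficient."""
        return sorted(s for s in self.beta if s)

    # -- evaluation ------------------------------------------------------

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        """Logit eta(x) = beta_0 + sum_S beta_S prod_{i in S} x_i for rows of X."""
        X = _validate_pm1(X, self.d)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        eta = np.full(X.shape[0], self.intercept)
        for s, b in self.beta.items():
            if s and b != 0.0:
                eta += b * X[:, s].prod(axis=1)
        return eta[0] if single else eta

    def conditional_prob(self, x: Sequence[int]) -> float:
        """``Pr(Y = 1 | X = x)`` through the sigmoid link; strictly in (0, 1)."""
        x = np.asarray(x)
        if x.ndim != 1:
            raise ValueError("conditional_prob takes a single length-d assignment")
        return float(expit(self.linear_predictor(x)))

    # -- exact enumeration (population oracle) ---------------------------

    def exact_joint(self, subset: Iterable[int] = (),
                    include_outcome: bool = True) -> JointTable:
        """Exact joint distribution of ``(X_subset, Y)`` by full 2^d enumeration.

        Marginalizes the model over every covariate outside ``subset``.
        Guarded at ``d <= MAX_ENUM_D``; larger models must be sampled.
        """
        if self.d > MAX_ENUM_D:
            raise EnumerationLimitError(
                f"exact_joint enumerates 2^d states; d={self.d} exceeds the "
                f"guard d <= {MAX_ENUM_D}. Use the sampling module instead.")
        sub = canonical_subset(subset, self.d, allow_empty=True)
        if not include_outcome and not sub:
            raise ValueError("empty subset with no outcome has no distribution")
        n = 1 << self.d
        idx = np.arange(n, dtype=np.int64)
        bits = (idx[:, None] >> np.arange(self.d)) & 1  # column i = bit of X_i
        w = np.where(bits == 1, self.p, self.q).prod(axis=1)
        code = np.zeros(n, dtype=np.int64)
        for i in sub:  # first listed variable = most significant
            code = (code << 1) | bits[:, i]
        k = len(sub)
        if include_outcome:
            X = 2.0 * bits - 1.0
            p_y1 = expit(self.linear_predictor(X))
            plus = np.bincount(code, weights=w * p_y1, minlength=1 << k)
            minus = np.bincount(code, weights=w * (1.0 - p_y1), minlength=1 << k)
            probs = np.stack([minus, plus], axis=-1).reshape((2,) * (k + 1))
        else:
            probs = np.bincount(code, weights=w, minlength=1 << k).reshape((2,) * k)
        return JointTable(sub, probs, has_outcome=include_outcome)

    # -- quadratic synergy approximation ---------------------------------

    def predicted_synergy(self, subset: Iterable[int]) -> float:
        """Leading-order synergy approximation (nats).

        For a highest-order interaction ``S`` (no coefficients on strict
        supersets of ``S``), the population synergy of ``(X_S, Y)`` is
        ``(1/8) beta_S^2 prod_{i in S} 4 p_i q_i + O(C^3)``; with uniform
        marginals this is ``beta_S^2 / 8``.
        """
        s = canonical_subset(subset, self.d)
        b = self.coefficient(s)
        idx = list(s)
        return float(b * b / 8.0 * np.prod(4.0 * self.p[idx] * self.q[idx]))

    def common_factor(self, subset: Iterable[int]) -> float:
        """The marginal-dependent factor ``(1/8) prod_{i in S} 4 p_i q_i``."""
        s = canonical_subset(subset, self.d)
        idx = list(s)
        return float(np.prod(4.0 * self.p[idx] * self.q[idx]) / 8.0)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "d": int(self.d),
            "p": [float(v) for v in self.p],
            "beta": [{"subset": [i + 1 for i in s], "coefficient": b}
                     for s, b in sorted(self.beta.items())],
            "C": self.C,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "InteractionModel":
        beta = {tuple(int(i) - 1 for i in rec["subset"]): float(rec["coefficient"])
                for rec in doc.get("beta", [])}
        return cls(d=int(doc["d"]), beta=beta, p=np.asarray(doc["p"], dtype=float),
                   C=doc.get("C"))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "InteractionModel":
        try:
            with open(path_or_text) as fh:
                doc = yaml.safe_load(fh)
        except (OSError, TypeError):
            doc = yaml.safe_load(path_or_text)
        return cls.from_dict(doc)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def random_model(d: int, n_main: int, n_pairs: int,
                 coeff_low: float = 1.0, coeff_high: float = 2.0,
                 p_grid: Sequence[float] = DEFAULT_P_GRID,
                 seed=None, intercept: float = 0.0) -> InteractionModel:
    """Draw a random interaction model following the simulation protocol.

    ``n_main`` distinct covariates receive main-effect coefficients and
    ``n_pairs`` distinct covariate pairs receive interaction coefficients,
    all drawn uniformly from ``[coeff_low, coeff_high]``; each marginal
    ``p_i`` is drawn uniformly from ``p_grid``.  The defaults reproduce the
    50-feature study conditions (coefficients U[1,2]; grid 0.1, ..., 0.9).
    """
    if not 0 <= n_main <= d:
        raise ValueError(f"n_main={n_main} must lie in [0, d={d}]")
    max_pairs = d * (d - 1) // 2
    if not 0 <= n_pairs <= max_pairs:
        raise ValueError(f"n_pairs={n_pairs} must lie in [0, {max_pairs}]")
    rng = np.random.default_rng(seed)
    beta: dict[Subset, float] = {}
    if intercept:
        beta[()] = float(intercept)
    mains = rng.choice(d, size=n_main, replace=False)
    for i in np.sort(mains):
        beta[(int(i),)] = float(rng.uniform(coeff_low, coeff_high))
    if n_pairs:
        all_pairs = [(i, j) for i in range(d) for j in range(i + 1, d)]
        chosen = rng.choice(len(all_pairs), size=n_pairs, replace=False)
        for k in np.sort(chosen):
            beta[all_pairs[k]] = float(rng.uniform(coeff_low, coeff_high))
    p = np.asarray(p_grid, dtype=float)[rng.integers(0, len(p_grid), size=d)]
    return InteractionModel(d=d, beta=beta, p=p)
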