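"""Plug-in information measures for interaction detection.

All quantities are Shannon measures in nats computed by the plug-in
principle: substitute cell probabilities (empirical frequencies, or the
exact population table from :meth:`InteractionModel.exact_joint`) into the
population formula, with ``0 log 0 := 0`` and no smoothing by default.

Measures
--------
``synergy``
    Multivariate synergy of a covariate set ``S`` and the outcome,
    ``Syn(X_S; Y) = sum over nonempty T subseteq S of
    (-1)^{|S|-|T|} I(X_T; Y)``.  For ``|S| = 1`` this is exactly the
    mutual information ``I(X_i; Y)``; for a pair it is
    ``I(X_i, X_j; Y) - I(X_i; Y) - I(X_j; Y)``.
``adjusted_synergy``
    ``Syn(X_S; Y)`` divided by the marginal-dependent common factor
    ``(1/8) prod_{i in S} 4 p_i q_i``; for a highest-order interaction it
    approaches the squared logistic interaction coefficient ``beta_S^2``.
``schneidman``
    Normalized synergy ``Syn / I(X_S; Y)`` (0 when the joint mutual
    information vanishes).
``ignac_nmi``
    Entropy-normalized interaction information
    ``Syn(X_S; Y) / H(X_S, Y)`` (for a pair, the interaction information
    of ``(X_i, X_j, Y)`` divided by their joint entropy).
``watanabe_tc``
    Total correlation ``sum_i H(Z_i) - H(Z_1..Z_n)`` of ``(X_S, Y)``.
``han_dtc``
    Dual total correlation ``H(Z_1..Z_n) - sum_i H(Z_i | rest)`` of
    ``(X_S, Y)``; for a pair plus outcome this equals
    ``H(X_i,X_j) + H(X_i,Y) + H(X_j,Y) - 2 H(X_i,X_j,Y)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .model import JointTable, canonical_subset
from .sampling import Dataset

__all__ = [
    "MEASURES",
    "PairScores",
    "SubsetScore",
    "adjusted_synergy",
    "comparison_measures",
    "empirical_table",
    "mutual_information",
    "pairwise_scores",
    "plugin_entropy",
    "synergy",
]

#: Identifiers of the six benchmark measures plus plain mutual information.
MEASURES = ("synergy", "adjusted_synergy", "schneidman", "ignac_nmi",
            "watanabe_tc", "han_dtc", "mutual_information")

_NEG_TOL = 1e-12  # plug-in MI/TC can go this far negative in floating point

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class SubsetScore:
    """A covariate subset, a measure identifier, and the estimated value in nats."""

    subset: tuple[int, ...]
    measure: str
    value: float
    n: int | None = None
    flag: bool = False  # set when a degenerate denominator forced a convention

    def __post_init__(self):
        object.__setattr__(self, "subset", canonical_subset(self.subset))
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; valid: {MEASURES}")

    @property
    def value_bits(self) -> float:
        """The value converted to bits, for display only."""
        return self.value / LN2


def plugin_entropy(table: JointTable) -> float:
    """Plug-in Shannon entropy of a joint table, in nats."""
    return table.entropy()


def empirical_table(data: Dataset, subset, include_outcome: bool = True,
                    pseudocount: float = 0.0) -> JointTable:
    """Empirical joint table of ``(X_subset[, Y])`` from a dataset.

    Cell values are counts / N; zero-count cells are present with
    probability 0.  ``pseudocount`` adds a flat count to every cell before
    normalizing (off by default; the sample-complexity theory analyzes the
    raw plug-in estimator).
    """
    sub = canonical_subset(subset, data.d)
    k = len(sub)
    bits = (data.X[:, sub] == 1).astype(np.int64)
    code = np.zeros(data.N, dtype=np.int64)
    for j in range(k):
        code = (code << 1) | bits[:, j]
    t = k
    if include_outcome:
        code = (code << 1) | (data.y == 1).astype(np.int64)
        t += 1
    counts = np.bincount(code, minlength=1 << t).astype(float) + pseudocount
    probs = (counts / counts.sum()).reshape((2,) * t)
    return JointTable(sub, probs, has_outcome=include_outcome)


def _as_table(source, subset, include_outcome: bool = True) -> JointTable:
    if isinstance(source, JointTable):
        return source.marginal(subset, include_outcome)
    if isinstance(source, Dataset):
        return empirical_table(source, subset, include_outcome)
    raise TypeError(f"source must be a Dataset or JointTable, got {type(source)}")


def _source_n(source) -> int | None:
    return source.N if isinstance(source, Dataset) else None


def _mi_with_outcome(table: JointTable, subset) -> float:
    """I(X_subset; Y) from a table that includes the outcome axis.

    Clipped at 0: plug-in mutual information is nonnegative in exact
    arithmetic, and clipping keeps the singleton-synergy reduction to
    mutual information exact to the last bit.
    """
    h_joint = table.marginal(subset, True).entropy()
    h_x = table.marginal(subset, False).entropy()
    h_y = table.marginal((), True).entropy()
    return max(h_x + h_y - h_joint, 0.0)


def mutual_information(source, subset) -> SubsetScore:
    """Plug-in mutual information ``I(X_subset; Y)`` in nats."""
    sub = canonical_subset(subset)
    table = _as_table(source, sub)
    return SubsetScore(sub, "mutual_information", _mi_with_outcome(table, sub),
                       n=_source_n(source))


def synergy(source, subset) -> SubsetScore:
    """Multivariate synergy ``Syn(X_S; Y)`` via the alternating subset sum."""
    sub = canonical_subset(subset)
    table = _as_table(source, sub)
    k = len(sub)
    total = 0.0
    for r in range(1, k + 1):
        sign = (-1) ** (k - r)
        for t_sub in itertools.combinations(sub, r):
            total += sign * _mi_with_outcome(table, t_sub)
    return SubsetScore(sub, "synergy", total, n=_source_n(source))


def adjusted_synergy(source, subset) -> SubsetScore:
    """Synergy normalized by the common factor ``(1/8) prod_{i in S} 4 p_i q_i``."""
    sub = canonical_subset(subset)
    table = _as_table(source, sub)
    factor = 1.0 / 8.0
    for i in sub:
        p = table.p_plus(i)
        if p <= 0.0 or p >= 1.0:
            raise ValueError(
                f"degenerate marginal p_{i}={p}: the adjusted-synergy "
                "normalizer prod 4 p_i q_i is zero")
        factor *= 4.0 * p * (1.0 - p)
    syn = synergy(table, sub).value
    return SubsetScore(sub, "adjusted_synergy", syn / factor, n=_source_n(source))


def comparison_measures(source, pair) -> list[SubsetScore]:
    """Schneidman, Ignac NMI, Watanabe TC, and Han DTC for a covariate pair."""
    sub = canonical_subset(pair)
    if len(sub) != 2:
        raise ValueError(f"comparison measures are defined for pairs, got {sub}")
    i, j = sub
    table = _as_table(source, sub)
    n = _source_n(source)
    h3 = table.entropy()
    h_ij = table.marginal(sub, False).entropy()
    h_iy = table.marginal((i,), True).entropy()
    h_jy = table.marginal((j,), True).entropy()
    h_i = table.marginal((i,), False).entropy()
    h_j = table.marginal((j,), False).entropy()
    h_y = table.marginal((), True).entropy()

    mi = max(h_ij + h_y - h3, 0.0)
    syn = mi - max(h_i + h_y - h_iy, 0.0) - max(h_j + h_y - h_jy, 0.0)
    tc = max(h_i + h_j + h_y - h3, 0.0)
    dtc = max(h_ij + h_iy + h_jy - 2.0 * h3, 0.0)
    schneid_flag = mi <= _NEG_TOL
    schneid = 0.0 if schneid_flag else syn / mi
    nmi_flag = h3 <= _NEG_TOL
    nmi = 0.0 if nmi_flag else syn / h3
    return [
        SubsetScore(sub, "schneidman", schneid, n=n, flag=schneid_flag),
        SubsetScore(sub, "ignac_nmi", nmi, n=n, flag=nmi_flag),
        SubsetScore(sub, "watanabe_tc", tc, n=n),
        SubsetScore(sub, "han_dtc", dtc, n=n),
    ]


# ---------------------------------------------------------------------------
# Vectorized all-pairs scoring
# ---------------------------------------------------------------------------

def _entropy_stack(p: np.ndarray, n_cell_axes: int) -> np.ndarray:
    """Entropy over the leading ``n_cell_axes`` axes of a probability stack."""
    return -xlogy(p, p).sum(axis=tuple(range(n_cell_axes)))


class PairScores:
    """All-pairs scores of every measure on one dataset.

    Built by :func:`pairwise_scores`; holds, for each measure, a symmetric
    ``d x d`` matrix of values (diagonal NaN) plus the per-pair
    complete-case sample count ``n``.  The heavy lifting is three
    ``d x d`` matrix products per outcome class, so scoring all
    ``d(d-1)/2`` pairs with all measures costs about as much as two
    passes over the data.
    """

    def __init__(self, matrices: dict[str, np.ndarray], n: np.ndarray):
        self.matrices = matrices
        self.n = n
        self.d = n.shape[0]

    def matrix(self, measure: str) -> np.ndarray:
        if measure not in self.matrices:
            raise ValueError(
                f"unknown measure {measure!r}; valid: {tuple(self.matrices)}")
        return self.matrices[measure]

    def score(self, measure: str, i: int, j: int) -> float:
        return float(self.matrix(measure)[i, j])

    def ranked(self, measure: str,
               allowed: np.ndarray | None = None) -> list[SubsetScore]:
        """All pairs sorted descending by value; ties broken lexicographically."""
        m = self.matrix(measure)
        iu, ju = np.triu_indices(self.d, k=1)
        if allowed is not None:
            keep = allowed[iu, ju]
            iu, ju = iu[keep], ju[keep]
        vals = m[iu, ju]
        order = np.lexsort((ju, iu, -vals))
        return [SubsetScore((int(iu[k]), int(ju[k])), measure, float(vals[k]),
                            n=int(self.n[iu[k], ju[k]]))
                for k in order]

    def top_pairs(self, measure: str, k: int,
                  allowed: np.ndarray | None = None) -> list[tuple[int, int]]:
        return [s.subset for s in self.ranked(measure, allowed)[:k]]


def pairwise_scores(X: np.ndarray, y: np.ndarray,
                    valid: np.ndarray | None = None,
                    measures=MEASURES) -> PairScores:
    """Score every covariate pair against the outcome with every measure.

    Parameters
    ----------
    X
        ``N x d`` matrix over ``{+1, -1}`` (entries at invalid positions are
        ignored).
    y
        Length-``N`` outcome over ``{+1, -1}``.
    valid
        Optional boolean ``N x d`` mask; a pair ``(i, j)`` is tabulated over
        the samples valid at both ``i`` and ``j`` (per-pair complete-case
        analysis).  Default: all valid.
    measures
        Iterable of measure identifiers to compute.

    Returns
    -------
    PairScores
    """
    X = np.asarray(X)
    y = np.asarray(y)
    N, d = X.shape
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measures {sorted(unknown)}; valid: {MEASURES}")
    if valid is None:
        valid = np.ones((N, d), dtype=bool)
    # 8-cell counts per pair: counts[a, b, c] = #{x_i = a, x_j = b, y = c}
    counts = np.empty((2, 2, 2, d, d))
    for c, cls in enumerate((-1, 1)):
        rows = y == cls
        V = valid[rows].astype(np.float64)
        B1 = (X[rows] == 1) * V
        B0 = V - B1
        n11 = B1.T @ B1
        n10 = B1.T @ B0
        n00 = B0.T @ B0
        counts[1, 1, c] = n11
        counts[1, 0, c] = n10
        counts[0, 1, c] = n10.T
        counts[0, 0, c] = n00
    n = counts.sum(axis=(0, 1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        P = counts / n
        h3 = _entropy_stack(P, 3)
        p_ij = P.sum(axis=2)
        p_iy = P.sum(axis=1)
        p_jy = P.sum(axis=0)
        h_ij = _entropy_stack(p_ij, 2)
        h_iy = _entropy_stack(p_iy, 2)
        h_jy = _entropy_stack(p_jy, 2)
        p_i = p_ij.sum(axis=1)
        p_j = p_ij.sum(axis=0)
        p_y = p_iy.sum(axis=0)
        h_i = _entropy_stack(p_i, 1)
        h_j = _entropy_stack(p_j, 1)
        h_y = _entropy_stack(p_y, 1)

        mi = np.maximum(h_ij + h_y - h3, 0.0)
        mi_i = np.maximum(h_i + h_y - h_iy, 0.0)
        mi_j = np.maximum(h_j + h_y - h_jy, 0.0)
        syn = mi - mi_i - mi_j

        out: dict[str, np.ndarray] = {}
        if "synergy" in measures:
            out["synergy"] = syn
        if "mutual_information" in measures:
            out["mutual_information"] = mi
        if "adjusted_synergy" in measures:
            pi, pj = p_i[1], p_j[1]
            factor = (4.0 * pi * (1 - pi)) * (4.0 * pj * (1 - pj)) / 8.0
            out["adjusted_synergy"] = np.where(factor > 0, syn / np.where(factor > 0, factor, 1.0), np.nan)
        if "schneidman" in measures:
            out["schneidman"] = np.where(mi > _NEG_TOL, syn / np.where(mi > 0, mi, 1.0), 0.0)
        if "ignac_nmi" in measures:
            out["ignac_nmi"] = np.where(h3 > _NEG_TOL, syn / np.where(h3 > 0, h3, 1.0), 0.0)
        if "watanabe_tc" in measures:
            out["watanabe_tc"] = np.maximum(h_i + h_j + h_y - h3, 0.0)
        if "han_dtc" in measures:
            out["han_dtc"] = np.maximum(h_ij + h_iy + h_jy - 2.0 * h3, 0.0)
    diag = np.eye(d, dtype=bool)
    for m in out.values():
        m[diag] = np.nan
    return PairScores(out, n)
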