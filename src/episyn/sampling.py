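"""Samplers for logistic interaction models.

Two designs are provided: independent covariates (each ``X_i`` an
independent two-point variable with ``Pr(X_i=+1)=p_i``) and the weakly
dependent construction in which a latent sign ``K`` is drawn uniformly on
``{+1,-1}`` for every observation and each covariate follows
``Pr(X_i=+1 | K) = p_i + mu*K``.  Marginals are unchanged and every pair
of distinct covariates has covariance exactly ``4 mu^2``.

Randomness is split into three fixed substreams (X draws, K draws, y
draws) via ``SeedSequence.spawn``, so a seed identifies a dataset
portably and ``mu = 0`` reproduces the independent sampler byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import InteractionModel

__all__ = ["Dataset", "sample_independent", "sample_dependent"]


@dataclass(frozen=True)
class Dataset:
    """An N x d matrix of +/-1 covariate observations with +/-1 outcomes."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        X = np.asarray(self.X, dtype=np.int8)
        y = np.asarray(self.y, dtype=np.int8)
        if X.ndim != 2 or y.ndim != 1:
            raise ValueError("X must be 2-D and y 1-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
        if X.shape[0] < 1:
            raise ValueError("dataset must contain at least one observation")
        if not np.isin(X, (-1, 1)).all() or not np.isin(y, (-1, 1)).all():
            raise ValueError("all entries of X and y must be +1 or -1")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def to_tsv(self, path) -> None:
        """Write as TSV with columns X1..Xd, Y (1-based covariate labels)."""
        df = pd.DataFrame(self.X, columns=[f"X{i+1}" for i in range(self.d)])
        df["Y"] = self.y
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Dataset":
        df = pd.read_csv(path, sep="\t")
        if "Y" not in df.columns:
            raise ValueError("TSV dataset must contain a Y column")
        y = df.pop("Y").to_numpy()
        return cls(df.to_numpy(), y)


def _split_streams(seed):
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(3)]


def _draw_outcome(model: InteractionModel, X: np.ndarray, rng) -> np.ndarray:
    p_y1 = expit(model.linear_predictor(X))
    return np.where(rng.random(X.shape[0]) < p_y1, 1, -1).astype(np.int8)


def sample_independent(model: InteractionModel, N: int, seed=None) -> Dataset:
    """Draw ``N`` observations with independent two-point covariates."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng_x, _rng_k, rng_y = _split_streams(seed)
    X = np.where(rng_x.random((N, model.d)) < model.p, 1, -1).astype(np.int8)
    y = _draw_outcome(model, X, rng_y)
    return Dataset(X, y)


def sample_dependent(model: InteractionModel, N: int, mu: float, seed=None) -> Dataset:
    """Draw ``N`` observations with weakly dependent covariates.

    A fresh latent ``K`` uniform on {+1,-1} is drawn for every observation;
    covariate ``i`` is +1 with probability ``p_i + mu*K``.  Requires
    ``0 <= mu < min_i min(p_i, q_i)`` so every conditional probability
    stays strictly inside (0, 1).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    bound = float(np.minimum(model.p, model.q).min())
    if not 0 <= mu < bound:
        raise ValueError(
            f"mu={mu} violates 0 <= mu < min_i min(p_i, q_i) = {bound:.6g}")
    rng_x, rng_k, rng_y = _split_streams(seed)
    if mu == 0:
        # identical stream usage as sample_independent (K stream untouched)
        X = np.where(rng_x.random((N, model.d)) < model.p, 1, -1).astype(np.int8)
    else:
        K = np.where(rng_k.random(N) < 0.5, 1.0, -1.0)
        cond_p = model.p[None, :] + mu * K[:, None]
        X = np.where(rng_x.random((N, model.d)) < cond_p, 1, -1).astype(np.int8)
    y = _draw_outcome(model, X, rng_y)
    return Dataset(X, y)
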