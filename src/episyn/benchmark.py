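"""Detection benchmark: planted-interaction recovery across sample sizes.

The study design: draw many random logistic interaction models, each with
a few planted main effects and interacting pairs; for each model and each
training-set size, sample a dataset, score every covariate pair with each
configured measure, and call the top-``k`` pairs detected.  Accuracy for a
measure at a sample size is the fraction of planted pairs recovered in
the top ``k``, averaged over models.

The defaults of :class:`BenchmarkConfig` are the 50-feature study
conditions: 1000 models, 3 main effects and 3 interacting pairs with
coefficients U[1, 2], marginals on the grid 0.1, ..., 0.9, and training
sizes 500 to 3000.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .measures import MEASURES, PairScores, SubsetScore, pairwise_scores
from .model import DEFAULT_P_GRID, InteractionModel, random_model
from .sampling import Dataset, sample_dependent, sample_independent

__all__ = [
    "BenchmarkConfig",
    "BenchmarkResult",
    "compare_measures",
    "detect_topk",
    "fit_log_law",
    "run_benchmark",
    "score_all_pairs",
]

#: Measures ranked in the simulation study (mutual information is reported
#: implicitly through Ignac's normalization, not ranked on its own).
BENCHMARK_MEASURES = ("synergy", "adjusted_synergy", "schneidman",
                      "ignac_nmi", "watanabe_tc", "han_dtc")

_PAIR_BUDGET = 20_000_000_000  # pairs x models x total samples guard; the
# full 50-feature protocol (1000 models, sizes 500..3000) is ~1.3e10


def score_all_pairs(data: Dataset, measure: str = "synergy") -> list[SubsetScore]:
    """Score all d(d-1)/2 covariate pairs, sorted descending (lexicographic ties)."""
    scores = pairwise_scores(data.X, data.y, measures=(measure,))
    return scores.ranked(measure)


def detect_topk(ranked, truth, k: int = 3) -> int:
    """Number of true pairs appearing among the top ``k`` of a ranked list."""
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds ranking length {len(ranked)}")
    truth_set = {tuple(sorted(t)) for t in truth}
    top = ranked[:k]
    top_pairs = {s.subset if isinstance(s, SubsetScore) else tuple(sorted(s))
                 for s in top}
    return len(top_pairs & truth_set)


@dataclass
class BenchmarkConfig:
    """Configuration of one benchmark run (defaults: 50-feature protocol)."""

    n_models: int = 1000
    d: int = 50
    n_main: int = 3
    n_pairs: int = 3
    coeff_range: tuple[float, float] = (1.0, 2.0)
    p_grid: tuple[float, ...] = DEFAULT_P_GRID
    sample_sizes: tuple[int, ...] = (500, 1000, 1500, 2000, 2500, 3000)
    mu: float = 0.0
    measures: tuple[str, ...] = BENCHMARK_MEASURES
    top_k: int = 3
    seed: int = 0

    def __post_init__(self):
        self.sample_sizes = tuple(int(n) for n in self.sample_sizes)
        if any(b <= a for a, b in zip(self.sample_sizes, self.sample_sizes[1:])):
            raise ValueError("sample_sizes must be strictly increasing")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measures {sorted(unknown)}")
        load = (self.d * (self.d - 1) // 2) * self.n_models * sum(self.sample_sizes)
        if load > _PAIR_BUDGET:
            raise ValueError(
                f"benchmark load {load:.3g} (pairs x models x samples) exceeds "
                f"the budget {_PAIR_BUDGET:.3g}; reduce n_models or sample_sizes")

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        import yaml
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "coeff_range" in doc:
            doc["coeff_range"] = tuple(doc["coeff_range"])
        for key in ("p_grid", "sample_sizes", "measures"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass
class BenchmarkResult:
    """Per-model, per-sample-size recovered counts for each measure."""

    config: BenchmarkConfig
    #: measure -> integer array (n_models, n_sample_sizes) of recovered counts
    recovered: dict[str, np.ndarray]
    #: truth pairs of each model (for reference/debugging)
    truths: list[tuple[tuple[int, int], ...]] = field(default_factory=list)

    @property
    def sample_sizes(self) -> tuple[int, ...]:
        return self.config.sample_sizes

    @property
    def measures(self) -> tuple[str, ...]:
        return tuple(self.recovered)

    def accuracy(self, measure: str) -> np.ndarray:
        """Mean fraction of planted pairs recovered, per sample size."""
        rec = self.recovered[measure]
        return rec.mean(axis=0) / self.config.n_pairs

    def accuracy_table(self) -> pd.DataFrame:
        """Tidy frame of (measure, N, accuracy)."""
        rows = [(m, n, a)
                for m in self.measures
                for n, a in zip(self.sample_sizes, self.accuracy(m))]
        return pd.DataFrame(rows, columns=["measure", "N", "accuracy"])

    def per_model_accuracy(self, measure: str, sample_sizes=None) -> np.ndarray:
        """Per-(model, N) accuracies pooled over the selected sizes, flattened."""
        idx = self._size_indices(sample_sizes)
        return (self.recovered[measure][:, idx] / self.config.n_pairs).ravel()

    def _size_indices(self, sample_sizes):
        if sample_sizes is None:
            return np.arange(len(self.sample_sizes))
        missing = set(sample_sizes) - set(self.sample_sizes)
        if missing:
            raise ValueError(f"sample sizes {sorted(missing)} not in result")
        return np.array([self.sample_sizes.index(n) for n in sample_sizes])

    def summary(self) -> str:
        wide = self.accuracy_table().pivot(index="measure", columns="N",
                                           values="accuracy")
        wide = wide.reindex(list(self.measures))
        lines = [
            "Detection benchmark"
            f" (models={self.config.n_models}, d={self.config.d},"
            f" pairs={self.config.n_pairs}, top-{self.config.top_k},"
            f" mu={self.config.mu})",
            "Accuracy (fraction of planted pairs in the top ranks):",
            wide.round(4).to_string(),
        ]
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        doc = {
            "config": {**asdict(self.config)},
            "accuracy": {m: list(map(float, self.accuracy(m)))
                         for m in self.measures},
            "sample_sizes": list(self.sample_sizes),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_benchmark(config: BenchmarkConfig, progress: bool = False) -> BenchmarkResult:
    """Run the planted-pair detection benchmark.

    For every model and every sample size a fresh dataset is drawn and all
    configured measures are scored on that same dataset (paired design),
    then the top-``k`` rule is applied per measure.  Fully reproducible
    from ``config.seed``.
    """
    cfg = config
    n_sizes = len(cfg.sample_sizes)
    recovered = {m: np.zeros((cfg.n_models, n_sizes), dtype=np.int64)
                 for m in cfg.measures}
    truths = []
    root = np.random.SeedSequence(cfg.seed)
    model_seeds = root.spawn(cfg.n_models)
    iterator = range(cfg.n_models)
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="benchmark models")
        except ImportError:  # pragma: no cover
            pass
    for m_idx in iterator:
        ss_model, *ss_data = model_seeds[m_idx].spawn(1 + n_sizes)
        model = random_model(cfg.d, cfg.n_main, cfg.n_pairs,
                             cfg.coeff_range[0], cfg.coeff_range[1],
                             cfg.p_grid, seed=ss_model)
        truth = tuple(s for s in model.interaction_subsets() if len(s) == 2)
        truths.append(truth)
        for s_idx, n in enumerate(cfg.sample_sizes):
            if cfg.mu == 0:
                data = sample_independent(model, n, seed=ss_data[s_idx])
            else:
                data = sample_dependent(model, n, cfg.mu, seed=ss_data[s_idx])
            scores = pairwise_scores(data.X, data.y, measures=cfg.measures)
            for meas in cfg.measures:
                top = scores.top_pairs(meas, cfg.top_k)
                recovered[meas][m_idx, s_idx] = len(set(top) & set(truth))
    return BenchmarkResult(cfg, recovered, truths)


@dataclass(frozen=True)
class MeasureComparison:
    measure_a: str
    measure_b: str
    sample_sizes: tuple[int, ...]
    accuracy_a: float
    accuracy_b: float
    difference_pp: float
    t_statistic: float
    p_value: float

    def __str__(self):
        return (f"{self.measure_a} vs {self.measure_b} over N={self.sample_sizes}: "
                f"{self.accuracy_a:.4f} vs {self.accuracy_b:.4f} "
                f"(diff {self.difference_pp:+.2f} pp, Welch t={self.t_statistic:.2f}, "
                f"p={self.p_value:.3g})")


def compare_measures(result: BenchmarkResult, measure_a: str, measure_b: str,
                     sample_sizes=None) -> MeasureComparison:
    """Welch two-sample t-test on per-model detection accuracies.

    Per-model per-sample-size accuracies are pooled across the selected
    sample sizes; the difference is reported in percentage points.
    """
    for m in (measure_a, measure_b):
        if m not in result.recovered:
            raise ValueError(f"measure {m!r} not in result (has {result.measures})")
    sizes = tuple(sample_sizes) if sample_sizes is not None else result.sample_sizes
    acc_a = result.per_model_accuracy(measure_a, sizes)
    acc_b = result.per_model_accuracy(measure_b, sizes)
    if measure_a == measure_b:
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_ind(acc_a, acc_b, equal_var=False)
    return MeasureComparison(
        measure_a, measure_b, sizes,
        float(acc_a.mean()), float(acc_b.mean()),
        float((acc_a.mean() - acc_b.mean()) * 100.0),
        float(t_stat), float(p_val))


@dataclass(frozen=True)
class LogLawFit:
    """Least-squares fit of N against log(1/error-rate)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def predict_n(self, error_rate: float) -> float:
        return self.intercept + self.slope * np.log(1.0 / error_rate)


def fit_log_law(result: BenchmarkResult, measure: str) -> LogLawFit:
    """Regress sample size on log(1/epsilon), epsilon the detection error rate.

    Sample sizes at which the error rate is exactly 0 or 1 carry no
    information about the law and are excluded with a warning.
    """
    acc = result.accuracy(measure)
    eps = 1.0 - acc
    ns = np.asarray(result.sample_sizes, dtype=float)
    keep = (eps > 0) & (eps < 1)
    if not keep.all():
        warnings.warn(
            f"excluding sample sizes {ns[~keep].astype(int).tolist()} with "
            "degenerate error rate (0 or 1) from the log-law fit")
    if keep.sum() < 3:
        raise ValueError("need at least 3 sample sizes with error rate in (0,1)")
    x = np.log(1.0 / eps[keep])
    if np.ptp(x) < 1e-12:  # error rate independent of N: flat law
        return LogLawFit(0.0, float(ns[keep].mean()), 0.0, int(keep.sum()))
    fit = stats.linregress(x, ns[keep])
    return LogLawFit(float(fit.slope), float(fit.intercept),
                     float(fit.rvalue ** 2), int(keep.sum()))


def plot_accuracy(result: BenchmarkResult, ax=None, measures=None):
    """Accuracy-versus-N curves, one line per measure."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for m in (measures or result.measures):
        ax.plot(result.sample_sizes, result.accuracy(m), marker="o", label=m)
    ax.set_xlabel("sample size N")
    ax.set_ylabel("detection accuracy")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    return ax
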