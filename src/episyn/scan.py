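"""Exhaustive pairwise interaction scan over SNPs, with enrichment testing.

:class:`SynergyScan` is the modelling object: build it from a binarized
genotype panel (or any +/-1 design matrix with an outcome), call
:meth:`SynergyScan.fit` to score every admissible SNP pair with a chosen
information measure, and get back a :class:`ScanResults` carrying the
ranked pair table, per-pair complete-case sample sizes, a ``summary()``
and Fisher's-exact enrichment against a reference pair list.

Pairs on the same chromosome closer than ``min_distance_bp`` are excluded
before ranking, the usual guard against ranking linkage-disequilibrium
neighbours as epistatic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import BinarizedGenotypes, GenotypePanel, binarize
from .measures import MEASURES, pairwise_scores
from .sampling import Dataset

__all__ = ["EnrichmentResult", "ScanResults", "SynergyScan", "enrichment_test",
           "pairwise_scan"]


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided hypergeometric (Fisher's exact) overlap test."""

    universe_size: int
    reference_size: int
    selected_size: int
    overlap: int
    p_value: float

    def __str__(self):
        return (f"enrichment: {self.overlap}/{self.selected_size} selected pairs "
                f"in reference ({self.reference_size} of {self.universe_size}); "
                f"one-sided p = {self.p_value:.4g}")


def enrichment_test(selected, reference, universe_size: int) -> EnrichmentResult:
    """Upper-tail hypergeometric p-value for the overlap of two pair sets.

    ``Pr(overlap >= observed)`` when ``selected_size`` items are drawn
    without replacement from a universe of ``universe_size`` containing
    ``reference_size`` marked items.
    """
    sel = {tuple(sorted(p)) for p in selected}
    ref = {tuple(sorted(p)) for p in reference}
    overlap = len(sel & ref)
    if universe_size < len(sel | ref):
        raise ValueError(
            f"universe_size={universe_size} smaller than |selected U reference|"
            f"={len(sel | ref)}")
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, len(ref), len(sel)))
    return EnrichmentResult(universe_size, len(ref), len(sel), overlap,
                            min(p, 1.0))


class SynergyScan:
    """Exhaustive pairwise interaction scan model.

    Parameters
    ----------
    X, y
        ``N x d`` matrix over {+1, -1} and length-``N`` outcome (+1 case,
        -1 control).
    valid
        Optional boolean mask of non-missing genotypes; pairs are scored
        by per-pair complete-case analysis.
    snp_ids, chrom, pos
        Optional marker metadata; required for distance filtering.
    """

    def __init__(self, X, y, valid=None, snp_ids=None, chrom=None, pos=None,
                 coding: str | None = None):
        X = np.asarray(X)
        self.y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be N x d with one outcome per row")
        if X.shape[1] < 2:
            raise ValueError("pairwise scan needs at least two SNPs")
        self.X = X
        self.valid = None if valid is None else np.asarray(valid, dtype=bool)
        d = X.shape[1]
        self.snp_ids = list(snp_ids) if snp_ids is not None else [f"X{i+1}" for i in range(d)]
        self.chrom = (np.asarray(chrom, dtype=object) if chrom is not None
                      else np.array(["0"] * d, dtype=object))
        self.pos = (np.asarray(pos, dtype=np.int64) if pos is not None
                    else np.zeros(d, dtype=np.int64))
        self.coding = coding

    @property
    def n_snps(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_panel(cls, panel: GenotypePanel, coding: str = "dominant") -> "SynergyScan":
        """Binarize a 0/1/2 genotype panel and build the scan model."""
        return cls.from_binarized(binarize(panel, coding))

    @classmethod
    def from_binarized(cls, b: BinarizedGenotypes) -> "SynergyScan":
        scan = cls(b.X, b.y, valid=b.valid, snp_ids=b.snp_ids,
                   chrom=b.chrom, pos=b.pos, coding=b.coding)
        scan.excluded = list(b.excluded)
        return scan

    @classmethod
    def from_dataset(cls, data: Dataset, **meta) -> "SynergyScan":
        return cls(data.X, data.y, **meta)

    def _allowed_mask(self, min_distance_bp: int) -> np.ndarray:
        d = self.n_snps
        allowed = ~np.eye(d, dtype=bool)
        if min_distance_bp > 0:
            same_chrom = self.chrom[:, None] == self.chrom[None, :]
            close = np.abs(self.pos[:, None] - self.pos[None, :]) < min_distance_bp
            allowed &= ~(same_chrom & close)
        return allowed

    def fit(self, measure: str = "adjusted_synergy",
            min_distance_bp: int = 0) -> "ScanResults":
        """Score every admissible pair and rank descending.

        Retained pairs lie on different chromosomes or at least
        ``min_distance_bp`` apart; ties in the measure value are broken by
        lexicographic SNP order for determinism.
        """
        if measure not in MEASURES:
            raise ValueError(f"unknown measure {measure!r}; valid: {MEASURES}")
        scores = pairwise_scores(self.X, self.y, valid=self.valid,
                                 measures=(measure,))
        allowed = self._allowed_mask(min_distance_bp)
        ranked = scores.ranked(measure, allowed=allowed)
        rows = [
            (self.snp_ids[i], self.snp_ids[j], measure, s.value, s.n,
             self.chrom[i], int(self.pos[i]), self.chrom[j], int(self.pos[j]))
            for s in ranked for i, j in [s.subset]
        ]
        table = pd.DataFrame(rows, columns=[
            "snp_a", "snp_b", "measure", "value", "n_complete",
            "chrom_a", "pos_a", "chrom_b", "pos_b"])
        return ScanResults(self, measure, min_distance_bp, table)


class ScanResults:
    """Ranked pair table from a :class:`SynergyScan` fit."""

    def __init__(self, model: SynergyScan, measure: str, min_distance_bp: int,
                 table: pd.DataFrame):
        self.model = model
        self.measure = measure
        self.min_distance_bp = min_distance_bp
        self.table = table
        if table.empty:
            import warnings
            warnings.warn("distance filter removed every pair; empty scan result")

    @property
    def n_pairs(self) -> int:
        """Number of pairs scored (the default enrichment universe)."""
        return len(self.table)

    def top(self, k: int) -> pd.DataFrame:
        return self.table.head(k)

    def top_pairs(self, k: int) -> list[tuple[str, str]]:
        return [tuple(sorted((a, b)))
                for a, b in zip(self.table["snp_a"].head(k),
                                self.table["snp_b"].head(k))]

    def enrichment(self, reference_pairs, top_k: int,
                   universe_size: int | None = None) -> EnrichmentResult:
        """Fisher's exact enrichment of the top-``k`` pairs in a reference list.

        The universe defaults to all pairs that passed the distance filter;
        pass ``universe_size`` explicitly to use a different convention.
        """
        universe = self.n_pairs if universe_size is None else universe_size
        return enrichment_test(self.top_pairs(top_k),
                               [tuple(sorted(p)) for p in reference_pairs],
                               universe)

    def summary(self, k: int = 15) -> str:
        coding = self.model.coding or "as-given"
        head = [
            f"Pairwise interaction scan: {self.model.n_snps} SNPs, "
            f"{self.n_pairs} pairs scored",
            f"measure: {self.measure} (nats-based); coding: {coding}; "
            f"min distance: {self.min_distance_bp} bp",
            f"top {min(k, self.n_pairs)} pairs:",
            self.top(k).to_string(index=False,
                                  float_format=lambda v: f"{v:.7f}"),
        ]
        return "\n".join(head)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def pairwise_scan(data, snp_ids=None, chrom=None, pos=None,
                  measure: str = "adjusted_synergy",
                  min_distance_bp: int = 0, valid=None) -> pd.DataFrame:
    """Functional wrapper: scan a +/-1 dataset and return the ranked table."""
    if isinstance(data, Dataset):
        X, y = data.X, data.y
    else:
        X, y = data
    scan = SynergyScan(X, y, valid=valid, snp_ids=snp_ids, chrom=chrom, pos=pos)
    return scan.fit(measure=measure, min_distance_bp=min_distance_bp).table
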