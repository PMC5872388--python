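"""Genotype panels: loading, orientation, and binarization.

A :class:`GenotypePanel` holds a sample x SNP matrix of allele counts
(0/1/2, ``-1`` for missing), per-SNP chromosome/position metadata, and a
case/control phenotype.  Two on-disk formats are supported:

* a CSV dialect with header ``sample_id, phenotype, <snp ids...>``;
  genotypes are 0/1/2 with ``NA`` for missing, phenotype is 1 for cases
  and 0 for controls;
* PLINK bed/bim/fam triplets (SNP-major bed).  No PLINK reader library is
  assumed; the 2-bit codec is implemented here and round-trip tested
  against its own writer.

The interaction measures operate on binary +/-1 variables, while SNP
genotypes are ternary, so a coding step is required.  Three codings are
provided, all with respect to the minor allele (orientation is flipped
when the stored allele count has frequency above 1/2):

``dominant``
    carriers of the minor allele (1 or 2 copies) -> +1, else -1;
``recessive``
    minor-allele homozygotes (2 copies) -> +1, else -1;
``genotype-major``
    the most frequent genotype value -> -1, everything else -> +1
    (ties broken toward the smaller genotype value).

SNPs that become constant under the chosen coding are excluded and listed
in the report.  Missing genotypes are retained as a validity mask for
per-pair complete-case analysis downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sampling import Dataset

__all__ = ["BinarizedGenotypes", "GenotypePanel", "GenotypeFormatError",
           "binarize", "load_genotypes", "CODINGS"]

MISSING = -1
CODINGS = ("dominant", "recessive", "genotype-major")


class GenotypeFormatError(ValueError):
    """Malformed genotype file (bad code, dimension mismatch, ...)."""


@dataclass
class GenotypePanel:
    """SNP metadata plus a genotype matrix in {0, 1, 2, missing}."""

    snp_ids: list[str]
    chrom: np.ndarray  # per-SNP chromosome label (string)
    pos: np.ndarray    # per-SNP 1-based base-pair position
    genotypes: np.ndarray  # n_samples x n_snps, int8, MISSING = -1
    phenotype: np.ndarray  # per-sample, +1 case / -1 control
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.snp_ids = list(self.snp_ids)
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise GenotypeFormatError("duplicate SNP ids in panel")
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if np.any(self.pos < 0):
            raise GenotypeFormatError("negative base-pair position")
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.ndim != 2 or g.shape[1] != len(self.snp_ids):
            raise GenotypeFormatError(
                f"genotype matrix shape {g.shape} inconsistent with "
                f"{len(self.snp_ids)} SNPs")
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            s, m = np.argwhere(bad)[0]
            raise GenotypeFormatError(
                f"invalid genotype code {int(np.asarray(self.genotypes)[s, m])} "
                f"at sample {s}, SNP {self.snp_ids[m]!r} (expected 0/1/2/NA)")
        self.genotypes = g
        y = np.asarray(self.phenotype, dtype=np.int8)
        if y.shape != (g.shape[0],) or not np.isin(y, (-1, 1)).all():
            raise GenotypeFormatError("phenotype must be +/-1 per sample")
        self.phenotype = y
        if not self.sample_ids:
            self.sample_ids = [f"S{i+1}" for i in range(g.shape[0])]
        if len(self.chrom) != len(self.snp_ids) or len(self.pos) != len(self.snp_ids):
            raise GenotypeFormatError("chrom/pos length mismatch with snp_ids")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def missing_rate(self) -> np.ndarray:
        """Per-SNP fraction of missing genotypes."""
        return (self.genotypes == MISSING).mean(axis=0)

    # -- CSV dialect -----------------------------------------------------

    @classmethod
    def from_csv(cls, path, chrom=None, pos=None) -> "GenotypePanel":
        """Read the CSV dialect (header: sample_id, phenotype, SNP ids).

        Chromosome/position metadata is not part of the CSV; pass it
        explicitly or accept placeholders (chromosome "0", positions 0),
        which disable distance-based filtering.
        """
        df = pd.read_csv(path, dtype={0: str})
        if df.shape[1] < 3 or list(df.columns[:2]) != ["sample_id", "phenotype"]:
            raise GenotypeFormatError(
                f"{path}: CSV header must start with sample_id, phenotype")
        snp_ids = list(df.columns[2:])
        g = np.full((len(df), len(snp_ids)), MISSING, dtype=np.int8)
        for c, name in enumerate(snp_ids):
            col = df[name]
            num = pd.to_numeric(col.replace("NA", np.nan), errors="coerce")
            bad = (num.notna() & ~num.isin((0, 1, 2))) | (num.isna() & col.notna())
            if bad.any():
                r = int(np.argmax(bad.to_numpy()))
                raise GenotypeFormatError(
                    f"{path}: invalid genotype {col.iloc[r]!r} at row {r + 2}, "
                    f"column {name!r}")
            obs = num.notna().to_numpy()
            g[obs, c] = num.to_numpy()[obs].astype(np.int8)
        phen_raw = df["phenotype"].to_numpy()
        if not np.isin(phen_raw, (0, 1)).all():
            raise GenotypeFormatError(f"{path}: phenotype must be 0 (control) or 1 (case)")
        y = np.where(phen_raw == 1, 1, -1).astype(np.int8)
        n = len(snp_ids)
        return cls(snp_ids,
                   chrom if chrom is not None else np.array(["0"] * n, dtype=object),
                   pos if pos is not None else np.zeros(n, dtype=np.int64),
                   g, y, sample_ids=list(df["sample_id"].astype(str)))

    def to_csv(self, path) -> None:
        out = pd.DataFrame(self.genotypes.astype(object), columns=self.snp_ids)
        out[self.genotypes == MISSING] = "NA"
        out.insert(0, "phenotype", np.where(self.phenotype == 1, 1, 0))
        out.insert(0, "sample_id", self.sample_ids)
        out.to_csv(path, index=False)

    # -- PLINK bed/bim/fam ----------------------------------------------

    @classmethod
    def from_plink(cls, prefix) -> "GenotypePanel":
        """Read a SNP-major PLINK bed/bim/fam triplet."""
        prefix = Path(prefix)
        bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                          names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                          dtype={"chrom": str, "snp": str})
        fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                          names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                          dtype={"fid": str, "iid": str})
        n_samples, n_snps = len(fam), len(bim)
        raw = Path(prefix.with_suffix(".bed")).read_bytes()
        if raw[:3] != b"\x6c\x1b\x01":
            raise GenotypeFormatError(
                f"{prefix}.bed: bad magic/mode bytes {raw[:3]!r} "
                "(expected SNP-major bed)")
        bytes_per_snp = (n_samples + 3) // 4
        body = np.frombuffer(raw[3:], dtype=np.uint8)
        if body.size != bytes_per_snp * n_snps:
            raise GenotypeFormatError(
                f"{prefix}.bed: {body.size} payload bytes, expected "
                f"{bytes_per_snp * n_snps} for {n_samples} samples x {n_snps} SNPs")
        blocks = body.reshape(n_snps, bytes_per_snp)
        shifts = np.arange(4) * 2
        codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
        codes = codes.reshape(n_snps, -1)[:, :n_samples]
        # 2-bit code -> count of A1 allele: 00->2, 10->1, 11->0, 01->missing
        lut = np.array([2, MISSING, 1, 0], dtype=np.int8)
        g = lut[codes].T  # samples x snps
        pheno = fam["pheno"].to_numpy(dtype=int)
        if not np.isin(pheno, (1, 2)).all():
            raise GenotypeFormatError(
                f"{prefix}.fam: phenotype must be 1 (control) or 2 (case)")
        y = np.where(pheno == 2, 1, -1).astype(np.int8)
        return cls(list(bim["snp"]), bim["chrom"].to_numpy(dtype=object),
                   bim["pos"].to_numpy(dtype=np.int64), g, y,
                   sample_ids=list(fam["iid"]))

    def to_plink(self, prefix) -> None:
        """Write a SNP-major bed/bim/fam triplet (alleles labelled A/B)."""
        prefix = Path(prefix)
        n = self.n_samples
        inv = np.empty(4, dtype=np.uint8)  # allele count -> 2-bit code
        inv[[2, 1, 0]] = [0b00, 0b10, 0b11]
        codes = np.where(self.genotypes.T == MISSING, 0b01,
                         inv[np.clip(self.genotypes.T, 0, 2)]).astype(np.uint8)
        pad = (-n) % 4
        if pad:
            codes = np.concatenate(
                [codes, np.zeros((self.n_snps, pad), dtype=np.uint8)], axis=1)
        codes = codes.reshape(self.n_snps, -1, 4)
        packed = (codes << (np.arange(4) * 2)).sum(axis=2).astype(np.uint8)
        prefix.with_suffix(".bed").write_bytes(b"\x6c\x1b\x01" + packed.tobytes())
        bim = pd.DataFrame({"chrom": self.chrom, "snp": self.snp_ids, "cm": 0,
                            "pos": self.pos, "a1": "A", "a2": "B"})
        bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
        fam = pd.DataFrame({"fid": self.sample_ids, "iid": self.sample_ids,
                            "pat": 0, "mat": 0, "sex": 0,
                            "pheno": np.where(self.phenotype == 1, 2, 1)})
        fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def load_genotypes(path, format: str = "csv") -> GenotypePanel:
    """Load a genotype panel from ``csv`` or ``plink`` input."""
    if format == "csv":
        return GenotypePanel.from_csv(path)
    if format == "plink":
        return GenotypePanel.from_plink(path)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'plink'")


@dataclass
class BinarizedGenotypes:
    """A +/-1 coded view of a panel with a validity mask for missing calls."""

    X: np.ndarray          # n_samples x n_kept, int8 in {+1,-1} (junk where invalid)
    valid: np.ndarray      # boolean mask, False where the genotype was missing
    y: np.ndarray          # +/-1 phenotype
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    coding: str
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (snp id, reason)
    flipped: list[str] = field(default_factory=list)  # SNPs re-oriented to minor allele

    @property
    def n_snps(self) -> int:
        return self.X.shape[1]

    def to_dataset(self) -> Dataset:
        """Complete-data view; refuses if any genotype is missing."""
        if not self.valid.all():
            raise ValueError(
                "panel has missing genotypes; use per-pair complete-case "
                "analysis (the scan does this) instead of a dense Dataset")
        return Dataset(self.X, self.y)


def binarize(panel: GenotypePanel, coding: str = "dominant") -> BinarizedGenotypes:
    """Code a 0/1/2 genotype panel to +/-1 covariates.

    Counts are first oriented to the minor allele (frequency computed over
    non-missing calls; exact 50/50 ties keep the stored orientation).
    Monomorphic-after-coding SNPs are excluded with a reason.
    """
    if coding not in CODINGS:
        raise ValueError(f"unknown coding {coding!r}; valid: {CODINGS}")
    g = panel.genotypes
    obs = g != MISSING
    flipped: list[str] = []
    g = g.copy()
    for m in range(panel.n_snps):
        col = g[obs[:, m], m]
        if col.size and col.mean() > 1.0:  # counted-allele frequency > 1/2
            g[obs[:, m], m] = 2 - col
            flipped.append(panel.snp_ids[m])

    X = np.empty_like(g)
    if coding == "dominant":
        X = np.where(g >= 1, 1, -1)
    elif coding == "recessive":
        X = np.where(g == 2, 1, -1)
    else:  # genotype-major
        X = np.empty(g.shape, dtype=np.int8)
        for m in range(panel.n_snps):
            col = g[:, m]
            vals, counts = np.unique(col[obs[:, m]], return_counts=True)
            if vals.size == 0:
                X[:, m] = -1
                continue
            major = vals[np.argmax(counts)]  # np.argmax: first max -> smaller value
            X[:, m] = np.where(col == major, -1, 1)
    X = X.astype(np.int8)

    keep, excluded = [], []
    for m in range(panel.n_snps):
        col = X[obs[:, m], m]
        if col.size == 0:
            excluded.append((panel.snp_ids[m], "all genotypes missing"))
        elif (col == col[0]).all():
            excluded.append((panel.snp_ids[m],
                             f"monomorphic under {coding} coding"))
        else:
            keep.append(m)
    keep = np.array(keep, dtype=int)
    return BinarizedGenotypes(
        X=X[:, keep], valid=obs[:, keep], y=panel.phenotype.copy(),
        snp_ids=[panel.snp_ids[m] for m in keep],
        chrom=panel.chrom[keep], pos=panel.pos[keep],
        coding=coding, excluded=excluded, flipped=flipped)
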