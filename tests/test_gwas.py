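"""Genotype loading, binarization, pairwise scan, enrichment testing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from episyn import (GenotypePanel, InteractionModel, SynergyScan, binarize,
                    enrichment_test, load_genotypes, pairwise_scan,
                    sample_independent)
from episyn.genotypes import GenotypeFormatError


def make_panel(genotypes, phenotype=None, chrom=None, pos=None):
    g = np.asarray(genotypes)
    n_snps = g.shape[1]
    if phenotype is None:
        phenotype = np.resize([1, -1], g.shape[0])
    return GenotypePanel(
        snp_ids=[f"rs{i+1}" for i in range(n_snps)],
        chrom=chrom if chrom is not None else ["1"] * n_snps,
        pos=pos if pos is not None else (np.arange(n_snps) + 1) * 10 ** 7,
        genotypes=g, phenotype=phenotype)


class TestLoading:
    def test_csv_round_trip(self, tmp_path):
        panel = make_panel([[0, 1], [2, -1], [1, 0]])
        path = tmp_path / "panel.csv"
        panel.to_csv(path)
        back = load_genotypes(path, format="csv")
        assert back.snp_ids == panel.snp_ids
        assert np.array_equal(back.genotypes, panel.genotypes)
        assert np.array_equal(back.phenotype, panel.phenotype)
        assert back.genotypes.shape == (3, 2)

    def test_csv_bad_code_reports_location(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,phenotype,rs1,rs2\nA,1,0,3\nB,0,1,2\n")
        with pytest.raises(GenotypeFormatError, match="rs2"):
            load_genotypes(path, format="csv")

    def test_plink_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(17, 5)).astype(np.int8)
        g[rng.random(g.shape) < 0.1] = -1  # missing
        panel = make_panel(g, chrom=["1", "1", "2", "6", "X"],
                           pos=[100, 2_000_000, 5, 7, 9])
        panel.to_plink(tmp_path / "fix")
        back = load_genotypes(tmp_path / "fix", format="plink")
        assert np.array_equal(back.genotypes, panel.genotypes)
        assert np.array_equal(back.phenotype, panel.phenotype)
        assert list(back.chrom) == list(panel.chrom)
        assert np.array_equal(back.pos, panel.pos)

    def test_plink_bad_magic(self, tmp_path):
        panel = make_panel([[0, 1], [1, 2]])
        panel.to_plink(tmp_path / "fix")
        bed = tmp_path / "fix.bed"
        bed.write_bytes(b"\x00\x00\x00" + bed.read_bytes()[3:])
        with pytest.raises(GenotypeFormatError, match="magic"):
            load_genotypes(tmp_path / "fix", format="plink")

    def test_invalid_code_in_matrix(self):
        with pytest.raises(GenotypeFormatError, match="rs2"):
            make_panel([[0, 3], [1, 2]])

    def test_missing_rate(self):
        panel = make_panel([[0, -1], [1, -1], [2, 0], [0, 1]])
        assert np.allclose(panel.missing_rate(), [0.0, 0.5])


class TestBinarize:
    def test_dominant_coding(self):
        panel = make_panel([[0], [1], [2], [1]])
        b = binarize(panel, "dominant")
        assert np.array_equal(b.X[:, 0], [-1, 1, 1, 1])

    def test_recessive_coding(self):
        panel = make_panel([[0], [1], [2], [1]])
        b = binarize(panel, "recessive")
        assert np.array_equal(b.X[:, 0], [-1, -1, 1, -1])

    def test_genotype_major_tie_break(self):
        # 2 zeros, 2 ones: tie broken toward the smaller genotype as major
        panel = make_panel([[0], [0], [1], [1]])
        b = binarize(panel, "genotype-major")
        assert np.array_equal(b.X[:, 0], [-1, -1, 1, 1])

    def test_minor_allele_orientation(self):
        # counted allele frequency 0.75 -> flipped so counts are minor-allele
        panel = make_panel([[2], [2], [1], [1]])
        b = binarize(panel, "dominant")
        assert b.flipped == ["rs1"]
        # after flip genotypes are 0,0,1,1 -> dominant -1,-1,1,1
        assert np.array_equal(b.X[:, 0], [-1, -1, 1, 1])

    def test_monomorphic_excluded_with_reason(self):
        panel = make_panel([[0, 1], [0, 2], [0, 1], [0, 0]])
        b = binarize(panel, "dominant")
        assert b.snp_ids == ["rs2"]
        assert b.excluded[0][0] == "rs1" and "monomorphic" in b.excluded[0][1]

    def test_missing_kept_as_mask(self):
        panel = make_panel([[0, 1], [-1, 2], [1, 0], [2, 1]])
        b = binarize(panel, "dominant")
        assert not b.valid[1, 0] and b.valid[1, 1]
        with pytest.raises(ValueError, match="missing"):
            b.to_dataset()

    def test_unknown_coding(self):
        with pytest.raises(ValueError):
            binarize(make_panel([[0], [1]]), "codominant")


class TestPairwiseScan:
    def test_pair_universe_size_73_snps(self):
        """73 SNPs with no distance filter yield C(73,2) = 2628 scored pairs."""
        rng = np.random.default_rng(1)
        X = rng.choice([-1, 1], size=(60, 73))
        y = rng.choice([-1, 1], size=60)
        table = pairwise_scan((X, y), measure="synergy")
        assert len(table) == comb(73, 2, exact=True) == 2628

    def test_distance_filter(self):
        X = np.resize([-1, 1, 1, -1], (40, 3))
        rng = np.random.default_rng(2)
        X = rng.choice([-1, 1], size=(40, 3))
        y = rng.choice([-1, 1], size=40)
        scan = SynergyScan(X, y, snp_ids=["a", "b", "c"],
                           chrom=["1", "1", "2"],
                           pos=[1_000_000, 1_500_000, 1_200_000])
        res = scan.fit(measure="synergy", min_distance_bp=1_000_000)
        kept = {tuple(sorted(p)) for p in zip(res.table.snp_a, res.table.snp_b)}
        # a-b are 500 kb apart on chr1 -> excluded; cross-chromosome pairs kept
        assert kept == {("a", "c"), ("b", "c")}

    def test_filter_removing_all_pairs_warns(self):
        rng = np.random.default_rng(3)
        X = rng.choice([-1, 1], size=(30, 2))
        y = rng.choice([-1, 1], size=30)
        scan = SynergyScan(X, y, chrom=["1", "1"], pos=[100, 200])
        with pytest.warns(UserWarning, match="empty"):
            res = scan.fit(min_distance_bp=10 ** 6)
        assert res.n_pairs == 0

    def test_planted_interaction_recovered_from_genotypes(self):
        """Genotypes carrying a planted pair interaction in the dominant
        +/-1 coding put that pair first in the ranked scan."""
        model = InteractionModel(d=12, beta={(3, 7): 2.0},
                                 p=np.full(12, 0.4))
        data = sample_independent(model, 3000, seed=21)
        # map +/-1 -> genotypes: +1 -> carrier (1 or 2 copies), -1 -> 0
        rng = np.random.default_rng(22)
        g = np.where(data.X == 1, rng.integers(1, 3, size=data.X.shape), 0)
        panel = make_panel(g.astype(np.int8), phenotype=data.y,
                           chrom=["%d" % (i + 1) for i in range(12)],
                           pos=[1000] * 12)
        scan = SynergyScan.from_panel(panel, coding="dominant")
        res = scan.fit(measure="adjusted_synergy")
        assert res.top_pairs(1) == [("rs4", "rs8")]
        assert res.table.iloc[0].n_complete == 3000

    def test_per_pair_complete_case_counts(self):
        g = np.array([[0, 1, 2], [1, -1, 0], [2, 1, -1], [0, 0, 1],
                      [1, 2, 0], [2, 0, 1]], dtype=np.int8)
        panel = make_panel(g)
        res = SynergyScan.from_panel(panel).fit(measure="synergy")
        row = res.table[(res.table.snp_a == "rs2") & (res.table.snp_b == "rs3")]
        assert int(row.n_complete.iloc[0]) == 4  # rows 1 and 2 dropped

    def test_column_order_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.choice([-1, 1], size=(300, 6))
        y = rng.choice([-1, 1], size=300)
        ids = [f"rs{i}" for i in range(6)]
        t1 = pairwise_scan((X, y), snp_ids=ids, measure="synergy")
        perm = [3, 1, 5, 0, 2, 4]
        t2 = pairwise_scan((X[:, perm], y), snp_ids=[ids[i] for i in perm],
                           measure="synergy")
        key = lambda t: {tuple(sorted((a, b))): v
                         for a, b, v in zip(t.snp_a, t.snp_b, t.value)}
        k1, k2 = key(t1), key(t2)
        assert k1.keys() == k2.keys()
        assert all(np.isclose(k1[p], k2[p]) for p in k1)

    def test_summary_mentions_measure_and_coding(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, size=(50, 4)).astype(np.int8)
        res = SynergyScan.from_panel(make_panel(g), coding="recessive").fit()
        text = res.summary(k=3)
        assert "adjusted_synergy" in text and "recessive" in text


class TestEnrichment:
    def test_exhaustive_hypergeometric_enumeration(self):
        """Upper-tail p-value matches brute-force enumeration of all
        selections, for every universe size up to 30."""
        rng = np.random.default_rng(6)
        for universe in (5, 11, 18, 30):
            items = [(i, i + 100) for i in range(universe)]
            n_ref = int(rng.integers(1, universe + 1))
            n_sel = int(rng.integers(1, universe + 1))
            reference = items[:n_ref]
            selected = list(rng.choice(universe, size=n_sel, replace=False))
            selected = [items[i] for i in selected]
            res = enrichment_test(selected, reference, universe)
            # enumeration oracle: sum hypergeometric point masses >= overlap
            total = comb(universe, n_sel, exact=True)
            p_exact = sum(
                comb(n_ref, o, exact=True)
                * comb(universe - n_ref, n_sel - o, exact=True)
                for o in range(res.overlap, min(n_ref, n_sel) + 1)) / total
            assert res.p_value == pytest.approx(p_exact, abs=1e-12)

    def test_small_worked_example(self):
        # universe 10, reference 4, selected 3, overlap 3 -> C(4,3)/C(10,3)
        ref = [(1, 2), (3, 4), (5, 6), (7, 8)]
        sel = [(1, 2), (3, 4), (5, 6)]
        res = enrichment_test(sel, ref, 10)
        assert res.p_value == pytest.approx(4 / 120, abs=1e-12)

    def test_degenerate_certainty(self):
        items = [(i, i + 1000) for i in range(6)]
        res = enrichment_test(items, items, 6)
        assert res.p_value == pytest.approx(1.0)

    def test_unordered_pair_matching(self):
        res = enrichment_test([("b", "a")], [("a", "b")], 10)
        assert res.overlap == 1

    def test_inconsistent_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            enrichment_test([(1, 2), (3, 4)], [(5, 6)], 2)

    def test_scan_results_enrichment_uses_scored_pairs_as_universe(self):
        rng = np.random.default_rng(7)
        X = rng.choice([-1, 1], size=(100, 6))
        y = rng.choice([-1, 1], size=100)
        res = SynergyScan(X, y).fit(measure="synergy")
        ref = res.top_pairs(2)
        enr = res.enrichment(ref, top_k=2)
        assert enr.universe_size == 15 and enr.overlap == 2
        assert enr.p_value == pytest.approx(1 / comb(15, 2, exact=True))
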