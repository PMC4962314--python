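"""LD computation, surrogate expansion and index-SNP filtering."""

import logging

import numpy as np
import pytest

from chromenrich.errors import DataIntegrityError, MonomorphicVariantError
from chromenrich.synthetic import gen_haplotypes_with_r2
from chromenrich.variants import (
    VariantRecord,
    compute_r2,
    expand_index,
    filter_index_snps,
    read_vcf,
)

from conftest import make_panel, write_vcf


class TestComputeR2:
    def test_worked_example(self):
        # 10 haplotypes: (1,1)x4, (1,0)x1, (0,1)x1, (0,0)x4
        x = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        y = np.array([1, 1, 1, 1, 0, 1, 0, 0, 0, 0])
        assert compute_r2(x, y) == pytest.approx(0.36, abs=1e-12)

    def test_self_ld_is_one(self):
        x = np.array([0, 1, 1, 0, 1])
        assert compute_r2(x, x) == pytest.approx(1.0, abs=1e-15)

    def test_independent_vectors(self):
        # 25 haplotypes in each of the four cells: D = 0
        x = np.repeat([0, 0, 1, 1], 25)
        y = np.repeat([0, 1, 0, 1], 25)
        assert compute_r2(x, y) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        x = (rng.random(40) < 0.4).astype(int)
        y = (rng.random(40) < 0.6).astype(int)
        assert compute_r2(x, y) == pytest.approx(compute_r2(y, x), abs=0)

    def test_matches_squared_pearson(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(4, 100))
            x = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int)
            y = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int)
            if x.min() == x.max() or y.min() == y.max():
                continue
            expected = float(np.corrcoef(x, y)[0, 1]) ** 2
            assert compute_r2(x, y) == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_raises(self):
        with pytest.raises(MonomorphicVariantError):
            compute_r2(np.zeros(10, dtype=int), np.array([0, 1] * 5))


class TestExpandIndex:
    def _panel_with_surrogate(self, r2_target=0.95, surrogate_pos=600_000):
        x, y = gen_haplotypes_with_r2(0.3, 0.3, r2_target, n_hap=2000, seed=5)
        rng = np.random.default_rng(9)
        noise = (rng.random(2000) < 0.4).astype(np.int8)
        return make_panel(
            {"rsIDX": x, "rsSUR": y, "rsBG": noise},
            {"rsIDX": 500_000, "rsSUR": surrogate_pos, "rsBG": 400_000},
        )

    def test_planted_surrogate_recovered(self):
        panel = self._panel_with_surrogate()
        index = next(v for v in panel.variants if v.rsid == "rsIDX")
        ss = expand_index(index, panel)
        assert "rsSUR" in ss.rsids
        # brute-force all-pairs check: membership iff r^2 >= 0.8 in window
        x = panel.column("rsIDX")
        for v in panel.variants:
            r2 = compute_r2(x, panel.column(v.rsid))
            assert (v.rsid in ss.rsids) == (r2 >= 0.8)

    def test_index_always_member_with_r2_one(self):
        panel = self._panel_with_surrogate()
        index = next(v for v in panel.variants if v.rsid == "rsIDX")
        ss = expand_index(index, panel)
        assert dict((v.rsid, r2) for v, r2 in ss.members)["rsIDX"] == 1.0
        assert len(ss) >= 1

    def test_surrogate_outside_window_excluded(self):
        panel = self._panel_with_surrogate(surrogate_pos=1_500_000)
        index = next(v for v in panel.variants if v.rsid == "rsIDX")
        ss = expand_index(index, panel)
        assert "rsSUR" not in ss.rsids

    def test_no_variant_reaches_threshold(self):
        rng = np.random.default_rng(3)
        cols = {
            "rsIDX": (rng.random(500) < 0.3).astype(np.int8),
            "rsA": (rng.random(500) < 0.3).astype(np.int8),
        }
        panel = make_panel(cols, {"rsIDX": 500_000, "rsA": 500_100})
        index = next(v for v in panel.variants if v.rsid == "rsIDX")
        ss = expand_index(index, panel)
        assert ss.rsids == {"rsIDX"}

    def test_invariant_to_variant_order(self):
        panel = self._panel_with_surrogate()
        reversed_panel = make_panel(
            {r: panel.column(r) for r in ["rsBG", "rsSUR", "rsIDX"]},
            {v.rsid: v.pos for v in panel.variants},
        )
        index = next(v for v in panel.variants if v.rsid == "rsIDX")
        a = expand_index(index, panel)
        b = expand_index(index, reversed_panel)
        assert [(v.rsid, r2) for v, r2 in a.members] == [(v.rsid, r2) for v, r2 in b.members]

    def test_absent_index_raises(self):
        panel = self._panel_with_surrogate()
        ghost = VariantRecord(rsid="rsGHOST", chrom="chr1", pos=10, ref="A", alt="C")
        with pytest.raises(KeyError):
            expand_index(ghost, panel)


class TestFilterIndexSnps:
    def _indices(self, n):
        return [
            VariantRecord(rsid=f"rs{i}", chrom="chr1", pos=100 + i, ref="A", alt="G")
            for i in range(n)
        ]

    def test_26_minus_5_leaves_21(self):
        indices = self._indices(26)
        exclusions = [("rs0", "assembly exception")] + [
            (f"rs{i}", "no SNPs with r^2 >= 0.8") for i in range(1, 5)
        ]
        assert len(filter_index_snps(indices, exclusions)) == 21

    def test_empty_exclusions_identity(self):
        indices = self._indices(5)
        assert filter_index_snps(indices, []) == indices

    def test_absent_rsid_warns_not_errors(self, caplog):
        indices = self._indices(3)
        with caplog.at_level(logging.WARNING):
            out = filter_index_snps(indices, [("rsNOPE", "whatever")])
        assert out == indices
        assert any("rsNOPE" in rec.message for rec in caplog.records)


class TestReadVcf:
    def test_biallelic_snps_and_matrix_shape(self, tmp_path):
        rows = [
            "chr1\t100\trsA\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0\t0|1",
            "chr1\t150\trsB\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1\t1|0\t0|0",
            "chr1\t200\trsC\tG\tA\t.\tPASS\t.\tGT\t1|1\t0|0\t0|1\t1|0",
        ]
        variants, panel = read_vcf(write_vcf(tmp_path / "a.vcf", rows))
        assert [v.rsid for v in variants] == ["rsA", "rsB", "rsC"]
        assert panel.haplotypes.shape == (8, 3)
        assert list(panel.column("rsA")) == [0, 1, 1, 1, 0, 0, 0, 1]

    def test_multiallelic_and_indel_records_skipped(self, tmp_path):
        rows = [
            "chr1\t100\trsA\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0\t0|1",
            "chr1\t120\trsMULTI\tA\tG,T\t.\tPASS\t.\tGT\t0|1\t1|2\t0|0\t0|1",
            "chr1\t150\trsB\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1\t1|0\t0|0",
            "chr1\t170\trsINDEL\tCA\tC\t.\tPASS\t.\tGT\t0|0\t0|1\t1|0\t0|0",
            "chr1\t200\trsC\tG\tA\t.\tPASS\t.\tGT\t1|1\t0|0\t0|1\t1|0",
        ]
        variants, _ = read_vcf(write_vcf(tmp_path / "b.vcf", rows))
        assert [v.rsid for v in variants] == ["rsA", "rsB", "rsC"]

    def test_region_filter(self, tmp_path):
        rows = [
            "chr1\t100\trsA\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0\t0|1",
            "chr1\t150\trsB\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1\t1|0\t0|0",
            "chr1\t300\trsC\tG\tA\t.\tPASS\t.\tGT\t1|1\t0|0\t0|1\t1|0",
        ]
        path = write_vcf(tmp_path / "c.vcf", rows)
        variants, _ = read_vcf(path, region="chr1:100-200")
        assert [v.rsid for v in variants] == ["rsA", "rsB"]

    def test_unphased_genotype_rejected(self, tmp_path):
        rows = ["chr1\t100\trsA\tA\tG\t.\tPASS\t.\tGT\t0/1\t1|1\t0|0\t0|1"]
        with pytest.raises(DataIntegrityError, match="rsA"):
            read_vcf(write_vcf(tmp_path / "d.vcf", rows))

    def test_missing_genotype_rejected(self, tmp_path):
        rows = ["chr1\t100\trsA\tA\tG\t.\tPASS\t.\tGT\t.|.\t1|1\t0|0\t0|1"]
        with pytest.raises(DataIntegrityError, match="rsA"):
            read_vcf(write_vcf(tmp_path / "e.vcf", rows))
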