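"""Hypergeometric enrichment, BH adjustment and matrix assembly."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from chromenrich.enrichment import (
    ACTIVE_UNION,
    EnrichmentResult,
    adjust_results,
    bh_adjust,
    build_matrix,
    enrich,
    hypergeom_sf,
)
from chromenrich.errors import DataIntegrityError
from chromenrich.segmentation import SegmentationTrack
from chromenrich.variants import IndexLocus, SurrogateSet, VariantRecord


def hypergeom_sf_exact(k, N, K, n):
    """Exact PMF-tail enumeration with integer arithmetic."""
    total = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return Fraction(total, comb(N, n))


def bh_reference(p):
    """Independent BH step-up: q_i = min over j >= rank(i) of p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestHypergeomSf:
    def test_tail_from_zero_is_one(self):
        assert hypergeom_sf(0, 50, 10, 5) == 1.0

    def test_certain_event(self):
        assert hypergeom_sf(4, 10, 10, 4) == pytest.approx(1.0, abs=1e-12)

    def test_worked_example(self):
        # C(5,4) C(5,0) / C(10,4) = 5/210
        assert hypergeom_sf(4, 10, 5, 4) == pytest.approx(5 / 210, rel=1e-12)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            N = int(rng.integers(2, 60))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            expected = float(hypergeom_sf_exact(k, N, K, n))
            assert hypergeom_sf(k, N, K, n) == pytest.approx(expected, rel=1e-10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_sf(3, 10, 12, 4)
        with pytest.raises(ValueError):
            hypergeom_sf(5, 10, 5, 4)


class TestBhAdjust:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_matches_independent_reference(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 40)))
            assert bh_adjust(p) == pytest.approx(bh_reference(p), abs=1e-12)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(2)
        p = rng.random(30)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _locus_fixture(labels_by_pos, n_risk):
    """Background of len(labels_by_pos) SNPs; first n_risk are the risk set."""
    variants = [
        VariantRecord(rsid=f"s{i}", chrom="chr1", pos=pos, ref="A", alt="G")
        for i, pos in enumerate(sorted(labels_by_pos))
    ]
    index = variants[0]
    locus = IndexLocus(index=index, window_start=0, window_end=1_000_000)
    risk = SurrogateSet(locus=locus, members=[(v, 1.0) for v in variants[:n_risk]])
    segments = [
        ("chr1", pos - 1, pos, labels_by_pos[pos])
        for pos in sorted(labels_by_pos)
        if labels_by_pos[pos] != "NONE"
    ]
    track = SegmentationTrack("ct", segments)
    return locus, risk, variants, track


class TestEnrich:
    def test_no_risk_in_category_gives_p_one(self):
        labels = {100 + 10 * i: ("EAR" if i >= 5 else "NONE") for i in range(10)}
        locus, risk, background, track = _locus_fixture(labels, n_risk=3)
        res = enrich(locus, risk, background, track, "EAR")
        assert res.k == 0 and res.p == 1.0

    def test_counts_and_p_match_enumeration(self):
        # all 4 risk SNPs in EAR; 6 of 12 background in EAR
        labels = {100 + 10 * i: ("EAR" if i < 4 or i >= 10 else "NONE") for i in range(12)}
        locus, risk, background, track = _locus_fixture(labels, n_risk=4)
        res = enrich(locus, risk, background, track, "EAR")
        assert (res.k, res.n, res.K, res.N) == (4, 4, 6, 12)
        assert res.p == pytest.approx(float(hypergeom_sf_exact(4, 12, 6, 4)), rel=1e-10)

    def test_union_counts_each_snp_once(self):
        labels = {100: "EAR", 110: "PAR", 120: "EPR", 130: "NONE", 140: "EAR"}
        locus, risk, background, track = _locus_fixture(labels, n_risk=3)
        r_union = enrich(locus, risk, background, track, ACTIVE_UNION)
        r_ear = enrich(locus, risk, background, track, "EAR")
        r_par = enrich(locus, risk, background, track, "PAR")
        assert r_union.k == 2  # one EAR + one PAR among first three
        assert r_union.k >= max(r_ear.k, r_par.k)
        assert r_union.K == r_ear.K + r_par.K

    def test_risk_not_subset_of_background_rejected(self):
        labels = {100 + 10 * i: "EAR" for i in range(5)}
        locus, risk, background, track = _locus_fixture(labels, n_risk=3)
        with pytest.raises(DataIntegrityError):
            enrich(locus, risk, background[1:], track, "EAR")

    def test_p_invariant_to_relabeling_outside_category(self):
        labels = {100 + 10 * i: ("EAR" if i % 3 == 0 else "NONE") for i in range(15)}
        relabeled = {pos: ("PPR" if lab == "NONE" else lab) for pos, lab in labels.items()}
        p = []
        for lab in (labels, relabeled):
            locus, risk, background, track = _locus_fixture(lab, n_risk=5)
            p.append(enrich(locus, risk, background, track, "EAR").p)
        assert p[0] == p[1]


class TestAdjustAndMatrix:
    def _results(self):
        out = []
        for locus in ("L1", "L2", "L3"):
            for ct in ("ctA", "ctB"):
                p = 0.01 if (locus, ct) == ("L1", "ctA") else 0.5
                out.append(
                    EnrichmentResult(locus_id=locus, cell_type=ct, category="EAR",
                                     k=1, n=2, K=5, N=20, p=p)
                )
        return out

    def test_family_grouping(self):
        by_locus = adjust_results(self._results(), family="locus")
        r = next(x for x in by_locus if x.locus_id == "L1" and x.cell_type == "ctA")
        assert r.q == pytest.approx(0.02)  # m=2 within locus L1
        by_ct = adjust_results(self._results(), family="cell_type")
        r = next(x for x in by_ct if x.locus_id == "L1" and x.cell_type == "ctA")
        assert r.q == pytest.approx(0.03)  # m=3 within cell type ctA

    def test_matrix_assembly_and_scale(self):
        results = adjust_results(self._results(), family="locus")
        for r in results:
            r.q = math.exp(-14.0) if r.locus_id == "L1" and r.cell_type == "ctA" else 1.0
        m = build_matrix(results, category="EAR", scale="neg_ln_q")
        assert m.values.shape == (2, 3)
        assert m.values.loc["ctA", "L1"] == pytest.approx(14.0)
        assert m.values.loc["ctB", "L2"] == 0.0

    def test_duplicate_result_rejected(self):
        results = self._results()
        adjust_results(results)
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix(results + [results[0]], category="EAR")

    def test_q_never_below_p(self):
        results = adjust_results(self._results(), family="locus")
        assert all(r.q >= r.p - 1e-15 for r in results)
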