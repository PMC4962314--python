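"""PWM scoring, exact match p-values and allele-aware disruption calls."""

import math

import numpy as np
import pytest

from chromenrich.errors import DataIntegrityError
from chromenrich.motif import (
    PWM,
    break_snp,
    raw_score,
    read_jaspar,
    reverse_complement,
    score_pvalue,
    score_window,
    write_jaspar,
)
from chromenrich.variants import VariantRecord

JASPAR_TEXT = """\
>MA0001.1\tTFA
A  [ 10   0  80   5 ]
C  [ 20  90   5   5 ]
G  [ 50   5  10  85 ]
T  [ 20   5   5   5 ]
>MA0002.1\tTFB
A  [ 0  100  0  0  0 ]
C  [ 100  0  0  0  100 ]
G  [ 0  0  100  0  0 ]
T  [ 0  0  0  100  0 ]
>MA0003.1\tTFC
A  [ 25  25 ]
C  [ 25  25 ]
G  [ 25  25 ]
T  [ 25  25 ]
"""


class TestReadJaspar:
    def test_counts_become_probabilities(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(JASPAR_TEXT)
        pwms = read_jaspar(str(path))
        assert len(pwms) == 3
        assert pwms[0].width == 4
        assert np.allclose(pwms[0].probs.sum(axis=1), 1.0)
        assert pwms[0].motif_id == "MA0001.1" and pwms[0].tf_name == "TFA"

    def test_pseudocount_removes_zeros(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(JASPAR_TEXT)
        pwms = read_jaspar(str(path), pseudocount=0.8)
        assert (pwms[1].probs > 0).all()

    def test_round_trip_consensus(self, tmp_path, toy_pwm):
        path = tmp_path / "out.jaspar"
        write_jaspar([toy_pwm], str(path))
        (back,) = read_jaspar(str(path))
        assert back.consensus == toy_pwm.consensus


class TestScoreWindow:
    def test_consensus_scores_one(self, toy_pwm):
        assert score_window(toy_pwm, "ACGT") == pytest.approx(1.0)

    def test_anticonsensus_scores_zero(self, toy_pwm):
        # any non-consensus base is equally minimal (prob 0.1 everywhere)
        assert score_window(toy_pwm, "CAAA") == pytest.approx(0.0)

    def test_hand_summed_log_ratio(self):
        probs = np.array([[0.4, 0.3, 0.2, 0.1],
                          [0.1, 0.6, 0.2, 0.1],
                          [0.25, 0.25, 0.25, 0.25]])
        pwm = PWM(motif_id="W3", tf_name="W3", probs=probs)
        raw = math.log(0.4 / 0.25) + math.log(0.6 / 0.25) + math.log(0.25 / 0.25)
        lo = sum(math.log(r.min() / 0.25) for r in probs)
        hi = sum(math.log(r.max() / 0.25) for r in probs)
        assert raw_score(pwm, "ACG") == pytest.approx(raw, abs=1e-12)
        assert score_window(pwm, "ACG") == pytest.approx((raw - lo) / (hi - lo), abs=1e-12)

    def test_ambiguous_base_rejected(self, toy_pwm):
        with pytest.raises(ValueError, match="ambiguous"):
            score_window(toy_pwm, "ACGN")


def exhaustive_tail(pwm):
    """All 4^w window scores with their background probabilities."""
    scores = np.zeros(1)
    weights = np.ones(1)
    for j in range(pwm.width):
        lr = pwm.log_ratios[j]
        scores = (scores[:, None] + lr[None, :]).ravel()
        weights = (weights[:, None] * pwm.background[None, :]).ravel()
    return scores, weights


class TestScorePvalue:
    def test_at_or_below_minimum_is_one(self, toy_pwm):
        assert score_pvalue(toy_pwm, toy_pwm.min_raw) == 1.0
        assert score_pvalue(toy_pwm, toy_pwm.min_raw - 5.0) == 1.0

    def test_above_maximum_is_zero(self, toy_pwm):
        assert score_pvalue(toy_pwm, toy_pwm.max_raw + 1e-6) == 0.0

    def test_consensus_pvalue_is_its_background_mass(self, toy_pwm):
        # only the consensus attains the maximum score
        assert score_pvalue(toy_pwm, toy_pwm.max_raw) == pytest.approx(0.25 ** 4, rel=1e-9)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            w = int(rng.integers(4, 7))
            probs = rng.dirichlet(np.full(4, 0.5), size=w) + 1e-3
            probs /= probs.sum(axis=1, keepdims=True)
            pwm = PWM(motif_id="R", tf_name="R", probs=probs)
            scores, weights = exhaustive_tail(pwm)
            delta = 1e-3 * (pwm.max_raw - pwm.min_raw)
            margin = (w + 1) * delta
            for raw in rng.uniform(pwm.min_raw, pwm.max_raw, size=10):
                dp = score_pvalue(pwm, raw)
                upper = weights[scores >= raw - margin].sum()
                lower = weights[scores >= raw + margin].sum()
                assert lower - 1e-12 <= dp <= upper + 1e-12


class TestStrandSymmetry:
    def test_minus_strand_equals_revcomp_window(self, toy_pwm):
        rng = np.random.default_rng(6)
        bases = np.array(list("ACGT"))
        for _ in range(200):
            seq = "".join(rng.choice(bases, size=toy_pwm.width))
            assert raw_score(toy_pwm.reverse_complement(), seq) == pytest.approx(
                raw_score(toy_pwm, reverse_complement(seq)), abs=1e-12
            )

    def test_palindromic_pwm_equal_strand_scores(self):
        probs = np.array([[0.7, 0.1, 0.1, 0.1],
                          [0.1, 0.6, 0.2, 0.1],
                          [0.1, 0.2, 0.6, 0.1],
                          [0.1, 0.1, 0.1, 0.7]])
        pwm = PWM(motif_id="PAL", tf_name="PAL", probs=probs)
        assert np.allclose(pwm.reverse_complement().probs, pwm.probs)
        rng = np.random.default_rng(7)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=4))
            assert raw_score(pwm, seq) == pytest.approx(
                raw_score(pwm.reverse_complement(), seq), abs=1e-12
            )


def sharp_pwm(width=10, seed=0):
    rng = np.random.default_rng(seed)
    probs = np.full((width, 4), 0.02)
    for j in range(width):
        probs[j, int(rng.integers(4))] = 0.94
    return PWM(motif_id="SHARP", tf_name="SHARP", probs=probs)


class TestBreakSnp:
    def _genome_with_site(self, pwm, pos0=50, seed=1):
        rng = np.random.default_rng(seed)
        seq = list(rng.choice(list("ACGT"), size=200))
        seq[pos0:pos0 + pwm.width] = list(pwm.consensus)
        return {"chrX": "".join(seq)}

    def test_destroying_planted_consensus(self):
        pwm = sharp_pwm()
        genome = self._genome_with_site(pwm, pos0=50)
        offset = 4
        ref = pwm.consensus[offset]
        alt = "ACGT"[int(pwm.probs[offset].argmin())]
        snp = VariantRecord(rsid="rsX", chrom="chrX", pos=51 + offset, ref=ref, alt=alt)
        (res,) = break_snp(snp, genome, [pwm])
        assert res.ref_score == pytest.approx(1.0)
        assert res.alt_score < 1.0
        assert res.allele_diff < 0
        assert res.ref_p <= 5e-5

    def test_snp_far_from_any_match_yields_nothing(self):
        pwm = sharp_pwm()
        genome = self._genome_with_site(pwm, pos0=50)
        # the planted site spans [50, 60); a SNP at 150 has no strong window
        base = genome["chrX"][149]
        alt = "A" if base != "A" else "C"
        snp = VariantRecord(rsid="rsY", chrom="chrX", pos=150, ref=base, alt=alt)
        assert break_snp(snp, genome, [pwm]) == []

    def test_ref_mismatch_with_genome_rejected(self):
        pwm = sharp_pwm()
        genome = self._genome_with_site(pwm)
        base = genome["chrX"][99]
        wrong = "A" if base != "A" else "C"
        snp = VariantRecord(rsid="rsZ", chrom="chrX", pos=100, ref=wrong, alt="T")
        with pytest.raises(DataIntegrityError):
            break_snp(snp, genome, [pwm])

    def test_motif_creation_has_positive_diff(self):
        pwm = sharp_pwm()
        genome = self._genome_with_site(pwm, pos0=50)
        # destroy the planted site in the genome, then restore it via alt
        offset = 4
        ref = "ACGT"[int(pwm.probs[offset].argmin())]
        seq = list(genome["chrX"])
        seq[50 + offset] = ref
        genome = {"chrX": "".join(seq)}
        alt = pwm.consensus[offset]
        snp = VariantRecord(rsid="rsW", chrom="chrX", pos=51 + offset, ref=ref, alt=alt)
        (res,) = break_snp(snp, genome, [pwm])
        assert res.alt_score == pytest.approx(1.0)
        assert res.allele_diff > 0
        assert res.alt_p <= 5e-5
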