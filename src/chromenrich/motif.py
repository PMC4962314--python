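"""Allele-aware PWM scanning: motif-match scores, p-values, disruptions.

A PWM match is scored as the weighted sum of per-position log-ratios
against a background base composition,

    raw(s) = sum_j log( prob[j, s_j] / background[s_j] ),

then min-max scaled to [0, 1] using the column-wise extremes of the
log-ratio matrix, so 1.0 is the consensus sequence and 0.0 the
anti-consensus.  The match p-value P(raw score of a random background
sequence >= x) is computed exactly (up to discretization) by dynamic
programming over the per-position score distribution.

For a SNP, every window of every PWM overlapping the SNP is scored on
both strands for the reference and the alternate allele; windows where
either allele reaches the match p-value cutoff (5e-5 by default) are
reported, keeping the best window/strand per (motif, SNP).  The score
difference between alleles quantifies motif disruption (negative: the
alternate allele weakens the match) or creation (positive).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from chromenrich.errors import DataIntegrityError
from chromenrich.variants import VariantRecord

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 5e-5
DEFAULT_PLOT_CUTOFF = 1e-5
DEFAULT_EFFECT_THRESHOLD = 0.4
DEFAULT_PSEUDOCOUNT = 0.8
# p-value DP bin width, as a fraction of the raw-score range; the induced
# score error (<= width * bin) is far below any score gap that matters at
# the 5e-5 cutoff
DEFAULT_EPS_FRAC = 1e-3

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
UNIFORM_BACKGROUND = np.full(4, 0.25)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass
class PWM:
    """Position probability matrix with a background base composition.

    ``probs`` is width x 4 in A, C, G, T order; each row sums to 1.
    """

    motif_id: str
    tf_name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: probs must be width x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: probability rows must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError(f"{self.motif_id}: background must sum to 1")
        if (self.probs <= 0).any():
            raise ValueError(f"{self.motif_id}: zero probabilities; apply a pseudocount")
        self._distribution: "_ScoreDistribution" | None = None
        self._rc: "PWM" | None = None

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_ratios(self) -> np.ndarray:
        return np.log(self.probs / self.background[None, :])

    @property
    def min_raw(self) -> float:
        return float(self.log_ratios.min(axis=1).sum())

    @property
    def max_raw(self) -> float:
        return float(self.log_ratios.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        if self._rc is None:
            rc = self.probs[::-1, ::-1].copy()
            self._rc = PWM(
                motif_id=self.motif_id, tf_name=self.tf_name, probs=rc,
                background=self.background[::-1].copy(), pseudocount=self.pseudocount,
            )
        return self._rc


def read_jaspar(
    path: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
) -> list[PWM]:
    """Read JASPAR-format count matrices into PWMs.

    Counts (or probabilities) are smoothed column-wise with
    ``pseudocount`` split according to the background, then normalized.
    """
    from Bio import motifs as bio_motifs

    background = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    pwms: list[PWM] = []
    with open(path) as handle:
        try:
            records = bio_motifs.parse(handle, "jaspar")
        except Exception as exc:  # biopython raises bare Exceptions on bad input
            raise ValueError(f"failed to parse JASPAR file {path}: {exc}") from exc
        for record in records:
            counts = np.array([list(record.counts[b]) for b in BASES], dtype=float).T
            if counts.ndim != 2 or counts.shape[1] != 4:
                raise ValueError(f"motif {record.matrix_id}: malformed count matrix")
            smoothed = counts + pseudocount * background[None, :]
            probs = smoothed / smoothed.sum(axis=1, keepdims=True)
            pwms.append(
                PWM(
                    motif_id=record.matrix_id or record.name,
                    tf_name=record.name or record.matrix_id,
                    probs=probs,
                    background=background.copy(),
                    pseudocount=pseudocount,
                )
            )
    return pwms


def write_jaspar(pwms: list[PWM], path: str, scale: int = 100) -> None:
    """Write PWMs as JASPAR count blocks (probabilities x ``scale``)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\t{pwm.tf_name}\n")
            counts = np.round(pwm.probs * scale).astype(int)
            for bi, base in enumerate(BASES):
                row = "  ".join(str(c) for c in counts[:, bi])
                fh.write(f"{base}  [ {row} ]\n")


def raw_score(pwm: PWM, seq: str) -> float:
    """Unscaled weighted-sum (log-ratio) score of one window."""
    seq = seq.upper()
    if len(seq) != pwm.width:
        raise ValueError(f"sequence length {len(seq)} != motif width {pwm.width}")
    lr = pwm.log_ratios
    total = 0.0
    for j, base in enumerate(seq):
        bi = _BASE_INDEX.get(base)
        if bi is None:
            raise ValueError(f"ambiguous base {base!r} at offset {j}")
        total += lr[j, bi]
    return total


def score_window(pwm: PWM, seq: str) -> float:
    """Min-max scaled match score in [0, 1]; 1.0 is the consensus."""
    raw = raw_score(pwm, seq)
    rng = pwm.max_raw - pwm.min_raw
    if rng == 0:
        return 1.0
    return (raw - pwm.min_raw) / rng


class _ScoreDistribution:
    """Discretized distribution of raw scores of random background windows.

    Per-position log-ratio scores are shifted to be non-negative and
    rounded to integer multiples of a bin width delta; the distribution
    of the binned sum is built by convolving the per-position base
    distributions.  Rounding moves any total score by at most
    width * delta / 2.
    """

    def __init__(self, pwm: PWM, eps_frac: float = DEFAULT_EPS_FRAC) -> None:
        lr = pwm.log_ratios
        col_min = lr.min(axis=1)
        score_range = pwm.max_raw - pwm.min_raw
        self.delta = max(eps_frac * score_range, 1e-12)
        self.min_raw = pwm.min_raw
        self.width = pwm.width
        shifted = lr - col_min[:, None]  # >= 0 per column
        bins = np.rint(shifted / self.delta).astype(np.int64)
        dist = np.array([1.0])
        for j in range(pwm.width):
            part = np.zeros(int(bins[j].max()) + 1)
            for bi in range(4):
                part[bins[j, bi]] += pwm.background[bi]
            dist = np.convolve(dist, part)
        # tail[i] = P(binned sum >= i)
        self.tail = np.concatenate([np.cumsum(dist[::-1])[::-1], [0.0]])

    def pvalue(self, raw: float) -> float:
        shifted = raw - self.min_raw
        idx = int(np.rint(shifted / self.delta))
        if idx <= 0:
            return 1.0
        # clamp into the binned support: per-column rounding can place the
        # exact maximum one bin past the distribution's top bin
        idx = min(idx, len(self.tail) - 2)
        return float(min(1.0, self.tail[idx]))


def score_pvalue(pwm: PWM, raw: float, eps_frac: float = DEFAULT_EPS_FRAC) -> float:
    """P(raw score of a random background window >= ``raw``).

    Exact up to discretization (bin width ``eps_frac`` of the raw-score
    range); the distribution is cached on the PWM.
    """
    if not math.isfinite(raw):
        raise ValueError("score must be finite")
    if pwm._distribution is None or pwm._distribution.delta != max(
        eps_frac * (pwm.max_raw - pwm.min_raw), 1e-12
    ):
        pwm._distribution = _ScoreDistribution(pwm, eps_frac=eps_frac)
    if raw <= pwm.min_raw:
        return 1.0
    if raw > pwm.max_raw:
        return 0.0
    return pwm._distribution.pvalue(raw)


@dataclass
class MotifBreakResult:
    """Best-scoring allele-aware match of one motif over one SNP."""

    variant: VariantRecord
    motif_id: str
    tf_name: str
    strand: str  # '+' or '-'
    offset: int  # SNP position within the plus-strand window, 0-based
    ref_score: float
    alt_score: float
    ref_p: float
    alt_p: float
    effect: str  # 'strong' or 'weak'

    @property
    def allele_diff(self) -> float:
        return self.alt_score - self.ref_score


def _fetch(genome, chrom: str, start0: int, end0: int) -> str:
    """Fetch genome sequence; accepts a pyfaidx.Fasta or a plain mapping."""
    seq = genome[chrom]
    if isinstance(seq, str):
        return seq[max(start0, 0):end0].upper()
    return str(seq[max(start0, 0):end0]).upper()


def break_snp(
    variant: VariantRecord,
    genome,
    pwms: list[PWM],
    cutoff: float = DEFAULT_CUTOFF,
    effect_threshold: float = DEFAULT_EFFECT_THRESHOLD,
) -> list[MotifBreakResult]:
    """Score every PWM window overlapping a SNP on both strands.

    Returns one result per motif whose best window/strand (by the smaller
    of the two allele p-values) reaches ``cutoff``.  The variant's ref
    allele must match the genome base at its position.
    """
    chrom_len = len(genome[variant.chrom])
    pos0 = variant.pos - 1
    genome_base = _fetch(genome, variant.chrom, pos0, pos0 + 1)
    if genome_base != variant.ref:
        raise DataIntegrityError(
            f"{variant.rsid}: ref allele {variant.ref} does not match genome "
            f"base {genome_base} at {variant.chrom}:{variant.pos}"
        )
    results: list[MotifBreakResult] = []
    for pwm in pwms:
        w = pwm.width
        rc_pwm = pwm.reverse_complement()
        best: tuple[float, MotifBreakResult] | None = None
        for offset in range(w):
            start = pos0 - offset
            if start < 0 or start + w > chrom_len:
                continue
            window = _fetch(genome, variant.chrom, start, start + w)
            if any(b not in _BASE_INDEX for b in window):
                logger.debug("%s: window at %d contains non-ACGT base; skipped",
                             variant.rsid, start)
                continue
            alt_window = window[:offset] + variant.alt + window[offset + 1:]
            for strand, matrix in (("+", pwm), ("-", rc_pwm)):
                ref_raw = raw_score(matrix, window)
                alt_raw = raw_score(matrix, alt_window)
                ref_p = score_pvalue(matrix, ref_raw)
                alt_p = score_pvalue(matrix, alt_raw)
                min_p = min(ref_p, alt_p)
                if best is None or min_p < best[0]:
                    ref_scaled = score_window(matrix, window)
                    alt_scaled = score_window(matrix, alt_window)
                    diff = alt_scaled - ref_scaled
                    res = MotifBreakResult(
                        variant=variant, motif_id=pwm.motif_id, tf_name=pwm.tf_name,
                        strand=strand, offset=offset,
                        ref_score=ref_scaled, alt_score=alt_scaled,
                        ref_p=ref_p, alt_p=alt_p,
                        effect="strong" if abs(diff) >= effect_threshold else "weak",
                    )
                    best = (min_p, res)
        if best is not None and best[0] <= cutoff:
            results.append(best[1])
    return results


def results_to_frame(results: list[MotifBreakResult]):
    """Tabulate motif-break calls for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "rsid": r.variant.rsid, "motif_id": r.motif_id, "tf_name": r.tf_name,
                "strand": r.strand, "offset": r.offset,
                "ref_score": r.ref_score, "alt_score": r.alt_score,
                "allele_diff": r.allele_diff, "ref_p": r.ref_p, "alt_p": r.alt_p,
                "effect": r.effect,
            }
            for r in results
        ]
    )


def plot_motif_context(
    result: MotifBreakResult,
    pwm: PWM,
    genome,
    path: str,
    flank: int = 5,
) -> str:
    """Plot the motif aligned with the genomic sequence around the SNP.

    Top panel: per-position information content (bits) of the matched
    strand's matrix, with the dominant base lettered.  Bottom panel: the
    surrounding genomic sequence with the variant position in red and
    the ref/alt alleles boxed.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = pwm if result.strand == "+" else pwm.reverse_complement()
    chrom = result.variant.chrom
    pos0 = result.variant.pos - 1
    start = pos0 - result.offset
    seq_start = max(0, start - flank)
    seq_end = min(len(genome[chrom]), start + matrix.width + flank)
    seq = _fetch(genome, chrom, seq_start, seq_end)

    fig, (ax_logo, ax_seq) = plt.subplots(
        2, 1, figsize=(max(4.0, 0.35 * len(seq)), 3.2), height_ratios=[3, 1]
    )
    info = 2.0 + (matrix.probs * np.log2(matrix.probs)).sum(axis=1)
    colors = {"A": "#109648", "C": "#255c99", "G": "#f7b32b", "T": "#d62839"}
    for j in range(matrix.width):
        gpos = start + j
        base = BASES[int(matrix.probs[j].argmax())]
        ax_logo.bar(gpos, info[j], width=0.85, color=colors[base], alpha=0.7)
        ax_logo.text(gpos, info[j] + 0.05, base, ha="center", fontsize=8, color=colors[base])
    ax_logo.set_xlim(seq_start - 0.5, seq_end - 0.5)
    ax_logo.set_ylim(0, 2.3)
    ax_logo.set_ylabel("bits")
    ax_logo.set_title(
        f"{result.tf_name} ({result.motif_id}), strand {result.strand}, "
        f"{result.variant.rsid} {result.variant.ref}>{result.variant.alt}",
        fontsize=9,
    )
    for i, base in enumerate(seq):
        gpos = seq_start + i
        is_snp = gpos == pos0
        ax_seq.text(gpos, 0.55, base, ha="center",
                    color="red" if is_snp else colors.get(base, "black"),
                    fontweight="bold" if is_snp else "normal", fontsize=10)
    ax_seq.text(pos0, 0.05, f"{result.variant.ref}/{result.variant.alt}", ha="center",
                color="red", fontsize=8,
                bbox=dict(edgecolor="red", facecolor="none", boxstyle="round"))
    ax_seq.set_xlim(seq_start - 0.5, seq_end - 0.5)
    ax_seq.set_ylim(0, 1)
    ax_seq.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
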