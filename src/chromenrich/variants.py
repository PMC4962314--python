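"""Variants, phased haplotypes and LD expansion of GWAS index SNPs.

An index SNP is the genome-wide-significant variant a GWAS reports at a
locus.  Because association signals are carried by haplotypes, the causal
variant may be any SNP correlated with the index; this module expands each
index SNP to its set of *surrogates* — panel SNPs within a window around
the index whose squared allelic correlation r^2 with the index reaches a
threshold (0.8 by default).  r^2 is computed from phased haplotypes:

    r^2 = D^2 / (pA (1 - pA) pB (1 - pB)),   D = pAB - pA * pB

where pA and pB are alt-allele frequencies at the two sites and pAB the
frequency of haplotypes carrying both alt alleles.  Unphased genotypes are
rejected rather than approximated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from chromenrich.errors import DataIntegrityError, MonomorphicVariantError

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_R2_MIN = 0.8

_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True, order=True)
class VariantRecord:
    """One biallelic SNP: identifier, 1-based coordinate, ref/alt alleles."""

    rsid: str = field(compare=False)
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical ({self.ref})")


@dataclass
class HaplotypePanel:
    """An ordered variant list plus a binary haplotype matrix.

    ``haplotypes`` has one row per haplotype (two per diploid sample) and
    one column per variant; 0 encodes the reference allele, 1 the
    alternate.
    """

    variants: list[VariantRecord]
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-dimensional")
        if self.haplotypes.shape[1] != len(self.variants):
            raise ValueError(
                f"haplotype matrix has {self.haplotypes.shape[1]} columns "
                f"but panel lists {len(self.variants)} variants"
            )
        if self.haplotypes.shape[0] < 2:
            raise ValueError("panel needs at least two haplotypes")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0 or 1")
        self._by_rsid = {v.rsid: i for i, v in enumerate(self.variants)}
        if len(self._by_rsid) != len(self.variants):
            raise ValueError("rsids are not unique within the panel")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def index_of(self, rsid: str) -> int:
        try:
            return self._by_rsid[rsid]
        except KeyError:
            raise KeyError(f"variant {rsid!r} not present in panel") from None

    def column(self, rsid: str) -> np.ndarray:
        return self.haplotypes[:, self.index_of(rsid)]


@dataclass(frozen=True)
class IndexLocus:
    """A GWAS index SNP with its surrounding background window.

    The window is centered on the index SNP (total span ``window_bp``,
    i.e. +/- window_bp/2) in 0-based half-open coordinates, clipped at
    chromosome bounds when a chromosome length is known.
    """

    index: VariantRecord
    window_start: int
    window_end: int
    window_bp: int = DEFAULT_WINDOW_BP

    def __post_init__(self) -> None:
        if not (self.window_start <= self.index.pos - 1 < self.window_end):
            raise ValueError(
                f"index SNP {self.index.rsid} at pos {self.index.pos} lies outside "
                f"its window [{self.window_start}, {self.window_end})"
            )

    @property
    def locus_id(self) -> str:
        return self.index.rsid

    def contains(self, variant: VariantRecord) -> bool:
        return (
            variant.chrom == self.index.chrom
            and self.window_start <= variant.pos - 1 < self.window_end
        )

    @classmethod
    def around(
        cls,
        index: VariantRecord,
        window_bp: int = DEFAULT_WINDOW_BP,
        chrom_length: int | None = None,
    ) -> "IndexLocus":
        half = window_bp // 2
        start = max(0, index.pos - 1 - half)
        end = index.pos - 1 + half
        if chrom_length is not None:
            end = min(end, chrom_length)
        return cls(index=index, window_start=start, window_end=end, window_bp=window_bp)


@dataclass
class SurrogateSet:
    """An index SNP's risk-SNP set: all window variants with r^2 >= r2_min."""

    locus: IndexLocus
    members: list[tuple[VariantRecord, float]]

    @property
    def rsids(self) -> set[str]:
        return {v.rsid for v, _ in self.members}

    @property
    def variants(self) -> list[VariantRecord]:
        return [v for v, _ in self.members]

    def __len__(self) -> int:
        return len(self.members)


def compute_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared allelic correlation between two binary haplotype vectors.

    Algebraically identical to the squared Pearson correlation of the two
    vectors; raises :class:`MonomorphicVariantError` when either vector is
    monomorphic, where LD is undefined.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("allele vectors must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("need at least two haplotypes")
    pA = float(x.mean())
    pB = float(y.mean())
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise MonomorphicVariantError("LD undefined for a monomorphic variant")
    pAB = float(np.logical_and(x == 1, y == 1).mean())
    D = pAB - pA * pB
    r2 = D * D / (pA * (1.0 - pA) * pB * (1.0 - pB))
    # guard rounding just past the boundary
    return min(max(r2, 0.0), 1.0)


def expand_index(
    index: VariantRecord,
    panel: HaplotypePanel,
    window_bp: int = DEFAULT_WINDOW_BP,
    r2_min: float = DEFAULT_R2_MIN,
    chrom_length: int | None = None,
) -> SurrogateSet:
    """Expand an index SNP to its surrogate set.

    Members are all panel variants inside the window whose r^2 with the
    index reaches ``r2_min``, plus the index itself (r^2 = 1 by
    definition); sorted by position.  Monomorphic panel variants are
    skipped with a log line.
    """
    locus = IndexLocus.around(index, window_bp=window_bp, chrom_length=chrom_length)
    x = panel.column(index.rsid)  # raises KeyError if absent
    members: list[tuple[VariantRecord, float]] = []
    for j, variant in enumerate(panel.variants):
        if not locus.contains(variant):
            continue
        if variant.rsid == index.rsid:
            members.append((variant, 1.0))
            continue
        try:
            r2 = compute_r2(x, panel.haplotypes[:, j])
        except MonomorphicVariantError:
            logger.debug("skipping monomorphic variant %s", variant.rsid)
            continue
        if r2 >= r2_min:
            members.append((variant, r2))
    members.sort(key=lambda item: item[0].pos)
    return SurrogateSet(locus=locus, members=members)


def filter_index_snps(
    indices: list[VariantRecord],
    exclusions: list[tuple[str, str]],
) -> list[VariantRecord]:
    """Drop excluded index SNPs, logging one line per removal with reason.

    An exclusion naming an rsid that is not in the input produces a
    warning, not an error.
    """
    present = {v.rsid for v in indices}
    drop: set[str] = set()
    for rsid, reason in exclusions:
        if rsid not in present:
            logger.warning("exclusion of absent index SNP %s ignored (%s)", rsid, reason)
            continue
        logger.info("removed index SNP %s: %s", rsid, reason)
        drop.add(rsid)
    return [v for v in indices if v.rsid not in drop]


def read_vcf(
    path: str,
    region: str | None = None,
) -> tuple[list[VariantRecord], HaplotypePanel]:
    """Read biallelic SNPs and phased haplotypes from a VCF file.

    Multiallelic records, indels and records with symbolic alleles are
    skipped.  The haplotype matrix has ``2 * n_samples`` rows in file
    sample order; ordering of variants matches file order.  Records with
    missing or unphased GT fields raise :class:`DataIntegrityError` — r^2
    is defined on haplotypes, so phase is required.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    want_chrom = want_start = want_end = None
    if region:
        # filter in-process so plain-text VCFs need no tabix index
        want_chrom, _, span = region.partition(":")
        if span:
            lo, _, hi = span.partition("-")
            want_start, want_end = int(lo), int(hi)
    for rec in vcf:
        if want_chrom is not None:
            if rec.CHROM != want_chrom:
                continue
            if want_start is not None and not (want_start <= rec.POS <= want_end):
                continue
        if len(rec.ALT) != 1:
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if ref not in _BASES or alt not in _BASES:
            continue
        rsid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        genotypes = rec.genotypes
        if genotypes is None:
            raise DataIntegrityError(f"record {rsid} at {rec.CHROM}:{rec.POS} has no GT field")
        col = np.empty(2 * len(genotypes), dtype=np.int8)
        for s, gt in enumerate(genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                raise DataIntegrityError(
                    f"record {rsid} at {rec.CHROM}:{rec.POS} has a missing genotype"
                )
            if not phased:
                raise DataIntegrityError(
                    f"record {rsid} at {rec.CHROM}:{rec.POS} is unphased; "
                    "r^2 is defined on haplotypes"
                )
            col[2 * s] = a0
            col[2 * s + 1] = a1
        variants.append(VariantRecord(rsid=rsid, chrom=rec.CHROM, pos=rec.POS, ref=ref, alt=alt))
        columns.append(col)
    matrix = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((2 * len(vcf.samples), 0), dtype=np.int8)
    )
    panel = HaplotypePanel(variants=list(variants), haplotypes=matrix)
    return variants, panel


def write_surrogates_tsv(surrogate_sets: list[SurrogateSet], path: str) -> None:
    """Write surrogate sets as TSV: rsid, chrom, pos, r2, index_rsid."""
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos\tr2\tindex_rsid\n")
        for ss in surrogate_sets:
            for variant, r2 in ss.members:
                fh.write(
                    f"{variant.rsid}\t{variant.chrom}\t{variant.pos}\t"
                    f"{r2:.6f}\t{ss.locus.index.rsid}\n"
                )


def read_index_snps_tsv(path: str) -> list[VariantRecord]:
    """Read an index-SNP table (TSV with header rsid, chrom, pos, ref, alt)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"rsid", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise DataIntegrityError(f"index SNP table {path} missing columns: {sorted(missing)}")
    return [
        VariantRecord(
            rsid=str(r.rsid), chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt)
        )
        for r in df.itertuples()
    ]
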