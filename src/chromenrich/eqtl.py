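"""eQTL linking: subset association tables by risk SNPs, check tissues.

An eQTL record associates a SNP with a gene's expression level in a
tissue.  The pipeline subsets a (pre-computed) eQTL association table to
the LD-expanded risk-SNP set at a significance threshold (2.5e-5 by
default) and asks whether significant associations occur in the tissues
where chromatin enrichment was observed.  Because epigenome and
expression panels use different tissue ontologies, the cell-type to
eQTL-tissue mapping is a user-supplied input and is never guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from chromenrich.enrichment import EnrichmentResult
from chromenrich.variants import VariantRecord

logger = logging.getLogger(__name__)

DEFAULT_EQTL_P = 2.5e-5
DEFAULT_FLANK_BP = 50_000


@dataclass(frozen=True)
class EQTLRecord:
    """One SNP-gene-tissue association with its effect sign and p-value."""

    rsid: str
    gene: str
    tissue: str
    effect_sign: str  # '+' or '-'
    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"{self.rsid}/{self.gene}: p must lie in [0, 1], got {self.p}")
        if self.effect_sign not in ("+", "-"):
            raise ValueError(f"{self.rsid}/{self.gene}: effect sign must be '+' or '-'")


def prefilter_associations(
    records: list[EQTLRecord],
    p_max: float = 0.05,
) -> list[EQTLRecord]:
    """Drop source records above a nominal significance threshold.

    Mirrors upstream association lists that are thresholded at nominal
    significance before proxy (LD) expansion; off by default in the
    pipeline.
    """
    return [r for r in records if r.p <= p_max]


def subset_eqtl(
    records: list[EQTLRecord],
    snps: set[str],
    p_max: float = DEFAULT_EQTL_P,
) -> list[EQTLRecord]:
    """Records whose rsid is in ``snps`` and p <= ``p_max``, input order."""
    return [r for r in records if r.rsid in snps and r.p <= p_max]


def window_snps_for_gene(
    variants: list[VariantRecord],
    anchor: tuple[str, int],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> set[str]:
    """rsids within +/- ``flank_bp`` (inclusive) of an anchor position."""
    chrom, pos = anchor
    return {v.rsid for v in variants if v.chrom == chrom and abs(v.pos - pos) <= flank_bp}


def tissue_concordance(
    enrich: list[EnrichmentResult],
    eqtl: list[EQTLRecord],
    tissue_map: list[tuple[str, str]],
    fdr: float = 0.05,
    risk_sets: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Cross-reference enrichment calls with eQTL hits per mapped tissue.

    One row per (locus, mapped cell type): ``enriched`` is true when any
    test for that locus in that cell type reaches q < ``fdr``;
    ``n_eqtl_genes`` counts distinct genes among eQTL records in the
    mapped expression tissue (restricted to the locus risk set when
    ``risk_sets`` maps locus ids to rsid sets).  eQTL records in tissues
    absent from the map are excluded with a log line.
    """
    mapped = dict(tissue_map)
    mapped_eqtl_tissues = set(mapped.values())
    for r in eqtl:
        if r.tissue not in mapped_eqtl_tissues:
            logger.warning("eQTL tissue %r has no cell-type mapping; record %s/%s excluded",
                           r.tissue, r.rsid, r.gene)
    rows = []
    loci = sorted({r.locus_id for r in enrich})
    for locus in loci:
        for cell_type, eqtl_tissue in tissue_map:
            hits = [r for r in enrich if r.locus_id == locus and r.cell_type == cell_type]
            if not hits:
                continue
            enriched = any(r.q < fdr for r in hits)
            rsids = risk_sets.get(locus) if risk_sets is not None else None
            genes = {
                r.gene
                for r in eqtl
                if r.tissue == eqtl_tissue and (rsids is None or r.rsid in rsids)
            }
            rows.append(
                {
                    "locus": locus, "cell_type": cell_type, "eqtl_tissue": eqtl_tissue,
                    "enriched": enriched, "n_eqtl_genes": len(genes),
                }
            )
    return pd.DataFrame(
        rows, columns=["locus", "cell_type", "eqtl_tissue", "enriched", "n_eqtl_genes"]
    )


def read_eqtl_tsv(path: str) -> list[EQTLRecord]:
    """Read an eQTL table: TSV with columns rsid, gene, tissue, sign, p."""
    df = pd.read_csv(path, sep="\t")
    required = {"rsid", "gene", "tissue", "sign", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"eQTL table {path} missing columns: {sorted(missing)}")
    return [
        EQTLRecord(rsid=str(r.rsid), gene=str(r.gene), tissue=str(r.tissue),
                   effect_sign=str(r.sign), p=float(r.p))
        for r in df.itertuples()
    ]


def write_eqtl_tsv(records: list[EQTLRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tgene\ttissue\tsign\tp\n")
        for r in records:
            fh.write(f"{r.rsid}\t{r.gene}\t{r.tissue}\t{r.effect_sign}\t{r.p:.6g}\n")


def read_tissue_map_tsv(path: str) -> list[tuple[str, str]]:
    """Read a two-column TSV mapping cell types to eQTL tissues."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"tissue map {path} needs two columns (cell_type, eqtl_tissue)")
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]
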