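"""End-to-end orchestration: config, preflight, stages, manifest.

The pipeline runs, in order: LD expansion of index SNPs, chromatin
segmentation per cell type, SNP annotation, per-locus hypergeometric
enrichment with FDR, clustering/heatmap of the enrichment matrix,
allele-aware motif-disruption scanning of regulatory risk SNPs, and eQTL
linking.  Every run writes a manifest echoing the configuration,
package versions, the seed and per-stage row counts, with checksums of
every result table, so a run is reproducible and every artifact
traceable.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from chromenrich import __version__
from chromenrich.enrichment import (
    ACTIVE_UNION,
    CATEGORIES,
    adjust_results,
    build_matrix,
    enrich,
    results_to_frame,
)
from chromenrich.clustering import average_linkage, euclidean_distances, render_heatmap
from chromenrich.errors import ChromenrichError, ConfigError, DataIntegrityError
from chromenrich.eqtl import (
    read_eqtl_tsv,
    read_tissue_map_tsv,
    subset_eqtl,
    tissue_concordance,
)
from chromenrich.motif import (
    break_snp,
    plot_motif_context,
    read_jaspar,
    results_to_frame as motif_frame,
)
from chromenrich.segmentation import (
    H3K4ME1,
    H3K4ME3,
    H3K27AC,
    annotate_snps,
    classify,
    read_bed3,
    write_bed4,
)
from chromenrich.variants import (
    expand_index,
    filter_index_snps,
    read_index_snps_tsv,
    read_vcf,
    write_surrogates_tsv,
)

logger = logging.getLogger(__name__)

STAGES = (
    "ld-expand", "segment", "annotate", "enrich",
    "cluster", "motif-break", "eqtl-link", "manifest",
)


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run.

    Thresholds default to the standard analysis settings: surrogates at
    r^2 >= 0.8 within a 1 Mb window, FDR < 0.05, motif-match p-value
    cutoff 5e-5 (plots at 1e-5), eQTL significance 2.5e-5.
    """

    index_snps: str = ""
    panel_vcf: str = ""
    peak_dir: str = ""
    genome_fasta: str | None = None
    pwm_file: str | None = None
    eqtl_tsv: str | None = None
    tissue_map: str | None = None
    exclusions: str | None = None
    outdir: str = "results"
    window_bp: int = 1_000_000
    r2_min: float = 0.8
    fdr: float = 0.05
    motif_cutoff: float = 5e-5
    plot_cutoff: float = 1e-5
    eqtl_p: float = 2.5e-5
    fdr_family: str = "locus"
    matrix_scale: str = "neg_ln_q"
    matrix_category: str = ACTIVE_UNION
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("r2_min", "fdr", "motif_cutoff", "plot_cutoff", "eqtl_p"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ConfigError(f"{name} must lie in (0, 1], got {value}")
        if self.window_bp < 2:
            raise ConfigError(f"window_bp must be >= 2, got {self.window_bp}")
        if self.fdr_family not in ("locus", "cell_type"):
            raise ConfigError(f"fdr_family must be 'locus' or 'cell_type'")
        if self.matrix_scale not in ("neg_ln_q", "neg_ln_p"):
            raise ConfigError(f"matrix_scale must be 'neg_ln_q' or 'neg_ln_p'")

    def preflight(self) -> None:
        """Validate thresholds and check every declared input exists."""
        self.validate()
        required = {"index_snps": self.index_snps, "panel_vcf": self.panel_vcf,
                    "peak_dir": self.peak_dir}
        for name, path in required.items():
            if not path:
                raise ConfigError(f"required input {name!r} not set")
            if not os.path.exists(path):
                raise ConfigError(f"{name}: no such path {path!r}")
        for name in ("genome_fasta", "pwm_file", "eqtl_tsv", "tissue_map", "exclusions"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise ConfigError(f"{name}: no such path {path!r}")


def discover_cell_types(peak_dir: str) -> list[str]:
    """Cell types with a complete <cell_type>.<mark>.bed trio in peak_dir."""
    found: dict[str, set[str]] = {}
    for path in glob.glob(os.path.join(peak_dir, "*.bed")):
        base = os.path.basename(path)[:-4]
        if "." not in base:
            continue
        ct, mark = base.rsplit(".", 1)
        found.setdefault(ct, set()).add(mark)
    complete = sorted(ct for ct, marks in found.items()
                      if {H3K4ME1, H3K4ME3, H3K27AC} <= marks)
    if not complete:
        raise ConfigError(f"no complete peak trios found under {peak_dir!r}")
    return complete


def _checksum(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the manifest dictionary.

    Any stage failure raises with the stage name attached; the manifest
    is only written on success.
    """
    config.preflight()
    os.makedirs(config.outdir, exist_ok=True)
    counts: dict[str, int] = {}
    outputs: list[str] = []
    stage = "preflight"
    try:
        # ---- ld-expand --------------------------------------------------
        stage = "ld-expand"
        indices = read_index_snps_tsv(config.index_snps)
        _, panel = read_vcf(config.panel_vcf)
        chrom_lengths: dict[str, int] = {}
        if config.genome_fasta:
            from pyfaidx import Fasta

            genome = Fasta(config.genome_fasta)
            chrom_lengths = {name: len(genome[name]) for name in genome.keys()}
        else:
            genome = None
        exclusions: list[tuple[str, str]] = []
        if config.exclusions:
            with open(config.exclusions) as fh:
                for line in fh:
                    line = line.strip()
                    if line and not line.startswith("#"):
                        rsid, _, reason = line.partition("\t")
                        exclusions.append((rsid, reason or "excluded"))
        indices = filter_index_snps(indices, exclusions)
        surrogate_sets = {}
        thin: list[tuple[str, str]] = []
        for index in indices:
            ss = expand_index(
                index, panel, window_bp=config.window_bp, r2_min=config.r2_min,
                chrom_length=chrom_lengths.get(index.chrom),
            )
            if len(ss) < 2:
                thin.append((index.rsid, f"no SNPs with r^2 >= {config.r2_min}"))
            else:
                surrogate_sets[index.rsid] = ss
        indices = filter_index_snps(indices, thin)
        if not indices:
            raise DataIntegrityError("no index SNPs left after LD expansion")
        surrogates_path = os.path.join(config.outdir, "surrogates.tsv")
        write_surrogates_tsv(list(surrogate_sets.values()), surrogates_path)
        outputs.append(surrogates_path)
        counts["ld-expand"] = sum(len(ss) for ss in surrogate_sets.values())

        # ---- segment ----------------------------------------------------
        stage = "segment"
        cell_types = discover_cell_types(config.peak_dir)
        seg_dir = os.path.join(config.outdir, "segmentation")
        os.makedirs(seg_dir, exist_ok=True)
        tracks = {}
        for ct in cell_types:
            track = classify(
                read_bed3(os.path.join(config.peak_dir, f"{ct}.{H3K4ME3}.bed"), H3K4ME3),
                read_bed3(os.path.join(config.peak_dir, f"{ct}.{H3K4ME1}.bed"), H3K4ME1),
                read_bed3(os.path.join(config.peak_dir, f"{ct}.{H3K27AC}.bed"), H3K27AC),
                ct,
            )
            tracks[ct] = track
            bed_path = os.path.join(seg_dir, f"{ct}.segmentation.bed")
            write_bed4(track, bed_path)
            outputs.append(bed_path)
        counts["segment"] = sum(len(t.segments) for t in tracks.values())

        # ---- annotate ---------------------------------------------------
        stage = "annotate"
        risk_variants = sorted(
            {v for ss in surrogate_sets.values() for v in ss.variants},
            key=lambda v: (v.chrom, v.pos),
        )
        annotations = []
        for ct, track in tracks.items():
            annotations.extend(annotate_snps(risk_variants, track))
        ann_path = os.path.join(config.outdir, "risk_snp_annotations.tsv")
        with open(ann_path, "w") as fh:
            fh.write("rsid\tchrom\tpos\tcell_type\tlabel\n")
            for a in annotations:
                fh.write(f"{a.variant.rsid}\t{a.variant.chrom}\t{a.variant.pos}\t"
                         f"{a.cell_type}\t{a.label}\n")
        outputs.append(ann_path)
        counts["annotate"] = len(annotations)

        # ---- enrich -----------------------------------------------------
        stage = "enrich"
        results = []
        for index in indices:
            ss = surrogate_sets[index.rsid]
            background = [v for v in panel.variants if ss.locus.contains(v)]
            for ct, track in tracks.items():
                for category in CATEGORIES:
                    results.append(enrich(ss.locus, ss, background, track, category))
        adjust_results(results, family=config.fdr_family)
        frame = results_to_frame(results)
        enrich_path = os.path.join(config.outdir, "enrichment.tsv")
        frame.to_csv(enrich_path, sep="\t", index=False, float_format="%.6g")
        outputs.append(enrich_path)
        counts["enrich"] = len(results)

        # ---- cluster ----------------------------------------------------
        stage = "cluster"
        matrix = build_matrix(results, category=config.matrix_category,
                              scale=config.matrix_scale)
        matrix_path = os.path.join(config.outdir, "enrichment_matrix.tsv")
        matrix.values.to_csv(matrix_path, sep="\t", float_format="%.6g")
        outputs.append(matrix_path)
        row_tree = average_linkage(euclidean_distances(matrix, axis="rows"))
        col_tree = average_linkage(euclidean_distances(matrix, axis="cols"))
        for name, tree in (("cell_types", row_tree), ("loci", col_tree)):
            nwk_path = os.path.join(config.outdir, f"dendrogram_{name}.nwk")
            with open(nwk_path, "w") as fh:
                fh.write(tree.to_newick() + "\n")
            outputs.append(nwk_path)
        heatmap_path = os.path.join(config.outdir, "heatmap.png")
        render_heatmap(matrix, row_tree, col_tree, heatmap_path)
        counts["cluster"] = matrix.values.size

        # ---- motif-break ------------------------------------------------
        stage = "motif-break"
        motif_results = []
        if genome is not None and config.pwm_file:
            pwms = read_jaspar(config.pwm_file)
            regulatory = {a.variant.rsid for a in annotations if a.label != "NONE"}
            for variant in risk_variants:
                if variant.rsid not in regulatory:
                    continue
                motif_results.extend(
                    break_snp(variant, genome, pwms, cutoff=config.motif_cutoff)
                )
            motif_path = os.path.join(config.outdir, "motif_breaks.tsv")
            motif_frame(motif_results).to_csv(motif_path, sep="\t", index=False,
                                              float_format="%.6g")
            outputs.append(motif_path)
            plot_dir = os.path.join(config.outdir, "motif_plots")
            os.makedirs(plot_dir, exist_ok=True)
            pwm_by_id = {p.motif_id: p for p in pwms}
            for r in motif_results:
                if min(r.ref_p, r.alt_p) < config.plot_cutoff:
                    plot_motif_context(
                        r, pwm_by_id[r.motif_id], genome,
                        os.path.join(plot_dir, f"{r.variant.rsid}_{r.motif_id}.png"),
                    )
        counts["motif-break"] = len(motif_results)

        # ---- eqtl-link --------------------------------------------------
        stage = "eqtl-link"
        n_eqtl = 0
        if config.eqtl_tsv:
            eqtl_records = read_eqtl_tsv(config.eqtl_tsv)
            risk_rsids = {v.rsid for v in risk_variants}
            hits = subset_eqtl(eqtl_records, risk_rsids, p_max=config.eqtl_p)
            eqtl_path = os.path.join(config.outdir, "eqtl_hits.tsv")
            with open(eqtl_path, "w") as fh:
                fh.write("rsid\tgene\ttissue\tsign\tp\n")
                for r in hits:
                    fh.write(f"{r.rsid}\t{r.gene}\t{r.tissue}\t{r.effect_sign}\t{r.p:.6g}\n")
            outputs.append(eqtl_path)
            n_eqtl = len(hits)
            if config.tissue_map:
                tmap = read_tissue_map_tsv(config.tissue_map)
                risk_sets_by_locus = {
                    lid: ss.rsids for lid, ss in surrogate_sets.items()
                }
                table = tissue_concordance(results, hits, tmap, fdr=config.fdr,
                                           risk_sets=risk_sets_by_locus)
                conc_path = os.path.join(config.outdir, "tissue_concordance.tsv")
                table.to_csv(conc_path, sep="\t", index=False)
                outputs.append(conc_path)
        counts["eqtl-link"] = n_eqtl

        # ---- manifest ---------------------------------------------------
        stage = "manifest"
        import scipy

        manifest = {
            "config": dataclasses.asdict(config),
            "versions": {
                "chromenrich": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
            },
            "seed": config.seed,
            "stages": list(STAGES),
            "counts": counts,
            "outputs": {os.path.relpath(p, config.outdir): _checksum(p) for p in outputs},
        }
        manifest_path = os.path.join(config.outdir, "manifest.json")
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    except ChromenrichError as exc:
        exc.args = (f"stage {stage!r} failed: {exc}",)
        raise
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
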