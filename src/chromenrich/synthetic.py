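"""Synthetic pipeline inputs with known planted truth.

The generator emulates, at desk scale, the three data sources the
pipeline consumes in production use:

* a phased haplotype panel — one chromosome per locus, an index SNP at
  the window center, surrogates planted at controllable pairwise r^2
  against the index, and background SNPs at a uniform per-bp density;
* per-cell-type peak tracks for the three histone marks — fixed-width
  enhancer peaks covering a configurable fraction of each window, with
  planted (locus, tissue) pairs where a configurable fraction of risk
  SNPs is forced inside active-enhancer peaks;
* a random genome with PWM consensus sites written in at planted
  positions, each carrying a SNP whose alternate allele destroys the
  match; and an eQTL table with planted significant SNP-gene-tissue
  triples among uniform noise records.

LD is planted pairwise against the index SNP only — enough to exercise
the r^2 threshold rule without simulating recombination.  All randomness
flows from a single seed through named substreams, so regeneration is
stable and emitted files are byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from chromenrich.eqtl import EQTLRecord, write_eqtl_tsv
from chromenrich.errors import FeasibilityError
from chromenrich.motif import PWM, BASES, write_jaspar

_BASE_IDX = {b: i for i, b in enumerate(BASES)}
from chromenrich.segmentation import (
    H3K4ME1,
    H3K4ME3,
    H3K27AC,
    PeakSet,
    classify,
    annotate_snps,
)
from chromenrich.variants import (
    HaplotypePanel,
    SurrogateSet,
    VariantRecord,
    compute_r2,
    expand_index,
)

# substream tags (second word of the rng seed sequence)
_S_GENOME, _S_PANEL, _S_PEAKS, _S_PWMS, _S_EQTL = 11, 23, 37, 53, 71


@dataclass(frozen=True)
class MotifPlant:
    """A motif consensus written into the genome with a disrupting SNP.

    ``pos`` is the 1-based SNP position; ``alt`` defaults to the base
    with the lowest probability in the SNP's motif column.
    """

    motif_id: str
    locus: int
    pos: int
    alt: str | None = None


@dataclass(frozen=True)
class PlantedBreak:
    """Realized truth for one planted motif-disrupting SNP."""

    rsid: str
    motif_id: str
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class ScenarioConfig:
    """Every knob of the synthetic scenario; defaults are the study
    conditions the pipeline is validated under.

    ``background_snp_density`` of 5e-4 per bp gives ~500 window SNPs per
    Mb, about the density of common biallelic SNPs; ``category_fraction``
    is the fraction of each window covered by active enhancer;
    ``planted`` lists (locus, tissue, risk_in_category_fraction) triples.
    """

    seed: int = 0
    n_haplotypes: int = 400
    n_loci: int = 8
    n_tissues: int = 10
    window_bp: int = 1_000_000
    background_snp_density: float = 5e-4
    category_fraction: float = 0.1
    n_surrogates: int = 15
    r2_low: float = 0.9
    r2_high: float = 0.99
    peak_width: int = 1000
    poised_enhancer_fraction: float = 0.1
    promoter_fraction: float = 0.1
    planted: list[tuple[int, int, float]] = field(default_factory=list)
    motif_plants: list[MotifPlant] = field(default_factory=list)
    n_motifs: int = 4
    motif_width: int = 10
    eqtl_plants: list[EQTLRecord] = field(default_factory=list)
    n_eqtl_noise: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.category_fraction <= 1.0:
            raise ValueError("category_fraction must lie in [0, 1]")
        for locus, tissue, frac in self.planted:
            if not (0 <= locus < self.n_loci and 0 <= tissue < self.n_tissues):
                raise ValueError(f"planted ({locus}, {tissue}) outside declared ranges")
            if not 0.0 <= frac <= 1.0:
                raise ValueError("risk_in_category_fraction must lie in [0, 1]")
        for plant in self.motif_plants:
            if not 0 <= plant.locus < self.n_loci:
                raise ValueError(f"motif plant locus {plant.locus} out of range")

    @property
    def cell_types(self) -> list[str]:
        return [f"tissue_{t:02d}" for t in range(self.n_tissues)]

    @property
    def chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_loci)]


@dataclass
class SyntheticTruth:
    """Planted parameters as realized in the emitted data."""

    surrogate_r2: dict[str, float]  # rsid -> empirical r^2 with its index
    planted_counts: dict[tuple[int, int], tuple[int, int, int, int]]  # (locus, tissue) -> k,n,K,N
    motif_breaks: list[PlantedBreak]
    eqtl_plants: list[EQTLRecord]

    def to_jsonable(self) -> dict:
        return {
            "surrogate_r2": self.surrogate_r2,
            "planted_counts": {
                f"{loc},{tis}": list(counts) for (loc, tis), counts in self.planted_counts.items()
            },
            "motif_breaks": [asdict(b) for b in self.motif_breaks],
            "eqtl_plants": [asdict(e) for e in self.eqtl_plants],
        }


@dataclass
class Scenario:
    """In-memory scenario: all inputs plus the realized truth."""

    config: ScenarioConfig
    index_snps: list[VariantRecord]
    panel: HaplotypePanel
    peaks: dict[str, dict[str, list[tuple[str, int, int]]]]  # cell_type -> mark -> peaks
    genome: dict[str, str]
    pwms: list[PWM]
    eqtl_records: list[EQTLRecord]
    tissue_map: list[tuple[str, str]]
    truth: SyntheticTruth
    risk_sets: dict[int, "SurrogateSet"] = field(default_factory=dict)


def gen_haplotypes_with_r2(
    pA: float,
    pB: float,
    r2_target: float,
    n_hap: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two binary haplotype columns with a target pairwise r^2.

    The four-cell haplotype distribution is set to pAB = pA*pB + D with
    D = sqrt(r2_target * pA(1-pA) pB(1-pB)); the empirical r^2 converges
    to the target as n_hap grows.  Raises :class:`FeasibilityError` when
    pAB would exceed min(pA, pB) (the Frechet upper bound).
    """
    if not (0 < pA < 1 and 0 < pB < 1 and 0 <= r2_target <= 1):
        raise ValueError("need 0 < pA, pB < 1 and r2_target in [0, 1]")
    D = math.sqrt(r2_target * pA * (1 - pA) * pB * (1 - pB))
    pAB = pA * pB + D
    if pAB > min(pA, pB) + 1e-12:
        raise FeasibilityError(
            f"infeasible target: pAB = pA*pB + D = {pAB:.4f} exceeds the Frechet "
            f"bound min(pA, pB) = {min(pA, pB):.4f} for pA={pA}, pB={pB}, "
            f"r2_target={r2_target}"
        )
    pAB = min(pAB, min(pA, pB))
    cells = np.array([1 - pA - pB + pAB, pB - pAB, pA - pAB, pAB])  # 00, 01, 10, 11
    cells = np.clip(cells, 0.0, None)
    cells /= cells.sum()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.choice(4, size=n_hap, p=cells)
    x = (draws >= 2).astype(np.int8)
    y = (draws % 2).astype(np.int8)
    return x, y


def _conditional_column(
    x: np.ndarray, r2_target: float, rng: np.random.Generator
) -> np.ndarray:
    """A column with target r^2 against ``x``, matching its allele freq."""
    pA = float(x.mean())
    D = math.sqrt(r2_target) * pA * (1 - pA)
    pAB = pA * pA + D
    p1_given_1 = pAB / pA
    p1_given_0 = (pA - pAB) / (1 - pA)
    u = rng.random(x.size)
    y = np.where(x == 1, u < p1_given_1, u < p1_given_0).astype(np.int8)
    if y.min() == y.max():  # degenerate draw at small n; break ties deterministically
        y[0] = 1 - y[0]
    return y


def _polymorphic_column(
    n_hap: int, maf: float, rng: np.random.Generator
) -> np.ndarray:
    col = (rng.random(n_hap) < maf).astype(np.int8)
    if col.min() == col.max():
        col[0] = 1 - col[0]
    return col


def _gen_pwms(config: ScenarioConfig) -> list[PWM]:
    """Sharp synthetic PWMs: one dominant base per column."""
    rng = np.random.default_rng([config.seed, _S_PWMS])
    pwms = []
    for m in range(config.n_motifs):
        w = config.motif_width
        probs = np.empty((w, 4))
        for j in range(w):
            dom = int(rng.integers(4))
            p_dom = float(rng.uniform(0.88, 0.97))
            rest = rng.dirichlet(np.ones(3)) * (1 - p_dom)
            row = np.empty(4)
            row[dom] = p_dom
            row[[i for i in range(4) if i != dom]] = rest
            probs[j] = row
        pwms.append(PWM(motif_id=f"M{m + 1}", tf_name=f"TF{m + 1}", probs=probs))
    return pwms


def _sample_positions(
    rng: np.random.Generator, lo: int, hi: int, k: int, exclude: set[int]
) -> list[int]:
    """k distinct positions in [lo, hi), avoiding ``exclude``, draw order."""
    out: list[int] = []
    seen = set(exclude)
    while len(out) < k:
        for pos in rng.integers(lo, hi, size=2 * (k - len(out)) + 8):
            pos = int(pos)
            if pos not in seen:
                seen.add(pos)
                out.append(pos)
                if len(out) == k:
                    break
    return out


_BASE_ARRAY = np.array(list(BASES))


def build_scenario(config: ScenarioConfig, with_genome: bool = True) -> Scenario:
    """Generate the full scenario in memory; see module docstring.

    ``with_genome=False`` skips the genome sequence (and hence motif
    plants), for callers that only exercise the LD/segmentation/
    enrichment stages; SNP alleles are then drawn at random.
    """
    if not with_genome and config.motif_plants:
        raise ValueError("motif plants require with_genome=True")
    n_bg = int(round(config.background_snp_density * config.window_bp))
    W = config.window_bp
    pw = config.peak_width
    n_cells = W // pw

    pwms = _gen_pwms(config)
    pwm_by_id = {p.motif_id: p for p in pwms}

    # --- genome, with motif consensus sites written in -------------------
    rng_genome = np.random.default_rng([config.seed, _S_GENOME])
    genome: dict[str, list[str]] = {}
    if with_genome:
        for chrom in config.chroms:
            idx = rng_genome.integers(0, 4, size=W)
            genome[chrom] = list(_BASE_ARRAY[idx])
    plant_specs: list[tuple[MotifPlant, str, int, str, str]] = []  # plant, chrom, offset, ref, alt
    for plant in config.motif_plants:
        pwm = pwm_by_id[plant.motif_id]
        chrom = config.chroms[plant.locus]
        lr = pwm.log_ratios
        # put the SNP on the most informative column so the alt allele
        # moves the score as far as possible
        offset = int((lr.max(axis=1) - lr.min(axis=1)).argmax())
        consensus = pwm.consensus
        start0 = plant.pos - 1 - offset
        if start0 < 0 or start0 + pwm.width > W:
            raise ValueError(f"motif plant at {chrom}:{plant.pos} does not fit in the window")
        genome[chrom][start0:start0 + pwm.width] = list(consensus)
        ref = consensus[offset]
        alt = plant.alt
        if alt is None:
            alt = BASES[int(lr[offset].argmin())]
        if alt == ref:
            raise ValueError(f"motif plant at {chrom}:{plant.pos}: alt equals consensus base")
        plant_specs.append((plant, chrom, offset, ref, alt))
    genome_str = {chrom: "".join(seq) for chrom, seq in genome.items()}

    # --- haplotype panel -------------------------------------------------
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    index_snps: list[VariantRecord] = []
    surrogate_rsids: dict[int, list[str]] = {}
    truth_r2: dict[str, float] = {}
    plant_variants: dict[tuple[int, int], str] = {}  # (locus, pos) -> rsid

    for i, chrom in enumerate(config.chroms):
        rng = np.random.default_rng([config.seed, _S_PANEL, i])
        index_pos = W // 2
        half = W // 2
        win_lo = max(1, index_pos - half + 1)
        win_hi = min(W - 1, index_pos + half - 1)

        def _alt_for(pos: int, rng=rng, chrom=chrom) -> tuple[str, str]:
            if with_genome:
                ref = genome_str[chrom][pos - 1]
            else:
                ref = BASES[int(rng.integers(4))]
            alt = BASES[(_BASE_IDX[ref] + int(rng.integers(1, 4))) % 4]
            return ref, alt

        plant_positions = {
            plant.pos: (plant, ref, alt)
            for plant, pchrom, _off, ref, alt in plant_specs
            if pchrom == chrom
        }
        used = {index_pos} | set(plant_positions)

        pA = float(rng.uniform(0.2, 0.5))
        x = _polymorphic_column(config.n_haplotypes, pA, rng)
        ref, alt = _alt_for(index_pos)
        index = VariantRecord(rsid=f"rsL{i + 1}", chrom=chrom, pos=index_pos, ref=ref, alt=alt)
        index_snps.append(index)
        locus_variants: list[tuple[VariantRecord, np.ndarray]] = [(index, x)]

        # surrogates at target r^2 against the index
        free = _sample_positions(rng, win_lo, win_hi, config.n_surrogates + n_bg, used)
        surrogate_rsids[i] = [index.rsid]
        for j in range(config.n_surrogates):
            pos = free.pop()
            used.add(pos)
            target = float(rng.uniform(config.r2_low, config.r2_high))
            col = _conditional_column(x, target, rng)
            ref, alt = _alt_for(pos)
            v = VariantRecord(rsid=f"rsL{i + 1}S{j + 1}", chrom=chrom, pos=pos, ref=ref, alt=alt)
            locus_variants.append((v, col))
            surrogate_rsids[i].append(v.rsid)
            truth_r2[v.rsid] = compute_r2(x, col)

        # motif-plant SNPs ride on near-perfect LD so they are risk SNPs
        for k, (pos, (plant, ref, alt)) in enumerate(sorted(plant_positions.items())):
            col = _conditional_column(x, 0.98, rng)
            v = VariantRecord(rsid=f"rsL{i + 1}M{k + 1}", chrom=chrom, pos=pos, ref=ref, alt=alt)
            locus_variants.append((v, col))
            surrogate_rsids[i].append(v.rsid)
            truth_r2[v.rsid] = compute_r2(x, col)
            plant_variants[(i, pos)] = v.rsid

        # background SNPs, LD-free
        for j in range(n_bg):
            pos = free.pop()
            used.add(pos)
            maf = float(rng.uniform(0.05, 0.5))
            col = _polymorphic_column(config.n_haplotypes, maf, rng)
            ref, alt = _alt_for(pos)
            v = VariantRecord(rsid=f"rsL{i + 1}B{j + 1}", chrom=chrom, pos=pos, ref=ref, alt=alt)
            locus_variants.append((v, col))

        locus_variants.sort(key=lambda item: item[0].pos)
        variants.extend(v for v, _ in locus_variants)
        columns.extend(c for _, c in locus_variants)

    panel = HaplotypePanel(variants=variants, haplotypes=np.stack(columns, axis=1))

    # --- risk sets (realized, via the pipeline's own LD expansion) -------
    risk_sets = {
        i: expand_index(index_snps[i], panel, window_bp=W, chrom_length=W)
        for i in range(config.n_loci)
    }

    # --- peak tracks ------------------------------------------------------
    planted_map = {(loc, tis): frac for loc, tis, frac in config.planted}
    n_active = int(round(config.category_fraction * n_cells))
    n_poised = int(round(config.poised_enhancer_fraction * n_active))
    n_prom = int(round(config.promoter_fraction * n_active))
    peaks: dict[str, dict[str, list[tuple[str, int, int]]]] = {
        ct: {H3K4ME1: [], H3K4ME3: [], H3K27AC: []} for ct in config.cell_types
    }
    for t, ct in enumerate(config.cell_types):
        for i, chrom in enumerate(config.chroms):
            rng = np.random.default_rng([config.seed, _S_PEAKS, t, i])
            chosen = rng.choice(n_cells, size=n_active + n_poised + n_prom, replace=False)
            active = set(int(c) for c in chosen[:n_active])
            poised = set(int(c) for c in chosen[n_active:n_active + n_poised])
            prom = set(int(c) for c in chosen[n_active + n_poised:])
            frac = planted_map.get((i, t))
            if frac is not None:
                for v in risk_sets[i].variants:
                    if rng.random() < frac:
                        cell = (v.pos - 1) // pw
                        active.add(cell)
                        poised.discard(cell)
                        prom.discard(cell)
            # planted motif-break SNPs must sit in regulatory chromatin in
            # at least one cell type so the scanner picks them up
            if t == 0:
                for (loc, pos), _rsid in plant_variants.items():
                    if loc == i:
                        cell = (pos - 1) // pw
                        active.add(cell)
                        poised.discard(cell)
                        prom.discard(cell)
            prom_active = {c for c in prom if rng.random() < 0.5}
            for cell in sorted(active | poised):
                peaks[ct][H3K4ME1].append((chrom, cell * pw, (cell + 1) * pw))
            for cell in sorted(prom):
                peaks[ct][H3K4ME3].append((chrom, cell * pw, (cell + 1) * pw))
            for cell in sorted(active | prom_active):
                peaks[ct][H3K27AC].append((chrom, cell * pw, (cell + 1) * pw))

    # --- realized counts for planted (locus, tissue) pairs ----------------
    planted_counts: dict[tuple[int, int], tuple[int, int, int, int]] = {}
    for (loc, tis), _frac in planted_map.items():
        ct = config.cell_types[tis]
        track = classify(
            PeakSet.from_tuples(H3K4ME3, peaks[ct][H3K4ME3]),
            PeakSet.from_tuples(H3K4ME1, peaks[ct][H3K4ME1]),
            PeakSet.from_tuples(H3K27AC, peaks[ct][H3K27AC]),
            ct,
        )
        chrom = config.chroms[loc]
        background = [v for v in panel.variants if v.chrom == chrom]
        labels = {a.variant.rsid: a.label for a in annotate_snps(background, track)}
        K = sum(1 for v in background if labels[v.rsid] == "EAR")
        rs = risk_sets[loc]
        k = sum(1 for r in rs.rsids if labels[r] == "EAR")
        planted_counts[(loc, tis)] = (k, len(rs), K, len(background))

    # --- motif-break truth ------------------------------------------------
    motif_breaks = [
        PlantedBreak(
            rsid=plant_variants[(plant.locus, plant.pos)],
            motif_id=plant.motif_id, chrom=chrom, pos=plant.pos, ref=ref, alt=alt,
        )
        for plant, chrom, _off, ref, alt in plant_specs
    ]

    # --- eQTL table -------------------------------------------------------
    rng_eqtl = np.random.default_rng([config.seed, _S_EQTL])
    tissue_map = [(ct, f"{ct}_expr") for ct in config.cell_types]
    eqtl_records = list(config.eqtl_plants)
    all_rsids = [v.rsid for v in panel.variants]
    expr_tissues = [b for _, b in tissue_map]
    for g in range(config.n_eqtl_noise):
        eqtl_records.append(
            EQTLRecord(
                rsid=all_rsids[int(rng_eqtl.integers(len(all_rsids)))],
                gene=f"NOISE{g + 1}",
                tissue=expr_tissues[int(rng_eqtl.integers(len(expr_tissues)))],
                effect_sign="+" if rng_eqtl.random() < 0.5 else "-",
                p=float(rng_eqtl.uniform(1e-4, 1.0)),
            )
        )

    truth = SyntheticTruth(
        surrogate_r2=truth_r2,
        planted_counts=planted_counts,
        motif_breaks=motif_breaks,
        eqtl_plants=list(config.eqtl_plants),
    )
    return Scenario(
        config=config, index_snps=index_snps, panel=panel, peaks=peaks,
        genome=genome_str, pwms=pwms, eqtl_records=eqtl_records,
        tissue_map=tissue_map, truth=truth, risk_sets=risk_sets,
    )


def default_scenario_config(seed: int = 0) -> ScenarioConfig:
    """The default study conditions: 8 loci x 10 tissues, one planted
    enrichment, two planted motif breaks, two planted eQTLs."""
    W = 1_000_000
    return ScenarioConfig(
        seed=seed,
        planted=[(0, 0, 0.8)],
        motif_plants=[
            MotifPlant("M1", locus=0, pos=W // 4),
            MotifPlant("M2", locus=1, pos=W // 4),
        ],
        eqtl_plants=[
            EQTLRecord(rsid="rsL1S1", gene="GENE1", tissue="tissue_00_expr",
                       effect_sign="-", p=1e-6),
            EQTLRecord(rsid="rsL2S3", gene="GENE2", tissue="tissue_01_expr",
                       effect_sign="+", p=5e-7),
        ],
    )


# ---------------------------------------------------------------------------
# file emission


def _write_vcf(scenario: Scenario, path: str) -> None:
    cfg = scenario.config
    n_samples = cfg.n_haplotypes // 2
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    H = scenario.panel.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=chromenrich-synthetic\n")
        for chrom in cfg.chroms:
            fh.write(f"##contig=<ID={chrom},length={cfg.window_bp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        gt_str = (("0|0", "0|1"), ("1|0", "1|1"))
        for j, v in enumerate(scenario.panel.variants):
            pairs = H[:, j].reshape(-1, 2)
            gts = "\t".join(gt_str[a][b] for a, b in pairs)
            fh.write(f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def _write_fasta(genome: dict[str, str], path: str, line: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), line):
                fh.write(seq[i:i + line] + "\n")


def _write_index_snps(index_snps: list[VariantRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos\tref\talt\n")
        for v in index_snps:
            fh.write(f"{v.rsid}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\n")


def _checksum(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def gen_scenario(config: ScenarioConfig, outdir: str) -> SyntheticTruth:
    """Generate a scenario and write every pipeline input under ``outdir``.

    Emits: panel.vcf, genome.fa, pwms.jaspar, eqtl.tsv, tissue_map.tsv,
    index_snps.tsv, peaks/<cell_type>.<mark>.bed, truth.json and a
    manifest.json with per-file checksums.  Outputs are byte-identical
    for identical configs.
    """
    scenario = build_scenario(config)
    os.makedirs(outdir, exist_ok=True)
    peak_dir = os.path.join(outdir, "peaks")
    os.makedirs(peak_dir, exist_ok=True)

    paths = {
        "panel_vcf": os.path.join(outdir, "panel.vcf"),
        "genome_fasta": os.path.join(outdir, "genome.fa"),
        "pwm_file": os.path.join(outdir, "pwms.jaspar"),
        "eqtl_tsv": os.path.join(outdir, "eqtl.tsv"),
        "tissue_map": os.path.join(outdir, "tissue_map.tsv"),
        "index_snps": os.path.join(outdir, "index_snps.tsv"),
    }
    _write_vcf(scenario, paths["panel_vcf"])
    _write_fasta(scenario.genome, paths["genome_fasta"])
    write_jaspar(scenario.pwms, paths["pwm_file"])
    write_eqtl_tsv(scenario.eqtl_records, paths["eqtl_tsv"])
    with open(paths["tissue_map"], "w") as fh:
        fh.write("cell_type\teqtl_tissue\n")
        for a, b in scenario.tissue_map:
            fh.write(f"{a}\t{b}\n")
    _write_index_snps(scenario.index_snps, paths["index_snps"])
    bed_paths = []
    for ct, marks in scenario.peaks.items():
        for mark, intervals in marks.items():
            p = os.path.join(peak_dir, f"{ct}.{mark}.bed")
            with open(p, "w") as fh:
                for chrom, start, end in intervals:
                    fh.write(f"{chrom}\t{start}\t{end}\n")
            bed_paths.append(p)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(scenario.truth.to_jsonable(), fh, indent=1, sort_keys=True)
    manifest = {
        "seed": config.seed,
        "n_loci": config.n_loci,
        "n_tissues": config.n_tissues,
        "files": {
            os.path.relpath(p, outdir): _checksum(p)
            for p in list(paths.values()) + bed_paths
        },
        "truth_summary": {
            "n_surrogates": len(scenario.truth.surrogate_r2),
            "n_planted_tests": len(scenario.truth.planted_counts),
            "n_motif_breaks": len(scenario.truth.motif_breaks),
            "n_eqtl_plants": len(scenario.truth.eqtl_plants),
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return scenario.truth
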