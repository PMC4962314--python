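"""Hypergeometric enrichment of risk SNPs in chromatin states with FDR.

For each (locus, cell type, category) the test asks: given N background
SNPs in the window of which K fall in the category, how surprising is it
that k of the n risk SNPs do?  Draws are without replacement, so the
probability of at least k hits is the hypergeometric upper tail

    P(X >= k),   X ~ Hypergeometric(N, K, n).

Categories are the four segmentation states plus the pooled active
category EAR&PAR (a SNP counts once if its label is EAR or PAR).
P-values are Benjamini-Hochberg adjusted; the multiple-testing family is
configurable — all (cell type x category) tests within one locus
(default), or all (locus x category) tests within one cell type.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from chromenrich.errors import DataIntegrityError
from chromenrich.segmentation import SegmentationTrack, annotate_snps
from chromenrich.variants import IndexLocus, SurrogateSet, VariantRecord

logger = logging.getLogger(__name__)

ACTIVE_UNION = "EAR&PAR"
CATEGORIES = ("EAR", "PAR", "EPR", "PPR", ACTIVE_UNION)

# floor for q before taking -ln, so matrix entries stay finite
_Q_FLOOR = 1e-300


@dataclass
class EnrichmentResult:
    """One (locus, cell type, category) hypergeometric test."""

    locus_id: str
    cell_type: str
    category: str
    k: int  # risk SNPs in category
    n: int  # risk SNPs
    K: int  # background SNPs in category
    N: int  # background SNPs in window
    p: float
    q: float = math.nan

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"invalid counts k={self.k}, n={self.n}, K={self.K}")
        if self.n > self.N or self.K > self.N:
            raise ValueError(f"counts exceed background: n={self.n}, K={self.K}, N={self.N}")

    @property
    def neg_ln_q(self) -> float:
        return -math.log(max(self.q, _Q_FLOOR))

    @property
    def neg_ln_p(self) -> float:
        return -math.log(max(self.p, _Q_FLOOR))


def hypergeom_sf(k, N, K, n):
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Evaluated through a direct tail summation that keeps relative
    precision at extreme tails.  Accepts scalars or equal-shaped arrays;
    returns a float for scalar input.
    """
    k_, N_, K_, n_ = (np.asarray(a) for a in (k, N, K, n))
    if np.any((K_ < 0) | (K_ > N_) | (n_ < 0) | (n_ > N_) | (k_ < 0) | (k_ > n_)):
        raise ValueError(f"invalid hypergeometric parameters k={k}, N={N}, K={K}, n={n}")
    # sf(k-1) = P(X >= k); scipy sums the pmf tail directly, which keeps
    # full relative precision even for extreme tails
    out = np.minimum(1.0, stats.hypergeom.sf(k_ - 1, N_, K_, n_))
    out = np.where(k_ == 0, 1.0, np.where(k_ > K_, 0.0, out))
    if np.ndim(k) == 0 and np.ndim(N) == 0:
        return float(out)
    return out


def enrich(
    locus: IndexLocus,
    risk: SurrogateSet,
    background: list[VariantRecord],
    track: SegmentationTrack,
    category: str,
) -> EnrichmentResult:
    """Test one (locus, cell type, category) against the local background.

    ``background`` must contain every risk SNP (risk SNPs are themselves
    window SNPs) and lie entirely inside the locus window.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    bg_rsids = {v.rsid for v in background}
    missing = risk.rsids - bg_rsids
    if missing:
        raise DataIntegrityError(
            f"risk SNPs absent from background at locus {locus.locus_id}: {sorted(missing)[:5]}"
        )
    outside = [v.rsid for v in background if not locus.contains(v)]
    if outside:
        raise DataIntegrityError(
            f"background SNPs outside window at locus {locus.locus_id}: {outside[:5]}"
        )
    in_cat = _category_matcher(category)
    annotated = annotate_snps(background, track)
    labels = {a.variant.rsid: a.label for a in annotated}
    K = sum(1 for v in background if in_cat(labels[v.rsid]))
    k = sum(1 for r in risk.rsids if in_cat(labels[r]))
    N = len(background)
    n = len(risk)
    p = hypergeom_sf(k, N, K, n)
    return EnrichmentResult(
        locus_id=locus.locus_id, cell_type=track.cell_type, category=category,
        k=k, n=n, K=K, N=N, p=p,
    )


def _category_matcher(category: str):
    if category == ACTIVE_UNION:
        return lambda label: label in ("EAR", "PAR")
    return lambda label: label == category


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def adjust_results(
    results: list[EnrichmentResult],
    family: str = "locus",
) -> list[EnrichmentResult]:
    """BH-adjust p-values in place, grouped by the chosen testing family.

    ``family="locus"`` (default): the family is all cell types and
    categories tested at one locus.  ``family="cell_type"``: all loci and
    categories tested in one cell type.
    """
    if family not in ("locus", "cell_type"):
        raise ValueError(f"unknown FDR family {family!r}")
    keyfn = (lambda r: r.locus_id) if family == "locus" else (lambda r: r.cell_type)
    groups: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        groups.setdefault(keyfn(r), []).append(r)
    for members in groups.values():
        qs = bh_adjust([r.p for r in members])
        for r, q in zip(members, qs):
            r.q = float(q)
    return results


@dataclass
class EnrichmentMatrix:
    """Cell types x loci matrix of -ln adjusted (or raw) p-values."""

    values: pd.DataFrame  # rows: cell types, columns: locus ids
    scale: str = "neg_ln_q"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("matrix entries must be finite")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("matrix entries must be non-negative")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.index)

    @property
    def loci(self) -> list[str]:
        return list(self.values.columns)


def build_matrix(
    results: list[EnrichmentResult],
    category: str = ACTIVE_UNION,
    scale: str = "neg_ln_q",
) -> EnrichmentMatrix:
    """Assemble the cell-type x locus matrix for one category.

    Missing (locus, cell type) combinations are stored as 0; a duplicate
    test for the same combination is an error.
    """
    if scale not in ("neg_ln_q", "neg_ln_p"):
        raise ValueError(f"unknown scale {scale!r}")
    selected = [r for r in results if r.category == category]
    seen: set[tuple[str, str]] = set()
    cell_types: list[str] = []
    loci: list[str] = []
    for r in selected:
        key = (r.locus_id, r.cell_type)
        if key in seen:
            raise ValueError(f"duplicate result for locus={r.locus_id}, cell_type={r.cell_type}")
        seen.add(key)
        if r.cell_type not in cell_types:
            cell_types.append(r.cell_type)
        if r.locus_id not in loci:
            loci.append(r.locus_id)
    df = pd.DataFrame(0.0, index=cell_types, columns=loci)
    for r in selected:
        df.loc[r.cell_type, r.locus_id] = r.neg_ln_q if scale == "neg_ln_q" else r.neg_ln_p
    return EnrichmentMatrix(values=df, scale=scale)


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results: locus, cell_type, category, k, n, K, N, p, q."""
    return pd.DataFrame(
        [
            {
                "locus": r.locus_id, "cell_type": r.cell_type, "category": r.category,
                "k": r.k, "n": r.n, "K": r.K, "N": r.N, "p": r.p, "q": r.q,
            }
            for r in results
        ]
    )
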