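"""Rules-based chromatin segmentation from three histone-mark peak sets.

Three marks are used: H3K4me3 (promoters), H3K4me1 (enhancers) and
H3K27ac (activity).  Rules, in decreasing precedence:

* bases under an H3K4me3 peak are promoters — PAR (promoter active
  region) if the peak overlaps any H3K27ac interval by at least one base,
  else PPR (promoter poised region);
* bases under an H3K4me1 peak but not under any H3K4me3 peak are
  enhancers — EAR (enhancer active region) if the containing H3K4me1 peak
  overlaps H3K27ac by at least one base, else EPR (enhancer poised
  region);
* everything else is NONE.

Activity is decided at the peak level: any one-base H3K27ac overlap
activates the whole peak.  Promoter precedence is resolved base-wise
where the two methylation marks overlap.  All coordinates are BED-style
0-based half-open; SNP positions are converted from 1-based VCF.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

from chromenrich.variants import VariantRecord

H3K4ME1 = "H3K4me1"
H3K4ME3 = "H3K4me3"
H3K27AC = "H3K27ac"
MARKS = (H3K4ME1, H3K4ME3, H3K27AC)

STATE_LABELS = ("EAR", "PAR", "EPR", "PPR", "NONE")

# browser-track colours: orange for EAR, rose for PAR, light purple for
# the poised states, white for unannotated
STATE_COLORS = {
    "EAR": "255,165,0",
    "PAR": "255,102,153",
    "EPR": "204,153,255",
    "PPR": "204,153,255",
    "NONE": "255,255,255",
}

Interval = tuple[int, int]


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of intervals; touching or overlapping runs are coalesced."""
    if not intervals:
        return []
    out: list[Interval] = []
    for start, end in sorted(intervals):
        if start >= end:
            raise ValueError(f"empty or inverted interval [{start}, {end})")
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def subtract_intervals(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Set difference a \\ b for merged, sorted interval lists."""
    out: list[Interval] = []
    j = 0
    for start, end in a:
        cur = start
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < end:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < end:
            out.append((cur, end))
    return out


def overlaps_any(interval: Interval, merged: list[Interval]) -> bool:
    """True if ``interval`` shares at least one base with any of ``merged``."""
    start, end = interval
    i = bisect_right(merged, (start, float("inf"))) - 1
    if i >= 0 and merged[i][1] > start:
        return True
    return i + 1 < len(merged) and merged[i + 1][0] < end


@dataclass
class PeakSet:
    """Peak calls for one histone mark; intervals merged per chromosome."""

    mark: str
    intervals: dict[str, list[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}; expected one of {MARKS}")
        self.intervals = {c: merge_intervals(iv) for c, iv in self.intervals.items()}

    @classmethod
    def from_tuples(cls, mark: str, peaks: list[tuple[str, int, int]]) -> "PeakSet":
        by_chrom: dict[str, list[Interval]] = {}
        for chrom, start, end in peaks:
            by_chrom.setdefault(chrom, []).append((start, end))
        return cls(mark=mark, intervals=by_chrom)

    def chrom(self, chrom: str) -> list[Interval]:
        return self.intervals.get(chrom, [])

    @property
    def chroms(self) -> set[str]:
        return set(self.intervals)


@dataclass
class SegmentationTrack:
    """Disjoint labeled genomic segments for one cell type."""

    cell_type: str
    segments: list[tuple[str, int, int, str]]

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments)
        self._starts: dict[str, list[int]] = {}
        self._by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, label in self.segments:
            self._by_chrom.setdefault(chrom, []).append((start, end, label))
        for chrom, segs in self._by_chrom.items():
            self._starts[chrom] = [s for s, _, _ in segs]

    def label_at(self, chrom: str, pos0: int) -> str:
        """State label at a 0-based position; NONE when uncovered."""
        segs = self._by_chrom.get(chrom)
        if not segs:
            return "NONE"
        i = bisect_right(self._starts[chrom], pos0) - 1
        if i >= 0 and segs[i][0] <= pos0 < segs[i][1]:
            return segs[i][2]
        return "NONE"


@dataclass(frozen=True)
class AnnotatedSNP:
    """A variant labeled with its chromatin state in one cell type."""

    variant: VariantRecord
    cell_type: str
    label: str


def classify(
    h3k4me3: PeakSet,
    h3k4me1: PeakSet,
    h3k27ac: PeakSet,
    cell_type: str,
) -> SegmentationTrack:
    """Segment one cell type's genome into EAR/PAR/EPR/PPR states.

    A chromosome present in one mark but absent in another is treated as
    having no peaks for the missing marks.  Adjacent same-label segments
    are coalesced, so the output is a minimal disjoint labeling whose
    non-NONE support equals the union of the two methylation marks.
    """
    if h3k4me3.mark != H3K4ME3 or h3k4me1.mark != H3K4ME1 or h3k27ac.mark != H3K27AC:
        raise ValueError("peak sets passed in wrong order (expected me3, me1, k27ac)")
    segments: list[tuple[str, int, int, str]] = []
    for chrom in h3k4me3.chroms | h3k4me1.chroms:
        me3 = h3k4me3.chrom(chrom)
        me1 = h3k4me1.chrom(chrom)
        ac = h3k27ac.chrom(chrom)
        labeled: list[tuple[int, int, str]] = []
        for peak in me3:
            label = "PAR" if overlaps_any(peak, ac) else "PPR"
            labeled.append((*peak, label))
        for peak in me1:
            label = "EAR" if overlaps_any(peak, ac) else "EPR"
            for piece in subtract_intervals([peak], me3):
                labeled.append((*piece, label))
        labeled.sort()
        # coalesce adjacent same-label segments
        merged: list[tuple[int, int, str]] = []
        for start, end, label in labeled:
            if merged and merged[-1][2] == label and merged[-1][1] == start:
                merged[-1] = (merged[-1][0], end, label)
            else:
                merged.append((start, end, label))
        segments.extend((chrom, s, e, lab) for s, e, lab in merged)
    return SegmentationTrack(cell_type=cell_type, segments=segments)


def annotate_snps(
    variants: list[VariantRecord],
    track: SegmentationTrack,
) -> list[AnnotatedSNP]:
    """Label each SNP with the state at its 0-based position (pos - 1)."""
    return [
        AnnotatedSNP(
            variant=v, cell_type=track.cell_type, label=track.label_at(v.chrom, v.pos - 1)
        )
        for v in variants
    ]


def read_bed3(path: str, mark: str) -> PeakSet:
    """Read a BED3 peak file (extra columns ignored) into a PeakSet."""
    peaks: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed BED line: {line!r}")
            peaks.append((fields[0], int(fields[1]), int(fields[2])))
    return PeakSet.from_tuples(mark, peaks)


def write_bed4(track: SegmentationTrack, path: str, colors: bool = False) -> None:
    """Write a segmentation as BED4 (BED9 with itemRgb when colors=True)."""
    with open(path, "w") as fh:
        if colors:
            fh.write(f'track name="{track.cell_type}" itemRgb="On"\n')
        for chrom, start, end, label in track.segments:
            if colors:
                rgb = STATE_COLORS[label]
                fh.write(f"{chrom}\t{start}\t{end}\t{label}\t0\t.\t{start}\t{end}\t{rgb}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")
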