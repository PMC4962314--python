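import numpy as np
import pytest

from chromenrich.motif import PWM
from chromenrich.variants import HaplotypePanel, VariantRecord


@pytest.fixture
def toy_pwm() -> PWM:
    """Width-4 PWM with a clear consensus ACGT."""
    probs = np.array(
        [
            [0.7, 0.1, 0.1, 0.1],
            [0.1, 0.7, 0.1, 0.1],
            [0.1, 0.1, 0.7, 0.1],
            [0.1, 0.1, 0.1, 0.7],
        ]
    )
    return PWM(motif_id="TOY1", tf_name="TOY", probs=probs)


def make_panel(columns: dict[str, np.ndarray], positions: dict[str, int],
               chrom: str = "chr1") -> HaplotypePanel:
    """Panel from named binary columns at given 1-based positions."""
    rsids = list(columns)
    variants = [
        VariantRecord(rsid=r, chrom=chrom, pos=positions[r], ref="A", alt="G")
        for r in rsids
    ]
    matrix = np.stack([np.asarray(columns[r], dtype=np.int8) for r in rsids], axis=1)
    return HaplotypePanel(variants=variants, haplotypes=matrix)


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
"""


def write_vcf(path, rows: list[str]) -> str:
    path.write_text(VCF_HEADER + "".join(r + "\n" for r in rows))
    return str(path)
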