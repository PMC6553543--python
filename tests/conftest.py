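import numpy as np
import pandas as pd
import pysam
import pytest

from polyac.counting import CountMatrix
from polyac.differential import DesignSpec

# Published worked example: two same-exon poly(A)-clusters of human CD9 and
# their per-sample read counts in a six-sample knockdown study.
CD9_SAMPLES = ["Ctrl1", "Ctrl2", "Ctrl3", "CFIm25-Kd1", "CFIm25-Kd2", "CFIm25-Kd3"]
CD9_PAC_ROWS = {
    "CD9_exon_chr12:6346929_PAS-1": [5, 267, 388, 4061, 2537, 4262],
    "CD9_exon_chr12:6346929_PAS-2": [1988, 1553, 1512, 2578, 1484, 2544],
}
CD9_GENE_ROW = [1993, 1820, 1900, 6639, 4021, 6806]


@pytest.fixture
def cd9_pac_counts() -> CountMatrix:
    return CountMatrix(
        "pac",
        pd.DataFrame.from_dict(CD9_PAC_ROWS, orient="index", columns=CD9_SAMPLES),
    )


@pytest.fixture
def cd9_design() -> DesignSpec:
    return DesignSpec(CD9_SAMPLES, ["Ctrl"] * 3 + ["Kd"] * 3, reference="Ctrl")


@pytest.fixture
def sam_writer(tmp_path):
    """Factory writing a small SAM from (qname, chrom, pos0, strand, length) tuples.

    ``pos0`` is the desired 3'-end coordinate of the read (junction base).
    """

    def write(reads, chrom_lengths=None, name="reads.sam"):
        chrom_lengths = chrom_lengths or {"chr1": 100_000}
        order = sorted(chrom_lengths)
        header = pysam.AlignmentHeader.from_dict({
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": chrom_lengths[c]} for c in order],
        })
        tid = {c: i for i, c in enumerate(order)}
        path = tmp_path / name
        recs = []
        for qname, chrom, pos, strand, length in reads:
            start = pos - length + 1 if strand == "+" else pos
            recs.append((tid[chrom], start, qname, chrom, strand, length))
        recs.sort()
        with pysam.AlignmentFile(str(path), "w", header=header) as fh:
            for t, start, qname, chrom, strand, length in recs:
                a = pysam.AlignedSegment(header)
                a.query_name = qname
                a.flag = 0 if strand == "+" else 16
                a.reference_id = t
                a.reference_start = start
                a.mapping_quality = 60
                a.cigarstring = f"{length}M"
                a.query_sequence = "A" * length
                a.query_qualities = pysam.qualitystring_to_array("I" * length)
                fh.write(a)
        return str(path)

    return write
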