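"""Shared fixtures: tiny crafted genomes, SAM/BEDPE fixtures, methylation TSVs.

Everything is generated programmatically at test time; nothing binary is
stored in the repository.
"""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from mbdqc.fragio import ReferenceGenome


@pytest.fixture()
def toy_genome() -> ReferenceGenome:
    # chr1: CpGs at known positions for hand counting; chr2 CpG-free
    return ReferenceGenome(
        {
            "chr1": "ACGCGTTTACGTAAACGTTTGCATGCGTAAAA" * 40,  # 1280 bp
            "chr2": "ATTTAATTAAATTTAATTAA" * 25,  # 500 bp
        }
    )


@pytest.fixture()
def random_genome() -> ReferenceGenome:
    rng = np.random.default_rng(421)
    seq = "".join(rng.choice(list("ACGTN"), size=10_000, p=[0.28, 0.21, 0.21, 0.28, 0.02]))
    return ReferenceGenome({"rand1": seq})


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:2000\n@SQ\tSN:chr2\tLN:1000\n"


def _sam_pair(name, chrom1, pos1, chrom2, pos2, mapq1=60, mapq2=60, unmapped2=False):
    """1-based SAM positions; proper inward FR pair unless stated otherwise."""
    lines = []
    flag1 = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate reverse, first
    flag2 = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, reverse, second
    if unmapped2:
        flag1 = 0x1 | 0x8 | 0x40
        flag2 = 0x1 | 0x4 | 0x80
    seq = "A" * 45
    qual = "I" * 45
    lines.append(
        f"{name}\t{flag1}\t{chrom1}\t{pos1}\t{mapq1}\t45M\t{chrom2 if not unmapped2 else '*'}"
        f"\t{pos2 if not unmapped2 else 0}\t0\t{seq}\t{qual}"
    )
    if unmapped2:
        lines.append(f"{name}\t{flag2}\t*\t0\t0\t*\t{chrom1}\t{pos1}\t0\t{seq}\t{qual}")
    else:
        lines.append(
            f"{name}\t{flag2}\t{chrom2}\t{pos2}\t{mapq2}\t45M\t{chrom1}\t{pos1}\t0\t{seq}\t{qual}"
        )
    return "\n".join(lines) + "\n"


@pytest.fixture()
def ten_pair_sam(tmp_path):
    """Ten pairs: 3 fail uniqueness (low MAPQ x2, unmapped mate x1), 1 is
    cross-chromosome; the remaining 6 yield fragments.  Hand-enumerated:

    keep  p01 chr1 [100, 445)     keep  p04 chr1 [500, 845)
    keep  p02 chr1 [ 10, 255)     keep  p05 chr1 [ 60, 305)
    keep  p03 chr1 [100, 445)     keep  p10 chr2 [ 50, 295)
    drop  p06 (mate MAPQ 5), p07 (both MAPQ 0), p08 (mate unmapped)
    drop  p09 (mates on chr1/chr2)
    """
    text = SAM_HEADER
    text += _sam_pair("p01", "chr1", 101, "chr1", 401)
    text += _sam_pair("p02", "chr1", 11, "chr1", 211)
    text += _sam_pair("p03", "chr1", 101, "chr1", 401)  # duplicate of p01
    text += _sam_pair("p04", "chr1", 501, "chr1", 801)
    text += _sam_pair("p05", "chr1", 61, "chr1", 261)
    text += _sam_pair("p06", "chr1", 101, "chr1", 301, mapq2=5)
    text += _sam_pair("p07", "chr1", 121, "chr1", 321, mapq1=0, mapq2=0)
    text += _sam_pair("p08", "chr1", 141, "chr1", 0, unmapped2=True)
    text += _sam_pair("p09", "chr1", 101, "chr2", 301)
    text += _sam_pair("p10", "chr2", 51, "chr2", 251)
    path = tmp_path / "ten_pairs.sam"
    path.write_text(text)
    return path


@pytest.fixture()
def rrbs_six_rows(tmp_path):
    """Six stranded records forming 3 CpGs.  Hand-merged expectation:

    chr1:10  (8+2)/(10+10)  = 0.50, coverage 20
    chr1:50  (5+4)/(12+8)   = 0.45, coverage 20
    chr2:7   (0+1)/(6+4)    = 0.10, coverage 10
    """
    rows = textwrap.dedent(
        """\
        chrom\tpos\tstrand\tmeth_count\ttotal_count
        chr1\t10\t+\t8\t10
        chr1\t11\t-\t2\t10
        chr1\t50\t+\t5\t12
        chr1\t51\t-\t4\t8
        chr2\t7\t+\t0\t6
        chr2\t8\t-\t1\t4
        """
    )
    path = tmp_path / "rrbs6.tsv"
    path.write_text(rows)
    return path
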