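"""Shared fixtures: a hand-built two-gene annotation with hand-written
bedGraph coverage, small enough that every index can be recomputed by hand
or by brute force."""

from __future__ import annotations

import numpy as np
import pytest

from risekit.annotation import GenomeAnnotation, parse_gtf
from risekit.coverage import CoverageTrack


TOY_GTF = """\
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\ttest\texon\t501\t620\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr2\ttest\texon\t101\t160\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";
chr2\ttest\texon\t301\t420\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";
"""
# gA (+, chr1): exons [100,200) [300,400) [500,620); introns [200,300), [400,500)
# gB (-, chr2): exons [100,160) [300,420); intron [160,300), rank 1 (5'SS at right end)


@pytest.fixture
def toy_gtf(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    return str(path)


@pytest.fixture
def toy_annotation(toy_gtf) -> GenomeAnnotation:
    return parse_gtf(toy_gtf, contig_lengths={"chr1": 1000, "chr2": 1000})


@pytest.fixture
def toy_coverage(toy_annotation) -> CoverageTrack:
    """Hand-written coverage: constant exon depth, distinct bin depths."""
    chr1 = np.zeros(1000)
    chr1[100:200] = 25.0  # gA exon 1
    chr1[300:400] = 25.0  # gA exon 2
    chr1[500:620] = 25.0  # gA exon 3
    chr1[200:225] = 10.0  # gA intron1 5'SS bin -> index 0.4
    chr1[275:300] = 20.0  # gA intron1 3'SS bin -> index 0.8
    chr1[400:425] = 9.0  # gA intron2 5'SS bin -> index 0.36
    chr1[475:500] = 12.0  # gA intron2 3'SS bin -> index 0.48
    chr2 = np.zeros(1000)
    chr2[100:160] = 40.0  # gB exon (rank 2: genomic left on minus strand)
    chr2[300:420] = 40.0  # gB exon rank 1
    # gB intron [160,300): length 140 -> bins at [160,185) ... [275,300)
    chr2[275:300] = 30.0  # genomic-right bin = 5'SS on minus strand -> 0.75
    chr2[160:185] = 16.0  # genomic-left bin = 3'SS on minus strand -> 0.4
    return CoverageTrack.from_arrays({"chr1": chr1, "chr2": chr2}, stranded=False)
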