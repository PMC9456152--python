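"""Per-base read coverage and RISE index computation.

The RISE index of a splice site is the per-nucleotide read mean of the
intron-terminal bin at that site divided by the per-nucleotide read mean of
the adjacent exon (the transcript-orientation upstream exon for a 5' splice
site, the downstream exon for a 3' splice site). Indexes above background in
nuclear RNA-seq mark pre-mRNA splicing intermediates whose intron end has not
yet been removed.

A site is *detected* when all four filters pass: bin mean > 8 reads/nt,
intron > 50 nt, adjacent exon > 12 nt, and adjacent exon base mean > 20
(taken from a differential-exon-usage table when supplied, else from
coverage). Thresholds are strict inequalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, Intron, Side, ss_bins

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageTrack",
    "RiseThresholds",
    "per_base_coverage",
    "compute_rise_indexes",
    "condition_means",
    "positional_trend",
    "nc_enrichment",
]


class CoverageTrack:
    """Per-base read depth per contig, optionally separated by strand.

    ``data`` maps a contig name (unstranded) or ``(contig, strand)`` tuple
    (stranded) to a nonnegative per-base count vector of the contig's length.
    """

    def __init__(self, data: dict, stranded: bool):
        self.data = data
        self.stranded = stranded

    def contig_array(self, contig: str, strand: str = "+") -> np.ndarray:
        if self.stranded:
            return self.data[(contig, strand)]
        return self.data[contig]

    def region_mean(self, contig: str, start: int, end: int, strand: str = "+") -> float:
        """Mean depth per nucleotide over ``[start, end)`` on the gene strand.

        For an unstranded track the strand argument is ignored.
        """
        if end <= start:
            raise ValueError(f"empty region [{start}, {end})")
        arr = self.contig_array(contig, strand)
        return float(arr[start:end].sum()) / (end - start)

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            {k: v * factor for k, v in self.data.items()}, self.stranded
        )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_arrays(cls, data: dict, stranded: bool = False) -> "CoverageTrack":
        return cls({k: np.asarray(v, dtype=float) for k, v in data.items()}, stranded)

    @classmethod
    def from_bedgraph(
        cls, path: str, contig_lengths: dict[str, int] | None = None
    ) -> "CoverageTrack":
        """Read a bedGraph file (0-based half-open intervals) as unstranded depth.

        Overlapping intervals on a contig are rejected: bedGraph is a step
        function, not an interval list.
        """
        records: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                fields = line.split()
                if len(fields) != 4:
                    raise ValueError(
                        f"{path} line {lineno}: expected 4 fields, got {len(fields)}"
                    )
                contig, start, end, value = (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    float(fields[3]),
                )
                if end <= start:
                    raise ValueError(f"{path} line {lineno}: empty interval")
                records.setdefault(contig, []).append((start, end, value))
        data = {}
        for contig, intervals in records.items():
            intervals.sort()
            for (s1, e1, _), (s2, _e2, _) in zip(intervals, intervals[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"{path}: overlapping bedGraph intervals on {contig} "
                        f"([{s1},{e1}) and starting {s2})"
                    )
            length = intervals[-1][1]
            if contig_lengths and contig in contig_lengths:
                length = max(length, contig_lengths[contig])
            arr = np.zeros(length, dtype=float)
            for s, e, v in intervals:
                arr[s:e] = v
            data[contig] = arr
        if contig_lengths:
            for contig, length in contig_lengths.items():
                data.setdefault(contig, np.zeros(length, dtype=float))
        return cls(data, stranded=False)

    @classmethod
    def from_bam(
        cls,
        path: str,
        contig_lengths: dict[str, int] | None = None,
        stranded: bool = True,
        regions: list[tuple[str, int, int]] | None = None,
        unique_only: bool = True,
        require_proper_pair: bool = True,
    ) -> "CoverageTrack":
        """Depth from a coordinate-sorted, indexed BAM.

        Coverage is the per-base read depth of the aligned blocks of each
        read (CIGAR-aware: N gaps spanning splice junctions contribute
        nothing). Secondary/supplementary/duplicate reads are skipped;
        ``unique_only`` additionally requires ``NH == 1`` when the tag is
        present. ``require_proper_pair`` applies only to paired reads.

        In stranded mode the fragment strand follows the dUTP convention
        (read 2 carries the transcript strand; read 1 is flipped).
        """
        import pysam

        with pysam.AlignmentFile(path, "rb") as bam:
            if not bam.has_index():
                raise ValueError(f"BAM file {path} has no index (.bai)")
            lengths = dict(zip(bam.references, bam.lengths))
            if contig_lengths:
                lengths.update(contig_lengths)
            data: dict = {}

            def _arr(contig: str, strand: str) -> np.ndarray:
                key = (contig, strand) if stranded else contig
                if key not in data:
                    data[key] = np.zeros(lengths[contig], dtype=float)
                return data[key]

            if regions is None:
                iterator = [(bam.fetch(c), c) for c in bam.references]
            else:
                iterator = [(bam.fetch(c, s, e), c) for c, s, e in regions]
            for reads, contig in iterator:
                for read in reads:
                    if read.is_unmapped or read.is_secondary or read.is_supplementary:
                        continue
                    if read.is_duplicate:
                        continue
                    if read.is_paired and require_proper_pair and not read.is_proper_pair:
                        continue
                    if unique_only and read.has_tag("NH") and read.get_tag("NH") != 1:
                        continue
                    if stranded:
                        reverse = read.is_reverse
                        if read.is_paired and read.is_read1:
                            reverse = not reverse
                        strand = "-" if reverse else "+"
                    else:
                        strand = "+"
                    arr = _arr(contig, strand)
                    for bstart, bend in read.get_blocks():
                        arr[bstart:bend] += 1.0
        for contig, length in lengths.items():
            if stranded:
                for strand in "+-":
                    data.setdefault((contig, strand), np.zeros(length, dtype=float))
            else:
                data.setdefault(contig, np.zeros(length, dtype=float))
        return cls(data, stranded)


def per_base_coverage(
    alignments_or_bedgraph: str,
    regions: list[tuple[str, int, int]] | None = None,
    contig_lengths: dict[str, int] | None = None,
    **kwargs,
) -> CoverageTrack:
    """Dispatch to the BAM or bedGraph reader based on the file extension."""
    if str(alignments_or_bedgraph).endswith((".bam", ".cram")):
        return CoverageTrack.from_bam(
            alignments_or_bedgraph, contig_lengths=contig_lengths, regions=regions, **kwargs
        )
    return CoverageTrack.from_bedgraph(alignments_or_bedgraph, contig_lengths=contig_lengths)


@dataclass(frozen=True)
class RiseThresholds:
    """Detection filters; every comparison is a strict inequality."""

    bin_mean_min: float = 8.0  # reads/nt in the splice-site bin
    intron_min_len: int = 50  # nt
    exon_min_len: int = 12  # nt
    exon_basemean_min: float = 20.0  # whole-cell poly(A) exon base mean


def _usage_lookup(usage_table: pd.DataFrame | None):
    """Map (gene_id, exon_id) or exon_id -> (base mean, row) from a usage table."""
    if usage_table is None:
        return {}
    lut = {}
    for _, row in usage_table.iterrows():
        lut[str(row["featureID"])] = row
    return lut


def compute_rise_indexes(
    annotation: GenomeAnnotation,
    coverage: dict[tuple[str, str], CoverageTrack],
    usage_table: pd.DataFrame | None = None,
    thresholds: RiseThresholds = RiseThresholds(),
) -> pd.DataFrame:
    """Per-replicate RISE indexes for every splice-site bin of every intron.

    ``coverage`` maps ``(condition, replicate)`` labels to tracks. Introns
    with identical coordinates shared by several transcripts of one gene are
    collapsed to a single representative. Terminal (3'-most) introns are
    included. The 5'SS bin is compared against the transcript-orientation
    upstream exon, the 3'SS bin against the downstream exon.

    Returns one row per (site, condition, replicate) with bin and exon means,
    the index (NaN when the exon mean is 0), and the four filter flags;
    detection should be assessed on condition means (:func:`condition_means`)
    because the bin-mean threshold applies to the replicate mean.
    """
    usage_lut = _usage_lookup(usage_table)
    missing_usage = 0
    rows = []
    for intron in annotation.deduplicated_introns():
        tx = annotation.transcripts[intron.transcript_id]
        gene = annotation.genes[tx.gene_id]
        if intron.length < 13:
            continue
        bins = ss_bins(intron, gene.strand)
        exon_by_id = {e.exon_id: e for e in tx.exons}
        for side, adjacent_id in (
            (Side.FIVE_PRIME_SS, intron.upstream_exon_id),
            (Side.THREE_PRIME_SS, intron.downstream_exon_id),
        ):
            ss_bin = bins.get(side)
            if ss_bin is None:  # single-bin intron: only a 5'SS bin exists
                continue
            exon = exon_by_id[adjacent_id]
            usage_row = usage_lut.get(adjacent_id)
            if usage_table is not None and usage_row is None:
                missing_usage += 1
            for (condition, replicate), track in coverage.items():
                bin_mean = track.region_mean(
                    gene.contig, ss_bin.start, ss_bin.end, gene.strand
                )
                exon_mean = track.region_mean(gene.contig, exon.start, exon.end, gene.strand)
                index = bin_mean / exon_mean if exon_mean > 0 else np.nan
                if usage_row is not None:
                    base_mean = float(usage_row["exonBaseMean"])
                else:
                    base_mean = exon_mean
                rows.append(
                    {
                        "site_id": f"{intron.intron_id}|{side.value}",
                        "gene_id": tx.gene_id,
                        "transcript_id": tx.transcript_id,
                        "intron_id": intron.intron_id,
                        "side": side.value,
                        "bin_start": ss_bin.start,
                        "bin_end": ss_bin.end,
                        "bin_len": ss_bin.length,
                        "bin_mean": bin_mean,
                        "exon_id": exon.exon_id,
                        "exon_len": exon.length,
                        "exon_mean": exon_mean,
                        "exon_base_mean": base_mean,
                        "index": index,
                        "condition": condition,
                        "replicate": replicate,
                        "intron_len": intron.length,
                        "bin_mean_pass": bin_mean > thresholds.bin_mean_min,
                        "intron_len_pass": intron.length > thresholds.intron_min_len,
                        "exon_len_pass": exon.length > thresholds.exon_min_len,
                        "exon_basemean_pass": exon_mean > 0
                        and base_mean > thresholds.exon_basemean_min,
                    }
                )
    if missing_usage:
        logger.info(
            "%d splice-site/exon lookups absent from the usage table; "
            "exon base mean taken from coverage for those",
            missing_usage,
        )
    return pd.DataFrame(rows)


def condition_means(
    table: pd.DataFrame, thresholds: RiseThresholds = RiseThresholds()
) -> pd.DataFrame:
    """Collapse a replicate-level index table to per-(site, condition) means.

    Bin and exon means are averaged over replicates, the index is the mean of
    replicate indexes, and filter flags are re-evaluated on the averaged
    values (the bin-mean filter applies to the replicate mean). The
    ``detected`` column is the conjunction of the four flags.
    """
    keys = [
        "site_id",
        "gene_id",
        "transcript_id",
        "intron_id",
        "side",
        "exon_id",
        "condition",
    ]
    grouped = (
        table.groupby(keys, as_index=False)
        .agg(
            bin_mean=("bin_mean", "mean"),
            exon_mean=("exon_mean", "mean"),
            exon_base_mean=("exon_base_mean", "mean"),
            index=("index", "mean"),
            intron_len=("intron_len", "first"),
            exon_len=("exon_len", "first"),
            bin_start=("bin_start", "first"),
            bin_end=("bin_end", "first"),
            n_replicates=("replicate", "nunique"),
        )
    )
    grouped["bin_mean_pass"] = grouped["bin_mean"] > thresholds.bin_mean_min
    grouped["intron_len_pass"] = grouped["intron_len"] > thresholds.intron_min_len
    grouped["exon_len_pass"] = grouped["exon_len"] > thresholds.exon_min_len
    grouped["exon_basemean_pass"] = (grouped["exon_mean"] > 0) & (
        grouped["exon_base_mean"] > thresholds.exon_basemean_min
    )
    grouped["detected"] = (
        grouped["bin_mean_pass"]
        & grouped["intron_len_pass"]
        & grouped["exon_len_pass"]
        & grouped["exon_basemean_pass"]
    )
    return grouped


def positional_trend(
    cond_means: pd.DataFrame,
    annotation: GenomeAnnotation,
    condition: str,
    five_prime_fraction: float = 0.40,
    three_prime_fraction: float = 0.20,
) -> dict:
    """Compare RISE indexes of 5'-end vs 3'-end exons of genes.

    Each detected site is assigned the relative position of its adjacent exon
    within its transcript (rank / exon count, transcript orientation). The 5'
    class holds sites with relative position <= ``five_prime_fraction``; the
    3' class those with relative position > 1 - ``three_prime_fraction``.
    Splicing completes 5'-to-3' on nascent transcripts, so intermediates —
    and hence indexes — accumulate toward the 3' end.

    Returns per-class mean, SEM and n plus a two-tailed two-sample t-test.
    """
    from scipy import stats

    sub = cond_means[(cond_means["condition"] == condition) & cond_means["detected"]]
    classes: dict[str, list[float]] = {"five_prime": [], "three_prime": []}
    for _, row in sub.iterrows():
        tx = annotation.transcripts[row["transcript_id"]]
        exon = next(e for e in tx.exons if e.exon_id == row["exon_id"])
        rel = exon.rank / len(tx.exons)
        if rel <= five_prime_fraction:
            classes["five_prime"].append(row["index"])
        elif rel > 1.0 - three_prime_fraction:
            classes["three_prime"].append(row["index"])
    out: dict = {}
    for name, vals in classes.items():
        arr = np.asarray(vals, dtype=float)
        out[name] = {
            "mean": float(arr.mean()) if arr.size else np.nan,
            "sem": float(stats.sem(arr)) if arr.size >= 2 else np.nan,
            "n": int(arr.size),
            "sem_defined": arr.size >= 2,
        }
    a, b = classes["five_prime"], classes["three_prime"]
    if len(a) >= 2 and len(b) >= 2:
        t, p = stats.ttest_ind(a, b)
        if np.isnan(t) and np.isclose(np.mean(a), np.mean(b)):
            t, p = 0.0, 1.0  # both classes constant and equal
        out["t_statistic"], out["p_value"] = float(t), float(p)
    else:
        out["t_statistic"], out["p_value"] = np.nan, np.nan
    return out


def nc_enrichment(
    nuclear_counts: pd.Series, cytoplasmic_counts: pd.Series
) -> pd.DataFrame:
    """Nuclear/cytoplasmic enrichment ratios per transcript.

    ratio = (count_N / library_N) / (count_C / library_C), with a 0.5-count
    continuity offset applied to zero counts. Transcripts absent from either
    table are omitted (the omission count is logged). Known nuclear RNAs
    (snRNAs, scaRNAs, 7SK) should show ratios orders of magnitude above 1;
    spliced cytoplasmic mRNAs below 1 — the fractionation quality control.
    """
    nuclear_counts = nuclear_counts.astype(float)
    cytoplasmic_counts = cytoplasmic_counts.astype(float)
    if (nuclear_counts < 0).any() or (cytoplasmic_counts < 0).any():
        raise ValueError("counts must be nonnegative")
    lib_n, lib_c = nuclear_counts.sum(), cytoplasmic_counts.sum()
    if lib_n <= 0 or lib_c <= 0:
        raise ValueError("library sizes must be positive")
    shared = nuclear_counts.index.intersection(cytoplasmic_counts.index)
    omitted = (len(nuclear_counts) - len(shared)) + (len(cytoplasmic_counts) - len(shared))
    if omitted:
        logger.info("%d transcripts absent from one table omitted from N/C ratios", omitted)
    n = nuclear_counts.loc[shared].where(nuclear_counts.loc[shared] > 0, 0.5)
    c = cytoplasmic_counts.loc[shared].where(cytoplasmic_counts.loc[shared] > 0, 0.5)
    ratio = (n / lib_n) / (c / lib_c)
    return pd.DataFrame(
        {
            "nuclear": nuclear_counts.loc[shared],
            "cytoplasmic": cytoplasmic_counts.loc[shared],
            "nc_ratio": ratio,
        }
    )
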