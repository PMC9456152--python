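"""Coverage extraction and RISE index computation."""

import numpy as np
import pandas as pd
import pytest

from risekit.annotation import Exon, Gene, GenomeAnnotation, Transcript, derive_introns
from risekit.coverage import (
    CoverageTrack,
    RiseThresholds,
    compute_rise_indexes,
    condition_means,
    nc_enrichment,
    positional_trend,
)

# hand-derived bin/exon intervals of the toy fixture (genomic, 0-based)
TOY_EXPECTED = {
    # site_id: (bin interval, exon interval)
    "gA.t1:intron1|5SS": ((200, 225), (100, 200)),
    "gA.t1:intron1|3SS": ((275, 300), (300, 400)),
    "gA.t1:intron2|5SS": ((400, 425), (300, 400)),
    "gA.t1:intron2|3SS": ((475, 500), (500, 620)),
    "gB.t1:intron1|5SS": ((285, 300), (300, 420)),  # minus strand: genomic right
    "gB.t1:intron1|3SS": ((160, 185), (100, 160)),
}
TOY_CONTIG = {
    "gA.t1:intron1|5SS": "chr1",
    "gA.t1:intron1|3SS": "chr1",
    "gA.t1:intron2|5SS": "chr1",
    "gA.t1:intron2|3SS": "chr1",
    "gB.t1:intron1|5SS": "chr2",
    "gB.t1:intron1|3SS": "chr2",
}


class TestBedGraph:
    def test_interval_fill(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t100\t110\t7\n")
        track = CoverageTrack.from_bedgraph(str(p), {"chr1": 200})
        arr = track.contig_array("chr1")
        assert arr[99] == 0 and arr[110] == 0
        assert np.all(arr[100:110] == 7)

    def test_overlapping_intervals_rejected(self, tmp_path):
        p = tmp_path / "b.bedgraph"
        p.write_text("chr1\t100\t110\t7\nchr1\t105\t120\t3\n")
        with pytest.raises(ValueError, match="overlap"):
            CoverageTrack.from_bedgraph(str(p))


class TestBamCoverage:
    @pytest.fixture
    def bam(self, tmp_path):
        import pysam

        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "chr1", "LN": 5000}]}
        path = str(tmp_path / "toy.bam")
        with pysam.AlignmentFile(path, "wb", header=header) as out:
            a = pysam.AlignedSegment(out.header)
            a.query_name = "plain"
            a.query_sequence = "A" * 50
            a.flag = 0
            a.reference_id = 0
            a.reference_start = 100
            a.mapping_quality = 60
            a.cigarstring = "50M"
            out.write(a)
            b = pysam.AlignedSegment(out.header)
            b.query_name = "spliced"
            b.query_sequence = "A" * 50
            b.flag = 0
            b.reference_id = 0
            b.reference_start = 300
            b.mapping_quality = 60
            b.cigarstring = "20M1000N30M"
            out.write(b)
        pysam.index(path)
        return path

    def test_ungapped_read_adds_one_over_span(self, bam):
        track = CoverageTrack.from_bam(bam, stranded=False)
        arr = track.contig_array("chr1")
        assert np.all(arr[100:150] == 1)
        assert arr[99] == 0 and arr[150] == 0

    def test_spliced_read_skips_n_gap(self, bam):
        track = CoverageTrack.from_bam(bam, stranded=False)
        arr = track.contig_array("chr1")
        assert np.all(arr[300:320] == 1)
        assert np.all(arr[320:1320] == 0)
        assert np.all(arr[1320:1350] == 1)

    def test_unindexed_bam_raises_naming_file(self, tmp_path, bam):
        import shutil

        orphan = str(tmp_path / "orphan.bam")
        shutil.copy(bam, orphan)
        with pytest.raises(ValueError, match="orphan.bam"):
            CoverageTrack.from_bam(orphan)


class TestRiseIndexes:
    def test_matches_brute_force_recomputation(self, toy_annotation, toy_coverage):
        """Indexes equal an independent per-base recomputation exactly."""
        table = compute_rise_indexes(
            toy_annotation, {("NT", "rep1"): toy_coverage}, None
        )
        assert set(table["site_id"]) == set(TOY_EXPECTED)
        for row in table.itertuples():
            (bs, be), (es, ee) = TOY_EXPECTED[row.site_id]
            arr = toy_coverage.contig_array(TOY_CONTIG[row.site_id])
            bin_mean = sum(float(arr[i]) for i in range(bs, be)) / (be - bs)
            exon_mean = sum(float(arr[i]) for i in range(es, ee)) / (ee - es)
            assert row.bin_mean == bin_mean
            assert row.exon_mean == exon_mean
            assert row.index == bin_mean / exon_mean

    def test_hand_computed_index_values(self, toy_annotation, toy_coverage):
        table = compute_rise_indexes(
            toy_annotation, {("NT", "rep1"): toy_coverage}, None
        )
        idx = table.set_index("site_id")["index"]
        assert idx["gA.t1:intron1|5SS"] == pytest.approx(10 / 25)
        assert idx["gA.t1:intron1|3SS"] == pytest.approx(20 / 25)
        assert idx["gB.t1:intron1|5SS"] == pytest.approx(30 / 40)
        assert idx["gB.t1:intron1|3SS"] == pytest.approx(16 / 40)

    def test_bin_mean_threshold_is_strict(self, toy_annotation):
        """A bin mean of exactly 8 reads/nt fails the 'more than 8' filter."""
        chr1 = np.zeros(1000)
        chr1[100:200] = 25.0
        chr1[300:400] = 25.0
        chr1[500:620] = 25.0
        chr1[200:225] = 8.0  # exactly at the threshold
        chr1[275:300] = 8.0001
        cov = CoverageTrack.from_arrays({"chr1": chr1, "chr2": np.zeros(1000)})
        table = compute_rise_indexes(toy_annotation, {("NT", "r1"): cov}, None)
        flags = table.set_index("site_id")["bin_mean_pass"]
        assert not flags["gA.t1:intron1|5SS"]
        assert flags["gA.t1:intron1|3SS"]

    def test_zero_bin_mean_gives_zero_index_and_fails(self, toy_annotation):
        chr1 = np.zeros(1000)
        chr1[100:200] = 25.0
        chr1[300:400] = 25.0
        chr1[500:620] = 25.0
        cov = CoverageTrack.from_arrays({"chr1": chr1, "chr2": np.zeros(1000)})
        table = compute_rise_indexes(toy_annotation, {("NT", "r1"): cov}, None)
        row = table[table.site_id == "gA.t1:intron1|5SS"].iloc[0]
        assert row["index"] == 0.0
        assert not row["bin_mean_pass"]

    def test_zero_exon_mean_gives_undefined_index(self, toy_annotation):
        chr1 = np.zeros(1000)
        chr1[200:225] = 10.0  # bin covered, exon empty
        cov = CoverageTrack.from_arrays({"chr1": chr1, "chr2": np.zeros(1000)})
        table = compute_rise_indexes(toy_annotation, {("NT", "r1"): cov}, None)
        row = table[table.site_id == "gA.t1:intron1|5SS"].iloc[0]
        assert np.isnan(row["index"])
        assert not row["exon_basemean_pass"]

    def test_scale_invariance(self, toy_annotation, toy_coverage):
        """Multiplying all coverage by a constant leaves every index unchanged."""
        t1 = compute_rise_indexes(toy_annotation, {("NT", "r1"): toy_coverage}, None)
        t2 = compute_rise_indexes(
            toy_annotation, {("NT", "r1"): toy_coverage.scaled(7.3)}, None
        )
        assert np.allclose(t1["index"], t2["index"])

    def test_monotone_filter_property(self, toy_annotation, toy_coverage):
        """Raising any threshold never enlarges the detected-site set."""
        base = RiseThresholds()
        table = compute_rise_indexes(
            toy_annotation, {("NT", "r1"): toy_coverage}, None, base
        )
        detected0 = set(
            condition_means(table, base).query("detected")["site_id"]
        )
        for stricter in (
            RiseThresholds(bin_mean_min=15),
            RiseThresholds(intron_min_len=120),
            RiseThresholds(exon_min_len=100),
            RiseThresholds(exon_basemean_min=30),
        ):
            t = compute_rise_indexes(
                toy_annotation, {("NT", "r1"): toy_coverage}, None, stricter
            )
            detected = set(condition_means(t, stricter).query("detected")["site_id"])
            assert detected <= detected0

    def test_replicate_means_average_indexes(self, toy_annotation, toy_coverage):
        cov2 = toy_coverage.scaled(1.0)
        cov2.data["chr1"] = toy_coverage.data["chr1"].copy()
        cov2.data["chr1"][200:225] = 20.0  # rep2 bin mean 20 vs rep1 10
        table = compute_rise_indexes(
            toy_annotation, {("NT", "rep1"): toy_coverage, ("NT", "rep2"): cov2}, None
        )
        means = condition_means(table).set_index("site_id")
        assert means.loc["gA.t1:intron1|5SS", "index"] == pytest.approx(
            (10 / 25 + 20 / 25) / 2
        )
        assert means.loc["gA.t1:intron1|5SS", "n_replicates"] == 2


def _grid_annotation(n_genes: int, intron_len=100, exon_len=100):
    """n identical two-exon genes, ten per contig."""
    ann = GenomeAnnotation()
    per_contig = 10
    gene_span = exon_len * 2 + intron_len + 200
    for g in range(n_genes):
        contig = f"c{g // per_contig}"
        offset = (g % per_contig) * gene_span + 100
        gene_id, tx_id = f"g{g}", f"g{g}.t1"
        exons = [
            Exon(f"{tx_id}:exon1", tx_id, offset, offset + exon_len, 1),
            Exon(
                f"{tx_id}:exon2",
                tx_id,
                offset + exon_len + intron_len,
                offset + 2 * exon_len + intron_len,
                2,
            ),
        ]
        tx = Transcript(tx_id, gene_id, exons=exons)
        tx.introns = derive_introns(exons, "+", tx_id)
        ann.transcripts[tx_id] = tx
        ann.genes[gene_id] = Gene(gene_id, contig, "+", exons[0].start, exons[-1].end, [tx_id])
        ann.contigs[contig] = per_contig * gene_span + 200
    return ann


def test_poisson_parameter_recovery():
    """Poisson(E) exons and Poisson(E*d) bins, E=100, d=0.3, 200 sites:
    the mean estimated index lies within 3 SE of 0.3."""
    rng = np.random.default_rng(42)
    ann = _grid_annotation(100)  # 100 introns -> 200 splice sites
    data = {c: np.zeros(L) for c, L in ann.contigs.items()}
    E, d = 100.0, 0.3
    for tx in ann.transcripts.values():
        gene = ann.genes[tx.gene_id]
        arr = data[gene.contig]
        for e in tx.exons:
            arr[e.start:e.end] = rng.poisson(E, e.length)
        intron = tx.introns[0]
        arr[intron.start:intron.end] = 0.0
        from risekit.annotation import ss_bins

        for b in ss_bins(intron, "+").values():
            arr[b.start:b.end] = rng.poisson(E * d, b.length)
    cov = CoverageTrack.from_arrays(data)
    table = compute_rise_indexes(ann, {("NT", "r1"): cov}, None)
    est = table["index"].to_numpy()
    assert len(est) == 200
    se = est.std(ddof=1) / np.sqrt(len(est))
    assert abs(est.mean() - d) < 3 * se


class TestPositionalTrend:
    @staticmethod
    def _ten_exon_annotation():
        ann = GenomeAnnotation()
        tx_id = "g.t1"
        exons = [Exon(f"{tx_id}:exon{i+1}", tx_id, i * 200, i * 200 + 100, i + 1) for i in range(10)]
        tx = Transcript(tx_id, "g", exons=exons)
        tx.introns = derive_introns(exons, "+", tx_id)
        ann.transcripts[tx_id] = tx
        ann.genes["g"] = Gene("g", "c0", "+", 0, exons[-1].end, [tx_id])
        ann.contigs["c0"] = 3000
        return ann

    @staticmethod
    def _fake_sites(index_by_exon_rank, condition="NT"):
        rows = []
        for i, (rank, idx) in enumerate(index_by_exon_rank):
            rows.append(
                {
                    "site_id": f"s{i}",
                    "condition": condition,
                    "detected": True,
                    "index": idx,
                    "transcript_id": "g.t1",
                    "exon_id": f"g.t1:exon{rank}",
                }
            )
        return pd.DataFrame(rows)

    def test_recovers_simulated_class_means(self):
        """Class means 0.2 (5' 40% of exons) vs 0.4 (3' 20%) are recovered
        within 3 SEM at n = 60 per class."""
        rng = np.random.default_rng(7)
        ann = self._ten_exon_annotation()
        entries = [(rng.integers(1, 5), rng.normal(0.2, 0.1)) for _ in range(60)]
        entries += [(rng.integers(9, 11), rng.normal(0.4, 0.1)) for _ in range(60)]
        res = positional_trend(self._fake_sites(entries), ann, "NT")
        assert res["five_prime"]["n"] == 60 and res["three_prime"]["n"] == 60
        assert abs(res["five_prime"]["mean"] - 0.2) < 3 * res["five_prime"]["sem"]
        assert abs(res["three_prime"]["mean"] - 0.4) < 3 * res["three_prime"]["sem"]
        assert res["p_value"] < 1e-6

    def test_equal_indexes_give_equal_means_and_p_one(self):
        ann = self._ten_exon_annotation()
        entries = [(2, 0.3)] * 10 + [(10, 0.3)] * 10
        res = positional_trend(self._fake_sites(entries), ann, "NT")
        assert res["five_prime"]["mean"] == res["three_prime"]["mean"]
        assert res["p_value"] == pytest.approx(1.0)

    def test_small_class_flags_undefined_sem(self):
        ann = self._ten_exon_annotation()
        res = positional_trend(self._fake_sites([(2, 0.3), (10, 0.1), (10, 0.2)]), ann, "NT")
        assert not res["five_prime"]["sem_defined"]


class TestNcEnrichment:
    def test_equal_normalized_counts_give_ratio_one(self):
        n = pd.Series({"t1": 50, "t2": 50})
        c = pd.Series({"t1": 50, "t2": 50})
        out = nc_enrichment(n, c)
        assert np.allclose(out["nc_ratio"], 1.0)

    def test_hundredfold_enrichment(self):
        n = pd.Series({"t1": 900, "rest": 10**6 - 900})
        c = pd.Series({"t1": 9, "rest": 10**6 - 9})
        out = nc_enrichment(n, c)
        assert out.loc["t1", "nc_ratio"] == pytest.approx(100.0, rel=1e-3)

    def test_zero_count_continuity_offset(self):
        n = pd.Series({"t1": 10, "t2": 90})
        c = pd.Series({"t1": 0, "t2": 100})
        out = nc_enrichment(n, c)
        assert out.loc["t1", "nc_ratio"] == pytest.approx((10 / 100) / (0.5 / 100))

    def test_missing_transcripts_omitted(self):
        n = pd.Series({"t1": 10, "only_n": 5})
        c = pd.Series({"t1": 10, "only_c": 5})
        out = nc_enrichment(n, c)
        assert list(out.index) == ["t1"]
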