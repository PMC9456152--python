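"""Synthetic nuclear RNA-seq data with known splicing-delay ground truth.

The generator emulates the data-generating assumptions behind the RISE
analysis: multi-exon genes whose intron-terminal bins accumulate reads in
proportion to a latent per-splice-site *delay fraction* d (the fraction of
transcripts whose intron end is still unspliced), with

* designed correlation of delays within intron-definition (type I) pairs
  (rho_I) and exon-definition (type II) pairs (rho_II), generated on the
  logit scale so d stays in (0, 1);
* inverse coupling of exon usage to the local delay;
* Poisson read noise on per-base coverage (exon bases at the gene's
  expression E reads/nt, splice-site bins at E*d, intron bodies at a small
  background fraction of E);
* three conditions — NT, KCl (a multiplicative delay shift on a regulated
  subset of sites), and KCl+5azaC (the KCl shift attenuated) — in
  triplicate.

Every quantity is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .annotation import (
    Exon,
    Gene,
    GenomeAnnotation,
    Side,
    Transcript,
    derive_introns,
    ss_bins,
    write_gtf,
)
from .coverage import CoverageTrack

__all__ = ["SimConfig", "SimTruth", "simulate_annotation", "simulate_site_delays",
           "simulate_coverage", "write_fasta", "write_bedgraph"]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults emulate a nuclear RNA-seq experiment over a compact synthetic
    genome: gene structures with log-normal exon (~120 nt median) and intron
    (~400 nt median) lengths, splice-site delay fractions around 0.25 with
    pairing correlations rho_I = 0.4 < rho_II = 0.7 (exon definition couples
    sites more tightly than intron definition), mean expression ~100
    reads/nt, a 1.5x KCl delay shift on a 20% regulated subset, and 5azaC
    attenuating 80% of that shift. Three replicates per condition.
    """

    n_genes: int = 120
    exons_per_gene: tuple[int, int] = (4, 9)  # inclusive uniform range
    exon_len_log_mean: float = math.log(120.0)
    exon_len_log_sd: float = 0.45
    min_exon_len: int = 20
    intron_len_log_mean: float = math.log(400.0)
    intron_len_log_sd: float = 0.7
    min_intron_len: int = 60
    genes_per_contig: int = 20
    intergenic_gap: int = 200
    frac_type_i: float = 0.5  # fraction of introns carrying a type I pair
    frac_type_ii: float = 0.4  # fraction of internal exons carrying a type II pair
    rho_i: float = 0.4
    rho_ii: float = 0.7
    delay_logit_mean: float = -1.1  # logit(0.25)
    delay_logit_sd: float = 0.8
    usage_base_range: tuple[float, float] = (0.6, 0.95)
    usage_coupling: float = 0.5  # psi = base - coupling * local delay
    expression_log_mean: float = math.log(100.0)  # reads/nt
    expression_log_sd: float = 0.5
    background: float = 0.01  # intron-body coverage as a fraction of E
    conditions: tuple[str, ...] = ("NT", "KCl", "KCl_5azaC")
    replicates: int = 3
    kcl_shift: float = 1.5  # multiplicative delay shift in KCl
    regulated_fraction: float = 0.2  # fraction of sites carrying the shift
    azac_attenuation: float = 0.8  # fraction of the KCl shift removed by 5azaC
    max_delay: float = 0.95
    #: probability that a non-anchor splice-site window position carries the
    #: canonical template base (the GT/AG anchors are always written); 1.0
    #: reproduces the template at every site
    consensus_fidelity: float = 0.85
    #: per-window-position probability that the base deviates from the
    #: canonical splice-site consensus, overriding ``consensus_fidelity``
    #: at that position; keys are window position labels
    deviation_probs_5ss: dict = field(default_factory=dict)
    deviation_probs_3ss: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_type_i", "frac_type_ii", "regulated_fraction",
                     "azac_attenuation", "background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("rho_i", "rho_ii"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1], got {v}")
        if self.min_intron_len < 13:
            raise ValueError("min_intron_len must be >= 13 (shortest binnable intron)")


@dataclass
class SimTruth:
    """Latent ground truth of one simulated experiment."""

    sites: pd.DataFrame  # per splice site: delays per condition, regulation
    exons: pd.DataFrame  # per exon: usage per condition
    genes: pd.DataFrame  # per gene: expression (reads/nt)
    pairs: pd.DataFrame  # assigned type I/II pairings
    conditions: tuple[str, ...]


# canonical splice-site window templates (donor CAG|GTAAGTAAGT exon|intron,
# acceptor polypyrimidine ... AG|GT); only positions actually written to the
# genome when embedding deviations — the invariant GT/AG is always written.
_DONOR_TEMPLATE = "CAGGTAAGTAAGT"  # 3 exonic + 10 intronic
_ACCEPTOR_TEMPLATE = "TTTTTTTTTTTTCTTTTCAGGT"  # 20 intronic + 2 exonic
_DONOR_ANCHORS = frozenset({1, 2})  # the invariant GT
_ACCEPTOR_ANCHORS = frozenset({-2, -1})  # the invariant AG


def _draw_lengths(rng, n, log_mean, log_sd, minimum):
    raw = np.exp(rng.normal(log_mean, log_sd, size=n))
    return np.maximum(np.round(raw).astype(int), minimum)


def simulate_annotation(
    config: SimConfig, seed: int | None = None
) -> tuple[GenomeAnnotation, dict[str, str]]:
    """Random gene structures and a genome with consensus splice sites.

    Genes are laid head-to-tail (random strand) on contigs of up to
    ``genes_per_contig`` genes. Intron boundaries receive the invariant
    GT..AG dinucleotides (strand-aware); ``deviation_probs_*`` introduce
    per-position deviations from the canonical window templates to create
    weak sites. Returns the annotation and a contig -> sequence dict.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ann = GenomeAnnotation()
    contig_seqs: dict[str, list] = {}
    contig_id, genes_on_contig, cursor = 0, 0, 0

    for g in range(config.n_genes):
        if genes_on_contig == 0:
            contig_id += 1
            cursor = config.intergenic_gap
        contig = f"chr{contig_id}"
        gene_id = f"g{g + 1:04d}"
        tx_id = f"{gene_id}.t1"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = _draw_lengths(
            rng, n_exons, config.exon_len_log_mean, config.exon_len_log_sd,
            config.min_exon_len,
        )
        intron_lens = _draw_lengths(
            rng, n_exons - 1, config.intron_len_log_mean, config.intron_len_log_sd,
            config.min_intron_len,
        )
        exons = []
        pos = cursor
        for i in range(n_exons):
            start, end = pos, pos + int(exon_lens[i])
            rank = i + 1 if strand == "+" else n_exons - i
            exons.append(Exon(f"{tx_id}:exon{rank}", tx_id, start, end, rank))
            pos = end + (int(intron_lens[i]) if i < n_exons - 1 else 0)
        tx = Transcript(tx_id, gene_id, exons=exons)
        tx.introns = derive_introns(exons, strand, tx_id)
        ann.transcripts[tx_id] = tx
        ann.genes[gene_id] = Gene(
            gene_id, contig, strand, exons[0].start, exons[-1].end, [tx_id]
        )
        cursor = exons[-1].end + config.intergenic_gap
        genes_on_contig += 1
        if genes_on_contig >= config.genes_per_contig:
            ann.contigs[contig] = cursor
            genes_on_contig = 0
        else:
            ann.contigs[contig] = cursor

    # genome: random bases, then splice-site sequences
    for contig, length in ann.contigs.items():
        contig_seqs[contig] = list(rng.choice(list("ACGT"), size=length))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    base_dev = 1.0 - config.consensus_fidelity

    def _write_window(contig, genomic_positions, template_bases, strand, dev_probs,
                      labels, anchors):
        seq = contig_seqs[contig]
        for pos, base, label in zip(genomic_positions, template_bases, labels):
            written = base if strand == "+" else comp[base]
            p_dev = dev_probs.get(label, 0.0 if label in anchors else base_dev)
            if p_dev > 0 and rng.random() < p_dev:
                alternatives = [b for b in "ACGT" if b != written]
                written = alternatives[int(rng.integers(3))]
            seq[pos] = written

    donor_labels = list(range(-3, 0)) + list(range(1, 11))
    acceptor_labels = list(range(-20, 0)) + [1, 2]
    for tx in ann.transcripts.values():
        gene = ann.genes[tx.gene_id]
        for intron in tx.introns:
            s, e = intron.start, intron.end
            if gene.strand == "+":
                # donor window genomic [s-3, s+10), template in genomic order
                _write_window(
                    gene.contig, range(s - 3, s + 10), _DONOR_TEMPLATE, "+",
                    config.deviation_probs_5ss, donor_labels, _DONOR_ANCHORS,
                )
                _write_window(
                    gene.contig, range(e - 20, e + 2), _ACCEPTOR_TEMPLATE, "+",
                    config.deviation_probs_3ss, acceptor_labels, _ACCEPTOR_ANCHORS,
                )
            else:
                # donor at genomic right end: template positions run right-to-left
                _write_window(
                    gene.contig, range(e + 2, e - 11, -1), _DONOR_TEMPLATE, "-",
                    config.deviation_probs_5ss, donor_labels, _DONOR_ANCHORS,
                )
                _write_window(
                    gene.contig, range(s + 19, s - 3, -1), _ACCEPTOR_TEMPLATE, "-",
                    config.deviation_probs_3ss, acceptor_labels, _ACCEPTOR_ANCHORS,
                )
    genome = {c: "".join(s) for c, s in contig_seqs.items()}
    return ann, genome


def simulate_site_delays(
    config: SimConfig, annotation: GenomeAnnotation, seed: int | None = None
) -> SimTruth:
    """Assign pairings and draw correlated latent delays, usage, expression.

    Delays are standard-normal z-scores on the logit scale, mapped through
    d = expit(mu + sigma * z). Each assigned pair's members are drawn with
    the target correlation; when a site already carries a z from an earlier
    pair (a mixed site shared between a type I and a type II pair), its
    partner is drawn conditionally (z2 = rho*z1 + sqrt(1-rho^2)*eps), which
    preserves the pairwise correlation exactly. Regulated sites multiply
    their delay by ``kcl_shift`` in KCl; 5azaC removes ``azac_attenuation``
    of that shift. Exon usage is base usage minus ``usage_coupling`` times
    the mean delay of the exon's flanking sites, clipped to [0.02, 0.99].
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    z: dict[str, float] = {}
    site_meta: dict[str, dict] = {}
    pair_rows = []

    def _site(intron, side: Side, adjacent_exon_id: str, tx: Transcript):
        sid = f"{intron.intron_id}|{side.value}"
        if sid not in site_meta:
            site_meta[sid] = {
                "site_id": sid,
                "gene_id": tx.gene_id,
                "transcript_id": tx.transcript_id,
                "intron_id": intron.intron_id,
                "side": side.value,
                "exon_id": adjacent_exon_id,
            }
        return sid

    def _draw_pair(s1: str, s2: str, rho: float):
        if s1 in z and s2 in z:
            return
        if s1 not in z and s2 not in z:
            z1 = rng.normal()
            z[s1] = z1
            z[s2] = rho * z1 + math.sqrt(1 - rho * rho) * rng.normal()
        else:
            anchor, new = (s1, s2) if s1 in z else (s2, s1)
            z[new] = rho * z[anchor] + math.sqrt(1 - rho * rho) * rng.normal()

    for tx_id in sorted(annotation.transcripts):
        tx = annotation.transcripts[tx_id]
        by_rank = sorted(tx.introns, key=lambda i: i.rank)
        exon_by_id = {e.exon_id: e for e in tx.exons}
        type_i = {i.intron_id: rng.random() < config.frac_type_i for i in by_rank}
        type_ii = {}
        for up, down in zip(by_rank, by_rank[1:]):
            type_ii[(up.intron_id, down.intron_id)] = rng.random() < config.frac_type_ii
        for k, intron in enumerate(by_rank):
            s5 = _site(intron, Side.FIVE_PRIME_SS, intron.upstream_exon_id, tx)
            s3 = _site(intron, Side.THREE_PRIME_SS, intron.downstream_exon_id, tx)
            if type_i[intron.intron_id]:
                _draw_pair(s5, s3, config.rho_i)
                pair_rows.append(
                    {
                        "pair_type": "I",
                        "gene_id": tx.gene_id,
                        "element_id": intron.intron_id,
                        "element_len": intron.length,
                        "five_site_id": s5,
                        "three_site_id": s3,
                    }
                )
            if k + 1 < len(by_rank):
                down = by_rank[k + 1]
                if type_ii[(intron.intron_id, down.intron_id)]:
                    exon = exon_by_id[intron.downstream_exon_id]
                    s3_up = _site(intron, Side.THREE_PRIME_SS, intron.downstream_exon_id, tx)
                    s5_down = _site(down, Side.FIVE_PRIME_SS, down.upstream_exon_id, tx)
                    _draw_pair(s3_up, s5_down, config.rho_ii)
                    pair_rows.append(
                        {
                            "pair_type": "II",
                            "gene_id": tx.gene_id,
                            "element_id": exon.exon_id,
                            "element_len": exon.length,
                            "five_site_id": s5_down,
                            "three_site_id": s3_up,
                        }
                    )
    for sid in sorted(site_meta):
        if sid not in z:
            z[sid] = rng.normal()

    site_ids = sorted(site_meta)
    zs = np.array([z[s] for s in site_ids])
    d_nt = expit(config.delay_logit_mean + config.delay_logit_sd * zs)
    regulated = rng.random(len(site_ids)) < config.regulated_fraction
    shift_kcl = np.where(regulated, config.kcl_shift, 1.0)
    residual = 1.0 + (config.kcl_shift - 1.0) * (1.0 - config.azac_attenuation)
    shift_aza = np.where(regulated, residual, 1.0)
    delays = {"NT": d_nt}
    for cond in config.conditions:
        if cond == "NT":
            continue
        s = shift_aza if "azac" in cond.lower() else shift_kcl
        delays[cond] = np.minimum(d_nt * s, config.max_delay)

    sites = pd.DataFrame([site_meta[s] for s in site_ids])
    sites["z"] = zs
    sites["regulated"] = regulated
    for cond in config.conditions:
        sites[f"d_{cond}"] = delays[cond]

    genes_df = pd.DataFrame(
        {
            "gene_id": sorted(annotation.genes),
            "expression": np.exp(
                rng.normal(
                    config.expression_log_mean,
                    config.expression_log_sd,
                    size=len(annotation.genes),
                )
            ),
        }
    )

    # exon usage, coupled to the mean delay of flanking sites
    d_by_site = {cond: dict(zip(site_ids, delays[cond])) for cond in config.conditions}
    reg_by_site = dict(zip(site_ids, regulated))
    exon_rows = []
    for tx_id in sorted(annotation.transcripts):
        tx = annotation.transcripts[tx_id]
        flank: dict[str, list[str]] = {e.exon_id: [] for e in tx.exons}
        for intron in tx.introns:
            flank[intron.upstream_exon_id].append(
                f"{intron.intron_id}|{Side.FIVE_PRIME_SS.value}"
            )
            flank[intron.downstream_exon_id].append(
                f"{intron.intron_id}|{Side.THREE_PRIME_SS.value}"
            )
        for exon in sorted(tx.exons, key=lambda e: e.rank):
            base_u = rng.uniform(*config.usage_base_range)
            row = {
                "exon_id": exon.exon_id,
                "gene_id": tx.gene_id,
                "transcript_id": tx_id,
                "base_usage": base_u,
                "regulated": any(bool(reg_by_site[s]) for s in flank[exon.exon_id]),
            }
            for cond in config.conditions:
                local = [d_by_site[cond][s] for s in flank[exon.exon_id] if s in d_by_site[cond]]
                d_local = float(np.mean(local)) if local else 0.0
                row[f"usage_{cond}"] = float(
                    np.clip(base_u - config.usage_coupling * d_local, 0.02, 0.99)
                )
            exon_rows.append(row)

    return SimTruth(
        sites=sites,
        exons=pd.DataFrame(exon_rows),
        genes=genes_df,
        pairs=pd.DataFrame(pair_rows),
        conditions=config.conditions,
    )


def simulate_coverage(
    truth: SimTruth,
    annotation: GenomeAnnotation,
    config: SimConfig,
    seed: int | None = None,
    noiseless: bool = False,
) -> tuple[dict[tuple[str, str], CoverageTrack], pd.DataFrame]:
    """Per-condition x replicate coverage tracks and the exon-usage table.

    Exon bases draw Poisson(E); each splice-site bin draws Poisson(E * d) at
    its site's delay; intron bodies draw Poisson(E * background).
    ``noiseless=True`` replaces every Poisson draw with its mean (exact
    identifiability checks). The usage table follows the
    differential-exon-usage layout (groupID, featureID, exonBaseMean,
    usage_<cond>, log2fold, pvalue); p-values come from a two-proportion
    z-test on simulated inclusion counts between KCl and NT — a synthetic
    stand-in for an external differential-usage analysis.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    expr = dict(zip(truth.genes["gene_id"], truth.genes["expression"]))
    d_cols = {c: dict(zip(truth.sites["site_id"], truth.sites[f"d_{c}"])) for c in truth.conditions}

    def _poisson(lam, size):
        if noiseless:
            return np.full(size, lam, dtype=float)
        return rng.poisson(lam, size=size).astype(float)

    tracks: dict[tuple[str, str], CoverageTrack] = {}
    for cond in truth.conditions:
        for rep_i in range(config.replicates):
            rep = f"rep{rep_i + 1}"
            data = {c: np.zeros(L, dtype=float) for c, L in annotation.contigs.items()}
            for tx_id in sorted(annotation.transcripts):
                tx = annotation.transcripts[tx_id]
                gene = annotation.genes[tx.gene_id]
                arr = data[gene.contig]
                E = expr[tx.gene_id]
                for exon in tx.exons:
                    arr[exon.start:exon.end] = _poisson(E, exon.length)
                for intron in tx.introns:
                    arr[intron.start:intron.end] = _poisson(
                        E * config.background, intron.length
                    )
                    if intron.length < 13:
                        continue
                    for side, b in ss_bins(intron, gene.strand).items():
                        sid = f"{intron.intron_id}|{side.value}"
                        d = d_cols[cond].get(sid, 0.0)
                        arr[b.start:b.end] = _poisson(E * d, b.length)
            tracks[(cond, rep)] = CoverageTrack(data, stranded=False)

    usage = _usage_table(truth, config, rng, noiseless)
    return tracks, usage


def _usage_table(truth: SimTruth, config: SimConfig, rng, noiseless: bool) -> pd.DataFrame:
    """Differential-usage table from binomial inclusion counts (synthetic)."""
    expr = dict(zip(truth.genes["gene_id"], truth.genes["expression"]))
    rows = []
    for r in truth.exons.itertuples(index=False):
        E = expr[r.gene_id]
        n_trials = max(20, int(round(E)) * config.replicates)
        psi = {c: getattr(r, f"usage_{c}") for c in truth.conditions}
        if noiseless:
            counts = {c: psi[c] * n_trials for c in truth.conditions}
        else:
            counts = {c: int(rng.binomial(n_trials, psi[c])) for c in truth.conditions}
        k1, k2 = counts["NT"], counts.get("KCl", counts["NT"])
        p1, p2 = k1 / n_trials, k2 / n_trials
        pool = (k1 + k2) / (2 * n_trials)
        se = math.sqrt(max(pool * (1 - pool) * 2 / n_trials, 1e-12))
        zstat = (p2 - p1) / se if se > 0 else 0.0
        pvalue = 2 * stats.norm.sf(abs(zstat))
        row = {
            "groupID": r.gene_id,
            "featureID": r.exon_id,
            "exonBaseMean": E,
            "pvalue": float(pvalue),
            "log2fold": float(np.log2(max(p2, 1e-6) / max(p1, 1e-6))),
        }
        for c in truth.conditions:
            row[f"usage_{c}"] = psi[c]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file writers (deterministic, text formats)


def write_fasta(genome: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for contig in sorted(genome):
            fh.write(f">{contig}\n")
            seq = genome[contig]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """Write an unstranded coverage track as run-length-encoded bedGraph."""
    if track.stranded:
        raise ValueError("bedGraph output is unstranded; collapse strands first")
    with open(path, "w") as fh:
        for contig in sorted(track.data):
            arr = track.data[contig]
            if len(arr) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    text = f"{v:.6g}" if v != int(v) else str(int(v))
                    fh.write(f"{contig}\t{s}\t{e}\t{text}\n")


def write_truth(truth: SimTruth, prefix: str) -> None:
    truth.sites.to_csv(f"{prefix}.sites.tsv", sep="\t", index=False)
    truth.exons.to_csv(f"{prefix}.exons.tsv", sep="\t", index=False)
    truth.genes.to_csv(f"{prefix}.genes.tsv", sep="\t", index=False)
    truth.pairs.to_csv(f"{prefix}.pairs.tsv", sep="\t", index=False)
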