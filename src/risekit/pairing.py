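"""Splice-site pairing of RISE sites across introns (type I) or exons (type II).

Intron definition pairs the 5'SS and 3'SS of the *same intron* (type I);
exon definition pairs the 3'SS of intron k with the 5'SS of intron k+1
across the exon between them (type II). Detected sites participating in
neither adjacency are type III (recorded, excluded from pairing statistics).
A single site can belong to one type I and one type II pair at once (mixed);
those competing configurations are analysed in :mod:`risekit.condition`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation, Side

__all__ = [
    "classify_pairs",
    "pair_correlation",
    "permutation_null",
    "length_association",
]


def _representative_intron_ids(annotation: GenomeAnnotation) -> dict:
    """Map (gene, contig, start, end) -> representative (deduplicated) intron id."""
    rep = {}
    for intron in annotation.deduplicated_introns():
        tx = annotation.transcripts[intron.transcript_id]
        gene = annotation.genes[tx.gene_id]
        rep[(tx.gene_id, gene.contig, intron.start, intron.end)] = intron.intron_id
    return rep


def classify_pairs(
    cond_means: pd.DataFrame, annotation: GenomeAnnotation
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enumerate type I / type II pairs among detected RISE sites.

    ``cond_means`` is the per-(site, condition) table from
    :func:`risekit.coverage.condition_means`. A pair is emitted when both
    member sites are detected in at least one common condition (a pair must
    be a simultaneous observation); per-condition indexes of both members are
    carried along as ``idx5_<cond>`` / ``idx3_<cond>`` with a
    ``both_detected_<cond>`` flag.

    Returns ``(pairs, site_classes)``. ``pairs`` has one row per pair with
    ``pair_type`` "I" (element = the intron) or "II" (element = the spanned
    exon). ``site_classes`` labels every detected site I/II/mixed/III.
    Deterministic and independent of row order.
    """
    conditions = sorted(cond_means["condition"].unique())
    det = cond_means[cond_means["detected"]]
    # site_id -> condition -> index
    idx_of: dict[tuple[str, str], float] = {
        (r.site_id, r.condition): r.index for r in det.itertuples()
    }
    detected_sites = set(det["site_id"])
    known_introns = {i.intron_id for i in annotation.introns()}
    for site in detected_sites:
        intron_id = site.rsplit("|", 1)[0]
        if intron_id not in known_introns:
            raise ValueError(f"site {site} references unknown intron {intron_id}")

    rep = _representative_intron_ids(annotation)
    pairs = []
    seen_pair_keys = set()

    def _emit(pair_type, gene_id, element_id, element_len, five_id, three_id, key):
        if key in seen_pair_keys:
            return
        seen_pair_keys.add(key)
        common = [
            c
            for c in conditions
            if (five_id, c) in idx_of and (three_id, c) in idx_of
        ]
        if not common:
            return
        row = {
            "pair_type": pair_type,
            "gene_id": gene_id,
            "element_id": element_id,
            "element_len": element_len,
            "five_site_id": five_id,
            "three_site_id": three_id,
        }
        for c in conditions:
            row[f"idx5_{c}"] = idx_of.get((five_id, c), np.nan)
            row[f"idx3_{c}"] = idx_of.get((three_id, c), np.nan)
            row[f"both_detected_{c}"] = c in common
        pairs.append(row)

    for tx_id in sorted(annotation.transcripts):
        tx = annotation.transcripts[tx_id]
        gene = annotation.genes[tx.gene_id]
        by_rank = sorted(tx.introns, key=lambda i: i.rank)
        exon_by_id = {e.exon_id: e for e in tx.exons}
        rep_id = {
            i.intron_id: rep[(tx.gene_id, gene.contig, i.start, i.end)] for i in by_rank
        }
        for intron in by_rank:
            rid = rep_id[intron.intron_id]
            five = f"{rid}|{Side.FIVE_PRIME_SS.value}"
            three = f"{rid}|{Side.THREE_PRIME_SS.value}"
            if five in detected_sites and three in detected_sites:
                key = ("I", tx.gene_id, gene.contig, intron.start, intron.end)
                _emit("I", tx.gene_id, rid, intron.length, five, three, key)
        for up, down in zip(by_rank, by_rank[1:]):
            # exon between consecutive introns: 3'SS of `up`, 5'SS of `down`
            exon = exon_by_id[up.downstream_exon_id]
            three = f"{rep_id[up.intron_id]}|{Side.THREE_PRIME_SS.value}"
            five = f"{rep_id[down.intron_id]}|{Side.FIVE_PRIME_SS.value}"
            if three in detected_sites and five in detected_sites:
                key = ("II", tx.gene_id, gene.contig, exon.start, exon.end)
                _emit("II", tx.gene_id, exon.exon_id, exon.length, five, three, key)

    pairs_df = pd.DataFrame(pairs)
    if not pairs_df.empty:
        pairs_df = pairs_df.sort_values(
            ["gene_id", "pair_type", "element_id"], kind="mergesort"
        ).reset_index(drop=True)
        pairs_df.insert(0, "pair_id", [f"pair{i:05d}" for i in range(len(pairs_df))])

    in_type: dict[str, set] = {s: set() for s in detected_sites}
    if not pairs_df.empty:
        for r in pairs_df.itertuples():
            in_type[r.five_site_id].add(r.pair_type)
            in_type[r.three_site_id].add(r.pair_type)
    site_rows = []
    for site in sorted(detected_sites):
        types = in_type[site]
        if {"I", "II"} <= types:
            label = "mixed"
        elif types:
            label = next(iter(types))
        else:
            label = "III"
        site_rows.append(
            {
                "site_id": site,
                "in_type_I": "I" in types,
                "in_type_II": "II" in types,
                "mixed": label == "mixed",
                "class": label,
            }
        )
    return pairs_df, pd.DataFrame(site_rows)


def _pair_vectors(
    pairs: pd.DataFrame, condition: str, pair_type: str | None
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    sub = pairs[pairs[f"both_detected_{condition}"]]
    if pair_type is not None:
        sub = sub[sub["pair_type"] == pair_type]
    return (
        sub[f"idx5_{condition}"].to_numpy(float),
        sub[f"idx3_{condition}"].to_numpy(float),
        sub,
    )


def _transform(x: np.ndarray, transform: str | None) -> np.ndarray:
    if transform == "log10":
        if np.any(x <= 0):
            raise ValueError("log10 transform requires strictly positive values")
        return np.log10(x)
    if transform is None:
        return x
    raise ValueError(f"unknown transform {transform!r}")


def pair_correlation(
    pairs: pd.DataFrame,
    condition: str,
    axis: str = "paired-index",
    transform: str | None = "log10",
    pair_type: str | None = None,
    usage: pd.Series | None = None,
    sites: pd.DataFrame | None = None,
    side: str = "5SS",
) -> dict:
    """Pearson correlation of paired indexes, or of indexes vs exon usage.

    ``axis="paired-index"`` correlates log10 5'SS vs log10 3'SS indexes of
    the pairs both-detected in ``condition``. ``axis="index-vs-usage"``
    correlates the (log10) index of each detected site of the given ``side``
    (from the ``sites`` condition-mean table) against its adjacent exon's
    usage value (``usage``: exon_id -> usage, untransformed).

    Returns ``{"r", "n", "defined"}``; zero variance on either axis yields
    ``defined=False`` with ``r`` NaN.
    """
    if axis == "paired-index":
        x, y, _ = _pair_vectors(pairs, condition, pair_type)
        x, y = _transform(x, transform), _transform(y, transform)
    elif axis == "index-vs-usage":
        if usage is None or sites is None:
            raise ValueError("index-vs-usage requires `usage` and `sites`")
        sub = sites[
            (sites["condition"] == condition)
            & sites["detected"]
            & (sites["side"] == side)
            & sites["exon_id"].isin(usage.index)
        ]
        x = _transform(sub["index"].to_numpy(float), transform)
        y = usage.loc[sub["exon_id"]].to_numpy(float)
    else:
        raise ValueError(f"unknown axis {axis!r}")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": np.nan, "n": n, "defined": False}
    r, _ = stats.pearsonr(x, y)
    return {"r": float(r), "n": n, "defined": True}


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    return float((xc * yc).sum() / denom) if denom > 0 else np.nan


def permutation_null(
    pairs: pd.DataFrame,
    condition: str,
    scope: str = "global",
    n_perm: int = 999,
    seed: int | None = None,
    pair_type: str | None = None,
    transform: str | None = "log10",
) -> dict:
    """Randomization null for the paired-index correlation.

    The 3'SS partners are shuffled among pairs — globally, or only within
    each gene's pair set (``scope="within-gene"``), which preserves gene-level
    index offsets and so tests for pairing beyond co-residence in a gene.
    Empirical p = (1 + #{null r >= observed r}) / (1 + n_perm).
    """
    if scope not in ("global", "within-gene"):
        raise ValueError(f"unknown scope {scope!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a meaningful null")
    x, y, sub = _pair_vectors(pairs, condition, pair_type)
    x, y = _transform(x, transform), _transform(y, transform)
    if len(x) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(x)}")
    rng = np.random.default_rng(seed)
    observed = _pearson(x, y)
    if scope == "within-gene":
        genes = sub["gene_id"].to_numpy()
        groups = [np.flatnonzero(genes == g) for g in pd.unique(genes)]
        if all(len(g) < 2 for g in groups):
            raise ValueError(
                "within-gene scope: every gene holds a single pair; "
                "the shuffle would be the identity"
            )
    null = np.empty(n_perm)
    for i in range(n_perm):
        if scope == "global":
            yp = y[rng.permutation(len(y))]
        else:
            yp = y.copy()
            for g in groups:
                yp[g] = y[g[rng.permutation(len(g))]]
        null[i] = _pearson(x, yp)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return {
        "observed_r": observed,
        "null_r": null,
        "null_mean_r": float(null.mean()),
        "p_value": float(p),
        "n_pairs": len(x),
        "n_perm": n_perm,
        "scope": scope,
    }


def length_association(
    pairs: pd.DataFrame,
    condition: str,
    intron_cutoff: int = 1000,
    exon_cutoff: int = 100,
    bin_edges: np.ndarray | None = None,
    max_exon_len_for_r: int | None = 400,
) -> dict:
    """Length distributions per pair type and index-length correlations.

    Per type: fraction of spanned elements below the cutoff (introns <
    ``intron_cutoff`` for type I, exons < ``exon_cutoff`` for type II), the
    binned percent length distribution, and the Pearson r of the pair mean
    index vs element length (type II optionally restricted to exons <
    ``max_exon_len_for_r``, where exon-definition delay is expected to scale
    with length). Short-intron-type-I vs type-II counts at ``intron_cutoff``
    are compared with a hypergeometric upper-tail test.
    """
    out: dict = {}
    if bin_edges is None:
        bin_edges = np.array([0, 100, 200, 400, 700, 1000, 2000, 3000, 5000, np.inf])
    short_counts = {}
    for ptype, cutoff in (("I", intron_cutoff), ("II", exon_cutoff)):
        sub = pairs[(pairs["pair_type"] == ptype) & pairs[f"both_detected_{condition}"]]
        if sub.empty:
            out[ptype] = {"n": 0, "note": "empty type class; distributions omitted"}
            short_counts[ptype] = (0, 0)
            continue
        lengths = sub["element_len"].to_numpy(float)
        mean_idx = 0.5 * (
            np.log10(sub[f"idx5_{condition}"].to_numpy(float))
            + np.log10(sub[f"idx3_{condition}"].to_numpy(float))
        )
        hist, _ = np.histogram(lengths, bins=bin_edges)
        mask = np.ones(len(lengths), bool)
        if ptype == "II" and max_exon_len_for_r is not None:
            mask = lengths < max_exon_len_for_r
        if mask.sum() >= 3 and np.std(lengths[mask]) > 0 and np.std(mean_idx[mask]) > 0:
            r, _ = stats.pearsonr(mean_idx[mask], lengths[mask])
            r_defined = True
        else:
            r, r_defined = np.nan, False
        short = int(np.sum(lengths < cutoff))
        short_counts[ptype] = (short, len(lengths))
        out[ptype] = {
            "n": len(lengths),
            "fraction_below_cutoff": short / len(lengths),
            "cutoff": cutoff,
            "hist_percent": (100.0 * hist / len(lengths)).tolist(),
            "bin_edges": bin_edges.tolist(),
            "index_length_r": float(r) if r_defined else np.nan,
            "index_length_r_defined": r_defined,
        }
    # are short elements over-represented among type I relative to type II?
    (k_i, n_i), (k_ii, n_ii) = short_counts["I"], short_counts["II"]
    if n_i and n_ii:
        pop, successes = n_i + n_ii, k_i + k_ii
        out["short_enrichment_p"] = float(
            stats.hypergeom.sf(k_i - 1, pop, successes, n_i)
        )
    else:
        out["short_enrichment_p"] = np.nan
    return out
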