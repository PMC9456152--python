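"""Splice-site position frequency matrices and consensus-normalized scoring.

Windows around the two splice sites of an intron:

* 5'SS (donor): 3 exonic + 10 intronic bases, labelled -3..-1, +1..+10,
  where +1/+2 are the first two intron bases (the GT of the consensus).
* 3'SS (acceptor): 20 intronic + 2 exonic bases, labelled -20..-1, +1/+2,
  where -2/-1 are the last two intron bases (the AG).

A site's *matrix index* against a position frequency matrix is the mean over
window positions of f(position, observed base) / f(position, consensus base):
the consensus sequence scores exactly 1 and every deviation lowers the score
in proportion to how rare the observed base is. A per-position log-odds
variant is also provided. Information content per position is
IC = 2 + sum_b f_b log2 f_b bits (0 for a uniform column, 2 for an invariant
one), the quantity sequence-logo plotters stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation, Intron, Side

__all__ = [
    "WINDOWS",
    "FrequencyMatrix",
    "extract_site_sequences",
    "build_frequency_matrix",
    "site_matrix_index",
    "group_index_comparison",
    "reverse_complement",
]

NUCLEOTIDES = "ACGT"
_NT_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: (exonic flank, intronic span) lengths per site kind
WINDOWS = {
    Side.FIVE_PRIME_SS: {"exonic": 3, "intronic": 10},  # 13 nt
    Side.THREE_PRIME_SS: {"intronic": 20, "exonic": 2},  # 22 nt
}


def window_length(kind: Side) -> int:
    w = WINDOWS[kind]
    return w["exonic"] + w["intronic"]


def position_labels(kind: Side) -> list[int]:
    """Window position labels; negative upstream of the boundary, no zero."""
    if kind is Side.FIVE_PRIME_SS:
        return list(range(-3, 0)) + list(range(1, 11))
    return list(range(-20, 0)) + [1, 2]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_site_sequences(
    genome,
    annotation: GenomeAnnotation,
    sites: list[tuple[Intron, Side]],
    kind: Side,
) -> list[tuple[str, str]]:
    """Strand-aware splice-site window sequences.

    ``genome`` maps contig -> sequence (a plain dict of strings or a
    ``pyfaidx.Fasta``). Minus-strand windows are reverse-complemented so that
    every returned 5'SS sequence starts its intronic span with the intron's
    first bases and every 3'SS sequence ends its intronic span with the
    intron's last bases. Out-of-bounds windows are skipped with a notice;
    non-ACGT bases are retained in the sequence (they are ignored when
    counting frequencies).

    Returns ``(site_id, sequence)`` tuples, uppercased.
    """
    if any(s is not kind for _, s in sites):
        raise ValueError("all sites must match `kind`")
    w = WINDOWS[kind]
    out = []
    for intron, side in sites:
        gene = annotation.gene_of_transcript(intron.transcript_id)
        contig_seq = genome[gene.contig]
        contig_len = len(contig_seq)
        if kind is Side.FIVE_PRIME_SS:
            # window straddles the intron start (transcript orientation)
            if gene.strand == "+":
                start, end = intron.start - w["exonic"], intron.start + w["intronic"]
            else:
                start, end = intron.end - w["intronic"], intron.end + w["exonic"]
        else:
            # window straddles the intron end
            if gene.strand == "+":
                start, end = intron.end - w["intronic"], intron.end + w["exonic"]
            else:
                start, end = intron.start - w["exonic"], intron.start + w["intronic"]
        if start < 0 or end > contig_len:
            continue
        seq = str(contig_seq[start:end]).upper()
        if gene.strand == "-":
            seq = reverse_complement(seq)
        out.append((f"{intron.intron_id}|{side.value}", seq))
    return out


@dataclass
class FrequencyMatrix:
    """Position x nucleotide frequencies of one splice-site window."""

    kind: Side
    frequencies: np.ndarray  # (window length, 4), rows sum to 1
    consensus: str
    information_content: np.ndarray  # bits per position
    n_sequences: int
    consensus_ties: list[int]  # positions where the argmax was tied

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.frequencies, columns=list(NUCLEOTIDES), index=position_labels(self.kind)
        )

    @classmethod
    def uniform(cls, kind: Side) -> "FrequencyMatrix":
        L = window_length(kind)
        return cls(
            kind=kind,
            frequencies=np.full((L, 4), 0.25),
            consensus="A" * L,
            information_content=np.zeros(L),
            n_sequences=0,
            consensus_ties=list(range(L)),
        )


def build_frequency_matrix(sequences: list[str], kind: Side) -> FrequencyMatrix:
    """Count per-position nucleotide frequencies over equal-length sequences.

    Non-ACGT characters are excluded from the counts at their position.
    Consensus ties break alphabetically and are recorded.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    L = window_length(kind)
    if any(len(s) != L for s in sequences):
        raise ValueError(f"all sequences must have window length {L} for {kind}")
    counts = np.zeros((L, 4), dtype=float)
    for seq in sequences:
        for pos, base in enumerate(seq.upper()):
            j = _NT_INDEX.get(base)
            if j is not None:
                counts[pos, j] += 1
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("a window position has no ACGT observations")
    freqs = counts / totals
    cons_idx = freqs.argmax(axis=1)  # argmax ties break to the lowest index = alphabetical
    ties = [
        int(p)
        for p in range(L)
        if int(np.sum(freqs[p] == freqs[p, cons_idx[p]])) > 1
    ]
    consensus = "".join(NUCLEOTIDES[i] for i in cons_idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    return FrequencyMatrix(
        kind=kind,
        frequencies=freqs,
        consensus=consensus,
        information_content=ic,
        n_sequences=len(sequences),
        consensus_ties=ties,
    )


def site_matrix_index(sequence: str, matrix: FrequencyMatrix) -> dict:
    """Consensus-normalized matrix score of one splice-site sequence.

    index = mean over positions of f(pos, observed) / f(pos, consensus);
    positions whose observed base is not ACGT are excluded from the mean. A
    log-odds variant, mean of log2(f(observed)/f(consensus)), is reported
    alongside (0 for the consensus, -inf if any observed base has frequency
    0).
    """
    L = matrix.frequencies.shape[0]
    if len(sequence) != L:
        raise ValueError(f"sequence length {len(sequence)} != window length {L}")
    sequence = sequence.upper()
    ratios = []
    for pos, base in enumerate(sequence):
        j = _NT_INDEX.get(base)
        if j is None:
            continue
        cons = _NT_INDEX[matrix.consensus[pos]]
        ratios.append(matrix.frequencies[pos, j] / matrix.frequencies[pos, cons])
    if not ratios:
        raise ValueError("no scorable (ACGT) positions in sequence")
    ratios = np.asarray(ratios)
    with np.errstate(divide="ignore"):
        log_odds = float(np.mean(np.log2(ratios))) if np.all(ratios > 0) else -np.inf
    return {
        "sequence": sequence,
        "index": float(ratios.mean()),
        "log_odds": log_odds,
        "per_position_ratio": ratios.tolist(),
        "n_positions": len(ratios),
    }


def group_index_comparison(
    group_indexes: dict[str, np.ndarray], reference: float = 1.0
) -> dict:
    """One-sample t-tests of each group's mean matrix index against the
    genome-consensus reference, plus a two-sample test between the first two
    groups (typically the type I vs type II RISE-associated sites).

    Zero-variance groups are flagged with undefined tests.
    """
    out: dict = {"reference": reference, "groups": {}}
    names = list(group_indexes)
    for name in names:
        vals = np.asarray(group_indexes[name], dtype=float)
        if vals.size < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
        entry = {
            "mean": float(vals.mean()),
            "sem": float(stats.sem(vals)),
            "n": int(vals.size),
        }
        if vals.std(ddof=1) > 0:
            t, p = stats.ttest_1samp(vals, reference)
            entry.update(t_statistic=float(t), p_value=float(p), defined=True)
        else:
            entry.update(t_statistic=np.nan, p_value=np.nan, defined=False)
        out["groups"][name] = entry
    if len(names) >= 2:
        a = np.asarray(group_indexes[names[0]], dtype=float)
        b = np.asarray(group_indexes[names[1]], dtype=float)
        if a.std(ddof=1) > 0 or b.std(ddof=1) > 0:
            t, p = stats.ttest_ind(a, b)
            out["between"] = {
                "groups": (names[0], names[1]),
                "t_statistic": float(t),
                "p_value": float(p),
                "defined": True,
            }
        else:
            out["between"] = {
                "groups": (names[0], names[1]),
                "t_statistic": np.nan,
                "p_value": np.nan,
                "defined": False,
            }
    return out
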