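"""Gene annotation model: exons, derived introns, and intron-end bins.

All coordinates are internally 0-based half-open ``[start, end)``; GTF I/O
converts from/to the 1-based closed GTF convention at the boundary.

Introns are the gaps between consecutive exons of a transcript. The terminal
bins of each intron (the 5' splice-site bin at the intron start and the 3'
splice-site bin at the intron end, in transcript orientation) are where
splicing-intermediate reads accumulate; :func:`tile_intron_bins` tiles an
intron into 25-nt bins in plus-strand genomic order, merging a short remainder
(<= 12 nt) into the last bin so that merged terminal bins are 26-37 nt.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "Side",
    "Exon",
    "Intron",
    "IntronBin",
    "Transcript",
    "Gene",
    "GenomeAnnotation",
    "GtfParseError",
    "parse_gtf",
    "derive_introns",
    "tile_intron_bins",
    "write_gtf",
    "write_bed",
]

BIN_LENGTH = 25
#: a merged terminal bin absorbs remainders of 1-12 nt -> lengths 26-37
MAX_MERGED_REMAINDER = 12
#: the shortest interval that can stand as a bin on its own
MIN_BIN_LENGTH = 13


class Side(str, enum.Enum):
    """Which end of the intron a bin occupies, in transcript orientation."""

    FIVE_PRIME_SS = "5SS"
    THREE_PRIME_SS = "3SS"
    INTERNAL = "internal"


@dataclass(frozen=True)
class Exon:
    exon_id: str
    transcript_id: str
    start: int
    end: int
    rank: int  # 1-based, transcript orientation

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Intron:
    intron_id: str
    transcript_id: str
    start: int
    end: int
    rank: int  # 1-based, transcript orientation
    upstream_exon_id: str  # transcript-orientation upstream (donor-side) exon
    downstream_exon_id: str  # transcript-orientation downstream (acceptor-side) exon

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IntronBin:
    intron_id: str
    side: Side
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    exons: list[Exon] = field(default_factory=list)  # genomic order
    introns: list[Intron] = field(default_factory=list)  # genomic order


@dataclass
class Gene:
    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    start: int
    end: int
    transcript_ids: list[str] = field(default_factory=list)


class GtfParseError(ValueError):
    pass


@dataclass
class GenomeAnnotation:
    """Genes, transcripts, exons and derived introns of one genome build."""

    contigs: dict[str, int] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def exons(self) -> Iterable[Exon]:
        for tx in self.transcripts.values():
            yield from tx.exons

    def introns(self) -> Iterable[Intron]:
        for tx in self.transcripts.values():
            yield from tx.introns

    def exon_by_id(self, exon_id: str) -> Exon:
        tx_id = exon_id.rsplit(":", 1)[0]
        for exon in self.transcripts[tx_id].exons:
            if exon.exon_id == exon_id:
                return exon
        raise KeyError(exon_id)

    def intron_by_id(self, intron_id: str) -> Intron:
        tx_id = intron_id.rsplit(":", 1)[0]
        for intron in self.transcripts[tx_id].introns:
            if intron.intron_id == intron_id:
                return intron
        raise KeyError(intron_id)

    def gene_of_transcript(self, transcript_id: str) -> Gene:
        return self.genes[self.transcripts[transcript_id].gene_id]

    def strand_of_transcript(self, transcript_id: str) -> str:
        return self.gene_of_transcript(transcript_id).strand

    def deduplicated_introns(self) -> list[Intron]:
        """One intron per distinct (gene, contig, interval).

        Transcripts of the same gene frequently share introns; keeping one
        representative avoids double counting a splice site. The
        representative is the intron of the lexicographically first
        transcript id.
        """
        seen: dict[tuple[str, str, int, int], Intron] = {}
        for tx in sorted(self.transcripts.values(), key=lambda t: t.transcript_id):
            gene = self.genes[tx.gene_id]
            for intron in tx.introns:
                key = (tx.gene_id, gene.contig, intron.start, intron.end)
                seen.setdefault(key, intron)
        return list(seen.values())


def derive_introns(
    ordered_exons: Sequence[Exon],
    strand: str,
    transcript_id: str | None = None,
) -> list[Intron]:
    """Derive the n-1 introns between n genomically sorted exons.

    ``ordered_exons`` must be sorted by genomic start and non-overlapping.
    Intron ranks and the upstream/downstream flanking-exon assignments follow
    transcript orientation: on the minus strand the genomically last gap is
    intron 1 and its upstream (donor-side) exon is the genomically right one.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    for a, b in zip(ordered_exons, ordered_exons[1:]):
        if b.start < a.start:
            raise ValueError("exons must be sorted by genomic start")
        if b.start < a.end:
            raise ValueError(f"overlapping exons {a.exon_id} and {b.exon_id}")
    if len(ordered_exons) < 2:
        return []
    tx_id = transcript_id or ordered_exons[0].transcript_id
    n_gaps = len(ordered_exons) - 1
    introns = []
    for i in range(n_gaps):
        left, right = ordered_exons[i], ordered_exons[i + 1]
        if strand == "+":
            rank, up, down = i + 1, left, right
        else:
            rank, up, down = n_gaps - i, right, left
        introns.append(
            Intron(
                intron_id=f"{tx_id}:intron{rank}",
                transcript_id=tx_id,
                start=left.end,
                end=right.start,
                rank=rank,
                upstream_exon_id=up.exon_id,
                downstream_exon_id=down.exon_id,
            )
        )
    return introns


def tile_intron_bins(
    intron: Intron, strand: str, bin_length: int = BIN_LENGTH
) -> list[IntronBin]:
    """Tile an intron into bins of ``bin_length`` in plus-strand genomic order.

    Tiling always proceeds from the genomic left end regardless of gene
    strand. A remainder of 1-12 nt is merged into the last bin (so merged
    terminal bins run 26-37 nt at the default bin length); a remainder of
    13-24 nt stands as its own terminal bin. The genomically first and last
    bins carry the splice-site side labels according to ``strand``: on the
    plus strand the first bin is the 5'SS bin, on the minus strand the last
    one is.

    An intron shorter than 13 nt cannot form a bin and raises ``ValueError``.
    An intron short enough to yield a single bin gets the 5'SS label on that
    bin; such introns are below the minimum-length filter of the RISE
    analysis and never reach index computation.
    """
    length = intron.length
    if length < MIN_BIN_LENGTH:
        raise ValueError(
            f"intron {intron.intron_id} is {length} nt; minimum binnable length "
            f"is {MIN_BIN_LENGTH} nt"
        )
    n_full, remainder = divmod(length, bin_length)
    edges = [intron.start + i * bin_length for i in range(n_full + 1)]
    if remainder == 0:
        pass
    elif remainder <= MAX_MERGED_REMAINDER:
        if n_full == 0:  # length 13-24 handled by the standalone branch below
            raise AssertionError("unreachable: remainder <= 12 implies n_full >= 1")
        edges[-1] = intron.end  # merge into last bin
    else:
        edges.append(intron.end)  # standalone short terminal bin
    bins = []
    last = len(edges) - 2
    for i in range(last + 1):
        if i == 0 and strand == "+" or i == last and strand == "-":
            side = Side.FIVE_PRIME_SS
        elif i == last and strand == "+" or i == 0 and strand == "-":
            side = Side.THREE_PRIME_SS
        else:
            side = Side.INTERNAL
        bins.append(IntronBin(intron.intron_id, side, edges[i], edges[i + 1]))
    return bins


def ss_bins(intron: Intron, strand: str) -> dict[Side, IntronBin]:
    """The two splice-site bins of an intron, keyed by side."""
    tiles = tile_intron_bins(intron, strand)
    return {b.side: b for b in tiles if b.side is not Side.INTERNAL}


# ---------------------------------------------------------------------------
# GTF I/O

_REQUIRED_N_FIELDS = 9


def _parse_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise GtfParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_gtf(path: str, contig_lengths: dict[str, int] | None = None) -> GenomeAnnotation:
    """Parse a GTF file (Ensembl dialect) into a :class:`GenomeAnnotation`.

    Only ``exon`` features are used; genes and transcripts are reconstructed
    from their ``gene_id``/``transcript_id`` attributes. GTF 1-based closed
    coordinates are converted to 0-based half-open. Introns are derived per
    transcript. A transcript with overlapping exons is rejected with its id.

    ``contig_lengths`` fixes contig sizes; otherwise each contig's length is
    the rightmost exon coordinate seen on it.
    """
    per_tx: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, contig, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _REQUIRED_N_FIELDS:
                raise GtfParseError(
                    f"line {lineno}: expected {_REQUIRED_N_FIELDS} tab-separated "
                    f"fields, got {len(fields)}"
                )
            contig, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature != "exon":
                continue
            try:
                start_1, end_1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinate") from exc
            if start_1 < 1 or end_1 < start_1:
                raise GtfParseError(f"line {lineno}: invalid interval {start_1}-{end_1}")
            if strand not in ("+", "-"):
                raise GtfParseError(f"line {lineno}: invalid strand {strand!r}")
            attrs = _parse_attributes(attr_s, lineno)
            try:
                gene_id, tx_id = attrs["gene_id"], attrs["transcript_id"]
            except KeyError as exc:
                raise GtfParseError(f"line {lineno}: missing attribute {exc}") from exc
            prior = tx_meta.setdefault(tx_id, (gene_id, contig, strand))
            if prior != (gene_id, contig, strand):
                raise GtfParseError(
                    f"line {lineno}: transcript {tx_id} spans conflicting "
                    f"gene/contig/strand assignments"
                )
            per_tx.setdefault(tx_id, []).append((start_1 - 1, end_1))

    ann = GenomeAnnotation(contigs=dict(contig_lengths or {}))
    for tx_id in sorted(per_tx):
        gene_id, contig, strand = tx_meta[tx_id]
        intervals = sorted(per_tx[tx_id])
        for (s1, e1), (s2, _e2) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise GtfParseError(f"transcript {tx_id} has overlapping exons")
        n = len(intervals)
        exons = [
            Exon(
                exon_id=f"{tx_id}:exon{(i + 1) if strand == '+' else (n - i)}",
                transcript_id=tx_id,
                start=s,
                end=e,
                rank=(i + 1) if strand == "+" else (n - i),
            )
            for i, (s, e) in enumerate(intervals)
        ]
        tx = Transcript(tx_id, gene_id, exons=exons)
        tx.introns = derive_introns(exons, strand, tx_id)
        ann.transcripts[tx_id] = tx
        gene = ann.genes.get(gene_id)
        if gene is None:
            gene = Gene(gene_id, contig, strand, intervals[0][0], intervals[-1][1])
            ann.genes[gene_id] = gene
        gene.start = min(gene.start, intervals[0][0])
        gene.end = max(gene.end, intervals[-1][1])
        gene.transcript_ids.append(tx_id)
        if contig_lengths is None:
            ann.contigs[contig] = max(ann.contigs.get(contig, 0), intervals[-1][1])
    return ann


def write_gtf(ann: GenomeAnnotation, path: str, source: str = "risekit") -> None:
    """Write exon features back out as GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for tx_id in sorted(ann.transcripts):
            tx = ann.transcripts[tx_id]
            gene = ann.genes[tx.gene_id]
            for exon in tx.exons:
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx_id}"; '
                    f'exon_number "{exon.rank}";'
                )
                fh.write(
                    "\t".join(
                        [
                            gene.contig,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            gene.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def write_bed(
    ann: GenomeAnnotation, path: str, what: str = "introns", bin_length: int = BIN_LENGTH
) -> None:
    """Write derived introns or intron bins as 6-column BED (0-based half-open)."""
    if what not in ("introns", "bins"):
        raise ValueError("what must be 'introns' or 'bins'")
    with open(path, "w") as fh:
        for tx_id in sorted(ann.transcripts):
            tx = ann.transcripts[tx_id]
            gene = ann.genes[tx.gene_id]
            for intron in tx.introns:
                if what == "introns":
                    fh.write(
                        f"{gene.contig}\t{intron.start}\t{intron.end}\t"
                        f"{intron.intron_id}\t0\t{gene.strand}\n"
                    )
                else:
                    if intron.length < MIN_BIN_LENGTH:
                        continue
                    for b in tile_intron_bins(intron, gene.strand, bin_length):
                        fh.write(
                            f"{gene.contig}\t{b.start}\t{b.end}\t"
                            f"{b.intron_id}|{b.side.value}\t0\t{gene.strand}\n"
                        )
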