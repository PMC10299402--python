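"""Gene structures and coordinate conversion.

Loads gene models from GFF3 + FASTA, represents transcripts as ordered
exon lists in 5'->3' transcript orientation, and converts between genomic
and spliced-mRNA coordinates.  All internal coordinates are 0-based
half-open; GFF3's 1-based inclusive convention is converted at the I/O
boundary.  Minus-strand genes are reverse-complemented on sequence
extraction so that every downstream analysis works on the sense strand.
"""

from __future__ import annotations

import tempfile
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO

DNA_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GeneModelError(ValueError):
    """Raised for malformed or inconsistent gene-model input."""


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One contig of uppercase DNA."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GeneModelError(f"contig {self.contig_id!r} has empty sequence")
        if set(self.sequence) - DNA_ALPHABET:
            bad = sorted(set(self.sequence) - DNA_ALPHABET)
            raise GeneModelError(
                f"contig {self.contig_id!r} contains non-DNA characters {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ExonRec:
    """A single exon in genomic coordinates (0-based half-open)."""

    exon_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise GeneModelError(
                f"exon {self.exon_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise GeneModelError(f"exon {self.exon_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int, str]:
        """Genomic identity used for constitutivity comparison."""
        return (self.contig, self.start, self.end, self.strand)


@dataclass
class TranscriptRec:
    """A transcript: exons in 5'->3' transcript order plus spliced CDS bounds.

    ``cds_start`` is the spliced-mRNA coordinate of the A of the ATG;
    ``cds_end`` is one past the stop codon; ``polyA_pos`` is the spliced
    coordinate of the mRNA 3' end (== spliced length).
    """

    transcript_id: str
    exons: list[ExonRec]
    cds_start: int
    cds_end: int
    polyA_pos: int
    _offsets: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise GeneModelError(f"transcript {self.transcript_id!r} has no exons")
        offsets, total = [], 0
        for ex in self.exons:
            offsets.append(total)
            total += ex.length
        self._offsets = offsets
        if total != self.polyA_pos:
            raise GeneModelError(
                f"transcript {self.transcript_id!r}: polyA_pos {self.polyA_pos} "
                f"!= spliced length {total}"
            )
        if not (0 <= self.cds_start < self.cds_end <= self.polyA_pos):
            raise GeneModelError(
                f"transcript {self.transcript_id!r}: bad CDS bounds "
                f"[{self.cds_start}, {self.cds_end}) in mRNA of length {total}"
            )
        if (self.cds_end - self.cds_start) % 3:
            raise GeneModelError(
                f"transcript {self.transcript_id!r}: CDS length "
                f"{self.cds_end - self.cds_start} not divisible by 3"
            )

    @property
    def spliced_length(self) -> int:
        return self.polyA_pos

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    def exon_by_id(self, exon_id: str) -> ExonRec:
        for ex in self.exons:
            if ex.exon_id == exon_id:
                return ex
        raise GeneModelError(
            f"exon {exon_id!r} not in transcript {self.transcript_id!r}"
        )

    def exon_index(self, exon_id: str) -> int:
        for i, ex in enumerate(self.exons):
            if ex.exon_id == exon_id:
                return i
        raise GeneModelError(
            f"exon {exon_id!r} not in transcript {self.transcript_id!r}"
        )


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptRec]
    canonical_transcript_id: str

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise GeneModelError(f"gene {self.gene_id!r} has no transcripts")
        ids = {tx.transcript_id for tx in self.transcripts}
        if self.canonical_transcript_id not in ids:
            raise GeneModelError(
                f"canonical transcript {self.canonical_transcript_id!r} "
                f"not among {sorted(ids)}"
            )

    @property
    def canonical(self) -> TranscriptRec:
        for tx in self.transcripts:
            if tx.transcript_id == self.canonical_transcript_id:
                return tx
        raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# sequence extraction and coordinate conversion


def exon_sequence(exon: ExonRec, genome: GenomeSequence) -> str:
    """Sense-strand sequence of one exon."""
    if exon.contig != genome.contig_id:
        raise GeneModelError(
            f"exon {exon.exon_id!r} is on {exon.contig!r}, not {genome.contig_id!r}"
        )
    if exon.end > len(genome):
        raise GeneModelError(
            f"exon {exon.exon_id!r} [{exon.start}, {exon.end}) outside contig "
            f"{genome.contig_id!r} of length {len(genome)}"
        )
    seq = genome.sequence[exon.start : exon.end]
    return revcomp(seq) if exon.strand == "-" else seq


def spliced_mrna(tx: TranscriptRec, genome: GenomeSequence) -> str:
    """Mature mRNA: concatenated sense-strand exon sequences in transcript order."""
    return "".join(exon_sequence(ex, genome) for ex in tx.exons)


def to_spliced_coord(tx: TranscriptRec, exon_id: str, offset_in_exon: int) -> int:
    """Spliced-mRNA coordinate of a within-exon offset (0 <= offset <= length)."""
    i = tx.exon_index(exon_id)
    ex = tx.exons[i]
    if not 0 <= offset_in_exon <= ex.length:
        raise GeneModelError(
            f"offset {offset_in_exon} outside exon {exon_id!r} of length {ex.length}"
        )
    return tx._offsets[i] + offset_in_exon


def to_exon_coord(tx: TranscriptRec, spliced_pos: int) -> tuple[str, int]:
    """Inverse of :func:`to_spliced_coord`: (exon_id, offset_in_exon).

    A position on an exon junction is attributed to the downstream exon
    (offset 0), except the transcript 3' end, which is reported as
    (last exon, exon length).
    """
    if not 0 <= spliced_pos <= tx.spliced_length:
        raise GeneModelError(
            f"spliced position {spliced_pos} outside transcript of length "
            f"{tx.spliced_length}"
        )
    i = bisect_right(tx._offsets, spliced_pos) - 1
    if i == len(tx.exons):
        i -= 1
    return tx.exons[i].exon_id, spliced_pos - tx._offsets[i]


def constitutive_exons(gene: GeneModel) -> set[str]:
    """Exon ids (of the canonical transcript) whose genomic boundaries are
    identical in every transcript of the gene."""
    keysets = [{ex.key for ex in tx.exons} for tx in gene.transcripts]
    shared = set.intersection(*keysets)
    return {ex.exon_id for ex in gene.canonical.exons if ex.key in shared}


# ---------------------------------------------------------------------------
# GFF3 + FASTA input


def read_fasta(fasta_source) -> dict[str, GenomeSequence]:
    """Read a (possibly multi-record, wrapped or unwrapped) FASTA file."""
    contigs = {}
    for rec in SeqIO.parse(str(fasta_source), "fasta"):
        contigs[rec.id] = GenomeSequence(rec.id, str(rec.seq).upper())
    if not contigs:
        raise GeneModelError(f"no FASTA records in {fasta_source!r}")
    return contigs


def _spliced_cds_bounds(exons: list[ExonRec], cds_features) -> tuple[int, int]:
    """Map genomic CDS extent onto spliced coordinates of ``exons``."""
    cds_len = sum(f.end - f.start + 1 for f in cds_features)
    if cds_len % 3:
        raise GeneModelError(f"CDS length {cds_len} not divisible by 3")
    strand = exons[0].strand
    if strand == "+":
        g_first = min(f.start for f in cds_features) - 1  # 0-based
    else:
        g_first = max(f.end for f in cds_features) - 1
    offset = 0
    for ex in exons:
        if ex.start <= g_first < ex.end:
            within = (g_first - ex.start) if strand == "+" else (ex.end - 1 - g_first)
            start = offset + within
            return start, start + cds_len
        offset += ex.length
    raise GeneModelError("CDS start does not fall inside any exon")


def read_gene_model(gff3_source, fasta_source, gene_id: str) -> GeneModel:
    """Load one gene from GFF3 (gene/mRNA/exon/CDS with ID/Parent attributes).

    The canonical transcript is the one with the longest CDS; ties break
    lexicographically on transcript id.
    """
    contigs = read_fasta(fasta_source)
    db = gffutils.create_db(
        str(gff3_source),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    try:
        gene = db[gene_id]
    except gffutils.FeatureNotFoundError as exc:
        raise GeneModelError(f"gene {gene_id!r} not found in {gff3_source!r}") from exc

    transcripts = []
    for mrna in db.children(gene, featuretype="mRNA"):
        exon_feats = sorted(db.children(mrna, featuretype="exon"), key=lambda f: f.start)
        cds_feats = list(db.children(mrna, featuretype="CDS"))
        if not exon_feats:
            raise GeneModelError(f"mRNA {mrna.id!r} has no exon features")
        if not cds_feats:
            raise GeneModelError(f"mRNA {mrna.id!r} has no CDS features")
        strand = mrna.strand
        if strand == "-":
            exon_feats = exon_feats[::-1]
        exons = []
        for i, f in enumerate(exon_feats, start=1):
            if f.start > f.end:
                raise GeneModelError(
                    f"exon feature in mRNA {mrna.id!r} has start > end "
                    f"({f.start} > {f.end})"
                )
            contig = contigs.get(f.seqid)
            if contig is None:
                raise GeneModelError(f"contig {f.seqid!r} not present in FASTA")
            exon_id = f.attributes.get("ID", [f"{mrna.id}.exon{i}"])[0]
            ex = ExonRec(exon_id, f.seqid, f.start - 1, f.end, strand)
            if ex.end > len(contig):
                raise GeneModelError(
                    f"exon {exon_id!r} extends past contig {f.seqid!r}"
                )
            exons.append(ex)
        cds_start, cds_end = _spliced_cds_bounds(exons, cds_feats)
        total = sum(ex.length for ex in exons)
        transcripts.append(TranscriptRec(mrna.id, exons, cds_start, cds_end, total))

    if not transcripts:
        raise GeneModelError(f"gene {gene_id!r} has no mRNA children")
    canonical = min(
        transcripts, key=lambda tx: (-(tx.cds_end - tx.cds_start), tx.transcript_id)
    )
    return GeneModel(gene_id, transcripts, canonical.transcript_id)


# ---------------------------------------------------------------------------
# GFF3 + FASTA output (used by the fixtures subcommand and report writers)


def write_fasta(contigs: dict[str, GenomeSequence], path) -> None:
    with open(path, "w") as fh:
        for name, contig in contigs.items():
            fh.write(f">{name}\n")
            seq = contig.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gff3(gene: GeneModel, path) -> None:
    """Serialize a GeneModel back to GFF3 (1-based inclusive)."""
    lines = ["##gff-version 3"]
    g_start = min(ex.start for tx in gene.transcripts for ex in tx.exons)
    g_end = max(ex.end for tx in gene.transcripts for ex in tx.exons)
    contig = gene.canonical.exons[0].contig
    strand = gene.canonical.strand
    lines.append(
        f"{contig}\traidesign\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t"
        f"ID={gene.gene_id}"
    )
    for tx in gene.transcripts:
        t_start = min(ex.start for ex in tx.exons)
        t_end = max(ex.end for ex in tx.exons)
        lines.append(
            f"{contig}\traidesign\tmRNA\t{t_start + 1}\t{t_end}\t.\t{strand}\t.\t"
            f"ID={tx.transcript_id};Parent={gene.gene_id}"
        )
        for ex in tx.exons:
            lines.append(
                f"{contig}\traidesign\texon\t{ex.start + 1}\t{ex.end}\t.\t{strand}\t.\t"
                f"ID={ex.exon_id};Parent={tx.transcript_id}"
            )
        for c_start, c_end in _genomic_cds_segments(tx):
            lines.append(
                f"{contig}\traidesign\tCDS\t{c_start + 1}\t{c_end}\t.\t{strand}\t0\t"
                f"ID={tx.transcript_id}.cds;Parent={tx.transcript_id}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _genomic_cds_segments(tx: TranscriptRec) -> list[tuple[int, int]]:
    """Genomic (0-based half-open) CDS segments of a transcript."""
    segments = []
    for i, ex in enumerate(tx.exons):
        lo = max(tx.cds_start, tx._offsets[i])
        hi = min(tx.cds_end, tx._offsets[i] + ex.length)
        if lo >= hi:
            continue
        a, b = lo - tx._offsets[i], hi - tx._offsets[i]
        if ex.strand == "+":
            segments.append((ex.start + a, ex.start + b))
        else:
            segments.append((ex.end - b, ex.end - a))
    return sorted(segments)
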