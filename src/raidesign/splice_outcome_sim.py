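"""Simulate splicing outcomes of an rAI-edited allele.

Pre-recombinase, the intact cassette behaves as an intron and splices
itself out: the simulated mature mRNA must equal the wild-type mRNA
byte-for-byte (the central invariant of the whole approach).  After
recombinase excision of the branchpoint, the residual intron can no
longer remove itself and several splice products become possible:

``rai_sds_to_downstream_sas``
    the cassette's donor splices to the downstream exon's acceptor,
    deleting the exon tail 3' of the insertion point;
``exon_sds_retained_residual``
    the exon's own donor splices as usual and the residual stays in the
    mRNA as an insertion;
``rai_sas_upstream_fusion``
    a cryptic donor inside the upstream mini-exon pairs with the
    residual's still-strong acceptor (only emitted when such a donor
    scores above a configurable PWM threshold);
``exon_skip``
    the whole edited exon is skipped.

Relative abundances of these products are deliberately not estimated;
each is enumerated and annotated (reading-frame shift, premature
termination codons, 3'UTR length) so the placement engine can require
every plausible product to be knockout-competent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .config import RuleConfig
from .rai_registry import RAICassette, STOP_CODONS
from .splice_scoring import PwmModel, build_default_pwms, scan_sites
from .transcript_model import (
    GeneModel,
    GenomeSequence,
    GeneModelError,
    TranscriptRec,
    exon_sequence,
    revcomp,
    spliced_mrna,
)


class SimulationError(ValueError):
    """Raised for invalid edits or state-machine misuse."""


@dataclass(frozen=True)
class EditedAllele:
    """A gene with a cassette (or its residual) inserted into one exon.

    ``state`` is ``pre_recombinase`` (full cassette at the gap) or
    ``post_recombinase`` (residual at the same gap).
    """

    gene: GeneModel
    genome: GenomeSequence
    exon_id: str
    offset: int
    cassette: RAICassette
    state: str = "pre_recombinase"

    @property
    def transcript(self) -> TranscriptRec:
        return self.gene.canonical

    @property
    def insert_seq(self) -> str:
        return (self.cassette.sequence if self.state == "pre_recombinase"
                else self.cassette.residual)

    @property
    def exon_seq(self) -> str:
        ex = self.transcript.exon_by_id(self.exon_id)
        return exon_sequence(ex, self.genome)

    @property
    def edited_exon_seq(self) -> str:
        """The edited exon region: mini-exon A + insert + mini-exon B."""
        seq = self.exon_seq
        return seq[: self.offset] + self.insert_seq + seq[self.offset :]

    @property
    def insertion_gap_genomic(self) -> int:
        """Genomic coordinate of the insertion gap (0-based gap index)."""
        ex = self.transcript.exon_by_id(self.exon_id)
        return ex.start + self.offset if ex.strand == "+" else ex.end - self.offset

    def edited_genome(self) -> GenomeSequence:
        """Reference contig with the insert placed at the genomic gap;
        all downstream coordinates are thereby lifted by the insert length."""
        gap = self.insertion_gap_genomic
        ins = self.insert_seq
        ex = self.transcript.exon_by_id(self.exon_id)
        if ex.strand == "-":
            ins = revcomp(ins)
        seq = self.genome.sequence
        return GenomeSequence(self.genome.contig_id, seq[:gap] + ins + seq[gap:])


@dataclass(frozen=True)
class PTC:
    """A premature termination codon in a splice product's reading frame."""

    position: int  # spliced coordinate of the stop codon's first base
    distance_to_next_junction_3prime: int | None  # None if in the last exon
    distance_from_start_codon: int
    in_last_exon: bool
    in_penultimate_tail: bool

    def __post_init__(self) -> None:
        if self.distance_from_start_codon < 0:
            raise SimulationError("PTC upstream of the start codon")
        d = self.distance_to_next_junction_3prime
        if d is not None and d < 0:
            raise SimulationError("negative junction distance")


@dataclass(frozen=True)
class SpliceProduct:
    """One predicted mature mRNA with frame status and PTC annotation."""

    scenario: str
    mrna: str
    frame_shift: int  # {0,1,2}: net indel length mod 3 relative to wild type
    junctions: tuple[int, ...]  # spliced coordinates of exon-exon joins
    cds_start: int  # start-codon position in this product
    wt_stop_position: int  # position the natural stop occupies in this product
    ptcs: tuple[PTC, ...] = ()
    utr3_len: int = 0

    def __post_init__(self) -> None:
        if list(self.junctions) != sorted(set(self.junctions)):
            raise SimulationError("junctions must be strictly increasing")
        if list(self.ptcs) != sorted(self.ptcs, key=lambda p: p.position):
            raise SimulationError("PTCs must be sorted 5'->3'")


SCENARIOS = (
    "normal_self_splice",
    "rai_sds_to_downstream_sas",
    "exon_sds_retained_residual",
    "rai_sas_upstream_fusion",
    "exon_skip",
)


def insert_cassette(gene: GeneModel, genome: GenomeSequence, exon_id: str,
                    offset: int, cassette: RAICassette) -> EditedAllele:
    """Insert a cassette into an exon of the canonical transcript,
    splitting it into two mini-exons joined by the cassette."""
    ex = gene.canonical.exon_by_id(exon_id)
    if not 0 < offset < ex.length:
        raise SimulationError(
            f"offset {offset} must fall strictly inside exon {exon_id!r} "
            f"(length {ex.length})"
        )
    return EditedAllele(gene, genome, exon_id, offset, cassette,
                        state="pre_recombinase")


def apply_recombinase(allele: EditedAllele) -> EditedAllele:
    """Excise between the direct repeats: full cassette -> residual."""
    if allele.state != "pre_recombinase":
        raise SimulationError(
            f"recombinase already applied (state {allele.state!r})"
        )
    return replace(allele, state="post_recombinase")


def _exon_seqs(allele: EditedAllele) -> tuple[list[str], int]:
    tx = allele.transcript
    seqs = [exon_sequence(ex, allele.genome) for ex in tx.exons]
    return seqs, tx.exon_index(allele.exon_id)


def _product(allele: EditedAllele, scenario: str, exon_parts: list[str],
             config: RuleConfig) -> SpliceProduct:
    """Assemble a product from per-exon segments and annotate it."""
    tx = allele.transcript
    mrna = "".join(exon_parts)
    junctions = []
    acc = 0
    for part in exon_parts[:-1]:
        acc += len(part)
        junctions.append(acc)
    wt = spliced_mrna(tx, allele.genome)
    delta = len(mrna) - len(wt)
    # single contiguous edit: the start codon moves only if the edit is 5' of it
    lcp = _common_prefix(mrna, wt)
    cds_start = tx.cds_start if tx.cds_start <= lcp else tx.cds_start + delta
    wt_stop = (tx.cds_end - 3) if (tx.cds_end - 3) <= lcp else (tx.cds_end - 3) + delta
    # frame shift convention: indel length mod 3 (0 = reading frame preserved)
    frame_shift = abs(delta) % 3
    product = SpliceProduct(
        scenario=scenario,
        mrna=mrna,
        frame_shift=frame_shift,
        junctions=tuple(junctions),
        cds_start=cds_start,
        wt_stop_position=wt_stop,
    )
    try:
        ptcs = annotate_ptcs(product, tx, config)
    except SimulationError:
        # the edit removed the start codon: no ORF, nothing to annotate
        return replace(product, ptcs=(), utr3_len=0)
    first_end = (ptcs[0].position + 3) if ptcs else (wt_stop + 3)
    utr3 = len(mrna) - first_end
    return replace(product, ptcs=tuple(ptcs), utr3_len=utr3)


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def simulate_pre_splice(allele: EditedAllele, config: RuleConfig | None = None
                        ) -> SpliceProduct:
    """Pre-recombinase splicing: the intact cassette excises itself at its
    GT...AG ends and the natural introns are removed as usual."""
    if allele.state != "pre_recombinase":
        raise SimulationError("pre-splice simulation requires the intact cassette")
    config = config or RuleConfig()
    ins = allele.insert_seq
    if ins[:2] != "GT" or ins[-2:] != "AG":
        raise SimulationError("cassette ends are not GT...AG")  # pragma: no cover
    seqs, i = _exon_seqs(allele)
    edited = allele.edited_exon_seq
    # self-excision of the cassette intron at its annotated span
    restored = edited[: allele.offset] + edited[allele.offset + len(ins):]
    parts = seqs[:i] + [restored] + seqs[i + 1:]
    return _product(allele, "normal_self_splice", parts, config)


def enumerate_products(allele: EditedAllele,
                       pwms: tuple[PwmModel, PwmModel] | None = None,
                       config: RuleConfig | None = None) -> list[SpliceProduct]:
    """All plausible post-recombinase splice products, annotated.

    Scenarios (1) donor-readthrough to the downstream acceptor and
    (2) residual retention are always emitted; cryptic-donor fusion and
    whole-exon skipping are emitted when their preconditions hold.
    """
    if allele.state != "post_recombinase":
        raise SimulationError("product enumeration requires the recombined allele")
    config = config or RuleConfig()
    donor_pwm = (pwms or build_default_pwms())[0]
    seqs, i = _exon_seqs(allele)
    tx = allele.transcript
    exon = seqs[i]
    residual = allele.insert_seq
    products = []

    # (1) rAI donor -> downstream exon acceptor: exon tail + residual lost
    if i + 1 < len(seqs):
        parts = seqs[:i] + [exon[: allele.offset]] + seqs[i + 1:]
        products.append(_product(allele, "rai_sds_to_downstream_sas", parts, config))

    # (2) exon donor as usual: residual retained as an insertion
    parts = seqs[:i] + [exon[: allele.offset] + residual + exon[allele.offset:]] \
        + seqs[i + 1:]
    products.append(_product(allele, "exon_sds_retained_residual", parts, config))

    # cryptic donor in mini-exon A -> residual acceptor
    mini_a = exon[: allele.offset]
    for hit in scan_sites(donor_pwm, mini_a, config.cryptic_donor_threshold):
        p = hit.position
        parts = seqs[:i] + [exon[:p] + exon[allele.offset:]] + seqs[i + 1:]
        products.append(_product(allele, "rai_sas_upstream_fusion", parts, config))

    # whole-exon skip (branchpoint-loss-induced)
    if 0 < i < len(seqs) - 1:
        parts = seqs[:i] + seqs[i + 1:]
        products.append(_product(allele, "exon_skip", parts, config))

    return products


def annotate_ptcs(product: SpliceProduct, tx: TranscriptRec,
                  config: RuleConfig | None = None) -> list[PTC]:
    """Scan the product's reading frame from the start codon; every stop
    codon 5' of the natural stop's position is a premature termination codon.

    Distances to the next downstream exon-exon junction use the stop
    codon's first base.  The penultimate-tail flag marks PTCs within the
    last ``nmdetective_penultimate_tail`` nt of the penultimate exon.
    """
    config = config or RuleConfig()
    mrna = product.mrna
    if product.cds_start < 0 or mrna[product.cds_start : product.cds_start + 3] != "ATG":
        raise SimulationError(
            f"no start codon at product position {product.cds_start}"
        )
    junctions = product.junctions
    last_junction = junctions[-1] if junctions else None
    prev_junction = junctions[-2] if len(junctions) > 1 else 0
    ptcs = []
    for pos in range(product.cds_start, len(mrna) - 2, 3):
        if mrna[pos : pos + 3] not in STOP_CODONS:
            continue
        if pos >= product.wt_stop_position:
            break
        downstream = [j for j in junctions if j > pos]
        dist_junction = (downstream[0] - pos) if downstream else None
        in_last = last_junction is None or pos >= last_junction
        in_tail = (
            last_junction is not None
            and prev_junction <= pos < last_junction
            and last_junction - pos <= config.nmdetective_penultimate_tail
        )
        ptcs.append(PTC(
            position=pos,
            distance_to_next_junction_3prime=dist_junction,
            distance_from_start_codon=pos - product.cds_start,
            in_last_exon=in_last,
            in_penultimate_tail=in_tail,
        ))
    return ptcs


def count_ptcs_in_window(ptcs, config: RuleConfig) -> int:
    """PTCs whose distance to the next downstream junction falls in the
    [ptc_window_min, ptc_window_max] band (inclusive bounds)."""
    return sum(
        1 for p in ptcs
        if p.distance_to_next_junction_3prime is not None
        and config.ptc_window_min <= p.distance_to_next_junction_3prime
        <= config.ptc_window_max
    )
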