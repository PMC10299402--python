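"""Deterministic toy gene models for testing every stage of the pipeline.

Generates random genes with canonical splice-site context (exons end
MAG|, introns run GT...branchpoint...polypyrimidine...CAG|G), a clean
single-stop open reading frame, and requested planted features (MAG-R
insertion points, cryptic donor 9-mers, stop codons).  Accidental
confounders — in-frame stops, unplanted MAG-R sites inside an exon's
insertion zone — are removed by seeded rejection/repair, so a fixture
violates exactly the rules it was built to violate and nothing else.

These fixtures emulate gene architecture and splice-site consensus only:
base composition is uniform and there are no splicing-regulatory-element
landscapes, repeats, or realistic codon usage.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .config import RuleConfig
from .transcript_model import (
    ExonRec,
    GeneModel,
    GenomeSequence,
    TranscriptRec,
    revcomp,
)

STOPS = {"TAA", "TAG", "TGA"}
PLANT_KINDS = {"mag_r_site", "cryptic_donor", "stop_codon"}
CRYPTIC_DONOR_9MER = "CAGGTAAGT"  # consensus MAG|GTRAGT embedded in an exon


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class Planted:
    kind: str  # mag_r_site | cryptic_donor | stop_codon
    exon_index: int
    offset: int  # exon-local; for mag_r_site this is the insertion gap index

    def __post_init__(self) -> None:
        if self.kind not in PLANT_KINDS:
            raise FixtureError(f"unknown planted feature kind {self.kind!r}")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    exon_lengths: tuple[int, ...] = (300, 250, 1200)
    intron_lengths: tuple[int, ...] = (150, 150)
    cds_start: int = 30
    cds_end: int | None = None  # default: near the mRNA 3' end, frame-aligned
    planted: tuple[Planted, ...] = ()
    strand: str = "+"
    contig: str = "chrT"
    gene_id: str = "toygene"
    flank: int = 120
    #: exon indices whose [100, len-55) zone must contain only planted MAG-R
    clean_zones: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise FixtureError("need exactly n_exons - 1 intron lengths")
        if any(l <= 0 for l in self.exon_lengths):
            raise FixtureError("exon lengths must be positive")
        if any(l < 30 for l in self.intron_lengths):
            raise FixtureError("introns must be at least 30 nt")
        if self.strand not in {"+", "-"}:
            raise FixtureError(f"bad strand {self.strand!r}")


def _spliced_offsets(exon_lengths) -> list[int]:
    out, acc = [], 0
    for l in exon_lengths:
        out.append(acc)
        acc += l
    return out


def _resolve_cds_end(spec: FixtureSpec) -> int:
    total = sum(spec.exon_lengths)
    if spec.cds_end is not None:
        end = spec.cds_end
    else:
        end = total - 30
        end -= (end - spec.cds_start) % 3
    if not (spec.cds_start + 3 <= end <= total) or (end - spec.cds_start) % 3:
        raise FixtureError(f"infeasible CDS bounds [{spec.cds_start}, {end})")
    return end


def _constrained_positions(spec: FixtureSpec, cds_end: int) -> dict[int, str]:
    """Fixed mRNA characters: junction consensus, ATG, natural stop, plants."""
    offsets = _spliced_offsets(spec.exon_lengths)
    fixed: dict[int, str] = {}

    def put(pos: int, text: str) -> None:
        for k, ch in enumerate(text):
            if not 0 <= pos + k < sum(spec.exon_lengths):
                raise FixtureError(f"planted text at {pos} leaves the mRNA")
            prev = fixed.get(pos + k)
            if prev is not None and prev != ch:
                raise FixtureError(f"conflicting constraints at mRNA position {pos + k}")
            fixed[pos + k] = ch

    n = len(spec.exon_lengths)
    for i, l in enumerate(spec.exon_lengths):
        if i < n - 1:
            put(offsets[i] + l - 3, "CAG")  # donor-side exon consensus MAG
        if i > 0:
            put(offsets[i], "G")  # acceptor-side exonic G
    put(spec.cds_start, "ATG")
    put(cds_end - 3, "TAA")
    for p in spec.planted:
        if not 0 <= p.exon_index < n:
            raise FixtureError(f"planted feature in nonexistent exon {p.exon_index}")
        base = offsets[p.exon_index]
        l = spec.exon_lengths[p.exon_index]
        if p.kind == "mag_r_site":
            if not 3 <= p.offset < l:
                raise FixtureError(f"MAG-R gap {p.offset} infeasible in {l}-nt exon")
            put(base + p.offset - 3, "CAGG")
        elif p.kind == "cryptic_donor":
            if p.offset + len(CRYPTIC_DONOR_9MER) > l:
                raise FixtureError("cryptic donor 9-mer leaves the exon")
            put(base + p.offset, CRYPTIC_DONOR_9MER)
        elif p.kind == "stop_codon":
            if p.offset + 3 > l:
                raise FixtureError("planted stop leaves the exon")
            put(base + p.offset, "TAA")
    return fixed


def _planted_spans(spec: FixtureSpec) -> list[tuple[int, int]]:
    offsets = _spliced_offsets(spec.exon_lengths)
    spans = []
    for p in spec.planted:
        base = offsets[p.exon_index]
        if p.kind == "mag_r_site":
            spans.append((base + p.offset - 3, base + p.offset + 1))
        elif p.kind == "cryptic_donor":
            spans.append((base + p.offset, base + p.offset + 9))
        else:
            spans.append((base + p.offset, base + p.offset + 3))
    return spans


def _mag_r_gaps(seq: str) -> set[int]:
    return {
        o for o in range(3, len(seq))
        if seq[o - 3 : o] in {"AAG", "CAG"} and seq[o] in {"A", "G"}
    }


def make_toy_gene(spec: FixtureSpec,
                  config: RuleConfig | None = None,
                  max_attempts: int = 300) -> tuple[GeneModel, GenomeSequence]:
    """Generate a (GeneModel, GenomeSequence) pair for the spec, seeded.

    The open reading frame contains no in-frame stop other than the
    natural TAA and any explicitly planted ones; exons listed in
    ``clean_zones`` carry no unplanted MAG-R gap inside the usable
    insertion zone [five_prime_exclusion, length - three_prime_exclusion).
    """
    config = config or RuleConfig()
    rng = random.Random(spec.seed)
    cds_end = _resolve_cds_end(spec)
    fixed = _constrained_positions(spec, cds_end)
    planted_spans = _planted_spans(spec)
    offsets = _spliced_offsets(spec.exon_lengths)
    total = sum(spec.exon_lengths)

    planted_mag_gaps = {
        i: {p.offset for p in spec.planted
            if p.kind == "mag_r_site" and p.exon_index == i}
        for i in range(len(spec.exon_lengths))
    }

    for _ in range(max_attempts):
        mrna = [fixed.get(i) or rng.choice("ACGT") for i in range(total)]
        if _repair_orf(mrna, spec.cds_start, cds_end, fixed, planted_spans, rng):
            seq = "".join(mrna)
            if _zones_clean(seq, spec, config, offsets, planted_mag_gaps):
                return _assemble(spec, seq, cds_end, rng)
    raise FixtureError(
        f"could not satisfy fixture constraints in {max_attempts} attempts "
        f"(seed {spec.seed})"
    )


def _repair_orf(mrna: list[str], cds_start: int, cds_end: int,
                fixed: dict[int, str], planted_spans, rng,
                rounds: int = 40) -> bool:
    """Randomize free bases of any unplanted in-frame stop codon."""
    for _ in range(rounds):
        dirty = False
        for pos in range(cds_start, cds_end - 3, 3):
            codon = "".join(mrna[pos : pos + 3])
            if codon not in STOPS:
                continue
            if any(lo <= pos < hi or lo < pos + 3 <= hi for lo, hi in planted_spans):
                continue  # planted stop or plant-overlapping codon stays
            free = [k for k in range(pos, pos + 3) if k not in fixed]
            if not free:
                return False  # fully constrained stop codon: infeasible
            for k in free:
                mrna[k] = rng.choice("ACGT")
            dirty = True
        if not dirty:
            return True
    return False


def _zones_clean(seq: str, spec: FixtureSpec, config: RuleConfig,
                 offsets, planted_mag_gaps) -> bool:
    for i in spec.clean_zones:
        lo = config.five_prime_exclusion
        hi = spec.exon_lengths[i] - config.three_prime_exclusion
        exon_seq = seq[offsets[i] : offsets[i] + spec.exon_lengths[i]]
        found = {o for o in _mag_r_gaps(exon_seq) if lo <= o < hi}
        if found - planted_mag_gaps[i]:
            return False
    return True


def _assemble(spec: FixtureSpec, mrna: str, cds_end: int, rng
              ) -> tuple[GeneModel, GenomeSequence]:
    offsets = _spliced_offsets(spec.exon_lengths)
    introns = []
    for l in spec.intron_lengths:
        core = "".join(rng.choice("ACGT") for _ in range(l - 26))
        introns.append("GTAAGT" + core + "CTAAC" + "TCTTTCTTTTCAG")
    flank5 = "".join(rng.choice("ACGT") for _ in range(spec.flank))
    flank3 = "".join(rng.choice("ACGT") for _ in range(spec.flank))

    pieces, genomic_exons, pos = [flank5], [], spec.flank
    for i, l in enumerate(spec.exon_lengths):
        exon_seq = mrna[offsets[i] : offsets[i] + l]
        genomic_exons.append((pos, pos + l))
        pieces.append(exon_seq)
        pos += l
        if i < len(introns):
            pieces.append(introns[i])
            pos += len(introns[i])
    pieces.append(flank3)
    genome_seq = "".join(pieces)

    if spec.strand == "-":
        n = len(genome_seq)
        genome_seq = revcomp(genome_seq)
        genomic_exons = [(n - e, n - s) for s, e in genomic_exons]

    exons = [
        ExonRec(f"exon{i + 1}", spec.contig, s, e, spec.strand)
        for i, (s, e) in enumerate(genomic_exons)
    ]
    tx = TranscriptRec(f"{spec.gene_id}.t1", exons, spec.cds_start, cds_end,
                       sum(spec.exon_lengths))
    gene = GeneModel(spec.gene_id, [tx], tx.transcript_id)
    return gene, GenomeSequence(spec.contig, genome_seq)


def add_skipping_transcript(gene: GeneModel, skip_index: int,
                            transcript_id: str | None = None) -> GeneModel:
    """Add an isoform that skips one internal exon of the canonical
    transcript (making that exon non-constitutive)."""
    tx = gene.canonical
    if not 0 < skip_index < len(tx.exons) - 1:
        raise FixtureError("can only skip an internal exon")
    exons = [ex for i, ex in enumerate(tx.exons) if i != skip_index]
    alt = TranscriptRec(
        transcript_id or f"{gene.gene_id}.t{len(gene.transcripts) + 1}",
        exons, 0, 3, sum(ex.length for ex in exons))
    return GeneModel(gene.gene_id, [*gene.transcripts, alt],
                     gene.canonical_transcript_id)


def add_alt_boundary_transcript(gene: GeneModel, exon_index: int, trim: int,
                                transcript_id: str | None = None) -> GeneModel:
    """Add an isoform whose ``exon_index`` exon has a shifted 3' boundary."""
    tx = gene.canonical
    ex = tx.exons[exon_index]
    if not 0 < trim < ex.length:
        raise FixtureError(f"trim {trim} infeasible for exon of length {ex.length}")
    if ex.strand == "+":
        alt_ex = ExonRec(f"{ex.exon_id}_alt", ex.contig, ex.start,
                         ex.end - trim, ex.strand)
    else:
        alt_ex = ExonRec(f"{ex.exon_id}_alt", ex.contig, ex.start + trim,
                         ex.end, ex.strand)
    exons = [alt_ex if i == exon_index else e for i, e in enumerate(tx.exons)]
    alt = TranscriptRec(
        transcript_id or f"{gene.gene_id}.t{len(gene.transcripts) + 1}",
        exons, 0, 3, sum(e.length for e in exons))
    return GeneModel(gene.gene_id, [*gene.transcripts, alt],
                     gene.canonical_transcript_id)


# ---------------------------------------------------------------------------
# rule-violation suite


@dataclass(frozen=True)
class ViolationCase:
    name: str
    gene: GeneModel
    genome: GenomeSequence
    exon_id: str
    offset: int | None  # None: the violated rule is exon-level only
    expected_rule: str


def make_rule_violation_suite(seed: int = 7) -> list[ViolationCase]:
    """One fixture per fail-able placement rule, each violating exactly
    that rule (cross-validated in the test suite)."""
    cases = []

    def toy(seed_off, **kw):
        kw.setdefault("intron_lengths", (150,) * (len(kw["exon_lengths"]) - 1))
        return make_toy_gene(FixtureSpec(seed=seed + seed_off, **kw))

    # five_prime_exclusion: the classic failure — gap 46 nt from the exon
    # 5' end of a constitutive exon, all other rules satisfied
    gene, genome = toy(1, exon_lengths=(250, 400, 600, 700),
                       planted=(Planted("mag_r_site", 1, 46),))
    cases.append(ViolationCase("phf21a_like", gene, genome, "exon2", 46,
                               "five_prime_exclusion"))

    gene, genome = toy(2, exon_lengths=(250, 400, 600, 700),
                       planted=(Planted("mag_r_site", 1, 350),))
    cases.append(ViolationCase("three_prime_too_close", gene, genome,
                               "exon2", 350, "three_prime_exclusion"))

    gene, genome = toy(3, exon_lengths=(250, 400, 600, 700),
                       planted=(Planted("mag_r_site", 2, 150),))
    cases.append(ViolationCase("beyond_ptc_window", gene, genome,
                               "exon3", 150, "ptc_window_max"))

    gene, genome = toy(4, exon_lengths=(250, 400, 600, 700), cds_start=450,
                       planted=(Planted("mag_r_site", 1, 280),))
    cases.append(ViolationCase("start_proximal", gene, genome,
                               "exon2", 280, "start_codon_exclusion"))

    gene, genome = toy(5, exon_lengths=(250, 120, 600, 700))
    cases.append(ViolationCase("short_exon", gene, genome, "exon2", None,
                               "min_exon_len"))

    gene, genome = toy(6, exon_lengths=(250, 400, 600, 700))
    cases.append(ViolationCase("last_exon", gene, genome, "exon4", None,
                               "last_exon"))

    gene, genome = toy(7, exon_lengths=(250, 400, 500, 300),
                       planted=(Planted("mag_r_site", 2, 150),))
    cases.append(ViolationCase("too_close_to_polyA", gene, genome,
                               "exon3", 150, "polyA_min_distance"))

    gene, genome = toy(8, exon_lengths=(250, 400, 600, 700),
                       planted=(Planted("mag_r_site", 1, 280),))
    gene = add_skipping_transcript(gene, 1)
    cases.append(ViolationCase("non_constitutive", gene, genome,
                               "exon2", 280, "constitutive"))

    return cases
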