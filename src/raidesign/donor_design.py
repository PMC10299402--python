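"""HDR donor oligos for cassette knock-in.

Because rAI cassettes are short (~200 nt), single-stranded DNA donors
with short homology arms work well provided the CRISPR-Cas9 cut site
lies within ~10 bp of the insertion gap.  Arms are copied verbatim from
the reference genome flanking the gap, on the gene's sense strand.
Published arm-length presets: 55/56 nt (default), 37/100 nt, 58/60 nt
(upstream/downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import RuleConfig
from .rai_registry import RAICassette
from .transcript_model import GeneModel, GenomeSequence, revcomp

#: published upstream/downstream arm-length combinations known to work
ARM_PRESETS = {
    "55/56": (55, 56),
    "37/100": (37, 100),
    "58/60": (58, 60),
}


class DonorDesignError(ValueError):
    pass


@dataclass(frozen=True)
class DonorOligo:
    """ssDNA repair template: up_arm + cassette + down_arm (gene sense strand
    unless ``strand`` is antisense)."""

    sequence: str
    arm_up_len: int
    arm_down_len: int
    gene_id: str
    exon_id: str
    offset: int
    cassette_name: str
    strand: str = "sense"

    def __len__(self) -> int:
        return len(self.sequence)


def design_donor(gene: GeneModel, genome: GenomeSequence, exon_id: str,
                 offset: int, cassette: RAICassette,
                 config: RuleConfig | None = None,
                 arm_up: int | None = None, arm_down: int | None = None,
                 strand: str = "sense") -> DonorOligo:
    """Build the HDR donor for one insertion gap.

    Arms default to the configured lengths (55/56).  The oligo is emitted
    on the gene's sense strand; ``strand='antisense'`` reverse-complements
    the whole oligo.
    """
    config = config or RuleConfig()
    if strand not in {"sense", "antisense"}:
        raise DonorDesignError(f"bad strand {strand!r}")
    arm_up = config.arm_len_up if arm_up is None else arm_up
    arm_down = config.arm_len_down if arm_down is None else arm_down
    ex = gene.canonical.exon_by_id(exon_id)
    if not 0 < offset < ex.length:
        raise DonorDesignError(
            f"offset {offset} outside exon {exon_id!r} of length {ex.length}"
        )
    seq = genome.sequence
    if ex.strand == "+":
        gap = ex.start + offset
        if gap - arm_up < 0 or gap + arm_down > len(seq):
            raise DonorDesignError("homology arm extends past the contig end")
        up = seq[gap - arm_up : gap]
        down = seq[gap : gap + arm_down]
    else:
        gap = ex.end - offset
        if gap + arm_up > len(seq) or gap - arm_down < 0:
            raise DonorDesignError("homology arm extends past the contig end")
        up = revcomp(seq[gap : gap + arm_up])
        down = revcomp(seq[gap - arm_down : gap])
    oligo = up + cassette.sequence + down
    if strand == "antisense":
        oligo = revcomp(oligo)
    return DonorOligo(
        sequence=oligo,
        arm_up_len=arm_up,
        arm_down_len=arm_down,
        gene_id=gene.gene_id,
        exon_id=exon_id,
        offset=offset,
        cassette_name=cassette.name,
        strand=strand,
    )


def cut_site_check(cut_pos: int, insertion_gap: int,
                   config: RuleConfig | None = None,
                   cut_contig: str | None = None,
                   gap_contig: str | None = None) -> tuple[int, str]:
    """Distance (bp) between the guide cut and the insertion gap, with a
    pass/warn verdict against the configured maximum (default 10 bp)."""
    config = config or RuleConfig()
    if cut_contig is not None and gap_contig is not None and cut_contig != gap_contig:
        raise DonorDesignError(
            f"cut site on {cut_contig!r} but insertion on {gap_contig!r}"
        )
    distance = abs(cut_pos - insertion_gap)
    verdict = "pass" if distance <= config.cut_site_max_distance else "warn"
    return distance, verdict


def write_donor_fasta(donor: DonorOligo, path) -> None:
    header = (f"{donor.gene_id}|{donor.exon_id}|gap{donor.offset}|"
              f"{donor.cassette_name}|arms{donor.arm_up_len}/{donor.arm_down_len}|"
              f"{donor.strand}")
    with open(path, "w") as fh:
        fh.write(f">{header}\n")
        for i in range(0, len(donor.sequence), 70):
            fh.write(donor.sequence[i : i + 70] + "\n")
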