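"""Registry of recombinase-regulated artificial intron (rAI) cassettes.

A cassette is a short synthetic intron carrying two direct-repeat
recombinase recognition sites (loxP for Cre, FRT for Flp) that flank its
branchpoint.  Intact, the cassette splices itself out; once the
recombinase excises the segment between the direct repeats the branchpoint
is lost and the shortened residual intron is retained in the mRNA.

The packaged DECAI / AIv4 / SCON-loxP / SCON-FRT entries are synthetic
stand-in constructs (see ``data/cassettes_synthetic.fasta``) built to the
published architecture: DECAI and AIv4 are 201 nt with a 54-nt Cre
residual (divisible by 3) and stop codons in all three frames; AIv4
differs from DECAI by the single substitution 75A>G; the SCON variants
are 189 nt with a 55-nt residual (not divisible by 3), SCON-FRT carrying
stop codons in only two frames.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import yaml
from Bio import SeqIO

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: lengths the packaged constructs must reproduce (full, residual)
EXPECTED_LENGTHS = {
    "DECAI": (201, 54),
    "AIv4": (201, 54),
    "SCON-loxP": (189, 55),
    "SCON-FRT": (189, 55),
}


class CassetteError(ValueError):
    """Raised when a cassette fails anatomical validation."""


@dataclass(frozen=True)
class RAICassette:
    """An rAI cassette, 5'->3' in the orientation inserted into the exon.

    ``site_spans`` are the two direct-repeat recombinase sites, 0-based
    half-open within the cassette.  ``residual`` is the sequence left after
    direct-repeat excision (one full site copy retained).
    """

    name: str
    sequence: str
    recombinase: str
    site_spans: tuple[tuple[int, int], tuple[int, int]]
    branchpoint_span: tuple[int, int] | None = None
    residual: str = field(init=False)

    def __post_init__(self) -> None:
        seq = self.sequence
        (s1, e1), (s2, e2) = self.site_spans
        if not (0 <= s1 < e1 <= s2 < e2 <= len(seq)) and not (s1, e1) == (s2, e2):
            raise CassetteError(
                f"{self.name}: site spans {self.site_spans} out of order or bounds"
            )
        if seq[:2] != "GT" or seq[-2:] != "AG":
            raise CassetteError(
                f"{self.name}: cassette must start GT and end AG "
                f"(found {seq[:2]}...{seq[-2:]})"
            )
        if seq[s1:e1] != seq[s2:e2]:
            raise CassetteError(
                f"{self.name}: recombinase sites are not identical direct repeats"
            )
        if self.branchpoint_span is not None:
            b1, b2 = self.branchpoint_span
            if (s1, e1) != (s2, e2) and not (e1 <= b1 < b2 <= s2):
                raise CassetteError(
                    f"{self.name}: branchpoint span {self.branchpoint_span} does "
                    f"not lie between the recombinase sites"
                )
        object.__setattr__(self, "residual", recombine(self))

    @property
    def donor_motif(self) -> str:
        return self.sequence[:2]

    @property
    def acceptor_motif(self) -> str:
        return self.sequence[-2:]

    @property
    def checksum(self) -> str:
        return hashlib.sha256(self.sequence.encode()).hexdigest()

    def __len__(self) -> int:
        return len(self.sequence)


def recombine(cassette: RAICassette) -> str:
    """Residual intron after recombinase excision between the direct repeats.

    Standard direct-repeat excision: everything from the start of site 1
    through the end of site 2 is replaced by a single (left-anchored) copy
    of the site.  Applying this to an already-recombined cassette (both
    spans equal, i.e. one site) returns the sequence unchanged.
    """
    seq = cassette.sequence
    (s1, e1), (_, e2) = cassette.site_spans
    return seq[:s1] + seq[s1:e1] + seq[e2:]


def residual_frame_shift(cassette: RAICassette) -> int:
    """Reading-frame shift caused by a retained residual: len(residual) mod 3."""
    return len(cassette.residual) % 3


def stop_codon_frames(seq: str) -> set[int]:
    """Reading-frame offsets (relative to position 0) containing >=1 stop codon."""
    return {i % 3 for i in range(len(seq) - 2) if seq[i : i + 3] in STOP_CODONS}


def load_cassettes(fasta_source, annotation_source) -> dict[str, RAICassette]:
    """Load cassettes from FASTA plus a YAML sidecar.

    The sidecar maps each record name to ``recombinase``, ``site_spans``
    (0-based half-open), optional ``branchpoint_span`` and optional
    ``sha256`` checksum, which is verified when present.
    """
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_source), "fasta")}
    with open(annotation_source) as fh:
        meta = yaml.safe_load(fh)["cassettes"]
    cassettes = {}
    for name, seq in records.items():
        if name not in meta:
            raise CassetteError(f"no sidecar annotation for cassette {name!r}")
        info = meta[name]
        expected = info.get("sha256")
        if expected is not None:
            actual = hashlib.sha256(seq.encode()).hexdigest()
            if actual != expected:
                raise CassetteError(
                    f"{name}: checksum mismatch ({actual} != {expected})"
                )
        spans = tuple(tuple(span) for span in info["site_spans"])
        bp = info.get("branchpoint_span")
        cassettes[name] = RAICassette(
            name=name,
            sequence=seq,
            recombinase=info["recombinase"],
            site_spans=spans,  # type: ignore[arg-type]
            branchpoint_span=tuple(bp) if bp else None,
        )
    return cassettes


def load_cassette(fasta_source, annotation_source, name: str | None = None) -> RAICassette:
    """Load a single cassette; ``name`` selects among multi-record files."""
    cassettes = load_cassettes(fasta_source, annotation_source)
    if name is None:
        if len(cassettes) != 1:
            raise CassetteError(
                f"file contains {len(cassettes)} cassettes; specify a name"
            )
        return next(iter(cassettes.values()))
    if name not in cassettes:
        raise CassetteError(f"cassette {name!r} not found in {sorted(cassettes)}")
    return cassettes[name]


def builtin_cassettes() -> dict[str, RAICassette]:
    """The packaged synthetic stand-in cassettes, checksum-verified, with
    their published full/residual lengths asserted."""
    data = resources.files("raidesign") / "data"
    cassettes = load_cassettes(
        data / "cassettes_synthetic.fasta", data / "cassettes_synthetic.yaml"
    )
    for name, (full_len, res_len) in EXPECTED_LENGTHS.items():
        cas = cassettes[name]
        if len(cas) != full_len or len(cas.residual) != res_len:
            raise CassetteError(
                f"{name}: packaged lengths {len(cas)}/{len(cas.residual)} do not "
                f"match expected {full_len}/{res_len}"
            )
    return cassettes


def get_cassette(name: str) -> RAICassette:
    cassettes = builtin_cassettes()
    if name not in cassettes:
        raise CassetteError(f"unknown cassette {name!r}; have {sorted(cassettes)}")
    return cassettes[name]
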