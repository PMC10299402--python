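"""Exon-selection and within-exon placement rules for rAI insertion.

Two layers of rules are applied.  Exon-level rules decide which exon can
host the cassette at all: constitutive in every annotated isoform, not
the last exon (NMD needs a downstream exon-junction complex), long
enough, far enough upstream of the polyA, and reachable at least 200 nt
downstream of the start codon.  Position-level rules then judge a
concrete insertion offset: at least 100 nt from the exon 5' end, at
least 55 nt (preferably 100) from the 3' end while staying within 400 nt
of it, and clear of the start-proximal zone.

Rules report pass/warn/fail rather than filtering silently, so a user
can deliberately bend a soft rule with predictor evidence.  Candidates
are ranked by a deterministic lexicographic order: no hard fails, fewer
warns, frameshift in every major splice product, more PTCs in the
55-400 nt junction window, closer to the exon 3' end, smaller splice
score drop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .config import RuleConfig
from .rai_registry import RAICassette
from .splice_outcome_sim import (
    apply_recombinase,
    count_ptcs_in_window,
    enumerate_products,
    insert_cassette,
)
from .transcript_model import (
    ExonRec,
    GeneModel,
    GenomeSequence,
    TranscriptRec,
    constitutive_exons,
    exon_sequence,
    to_spliced_coord,
)

__all__ = [
    "RuleConfig", "RuleResult", "RuleReport", "FramePlan", "InsertionCandidate",
    "select_exons", "find_mag_r_sites", "position_rules", "plan_frame",
    "build_candidates", "rank_candidates",
]

EXON_RULES = (
    "constitutive", "last_exon", "min_exon_len", "polyA_min_distance",
    "start_codon_window", "flanking_constitutive",
)
POSITION_RULES = (
    "five_prime_exclusion", "three_prime_exclusion", "ptc_window_max",
    "start_codon_exclusion",
)


@dataclass(frozen=True)
class RuleResult:
    rule_id: str
    verdict: str  # pass | warn | fail
    measured: float | int | str
    units: str
    threshold: float | int | str
    note: str = ""

    def __post_init__(self) -> None:
        if self.verdict not in {"pass", "warn", "fail"}:
            raise ValueError(f"bad verdict {self.verdict!r}")


@dataclass(frozen=True)
class RuleReport:
    results: tuple[RuleResult, ...]

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.results]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate rule ids in report: {ids}")

    def get(self, rule_id: str) -> RuleResult:
        for r in self.results:
            if r.rule_id == rule_id:
                return r
        raise KeyError(rule_id)

    @property
    def failed(self) -> tuple[str, ...]:
        return tuple(r.rule_id for r in self.results if r.verdict == "fail")

    @property
    def warned(self) -> tuple[str, ...]:
        return tuple(r.rule_id for r in self.results if r.verdict == "warn")

    @property
    def has_fail(self) -> bool:
        return any(r.verdict == "fail" for r in self.results)

    def merged(self, other: "RuleReport") -> "RuleReport":
        return RuleReport(self.results + other.results)


@dataclass(frozen=True)
class FramePlan:
    """Reading-frame consequences of the two major post-recombinase products.

    Scenario 1: the rAI donor splices to the downstream exon acceptor,
    deleting the exon tail — shift = tail length mod 3.  Scenario 2: the
    residual is retained — shift = residual length mod 3.  The placement
    is frameshift-proof only when both shifts are non-zero.
    """

    scenario1_shift: int
    scenario2_shift: int
    ptc_count_scenario1: int
    ptc_count_scenario2: int
    frameshift_ok: bool


@dataclass(frozen=True)
class InsertionCandidate:
    exon_id: str
    offset: int  # 0-based gap index within the exon
    motif: str  # e.g. "CAG-G"
    rule_report: RuleReport
    frame_plan: FramePlan
    rank_score: float = 0.0
    tail: int = 0  # nt from insertion gap to exon 3' end
    score_drop_percent: float | None = None


def _verdict(measured, fail_when, warn_when=None) -> str:
    if fail_when:
        return "fail"
    if warn_when:
        return "warn"
    return "pass"


def select_exons(gene: GeneModel, config: RuleConfig | None = None
                 ) -> list[tuple[str, RuleReport]]:
    """Exon-level rule reports for every exon of the canonical transcript.

    Single-exon genes waive the last-exon and polyA rules (no junctions:
    NMD by junction marking cannot occur; knockout must rely on the long
    3'UTR and truncation instead, which the report notes).  For the last
    exon of a multi-exon gene, the polyA rule is reported as subsumed by
    the hard last-exon failure.
    """
    config = config or RuleConfig()
    tx = gene.canonical
    const = constitutive_exons(gene)
    single_exon = len(tx.exons) == 1
    reports = []
    for i, ex in enumerate(tx.exons):
        is_last = i == len(tx.exons) - 1
        results = []

        results.append(RuleResult(
            "constitutive",
            "pass" if ex.exon_id in const else "fail",
            "identical in all transcripts" if ex.exon_id in const else
            "boundary or presence varies",
            "", "required",
        ))

        if single_exon:
            results.append(RuleResult(
                "last_exon", "pass", "single-exon gene", "", "waived",
                note="no exon junctions: knockout must rely on long-3'UTR "
                     "degradation and truncation",
            ))
        else:
            results.append(RuleResult(
                "last_exon", "fail" if is_last else "pass",
                "last exon" if is_last else f"exon {i + 1} of {len(tx.exons)}",
                "", "not last",
            ))

        results.append(RuleResult(
            "min_exon_len",
            _verdict(ex.length, ex.length < config.min_exon_len,
                     ex.length < config.preferred_exon_len),
            ex.length, "nt", config.min_exon_len,
        ))

        if single_exon or is_last:
            results.append(RuleResult(
                "polyA_min_distance", "pass",
                "not applicable", "nt", config.polyA_min_distance,
                note="single-exon gene" if single_exon
                else "subsumed by last-exon rule",
            ))
        else:
            dist = tx.polyA_pos - to_spliced_coord(tx, ex.exon_id, ex.length)
            results.append(RuleResult(
                "polyA_min_distance",
                _verdict(dist, dist < config.polyA_min_distance,
                         dist < config.polyA_preferred_distance),
                dist, "nt", config.polyA_min_distance,
            ))

        # furthest-3' insertion gap must clear the start-proximal zone
        max_gap = to_spliced_coord(tx, ex.exon_id, ex.length) - 1
        reach = max_gap - tx.cds_start
        results.append(RuleResult(
            "start_codon_window",
            "pass" if reach >= config.start_codon_exclusion else "fail",
            reach, "nt", config.start_codon_exclusion,
        ))

        neighbors = [tx.exons[j].exon_id for j in (i - 1, i + 1)
                     if 0 <= j < len(tx.exons)]
        flank_ok = all(n in const for n in neighbors)
        results.append(RuleResult(
            "flanking_constitutive", "pass" if flank_ok else "warn",
            "constitutive" if flank_ok else "variable neighbor", "", "preferred",
        ))
        reports.append((ex.exon_id, RuleReport(tuple(results))))
    return reports


def find_mag_r_sites(exon_seq: str) -> list[tuple[int, str]]:
    """All MAG-R insertion points: gap offsets where the 3 nt upstream are
    AAG or CAG and the next base is A or G.  Inserting the cassette in the
    gap recreates canonical donor (MAG|GT...) and acceptor (...AG|R)
    junction context."""
    sites = []
    for o in range(3, len(exon_seq)):
        if exon_seq[o - 3 : o] in {"AAG", "CAG"} and exon_seq[o] in {"A", "G"}:
            sites.append((o, f"{exon_seq[o - 3:o]}-{exon_seq[o]}"))
    return sites


def position_rules(exon: ExonRec, offset: int, tx: TranscriptRec,
                   config: RuleConfig | None = None) -> RuleReport:
    """Within-exon placement rules for one insertion gap offset."""
    config = config or RuleConfig()
    if not 0 < offset < exon.length:
        raise ValueError(
            f"offset {offset} outside exon {exon.exon_id!r} of length {exon.length}"
        )
    tail = exon.length - offset
    results = [
        RuleResult(
            "five_prime_exclusion",
            "fail" if offset < config.five_prime_exclusion else "pass",
            offset, "nt", config.five_prime_exclusion,
            note="distance measured to the insertion gap index",
        ),
        RuleResult(
            "three_prime_exclusion",
            _verdict(tail, tail < config.three_prime_exclusion,
                     tail < config.three_prime_preferred),
            tail, "nt", config.three_prime_exclusion,
        ),
        RuleResult(
            "ptc_window_max",
            "fail" if tail > config.ptc_window_max else "pass",
            tail, "nt", config.ptc_window_max,
        ),
    ]
    spliced = to_spliced_coord(tx, exon.exon_id, offset)
    from_start = spliced - tx.cds_start
    results.append(RuleResult(
        "start_codon_exclusion",
        "fail" if from_start < config.start_codon_exclusion else "pass",
        from_start, "nt", config.start_codon_exclusion,
    ))
    return RuleReport(tuple(results))


def plan_frame(gene: GeneModel, genome: GenomeSequence, exon_id: str,
               offset: int, cassette: RAICassette,
               config: RuleConfig | None = None) -> FramePlan:
    """Reading-frame plan for one placement, with PTC counts from the
    simulated post-recombinase products."""
    config = config or RuleConfig()
    tx = gene.canonical
    ex = tx.exon_by_id(exon_id)
    i = tx.exon_index(exon_id)
    scenario1 = (ex.length - offset) % 3
    scenario2 = len(cassette.residual) % 3
    allele = apply_recombinase(
        insert_cassette(gene, genome, exon_id, offset, cassette))
    products = {p.scenario: p for p in enumerate_products(allele, config=config)}
    n1 = n2 = 0
    if "rai_sds_to_downstream_sas" in products:
        n1 = count_ptcs_in_window(products["rai_sds_to_downstream_sas"].ptcs, config)
    elif i == len(tx.exons) - 1 and len(tx.exons) > 1:
        raise ValueError("no downstream exon: scenario 1 undefined for the last exon")
    n2 = count_ptcs_in_window(products["exon_sds_retained_residual"].ptcs, config)
    return FramePlan(
        scenario1_shift=scenario1,
        scenario2_shift=scenario2,
        ptc_count_scenario1=n1,
        ptc_count_scenario2=n2,
        frameshift_ok=scenario1 != 0 and scenario2 != 0,
    )


def build_candidates(gene: GeneModel, genome: GenomeSequence,
                     cassette: RAICassette,
                     config: RuleConfig | None = None) -> list[InsertionCandidate]:
    """Enumerate every MAG-R site in every exon of the canonical transcript
    and attach rule reports and frame plans."""
    config = config or RuleConfig()
    tx = gene.canonical
    exon_reports = dict(select_exons(gene, config))
    candidates = []
    for i, ex in enumerate(tx.exons):
        seq = exon_sequence(ex, genome)
        exon_report = _drop_rule(exon_reports[ex.exon_id], "start_codon_window")
        for offset, motif in find_mag_r_sites(seq):
            pos_report = position_rules(ex, offset, tx, config)
            if i == len(tx.exons) - 1 and len(tx.exons) > 1:
                plan = FramePlan((ex.length - offset) % 3,
                                 len(cassette.residual) % 3, 0, 0, False)
            else:
                plan = plan_frame(gene, genome, ex.exon_id, offset, cassette, config)
            candidates.append(InsertionCandidate(
                exon_id=ex.exon_id,
                offset=offset,
                motif=motif,
                rule_report=exon_report.merged(pos_report),
                frame_plan=plan,
                tail=ex.length - offset,
            ))
    return rank_candidates(candidates, tx)


def candidate_report(gene: GeneModel, exon_id: str, offset: int | None,
                     config: RuleConfig | None = None) -> RuleReport:
    """Combined rule report for an explicit placement (audit mode).

    With an offset, exon-level rules are merged with the position rules
    (the coarse exon-level start-codon reachability check is replaced by
    the exact position-level measurement).  Without an offset only the
    exon-level report is returned.
    """
    config = config or RuleConfig()
    exon_report = dict(select_exons(gene, config))[exon_id]
    if offset is None:
        return exon_report
    tx = gene.canonical
    pos_report = position_rules(tx.exon_by_id(exon_id), offset, tx, config)
    return _drop_rule(exon_report, "start_codon_window").merged(pos_report)


def _drop_rule(report: RuleReport, rule_id: str) -> RuleReport:
    """Remove the exon-level start-codon reachability rule from candidate
    reports: candidates carry the exact position-level measurement instead."""
    return RuleReport(tuple(r for r in report.results if r.rule_id != rule_id))


def _sort_key(cand: InsertionCandidate, exon_order: dict[str, int]):
    drop = cand.score_drop_percent
    return (
        cand.rule_report.has_fail,
        len(cand.rule_report.failed),
        len(cand.rule_report.warned),
        not cand.frame_plan.frameshift_ok,
        -max(cand.frame_plan.ptc_count_scenario1,
             cand.frame_plan.ptc_count_scenario2),
        cand.tail,
        drop if drop is not None else 0.0,
        exon_order.get(cand.exon_id, len(exon_order)),
        cand.offset,
    )


def rank_candidates(candidates: list[InsertionCandidate],
                    tx: TranscriptRec | None = None) -> list[InsertionCandidate]:
    """Deterministic total order; hard-fail candidates sort last.

    ``rank_score`` is a 0-1000 display score for BED output derived from
    the same components the ordering uses.
    """
    exon_order = ({ex.exon_id: i for i, ex in enumerate(tx.exons)} if tx else {})
    ranked = sorted(candidates, key=lambda c: _sort_key(c, exon_order))
    out = []
    for cand in ranked:
        out.append(replace(cand, rank_score=_rank_score(cand)))
    return out


def _rank_score(cand: InsertionCandidate) -> float:
    if cand.rule_report.has_fail:
        return 0.0
    score = 400.0 - 40.0 * len(cand.rule_report.warned)
    score = max(score, 0.0)
    if cand.frame_plan.frameshift_ok:
        score += 250.0
    n_ptc = max(cand.frame_plan.ptc_count_scenario1,
                cand.frame_plan.ptc_count_scenario2)
    score += 200.0 * min(n_ptc, 3) / 3.0
    score += 150.0 * max(0.0, 1.0 - cand.tail / 400.0)
    return round(min(score, 1000.0), 1)
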