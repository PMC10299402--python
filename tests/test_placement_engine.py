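"""Exon-selection rules, MAG-R scanning, frame planning and ranking."""

import random
from dataclasses import replace

import pytest

from raidesign.config import RuleConfig
from raidesign.placement_engine import (
    EXON_RULES,
    POSITION_RULES,
    FramePlan,
    InsertionCandidate,
    RuleReport,
    RuleResult,
    build_candidates,
    find_mag_r_sites,
    plan_frame,
    position_rules,
    rank_candidates,
    select_exons,
)
from raidesign.synthetic_fixtures import FixtureSpec, Planted, make_toy_gene
from raidesign.transcript_model import ExonRec


@pytest.fixture(scope="module")
def wide_gene():
    """4-exon gene with a comfortably rule-passing internal exon."""
    return make_toy_gene(FixtureSpec(
        seed=11, exon_lengths=(250, 400, 600, 700),
        intron_lengths=(150, 150, 150),
        planted=(Planted("mag_r_site", 1, 280),)))


@pytest.mark.parametrize("seq,expected", [
    ("TTCAGGTT", [(5, "CAG-G")]),
    ("TTAAGATT", [(5, "AAG-A")]),
    ("TTTAGGTT", []),          # TAG: T is not M
    ("CAGG", [(3, "CAG-G")]),
    ("CAGT", []),              # T is not R
])
def test_find_mag_r_sites(seq, expected):
    assert find_mag_r_sites(seq) == expected


class TestSelectExons:
    def test_last_exon_fails_last_exon_rule(self, wide_gene):
        gene, _ = wide_gene
        reports = dict(select_exons(gene))
        assert reports["exon4"].get("last_exon").verdict == "fail"

    def test_short_internal_exon_fails_length_rule(self):
        gene, _ = make_toy_gene(FixtureSpec(
            seed=12, exon_lengths=(250, 120, 600, 700),
            intron_lengths=(150, 150, 150)))
        rep = dict(select_exons(gene))["exon2"]
        assert rep.get("min_exon_len").verdict == "fail"
        assert rep.get("min_exon_len").measured == 120

    def test_good_internal_exon_passes_everything(self, wide_gene):
        gene, _ = wide_gene
        rep = dict(select_exons(gene))["exon2"]
        assert not rep.has_fail and not rep.warned

    def test_every_exon_rule_reported_exactly_once(self, wide_gene):
        gene, _ = wide_gene
        for _, rep in select_exons(gene):
            assert sorted(r.rule_id for r in rep.results) == sorted(EXON_RULES)

    def test_single_exon_gene_waives_junction_rules(self):
        gene, _ = make_toy_gene(FixtureSpec(
            seed=13, exon_lengths=(1500,), intron_lengths=()))
        rep = dict(select_exons(gene))["exon1"]
        assert rep.get("last_exon").verdict == "pass"
        assert "long-3'UTR" in rep.get("last_exon").note


class TestPositionRules:
    EXON = ExonRec("e", "chrT", 0, 250, "+")

    def _tx(self, exon_len=250):
        from raidesign.transcript_model import TranscriptRec
        ex = ExonRec("e", "chrT", 0, exon_len, "+")
        return ex, TranscriptRec("t", [ex], 0, exon_len - exon_len % 3, exon_len)

    def test_offset_46_fails_five_prime_rule(self):
        ex, tx = self._tx()
        rep = position_rules(ex, 46, tx, RuleConfig(start_codon_exclusion=0))
        assert rep.get("five_prime_exclusion").verdict == "fail"
        assert rep.get("five_prime_exclusion").measured == 46

    def test_mid_exon_offset_passes_both_end_rules(self):
        ex, tx = self._tx(300)
        rep = position_rules(ex, 150, tx, RuleConfig(start_codon_exclusion=0))
        assert rep.get("five_prime_exclusion").verdict == "pass"
        assert rep.get("three_prime_exclusion").verdict == "pass"  # tail 150

    def test_tail_in_warn_band_warns_3prime(self):
        ex, tx = self._tx(300)
        rep = position_rules(ex, 220, tx, RuleConfig(start_codon_exclusion=0))
        assert rep.get("three_prime_exclusion").verdict == "warn"  # tail 80

    def test_tail_below_55_fails_3prime_rule(self):
        ex, tx = self._tx(300)
        rep = position_rules(ex, 280, tx, RuleConfig(start_codon_exclusion=0))
        assert rep.get("three_prime_exclusion").verdict == "fail"
        assert rep.get("three_prime_exclusion").measured == 20

    def test_every_position_rule_reported_exactly_once(self):
        ex, tx = self._tx(300)
        rep = position_rules(ex, 150, tx, RuleConfig(start_codon_exclusion=0))
        assert sorted(r.rule_id for r in rep.results) == sorted(POSITION_RULES)

    def test_out_of_range_offset_rejected(self):
        ex, tx = self._tx()
        with pytest.raises(ValueError):
            position_rules(ex, 0, tx)


class TestPlanFrame:
    def test_scenario_shifts(self, wide_gene, scon, decai):
        gene, genome = wide_gene
        plan = plan_frame(gene, genome, "exon2", 280, scon)
        assert plan.scenario1_shift == (400 - 280) % 3 == 0
        assert plan.scenario2_shift == 1
        assert not plan.frameshift_ok  # scenario 1 stays in frame
        plan_d = plan_frame(gene, genome, "exon2", 280, decai)
        assert plan_d.scenario2_shift == 0
        assert not plan_d.frameshift_ok

    def test_out_of_frame_tail_with_scon_is_frameshift_ok(self, wide_gene, scon):
        gene, genome = wide_gene
        plan = plan_frame(gene, genome, "exon2", 279, scon)
        assert plan.scenario1_shift == 121 % 3 == 1
        assert plan.frameshift_ok


def _mk_candidate(offset, tail, frameshift_ok=True, n_ptc=2, warns=0,
                  fails=0, exon_id="exon2"):
    results = [RuleResult(f"w{i}", "warn", 0, "nt", 0) for i in range(warns)]
    results += [RuleResult(f"f{i}", "fail", 0, "nt", 0) for i in range(fails)]
    results += [RuleResult("ok", "pass", 0, "nt", 0)]
    return InsertionCandidate(
        exon_id=exon_id, offset=offset, motif="CAG-G",
        rule_report=RuleReport(tuple(results)),
        frame_plan=FramePlan(1, 1, n_ptc, n_ptc, frameshift_ok),
        tail=tail)


class TestRanking:
    def test_closer_to_3prime_end_ranks_first(self):
        ranked = rank_candidates([_mk_candidate(150, 200), _mk_candidate(200, 150)])
        assert [c.offset for c in ranked] == [200, 150]

    def test_frameshift_ok_ranks_first(self):
        a = _mk_candidate(150, 200, frameshift_ok=False)
        b = _mk_candidate(150, 200, frameshift_ok=True)
        ranked = rank_candidates([a, b])
        assert ranked[0].frame_plan.frameshift_ok

    def test_hard_fail_sorts_last_with_zero_score(self):
        bad = _mk_candidate(260, 90, fails=1)
        good = _mk_candidate(150, 200, warns=2)
        ranked = rank_candidates([bad, good])
        assert ranked[0].offset == 150
        assert ranked[-1].rank_score == 0.0

    def test_more_windowed_ptcs_rank_first(self):
        ranked = rank_candidates([_mk_candidate(150, 200, n_ptc=1),
                                  _mk_candidate(150, 200, n_ptc=3)])
        assert ranked[0].frame_plan.ptc_count_scenario1 == 3

    def test_empty_input_gives_empty_output(self):
        assert rank_candidates([]) == []

    def test_order_is_deterministic_under_shuffling(self, wide_gene, scon):
        gene, genome = wide_gene
        cands = build_candidates(gene, genome, scon)
        key = [(c.exon_id, c.offset) for c in cands]
        rng = random.Random(5)
        for _ in range(3):
            shuffled = list(cands)
            rng.shuffle(shuffled)
            assert [(c.exon_id, c.offset)
                    for c in rank_candidates(shuffled, gene.canonical)] == key


def test_relaxing_a_threshold_never_removes_a_passing_candidate(wide_gene, scon):
    gene, genome = wide_gene
    strict = RuleConfig()
    relaxed = RuleConfig(five_prime_exclusion=50, three_prime_exclusion=40,
                         polyA_min_distance=300, min_exon_len=100)
    def passing(cfg):
        return {(c.exon_id, c.offset)
                for c in build_candidates(gene, genome, scon, cfg)
                if not c.rule_report.has_fail}
    assert passing(strict) <= passing(relaxed)


def test_candidate_reports_cover_all_rules_exactly_once(wide_gene, scon):
    gene, genome = wide_gene
    expected = sorted(set(EXON_RULES) - {"start_codon_window"}
                      | set(POSITION_RULES))
    for cand in build_candidates(gene, genome, scon):
        assert sorted(r.rule_id for r in cand.rule_report.results) == expected
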