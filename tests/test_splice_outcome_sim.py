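"""Edited-allele construction, self-splicing, recombination and PTC annotation."""

import pytest
from Bio.Seq import Seq

from raidesign.placement_engine import find_mag_r_sites
from raidesign.splice_outcome_sim import (
    SimulationError,
    annotate_ptcs,
    apply_recombinase,
    count_ptcs_in_window,
    enumerate_products,
    insert_cassette,
    simulate_pre_splice,
)
from raidesign.splice_outcome_sim import PTC
from raidesign.synthetic_fixtures import FixtureSpec, Planted, make_toy_gene
from raidesign.transcript_model import exon_sequence, spliced_mrna


@pytest.fixture(scope="module")
def allele(toy, scon):
    gene, genome = toy
    return insert_cassette(gene, genome, "exon2", 180, scon)


def test_insert_grows_edited_region_by_cassette_length(allele, scon):
    exon_len = allele.transcript.exon_by_id("exon2").length
    assert len(allele.edited_exon_seq) == exon_len + len(scon)
    assert len(allele.edited_genome()) == len(allele.genome) + len(scon)


def test_edited_genome_lifts_downstream_sequence(allele):
    gap = allele.insertion_gap_genomic
    edited = allele.edited_genome().sequence
    original = allele.genome.sequence
    assert edited[:gap] == original[:gap]
    assert edited[gap + len(allele.insert_seq):] == original[gap:]


@pytest.mark.parametrize("offset", [0, 250])
def test_insertion_at_exon_boundary_rejected(toy, scon, offset):
    gene, genome = toy
    with pytest.raises(SimulationError, match="strictly inside"):
        insert_cassette(gene, genome, "exon2", offset, scon)


def test_self_splice_restores_wild_type_at_any_mag_r_gap(toy, scon):
    gene, genome = toy
    wt = spliced_mrna(gene.canonical, genome)
    exon2 = exon_sequence(gene.canonical.exons[1], genome)
    offsets = [o for o, _ in find_mag_r_sites(exon2)]
    assert offsets, "fixture must contain MAG-R gaps"
    mrnas = set()
    for o in offsets:
        pre = simulate_pre_splice(insert_cassette(gene, genome, "exon2", o, scon))
        mrnas.add(pre.mrna)
        assert pre.ptcs == ()
    assert mrnas == {wt}  # all placements restore the identical wild type


def test_self_splice_preserves_protein(allele):
    gene, genome = allele.gene, allele.genome
    tx = gene.canonical
    wt = spliced_mrna(tx, genome)
    pre = simulate_pre_splice(allele)
    wt_protein = str(Seq(wt[tx.cds_start:tx.cds_end]).translate())
    pre_protein = str(Seq(pre.mrna[tx.cds_start:tx.cds_end]).translate())
    assert pre_protein == wt_protein
    assert pre_protein.count("*") == 1 and pre_protein.endswith("*")


class TestRecombinase:
    def test_decai_edit_shrinks_by_147(self, toy, decai):
        gene, genome = toy
        allele = insert_cassette(gene, genome, "exon2", 180, decai)
        post = apply_recombinase(allele)
        assert len(allele.edited_exon_seq) - len(post.edited_exon_seq) == 201 - 54

    def test_scon_edit_shrinks_by_134(self, allele):
        post = apply_recombinase(allele)
        assert len(allele.edited_exon_seq) - len(post.edited_exon_seq) == 189 - 55

    def test_double_application_rejected(self, allele):
        post = apply_recombinase(allele)
        with pytest.raises(SimulationError, match="already"):
            apply_recombinase(post)

    def test_pre_splice_requires_intact_cassette(self, allele):
        with pytest.raises(SimulationError):
            simulate_pre_splice(apply_recombinase(allele))


class TestProducts:
    def test_scenario1_loses_the_exon_tail(self, toy, scon):
        gene, genome = toy
        wt = spliced_mrna(gene.canonical, genome)
        post = apply_recombinase(insert_cassette(gene, genome, "exon2", 180, scon))
        prods = {p.scenario: p for p in enumerate_products(post)}
        s1 = prods["rai_sds_to_downstream_sas"]
        tail = 250 - 180
        assert len(s1.mrna) == len(wt) - tail
        assert s1.frame_shift == tail % 3

    def test_scenario2_retains_the_55nt_residual(self, toy, scon):
        gene, genome = toy
        wt = spliced_mrna(gene.canonical, genome)
        post = apply_recombinase(insert_cassette(gene, genome, "exon2", 180, scon))
        s2 = {p.scenario: p for p in enumerate_products(post)}[
            "exon_sds_retained_residual"]
        assert len(s2.mrna) == len(wt) + 55
        assert scon.residual in s2.mrna
        assert s2.frame_shift == 1

    def test_decai_retained_residual_stays_in_frame_with_insert_ptc(self, toy, decai):
        gene, genome = toy
        post = apply_recombinase(insert_cassette(gene, genome, "exon2", 180, decai))
        s2 = {p.scenario: p for p in enumerate_products(post)}[
            "exon_sds_retained_residual"]
        assert s2.frame_shift == 0
        # the residual carries stops in all 3 frames, so one lands in frame
        gap = sum(ex.length for ex in gene.canonical.exons[:1]) + 180
        insert_ptcs = [p for p in s2.ptcs if gap <= p.position < gap + 54]
        assert insert_ptcs, "expected a PTC inside the retained residual"

    def test_products_differ_from_wild_type_only_downstream_of_insertion(
            self, toy, scon):
        gene, genome = toy
        wt = spliced_mrna(gene.canonical, genome)
        gap = gene.canonical.exons[0].length + 180
        post = apply_recombinase(insert_cassette(gene, genome, "exon2", 180, scon))
        for p in enumerate_products(post):
            if p.scenario == "exon_skip":
                continue  # loses sequence upstream of the gap by construction
            assert p.mrna[:gap] == wt[:gap]

    def test_exon_skip_removes_whole_edited_exon(self, toy, scon):
        gene, genome = toy
        post = apply_recombinase(insert_cassette(gene, genome, "exon2", 180, scon))
        skip = {p.scenario: p for p in enumerate_products(post)}["exon_skip"]
        tx = gene.canonical
        assert len(skip.mrna) == tx.spliced_length - tx.exons[1].length

    def test_single_exon_gene_emits_only_residual_retention(self, scon):
        gene, genome = make_toy_gene(FixtureSpec(
            seed=21, exon_lengths=(1500,), intron_lengths=()))
        gap = next(o for o, _ in find_mag_r_sites(
            exon_sequence(gene.canonical.exons[0], genome)) if 200 < o < 1100)
        post = apply_recombinase(insert_cassette(gene, genome, "exon1", gap, scon))
        prods = enumerate_products(post)
        assert {p.scenario for p in prods} == {"exon_sds_retained_residual"}

    def test_planted_cryptic_donor_triggers_upstream_fusion(self, scon, config):
        gene, genome = make_toy_gene(FixtureSpec(
            seed=22, planted=(Planted("cryptic_donor", 1, 60),
                              Planted("mag_r_site", 1, 180))))
        post = apply_recombinase(insert_cassette(gene, genome, "exon2", 180, scon))
        scenarios = [p.scenario for p in enumerate_products(post)]
        assert "rai_sas_upstream_fusion" in scenarios


class TestPtcAnnotation:
    def _oracle(self, mrna, cds_start, wt_stop):
        """Independent oracle: positions of '*' in the translated suffix."""
        n = len(mrna) - cds_start
        protein = str(Seq(mrna[cds_start : cds_start + 3 * (n // 3)]).translate())
        return [cds_start + 3 * i
                for i, aa in enumerate(protein) if aa == "*"
                if cds_start + 3 * i < wt_stop]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_translation_oracle_on_all_products(self, seed, scon, config):
        gene, genome = make_toy_gene(FixtureSpec(seed=seed))
        exon2 = exon_sequence(gene.canonical.exons[1], genome)
        gaps = [o for o, _ in find_mag_r_sites(exon2)][:3]
        for gap in gaps:
            post = apply_recombinase(
                insert_cassette(gene, genome, "exon2", gap, scon))
            for p in enumerate_products(post):
                expected = self._oracle(p.mrna, p.cds_start, p.wt_stop_position)
                assert [x.position for x in p.ptcs] == expected

    def test_wild_type_product_has_zero_ptcs(self, allele):
        pre = simulate_pre_splice(allele)
        assert pre.ptcs == ()
        assert annotate_ptcs(pre, allele.transcript) == []

    def test_window_bounds_are_inclusive(self, config):
        def ptc(dist):
            return PTC(position=1000, distance_to_next_junction_3prime=dist,
                       distance_from_start_codon=500, in_last_exon=False,
                       in_penultimate_tail=False)
        assert count_ptcs_in_window([ptc(55)], config) == 1
        assert count_ptcs_in_window([ptc(54)], config) == 0
        assert count_ptcs_in_window([ptc(400)], config) == 1
        assert count_ptcs_in_window([ptc(401)], config) == 0
        assert count_ptcs_in_window([ptc(None)], config) == 0
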