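"""Mutasome complex typing: colocalization, decision table, score filter."""

import pytest

from polcensus import complement_annotator as ca
from polcensus import complex_typer as ct
from polcensus import synthetic_data as sd
from polcensus.sequence_io import ProteinRecord


def _rec(pid, contig="c1", idx=None):
    return ProteinRecord(pid, "g", "M" * 10, contig, idx)


class TestColocalize:
    def test_adjacent_genes_colocalized(self):
        assert ct.colocalize([_rec("a", idx=10), _rec("b", idx=11)]) == ct.COLOCALIZED

    def test_different_contigs_co_occurrence(self):
        assert ct.colocalize([_rec("a", "c1", 10), _rec("b", "c2", 11)]) \
            == ct.CO_OCCURRENCE

    def test_window_boundary(self):
        assert ct.colocalize([_rec("a", idx=10), _rec("b", idx=15)],
                             window=5) == ct.COLOCALIZED
        assert ct.colocalize([_rec("a", idx=10), _rec("b", idx=16)],
                             window=5) == ct.CO_OCCURRENCE

    def test_unknown_context_warns(self):
        with pytest.warns(UserWarning):
            assert ct.colocalize([_rec("a", idx=None)]) == ct.CO_OCCURRENCE


@pytest.fixture(scope="module")
def showcase(registry, profiles):
    out = {}
    for plan in sd.complex_showcase_plans():
        sim = sd.simulate_genome(plan, registry, seed=1, mutation_rate=0.0)
        comp = ca.annotate_genome(sim.records, registry, profiles=profiles)
        out[plan.genome_id] = (plan, comp)
    return out


class TestDecisionTable:
    def test_all_eleven_types_recovered(self, showcase):
        recovered = 0
        for gid, (plan, comp) in showcase.items():
            got = sorted(c.complex_id for c in comp.complexes)
            if got == sorted(plan.expected_complexes):
                recovered += 1
        assert recovered == len(showcase) == 12

    def test_operon_members_colocalized(self, showcase):
        _, comp = showcase["cx02"]
        assert comp.complexes[0].evidence_level == ct.COLOCALIZED

    def test_solo_poly_no_calls(self, showcase):
        _, comp = showcase["cx12_solo"]
        assert comp.complexes == []
        solo = [a for a in comp.census() if a.group == "DinP"]
        assert solo and solo[0].recA_NT is False

    def test_variant_labels(self, showcase):
        _, comp = showcase["cx03"]
        assert comp.complexes[0].variant == "YqjX"
        _, comp6 = showcase["cx06"]
        assert comp6.complexes[0].variant == "scDinB2-like"

    def test_small_subunit_variants(self, registry, profiles):
        for small, label in (("YqjX-NTonly", "YqjX-NTonly"), ("YhjD", "YhjD")):
            plan = sd.GenomePlan("g", [
                sd.GenePlan("DnaE1"), sd.GenePlan("YqjW", operon="op"),
                sd.GenePlan(small, operon="op"), sd.GenePlan("RecA", operon="op")],
                decoys=0, expected_complexes=["YqjW-YqjX-RecA"])
            sim = sd.simulate_genome(plan, registry, seed=2, mutation_rate=0.0)
            comp = ca.annotate_genome(sim.records, registry, profiles=profiles)
            assert [c.complex_id for c in comp.complexes] == ["YqjW-YqjX-RecA"]
            assert comp.complexes[0].variant == label

    def test_polv_alongside_imuab_dnae2(self, registry, profiles):
        """A genome may host several calls of different types."""
        plan = sd.GenomePlan("g", [
            sd.GenePlan("DnaE1"),
            sd.GenePlan("UmuC", operon="op1"), sd.GenePlan("UmuD", operon="op1"),
            sd.GenePlan("RecA"),
            sd.GenePlan("DnaE2A", operon="op2"), sd.GenePlan("ImuB1", operon="op2"),
            sd.GenePlan("ImuA", operon="op2")], decoys=1)
        sim = sd.simulate_genome(plan, registry, seed=3, mutation_rate=0.0)
        comp = ca.annotate_genome(sim.records, registry, profiles=profiles)
        got = sorted(c.complex_id for c in comp.complexes)
        assert got == ["ImuA-ImuB-DnaE2", "UmuC-UmuD2-RecA"]

    def test_reca_nt_poly_always_called_in_reca_positive_genome(
            self, registry, profiles):
        """Fallback invariant: every RecA-NT PolY in a RecA-positive genome
        lands in at least one call; a PolY with no typed partner becomes
        PolY-RecA."""
        plan = sd.GenomePlan("g", [
            sd.GenePlan("DnaE1"),
            sd.GenePlan("UmuC", operon="op"), sd.GenePlan("UmuD", operon="op"),
            sd.GenePlan("PolY-core", recA_NT=True), sd.GenePlan("RecA")],
            decoys=0)
        sim = sd.simulate_genome(plan, registry, seed=4, mutation_rate=0.0)
        comp = ca.annotate_genome(sim.records, registry, profiles=profiles)
        got = sorted(c.complex_id for c in comp.complexes)
        assert got == ["PolY-RecA", "UmuC-UmuD2-RecA"]
        called = {pid for c in comp.complexes for pid in c.member_ids}
        for ann in comp.census():
            if ann.is_polY and ann.recA_NT:
                assert ann.protein_id in called

    def test_no_reca_no_fallback(self, registry, profiles):
        plan = sd.GenomePlan("g", [sd.GenePlan("DnaE1"),
                                   sd.GenePlan("PolY-core", recA_NT=True)],
                             decoys=0)
        sim = sd.simulate_genome(plan, registry, seed=5, mutation_rate=0.0)
        comp = ca.annotate_genome(sim.records, registry, profiles=profiles)
        assert comp.complexes == []
        options = ca.AnnotateOptions(assume_recA=True)
        comp2 = ca.annotate_genome(sim.records, registry, profiles=profiles,
                                   options=options)
        assert [c.complex_id for c in comp2.complexes] == ["PolY-RecA"]


class TestModelScoreFilter:
    @pytest.mark.parametrize("source,iptm,glob,clash,expected", [
        ("multimer-v2", 0.80, 0.45, False, True),
        ("multimer-v2", 0.65, None, False, True),     # at threshold passes
        ("multimer-v2", 0.649, None, False, False),
        ("v3", 0.70, None, False, True),
        ("v3", 0.68, None, False, False),             # below the v3 threshold
        ("multimer-v2", 0.80, 0.35, False, False),    # fails the global check
        ("multimer-v2", 0.80, 0.40, False, False),    # strictly greater needed
        ("multimer-v2", 0.80, 0.45, True, False),     # clash vetoes
    ])
    def test_thresholds(self, source, iptm, glob, clash, expected):
        score = ct.ModelScore("k", source, 0.8, iptm, glob, clash)
        ok, reasons = ct.model_score_passes(score)
        assert ok is expected, reasons

    def test_call_without_score_unfiltered(self):
        call = ct.ComplexCall("g", "PolY-RecA")
        ok, reasons = ct.apply_model_score_filter({}, call)
        assert ok and "sequence evidence" in reasons[0]

    def test_load_model_scores_skips_malformed(self, tmp_path):
        p = tmp_path / "scores.tsv"
        p.write_text("genome_id\tcomplex_id\tsource\tpTM\tipTM\tglobal\tclash\n"
                     "g1\tPolY-RecA\tmultimer-v2\t0.8\t0.9\t0.5\t0\n"
                     "g2\tPolY-RecA\tv3\tbad\tworse\t.\t0\n"
                     "g3\tPolY-RecA\tv3\t0.9\t1.4\t.\t0\n")
        with pytest.warns(UserWarning):
            scores = ct.load_model_scores(p)
        assert list(scores) == ["g1/PolY-RecA"]

    def test_failing_score_vetoes_call(self, registry, profiles):
        plan = sd.GenomePlan("g", [sd.GenePlan("DnaE1"),
                                   sd.GenePlan("PolY-core", recA_NT=True),
                                   sd.GenePlan("RecA")], decoys=0)
        sim = sd.simulate_genome(plan, registry, seed=6, mutation_rate=0.0)
        scores = {"g/PolY-RecA": ct.ModelScore("g/PolY-RecA", "v3", 0.6, 0.55)}
        comp = ca.annotate_genome(sim.records, registry, profiles=profiles,
                                  model_scores=scores)
        assert comp.complexes == []
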