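"""Replication-system typing, proofreader census, exonuclease
complementation, and the per-genome orchestrator."""

import itertools

import pytest

from polcensus import complement_annotator as ca
from polcensus import synthetic_data as sd


def _fake_ann(pid, family=None, group=None, **flags):
    ann = ca.PolymeraseAnnotation(protein_id=pid, family=family, group=group)
    return ann


class TestReplicationSystem:
    def test_exhaustive_truth_table(self):
        """All 16 presence/absence combinations of {PolC, DnaE1, DnaE3,
        DnaE2}: three systems, DnaE2 never replicative, error when no
        DnaE-type subunit exists."""
        for polc, e1, e3, e2 in itertools.product([0, 1], repeat=4):
            anns = []
            if polc:
                anns.append(_fake_ann("pc", "C", "PolC"))
            if e1:
                anns.append(_fake_ann("e1", "C", "DnaE1"))
            if e3:
                anns.append(_fake_ann("e3", "C", "DnaE3"))
            if e2:
                anns.append(_fake_ann("e2", "C", "DnaE2A"))
            if not (e1 or e3):
                with pytest.raises(ca.AnnotationError):
                    ca.classify_replication_system(anns)
                continue
            system = ca.classify_replication_system(anns).system
            if polc and e3:
                assert system == "PolC+DnaE3"
            elif polc and e1:
                assert system == "PolC+DnaE1"
            else:
                assert system == "DnaE1-only"

    def test_evidence_lists_contributors(self):
        rs = ca.classify_replication_system(
            [_fake_ann("a", "C", "PolC"), _fake_ann("b", "C", "DnaE1"),
             _fake_ann("c", "C", "DnaE2A")])
        assert rs.system == "PolC+DnaE1"
        assert set(rs.evidence) == {"a", "b"}

    def test_paralogs_do_not_change_typing(self):
        rs = ca.classify_replication_system(
            [_fake_ann("a", "C", "DnaE1"), _fake_ann("b", "C", "DnaE1")])
        assert rs.system == "DnaE1-only"
        assert len(rs.evidence) == 2


class TestProofreaderCensus:
    def test_clostridia_archetype_three_active(self, registry, profiles):
        plan = sd.GenomePlan("clost", [sd.GenePlan("PolC"),
                                       sd.GenePlan("DnaE1")], decoys=1)
        sim = sd.simulate_genome(plan, registry, seed=11, mutation_rate=0.0)
        comp = ca.annotate_genome(sim.records, registry, profiles=profiles)
        assert comp.replication_system.system == "PolC+DnaE1"
        assert sum(p.active for p in comp.proofreaders) == 3
        kinds = sorted((p.kind, p.active) for p in comp.proofreaders)
        assert kinds == [("DnaQ-domain", True), ("PHP", True), ("PHP", True)]

    def test_bacilli_archetype_one_active(self, registry, profiles):
        plan = sd.GenomePlan("bacil", [
            sd.GenePlan("PolC", motif_toggles={"PHP_AS": "broken"}),
            sd.GenePlan("DnaE3")], decoys=1)
        sim = sd.simulate_genome(plan, registry, seed=11, mutation_rate=0.0)
        comp = ca.annotate_genome(sim.records, registry, profiles=profiles)
        assert comp.replication_system.system == "PolC+DnaE3"
        active = [p for p in comp.proofreaders if p.active]
        assert len(active) == 1 and active[0].kind == "DnaQ-domain"

    def test_validated_standalone_dnaq_admitted(self, registry, profiles):
        plan = sd.GenomePlan("g", [sd.GenePlan("DnaE1"),
                                   sd.GenePlan("DnaQ-ecoli-like")], decoys=1)
        sim = sd.simulate_genome(plan, registry, seed=11, mutation_rate=0.05)
        comp = ca.annotate_genome(sim.records, registry, profiles=profiles)
        subunits = [p for p in comp.proofreaders if p.kind == "DnaQ-subunit"]
        assert len(subunits) == 1 and subunits[0].active

    def test_rogue_standalone_dnaq_rejected(self, registry, profiles):
        """A standalone DEDDh exonuclease without close homology to any
        validated reference is excluded (the conservative rule)."""
        plan = sd.GenomePlan("g", [sd.GenePlan("DnaE1"),
                                   sd.GenePlan("DnaQ-rogue")], decoys=1)
        sim = sd.simulate_genome(plan, registry, seed=11, mutation_rate=0.0)
        comp = ca.annotate_genome(sim.records, registry, profiles=profiles)
        assert not [p for p in comp.proofreaders if p.kind == "DnaQ-subunit"]
        # ... but it was seen as a candidate
        assert comp.accessories("DnaQ-candidate")

    def test_rogue_admitted_with_passing_model_score(self, registry, profiles):
        from polcensus.complex_typer import ModelScore
        plan = sd.GenomePlan("g", [sd.GenePlan("DnaE1"),
                                   sd.GenePlan("DnaQ-rogue")], decoys=1)
        sim = sd.simulate_genome(plan, registry, seed=11, mutation_rate=0.0)
        rogue_pid = [t.protein_id for t in sim.protein_truth
                     if t.group == "DnaQ-rogue"][0]
        scores = {rogue_pid: ModelScore(rogue_pid, "multimer-v2", 0.8, 0.9, 0.5)}
        comp = ca.annotate_genome(sim.records, registry, profiles=profiles,
                                  model_scores=scores)
        assert [p for p in comp.proofreaders if p.kind == "DnaQ-subunit"]

    def test_proofreader_count_bound(self, registry, profiles):
        plan = sd.GenomePlan("g", [sd.GenePlan("PolC"), sd.GenePlan("DnaE1"),
                                   sd.GenePlan("DnaE2A")], decoys=1)
        sim = sd.simulate_genome(plan, registry, seed=2, mutation_rate=0.0)
        comp = ca.annotate_genome(sim.records, registry, profiles=profiles)
        n_repl = sum(1 for a in comp.census()
                     if a.group in ("PolC", "DnaE1", "DnaE3"))
        assert len(comp.proofreaders) <= 2 * n_repl
        # DnaE2 PHP status is reported but never counted
        dnae2 = [a for a in comp.census() if a.group == "DnaE2A"][0]
        assert dnae2.php_active is False
        assert dnae2.protein_id not in {p.carrier_protein_id
                                        for p in comp.proofreaders}


class TestExo53:
    def _annotate(self, registry, profiles, genes):
        plan = sd.GenomePlan("g", genes, decoys=1)
        sim = sd.simulate_genome(plan, registry, seed=4, mutation_rate=0.0)
        return ca.annotate_genome(sim.records, registry, profiles=profiles)

    def test_canonical_pol_i(self, registry, profiles):
        comp = self._annotate(registry, profiles,
                              [sd.GenePlan("DnaE1"), sd.GenePlan("PolA1")])
        assert comp.exo53_status == "PolA1"

    def test_solo_fen_complements_missing_pol_i(self, registry, profiles):
        comp = self._annotate(registry, profiles,
                              [sd.GenePlan("DnaE1"), sd.GenePlan("PolA1-like"),
                               sd.GenePlan("soloFEN")])
        assert comp.exo53_status == "solo"

    def test_endosymbiont_case_none(self, registry, profiles):
        comp = self._annotate(registry, profiles, [sd.GenePlan("DnaE1")])
        assert comp.exo53_status == "none"

    def test_pol_i_with_dead_fen_falls_back_to_solo(self, registry, profiles):
        comp = self._annotate(
            registry, profiles,
            [sd.GenePlan("DnaE1"),
             sd.GenePlan("PolA1", motif_toggles={"FEN_AS": "broken"}),
             sd.GenePlan("soloFEN")])
        assert comp.exo53_status == "solo"


class TestAnnotateGenome:
    def test_planted_roster_recovered(self, registry, profiles):
        plan = sd.GenomePlan("g", [sd.GenePlan("DnaE1"), sd.GenePlan("PolA1"),
                                   sd.GenePlan("PolY-core")], decoys=2)
        sim = sd.simulate_genome(plan, registry, seed=8, mutation_rate=0.0)
        comp = ca.annotate_genome(sim.records, registry, profiles=profiles)
        assert comp.family_counts == {"A": 1, "C": 1, "Y": 1}
        assert comp.replication_system.system == "DnaE1-only"

    def test_removing_a_gene_is_local(self, registry, profiles):
        base = [sd.GenePlan("DnaE1"), sd.GenePlan("PolA1"),
                sd.GenePlan("PolY-core")]
        sim_full = sd.simulate_genome(sd.GenomePlan("g", base, decoys=0),
                                      registry, seed=8, mutation_rate=0.0)
        sim_cut = sd.simulate_genome(sd.GenomePlan("g", base[:2], decoys=0),
                                     registry, seed=8, mutation_rate=0.0)
        full = ca.annotate_genome(sim_full.records, registry, profiles=profiles)
        cut = ca.annotate_genome(sim_cut.records, registry, profiles=profiles)
        assert full.family_counts.get("Y", 0) == 1
        assert cut.family_counts.get("Y", 0) == 0
        assert cut.replication_system.system == full.replication_system.system
        assert cut.exo53_status == full.exo53_status

    def test_fragment_excluded_from_census(self, registry, profiles):
        plan = sd.GenomePlan("g", [sd.GenePlan("DnaE1"),
                                   sd.GenePlan("DnaE1", fragment=True)],
                             decoys=1)
        sim = sd.simulate_genome(plan, registry, seed=9, mutation_rate=0.0)
        comp = ca.annotate_genome(sim.records, registry, profiles=profiles)
        assert comp.family_counts == {"C": 1}
        frags = [a for a in comp.polymerases if a.fragment]
        assert len(frags) == 1

    def test_determinism_across_runs(self, registry, profiles):
        plan = sd.GenomePlan("g", [sd.GenePlan("DnaE1"), sd.GenePlan("UmuC"),
                                   sd.GenePlan("UmuD"), sd.GenePlan("RecA")],
                             decoys=2)
        sim = sd.simulate_genome(plan, registry, seed=10, mutation_rate=0.05)

        def snapshot():
            comp = ca.annotate_genome(sim.records, registry, profiles=profiles)
            return ([(a.protein_id, a.family, a.group, a.accessory_role)
                     for a in comp.polymerases],
                    [(c.complex_id, c.members) for c in comp.complexes])

        assert snapshot() == snapshot()

    def test_no_replicase_raises_with_genome_context(self, registry, profiles):
        plan = sd.GenomePlan("lonely", [sd.GenePlan("DnaE2A")], decoys=1)
        sim = sd.simulate_genome(plan, registry, seed=3, mutation_rate=0.0)
        with pytest.raises(ca.AnnotationError, match="lonely"):
            ca.annotate_genome(sim.records, registry, profiles=profiles)
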