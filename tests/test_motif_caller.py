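"""Active-site and interaction-motif calling rules."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polcensus import homology as H
from polcensus import motif_caller as mc
from polcensus._refs import mutate, rng_for
from polcensus.sequence_io import ProteinRecord


def _identity_mapping(mdef, offset=0):
    return {c: c + offset for c in mdef.columns}


def _with_motif(registry, motif_id, residues, length=120):
    """A synthetic sequence carrying `residues` at the motif's columns."""
    mdef = registry.motifs[motif_id]
    rng = rng_for("mc-fixture", motif_id, residues)
    seq = list("".join("A" for _ in range(length)))
    from polcensus._refs import sample_sequence
    seq = list(sample_sequence(rng, length))
    for col, res in zip(mdef.columns, residues):
        seq[col - 1] = res
    return "".join(seq)


class TestCallActiveSite:
    def test_php_conforming_pattern_is_active(self, registry):
        mdef = registry.motifs["PHP_AS"]
        seq = _with_motif(registry, "PHP_AS", "HHDHEHCDH")
        call = mc.call_active_site(seq, mdef, _identity_mapping(mdef))
        assert call.status == mc.ACTIVE
        assert call.matched_residues == "HHDHEHCDH"

    def test_php_alternate_allowed_residue_is_active(self, registry):
        mdef = registry.motifs["PHP_AS"]
        seq = _with_motif(registry, "PHP_AS", "HHDHEHHDH")   # [C/H] position
        assert mc.call_active_site(seq, mdef, _identity_mapping(mdef)).status == mc.ACTIVE

    def test_any_deviation_is_inactive(self, registry):
        mdef = registry.motifs["PHP_AS"]
        seq = _with_motif(registry, "PHP_AS", "HHDHQHCDH")   # E -> Q
        assert mc.call_active_site(seq, mdef, _identity_mapping(mdef)).status == mc.INACTIVE

    def test_deddh_vs_deddy_same_anchors(self, registry):
        """DEDDH at the anchors is active for the h variant; DEDDY at the
        same anchors is inactive for DEDDh but active for DEDDy."""
        h, y = registry.motifs["DEDDh"], registry.motifs["DEDDy"]
        seq_h = _with_motif(registry, "DEDDh", "DEDDH")
        seq_y = _with_motif(registry, "DEDDh", "DEDDY")
        m = _identity_mapping(h)
        assert mc.call_active_site(seq_h, h, m).status == mc.ACTIVE
        assert mc.call_active_site(seq_y, h, m).status == mc.INACTIVE
        assert mc.call_active_site(seq_y, y, m).status == mc.ACTIVE

    def test_uncovered_columns_are_undetermined(self, registry):
        mdef = registry.motifs["FEN_AS"]
        mapping = {c: c for c in mdef.columns[:-1]}   # last column deleted
        seq = _with_motif(registry, "FEN_AS", "DDEDD")
        assert mc.call_active_site(seq, mdef, mapping).status == mc.UNDETERMINED

    def test_x_policy(self, registry):
        mdef = registry.motifs["DEDDh"]
        seq = _with_motif(registry, "DEDDh", "DXDDH")
        m = _identity_mapping(mdef)
        assert mc.call_active_site(seq, mdef, m).status == mc.INACTIVE
        assert mc.call_active_site(seq, mdef, m, x_as_undetermined=True).status \
            == mc.UNDETERMINED

    def test_idempotent_and_case_insensitive(self, registry):
        mdef = registry.motifs["PHP_AS"]
        seq = _with_motif(registry, "PHP_AS", "HHDHEHCDH")
        m = _identity_mapping(mdef)
        first = mc.call_active_site(seq.lower(), mdef, m)
        second = mc.call_active_site(seq, mdef, m)
        assert first.status == second.status == mc.ACTIVE
        assert first.matched_residues == second.matched_residues


class TestAnchorAlign:
    def test_identity_for_consensus(self, profiles):
        prof = profiles["PHP"]
        hits = H.scan_domains(prof.consensus, [prof])
        mapping = mc.anchor_align(prof.consensus, hits[0])
        assert all(mapping[c] == c for c in mapping)

    def test_insertion_shifts_query_positions(self, registry, profiles):
        prof = profiles["PHP"]
        query = prof.consensus[:5] + "WWWWW" + prof.consensus[5:]
        hits = H.scan_domains(query, [prof])
        mapping = mc.anchor_align(query, hits[0])
        mdef = registry.motifs["PHP_AS"]
        for col in mdef.columns:
            assert mapping[col] == col + 5

    def test_truncation_before_motif_gives_undetermined(self, registry, profiles):
        prof = profiles["PHP"]
        mdef = registry.motifs["PHP_AS"]
        query = prof.consensus[:mdef.columns[0] + 2]   # ends inside the motif
        hits = H.scan_domains(query, [prof], tau=0.05)
        mapping = mc.anchor_align(query, hits[0]) if hits else {}
        call = mc.call_active_site(query, mdef, mapping)
        assert call.status == mc.UNDETERMINED


class TestInteractionMotifs:
    def test_clamp_present_in_designated_loop(self, registry, profiles, domain_profiles):
        info = registry.anchor_info["PolA2_r1"]
        seq = info.sequence
        lo, hi = info.clamp_span
        assert seq[lo - 1:hi] == "QSSLF"
        hits = H.scan_domains(seq, domain_profiles)
        calls = mc.detect_interaction_motifs(
            seq, registry.groups["PolA2"], hits, registry, profiles)
        clamp = {c.motif_id: c for c in calls}["CLAMP"]
        assert clamp.status == mc.PRESENT
        assert clamp.matched_residues == "QSSLF"

    def test_clamp_final_f_required(self, registry, profiles, domain_profiles):
        info = registry.anchor_info["PolA2_r1"]
        lo, hi = info.clamp_span
        seq = info.sequence[:hi - 1] + "A" + info.sequence[hi:]   # QSSLF -> QSSLA
        hits = H.scan_domains(seq, domain_profiles)
        calls = mc.detect_interaction_motifs(
            seq, registry.groups["PolA2"], hits, registry, profiles)
        assert {c.motif_id: c for c in calls}["CLAMP"].status == mc.ABSENT

    def test_recA_NT_present_then_scrambled(self, registry, profiles):
        """A UmuC-like protein with the packaged RecA-NT segment scores
        present; scrambling the segment removes the call."""
        import numpy as np
        info = registry.anchor_info["UmuC_r1"]
        seq = info.sequence
        assert mc.score_recA_NT(seq, registry, profiles).status == mc.PRESENT
        lo, hi = info.recA_nt_span
        rng = np.random.default_rng(20260926)
        segment = list(seq[lo - 1:hi])
        scrambled = seq[:lo - 1] + "".join(
            np.array(segment)[rng.permutation(len(segment))]) + seq[hi:]
        assert mc.score_recA_NT(scrambled, registry, profiles).status == mc.ABSENT


class TestPolymeraseActivity:
    def test_intact_catalytic_columns_active(self, registry):
        gdef = registry.groups["PolY-core"]
        mdef = registry.motifs["POL_AS_Y"]
        seq = _with_motif(registry, "POL_AS_Y", "DDE", length=200)
        call = mc.call_polymerase_activity(seq, gdef, _identity_mapping(mdef),
                                           registry)
        assert call.status == mc.ACTIVE

    def test_d_to_n_substitution_gives_ipoly(self, registry):
        gdef = registry.groups["PolY-core"]
        mdef = registry.motifs["POL_AS_Y"]
        seq = _with_motif(registry, "POL_AS_Y", "DNE", length=200)
        call = mc.call_polymerase_activity(seq, gdef, _identity_mapping(mdef),
                                           registry)
        assert call.status == mc.INACTIVE

    def test_polx1_exonuclease_only_class(self, registry, profiles):
        """PolX1 with a disrupted polymerase site but intact PHP motif: the
        polymerase is inactive while the PHP nuclease stays active."""
        from polcensus import complement_annotator as ca
        from polcensus import synthetic_data as sd
        plan = sd.GenomePlan("g", [
            sd.GenePlan("DnaE1"),
            sd.GenePlan("PolX1", motif_toggles={"POL_AS_X": "broken",
                                                "PHP_AS": "intact"})],
            decoys=0)
        sim = sd.simulate_genome(plan, registry, seed=5, mutation_rate=0.0)
        comp = ca.annotate_genome(sim.records, registry, profiles=profiles)
        polx = [a for a in comp.census() if a.group == "PolX1"][0]
        assert polx.polymerase_active is False
        assert polx.php_active is True


class TestExportCounts:
    def test_identical_calls_concentrate_counts(self):
        calls = [mc.MotifCall("p%d" % i, "DEDDh", mc.ACTIVE, "DEDDH")
                 for i in range(10)]
        mat = mc.export_motif_counts({"PolC": calls})["PolC"]
        assert mat.shape == (20, 5)
        assert (mat.sum(axis=0) == 10).all()
        assert mat.loc["D", "pos1"] == 10

    def test_column_sums_equal_determined_calls(self):
        calls = ([mc.MotifCall(f"p{i}", "DEDDh", mc.ACTIVE, "DEDDH") for i in range(6)]
                 + [mc.MotifCall(f"q{i}", "DEDDh", mc.INACTIVE, "DQDDH") for i in range(3)]
                 + [mc.MotifCall("u0", "DEDDh", mc.UNDETERMINED, "")])
        mat = mc.export_motif_counts({"g": calls})["g"]
        assert (mat.sum(axis=0) == 9).all()

    def test_all_undetermined_warns_empty(self):
        calls = [mc.MotifCall("p", "DEDDh", mc.UNDETERMINED, "")]
        with pytest.warns(UserWarning):
            mat = mc.export_motif_counts({"g": calls})["g"]
        assert mat.empty


@given(st.integers(0, 10_000))
@settings(max_examples=40, deadline=None)
def test_status_trichotomy(registry, profiles, seed):
    """For any mutated PHP-bearing protein, the PHP call is exactly one of
    active/inactive/undetermined."""
    base = registry.anchor_info["DnaE1_r1"].sequence
    seq = mutate(rng_for("trichotomy", seed), base, 0.15)
    prof = profiles["PHP"]
    hits = H.scan_domains(seq, [prof], tau=0.2)
    mapping = mc.anchor_align(seq, hits[0]) if hits else {}
    call = mc.call_active_site(seq, registry.motifs["PHP_AS"], mapping)
    assert call.status in (mc.ACTIVE, mc.INACTIVE, mc.UNDETERMINED)
    if call.status != mc.UNDETERMINED:
        assert len(call.matched_residues) == len(registry.motifs["PHP_AS"].columns)
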