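"""Per-genome integration of the polymerase complement.

Given a proteome, this module ties together domain scanning, group
assignment, and motif calling into a :class:`GenomeComplement`:

* replication-system typing — every bacterium carries one of three
  combinations of replicative C-family α-subunits (DnaE1-only,
  PolC + DnaE1, or PolC + DnaE3); DnaE2 is error-prone and never counts
  as replicative;
* a proofreader census over intrinsic PHP and DnaQ domains plus
  standalone DnaQ subunits, the latter admitted conservatively (close
  homology to a validated reference, or a passing structure-model score);
* 5'-3' exonuclease complementation — the FEN function is provided by
  Pol I (PolA1) or, in its absence, almost always by a standalone
  FEN-like nuclease;
* mutasome complex typing (delegated to :mod:`polcensus.complex_typer`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import complex_typer, homology, motif_caller
from .motif_caller import ABSENT, ACTIVE, INACTIVE, PRESENT, UNDETERMINED, MotifCall
from .registry import Registry
from .sequence_io import ProteinRecord

DNAQ_HOMOLOGY_THRESHOLD = 0.5      # "close homolog of a validated DnaQ"
POLX_LIKE_THRESHOLD = 0.5
DNAE_TIE_MARGIN = 0.05

REPLICATIVE_GROUPS = ("PolC", "DnaE1", "DnaE3")
DNAE2_GROUPS = ("DnaE2A", "DnaE2B", "DnaE2X")
VALIDATED_DNAQ = ("DnaQ-ecoli-like", "DnaQ-myco-like", "DnaQ-treponema-like")


class AnnotationError(ValueError):
    pass


@dataclass
class AnnotateOptions:
    tau: float = homology.DEFAULT_TAU
    edge_threshold: float = homology.DEFAULT_EDGE_THRESHOLD
    x_as_undetermined: bool = False
    assume_recA: bool = False
    require_colocalization: bool = False
    colocalization_window: int = 5
    dnaq_homology_threshold: float = DNAQ_HOMOLOGY_THRESHOLD


@dataclass
class PolymeraseAnnotation:
    protein_id: str
    family: str | None = None
    group: str | None = None
    fragment: bool = False
    architecture: tuple[str, ...] = ()
    hits: list = field(default_factory=list)
    motif_calls: dict = field(default_factory=dict)   # motif_id -> MotifCall
    accessory_role: str | None = None
    record: ProteinRecord | None = None
    assignment: homology.GroupAssignment | None = None
    notes: str = ""

    def _status(self, motif_id: str) -> str | None:
        call = self.motif_calls.get(motif_id)
        return call.status if call else None

    def _flag(self, motif_id: str) -> bool | None:
        status = self._status(motif_id)
        if status is None or status == UNDETERMINED:
            return None
        return status in (ACTIVE, PRESENT)

    @property
    def polymerase_active(self):
        if self.family:
            return self._flag(motif_caller.POL_AS_BY_FAMILY[self.family])
        return None

    @property
    def php_active(self):
        return self._flag("PHP_AS")

    @property
    def dnaq_active(self):
        """Active proofreading DnaQ site: DEDDh in C-family context and
        standalone subunits, DEDDy in A/B-family polymerase domains."""
        h, y = self._flag("DEDDh"), self._flag("DEDDy")
        if self.family in ("A", "B"):
            return y
        if h is not None:
            return h
        return y

    @property
    def exo53_active(self):
        return self._flag("FEN_AS")

    @property
    def clamp_motif(self):
        return self._flag("CLAMP")

    @property
    def recA_NT(self):
        return self._flag("RecA_NT")

    @property
    def imuBC_domain(self) -> bool:
        return any(h.domain_id == "ImuB-C" for h in self.hits)

    @property
    def is_polY(self) -> bool:
        return self.family == "Y" and not self.fragment


@dataclass
class ReplicationSystem:
    system: str                       # DnaE1-only | PolC+DnaE1 | PolC+DnaE3
    evidence: tuple[str, ...] = ()    # contributing protein ids
    ambiguous: bool = False


@dataclass(frozen=True)
class Proofreader:
    carrier_protein_id: str
    kind: str                         # PHP | DnaQ-domain | DnaQ-subunit
    active: bool


@dataclass
class GenomeComplement:
    genome_id: str
    polymerases: list[PolymeraseAnnotation] = field(default_factory=list)
    replication_system: ReplicationSystem | None = None
    proofreaders: list[Proofreader] = field(default_factory=list)
    exo53_status: str = "none"        # PolA1 | solo | none
    complexes: list = field(default_factory=list)
    family_counts: dict = field(default_factory=dict)
    group_counts: dict = field(default_factory=dict)

    def census(self) -> list[PolymeraseAnnotation]:
        """Polymerases that count: family-assigned, non-fragment."""
        return [a for a in self.polymerases
                if a.family is not None and not a.fragment
                and a.group != "PolX-like"]

    def accessories(self, role: str) -> list[PolymeraseAnnotation]:
        return [a for a in self.polymerases if a.accessory_role == role]


# ---------------------------------------------------------------------------
# replication system
# ---------------------------------------------------------------------------

def classify_replication_system(annotations: list[PolymeraseAnnotation]) -> ReplicationSystem:
    """Type the replicative system from the C-family group roster.

    DnaE2 never counts as a replicative subunit.  A complement with no
    replicative C-family polymerase is an error: every bacterial genome
    carries at least one DnaE-type α-subunit.
    """
    groups: dict[str, list[str]] = {}
    for ann in annotations:
        if ann.family == "C" and not ann.fragment and ann.group:
            groups.setdefault(ann.group, []).append(ann.protein_id)

    def _ev(*gids):
        return tuple(pid for g in gids for pid in groups.get(g, ()))

    has = {g: g in groups for g in ("PolC", "DnaE1", "DnaE3")}
    if has["PolC"] and has["DnaE3"]:
        return ReplicationSystem("PolC+DnaE3", _ev("PolC", "DnaE3"))
    if has["PolC"] and has["DnaE1"]:
        return ReplicationSystem("PolC+DnaE1", _ev("PolC", "DnaE1"))
    if has["DnaE1"] or has["DnaE3"]:
        return ReplicationSystem("DnaE1-only", _ev("DnaE1", "DnaE3"))
    raise AnnotationError("no replicative C-family polymerase (DnaE1/DnaE3 "
                          "or PolC+DnaE) in complement")


# ---------------------------------------------------------------------------
# proofreader census
# ---------------------------------------------------------------------------

def census_proofreaders(annotations: list[PolymeraseAnnotation],
                        standalone_candidates: list[PolymeraseAnnotation],
                        registry: Registry,
                        model_scores: dict | None = None,
                        homology_threshold: float = DNAQ_HOMOLOGY_THRESHOLD,
                        ) -> list[Proofreader]:
    """Census of 3'-5' proofreading nucleases associated with replication.

    Intrinsic PHP and DnaQ domains of replicative C-family polymerases are
    listed with their active-site status.  Standalone DnaQ-like proteins
    are plentiful, so a candidate is admitted as a DnaQ subunit only if it
    is a close homolog of a validated reference or a supplied
    structure-model score passes the confidence filter; everything else is
    rejected.  DnaE2 domains are never counted (DnaE2 is not known to
    cooperate with DnaQ; its PHP status is reported on the annotation but
    does not enter this census).
    """
    out: list[Proofreader] = []
    for ann in annotations:
        if ann.family != "C" or ann.fragment or ann.group not in REPLICATIVE_GROUPS:
            continue
        if "PHP" in ann.architecture and ann.php_active is not None:
            out.append(Proofreader(ann.protein_id, "PHP", bool(ann.php_active)))
        if "DnaQ-exo" in ann.architecture:
            active = ann._flag("DEDDh")
            if active is not None:
                out.append(Proofreader(ann.protein_id, "DnaQ-domain", bool(active)))

    validated_anchors = [(rid, registry.anchors[rid])
                         for comp in VALIDATED_DNAQ
                         for rid in registry.accessories[comp].anchor_refs]
    for ann in standalone_candidates:
        admitted = False
        if ann.record is not None:
            for rid, aseq in validated_anchors:
                sim = homology.pairwise_similarity(
                    ann.protein_id, ann.record.sequence, rid, aseq)
                if sim >= homology_threshold:
                    admitted = True
                    break
        if not admitted and model_scores and ann.protein_id in model_scores:
            ok, _ = complex_typer.model_score_passes(model_scores[ann.protein_id])
            admitted = ok
        if admitted:
            active = ann._flag("DEDDh")
            out.append(Proofreader(ann.protein_id, "DnaQ-subunit",
                                   bool(active) if active is not None else False))
    return out


# ---------------------------------------------------------------------------
# 5'-3' exonuclease complementation
# ---------------------------------------------------------------------------

def check_exo53_complementation(annotations: list[PolymeraseAnnotation],
                                solo_fen_hits: list[PolymeraseAnnotation]) -> str:
    """Who provides the 5'-3' exonuclease function.

    ``PolA1`` when a Pol I ortholog carries an active FEN domain; ``solo``
    when the genome instead encodes a standalone active FEN homolog;
    ``none`` otherwise (observed only in a handful of endosymbionts with
    tiny genomes).
    """
    for ann in annotations:
        if ann.group == "PolA1" and not ann.fragment and ann.exo53_active:
            return "PolA1"
    for ann in solo_fen_hits:
        if ann.exo53_active:
            return "solo"
    return "none"


# ---------------------------------------------------------------------------
# per-protein annotation
# ---------------------------------------------------------------------------

def _architecture(hits: list[homology.DomainHit]) -> tuple[str, ...]:
    ordered = sorted(hits, key=lambda h: (h.q_start, h.domain_id))
    seen, arch = set(), []
    for h in ordered:
        if h.domain_id not in seen:
            seen.add(h.domain_id)
            arch.append(h.domain_id)
    return tuple(arch)


def _best_hit(hits, domain_id) -> homology.DomainHit | None:
    cands = [h for h in hits if h.domain_id == domain_id]
    return max(cands, key=lambda h: h.norm_score) if cands else None


_ACCESSORY_LADDER = (
    # (defining domain, forbidden domains, role resolver)
    ("RecA-core", (), lambda d: "RecA"),
    ("ImuA-core", (), lambda d: "ImuA"),
    ("UmuD", (), lambda d: "UmuD"),
    ("SRAP", (), lambda d: "SRAP"),
    ("YqjX-NT", (), lambda d: ("YqjX" if "YqjX-C" in d
                               else "YhjD" if "CTD" in d else "YqjX-NTonly")),
    ("ImuB-C", ("core_Y",), lambda d: "ImuB-C-solo"),
    ("FEN-exo", ("core_A",), lambda d: "soloFEN"),
    ("DnaQ-exo", ("core_A", "core_B", "core_C"), lambda d: "DnaQ-candidate"),
)


def _accessory_role(domains: set[str]) -> str | None:
    for defining, forbidden, resolve in _ACCESSORY_LADDER:
        if defining in domains and not any(f in domains for f in forbidden):
            return resolve(domains)
    return None


def _call_motifs(ann: PolymeraseAnnotation, registry: Registry,
                 profiles, options: AnnotateOptions) -> None:
    """Populate motif calls for one annotated protein.

    Anchoring prefers the protein's own group (or accessory) reference
    alignment — the anchor set — over the family-generic domain profile:
    the sharper owner profile keeps a disrupted motif position as a
    diagonal mismatch instead of letting the aligner gap around it.
    """
    seq = ann.record
    hit_by_aln = {}
    for h in ann.hits:
        dom = registry.domains.get(h.domain_id)
        if dom is None:
            continue
        prev = hit_by_aln.get(dom.reference_alignment)
        if prev is None or h.norm_score > prev.norm_score:
            hit_by_aln[dom.reference_alignment] = h

    owner = None
    if ann.group and ann.group in registry.groups:
        owner = ann.group
    elif ann.accessory_role and ann.accessory_role in registry.accessories:
        owner = ann.accessory_role
    owner_map = None
    owner_sites: dict[tuple, tuple] = {}
    if owner is not None and registry.anchor_info:
        if owner in registry.groups:
            refs = registry.groups[owner].anchor_refs
        else:
            refs = registry.accessories[owner].anchor_refs
        info = registry.anchor_info.get(refs[0])
        prof = homology.owner_profile(registry, owner)
        if info is not None and prof is not None:
            _, pairs = homology.score_profile(prof, seq.sequence)
            owner_map = {int(prof.column_map[pc - 1]): qp for pc, qp in pairs}
            for site in info.motif_sites:
                mdef = registry.motifs[site.motif_id]
                owner_sites[(mdef.alignment_id, mdef.columns)] = site.positions

    def _mapping_for(mdef):
        if owner_map is not None:
            positions = owner_sites.get((mdef.alignment_id, mdef.columns))
            if positions is not None:
                return {c: owner_map[p]
                        for c, p in zip(mdef.columns, positions)
                        if p in owner_map}
        hit = hit_by_aln.get(mdef.alignment_id)
        return motif_caller.anchor_align(seq, hit) if hit else {}

    def _call(motif_id):
        mdef = registry.motifs[motif_id]
        ann.motif_calls[motif_id] = motif_caller.call_active_site(
            seq, mdef, _mapping_for(mdef),
            x_as_undetermined=options.x_as_undetermined)

    domains_present = {h.domain_id for h in ann.hits}
    if "PHP" in domains_present:
        _call("PHP_AS")
    if "DnaQ-exo" in domains_present:
        _call("DEDDh")
        _call("DEDDy")
    if "FEN-exo" in domains_present:
        _call("FEN_AS")
    if ann.family:
        motif_id = motif_caller.POL_AS_BY_FAMILY[ann.family]
        _call(motif_id)
    if ann.group and ann.group in registry.groups:
        gdef = registry.groups[ann.group]
        for call in motif_caller.detect_interaction_motifs(
                seq, gdef, ann.hits, registry, profiles):
            ann.motif_calls[call.motif_id] = call


def annotate_protein(record: ProteinRecord, registry: Registry, profiles,
                     options: AnnotateOptions,
                     hits: list[homology.DomainHit] | None = None,
                     ) -> PolymeraseAnnotation:
    """Scan and family-classify a single protein (group assignment happens
    at the genome level where family members are clustered together)."""
    if hits is None:
        domain_profiles = [p for name, p in profiles.items()
                           if name in registry.domains]
        hits = homology.scan_domains(record, domain_profiles, tau=options.tau)
    fam = homology.assign_family(hits)
    fragment = any(h.fragment for h in hits if h.domain_id.startswith("core_"))
    family = fam.family_id
    if family is None and fragment:
        frag_fam = homology.assign_family(hits, include_fragments=True)
        family = frag_fam.family_id
    ann = PolymeraseAnnotation(
        protein_id=record.protein_id, family=family, fragment=fragment,
        architecture=_architecture(hits), hits=hits, record=record)
    if ann.family is None:
        ann.accessory_role = _accessory_role({h.domain_id for h in hits})
    return ann


def _assign_groups(anns: list[PolymeraseAnnotation], registry: Registry,
                   options: AnnotateOptions) -> None:
    by_family: dict[str, list[PolymeraseAnnotation]] = {}
    for ann in anns:
        if ann.family and not ann.fragment:
            by_family.setdefault(ann.family, []).append(ann)
    for family, members in by_family.items():
        anchors = {}
        for gid in registry.family_groups(family):
            if gid == "PolX-like":
                continue    # no polymerase core; resolved separately below
            for rid in registry.groups[gid].anchor_refs:
                anchors[rid] = (gid, registry.anchors[rid])
        assignments = homology.cluster_groups(
            [a.record for a in members], anchors,
            edge_threshold=options.edge_threshold, family_id=family,
            registry=registry)
        by_pid = {a.protein_id: a for a in assignments}
        for ann in members:
            ann.assignment = by_pid[ann.protein_id]
            ann.group = ann.assignment.group_id
        if family == "C":
            _disambiguate_dnaE(members, registry)


def _disambiguate_dnaE(members, registry: Registry) -> None:
    """DnaE1 vs DnaE3 are the least separated replicative groups; when the
    anchor margin is small the PHP active-site signature breaks the tie
    (clostridial DnaE1 active vs bacilli DnaE3 inactive)."""
    for ann in members:
        if ann.group not in ("DnaE1", "DnaE3"):
            continue
        sims = {}
        for gid in ("DnaE1", "DnaE3"):
            best = max(homology.pairwise_similarity(
                ann.protein_id, ann.record.sequence, rid, registry.anchors[rid])
                for rid in registry.groups[gid].anchor_refs)
            sims[gid] = best
        margin = abs(sims["DnaE1"] - sims["DnaE3"])
        if margin >= DNAE_TIE_MARGIN:
            continue
        if ann.php_active is True:
            ann.group = "DnaE1"
        elif ann.php_active is False:
            ann.group = "DnaE3"
        else:
            ann.notes = "DnaE1/DnaE3 ambiguous"


def _resolve_polx_like(anns, registry: Registry) -> None:
    """PHP-only proteins close to PolX-like anchors are PolX-like members
    (X-family homologs lacking the entire polymerase domain)."""
    anchors = [(rid, registry.anchors[rid])
               for rid in registry.groups["PolX-like"].anchor_refs]
    for ann in anns:
        domains = {h.domain_id for h in ann.hits}
        if ann.family is not None or ann.accessory_role is not None:
            continue
        if "PHP" not in domains or any(d.startswith("core_") for d in domains):
            continue
        best = max(homology.pairwise_similarity(
            ann.protein_id, ann.record.sequence, rid, aseq)
            for rid, aseq in anchors)
        if best >= POLX_LIKE_THRESHOLD:
            ann.family = "X"
            ann.group = "PolX-like"


def annotate_genome(proteins: list[ProteinRecord], registry: Registry,
                    profiles: dict | None = None,
                    options: AnnotateOptions | None = None,
                    external_hits: dict | None = None,
                    model_scores: dict | None = None) -> GenomeComplement:
    """Full per-genome annotation: the orchestrator for one proteome."""
    if not proteins:
        raise AnnotationError("empty proteome")
    options = options or AnnotateOptions()
    if profiles is None:
        profiles = homology.build_profiles(registry)
    genome_id = proteins[0].genome_id

    try:
        anns = []
        for rec in sorted(proteins, key=lambda p: p.protein_id):
            hits = external_hits.get(rec.protein_id) if external_hits else None
            anns.append(annotate_protein(rec, registry, profiles, options,
                                         hits=hits))
        _assign_groups(anns, registry, options)
        _resolve_polx_like(anns, registry)
        for ann in anns:
            if ann.family or ann.accessory_role:
                _call_motifs(ann, registry, profiles, options)

        comp = GenomeComplement(genome_id=genome_id, polymerases=anns)
        census = comp.census()
        comp.replication_system = classify_replication_system(census)
        comp.proofreaders = census_proofreaders(
            census, comp.accessories("DnaQ-candidate"), registry,
            model_scores=model_scores,
            homology_threshold=options.dnaq_homology_threshold)
        comp.exo53_status = check_exo53_complementation(
            census, comp.accessories("soloFEN"))
        comp.complexes = complex_typer.type_complexes(
            comp, registry, options=options, model_scores=model_scores)
        for ann in census:
            comp.family_counts[ann.family] = comp.family_counts.get(ann.family, 0) + 1
            comp.group_counts[ann.group] = comp.group_counts.get(ann.group, 0) + 1
        return comp
    except AnnotationError as exc:
        raise AnnotationError(f"{genome_id}: {exc}") from exc
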