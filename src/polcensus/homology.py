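"""Profile-based domain detection and anchored group assignment.

This module stands in for a database-scale iterative search workflow.
Reference alignments from the registry are turned into position-specific
log-odds score matrices (PSSMs); proteins are scanned by affine-gap local
alignment of each profile, and hits are reported with scores normalized by
the profile's consensus self-score, so 1.0 means "as good as the consensus"
and the reliability gate is a single dimensionless threshold ``tau``.

Group assignment inside a family uses a thresholded similarity graph over
the query proteins and the registry anchor sequences: connected components
are labelled by the anchors they contain; components holding anchors of
several groups fall back to per-protein nearest-anchor assignment; anchor-
free components are reported as ``unassigned-novel``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import _align
from ._refs import AA, BACKGROUND
from .registry import Registry
from .sequence_io import ProteinRecord

# classic protein gap penalties (11/1 on the half-bit scale of BLOSUM62)
GAP_OPEN_BITS = 5.5
GAP_EXT_BITS = 0.5
PSEUDOCOUNT_ADMIX = 0.5     # pseudocount = 0.5 x background, renormalized
DEFAULT_TAU = 0.3           # reliability gate on norm_score
FRAGMENT_MIN_LENGTH = 200   # shorter polymerase-core carriers are fragments
DEFAULT_EDGE_THRESHOLD = 0.45

UNASSIGNED = "unassigned-novel"


class HomologyError(ValueError):
    pass


@dataclass
class Profile:
    """Log-odds PSSM over one reference alignment."""
    domain_id: str
    matrix: np.ndarray           # (n_columns, 21) bits; column 20 (X) is 0
    consensus: str
    self_score: float            # bits, consensus vs itself
    column_map: np.ndarray       # profile column (0-based) -> 1-based alignment column
    min_hit_length: int = 1

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[0]


@dataclass
class DomainHit:
    protein_id: str
    domain_id: str
    q_start: int                 # 1-based residue interval on the query
    q_end: int
    raw_score: float             # bits
    norm_score: float            # raw_score / profile self_score
    aligned_ref_columns: dict    # 1-based alignment column -> 1-based query position
    fragment: bool = False


@dataclass
class GroupAssignment:
    protein_id: str
    family_id: str
    group_id: str
    best_anchor_id: str | None
    similarity: float
    component_id: int


def build_profile(reference_alignment: list[tuple[str, str]],
                  background: np.ndarray = BACKGROUND,
                  domain_id: str = "profile",
                  min_hit_length: int = 1) -> Profile:
    """Build a PSSM from an alignment (list of (id, row) with '-' gaps).

    Columns with more than 50% gaps are dropped as non-match columns.
    Residue frequencies use Henikoff position-based sequence weighting and
    a background-proportional pseudocount; scores are log2 odds in bits.
    """
    if len(reference_alignment) < 2:
        raise HomologyError("profile construction needs at least 2 aligned sequences")
    rows = [row for _, row in reference_alignment]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise HomologyError(f"alignment rows have inconsistent lengths: {sorted(lengths)}")
    n_seq = len(rows)
    L = len(rows[0])

    # match columns: <= 50% gaps
    match_cols = [c for c in range(L)
                  if sum(r[c] == "-" for r in rows) <= n_seq / 2]
    if not match_cols:
        raise HomologyError("no match columns (alignment too gappy)")

    # Henikoff position-based weights
    weights = np.zeros(n_seq)
    for c in match_cols:
        col = [r[c] for r in rows]
        residues = [x for x in col if x != "-"]
        if not residues:
            continue
        counts: dict[str, int] = {}
        for x in residues:
            counts[x] = counts.get(x, 0) + 1
        r_distinct = len(counts)
        for s in range(n_seq):
            if col[s] != "-":
                weights[s] += 1.0 / (r_distinct * counts[col[s]])
    if weights.sum() == 0:
        weights[:] = 1.0
    weights /= weights.sum()

    matrix = np.zeros((len(match_cols), 21))
    consensus_chars = []
    for out_c, c in enumerate(match_cols):
        freq = np.zeros(20)
        total = 0.0
        for s in range(n_seq):
            ch = rows[s][c]
            if ch == "-" or ch == "X":
                continue
            freq[AA.index(ch)] += weights[s]
            total += weights[s]
        if total > 0:
            freq /= total
        adj = (freq + PSEUDOCOUNT_ADMIX * background) / (1.0 + PSEUDOCOUNT_ADMIX)
        matrix[out_c, :20] = np.log2(adj / background)
        consensus_chars.append(AA[int(np.argmax(freq))] if total > 0 else AA[0])

    consensus = "".join(consensus_chars)
    profile = Profile(domain_id=domain_id, matrix=matrix, consensus=consensus,
                      self_score=1.0,
                      column_map=np.array([c + 1 for c in match_cols]),
                      min_hit_length=min_hit_length)
    score, _ = _score_against(profile, consensus)
    profile.self_score = score
    return profile


def score_profile(profile: Profile, sequence: str):
    """Best local alignment of a profile against a sequence: (bits, pairs)."""
    q = _align.encode(sequence)
    return _align.local_profile_align(profile.matrix, q,
                                      GAP_OPEN_BITS, GAP_EXT_BITS)


_score_against = score_profile


def owner_profile(registry: Registry, owner_id: str) -> Profile | None:
    """Profile over one group's (or accessory's) own anchor set.

    Anchors of an owner are equal-length ungapped sequences, so they form
    a reference alignment in anchor coordinates; motif calling against
    this sharp profile is far less prone to local misregistration around
    a disrupted site than the family-generic domain profiles.  Cached on
    the registry instance.
    """
    cache = registry.__dict__.setdefault("_owner_profile_cache", {})
    if owner_id in cache:
        return cache[owner_id]
    if owner_id in registry.groups:
        refs = registry.groups[owner_id].anchor_refs
    elif owner_id in registry.accessories:
        refs = registry.accessories[owner_id].anchor_refs
    else:
        cache[owner_id] = None
        return None
    rows = [(rid, registry.anchors[rid]) for rid in refs]
    if len(rows) < 2 or len({len(s) for _, s in rows}) != 1:
        cache[owner_id] = None
        return None
    prof = build_profile(rows, domain_id=f"owner:{owner_id}")
    cache[owner_id] = prof
    return prof


def build_profiles(registry: Registry) -> dict[str, Profile]:
    """Profiles for every domain and profile-mode motif in the registry."""
    profiles: dict[str, Profile] = {}
    for dom in registry.domains.values():
        profiles[dom.domain_id] = build_profile(
            registry.alignments[dom.reference_alignment],
            domain_id=dom.domain_id, min_hit_length=dom.min_hit_length)
    for mdef in registry.motifs.values():
        if mdef.mode == "profile":
            profiles[mdef.motif_id] = build_profile(
                registry.alignments[mdef.alignment_id],
                domain_id=mdef.motif_id, min_hit_length=1)
    return profiles


def scan_domains(protein: ProteinRecord | str, profiles,
                 tau: float = DEFAULT_TAU) -> list[DomainHit]:
    """Scan one protein with a collection of domain profiles.

    Keeps, per domain, the best local hit with norm_score >= tau and an
    aligned span of at least the domain's min_hit_length.  Polymerase-core
    hits on proteins shorter than 200 residues are flagged ``fragment``
    (they are recorded but excluded from downstream censuses).
    """
    if isinstance(protein, ProteinRecord):
        pid, seq = protein.protein_id, protein.sequence
    else:
        pid, seq = "query", protein
    if not seq:
        raise HomologyError("empty sequence")
    if isinstance(profiles, dict):
        profiles = list(profiles.values())

    q = _align.encode(seq)
    hits: list[DomainHit] = []
    for profile in profiles:
        raw, pairs = _align.local_profile_align(profile.matrix, q,
                                                GAP_OPEN_BITS, GAP_EXT_BITS)
        if not pairs:
            continue
        norm = raw / profile.self_score
        if norm < tau:
            continue
        q_start, q_end = pairs[0][1], pairs[-1][1]
        if q_end - q_start + 1 < profile.min_hit_length:
            continue
        mapping = {int(profile.column_map[pc - 1]): qp for pc, qp in pairs}
        fragment = (profile.domain_id.startswith("core_")
                    and len(seq) < FRAGMENT_MIN_LENGTH)
        hits.append(DomainHit(protein_id=pid, domain_id=profile.domain_id,
                              q_start=q_start, q_end=q_end, raw_score=raw,
                              norm_score=norm, aligned_ref_columns=mapping,
                              fragment=fragment))
    hits.sort(key=lambda h: (-h.norm_score, h.domain_id))
    return hits


@dataclass
class FamilyAssignment:
    family_id: str | None
    margin: float | None = None       # norm-score gap to the runner-up family
    best_hit: DomainHit | None = None


def assign_family(hits: list[DomainHit],
                  include_fragments: bool = False) -> FamilyAssignment:
    """Family of the best polymerase-core hit (fragments excluded by default)."""
    core = [h for h in hits if h.domain_id.startswith("core_")
            and (include_fragments or not h.fragment)]
    if not core:
        return FamilyAssignment(None)
    core.sort(key=lambda h: (-h.norm_score, h.domain_id))
    best = core[0]
    margin = None
    for h in core[1:]:
        if h.domain_id != best.domain_id:
            margin = best.norm_score - h.norm_score
            break
    return FamilyAssignment(best.domain_id.removeprefix("core_"), margin, best)


# ---------------------------------------------------------------------------
# similarity-graph group assignment
# ---------------------------------------------------------------------------

_aligner = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        a.mode = "global"
        _aligner = a
    return _aligner


_pair_cache: dict[tuple[str, str], float] = {}
_self_cache: dict[str, float] = {}


def pairwise_similarity(id_a: str, seq_a: str, id_b: str, seq_b: str) -> float:
    """Global-alignment score normalized by the self-score of the shorter
    sequence.  Cached by sequence content (anchor sequences recur
    constantly); the ids are labels only."""
    ha, hb = hash(seq_a), hash(seq_b)
    key = (ha, hb) if ha <= hb else (hb, ha)
    if key in _pair_cache:
        return _pair_cache[key]
    aligner = _get_aligner()
    for h, s in ((ha, seq_a), (hb, seq_b)):
        if h not in _self_cache:
            _self_cache[h] = aligner.score(s, s)
    shorter = ha if len(seq_a) <= len(seq_b) else hb
    sim = aligner.score(seq_a, seq_b) / _self_cache[shorter]
    _pair_cache[key] = sim
    return sim


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # canonical: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def cluster_groups(proteins: list[ProteinRecord],
                   anchors: dict[str, tuple[str, str]],
                   edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
                   family_id: str | None = None,
                   registry: Registry | None = None) -> list[GroupAssignment]:
    """Assign proteins of one family to registry groups.

    ``anchors`` maps anchor ref id -> (group_id, sequence).  When
    ``registry`` and ``family_id`` are given, the input proteins are
    required to share that family (mixed input is an error upstream).
    Output order follows sorted protein_id, so the result is invariant to
    input order.
    """
    if not proteins:
        return []
    if family_id is None:
        family_id = "?"
    proteins = sorted(proteins, key=lambda p: p.protein_id)
    pids = [p.protein_id for p in proteins]
    if len(set(pids)) != len(pids):
        raise HomologyError("duplicate protein ids in clustering input")
    seqs = {p.protein_id: p.sequence for p in proteins}
    anchor_ids = sorted(anchors)
    for aid in anchor_ids:
        seqs[aid] = anchors[aid][1]
    nodes = pids + anchor_ids

    uf = _UnionFind(nodes)
    sims: dict[tuple[str, str], float] = {}
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            sim = pairwise_similarity(a, seqs[a], b, seqs[b])
            sims[(a, b)] = sims[(b, a)] = sim
            if sim >= edge_threshold:
                uf.union(a, b)

    comp_members: dict[str, list[str]] = {}
    for n in nodes:
        comp_members.setdefault(uf.find(n), []).append(n)
    comp_ids = {root: k for k, root in enumerate(sorted(comp_members))}

    out: list[GroupAssignment] = []
    for pid in pids:
        root = uf.find(pid)
        members = comp_members[root]
        comp_anchor_ids = [m for m in members if m in anchors]
        # nearest anchor over ALL anchors, for reporting
        best_aid, best_sim = None, -np.inf
        for aid in anchor_ids:
            s = sims.get((pid, aid), -np.inf)
            if s > best_sim or (s == best_sim and best_aid is not None and aid < best_aid):
                best_aid, best_sim = aid, s
        if not comp_anchor_ids:
            group = UNASSIGNED
        else:
            comp_groups = {anchors[a][0] for a in comp_anchor_ids}
            if len(comp_groups) == 1:
                group = next(iter(comp_groups))
            else:
                # mixed component: nearest anchor within the component
                near, near_sim = None, -np.inf
                for aid in sorted(comp_anchor_ids):
                    s = sims[(pid, aid)]
                    if s > near_sim:
                        near, near_sim = aid, s
                group = anchors[near][0]
        out.append(GroupAssignment(
            protein_id=pid, family_id=family_id, group_id=group,
            best_anchor_id=best_aid,
            similarity=float(best_sim) if np.isfinite(best_sim) else 0.0,
            component_id=comp_ids[root]))
    return out


def load_external_hits(path) -> dict[str, list[DomainHit]]:
    """Read an externally computed hit table
    (``protein_id domain_id q_start q_end norm_score``) keyed by protein."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "domain_id", "q_start", "q_end", "norm_score"}
    if not required.issubset(df.columns):
        raise HomologyError(f"hit table requires columns {sorted(required)}")
    out: dict[str, list[DomainHit]] = {}
    for r in df.itertuples():
        out.setdefault(r.protein_id, []).append(DomainHit(
            protein_id=r.protein_id, domain_id=r.domain_id,
            q_start=int(r.q_start), q_end=int(r.q_end),
            raw_score=float("nan"), norm_score=float(r.norm_score),
            aligned_ref_columns={}))
    return out
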