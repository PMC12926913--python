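"""Active-site and interaction-motif calling.

Active-site motifs (PHP ``HHDHEH[C/H]DH``, DnaQ ``DEDDh``/``DEDDy``, FEN
``D[D/E]EDD``, the per-family polymerase catalytic carboxylates) are called
by an exact-set rule on alignment-anchored positions: the site is *active*
only if every motif position carries an allowed residue, and *any*
deviation — substitution, deletion, or (by default) an X — makes it
*inactive*.  A protein whose domain hit does not cover all motif columns
is *undetermined*: only sequences that align over the motif can be judged.

Interaction motifs are handled two ways: the β-clamp binding motif
(``QxxLF``) is an exact-set pattern searched within a group-specified
region, while the RecA-NT motif is profile-scored against a packaged
sub-alignment with a score threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _align, homology
from .registry import GroupDef, MotifDef, Registry
from .sequence_io import ProteinRecord

ACTIVE = "active"
INACTIVE = "inactive"
PRESENT = "present"
ABSENT = "absent"
UNDETERMINED = "undetermined"

POSITIVE_STATUSES = (ACTIVE, PRESENT)

# per-family polymerase active-site motif ids
POL_AS_BY_FAMILY = {f: f"POL_AS_{f}" for f in "ABCXY"}


@dataclass
class MotifCall:
    protein_id: str
    motif_id: str
    status: str
    matched_residues: str = ""
    query_positions: tuple[int, ...] = ()
    evidence: str = ""

    @property
    def positive(self) -> bool:
        return self.status in POSITIVE_STATUSES


def _seq_of(protein) -> tuple[str, str]:
    if isinstance(protein, ProteinRecord):
        return protein.protein_id, protein.sequence.upper()
    return "query", str(protein).upper()


def anchor_align(protein, domain_hit: homology.DomainHit) -> dict[int, int]:
    """Gap-aware mapping of reference-alignment columns to query positions.

    The mapping comes from the profile local alignment in the domain hit;
    columns deleted in the query map to nothing.
    """
    if domain_hit is None:
        return {}
    return dict(domain_hit.aligned_ref_columns)


def call_active_site(protein, motif_def: MotifDef, mapping: dict[int, int],
                     x_as_undetermined: bool = False) -> MotifCall:
    """Exact-set active-site call on anchored motif columns."""
    pid, seq = _seq_of(protein)
    if motif_def.mode != "exact" or motif_def.columns is None:
        raise ValueError(f"{motif_def.motif_id} is not an anchored exact-set motif")
    positions = []
    for col in motif_def.columns:
        qp = mapping.get(col)
        if qp is None or not (1 <= qp <= len(seq)):
            return MotifCall(pid, motif_def.motif_id, UNDETERMINED,
                             evidence="motif columns not covered by alignment")
    positions = [mapping[col] for col in motif_def.columns]
    residues = "".join(seq[p - 1] for p in positions)
    status = ACTIVE
    for i, res in enumerate(residues):
        allowed = motif_def.allowed(i)
        if res == "X" and x_as_undetermined:
            return MotifCall(pid, motif_def.motif_id, UNDETERMINED,
                             matched_residues=residues,
                             query_positions=tuple(positions),
                             evidence="X at a motif position")
        if allowed and res not in allowed:
            status = INACTIVE
            break
    return MotifCall(pid, motif_def.motif_id, status,
                     matched_residues=residues,
                     query_positions=tuple(positions),
                     evidence="exact-set match")


def _search_exact_pattern(seq: str, pattern: tuple[str, ...],
                          lo: int, hi: int) -> tuple[int, str] | None:
    """First occurrence of the exact-set pattern within [lo, hi] (1-based,
    inclusive window on start positions)."""
    plen = len(pattern)
    sets = ["" if p == "x" else p for p in pattern]
    for start in range(lo - 1, min(hi, len(seq) - plen + 1)):
        window = seq[start:start + plen]
        if all((not sets[i]) or window[i] in sets[i] for i in range(plen)):
            return start + 1, window
    return None


def _clamp_window(seq_len: int, region: str,
                  hits: list[homology.DomainHit]) -> tuple[int, int] | None:
    if region == "exo_loop":
        exo = [h for h in hits if h.domain_id == "DnaQ-exo"]
        if not exo:
            return None
        h = max(exo, key=lambda h: h.norm_score)
        return h.q_start, h.q_end
    if region == "cterm_third":
        return max(1, seq_len - seq_len // 3), seq_len
    raise ValueError(f"unknown clamp region {region!r}")


def detect_interaction_motifs(protein, group_def: GroupDef,
                              hits: list[homology.DomainHit],
                              registry: Registry,
                              profiles: dict[str, homology.Profile]) -> list[MotifCall]:
    """β-clamp and RecA-NT calls for one protein of a known group.

    The clamp motif is searched only within the group's designated region
    (PolA2: the vestigial exonuclease-domain loop; clamp-bearing PolYs and
    PolBs: the C-terminal third).  RecA-NT is present when the profile
    score reaches the registry threshold.
    """
    pid, seq = _seq_of(protein)
    calls: list[MotifCall] = []

    expects_clamp = group_def.motif_status("CLAMP") is not None
    if expects_clamp and group_def.clamp_region:
        clamp = registry.motifs["CLAMP"]
        window = _clamp_window(len(seq), group_def.clamp_region, hits)
        if window is None:
            calls.append(MotifCall(pid, "CLAMP", UNDETERMINED,
                                   evidence="search region not located"))
        else:
            found = _search_exact_pattern(seq, clamp.pattern, *window)
            if found:
                pos, matched = found
                calls.append(MotifCall(
                    pid, "CLAMP", PRESENT, matched_residues=matched,
                    query_positions=tuple(range(pos, pos + len(matched))),
                    evidence=f"pattern in {group_def.clamp_region}"))
            else:
                calls.append(MotifCall(pid, "CLAMP", ABSENT,
                                       evidence=f"no match in {group_def.clamp_region}"))

    if group_def.motif_status("RecA_NT") is not None:
        calls.append(score_recA_NT(protein, registry, profiles))
    return calls


def score_recA_NT(protein, registry: Registry,
                  profiles: dict[str, homology.Profile]) -> MotifCall:
    """Profile-score the RecA-NT motif anywhere on the protein."""
    pid, seq = _seq_of(protein)
    mdef = registry.motifs["RecA_NT"]
    profile = profiles["RecA_NT"]
    raw, pairs = _align.local_profile_align(
        profile.matrix, _align.encode(seq),
        homology.GAP_OPEN_BITS, homology.GAP_EXT_BITS)
    norm = raw / profile.self_score
    if norm >= mdef.threshold and pairs:
        return MotifCall(pid, "RecA_NT", PRESENT,
                         matched_residues=seq[pairs[0][1] - 1:pairs[-1][1]],
                         query_positions=(pairs[0][1], pairs[-1][1]),
                         evidence=f"profile score {norm:.3f} >= {mdef.threshold}")
    return MotifCall(pid, "RecA_NT", ABSENT,
                     evidence=f"profile score {norm:.3f} < {mdef.threshold}")


def call_polymerase_activity(protein, group_def: GroupDef,
                             mapping: dict[int, int],
                             registry: Registry,
                             x_as_undetermined: bool = False) -> MotifCall:
    """Catalytic-carboxylate call on the family's polymerase core.

    Active only when all catalytic columns carry the allowed carboxylates;
    an inactive call drives the iPolY designation in Y-family.
    """
    motif_id = POL_AS_BY_FAMILY[group_def.family_id]
    return call_active_site(protein, registry.motifs[motif_id], mapping,
                            x_as_undetermined=x_as_undetermined)


def export_motif_counts(calls_by_group: dict[str, list[MotifCall]]):
    """Per-group position count matrices over motif columns.

    Returns group -> (20 x L) count DataFrame; undetermined calls are not
    counted, so column sums equal the number of determined calls.  Groups
    with only undetermined calls yield an empty matrix with a warning.
    """
    import warnings

    import pandas as pd

    from ._refs import AA

    out = {}
    for group, calls in calls_by_group.items():
        determined = [c for c in calls
                      if c.status != UNDETERMINED and c.matched_residues]
        if not determined:
            warnings.warn(f"{group}: no determined motif calls; empty matrix")
            out[group] = pd.DataFrame(index=list(AA))
            continue
        L = len(determined[0].matched_residues)
        counts = np.zeros((20, L), dtype=int)
        for c in determined:
            for j, res in enumerate(c.matched_residues[:L]):
                if res in AA:
                    counts[AA.index(res), j] += 1
        out[group] = pd.DataFrame(counts, index=list(AA),
                                  columns=[f"pos{j + 1}" for j in range(L)])
    return out


def summarize_recA_NT(calls: list[MotifCall]) -> str:
    """Group-level prevalence class of the RecA-NT motif: the fraction of
    members carrying it is summarized as most (>=0.9), partial (>=0.1),
    or none."""
    determined = [c for c in calls if c.status != UNDETERMINED]
    if not determined:
        return "none"
    frac = sum(c.positive for c in determined) / len(determined)
    if frac >= 0.9:
        return "most"
    if frac >= 0.1:
        return "partial"
    return "none"
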