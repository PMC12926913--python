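"""Inference of multimeric error-prone polymerase (mutasome) complexes.

Complex types are matched per genome against the registry decision table,
in priority order (most specific first; the presumed-ancestral PolY-RecA
dimer is the lowest-priority fallback).  Core members — the DnaE2 and the
PolY/iPolY of a call — are consumed when matched, so a protein fills the
core role of at most one call; accessory partners (RecA, UmuD, YqjX-like
small subunits, SRAP, standalone ImuB-C) can serve several calls.  One
genome may host calls of several different types (Pol V alongside
ImuA-ImuB-DnaE2 is a real co-occurrence pattern).

Evidence is graded by gene neighborhood: members that all lie within a
small gene-index window on one contig are "colocalized", otherwise the
call rests on co-occurrence.  Optional externally computed structure-model
confidence tables can veto calls via established score thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .registry import ComplexTypeDef, Registry

DEFAULT_WINDOW = 5
IPTM_THRESHOLD = {"multimer-v2": 0.65, "v3": 0.70}
GLOBAL_SCORE_THRESHOLD = 0.4

COLOCALIZED = "colocalized"
CO_OCCURRENCE = "co-occurrence"

# complex types where strict mode additionally demands colocalization
_STRICT_TYPES = ("DnaE2B-PolY-ImuBC-RecA", "DnaE2B-iPolY-RecA",
                 "DnaE2B-PolY-RecA", "DnaE2B-ImuBC",
                 "DnaE2X-iPolY-ImuBC-RecA")


@dataclass
class ComplexCall:
    genome_id: str
    complex_id: str
    members: tuple = ()               # ((role, protein_id), ...)
    evidence_level: str = CO_OCCURRENCE
    variant: str | None = None
    notes: str = ""

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(pid for _, pid in self.members)


@dataclass
class ModelScore:
    key: str                          # genome_id/complex_id or protein id
    source: str                       # multimer-v2 | v3
    pTM: float | None
    ipTM: float
    complementary_global_score: float | None = None
    clash: bool = False


def colocalize(member_records, window: int = DEFAULT_WINDOW) -> str:
    """Evidence grade for a member set: "colocalized" iff all members lie
    on one contig within `window` gene indices of each other."""
    contexts = []
    for rec in member_records:
        if rec is None or rec.gene_index is None:
            warnings.warn("complex member without gene context; "
                          "falling back to co-occurrence evidence")
            return CO_OCCURRENCE
        contexts.append((rec.contig_id, rec.gene_index))
    contigs = {c for c, _ in contexts}
    if len(contigs) != 1:
        return CO_OCCURRENCE
    indices = [i for _, i in contexts]
    return COLOCALIZED if max(indices) - min(indices) <= window else CO_OCCURRENCE


def _poly_matches(ann, comp) -> bool:
    if comp.groups is not None and ann.group not in comp.groups:
        return False
    if comp.recA_NT == "yes" and ann.recA_NT is not True:
        return False
    if comp.recA_NT == "no" and ann.recA_NT is not False:
        return False
    if comp.active == "yes" and ann.polymerase_active is not True:
        return False
    if comp.active == "no" and ann.polymerase_active is not False:
        return False
    return True


def _match_type(ct: ComplexTypeDef, pools, consumed, assume_recA) -> dict | None:
    """Try to fill every component of `ct` with distinct, eligible proteins.
    Returns role -> annotation (or None for an assumed RecA)."""
    chosen: dict[int, object] = {}
    used_ids: set[str] = set()
    for idx, comp in enumerate(ct.components):
        candidate = None
        if comp.role in ("dnaE2", "polY"):
            pool = pools[comp.role]
            for ann in pool:
                if ann.protein_id in consumed or ann.protein_id in used_ids:
                    continue
                if comp.role == "dnaE2" and (comp.groups is None
                                             or ann.group in comp.groups):
                    candidate = ann
                    break
                if comp.role == "polY" and _poly_matches(ann, comp):
                    candidate = ann
                    break
        elif comp.role == "accessory":
            if comp.accessory_id == "RecA" and assume_recA and not pools["acc"].get("RecA"):
                chosen[idx] = None
                continue
            for ann in pools["acc"].get(comp.accessory_id, ()):
                if ann.protein_id not in used_ids:
                    candidate = ann
                    break
        elif comp.role == "small":
            for option in comp.options:
                for ann in pools["acc"].get(option, ()):
                    if ann.protein_id not in used_ids:
                        candidate = ann
                        break
                if candidate:
                    break
        if candidate is None:
            return None
        chosen[idx] = candidate
        used_ids.add(candidate.protein_id)
    return chosen


def type_complexes(complement, registry: Registry, options=None,
                   model_scores: dict | None = None) -> list[ComplexCall]:
    """Match the registry decision table against one genome complement.

    ``complement`` provides ``census()`` (family-assigned annotations) and
    ``accessories(role)``.  RecA presence is detected by profile scan of
    the proteome (an ``assume_recA`` option restores permissive matching).
    Calls whose structure-model score row fails the confidence filter are
    dropped with a note.
    """
    assume_recA = bool(options and getattr(options, "assume_recA", False))
    require_coloc = bool(options and getattr(options, "require_colocalization", False))
    window = getattr(options, "colocalization_window", DEFAULT_WINDOW) if options else DEFAULT_WINDOW

    census = complement.census()
    pools = {
        "dnaE2": sorted((a for a in census if a.group
                         and a.group.startswith("DnaE2")),
                        key=lambda a: a.protein_id),
        "polY": sorted((a for a in census if a.is_polY),
                       key=lambda a: a.protein_id),
        "acc": {},
    }
    for role in ("RecA", "ImuA", "UmuD", "YqjX", "YqjX-NTonly", "YhjD",
                 "SRAP", "ImuB-C-solo"):
        members = sorted(complement.accessories(role),
                         key=lambda a: a.protein_id)
        if members:
            pools["acc"][role] = members

    calls: list[ComplexCall] = []
    consumed: set[str] = set()
    for ct in sorted(registry.complex_types, key=lambda t: t.priority):
        while True:
            chosen = _match_type(ct, pools, consumed, assume_recA)
            if chosen is None:
                break
            members = []
            records = []
            variant = None
            for idx, ann in chosen.items():
                comp = ct.components[idx]
                role_label = (comp.accessory_id if comp.role == "accessory"
                              else comp.role)
                if ann is None:     # assumed RecA
                    members.append((role_label, "(assumed-RecA)"))
                    continue
                members.append((role_label, ann.protein_id))
                records.append(ann.record)
                if ct.variant_from == comp.role:
                    variant = (ann.accessory_role if comp.role in ("small", "accessory")
                               else ann.group)
                if comp.role in ("dnaE2", "polY"):
                    consumed.add(ann.protein_id)
            evidence = colocalize(records, window=window)
            call = ComplexCall(genome_id=complement.genome_id,
                               complex_id=ct.complex_id,
                               members=tuple(members),
                               evidence_level=evidence, variant=variant)
            if require_coloc and ct.complex_id in _STRICT_TYPES \
                    and evidence != COLOCALIZED:
                call.notes = "rejected: colocalization required"
                continue
            if model_scores:
                key = f"{complement.genome_id}/{ct.complex_id}"
                score = model_scores.get(key)
                if score is not None:
                    ok, reasons = model_score_passes(score)
                    if not ok:
                        call.notes = "rejected by model-score filter: " + "; ".join(reasons)
                        continue
            calls.append(call)
    return calls


def model_score_passes(score: ModelScore) -> tuple[bool, list[str]]:
    """Structure-model confidence filter.

    Pass requires ipTM at or above the source-specific threshold (0.65 for
    multimer-v2, 0.70 for v3), a complementary global score above 0.4 when
    one is supplied, and no clash flag.
    """
    reasons = []
    thr = IPTM_THRESHOLD.get(score.source)
    if thr is None:
        reasons.append(f"unknown model source {score.source!r}")
    elif score.ipTM < thr:
        reasons.append(f"ipTM {score.ipTM} below {thr} ({score.source})")
    if (score.complementary_global_score is not None
            and not score.complementary_global_score > GLOBAL_SCORE_THRESHOLD):
        reasons.append(f"global score {score.complementary_global_score} "
                       f"not above {GLOBAL_SCORE_THRESHOLD}")
    if score.clash:
        reasons.append("clash flag set")
    return (not reasons), reasons


def apply_model_score_filter(model_scores: dict, call: ComplexCall) -> tuple[bool, list[str]]:
    """Apply the confidence filter to one call; calls without a score row
    remain unfiltered (sequence evidence only)."""
    key = f"{call.genome_id}/{call.complex_id}"
    score = model_scores.get(key)
    if score is None:
        return True, ["no model score supplied; sequence evidence only"]
    return model_score_passes(score)


def load_model_scores(path) -> dict[str, ModelScore]:
    """Read a model-score TSV
    (``genome_id complex_id source pTM ipTM global clash``); malformed
    rows are skipped with a warning."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns={"global": "global_score"})
    out: dict[str, ModelScore] = {}
    for r in df.itertuples():
        try:
            key = f"{r.genome_id}/{r.complex_id}"
            score = ModelScore(
                key=key, source=r.source,
                pTM=None if r.pTM in (".", None) else float(r.pTM),
                ipTM=float(r.ipTM),
                complementary_global_score=(
                    None if r.global_score in (".", None)
                    else float(r.global_score)),
                clash=str(r.clash).lower() in ("1", "true", "yes"))
        except (TypeError, ValueError, AttributeError) as exc:
            warnings.warn(f"skipping malformed model-score row {tuple(r)}: {exc}")
            continue
        for val in (score.pTM, score.ipTM, score.complementary_global_score):
            if val is not None and not (0.0 <= val <= 1.0):
                warnings.warn(f"skipping model-score row with out-of-range "
                              f"value {val} for {key}")
                score = None
                break
        if score is not None:
            out[key] = score
    return out
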