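"""Packaged, versioned knowledge base for bacterial DNA-polymerase annotation.

The registry encodes the classification the rest of the pipeline consumes:
the five bacterial polymerase families (A, B, C, X, Y), the named groups
within each family with their expected domain architectures and motif
expectations, active-site and interaction motif definitions, accessory
components (RecA, ImuA, UmuD, YqjX-like small subunits, SRAP, standalone
ImuB-C / FEN / validated DnaQ references), and the decision table of the
11 multimeric error-prone polymerase (mutasome) complex types.

Two physical representations exist:

* the packaged default — ontology TSVs shipped with the package plus a
  synthetic reference-sequence library generated deterministically (see
  :mod:`polcensus._refs`);
* a plain registry directory (``families.tsv``, ``groups.tsv``,
  ``domains.tsv``, ``motifs.tsv``, ``accessories.tsv``,
  ``complex_types.tsv``, ``refs/*.fasta``) that is diffable and
  user-extensible.  ``export_registry`` / ``load_registry`` round-trip a
  registry through this form bit-identically.

All motif coordinates are 1-based columns of the named reference alignment.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

from . import _refs

REGISTRY_VERSION = "polcensus-registry/1.0"

_TSV_FILES = ("families.tsv", "groups.tsv", "domains.tsv", "motifs.tsv",
              "accessories.tsv", "complex_types.tsv")

_POLYMERASE_ROLES = ("dnaE2", "polY")
_ROLES = ("dnaE2", "polY", "accessory", "small")


class RegistryError(ValueError):
    """Malformed registry input (parse failure)."""


class RegistryValidationError(RegistryError):
    """Registry parsed but violates a structural invariant."""


@dataclass(frozen=True)
class FamilyDef:
    family_id: str
    fold_class: str
    group_ids: tuple[str, ...]


@dataclass(frozen=True)
class GroupDef:
    group_id: str
    family_id: str
    expected_domains: tuple[str, ...]
    expected_motifs: tuple[tuple[str, str], ...]   # (motif_id, status)
    clamp_region: str | None                       # exo_loop | cterm_third | None
    anchor_refs: tuple[str, ...]
    notes: str = ""

    def motif_status(self, motif_id: str) -> str | None:
        for mid, status in self.expected_motifs:
            if mid == motif_id:
                return status
        return None


@dataclass(frozen=True)
class DomainDef:
    domain_id: str
    reference_alignment: str
    length: int
    min_hit_length: int
    description: str = ""


@dataclass(frozen=True)
class MotifDef:
    motif_id: str
    mode: str                                # "exact" | "profile"
    alignment_id: str | None
    columns: tuple[int, ...] | None          # 1-based alignment columns
    pattern: tuple[str, ...] | None          # per-position allowed residues
    threshold: float | None
    description: str = ""

    def allowed(self, position: int) -> str:
        """Allowed residues at a (0-based) motif position; '' means any."""
        spec = self.pattern[position]
        return "" if spec == "x" else spec

    def canonical_residues(self) -> str:
        return "".join("A" if p == "x" else p[0] for p in self.pattern)


@dataclass(frozen=True)
class AccessoryDef:
    component_id: str
    domains: tuple[str, ...]
    expected_motifs: tuple[tuple[str, str], ...]
    anchor_refs: tuple[str, ...]
    notes: str = ""


@dataclass(frozen=True)
class ComplexComponent:
    role: str                                # dnaE2 | polY | accessory | small
    groups: tuple[str, ...] | None = None    # group constraint (polY/dnaE2)
    recA_NT: str = "any"                     # yes | no | any
    active: str = "any"                      # yes | no | any
    accessory_id: str | None = None          # accessory role
    options: tuple[str, ...] | None = None   # small-subunit alternatives

    def signature(self):
        return (self.role, self.groups, self.recA_NT, self.active,
                self.accessory_id, self.options)


@dataclass(frozen=True)
class ComplexTypeDef:
    complex_id: str
    priority: int
    known: bool
    components: tuple[ComplexComponent, ...]
    variant_from: str | None                 # role whose filler labels the variant
    notes: str = ""


@dataclass
class Registry:
    families: dict[str, FamilyDef]
    groups: dict[str, GroupDef]
    domains: dict[str, DomainDef]
    motifs: dict[str, MotifDef]
    accessories: dict[str, AccessoryDef]
    complex_types: list[ComplexTypeDef]
    alignments: dict[str, list[tuple[str, str]]]    # alignment_id -> [(row id, row)]
    anchors: dict[str, str]                         # ref_id -> sequence
    anchor_info: dict[str, "_refs.AnchorInfo"] | None = None
    version: str = REGISTRY_VERSION

    # -- convenience ----------------------------------------------------
    def family_groups(self, family_id: str) -> tuple[str, ...]:
        return self.families[family_id].group_ids

    def group_family(self, group_id: str) -> str:
        return self.groups[group_id].family_id

    def core_domain(self, family_id: str) -> str:
        return f"core_{family_id}"

    def anchors_for(self, owner_id: str) -> dict[str, str]:
        """Anchor sequences of one group or accessory component."""
        if owner_id in self.groups:
            refs = self.groups[owner_id].anchor_refs
        elif owner_id in self.accessories:
            refs = self.accessories[owner_id].anchor_refs
        else:
            raise KeyError(f"unknown group or accessory: {owner_id}")
        return {r: self.anchors[r] for r in refs}


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _split(value: str) -> tuple[str, ...]:
    value = value.strip()
    if not value or value == ".":
        return ()
    return tuple(v.strip() for v in value.split(",") if v.strip())


def _parse_motif_list(value: str) -> tuple[tuple[str, str], ...]:
    out = []
    for item in _split(value):
        if ":" not in item:
            raise RegistryError(f"motif expectation must be 'id:status': {item!r}")
        mid, status = item.split(":", 1)
        out.append((mid.strip(), status.strip()))
    return tuple(out)


def _parse_component(spec: str) -> ComplexComponent:
    spec = spec.strip()
    if "(" not in spec or not spec.endswith(")"):
        raise RegistryError(f"malformed complex component: {spec!r}")
    role, inner = spec[:-1].split("(", 1)
    role = role.strip()
    if role not in _ROLES:
        raise RegistryError(f"unknown complex component role: {role!r}")
    if role == "accessory":
        return ComplexComponent(role=role, accessory_id=inner.strip())
    if role == "small":
        return ComplexComponent(role=role,
                                options=tuple(o.strip() for o in inner.split("|")))
    kwargs = {"role": role}
    for part in inner.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise RegistryError(f"malformed constraint {part!r} in {spec!r}")
        key, val = (s.strip() for s in part.split("=", 1))
        if key == "groups":
            kwargs["groups"] = tuple(g.strip() for g in val.split("|"))
        elif key in ("recA_NT", "active"):
            if val not in ("yes", "no", "any"):
                raise RegistryError(f"constraint {key}={val!r} must be yes/no/any")
            kwargs[key] = val
        else:
            raise RegistryError(f"unknown constraint key {key!r} in {spec!r}")
    return ComplexComponent(**kwargs)


def _read_tsv(text: str, path_label: str) -> list[dict]:
    rows = list(csv.DictReader(io.StringIO(text), delimiter="\t"))
    if not rows:
        raise RegistryError(f"{path_label}: empty table")
    return rows


def _parse_tables(tables: dict[str, str]) -> dict:
    """Parse the six ontology TSVs (name -> file text) into definition dicts."""
    families = {}
    for row in _read_tsv(tables["families.tsv"], "families.tsv"):
        families[row["family_id"]] = FamilyDef(
            family_id=row["family_id"],
            fold_class=row["fold_class"],
            group_ids=_split(row["group_ids"]),
        )

    groups = {}
    for row in _read_tsv(tables["groups.tsv"], "groups.tsv"):
        clamp = row.get("clamp_region", ".").strip()
        groups[row["group_id"]] = GroupDef(
            group_id=row["group_id"],
            family_id=row["family_id"],
            expected_domains=_split(row["domains"]),
            expected_motifs=_parse_motif_list(row["motifs"]),
            clamp_region=None if clamp in (".", "") else clamp,
            anchor_refs=_split(row["anchor_refs"]),
            notes=row.get("notes", ""),
        )

    domains = {}
    for row in _read_tsv(tables["domains.tsv"], "domains.tsv"):
        domains[row["domain_id"]] = DomainDef(
            domain_id=row["domain_id"],
            reference_alignment=row["reference_alignment"],
            length=int(row["length"]),
            min_hit_length=int(row["min_hit_length"]),
            description=row.get("description", ""),
        )

    motifs = {}
    for row in _read_tsv(tables["motifs.tsv"], "motifs.tsv"):
        cols = row["columns"].strip()
        pattern = row["pattern"].strip()
        thr = row["threshold"].strip()
        motifs[row["motif_id"]] = MotifDef(
            motif_id=row["motif_id"],
            mode=row["mode"],
            alignment_id=None if row["alignment_id"] == "." else row["alignment_id"],
            columns=None if cols == "." else tuple(int(c) for c in cols.split(",")),
            pattern=None if pattern == "." else tuple(pattern.split("-")),
            threshold=None if thr == "." else float(thr),
            description=row.get("description", ""),
        )

    accessories = {}
    for row in _read_tsv(tables["accessories.tsv"], "accessories.tsv"):
        accessories[row["component_id"]] = AccessoryDef(
            component_id=row["component_id"],
            domains=_split(row["domains"]),
            expected_motifs=_parse_motif_list(row["motifs"]) if row["motifs"] != "." else (),
            anchor_refs=_split(row["anchor_refs"]),
            notes=row.get("notes", ""),
        )

    complex_types = []
    for row in _read_tsv(tables["complex_types.tsv"], "complex_types.tsv"):
        variant = row["variant_from"].strip()
        complex_types.append(ComplexTypeDef(
            complex_id=row["complex_id"],
            priority=int(row["priority"]),
            known=row["known"].strip().lower() in ("yes", "true", "1"),
            components=tuple(_parse_component(c)
                             for c in row["components"].split(" + ")),
            variant_from=None if variant in (".", "") else variant,
            notes=row.get("notes", ""),
        ))
    complex_types.sort(key=lambda t: t.priority)

    return dict(families=families, groups=groups, domains=domains,
                motifs=motifs, accessories=accessories,
                complex_types=complex_types)


# ---------------------------------------------------------------------------
# synthetic reference library for the default registry
# ---------------------------------------------------------------------------

def _motif_plants_for(defs, owner_motifs, alignment_id):
    """Exact-set motifs of `owner_motifs` living on `alignment_id`,
    as (MotifDef, status) pairs."""
    out = []
    for mid, status in owner_motifs:
        mdef = defs["motifs"][mid]
        if mdef.mode == "exact" and mdef.alignment_id == alignment_id:
            out.append((mdef, status))
    return out


def _plant_motif(seq_list, mdef: MotifDef, status: str):
    """Write intact or canonically broken motif residues into a domain
    variant (list of chars, domain-local coordinates)."""
    canon = mdef.canonical_residues()
    for col, res in zip(mdef.columns, canon):
        seq_list[col - 1] = res
    planted = "active"
    if status == "inactive":
        pos, res = _refs.MOTIF_BREAKS[mdef.motif_id]
        seq_list[mdef.columns[pos - 1] - 1] = res
        planted = "inactive"
    return planted


def _assemble_anchor(ref_id, owner_id, arch, motif_specs, clamp_region,
                     defs, consensi, protected_cols, recA_status):
    """Build one primary anchor sequence plus its ground-truth layout."""
    clamp_motif = defs["motifs"]["CLAMP"]
    parts: list[str] = []
    pos = 0
    info = _refs.AnchorInfo(ref_id=ref_id, group_id=owner_id, sequence="")

    def _append(segment: str):
        nonlocal pos
        parts.append(segment)
        pos += len(segment)

    for dom_idx, domain_id in enumerate(arch):
        _append(_refs.linker(owner_id, f"L{dom_idx}"))
        aln_id = defs["domains"][domain_id].reference_alignment
        variant = list(_refs.group_domain_variant(
            owner_id, domain_id, consensi[aln_id], protected_cols[aln_id]))
        offset = pos
        for mdef, status in _motif_plants_for(defs, motif_specs, aln_id):
            planted = _plant_motif(variant, mdef, status)
            info.motif_sites.append(_refs.MotifSite(
                motif_id=mdef.motif_id,
                positions=tuple(offset + c for c in mdef.columns),
                planted_status=planted))
        if clamp_region == "exo_loop" and domain_id == "DnaQ-exo":
            for col, res in zip(_refs.CLAMP_EXO_COLUMNS, _refs.CLAMP_EXO_LOOP):
                variant[col - 1] = res
            info.clamp_span = (offset + _refs.CLAMP_EXO_COLUMNS[0],
                               offset + _refs.CLAMP_EXO_COLUMNS[-1])
        _append("".join(variant))
        info.domain_spans[domain_id] = (offset + 1, pos)
        if domain_id == "LF" and recA_status == "required":
            _append(_refs.linker(owner_id, "Lrec"))
            seg = _refs.mutate(_refs.rng_for("recant", owner_id),
                               consensi["RecA_NT"], _refs.MOTIF_SEGMENT_RATE)
            start = pos + 1
            _append(seg)
            info.recA_nt_span = (start, pos)

    if clamp_region == "cterm_third":
        _append(_refs.linker(owner_id, "Lclamp", 8))
        start = pos + 1
        _append(_refs.CLAMP_CTERM)
        info.clamp_span = (start, pos)
        _append(_refs.linker(owner_id, "Ltail", 6))

    seq = "".join(parts)
    if clamp_region is not None:
        pattern_sets = tuple("" if p == "x" else p for p in clamp_motif.pattern)
        seq = _refs.scrub_pattern(seq, pattern_sets, info.protected_positions)
    info.sequence = seq
    return info


def _sibling_anchor(ref_id, primary: "_refs.AnchorInfo", k: int):
    rng = _refs.rng_for("sibling", primary.group_id, k)
    seq = _refs.mutate(rng, primary.sequence, _refs.ANCHOR_SIBLING_RATE,
                       primary.protected_positions)
    return _refs.AnchorInfo(
        ref_id=ref_id, group_id=primary.group_id, sequence=seq,
        domain_spans=dict(primary.domain_spans),
        motif_sites=list(primary.motif_sites),
        recA_nt_span=primary.recA_nt_span,
        clamp_span=primary.clamp_span)


def _build_reference_library(defs) -> tuple[dict, dict, dict]:
    """Generate alignments, anchors, and anchor layouts for the ontology."""
    # canonical residues per alignment column (later motifs overwrite earlier)
    plant_cols: dict[str, dict[int, str]] = {}
    protected_cols: dict[str, frozenset[int]] = {}
    for mdef in defs["motifs"].values():
        if mdef.mode != "exact" or mdef.alignment_id is None:
            continue
        cols = plant_cols.setdefault(mdef.alignment_id, {})
        for c, r in zip(mdef.columns, mdef.canonical_residues()):
            cols[c] = r

    consensi: dict[str, str] = {}
    alignments: dict[str, list[tuple[str, str]]] = {}
    for dom in defs["domains"].values():
        aln = dom.reference_alignment
        if aln in consensi:
            continue
        cols = plant_cols.get(aln, {})
        protected_cols[aln] = frozenset(c - 1 for c in cols)
        consensi[aln] = _refs.build_domain_consensus(aln, dom.length, cols)
        alignments[aln] = _refs.build_domain_alignment(aln, consensi[aln],
                                                       protected_cols[aln])
    # profile-mode motif sub-alignments (RecA-NT)
    for mdef in defs["motifs"].values():
        if mdef.mode == "profile" and mdef.alignment_id not in consensi:
            aln = mdef.alignment_id
            protected_cols[aln] = frozenset()
            consensi[aln] = _refs.build_domain_consensus(
                aln, _refs.RECA_NT_LENGTH, {})
            alignments[aln] = _refs.build_domain_alignment(
                aln, consensi[aln], protected_cols[aln])

    anchors: dict[str, str] = {}
    anchor_info: dict[str, _refs.AnchorInfo] = {}

    def _emit(owner_id, refs, arch, motif_specs, clamp_region, recA_status):
        primary = _assemble_anchor(refs[0], owner_id, arch, motif_specs,
                                   clamp_region, defs, consensi,
                                   protected_cols, recA_status)
        infos = [primary] + [_sibling_anchor(r, primary, k)
                             for k, r in enumerate(refs[1:], start=1)]
        for inf in infos:
            anchors[inf.ref_id] = inf.sequence
            anchor_info[inf.ref_id] = inf

    for group in defs["groups"].values():
        recA = group.motif_status("RecA_NT") or "absent"
        specs = tuple((m, s) for m, s in group.expected_motifs
                      if m not in ("RecA_NT", "CLAMP"))
        _emit(group.group_id, group.anchor_refs, group.expected_domains,
              specs, group.clamp_region, recA)
    for acc in defs["accessories"].values():
        _emit(acc.component_id, acc.anchor_refs, acc.domains,
              acc.expected_motifs, None, "absent")

    return alignments, anchors, anchor_info


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _validate_table_refs(defs) -> None:
    """Cross-table id resolution, checked before any reference sequences
    are built so that a dangling id fails fast with a named error."""
    problems = []
    for owner in list(defs["groups"].values()) + list(defs["accessories"].values()):
        oid = getattr(owner, "group_id", None) or owner.component_id
        domains = getattr(owner, "expected_domains", None) or owner.domains
        for d in domains:
            if d not in defs["domains"]:
                problems.append(f"{oid}: dangling domain reference: {d}")
        for mid, _ in owner.expected_motifs:
            if mid not in defs["motifs"]:
                problems.append(f"{oid}: dangling motif reference: {mid}")
    if problems:
        raise RegistryValidationError("; ".join(problems))


def validate_registry(reg: Registry) -> None:
    problems: list[str] = []

    if set(reg.families) != {"A", "B", "C", "X", "Y"}:
        problems.append(f"families must be exactly A,B,C,X,Y; got {sorted(reg.families)}")

    owner_of: dict[str, str] = {}
    for fam in reg.families.values():
        for gid in fam.group_ids:
            if gid in owner_of:
                problems.append(f"group {gid} listed under two families")
            owner_of[gid] = fam.family_id
    for gid, group in reg.groups.items():
        if owner_of.get(gid) != group.family_id:
            problems.append(f"group {gid}: family link inconsistent")
    for gid in owner_of:
        if gid not in reg.groups:
            problems.append(f"dangling group reference: {gid}")

    def _check_owner(owner_id, domains, motifs, anchor_refs, assignable=True):
        for d in domains:
            if d not in reg.domains:
                problems.append(f"{owner_id}: dangling domain reference: {d}")
        for mid, status in motifs:
            if mid not in reg.motifs:
                problems.append(f"{owner_id}: dangling motif reference: {mid}")
            if status not in ("required", "typical", "inactive", "absent", "partial"):
                problems.append(f"{owner_id}: unknown motif status {status!r}")
        if assignable and not anchor_refs:
            problems.append(f"{owner_id}: anchor_refs empty")
        for r in anchor_refs:
            if r not in reg.anchors:
                problems.append(f"{owner_id}: dangling anchor reference: {r}")

    for group in reg.groups.values():
        _check_owner(group.group_id, group.expected_domains,
                     group.expected_motifs, group.anchor_refs)
    for acc in reg.accessories.values():
        _check_owner(acc.component_id, acc.domains, acc.expected_motifs,
                     acc.anchor_refs)

    for dom in reg.domains.values():
        if dom.min_hit_length <= 0:
            problems.append(f"{dom.domain_id}: min_hit_length must be > 0")
        if dom.reference_alignment not in reg.alignments:
            problems.append(f"{dom.domain_id}: missing alignment "
                            f"{dom.reference_alignment}")

    for aln_id, rows in reg.alignments.items():
        lens = {len(s) for _, s in rows}
        if len(lens) > 1:
            problems.append(f"alignment {aln_id}: inconsistent row lengths {sorted(lens)}")

    for mdef in reg.motifs.values():
        if mdef.mode == "exact" and mdef.columns is not None:
            if len(mdef.pattern) != len(mdef.columns):
                problems.append(f"{mdef.motif_id}: pattern length "
                                f"{len(mdef.pattern)} != columns {len(mdef.columns)}")
            aln = reg.alignments.get(mdef.alignment_id)
            if aln is None:
                problems.append(f"{mdef.motif_id}: missing alignment {mdef.alignment_id}")
            elif max(mdef.columns) > len(aln[0][1]):
                problems.append(f"{mdef.motif_id}: column beyond alignment end")
        if mdef.mode == "profile":
            if mdef.alignment_id not in reg.alignments:
                problems.append(f"{mdef.motif_id}: profile motif needs packaged "
                                f"sub-alignment {mdef.alignment_id}")
            if mdef.threshold is None:
                problems.append(f"{mdef.motif_id}: profile motif needs a threshold")

    if len(reg.complex_types) != 11:
        problems.append(f"expected 11 complex types, got {len(reg.complex_types)}")
    signatures = {}
    for ct in reg.complex_types:
        sig = tuple(sorted(c.signature() for c in ct.components))
        if sig in signatures:
            problems.append(f"complex types {signatures[sig]} and {ct.complex_id} "
                            f"have identical component sets")
        signatures[sig] = ct.complex_id
        for comp in ct.components:
            if comp.groups:
                for g in comp.groups:
                    if g not in reg.groups:
                        problems.append(f"{ct.complex_id}: dangling group "
                                        f"constraint: {g}")
            if comp.accessory_id and comp.accessory_id not in reg.accessories:
                problems.append(f"{ct.complex_id}: dangling accessory "
                                f"reference: {comp.accessory_id}")
            if comp.options:
                for o in comp.options:
                    if o not in reg.accessories:
                        problems.append(f"{ct.complex_id}: dangling small-subunit "
                                        f"reference: {o}")
    known = {ct.complex_id for ct in reg.complex_types if ct.known}
    if known != {"UmuC-UmuD2-RecA", "ImuA-ImuB-DnaE2"}:
        problems.append(f"exactly Pol V and ImuA-ImuB-DnaE2 must be flagged as "
                        f"previously characterized; got {sorted(known)}")

    if problems:
        raise RegistryValidationError("; ".join(problems))


# ---------------------------------------------------------------------------
# loading / export
# ---------------------------------------------------------------------------

def _packaged_tables() -> dict[str, str]:
    from importlib import resources
    base = resources.files("polcensus.data") / "registry"
    return {name: (base / name).read_text() for name in _TSV_FILES}


def _read_fasta(path: Path) -> list[tuple[str, str]]:
    from Bio import SeqIO
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def load_registry(path: str | Path | None = None,
                  tables: dict[str, str] | None = None) -> Registry:
    """Load and validate a registry.

    With no arguments the packaged default is returned: ontology tables
    shipped with the package plus the deterministic synthetic reference
    library.  With ``path``, a registry directory (TSVs + ``refs/``) is
    read instead.  ``tables`` overrides individual TSV texts of the
    default (used mainly to test validation).
    """
    if path is None:
        texts = _packaged_tables()
        if tables:
            texts.update(tables)
        defs = _parse_tables(texts)
        _validate_table_refs(defs)
        alignments, anchors, anchor_info = _build_reference_library(defs)
        reg = Registry(**defs, alignments=alignments, anchors=anchors,
                       anchor_info=anchor_info)
    else:
        path = Path(path)
        texts = {}
        for name in _TSV_FILES:
            fp = path / name
            if not fp.exists():
                raise RegistryError(f"missing registry table: {fp}")
            texts[name] = fp.read_text()
        defs = _parse_tables(texts)
        alignments = {}
        for fp in sorted((path / "refs").glob("aln_*.fasta")):
            alignments[fp.stem[len("aln_"):]] = _read_fasta(fp)
        anchors = dict(_read_fasta(path / "refs" / "anchors.fasta"))
        sites = path / "refs" / "anchor_sites.tsv"
        anchor_info = _read_anchor_sites(sites, anchors) if sites.exists() else None
        reg = Registry(**defs, alignments=alignments, anchors=anchors,
                       anchor_info=anchor_info)
    validate_registry(reg)
    return reg


def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def export_registry(reg: Registry, out_dir: str | Path) -> Path:
    """Write a registry to its plain-text directory form."""
    out = Path(out_dir)
    (out / "refs").mkdir(parents=True, exist_ok=True)

    def _tsv(name, header, rows):
        with open(out / name, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")

    _tsv("families.tsv", ["family_id", "fold_class", "group_ids"],
         [[f.family_id, f.fold_class, ",".join(f.group_ids)]
          for f in reg.families.values()])
    _tsv("groups.tsv",
         ["group_id", "family_id", "domains", "motifs", "clamp_region",
          "anchor_refs", "notes"],
         [[g.group_id, g.family_id, ",".join(g.expected_domains),
           ",".join(f"{m}:{s}" for m, s in g.expected_motifs),
           g.clamp_region or ".", ",".join(g.anchor_refs), g.notes]
          for g in reg.groups.values()])
    _tsv("domains.tsv",
         ["domain_id", "reference_alignment", "length", "min_hit_length",
          "description"],
         [[d.domain_id, d.reference_alignment, str(d.length),
           str(d.min_hit_length), d.description] for d in reg.domains.values()])
    _tsv("motifs.tsv",
         ["motif_id", "mode", "alignment_id", "columns", "pattern",
          "threshold", "description"],
         [[m.motif_id, m.mode, m.alignment_id or ".",
           ",".join(str(c) for c in m.columns) if m.columns else ".",
           "-".join(m.pattern) if m.pattern else ".",
           repr(m.threshold) if m.threshold is not None else ".",
           m.description] for m in reg.motifs.values()])
    _tsv("accessories.tsv",
         ["component_id", "domains", "motifs", "anchor_refs", "notes"],
         [[a.component_id, ",".join(a.domains),
           ",".join(f"{m}:{s}" for m, s in a.expected_motifs) or ".",
           ",".join(a.anchor_refs), a.notes] for a in reg.accessories.values()])
    _tsv("complex_types.tsv",
         ["complex_id", "priority", "known", "components", "variant_from",
          "notes"],
         [[c.complex_id, str(c.priority), "yes" if c.known else "no",
           " + ".join(_component_to_str(comp) for comp in c.components),
           c.variant_from or ".", c.notes] for c in reg.complex_types])

    for aln_id in sorted(reg.alignments):
        _write_fasta(out / "refs" / f"aln_{aln_id}.fasta", reg.alignments[aln_id])
    _write_fasta(out / "refs" / "anchors.fasta", sorted(reg.anchors.items()))
    if reg.anchor_info is not None:
        _write_anchor_sites(reg.anchor_info, out / "refs" / "anchor_sites.tsv")
    return out


def _span_str(span) -> str:
    return "." if span is None else f"{span[0]}-{span[1]}"


def _parse_span(text):
    if text == ".":
        return None
    lo, hi = text.split("-")
    return (int(lo), int(hi))


def _write_anchor_sites(anchor_info: dict, path: Path) -> None:
    """Anchor layout table: where each motif and span sits inside each
    anchor sequence (1-based anchor coordinates)."""
    with open(path, "w") as fh:
        fh.write("ref_id\tgroup_id\tdomain_spans\tmotif_sites\t"
                 "recA_nt_span\tclamp_span\n")
        for rid in sorted(anchor_info):
            info = anchor_info[rid]
            doms = ";".join(f"{d}:{s}-{e}"
                            for d, (s, e) in info.domain_spans.items())
            sites = ";".join(
                f"{s.motif_id}:{s.planted_status}:"
                + "|".join(str(p) for p in s.positions)
                for s in info.motif_sites)
            fh.write(f"{rid}\t{info.group_id}\t{doms or '.'}\t{sites or '.'}\t"
                     f"{_span_str(info.recA_nt_span)}\t"
                     f"{_span_str(info.clamp_span)}\n")


def _read_anchor_sites(path: Path, anchors: dict[str, str]) -> dict:
    out = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, gid, doms, sites, rec_span, clamp_span = \
                line.rstrip("\n").split("\t")
            info = _refs.AnchorInfo(ref_id=rid, group_id=gid,
                                    sequence=anchors[rid])
            if doms != ".":
                for item in doms.split(";"):
                    d, span = item.split(":")
                    info.domain_spans[d] = _parse_span(span)
            if sites != ".":
                for item in sites.split(";"):
                    mid, status, positions = item.split(":")
                    info.motif_sites.append(_refs.MotifSite(
                        motif_id=mid,
                        positions=tuple(int(p) for p in positions.split("|")),
                        planted_status=status))
            info.recA_nt_span = _parse_span(rec_span)
            info.clamp_span = _parse_span(clamp_span)
            out[rid] = info
    return out


def _component_to_str(comp: ComplexComponent) -> str:
    if comp.role == "accessory":
        return f"accessory({comp.accessory_id})"
    if comp.role == "small":
        return f"small({'|'.join(comp.options)})"
    fields = []
    if comp.groups:
        fields.append("groups=" + "|".join(comp.groups))
    if comp.recA_NT != "any":
        fields.append(f"recA_NT={comp.recA_NT}")
    if comp.active != "any":
        fields.append(f"active={comp.active}")
    return f"{comp.role}({';'.join(fields)})"


def list_complex_types(reg: Registry,
                       component_filter: str | None = None) -> list[ComplexTypeDef]:
    """Complex types in priority order, optionally restricted to those
    containing a given component (role name, group id — or a group-id
    prefix such as ``DnaE2`` — or accessory id)."""
    types = sorted(reg.complex_types, key=lambda t: t.priority)
    if component_filter is None:
        return types
    f = component_filter
    known_vocab = (f in _ROLES or f in reg.groups or f in reg.accessories
                   or any(g.startswith(f) for g in reg.groups))
    if not known_vocab:
        raise ValueError(f"unknown component role or id: {f!r}")

    def _matches(ct: ComplexTypeDef) -> bool:
        for comp in ct.components:
            if comp.role == f:
                return True
            if comp.accessory_id == f:
                return True
            if comp.groups and any(g == f or g.startswith(f) for g in comp.groups):
                return True
            if comp.options and f in comp.options:
                return True
        return False

    return [ct for ct in types if _matches(ct)]
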