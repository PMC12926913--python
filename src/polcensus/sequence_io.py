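"""Readers and writers for proteomes, gene features, metadata, and outputs.

Conventions: amino-acid FASTA input, 1-based inclusive coordinates (GFF),
gene order expressed as a per-contig ``gene_index`` (rank of the CDS by
start coordinate).  Neighborhood analysis downstream works on gene order,
not on base-pair distance.  Output tables are UTF-8 TSV with ``.`` for
missing values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")
# selenocysteine / pyrrolysine are outside the 20-letter profile alphabet
_NONSTANDARD = {"U": "X", "O": "X", "B": "X", "Z": "X", "J": "X", "*": ""}


class SequenceIOError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with its genome and gene-order context."""
    protein_id: str
    genome_id: str
    sequence: str
    contig_id: str = "unknown"
    gene_index: int | None = None
    strand: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self):
        if not self.sequence:
            raise SequenceIOError(f"{self.protein_id}: empty sequence")
        if self.start is not None and self.end is not None and self.end < self.start:
            raise SequenceIOError(f"{self.protein_id}: end < start")

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeRecord:
    """Per-genome metadata: taxonomy, genome properties, environment labels."""
    genome_id: str
    taxonomy: tuple[str, ...] = ()      # (phylum, class, order, family, genus, species)
    size_bp: int = 1
    gc_percent: float = 50.0
    oxygen_labels: tuple[str, ...] = ()
    growth_temp_c: float | None = None
    gram: str | None = None

    def __post_init__(self):
        if self.size_bp <= 0:
            raise SequenceIOError(f"{self.genome_id}: size_bp must be positive")
        if not (0.0 <= self.gc_percent <= 100.0):
            raise SequenceIOError(f"{self.genome_id}: gc_percent outside [0,100]")

    def rank(self, name: str) -> str | None:
        ranks = ("phylum", "class", "order", "family", "genus", "species")
        try:
            value = self.taxonomy[ranks.index(name)]
        except (ValueError, IndexError):
            return None
        return value or None


def _normalize_sequence(protein_id: str, raw: str) -> str:
    seq = raw.upper()
    for bad, repl in _NONSTANDARD.items():
        if bad in seq:
            if bad in "UO":
                warnings.warn(f"{protein_id}: nonstandard residue {bad} mapped to X")
            seq = seq.replace(bad, repl)
    extra = set(seq) - VALID_RESIDUES
    if extra:
        raise SequenceIOError(f"{protein_id}: invalid residues {sorted(extra)}")
    return seq


def read_proteome(fasta_source, genome_id: str,
                  features: dict | None = None) -> list[ProteinRecord]:
    """Read an amino-acid FASTA into ProteinRecords.

    The first whitespace-delimited token of each header is the protein id.
    Gene context is taken from ``features`` (see :func:`read_features`)
    when given; otherwise gene_index follows FASTA order on a single
    implicit contig.
    """
    records = list(SeqIO.parse(fasta_source, "fasta"))
    if not records:
        raise SequenceIOError(f"{genome_id}: empty FASTA")
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(records, start=1):
        pid = rec.id
        if pid in seen:
            raise SequenceIOError(f"{genome_id}: duplicate protein id {pid!r}")
        seen.add(pid)
        seq = _normalize_sequence(pid, str(rec.seq))
        if features is not None:
            if pid in features:
                contig, gene_index, strand, start, end = features[pid]
                out.append(ProteinRecord(pid, genome_id, seq, contig,
                                         gene_index, strand, start, end))
            else:
                warnings.warn(f"{genome_id}: no feature row for {pid}; "
                              f"gene context unknown")
                out.append(ProteinRecord(pid, genome_id, seq))
        else:
            out.append(ProteinRecord(pid, genome_id, seq, "contig_1", i))
    return out


def write_proteome(records: list[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


_FEATURE_COLUMNS = ["protein_id", "contig", "gene_index", "strand", "start", "end"]


def read_features(path, genome_id: str) -> dict[str, tuple]:
    """Gene coordinates from GFF3 (CDS rows) or a feature TSV.

    Returns ``protein_id -> (contig, gene_index, strand, start, end)``
    where gene_index is the 1-based rank of the CDS by start coordinate
    within its contig.  A TSV must carry the columns
    ``protein_id contig gene_index strand start end`` (gene_index may be
    ``.``, in which case it is recomputed from starts).
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        rows = _read_gff_cds(path)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        missing = [c for c in _FEATURE_COLUMNS if c not in df.columns and c != "gene_index"]
        if missing or not set(["protein_id", "contig", "strand", "start", "end"]).issubset(df.columns):
            raise SequenceIOError(
                f"{genome_id}: feature TSV requires columns {_FEATURE_COLUMNS}; "
                f"missing {missing}")
        rows = [(r.protein_id, r.contig, r.strand, int(r.start), int(r.end))
                for r in df.itertuples()]

    by_contig: dict[str, list] = {}
    for pid, contig, strand, start, end in rows:
        by_contig.setdefault(contig, []).append((start, pid, strand, end))
    out: dict[str, tuple] = {}
    for contig, items in by_contig.items():
        items.sort(key=lambda t: (t[0], t[1]))
        for rank, (start, pid, strand, end) in enumerate(items, start=1):
            out[pid] = (contig, rank, strand, start, end)
    return out


def _read_gff_cds(path: Path) -> list[tuple]:
    import gffutils
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for cds in db.features_of_type("CDS"):
        pid = (cds.attributes.get("ID") or cds.attributes.get("protein_id")
               or cds.attributes.get("locus_tag"))
        if not pid:
            raise SequenceIOError(f"{path}: CDS row without ID/protein_id/locus_tag")
        rows.append((pid[0], cds.seqid, cds.strand, cds.start, cds.end))
    return rows


def read_metadata(path) -> dict[str, GenomeRecord]:
    """Per-genome metadata TSV with columns genome_id, phylum..species,
    size_bp, gc_percent, oxygen_labels (|-separated), growth_temp_c, gram."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    out = {}
    for r in df.itertuples():
        taxonomy = tuple(getattr(r, rank, ".")
                         for rank in ("phylum", "class_", "order", "family",
                                      "genus", "species"))
        taxonomy = tuple("" if t == "." else t for t in taxonomy)
        out[r.genome_id] = GenomeRecord(
            genome_id=r.genome_id,
            taxonomy=taxonomy,
            size_bp=int(r.size_bp),
            gc_percent=float(r.gc_percent),
            oxygen_labels=tuple(x for x in str(r.oxygen_labels).split("|")
                                if x and x != "."),
            growth_temp_c=None if r.growth_temp_c == "." else float(r.growth_temp_c),
            gram=None if r.gram == "." else r.gram,
        )
    return out


def write_metadata(records: dict[str, GenomeRecord], path) -> None:
    rows = []
    for g in records.values():
        tax = list(g.taxonomy) + [""] * (6 - len(g.taxonomy))
        rows.append({
            "genome_id": g.genome_id,
            "phylum": tax[0] or ".", "class_": tax[1] or ".",
            "order": tax[2] or ".", "family": tax[3] or ".",
            "genus": tax[4] or ".", "species": tax[5] or ".",
            "size_bp": g.size_bp, "gc_percent": g.gc_percent,
            "oxygen_labels": "|".join(g.oxygen_labels) or ".",
            "growth_temp_c": "." if g.growth_temp_c is None else g.growth_temp_c,
            "gram": g.gram or ".",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_features(features: dict[str, tuple], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_FEATURE_COLUMNS) + "\n")
        for pid, (contig, gi, strand, start, end) in features.items():
            fh.write(f"{pid}\t{contig}\t{gi}\t{strand}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# annotation output tables
# ---------------------------------------------------------------------------

PROTEIN_TABLE_COLUMNS = [
    "genome_id", "protein_id", "family", "group", "fragment", "architecture",
    "polymerase_active", "php_active", "dnaq_active", "exo53_active",
    "clamp_motif", "recA_NT", "imuBC_domain", "accessory_role",
]
GENOME_TABLE_COLUMNS = [
    "genome_id", "replication_system", "exo53_status", "n_proofreaders_active",
    "count_A", "count_B", "count_C", "count_X", "count_Y", "n_complexes",
]
COMPLEX_TABLE_COLUMNS = [
    "genome_id", "complex_id", "members", "evidence_level", "variant", "notes",
]


def _flag(value) -> str:
    if value is None:
        return "."
    return "1" if value else "0"


def write_annotations(complements, out_dir, registry_version: str) -> dict[str, Path]:
    """Write the three output tables (per-protein, per-genome, complex calls)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": out / "proteins.tsv",
        "genomes": out / "genomes.tsv",
        "complexes": out / "complexes.tsv",
    }
    header = f"# registry: {registry_version}\n"

    with open(paths["proteins"], "w") as fh:
        fh.write(header)
        fh.write("\t".join(PROTEIN_TABLE_COLUMNS) + "\n")
        for comp in complements:
            for ann in comp.polymerases:
                fh.write("\t".join([
                    comp.genome_id, ann.protein_id, ann.family or ".",
                    ann.group or ".", _flag(ann.fragment),
                    "+".join(ann.architecture) or ".",
                    _flag(ann.polymerase_active), _flag(ann.php_active),
                    _flag(ann.dnaq_active), _flag(ann.exo53_active),
                    _flag(ann.clamp_motif), _flag(ann.recA_NT),
                    _flag(ann.imuBC_domain), ann.accessory_role or ".",
                ]) + "\n")

    with open(paths["genomes"], "w") as fh:
        fh.write(header)
        fh.write("\t".join(GENOME_TABLE_COLUMNS) + "\n")
        for comp in complements:
            n_active = sum(1 for p in comp.proofreaders if p.active)
            fh.write("\t".join([
                comp.genome_id, comp.replication_system.system,
                comp.exo53_status, str(n_active),
                *(str(comp.family_counts.get(f, 0)) for f in "ABCXY"),
                str(len(comp.complexes)),
            ]) + "\n")

    with open(paths["complexes"], "w") as fh:
        fh.write(header)
        fh.write("\t".join(COMPLEX_TABLE_COLUMNS) + "\n")
        for comp in complements:
            for call in comp.complexes:
                members = ",".join(f"{role}={pid}" for role, pid in call.members)
                fh.write("\t".join([
                    comp.genome_id, call.complex_id, members,
                    call.evidence_level, call.variant or ".", call.notes or ".",
                ]) + "\n")
    return paths


def read_protein_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)
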