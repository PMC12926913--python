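"""Synthetic proteome cohorts with fully known ground truth.

The generator emulates, at desk scale, the kind of genome collection the
annotation pipeline targets: each genome is a small proteome containing
polymerase genes of defined family/group sampled from the registry anchor
sequences, with exact-set active-site motifs independently intact or
disrupted, interaction motifs planted or removed, operon-like gene orders
for complex-type members, composition-preserving shuffled decoys, and a
metadata layer (taxonomy, genome size, oxygen/temperature labels) whose
association between an environment class and a chosen feature follows a
configurable odds ratio.

Motif columns are protected from background mutation, so motif status is
exactly controlled: the mutation-rate sweep probes detector sensitivity
(domain scanning, anchoring) separately from call correctness.  Everything
is a pure function of the supplied seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from zlib import crc32

import numpy as np
import pandas as pd

from . import _refs
from .registry import Registry
from .sequence_io import (GenomeRecord, ProteinRecord, write_features,
                          write_metadata, write_proteome)

DEFAULT_MUTATION_RATE = 0.05


class SimConfigError(ValueError):
    pass


@dataclass
class GenePlan:
    """One planted gene: a registry group/accessory (or the synthetic
    ``DnaQ-rogue`` negative control) with per-motif toggles."""
    group: str
    motif_toggles: dict = field(default_factory=dict)   # motif_id -> intact|broken
    recA_NT: bool | None = None                         # None = anchor default
    clamp: bool | None = None
    fragment: bool = False
    operon: str | None = None


@dataclass
class GenomePlan:
    genome_id: str
    genes: list
    decoys: int = 2
    expected_complexes: list = field(default_factory=list)
    size_bp: int = 4_000_000
    taxonomy: tuple = ("Planctomycetes", "Planctomycetia", "", "", "", "")
    oxygen_labels: tuple = ()
    growth_temp_c: float | None = None
    gram: str | None = None


@dataclass
class EnrichmentPlan:
    """Cohort-level association between an environment class and a planted
    feature, expressed as an odds ratio."""
    feature: str = "polY:solo"
    odds_ratio: float = 1.0
    variable: str = "oxygen"                 # oxygen | temperature
    baseline_prevalence: float = 0.3         # in the reference class
    class_balance: float = 0.5


@dataclass
class SimConfig:
    n_genomes: int = 20
    seed: int = 0
    mutation_rate: float = DEFAULT_MUTATION_RATE
    plans: list | None = None
    enrichment: EnrichmentPlan | None = None
    decoys_per_genome: int = 2
    emit_sequences: bool = True


@dataclass
class ProteinTruth:
    protein_id: str
    group: str
    family: str | None
    motif_statuses: dict                    # motif_id -> active/inactive/present/absent
    fragment: bool = False


@dataclass
class GenomeTruth:
    genome_id: str
    replication_system: str | None
    exo53_status: str
    n_active_proofreaders: int
    complex_types: tuple
    feature_flags: dict = field(default_factory=dict)
    env_class: str | None = None


@dataclass
class SimulatedGenome:
    genome_id: str
    records: list
    features: dict
    protein_truth: list
    genome_truth: GenomeTruth
    metadata: GenomeRecord


@dataclass
class Cohort:
    genomes: dict
    config: SimConfig

    @property
    def metadata(self) -> dict[str, GenomeRecord]:
        return {g.genome_id: g.metadata for g in self.genomes.values()}

    def truth_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        prot_rows, gen_rows = [], []
        for g in self.genomes.values():
            for t in g.protein_truth:
                prot_rows.append({
                    "genome_id": g.genome_id, "protein_id": t.protein_id,
                    "group": t.group, "family": t.family or ".",
                    "fragment": int(t.fragment),
                    "motifs": ";".join(f"{m}={s}" for m, s in
                                       sorted(t.motif_statuses.items())),
                })
            gt = g.genome_truth
            gen_rows.append({
                "genome_id": gt.genome_id,
                "replication_system": gt.replication_system or ".",
                "exo53_status": gt.exo53_status,
                "n_active_proofreaders": gt.n_active_proofreaders,
                "complex_types": ",".join(gt.complex_types) or ".",
                "env_class": gt.env_class or ".",
                **{f"feature_{k}": int(v) for k, v in gt.feature_flags.items()},
            })
        prot_cols = ["genome_id", "protein_id", "group", "family",
                     "fragment", "motifs"]
        gen_cols = ["genome_id", "replication_system", "exo53_status",
                    "n_active_proofreaders", "complex_types", "env_class"]
        return (pd.DataFrame(prot_rows, columns=prot_cols if not prot_rows else None),
                pd.DataFrame(gen_rows, columns=gen_cols if not gen_rows else None))


def _rng(seed: int, *tags) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2 ** 31)]
                                 + [crc32(str(t).encode()) for t in tags])


# ---------------------------------------------------------------------------
# single-gene emission
# ---------------------------------------------------------------------------

def _anchor_for(registry: Registry, group: str) -> "_refs.AnchorInfo":
    if registry.anchor_info is None:
        raise SimConfigError("simulation requires the default registry "
                             "(anchor layouts are not serialized)")
    if group in registry.groups:
        ref = registry.groups[group].anchor_refs[0]
    elif group in registry.accessories:
        ref = registry.accessories[group].anchor_refs[0]
    else:
        raise SimConfigError(f"unknown group or accessory in plan: {group!r}")
    return registry.anchor_info[ref]


def _rogue_dnaq(registry: Registry) -> tuple[str, dict]:
    """A standalone DEDDh exonuclease deliberately distant from every
    validated DnaQ reference: detected as a DnaQ candidate but rejected by
    the conservative subunit rule."""
    cons = dict(registry.alignments["DnaQ-exo"])["DnaQ-exo_cons"]
    mdef = registry.motifs["DEDDh"]
    protected = frozenset(c - 1 for c in mdef.columns)
    rng = _refs.rng_for("rogue-dnaq")
    seq = list(_refs.mutate(rng, cons, _refs.ROGUE_DIVERGENCE, protected))
    for col, res in zip(mdef.columns, mdef.canonical_residues()):
        seq[col - 1] = res
    positions = {mdef.motif_id: tuple(mdef.columns)}
    return "".join(seq), positions


def emit_gene(gene: GenePlan, registry: Registry, rng: np.random.Generator,
              mutation_rate: float) -> tuple[str, dict]:
    """Emit one planted gene sequence plus its motif truth statuses."""
    truth: dict[str, str] = {}

    if gene.group == "DnaQ-rogue":
        seq, _ = _rogue_dnaq(registry)
        truth["DEDDh"] = "active"
        return seq, truth

    info = _anchor_for(registry, gene.group)
    gdef = registry.groups.get(gene.group)
    seq = list(_refs.mutate(rng, info.sequence, mutation_rate,
                            info.protected_positions))

    sites = {s.motif_id: s for s in info.motif_sites}
    for site in info.motif_sites:
        truth[site.motif_id] = site.planted_status

    for motif_id, want in gene.motif_toggles.items():
        site = sites.get(motif_id)
        if site is None:
            raise SimConfigError(f"{gene.group} does not carry motif {motif_id}")
        if want not in ("intact", "broken"):
            raise SimConfigError(f"motif toggle must be intact/broken, got {want!r}")
        mdef = registry.motifs[motif_id]
        for pos, res in zip(site.positions, mdef.canonical_residues()):
            seq[pos - 1] = res
        if want == "broken":
            bpos, bres = _refs.MOTIF_BREAKS[motif_id]
            seq[site.positions[bpos - 1] - 1] = bres
        truth[motif_id] = "active" if want == "intact" else "inactive"

    # RecA-NT interaction motif
    recA_cons = dict(registry.alignments["RecA_NT"])["RecA_NT_cons"]
    if gene.recA_NT is True:
        if info.recA_nt_span is None:
            if gdef is None or gdef.motif_status("RecA_NT") is None:
                raise SimConfigError(f"{gene.group} cannot carry RecA_NT")
            seq += list(_refs.linker(gene.group, "simrec")) + list(recA_cons)
        truth["RecA_NT"] = "present"
    elif gene.recA_NT is False:
        if info.recA_nt_span is not None:
            lo, hi = info.recA_nt_span
            segment = seq[lo - 1:hi]
            seq[lo - 1:hi] = [segment[i] for i in rng.permutation(len(segment))]
        truth["RecA_NT"] = "absent"
    elif info.recA_nt_span is not None:
        truth["RecA_NT"] = "present"
    elif gdef is not None and gdef.motif_status("RecA_NT") is not None:
        truth["RecA_NT"] = "absent"

    # beta-clamp motif
    if gene.clamp is not None and (gdef is None or gdef.clamp_region is None):
        raise SimConfigError(f"{gene.group} has no clamp-motif region")
    if gdef is not None and gdef.clamp_region is not None:
        region = _clamp_region_span(gdef.clamp_region, info, len(seq))
        if gene.clamp is False:
            if info.clamp_span is not None:
                seq[info.clamp_span[1] - 1] = "A"   # QxxLF -> QxxLA
            seq = _scrub_region(seq, registry, region)
            truth["CLAMP"] = "absent"
        else:
            truth["CLAMP"] = "present" if info.clamp_span is not None else "absent"

    if gene.fragment:
        fam = gdef.family_id if gdef else None
        core = f"core_{fam}" if fam else None
        span = info.domain_spans.get(core) if core else None
        if span is None:
            raise SimConfigError(f"fragment toggle needs a polymerase core "
                                 f"({gene.group})")
        start = span[0] - 1
        seq = seq[start:start + 150]
        truth = {"fragment": "true"}

    return "".join(seq), truth


def _clamp_region_span(region: str, info, seq_len: int) -> tuple[int, int]:
    if region == "exo_loop":
        return info.domain_spans["DnaQ-exo"]
    return (max(1, seq_len - seq_len // 3), seq_len)


def _scrub_region(seq: list, registry: Registry, span: tuple[int, int]) -> list:
    pattern = tuple("" if p == "x" else p for p in registry.motifs["CLAMP"].pattern)
    lo, hi = span
    piece = "".join(seq[lo - 1:hi])
    piece = _refs.scrub_pattern(piece, pattern, frozenset())
    seq[lo - 1:hi] = list(piece)
    return seq


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def simulate_genome(plan: GenomePlan, registry: Registry, seed: int,
                    mutation_rate: float = DEFAULT_MUTATION_RATE,
                    ) -> SimulatedGenome:
    """Emit one genome: proteome records, gene features, and planted truth.

    Genes of one operon label receive adjacent gene indices; decoys
    (composition-preserving shuffles of random anchors) are interleaved
    between operon blocks.
    """
    rng = _rng(seed, "genome", plan.genome_id)

    # operon blocks stay contiguous, in first-appearance order
    blocks: list[list[GenePlan]] = []
    block_of: dict[str, list] = {}
    for gene in plan.genes:
        if gene.operon is not None:
            if gene.operon not in block_of:
                block_of[gene.operon] = []
                blocks.append(block_of[gene.operon])
            block_of[gene.operon].append(gene)
        else:
            blocks.append([gene])

    anchor_ids = sorted(registry.anchors)
    entries: list[tuple[str | None, GenePlan | None]] = []   # (decoy seq, gene)
    decoys_left = plan.decoys
    for block in blocks:
        for gene in block:
            entries.append((None, gene))
        if decoys_left > 0:
            src = registry.anchors[anchor_ids[rng.integers(len(anchor_ids))]]
            shuffled = "".join(np.array(list(src))[rng.permutation(len(src))])
            entries.append((shuffled, None))
            decoys_left -= 1
    for _ in range(decoys_left):
        src = registry.anchors[anchor_ids[rng.integers(len(anchor_ids))]]
        entries.append(("".join(np.array(list(src))[rng.permutation(len(src))]),
                        None))

    records, features, truths = [], {}, []
    pos_bp = 1
    for idx, (decoy_seq, gene) in enumerate(entries, start=1):
        pid = f"{plan.genome_id}_p{idx:03d}"
        if gene is not None:
            seq, motif_truth = emit_gene(gene, registry, rng, mutation_rate)
            fam = (registry.groups[gene.group].family_id
                   if gene.group in registry.groups else None)
            truths.append(ProteinTruth(
                protein_id=pid, group=gene.group, family=fam,
                motif_statuses=motif_truth,
                fragment=gene.fragment))
        else:
            seq = decoy_seq
            truths.append(ProteinTruth(protein_id=pid, group="decoy",
                                       family=None, motif_statuses={}))
        end = pos_bp + 3 * len(seq) - 1
        features[pid] = ("c1", idx, "+", pos_bp, end)
        pos_bp = end + 200
        records.append(ProteinRecord(pid, plan.genome_id, seq, "c1", idx,
                                     "+", features[pid][3], features[pid][4]))

    genome_truth = GenomeTruth(
        genome_id=plan.genome_id,
        replication_system=_planted_replication_system(plan, registry),
        exo53_status=_planted_exo53(plan),
        n_active_proofreaders=_planted_proofreaders(plan, registry),
        complex_types=tuple(plan.expected_complexes))

    metadata = GenomeRecord(
        genome_id=plan.genome_id, taxonomy=plan.taxonomy,
        size_bp=plan.size_bp, gc_percent=50.0,
        oxygen_labels=plan.oxygen_labels,
        growth_temp_c=plan.growth_temp_c, gram=plan.gram)

    return SimulatedGenome(plan.genome_id, records, features, truths,
                           genome_truth, metadata)


def _planted_replication_system(plan: GenomePlan, registry: Registry) -> str | None:
    groups = {g.group for g in plan.genes if not g.fragment}
    if "PolC" in groups and "DnaE3" in groups:
        return "PolC+DnaE3"
    if "PolC" in groups and "DnaE1" in groups:
        return "PolC+DnaE1"
    if "DnaE1" in groups or "DnaE3" in groups:
        return "DnaE1-only"
    return None


def _planted_exo53(plan: GenomePlan) -> str:
    for g in plan.genes:
        if g.group == "PolA1" and not g.fragment \
                and g.motif_toggles.get("FEN_AS", "intact") == "intact":
            return "PolA1"
    for g in plan.genes:
        if g.group == "soloFEN" and g.motif_toggles.get("FEN_AS", "intact") == "intact":
            return "solo"
    return "none"


def _planted_motif_status(registry: Registry, gene: GenePlan,
                          motif_id: str) -> str | None:
    info = _anchor_for(registry, gene.group)
    site = next((s for s in info.motif_sites if s.motif_id == motif_id), None)
    if site is None:
        return None
    toggle = gene.motif_toggles.get(motif_id)
    if toggle == "intact":
        return "active"
    if toggle == "broken":
        return "inactive"
    return site.planted_status


def _planted_proofreaders(plan: GenomePlan, registry: Registry) -> int:
    """Expected number of *active* proofreaders: intrinsic PHP/DnaQ of
    replicative C-family genes plus validated standalone DnaQ subunits."""
    count = 0
    for gene in plan.genes:
        if gene.fragment or gene.group == "DnaQ-rogue":
            continue
        if gene.group in ("PolC", "DnaE1", "DnaE3"):
            for motif_id in ("PHP_AS", "DEDDh"):
                if _planted_motif_status(registry, gene, motif_id) == "active":
                    count += 1
        elif gene.group.startswith("DnaQ-"):
            if _planted_motif_status(registry, gene, "DEDDh") == "active":
                count += 1
    return count


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

_PHYLA = ("Proteobacteria", "Firmicutes", "Actinobacteria", "Bacteroidetes",
          "Cyanobacteria")


def _default_plan(i: int, rng: np.random.Generator, feature_on: bool,
                  env_class: str | None, variable: str) -> GenomePlan:
    """A 'typical' genome: a replicative system cycling through the three
    types, Pol I, one Y-family member, RecA, and optional feature gene."""
    genes = [GenePlan("PolA1")]
    sys_kind = i % 3
    if sys_kind == 0:
        genes.append(GenePlan("DnaE1"))
    elif sys_kind == 1:
        genes += [GenePlan("PolC"), GenePlan("DnaE1")]
    else:
        genes += [GenePlan("PolC"), GenePlan("DnaE3")]
    genes.append(GenePlan("PolY-core", recA_NT=bool(i % 2)))
    genes.append(GenePlan("RecA"))
    size = int(rng.normal(4.0e6, 0.9e6))
    size = max(600_000, size)
    # larger genomes carry extra Y-family members
    extra = int(rng.poisson(max(0.0, (size - 2.5e6) / 2.0e6)))
    for k in range(min(extra, 3)):
        genes.append(GenePlan("UmuC" if k % 2 else "PolY-core",
                              recA_NT=False if k % 2 == 0 else None))
    if feature_on:
        genes.append(GenePlan("DinP"))   # solo PolY: no RecA-NT, no partner

    oxygen = ()
    temp = None
    if variable == "oxygen" and env_class:
        oxygen = (env_class,)
        temp = float(rng.normal(32, 4))
    elif variable == "temperature" and env_class:
        temp = float(rng.normal(52, 3)) if env_class == "thermophile-incl-hyper" \
            else float(rng.normal(32, 4))
        oxygen = ("aerobe",)
    phylum = _PHYLA[i % len(_PHYLA)]
    return GenomePlan(
        genome_id=f"g{i:04d}", genes=genes, size_bp=size,
        taxonomy=(phylum, "", "", "", "", f"species_{i}"),
        oxygen_labels=oxygen, growth_temp_c=temp,
        gram=("positive" if i % 2 else "negative"))


def plan_enrichment_flags(n: int, plan: EnrichmentPlan, rng: np.random.Generator,
                          ) -> tuple[list[str], list[bool], float]:
    """Assign environment classes and feature flags realizing the plan's
    odds ratio.  Raises when the requested OR is infeasible for the class
    sizes (expected positives outside [1, n_class - 1])."""
    if not (0.0 < plan.baseline_prevalence < 1.0):
        raise SimConfigError("baseline_prevalence must be in (0, 1)")
    n1 = int(round(n * plan.class_balance))
    n2 = n - n1
    odds0 = plan.baseline_prevalence / (1 - plan.baseline_prevalence)
    odds1 = plan.odds_ratio * odds0
    p1 = odds1 / (1 + odds1)
    p0 = plan.baseline_prevalence
    for n_c, p_c in ((n1, p1), (n2, p0)):
        if n_c > 0 and not (1.0 <= n_c * p_c <= n_c - 1.0):
            p_max = (n1 - 1.0) / n1 if n1 > 1 else 0.5
            max_or = (p_max / (1 - p_max)) / odds0
            raise SimConfigError(
                f"odds ratio {plan.odds_ratio} infeasible for class sizes "
                f"({n1}/{n2}); maximal feasible OR ~ {max_or:.2f}")
    if plan.variable == "oxygen":
        class_labels = ("aerobe", "anaerobe")
    else:
        class_labels = ("thermophile-incl-hyper", "mesophile-incl-psychro")
    classes = [class_labels[0]] * n1 + [class_labels[1]] * n2
    perm = rng.permutation(n)
    classes = [classes[perm[i]] for i in range(n)]
    flags = [bool(rng.random() < (p1 if cls == class_labels[0] else p0))
             for cls in classes]
    return classes, flags, p1


def simulate_cohort(config: SimConfig, registry: Registry | None = None,
                    out_dir=None) -> Cohort:
    """Simulate a genome cohort; optionally write it as a directory of
    per-genome FASTA + feature TSVs, a metadata table, and truth tables."""
    from .registry import load_registry
    if registry is None:
        registry = load_registry()
    rng = _rng(config.seed, "cohort")

    plans = config.plans
    env_classes: list[str | None]
    flags: list[bool]
    if plans is None:
        n = config.n_genomes
        if config.enrichment is not None:
            env_classes, flags, _ = plan_enrichment_flags(n, config.enrichment, rng)
            variable = config.enrichment.variable
        else:
            env_classes, flags, variable = [None] * n, [False] * n, "oxygen"
        plans = [_default_plan(i, rng, flags[i], env_classes[i], variable)
                 for i in range(n)]
    else:
        env_classes = [None] * len(plans)
        flags = [False] * len(plans)

    genomes: dict[str, SimulatedGenome] = {}
    for i, plan in enumerate(plans):
        if config.emit_sequences:
            sim = simulate_genome(plan, registry, config.seed,
                                  mutation_rate=config.mutation_rate)
        else:
            sim = SimulatedGenome(
                plan.genome_id, records=[], features={}, protein_truth=[],
                genome_truth=GenomeTruth(
                    plan.genome_id,
                    _planted_replication_system(plan, registry),
                    _planted_exo53(plan), 0, tuple(plan.expected_complexes)),
                metadata=GenomeRecord(
                    genome_id=plan.genome_id, taxonomy=plan.taxonomy,
                    size_bp=plan.size_bp, gc_percent=50.0,
                    oxygen_labels=plan.oxygen_labels,
                    growth_temp_c=plan.growth_temp_c, gram=plan.gram))
        sim.genome_truth.env_class = env_classes[i]
        if config.enrichment is not None:
            sim.genome_truth.feature_flags[config.enrichment.feature] = flags[i]
        genomes[plan.genome_id] = sim

    cohort = Cohort(genomes=genomes, config=config)
    if out_dir is not None:
        _write_cohort(cohort, out_dir)
    return cohort


def _write_cohort(cohort: Cohort, out_dir) -> None:
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    for g in cohort.genomes.values():
        if g.records:
            write_proteome(g.records, out / f"{g.genome_id}.faa")
            write_features(g.features, out / f"{g.genome_id}.features.tsv")
    write_metadata(cohort.metadata, out / "meta.tsv")
    prot, gen = cohort.truth_frames()
    prot.to_csv(out / "truth" / "proteins.tsv", sep="\t", index=False)
    gen.to_csv(out / "truth" / "genomes.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# showcase plans used by tests and the verification script
# ---------------------------------------------------------------------------

def complex_showcase_plans() -> list[GenomePlan]:
    """Twelve genomes: one per mutasome complex type (11) plus a solo-PolY
    genome expected to yield no complex call."""
    def gp(gid, genes, expected):
        return GenomePlan(genome_id=gid, genes=genes, decoys=1,
                          expected_complexes=expected)

    plans = [
        gp("cx01", [GenePlan("DnaE1"),
                    GenePlan("DnaE2A", operon="op"),
                    GenePlan("ImuB1", operon="op"),
                    GenePlan("ImuA", operon="op")],
           ["ImuA-ImuB-DnaE2"]),
        gp("cx02", [GenePlan("DnaE1"),
                    GenePlan("UmuC", operon="op"),
                    GenePlan("UmuD", operon="op"),
                    GenePlan("RecA", operon="op")],
           ["UmuC-UmuD2-RecA"]),
        gp("cx03", [GenePlan("DnaE1"),
                    GenePlan("YqjW", operon="op"),
                    GenePlan("YqjX", operon="op"),
                    GenePlan("RecA", operon="op")],
           ["YqjW-YqjX-RecA"]),
        gp("cx04", [GenePlan("DnaE1"),
                    GenePlan("DnaE2X", operon="op"),
                    GenePlan("gbDinB2-like", operon="op"),
                    GenePlan("ImuB-C-solo", operon="op"),
                    GenePlan("RecA")],
           ["DnaE2X-iPolY-ImuBC-RecA"]),
        gp("cx05", [GenePlan("DnaE1"),
                    GenePlan("DnaE2B", operon="op"),
                    GenePlan("PolY-core", recA_NT=True, operon="op"),
                    GenePlan("ImuB-C-solo", operon="op"),
                    GenePlan("RecA")],
           ["DnaE2B-PolY-ImuBC-RecA"]),
        gp("cx06", [GenePlan("DnaE1"),
                    GenePlan("DnaE2B", operon="op"),
                    GenePlan("scDinB2-like", operon="op"),
                    GenePlan("RecA")],
           ["DnaE2B-iPolY-RecA"]),
        gp("cx07", [GenePlan("DnaE1"),
                    GenePlan("DnaE2B", operon="op"),
                    GenePlan("PolY-core", recA_NT=True, operon="op"),
                    GenePlan("RecA")],
           ["DnaE2B-PolY-RecA"]),
        gp("cx08", [GenePlan("DnaE1"),
                    GenePlan("DnaE2B", operon="op"),
                    GenePlan("ImuB-C-solo", operon="op")],
           ["DnaE2B-ImuBC"]),
        gp("cx09", [GenePlan("DnaE1"),
                    GenePlan("UmuC", operon="op"),
                    GenePlan("SRAP", operon="op")],
           ["UmuC-SRAP"]),
        gp("cx10", [GenePlan("DnaE1"),
                    GenePlan("PolY-core", recA_NT=True, operon="op"),
                    GenePlan("ImuB-C-solo", operon="op")],
           ["PolY-ImuBC"]),
        gp("cx11", [GenePlan("DnaE1"),
                    GenePlan("PolY-core", recA_NT=True),
                    GenePlan("RecA")],
           ["PolY-RecA"]),
        gp("cx12_solo", [GenePlan("DnaE1"),
                         GenePlan("DinP"),
                         GenePlan("RecA")],
           []),
    ]
    return plans
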