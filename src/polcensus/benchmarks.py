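"""Verification experiments exercising the pipeline end to end.

Each routine builds its own inputs (synthetic cohorts with planted truth,
exhaustive rule grids, enumeration oracles), runs the relevant pipeline
stage from scratch, and measures agreement with the planted or enumerated
truth.  They are used both by the test suite and by the repository's
acceptance script.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from . import complement_annotator as ca
from . import complex_typer as ct
from . import homology, stats_summary, synthetic_data as sd
from .registry import Registry


# ---------------------------------------------------------------------------
# motif-calling rule fidelity
# ---------------------------------------------------------------------------

_MOTIF_TEMPLATES = (
    ("DnaE1", "PHP_AS"),
    ("PolC", "PHP_AS"),
    ("PolC", "DEDDh"),
    ("PolA1", "DEDDy"),
    ("PolA1", "FEN_AS"),
)


def motif_fidelity(registry: Registry, profiles, mutation_rate: float,
                   seed: int, n_genes: int = 200) -> tuple[int, int]:
    """Plant `n_genes` domains with independently toggled PHP / DEDDh /
    DEDDy / FEN active sites, annotate, and count correct active/inactive
    calls for the toggled motif.  Returns (n_correct, n_total)."""
    rng = np.random.default_rng([seed % (2 ** 31), 2])
    genes_per_genome = 10
    plans = []
    truth = {}   # (genome_id, plan position) -> (motif, status)
    gene_idx = 0
    while gene_idx < n_genes:
        gid = f"mf{len(plans):03d}"
        genes = []
        for _ in range(min(genes_per_genome, n_genes - gene_idx)):
            group, motif = _MOTIF_TEMPLATES[gene_idx % len(_MOTIF_TEMPLATES)]
            toggle = "intact" if rng.random() < 0.5 else "broken"
            genes.append(sd.GenePlan(group, motif_toggles={motif: toggle}))
            truth[(gid, len(genes) - 1)] = (motif,
                                            "active" if toggle == "intact"
                                            else "inactive")
            gene_idx += 1
        if not any(g.group in ("DnaE1", "PolC") for g in genes):
            genes.insert(0, sd.GenePlan("DnaE1"))
        plans.append(sd.GenomePlan(gid, genes, decoys=1))

    n_total = n_correct = 0
    for plan in plans:
        sim = sd.simulate_genome(plan, registry, seed=seed,
                                 mutation_rate=mutation_rate)
        comp = ca.annotate_genome(sim.records, registry, profiles=profiles)
        by_pid = {a.protein_id: a for a in comp.polymerases}
        planted = [t for t in sim.protein_truth if t.group != "decoy"]
        for pos, t in enumerate(planted):
            key = (plan.genome_id, pos)
            if key not in truth:
                continue
            motif, want = truth[key]
            call = by_pid[t.protein_id].motif_calls.get(motif)
            n_total += 1
            n_correct += (call is not None and call.status == want)
    return n_correct, n_total


# ---------------------------------------------------------------------------
# replication-system truth table
# ---------------------------------------------------------------------------

def replication_truth_table() -> tuple[int, int]:
    """All 16 presence/absence combinations of {PolC, DnaE1, DnaE3, DnaE2}
    against the three-system rule (DnaE2 never replicative; error without
    a DnaE-type subunit).  Returns (n_correct_rows, 16)."""
    correct = 0
    for polc, e1, e3, e2 in itertools.product([0, 1], repeat=4):
        anns = []
        if polc:
            anns.append(ca.PolymeraseAnnotation("pc", "C", "PolC"))
        if e1:
            anns.append(ca.PolymeraseAnnotation("e1", "C", "DnaE1"))
        if e3:
            anns.append(ca.PolymeraseAnnotation("e3", "C", "DnaE3"))
        if e2:
            anns.append(ca.PolymeraseAnnotation("e2", "C", "DnaE2A"))
        if not (e1 or e3):
            expected = None
        elif polc and e3:
            expected = "PolC+DnaE3"
        elif polc and e1:
            expected = "PolC+DnaE1"
        else:
            expected = "DnaE1-only"
        try:
            got = ca.classify_replication_system(anns).system
        except ca.AnnotationError:
            got = None
        correct += (got == expected)
    return correct, 16


# ---------------------------------------------------------------------------
# proofreader archetypes
# ---------------------------------------------------------------------------

def proofreader_archetypes(registry: Registry, profiles,
                           seed: int) -> tuple[int, int]:
    """Active-proofreader counts of the two archetypal genomes:
    a Clostridia-like PolC+DnaE1 genome and a Bacilli-like PolC+DnaE3
    genome with an inactivated PolC PHP."""
    clost = sd.GenomePlan("clost", [sd.GenePlan("PolC"), sd.GenePlan("DnaE1")],
                          decoys=1)
    bacil = sd.GenomePlan("bacil", [
        sd.GenePlan("PolC", motif_toggles={"PHP_AS": "broken"}),
        sd.GenePlan("DnaE3")], decoys=1)
    counts = []
    for plan in (clost, bacil):
        sim = sd.simulate_genome(plan, registry, seed=seed, mutation_rate=0.0)
        comp = ca.annotate_genome(sim.records, registry, profiles=profiles)
        counts.append(sum(p.active for p in comp.proofreaders))
    return counts[0], counts[1]


# ---------------------------------------------------------------------------
# complex typing
# ---------------------------------------------------------------------------

@dataclass
class ComplexRecovery:
    n_correct: int          # genomes whose call set equals the planted set
    n_genomes: int          # 12 (11 single-type + 1 solo PolY)
    n_types_recovered: int  # of the 11 single-type genomes
    solo_calls: int         # calls on the solo-PolY genome (expected 0)


def complex_recovery(registry: Registry, profiles, seed: int) -> ComplexRecovery:
    n_correct = n_types = 0
    solo_calls = 0
    plans = sd.complex_showcase_plans()
    for plan in plans:
        sim = sd.simulate_genome(plan, registry, seed=seed, mutation_rate=0.0)
        comp = ca.annotate_genome(sim.records, registry, profiles=profiles)
        got = sorted(c.complex_id for c in comp.complexes)
        if got == sorted(plan.expected_complexes):
            n_correct += 1
            if plan.expected_complexes:
                n_types += 1
        if not plan.expected_complexes:
            solo_calls += len(comp.complexes)
    return ComplexRecovery(n_correct, len(plans), n_types, solo_calls)


_MODEL_FILTER_CASES = (
    # (source, ipTM, global, clash) -> expected pass
    (("multimer-v2", 0.80, 0.45, False), True),
    (("multimer-v2", 0.65, None, False), True),
    (("multimer-v2", 0.649, None, False), False),
    (("v3", 0.70, None, False), True),
    (("v3", 0.68, None, False), False),
    (("multimer-v2", 0.80, 0.41, False), True),
    (("multimer-v2", 0.80, 0.40, False), False),
    (("multimer-v2", 0.80, 0.35, False), False),
    (("multimer-v2", 0.80, 0.45, True), False),
)


def model_filter_boundaries() -> tuple[int, int]:
    """Pass/fail agreement of the structure-model score filter at the
    ipTM 0.65 / 0.70 and global-score 0.4 boundaries."""
    correct = 0
    for (source, iptm, glob, clash), expected in _MODEL_FILTER_CASES:
        score = ct.ModelScore("k", source, 0.8, iptm, glob, clash)
        ok, _ = ct.model_score_passes(score)
        correct += (ok is expected)
    return correct, len(_MODEL_FILTER_CASES)


# ---------------------------------------------------------------------------
# Fisher's exact test vs enumeration oracle
# ---------------------------------------------------------------------------

def fisher_oracle_sweep(n_max: int = 40) -> tuple[float, int]:
    """Compare the exact two-sided p against a brute-force enumeration
    oracle for every 2x2 table with total N <= n_max.  The oracle
    enumerates all tables with the observed margins, computes exact
    integer hypergeometric weights, and sums those no likelier than the
    observed table.  Returns (max |delta p|, n_tables)."""
    max_dp = 0.0
    n_tables = 0
    for n in range(1, n_max + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    p = stats_summary.fisher_exact_two_sided(a, b, c, d)
                    # oracle: integer weights over the margin-fixed family
                    r1, r2, c1 = a + b, c + d, a + c
                    denom = math.comb(n, c1)
                    w_obs = math.comb(r1, a) * math.comb(r2, c)
                    acc = 0
                    for aa in range(min(r1, c1) + 1):
                        cc = c1 - aa
                        if cc > r2:
                            continue
                        w = math.comb(r1, aa) * math.comb(r2, cc)
                        if w <= w_obs:
                            acc += w
                    p_oracle = acc / denom
                    max_dp = max(max_dp, abs(p - p_oracle))
                    n_tables += 1
    return max_dp, n_tables


# ---------------------------------------------------------------------------
# enrichment parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRecovery:
    coverage: float          # fraction of replicates whose 95% CI covers the OR
    n_coverage_reps: int
    type1_rate: float        # rejection rate at alpha=0.05 under OR=1
    n_null_reps: int


def enrichment_recovery(seed: int, n_coverage_reps: int = 100,
                        n_null_reps: int = 500, n_genomes: int = 400,
                        odds_ratio: float = 4.0) -> EnrichmentRecovery:
    """Simulate cohorts with a planted enrichment odds ratio and measure
    (i) 95%-CI coverage of the planted OR over replicates and (ii) the
    type-I error of the two-sided test at alpha = 0.05 under the null."""
    def one(rep_seed: int, or_value: float):
        cfg = sd.SimConfig(
            n_genomes=n_genomes, seed=rep_seed, emit_sequences=False,
            enrichment=sd.EnrichmentPlan(feature="polY:solo",
                                         odds_ratio=or_value))
        cohort = sd.simulate_cohort(cfg)
        flags = {g.genome_id: g.genome_truth.feature_flags["polY:solo"]
                 for g in cohort.genomes.values()}
        classes = {g.genome_id: g.genome_truth.env_class
                   for g in cohort.genomes.values()}
        return stats_summary.fisher_enrichment(flags, classes)

    base = seed % (2 ** 20)
    covered = 0
    for rep in range(n_coverage_reps):
        res = one(base + 7919 * rep + 1, odds_ratio)
        lo, hi = res.ci95
        covered += (lo <= odds_ratio <= hi)
    rejected = 0
    for rep in range(n_null_reps):
        res = one(base + 104729 + 7919 * rep, 1.0)
        rejected += (res.p_two_sided < 0.05)
    return EnrichmentRecovery(covered / n_coverage_reps, n_coverage_reps,
                              rejected / n_null_reps, n_null_reps)
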