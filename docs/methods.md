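# Methods

This note documents the models and procedures implemented in
`polcensus`, the parameters that matter, the synthetic data the tests
run on, and the design choices made where the design was genuinely open.

## The annotation model

A bacterial proteome is annotated in five stages.

**1. Domain scanning.** Each reference alignment in the registry is
compiled to a position-specific score matrix (PSSM): per-column log₂
odds of the (Henikoff position-weighted) residue frequency over the
Robinson–Robinson background, with a background-proportional pseudocount
(admixture 0.5, renormalized). Columns with more than 50% gaps are
dropped as non-match columns. Proteins are scanned by affine-gap
Smith–Waterman (gap open 11, extend 1 on the half-bit scale — the
classic protein defaults; scores are reported in bits). Every hit is
normalized by the profile's consensus self-score, so `norm_score` is
dimensionless in (0, 1]; the reliability gate is `tau = 0.3` (the
stand-in for a search-probability cutoff in a database-scale workflow).
Polymerase-core hits on proteins shorter than 200 residues are kept but
flagged `fragment` and excluded from all censuses. On
composition-preserving shuffled sequences the false-positive rate of the
scan at `tau = 0.3` is below 1% (measured over 1000 shuffles in the test
suite), so decoys essentially never enter the roster.

**2. Family and group assignment.** The family is that of the best
non-fragment polymerase-core hit (`core_A` … `core_Y`). Within a family,
groups are assigned by a similarity graph over the query proteins and the
registry anchor sequences: pairwise global alignments (BLOSUM62, 11/1),
similarity = score normalized by the self-score of the shorter sequence,
edges at ≥ 0.45. A connected component containing anchors of exactly one
group adopts that group; mixed components fall back to per-protein
nearest-anchor assignment; anchor-free components are
`unassigned-novel`. DnaE1 vs DnaE3 — the least separated replicative
groups — get a tie-break when the anchor margin is under 0.05: an active
PHP site votes DnaE1, an inactive one DnaE3 (the two signatures contrast
sharply between the PolC+DnaE1 and PolC+DnaE3 clades); still-ambiguous
proteins are flagged.

**3. Motif calling.** Exact-set active-site motifs (PHP
`HHDHEH[C/H]DH`; DnaQ `DEDDh`/`DEDDy` — same anchor columns, different
final residue; FEN `D[D/E]EDD`; the per-family catalytic carboxylates,
`D-D-E` for Klenow-fold families and a `D-D-D` triad for Polβ-fold
families) are read off alignment-anchored columns. The call is *active*
only if every position carries an allowed residue; any deviation,
including a deletion or an `X`, is *inactive* (a `--x-as-undetermined`
flag relaxes the X rule); proteins whose alignment does not cover all
motif columns are *undetermined* — only sequences that align over the
motif are judged. Anchoring prefers the protein's own group (or
accessory) reference alignment over the family-generic domain profile:
the owner profile is much sharper, so a single disrupted position stays
a diagonal mismatch instead of being gapped around, which matters
precisely for the inactive sites the pipeline is supposed to detect.
Interaction motifs are handled two ways: the β-clamp motif `QxxLF` is an
exact pattern searched only within the group-designated region (the
vestigial exonuclease loop for PolA2, the C-terminal third for
clamp-bearing PolYs and PolBs), while RecA-NT is profile-scored against
a packaged 25-column sub-alignment with a present/absent threshold of
0.5 on the normalized score. Group-level RecA-NT prevalence is
summarized as most/partial/none at fractions 0.9/0.1.

**4. Per-genome integration.** Replication system: PolC + DnaE3 →
`PolC+DnaE3`; else PolC + DnaE1 → `PolC+DnaE1`; else any DnaE1/DnaE3 →
`DnaE1-only`; DnaE2 never counts as replicative, and a complement with
no DnaE-type subunit is a hard error (every bacterial genome carries
one). The proofreader census lists intrinsic PHP and DnaQ domains of the
replicative C-family proteins with their active-site status; standalone
DnaQ-like proteins are admitted as DnaQ subunits only if their
normalized similarity to a validated reference (Pol III ε-type,
noncanonical mycobacterial, or *Treponema*-type) reaches 0.5, or a
user-supplied structure-model score passes the confidence filter —
everything else is rejected, because standalone DEDDh exonucleases are
plentiful and mostly unrelated to replication. DnaE2's PHP status is
reported but never counted as a replicative proofreader. The 5′–3′
exonuclease status is `PolA1` (Pol I with an active FEN domain), `solo`
(standalone active FEN homolog), or `none`.

**5. Complex typing.** The registry's decision table defines 11 mutasome
types over component roles (a DnaE2 group, a PolY/iPolY with constraints
on RecA-NT and polymerase activity, and accessory partners: RecA, ImuA,
UmuD, three YqjX-like small-subunit variants, SRAP, standalone ImuB-C).
Matching proceeds in priority order, most specific first; the
presumed-ancestral PolY–RecA dimer is the lowest-priority fallback, so
every RecA-NT-bearing PolY in a RecA-positive genome ends up in at least
one call and a PolY without the motif and without a typed partner (solo
PolY) ends up in none. Core members (the DnaE2 and the PolY of a call)
are consumed once matched; accessories are reusable across calls, which
is how one genome hosts, e.g., Pol V alongside ImuA–ImuB–DnaE2. RecA
presence is detected by profile scan, not assumed (`--assume-recA`
restores permissive matching). Evidence is `colocalized` when all
members sit on one contig within a 5-gene-index window (neighborhoods
are computed on gene order, not base pairs), otherwise `co-occurrence`;
colocalization upgrades evidence but is not required for a call
(`--require-colocalization` makes it mandatory for the DnaE2B/X partner
types). Optional model-score tables veto calls below the established
confidence thresholds: ipTM ≥ 0.65 (Multimer-class source) or ≥ 0.70
(v3-class source), complementary global score > 0.4 when present, and no
clash flag.

## Statistics

Oxygen labels are mapped to aerobe (anything that can use oxygen,
facultative anaerobes included) or anaerobe, then majority-voted with
equal source weighting; a tie means missing. Growth temperature is
categorized psychrophile (< 20 °C), mesophile [20, 45), thermophile
[45, 60), hyperthermophile (≥ 60); the interval boundaries are half-open
with the upper rule fixed by the ≥ 60 °C definition, and the binary
split for testing merges psychrophiles with mesophiles and
hyperthermophiles with thermophiles. Multiple temperature sources are
consulted in a fixed priority order, first available wins.

Enrichment uses the two-sided Fisher exact test. The p-value is computed
by integer enumeration of the hypergeometric support (all tables with
the observed margins share the denominator C(N, c₁), so tables are
compared and summed by exact integer weights); this is reproducible to
machine precision and is checked in the tests against an independently
written enumeration oracle (exhaustively for all tables with N ≤ 40)
and against an independent library implementation. The odds ratio is the
sample cross-product ad/bc; the 95% CI is the Woolf (log-OR normal)
interval, with the Haldane–Anscombe 0.5 correction applied only when a
zero cell exists. No multiple-testing correction is applied by default
(per-test two-sided p-values are reported); a Benjamini–Hochberg helper
is available. Count-vs-genome-size association is reported as Spearman
rank correlation (primary) and Pearson (secondary), overall and per
family; zero-variance inputs are reported as undefined rather than
guessed. The per-taxon summary is the percentage of genomes in a taxon
carrying at least one instance of each feature (families, groups,
active motifs, complex types, replication systems).

## The synthetic reference library and data generator

The registry's ontology tables are curated; its reference *sequences*
are synthetic, generated from the fixed seed 20260926. Each domain gets
a background-sampled consensus with the canonical motif residues planted
at the declared columns, plus five 8%-diverged rows forming its
reference alignment. Each group's anchor is a concatenation of
30%-diverged group-specific domain variants (motif columns overwritten
per the group's expectation — intact, or disrupted by one canonical
substitution such as E→Q in the PHP site), linkers, and, where expected,
the RecA-NT segment and a planted clamp motif; two 5%-diverged sibling
anchors complete each group's anchor set. These rates were chosen so
that within-group similarity (≈ 0.92) sits far above the clustering edge
threshold while between-group similarity (≈ 0.38–0.40) sits below it,
and every 30%-diverged variant still scores ≥ 0.5 against its domain
profile. Accidental `QxxLF` occurrences are scrubbed from clamp-bearing
anchors so the clamp call is exactly controlled.

The cohort generator emits genomes by mutating group anchors at a
configurable per-residue rate *outside* motif columns (motif status is
therefore exactly controlled; the mutation-rate sweep probes detector
sensitivity separately from call correctness), applying per-motif
intact/broken toggles, inserting or scrambling interaction-motif
segments, truncating fragments to 150 residues of the core, placing
operon members at adjacent gene indices, and interleaving
composition-preserving shuffled decoys (harder negatives than i.i.d.
residues). Metadata links an environment class to a feature through a
configurable odds ratio: class assignment is a balanced permutation and
feature presence is Bernoulli with class-specific probabilities derived
from the baseline prevalence (0.3 in the reference class) and the target
OR; a requested OR whose expected positive count leaves [1, n−1] in
either class is rejected with the maximal feasible OR in the message.
Everything is a pure function of the supplied seed; two runs are
byte-identical.

What the generator does *not* emulate: phylogenetic correlation among
genomes, indel evolution, domain shuffling, compositional biases, or
genuinely novel groups. Passing tests therefore demonstrate that the
annotation *rules* are implemented faithfully and are robust to point
divergence up to ~10%, not that the profiles would recover remote
homologs in real proteomes; on real data the scanner's sensitivity is
bounded by the desk-scale profile construction, and externally computed
hit tables can be injected to bypass it.

## Verification scale

The verification experiments run at desk scale on one CPU: 200 planted
domains per mutation rate for motif fidelity; the exhaustive 16-row
replication-system grid; 12 showcase genomes for complex typing; all
135,750 2×2 tables with N ≤ 40 for the Fisher oracle; 100 replicates of
n = 400 cohorts for CI coverage and 500 for the null rejection rate
(metadata-level simulation — the feature flags and classes are the
planted truth that sequence-level annotation reproduces exactly at zero
mutation). Genome-scale headline distributions (family prevalences
across thousands of genomes) are outside this package's verification
scope, because they are properties of a specific genome collection
rather than of the method.

## Known limitations

* Group assignment quality is bounded by the anchor sets; a real
  deployment would extend `groups.tsv`/`refs/` with curated anchors.
* The DnaQ-subunit homology gate (0.5) and the RecA-NT threshold (0.5)
  are package defaults chosen on the synthetic library, configurable but
  not calibrated against experimental data.
* The complex typer treats accessory subunits as reusable across calls
  and core members as consumed; genomes with unusual paralog expansions
  may warrant manual review of the call list.
* Phylogenetically corrected enrichment (tree-aware contrasts) is out of
  scope; the Fisher tests treat genomes as independent.
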