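"""Deterministic construction of the synthetic reference library.

The packaged ontology (families, groups, motifs, domain architectures,
complex types) encodes the published classification of bacterial DNA
polymerases.  The *sequences* behind it — per-domain reference alignments
and per-group anchor sequences — are synthetic: they are generated here
from a fixed seed, with the field's canonical active-site and interaction
motifs planted at declared alignment columns.  Group anchors within a
family share a common domain consensus but diverge from it far enough
that groups are separable by similarity, while remaining detectable by
the domain profiles.

Everything is a pure function of ``REGISTRY_SEED`` and the ontology
tables, so two builds of the default registry are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from zlib import crc32

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

# Robinson-Robinson amino-acid background frequencies, in AA order.
_RR = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}
BACKGROUND = np.array([_RR[a] for a in AA])
BACKGROUND = BACKGROUND / BACKGROUND.sum()

REGISTRY_SEED = 20260926

# Construction constants (documented in docs/methods.md).
N_ALIGNMENT_VARIANTS = 5      # rows added to each reference alignment
ALIGNMENT_VARIANT_RATE = 0.08  # divergence of alignment rows from consensus
GROUP_DIVERGENCE = 0.30        # divergence of a group's domain variant
ROGUE_DIVERGENCE = 0.45        # divergence of the "rogue DnaQ" construct
ANCHOR_SIBLING_RATE = 0.05     # divergence of anchors r2/r3 from r1
MOTIF_SEGMENT_RATE = 0.08      # divergence of per-group RecA-NT segments
RECA_NT_LENGTH = 25
LINKER_LENGTH = 5

CLAMP_EXO_LOOP = "QSSLF"       # planted in the vestigial exonuclease loop
CLAMP_CTERM = "QADLF"          # planted near the C-terminus
# 1-based columns of the DnaQ-exo alignment overwritten by the exo-loop clamp
CLAMP_EXO_COLUMNS = (30, 31, 32, 33, 34)

# Position (1-based within the motif) substituted to disrupt an active site,
# and the residue substituted in.  Any deviation from the allowed sets makes
# a site "inactive", so one canonical break per motif suffices.
MOTIF_BREAKS = {
    "PHP_AS": (5, "Q"),     # E -> Q
    "DEDDh": (2, "Q"),
    "DEDDy": (2, "Q"),
    "FEN_AS": (3, "Q"),
    "POL_AS_A": (2, "N"),   # D -> N
    "POL_AS_B": (2, "N"),
    "POL_AS_C": (2, "N"),
    "POL_AS_X": (2, "N"),
    "POL_AS_Y": (2, "N"),
}


def rng_for(*tags) -> np.random.Generator:
    """A Generator seeded stably from the registry seed and string tags."""
    return np.random.default_rng([REGISTRY_SEED] + [crc32(str(t).encode()) for t in tags])


def sample_sequence(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(20, size=length, p=BACKGROUND)
    return "".join(AA[i] for i in idx)


def mutate(rng: np.random.Generator, seq: str, rate: float,
           protected: frozenset[int] | set[int] = frozenset()) -> str:
    """Substitute residues at `rate` per position, skipping `protected`
    (0-based positions).  Replacement is drawn from the background and is
    always different from the original residue."""
    out = list(seq)
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        if i in protected:
            continue
        old = out[i]
        new = old
        while new == old:
            new = AA[rng.choice(20, p=BACKGROUND)]
        out[i] = new
    return "".join(out)


def scrub_pattern(seq: str, pattern_sets, protected: frozenset[int],
                  replacement: str = "G") -> str:
    """Destroy accidental occurrences of an exact-set pattern (e.g. QxxLF)
    outside protected spans by rewriting the last constrained position."""
    out = list(seq)
    plen = len(pattern_sets)
    i = 0
    while i <= len(out) - plen:
        window = out[i:i + plen]
        if all(window[j] in pattern_sets[j] or not pattern_sets[j]
               for j in range(plen)):
            span = set(range(i, i + plen))
            if not (span & protected):
                out[i + plen - 1] = replacement
        i += 1
    return "".join(out)


@dataclass
class MotifSite:
    """Placement of one motif inside an anchor sequence."""
    motif_id: str
    positions: tuple[int, ...]      # 1-based positions in the anchor
    planted_status: str             # active | inactive


@dataclass
class AnchorInfo:
    """Ground-truth layout of one anchor sequence."""
    ref_id: str
    group_id: str                   # group or accessory component id
    sequence: str
    domain_spans: dict = field(default_factory=dict)   # domain_id -> (start, end) 1-based
    motif_sites: list = field(default_factory=list)    # list[MotifSite]
    recA_nt_span: tuple | None = None                  # (start, end) 1-based
    clamp_span: tuple | None = None

    @property
    def protected_positions(self) -> frozenset[int]:
        """0-based positions that the cohort simulator must not mutate."""
        prot = set()
        for site in self.motif_sites:
            prot.update(p - 1 for p in site.positions)
        for span in (self.recA_nt_span, self.clamp_span):
            if span is not None:
                prot.update(range(span[0] - 1, span[1]))
        return frozenset(prot)


def build_domain_consensus(domain_id: str, length: int,
                           motif_columns: dict[int, str]) -> str:
    """Random consensus with canonical motif residues planted.

    motif_columns maps 1-based column -> canonical residue.
    """
    rng = rng_for("domain", domain_id)
    seq = list(sample_sequence(rng, length))
    for col, res in motif_columns.items():
        seq[col - 1] = res
    return "".join(seq)


def build_domain_alignment(domain_id: str, consensus: str,
                           protected: frozenset[int]) -> list[tuple[str, str]]:
    rows = [(f"{domain_id}_cons", consensus)]
    for k in range(N_ALIGNMENT_VARIANTS):
        rng = rng_for("alnrow", domain_id, k)
        rows.append((f"{domain_id}_v{k + 1}",
                     mutate(rng, consensus, ALIGNMENT_VARIANT_RATE, protected)))
    return rows


def group_domain_variant(owner_id: str, domain_id: str, consensus: str,
                         protected: frozenset[int],
                         divergence: float = GROUP_DIVERGENCE) -> str:
    rng = rng_for("groupvar", owner_id, domain_id)
    return mutate(rng, consensus, divergence, protected)


def linker(owner_id: str, tag, length: int = LINKER_LENGTH) -> str:
    return sample_sequence(rng_for("linker", owner_id, tag), length)
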