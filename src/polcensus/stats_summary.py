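"""Metadata harmonization, distribution summaries, and enrichment tests.

Environmental metadata is noisy and multi-source, so it is reduced to two
binary axes before testing: oxygen usage collapses to aerobe (anything that
can use oxygen, facultative anaerobes included) vs anaerobe, with
conflicting multi-source labels resolved by majority vote and ties treated
as missing; optimal growth temperature collapses to four categories —
psychrophile (<20°C), mesophile [20, 45)°C, thermophile [45, 60)°C,
hyperthermophile (≥60°C) — and, for testing, to the binary
mesophile-incl-psychrophile vs thermophile-incl-hyperthermophile split.

Presence/absence of a polymerase feature across genomes is compared
between environmental classes by a two-sided Fisher's exact test on the
2×2 table, reported with the sample odds ratio (ad/bc) and a 95% Woolf
(log-OR normal) confidence interval, Haldane–Anscombe 0.5-corrected only
when a zero cell exists.  The p-value is computed by exact integer
enumeration of the hypergeometric support (probabilities at most that of
the observed table are summed), so it is reproducible to machine precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sequence_io import GenomeRecord

OXYGEN_AEROBE_LABELS = {
    "aerobe", "aerobic", "obligate aerobe", "facultative", "facultative anaerobe",
    "facultative aerobe", "microaerophile", "microaerophilic", "aerotolerant",
}
OXYGEN_ANAEROBE_LABELS = {
    "anaerobe", "anaerobic", "obligate anaerobe", "strict anaerobe",
}

TEMP_SOURCE_PRIORITY = ("engqvist", "bacdive", "tempura")

MISSING = "missing"


@dataclass
class EnvironmentRecord:
    genome_id: str
    oxygen_class: str          # aerobe | anaerobe | missing
    temp_category: str         # psychrophile | mesophile | thermophile | hyperthermophile | missing
    temp_binary: str           # mesophile-incl-psychro | thermophile-incl-hyper | missing
    gram: str | None = None


@dataclass
class EnrichmentResult:
    feature: str
    variable: str
    table: tuple               # ((a, b), (c, d))
    odds_ratio: float
    ci95: tuple
    p_two_sided: float
    undefined: bool = False
    note: str = ""


def classify_temperature(temp_c: float | None) -> str:
    """Growth-temperature category; boundaries are half-open with the
    upper rule fixed by the >= 60°C hyperthermophile definition."""
    if temp_c is None:
        return MISSING
    if temp_c < 20.0:
        return "psychrophile"
    if temp_c < 45.0:
        return "mesophile"
    if temp_c < 60.0:
        return "thermophile"
    return "hyperthermophile"


def _temp_binary(category: str) -> str:
    if category in ("psychrophile", "mesophile"):
        return "mesophile-incl-psychro"
    if category in ("thermophile", "hyperthermophile"):
        return "thermophile-incl-hyper"
    return MISSING


def harmonize_oxygen(labels) -> str:
    """Majority vote over mapped labels; facultative counts as aerobe;
    a tie is treated as data-not-available."""
    votes = {"aerobe": 0, "anaerobe": 0}
    for raw in labels:
        lab = str(raw).strip().lower()
        if lab in OXYGEN_AEROBE_LABELS:
            votes["aerobe"] += 1
        elif lab in OXYGEN_ANAEROBE_LABELS:
            votes["anaerobe"] += 1
        elif lab:
            warnings.warn(f"unmappable oxygen label ignored: {raw!r}")
    if votes["aerobe"] == votes["anaerobe"]:
        return MISSING
    return "aerobe" if votes["aerobe"] > votes["anaerobe"] else "anaerobe"


def harmonize_metadata(genome_records: dict[str, GenomeRecord],
                       temp_sources: dict[str, dict[str, float]] | None = None,
                       source_priority=TEMP_SOURCE_PRIORITY,
                       ) -> dict[str, EnvironmentRecord]:
    """Reduce raw per-genome metadata to harmonized environment classes.

    ``temp_sources`` optionally maps genome_id -> {source_name: temp_C};
    sources are consulted in ``source_priority`` order and the first
    available value wins, falling back to the record's own growth_temp_c.
    """
    out: dict[str, EnvironmentRecord] = {}
    for gid, rec in genome_records.items():
        temp = None
        if temp_sources and gid in temp_sources:
            per_source = temp_sources[gid]
            for source in source_priority:
                if source in per_source and per_source[source] is not None:
                    temp = per_source[source]
                    break
        if temp is None:
            temp = rec.growth_temp_c
        category = classify_temperature(temp)
        out[gid] = EnvironmentRecord(
            genome_id=gid,
            oxygen_class=harmonize_oxygen(rec.oxygen_labels),
            temp_category=category,
            temp_binary=_temp_binary(category),
            gram=rec.gram)
    return out


# ---------------------------------------------------------------------------
# Fisher's exact enrichment
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided p for a 2×2 table by integer enumeration.

    All tables with the observed margins are enumerated; hypergeometric
    probabilities share the denominator C(N, a+c), so tables are compared
    by exact integer numerators and the summation is exact.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) < 0:
        raise ValueError("negative cell count")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    u_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = math.comb(n, c1)
    acc = 0
    for k in range(lo, hi + 1):
        u = math.comb(r1, k) * math.comb(r2, c1 - k)
        if u <= u_obs:
            acc += u
    return float(Fraction(acc, total))


def fisher_enrichment(presence_flags: dict[str, bool],
                      env_classes: dict[str, str],
                      feature: str = "feature",
                      variable: str = "environment") -> EnrichmentResult:
    """Fisher's exact test of feature presence between two environment
    classes.  Genomes with a missing class are excluded.  The table is

        [[present & class1, absent & class1],
         [present & class2, absent & class2]]

    with classes in sorted label order.
    """
    keep = [g for g, cls in env_classes.items()
            if cls not in (MISSING, None) and g in presence_flags]
    classes = sorted({env_classes[g] for g in keep})
    if len(classes) != 2:
        return EnrichmentResult(feature, variable, ((0, 0), (0, 0)),
                                float("nan"), (float("nan"), float("nan")),
                                float("nan"), undefined=True,
                                note=f"need exactly 2 classes, got {classes}")
    c1, c2 = classes
    a = sum(1 for g in keep if env_classes[g] == c1 and presence_flags[g])
    b = sum(1 for g in keep if env_classes[g] == c1 and not presence_flags[g])
    c = sum(1 for g in keep if env_classes[g] == c2 and presence_flags[g])
    d = sum(1 for g in keep if env_classes[g] == c2 and not presence_flags[g])
    table = ((a, b), (c, d))

    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        return EnrichmentResult(feature, variable, table, float("nan"),
                                (float("nan"), float("nan")), float("nan"),
                                undefined=True, note="degenerate margin")

    p = fisher_exact_two_sided(a, b, c, d)
    odds_ratio = (a * d) / (b * c) if b * c > 0 else float("inf")
    if 0 in (a, b, c, d):
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    log_or = math.log((aa * dd) / (bb * cc))
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = sps.norm.ppf(0.975)
    ci = (math.exp(log_or - z * se), math.exp(log_or + z * se))
    return EnrichmentResult(feature, variable, table, odds_ratio, ci, p)


def benjamini_hochberg(results: list[EnrichmentResult]) -> list[float]:
    """Optional FDR adjustment across a batch of enrichment results."""
    from statsmodels.stats.multitest import multipletests
    ps = [r.p_two_sided for r in results]
    return list(multipletests(ps, method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# distribution summaries
# ---------------------------------------------------------------------------

def count_correlation(complements, genome_records: dict[str, GenomeRecord]) -> dict:
    """Correlation of polymerase counts with genome size.

    Rank correlation (Spearman) is primary; Pearson secondary.  Returned
    per overall count and per family.  Undefined correlations (zero count
    variance) are reported as None.
    """
    comps = [c for c in complements if c.genome_id in genome_records]
    if len(comps) < 3:
        raise ValueError("count_correlation needs at least 3 genomes")
    sizes = np.array([genome_records[c.genome_id].size_bp for c in comps], dtype=float)

    def _corr(counts: np.ndarray) -> dict:
        if np.all(counts == counts[0]) or np.all(sizes == sizes[0]):
            return {"spearman_rho": None, "spearman_p": None,
                    "pearson_r": None, "pearson_p": None, "n": len(counts)}
        rho, rho_p = sps.spearmanr(sizes, counts)
        r, r_p = sps.pearsonr(sizes, counts)
        return {"spearman_rho": float(rho), "spearman_p": float(rho_p),
                "pearson_r": float(r), "pearson_p": float(r_p),
                "n": len(counts)}

    totals = np.array([sum(c.family_counts.values()) for c in comps], dtype=float)
    out = {"overall": _corr(totals), "per_family": {}}
    for fam in "ABCXY":
        counts = np.array([c.family_counts.get(fam, 0) for c in comps], dtype=float)
        out["per_family"][fam] = _corr(counts)
    return out


def genome_features(complement) -> dict[str, bool]:
    """Binary feature vector of one genome complement, used for the
    per-taxon heat-map matrix and as enrichment inputs."""
    feats: dict[str, bool] = {}
    census = complement.census()
    for fam in "ABCXY":
        feats[f"family:{fam}"] = any(a.family == fam for a in census)
    for ann in census:
        if ann.group:
            feats[f"group:{ann.group}"] = True
    polys = [a for a in census]
    feats["active:PHP_AS"] = any(a.php_active for a in polys)
    feats["active:DEDDh"] = any(a._flag("DEDDh") for a in polys)
    feats["active:DEDDy"] = any(a._flag("DEDDy") for a in polys)
    feats["active:FEN_AS"] = any(a.exo53_active for a in polys)
    feats["exo53:any"] = complement.exo53_status in ("PolA1", "solo")
    feats[f"replication:{complement.replication_system.system}"] = True
    poly_y = [a for a in census if a.family == "Y"]
    feats["polY:any"] = bool(poly_y)
    feats["polY:recA_NT"] = any(a.recA_NT for a in poly_y)
    feats["polY:solo"] = any(a.recA_NT is False for a in poly_y)
    feats["polA1:exo35_active"] = any(a.group == "PolA1" and a.dnaq_active
                                      for a in census)
    feats["polA1:exo35_inactive"] = any(a.group == "PolA1" and a.dnaq_active is False
                                        for a in census)
    for call in complement.complexes:
        feats[f"complex:{call.complex_id}"] = True
    return feats


def taxon_feature_matrix(complements, genome_records: dict[str, GenomeRecord],
                         rank: str = "phylum",
                         features: list[str] | None = None) -> pd.DataFrame:
    """Percentage of genomes per taxon carrying at least one instance of
    each feature.  Taxa with zero genomes at the requested rank are
    omitted; cells are in [0, 100]."""
    rows = []
    for comp in complements:
        rec = genome_records.get(comp.genome_id)
        if rec is None:
            continue
        taxon = rec.rank(rank)
        if taxon is None:
            continue
        feats = genome_features(comp)
        feats["_taxon"] = taxon
        rows.append(feats)
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    taxa = df.pop("_taxon")
    df = df.eq(True)   # missing cells (feature never seen) become False
    if features is not None:
        for f in features:
            if f not in df.columns:
                df[f] = False
        df = df[features]
    pct = df.astype(float).groupby(taxa).mean() * 100.0
    return pct.sort_index()
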