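"""Metadata harmonization, Fisher enrichment, summaries."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from polcensus import stats_summary as ss
from polcensus.sequence_io import GenomeRecord


def _genome(gid, oxygen=(), temp=None, size=4_000_000, taxonomy=()):
    return GenomeRecord(genome_id=gid, taxonomy=taxonomy, size_bp=size,
                        gc_percent=50.0, oxygen_labels=tuple(oxygen),
                        growth_temp_c=temp)


class TestHarmonize:
    def test_facultative_counts_as_aerobe(self):
        assert ss.harmonize_oxygen(["aerobe", "facultative anaerobe"]) == "aerobe"

    def test_tie_is_missing(self):
        assert ss.harmonize_oxygen(["aerobe", "anaerobe"]) == ss.MISSING

    def test_majority_vote(self):
        assert ss.harmonize_oxygen(["anaerobe", "anaerobe", "aerobe"]) == "anaerobe"

    def test_label_order_invariance(self):
        labels = ["aerobe", "anaerobe", "facultative", "obligate anaerobe"]
        results = {ss.harmonize_oxygen(p)
                   for p in itertools.permutations(labels)}
        assert len(results) == 1

    def test_unmappable_label_warns_and_is_ignored(self):
        with pytest.warns(UserWarning, match="unmappable"):
            assert ss.harmonize_oxygen(["aerobe", "sporulating"]) == "aerobe"

    @pytest.mark.parametrize("temp,category", [
        (15.0, "psychrophile"), (19.999, "psychrophile"),
        (20.0, "mesophile"), (30.0, "mesophile"), (44.9, "mesophile"),
        (45.0, "thermophile"), (50.0, "thermophile"), (59.9, "thermophile"),
        (60.0, "hyperthermophile"), (70.0, "hyperthermophile"),
        (None, ss.MISSING),
    ])
    def test_temperature_categories(self, temp, category):
        assert ss.classify_temperature(temp) == category

    def test_temp_binary_consistent(self):
        recs = {"g1": _genome("g1", temp=50.0), "g2": _genome("g2", temp=10.0),
                "g3": _genome("g3")}
        env = ss.harmonize_metadata(recs)
        assert env["g1"].temp_binary == "thermophile-incl-hyper"
        assert env["g2"].temp_binary == "mesophile-incl-psychro"
        assert env["g3"].temp_binary == ss.MISSING

    def test_temperature_source_priority(self):
        recs = {"g": _genome("g", temp=70.0)}
        env = ss.harmonize_metadata(
            recs, temp_sources={"g": {"bacdive": 50.0, "tempura": 10.0}})
        # bacdive outranks tempura; both outrank the record fallback
        assert env["g"].temp_category == "thermophile"


def _oracle_two_sided_p(a, b, c, d):
    """Independent brute force: enumerate every 2x2 table with the observed
    margins, accumulate exact hypergeometric probabilities of tables no
    more probable than the observed one."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    p_obs = Fraction(math.comb(r1, a) * math.comb(r2, c), denom)
    total = Fraction(0)
    for aa in range(0, r1 + 1):
        cc = c1 - aa
        if cc < 0 or cc > r2:
            continue
        p = Fraction(math.comb(r1, aa) * math.comb(r2, cc), denom)
        if p <= p_obs:
            total += p
    return float(total)


class TestFisher:
    def test_worked_example_3113(self):
        p = ss.fisher_exact_two_sided(3, 1, 1, 3)
        assert p == pytest.approx(34 / 70, abs=1e-15)
        res = ss.fisher_enrichment(
            {f"g{i}": i in (0, 1, 2, 4) for i in range(8)},
            {f"g{i}": ("x" if i < 4 else "y") for i in range(8)})
        assert res.table == ((3, 1), (1, 3))
        assert res.odds_ratio == pytest.approx(9.0)
        assert res.p_two_sided == pytest.approx(34 / 70, abs=1e-15)

    def test_symmetric_table(self):
        assert ss.fisher_exact_two_sided(5, 5, 5, 5) == pytest.approx(1.0)

    def test_extreme_table(self):
        p = ss.fisher_exact_two_sided(10, 0, 0, 10)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_matches_enumeration_oracle_small_tables(self):
        """Exhaustive agreement with the brute-force oracle for all tables
        with N <= 18 (the full N <= 40 sweep runs in the acceptance suite)."""
        for n in range(1, 19):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        assert ss.fisher_exact_two_sided(a, b, c, d) == \
                            pytest.approx(_oracle_two_sided_p(a, b, c, d),
                                          abs=1e-12)

    @given(st.tuples(st.integers(0, 25), st.integers(0, 25),
                     st.integers(0, 25), st.integers(0, 25)))
    @settings(max_examples=150, deadline=None)
    def test_matches_scipy(self, table):
        """Cross-check against an independent implementation."""
        a, b, c, d = table
        p = ss.fisher_exact_two_sided(a, b, c, d)
        p_scipy = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        assert p == pytest.approx(min(p_scipy, 1.0), abs=1e-9)

    def test_or_and_ci_against_statsmodels(self):
        import statsmodels.api as sm
        table = np.array([[12, 5], [7, 20]])
        t22 = sm.stats.Table2x2(table)
        res = ss.fisher_enrichment(
            {f"a{i}": True for i in range(12)}
            | {f"b{i}": False for i in range(5)}
            | {f"c{i}": True for i in range(7)}
            | {f"d{i}": False for i in range(20)},
            {f"a{i}": "x" for i in range(12)}
            | {f"b{i}": "x" for i in range(5)}
            | {f"c{i}": "y" for i in range(7)}
            | {f"d{i}": "y" for i in range(20)})
        assert res.odds_ratio == pytest.approx(t22.oddsratio)
        lo, hi = t22.oddsratio_confint()
        assert res.ci95 == pytest.approx((lo, hi), rel=1e-6)

    def test_zero_cell_uses_haldane_correction(self):
        flags = {f"a{i}": True for i in range(10)} \
            | {f"b{i}": False for i in range(5)} \
            | {f"c{i}": False for i in range(10)}
        classes = {f"a{i}": "x" for i in range(10)} \
            | {f"b{i}": "x" for i in range(5)} \
            | {f"c{i}": "y" for i in range(10)}
        res = ss.fisher_enrichment(flags, classes)
        assert math.isinf(res.odds_ratio)
        assert np.isfinite(res.ci95[0]) and np.isfinite(res.ci95[1])

    def test_degenerate_margin_is_undefined(self):
        res = ss.fisher_enrichment({"a": True, "b": False},
                                   {"a": "x", "b": "x"})
        assert res.undefined

    def test_missing_class_excluded(self):
        res = ss.fisher_enrichment(
            {"a": True, "b": False, "c": True, "d": False, "e": True},
            {"a": "x", "b": "x", "c": "y", "d": "y", "e": ss.MISSING})
        assert sum(sum(row) for row in res.table) == 4


class _FakeComplement:
    def __init__(self, gid, counts, groups=()):
        self.genome_id = gid
        self.family_counts = counts
        self.exo53_status = "PolA1"
        self.complexes = []
        from polcensus.complement_annotator import ReplicationSystem
        self.replication_system = ReplicationSystem("DnaE1-only")
        self._groups = groups

    def census(self):
        from polcensus.complement_annotator import PolymeraseAnnotation
        out = []
        for i, (fam, grp) in enumerate(self._groups):
            out.append(PolymeraseAnnotation(protein_id=f"{self.genome_id}_p{i}",
                                            family=fam, group=grp))
        return out

    def accessories(self, role):
        return []


class TestCountCorrelation:
    def test_proportional_counts_give_rho_one(self):
        recs, comps = {}, []
        for i in range(10):
            size = 1_000_000 * (i + 1)
            recs[f"g{i}"] = _genome(f"g{i}", size=size)
            comps.append(_FakeComplement(f"g{i}", {"Y": i + 1}))
        out = ss.count_correlation(comps, recs)
        assert out["overall"]["spearman_rho"] == pytest.approx(1.0)

    def test_constant_counts_undefined(self):
        recs = {f"g{i}": _genome(f"g{i}", size=1_000_000 * (i + 1))
                for i in range(5)}
        comps = [_FakeComplement(f"g{i}", {"Y": 3}) for i in range(5)]
        out = ss.count_correlation(comps, recs)
        assert out["overall"]["spearman_rho"] is None

    def test_poisson_counts_match_rank_oracle(self):
        """Counts Poisson with mean linear in size: rank correlation agrees
        with a brute-force rank statistic within 0.1."""
        rng = np.random.default_rng(20260926)
        sizes = rng.uniform(1e6, 9e6, size=200)
        counts = rng.poisson(sizes / 1e6)
        recs, comps = {}, []
        for i, (s, k) in enumerate(zip(sizes, counts)):
            recs[f"g{i}"] = _genome(f"g{i}", size=int(s))
            comps.append(_FakeComplement(f"g{i}", {"Y": int(k)}))
        out = ss.count_correlation(comps, recs)

        def _ranks(x):
            order = np.argsort(x, kind="mergesort")
            ranks = np.empty(len(x))
            sx = np.asarray(x)[order]
            i = 0
            while i < len(x):
                j = i
                while j + 1 < len(x) and sx[j + 1] == sx[i]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks
        rx, ry = _ranks(sizes), _ranks(counts.astype(float))
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert out["overall"]["spearman_rho"] == pytest.approx(oracle, abs=0.1)
        assert out["overall"]["spearman_rho"] > 0

    def test_requires_three_genomes(self):
        with pytest.raises(ValueError):
            ss.count_correlation([_FakeComplement("g0", {"Y": 1})],
                                 {"g0": _genome("g0")})


class TestTaxonMatrix:
    def test_percentages(self):
        recs, comps = {}, []
        for i in range(10):
            recs[f"g{i}"] = _genome(f"g{i}", taxonomy=("PhyA",))
            groups = [("Y", "PolY-core")] if i < 9 else []
            comps.append(_FakeComplement(f"g{i}", {"Y": 1}, groups))
        mat = ss.taxon_feature_matrix(comps, recs, rank="phylum")
        assert mat.loc["PhyA", "family:Y"] == pytest.approx(90.0)
        assert mat.loc["PhyA", "family:X"] == pytest.approx(0.0)
        assert ((mat.values >= 0) & (mat.values <= 100)).all()

    def test_taxon_without_rank_omitted(self):
        recs = {"g0": _genome("g0", taxonomy=("PhyA",)),
                "g1": _genome("g1", taxonomy=("",))}
        comps = [_FakeComplement("g0", {}), _FakeComplement("g1", {})]
        mat = ss.taxon_feature_matrix(comps, recs, rank="phylum")
        assert list(mat.index) == ["PhyA"]
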