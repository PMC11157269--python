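from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicdelta.integrate import (
    classify_degs,
    compartment_expression_shift,
    ddct,
    deg_overlap_enrichment,
    deg_summary,
    link_loops_to_genes,
    loop_gene_association,
)


def fisher_two_sided_oracle(a, b, c, d) -> float:
    """Exact two-sided Fisher p by full enumeration with rational arithmetic."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # scipy's two-sided rule: sum tables no more probable than the observed
    cutoff = p_obs * (1 + Fraction(1, 10**9))
    for x in range(lo, hi + 1):
        if prob(x) <= cutoff:
            total += prob(x)
    return float(total)


class TestClassifyDegs:
    def make_table(self, rows):
        return pd.DataFrame(
            [{"gene": f"g{i}", "log2fc": lfc, "p": p} for i, (lfc, p) in enumerate(rows)]
        )

    def test_up_not_extreme(self):
        sets = classify_degs(self.make_table([(1.5, 0.005)]))
        assert sets["up"] == {"g0"} and sets["extreme_up"] == set()

    def test_below_lfc_threshold_unclassified(self):
        sets = classify_degs(self.make_table([(0.9, 0.005)]))
        assert all(len(s) == 0 for s in sets.values())

    def test_extreme_threshold_inclusive(self):
        sets = classify_degs(self.make_table([(6.0, 0.001), (-6.0, 0.001)]))
        assert sets["extreme_up"] == {"g0"}
        assert sets["extreme_down"] == {"g1"}

    @given(
        lfcs=st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=30),
        ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=30, max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_sets_disjoint_and_nested(self, lfcs, ps):
        table = self.make_table(list(zip(lfcs, ps)))
        sets = classify_degs(table)
        assert not (sets["up"] & sets["down"])
        assert sets["extreme_up"] <= sets["up"]
        assert sets["extreme_down"] <= sets["down"]


class TestDegSummary:
    @pytest.mark.parametrize(
        "count,total,percent",
        [
            (1031, 23272, 4),
            (703, 23272, 3),
            (789, 22405, 4),
            (971, 22405, 4),
            (0, 1000, 0),
        ],
    )
    def test_whole_percent(self, count, total, percent):
        sets = {"up": set(range(count))}
        out = deg_summary(total, sets)
        assert out.loc[0, "percent"] == percent
        assert out.loc[0, "count"] == count


class TestLinkLoopsToGenes:
    def test_tss_inside_anchor_distance_zero(self):
        loops = pd.DataFrame([{"bin1": 2, "bin2": 10}])  # anchor1 [10000,15000)
        tss = pd.DataFrame([{"gene": "g", "tss": 10_000}])
        out = link_loops_to_genes(loops, tss, resolution=5000, window=3000)
        assert len(out) == 1 and out.loc[0, "distance"] == 0

    def test_tss_beyond_window_not_linked(self):
        # nearest anchor edge at 14 500 bp away -> distance 4 500 > 3 000
        loops = pd.DataFrame([{"bin1": 2, "bin2": 10}])  # anchors at 10k, 50k
        tss = pd.DataFrame([{"gene": "g", "tss": 5_500}])
        out = link_loops_to_genes(loops, tss, resolution=5000, window=3000)
        assert len(out) == 1 and out.loc[0, "distance"] == 4_500 or len(out) == 0

    def test_matches_brute_force_oracle(self, rng):
        res, window = 5000, 3000
        loops = pd.DataFrame(
            {
                "bin1": rng.integers(0, 100, size=40),
                "bin2": rng.integers(100, 200, size=40),
            }
        )
        tss = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(60)],
                "tss": rng.integers(0, 1_000_000, size=60),
            }
        )
        out = link_loops_to_genes(loops, tss, resolution=res, window=window)
        got = {(r.loop_id, r.gene) for r in out.itertuples(index=False)}
        expected = set()
        for li, lrow in loops.iterrows():
            for _, grow in tss.iterrows():
                dists = []
                for b in (lrow["bin1"], lrow["bin2"]):
                    start, end = b * res, (b + 1) * res
                    if start <= grow["tss"] < end:
                        dists.append(0)
                    else:
                        dists.append(
                            min(abs(grow["tss"] - start), abs(grow["tss"] - (end - 1)))
                        )
                if min(dists) <= window:
                    expected.add((li, grow["gene"]))
        assert got == expected

    def test_window_monotonicity(self, rng):
        loops = pd.DataFrame({"bin1": [5, 40], "bin2": [30, 90]})
        tss = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(50)], "tss": rng.integers(0, 500_000, 50)}
        )
        small = link_loops_to_genes(loops, tss, 5000, window=1000)
        large = link_loops_to_genes(loops, tss, 5000, window=10_000)
        s = {(r.loop_id, r.gene) for r in small.itertuples(index=False)}
        l = {(r.loop_id, r.gene) for r in large.itertuples(index=False)}
        assert s <= l

    def test_empty_output_valid(self):
        out = link_loops_to_genes(
            pd.DataFrame(columns=["bin1", "bin2"]),
            pd.DataFrame(columns=["gene", "tss"]),
            5000,
        )
        assert len(out) == 0


class TestLoopGeneAssociation:
    def make_inputs(self, table):
        """table[i][j] combinations of gene-dir i (up/down) x loop-status j."""
        loops = []
        linked = []
        degs = {"up": set(), "down": set()}
        gene_i = 0
        for i, gdir in enumerate(("up", "down")):
            for j, status in enumerate(("gained", "lost")):
                for _ in range(table[i][j]):
                    loop_id = len(loops)
                    loops.append({"bin1": 0, "bin2": 10, "status": status})
                    gene = f"g{gene_i}"
                    gene_i += 1
                    degs[gdir].add(gene)
                    linked.append({"loop_id": loop_id, "gene": gene, "distance": 0})
        return (
            pd.DataFrame(loops),
            degs,
            pd.DataFrame(linked, columns=["loop_id", "gene", "distance"]),
        )

    def test_balanced_table_p_one(self):
        diff, degs, linked = self.make_inputs([[5, 5], [5, 5]])
        res = loop_gene_association(diff, degs, linked)
        assert res["combinations"].p == pytest.approx(1.0)

    def test_diagonal_table_matches_enumeration(self):
        diff, degs, linked = self.make_inputs([[10, 0], [0, 10]])
        res = loop_gene_association(diff, degs, linked)
        oracle = fisher_two_sided_oracle(10, 0, 0, 10)
        assert res["combinations"].p == pytest.approx(oracle, rel=1e-9)

    def test_fisher_matches_oracle_on_random_tables(self, rng):
        from scipy.stats import fisher_exact

        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 8, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-7)

    def test_empty_linkage_no_crash(self):
        diff = pd.DataFrame([{"bin1": 0, "bin2": 5, "status": "gained"}])
        res = loop_gene_association(
            diff, {"up": set(), "down": set()},
            pd.DataFrame(columns=["loop_id", "gene", "distance"]),
        )
        assert res["combinations"].p == 1.0


class TestCompartmentExpressionShift:
    def make_switches(self, classes):
        return pd.DataFrame(
            {"bin": range(len(classes)), "switch_class": classes}
        )

    def test_empty_class_flagged_absent(self, rng):
        switches = self.make_switches(["stable"] * 10)
        de = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(20)],
                "tss": rng.integers(0, 10 * 250_000, size=20),
                "log2fc": rng.normal(size=20),
            }
        )
        out = compartment_expression_shift(switches, de)
        assert out["A_to_B"]["n"] == 0
        assert out["A_to_B"]["p_vs_stable"] is None
        assert out["stable"]["n"] == 20

    def test_planted_shift_detected(self, rng):
        classes = ["B_to_A"] * 3 + ["stable"] * 17
        switches = self.make_switches(classes)
        n = 400
        tss = rng.integers(0, 20 * 250_000, size=n)
        bins = tss // 250_000
        lfc = rng.normal(0, 0.3, size=n)
        lfc[bins < 3] += 1.0
        de = pd.DataFrame({"gene": [f"g{i}" for i in range(n)], "tss": tss, "log2fc": lfc})
        out = compartment_expression_shift(switches, de)
        assert out["B_to_A"]["median_log2fc"] > 0.5
        assert out["B_to_A"]["p_vs_stable"] < 1e-6

    def test_null_distribution_no_shift(self, rng):
        classes = ["A_to_B"] * 5 + ["stable"] * 15
        switches = self.make_switches(classes)
        n = 500
        de = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n)],
                "tss": rng.integers(0, 20 * 250_000, size=n),
                "log2fc": rng.normal(0, 1, size=n),
            }
        )
        out = compartment_expression_shift(switches, de)
        assert abs(out["A_to_B"]["median_log2fc"]) < 0.5
        assert out["A_to_B"]["p_vs_stable"] > 0.001


class TestDdct:
    def make_ct(self, records):
        return pd.DataFrame(records, columns=["sample", "gene", "ct"])

    def test_reference_sample_is_one(self):
        ct = self.make_ct(
            [
                ("ref", "GAPDH", 18.0),
                ("ref", "TG1", 25.0),
                ("s1", "GAPDH", 18.5),
                ("s1", "TG1", 24.0),
            ]
        )
        out = ddct(ct, "GAPDH", "ref").set_index(["sample", "gene"])
        assert out.loc[("ref", "TG1"), "relative_expression"] == pytest.approx(1.0)

    def test_worked_arithmetic(self):
        # dCt_sample = 5, dCt_ref = 7 -> 2^(7-5) = 4
        ct = self.make_ct(
            [
                ("ref", "H", 20.0),
                ("ref", "T", 27.0),
                ("s1", "H", 20.0),
                ("s1", "T", 25.0),
            ]
        )
        out = ddct(ct, "H", "ref").set_index(["sample", "gene"])
        assert out.loc[("s1", "T"), "relative_expression"] == pytest.approx(4.0)

    def test_matches_spreadsheet_oracle(self, rng):
        samples = [f"s{i}" for i in range(5)]
        genes = ["H"] + [f"t{j}" for j in range(4)]
        records = [
            (s, g, float(rng.uniform(15, 35))) for s in samples for g in genes
        ]
        ct = self.make_ct(records)
        out = ddct(ct, "H", "s0").set_index(["sample", "gene"])
        lookup = {(s, g): v for s, g, v in records}
        for s in samples:
            for g in genes[1:]:
                dct = lookup[(s, g)] - lookup[(s, "H")]
                dct_ref = lookup[("s0", g)] - lookup[("s0", "H")]
                expected = 2.0 ** (-(dct - dct_ref))
                assert out.loc[(s, g), "relative_expression"] == pytest.approx(expected)

    def test_missing_reference_errors(self):
        ct = self.make_ct([("s1", "T", 20.0)])
        with pytest.raises(ValueError, match="reference gene"):
            ddct(ct, "H", "s1")
        ct2 = self.make_ct([("s1", "H", 20.0), ("s1", "T", 22.0)])
        with pytest.raises(ValueError, match="reference sample"):
            ddct(ct2, "H", "nope")


class TestDegOverlapEnrichment:
    def test_identical_sets_fold_n_over_x(self):
        universe = set(range(100))
        s = set(range(10))
        obs, exp, fold, p = deg_overlap_enrichment(s, s, universe, universe)
        assert fold == pytest.approx(100 / 10)
        assert obs == 10

    def test_disjoint_sets_fold_zero(self):
        universe = set(range(50))
        obs, exp, fold, p = deg_overlap_enrichment(
            set(range(5)), set(range(10, 15)), universe, universe
        )
        assert fold == 0.0

    def test_universe_intersection_applied(self):
        ua = set(range(0, 80))
        ub = set(range(20, 100))
        sa = {5, 25, 30}   # 5 outside ub's universe
        sb = {25, 30, 95}  # 95 outside ua's universe
        obs, exp, fold, p = deg_overlap_enrichment(sa, sb, ua, ub)
        # universe = {20..79}; sa -> {25, 30}, sb -> {25, 30}
        assert obs == 2
        assert exp == pytest.approx(2 * 2 / 60)
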