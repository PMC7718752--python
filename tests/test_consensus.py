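"""Compendium merge rules, consensus/decision-tree classification,
chimeric-block detection (with brute-force oracle) and contingency /
loglinear analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from linkagekit import consensus as cons
from linkagekit import io as lio


def make_map(assignments, family="famA", method="ML", parent="average"):
    """assignments: list of (marker, lg, cm)."""
    return lio.LinkageMap(
        family, parent,
        pd.DataFrame(assignments, columns=["marker", "linkage_group", "position_cm"]),
        method=method,
    )


def make_coords(rows):
    """rows: list of (marker, contig, contig_pos); chromosome mirrors contig."""
    return pd.DataFrame(
        [(m, c, p, f"chr_{c}", p) for m, c, p in rows],
        columns=["marker", "contig", "contig_pos", "chrom", "chrom_pos"],
    )


def comp_from_snps(snps: pd.DataFrame) -> cons.Compendium:
    """Build a Compendium directly from a per-SNP table (test shortcut)."""
    empty = snps.iloc[0:0]
    comp = cons.Compendium(snps, snps, empty, empty, [])
    comp.contig_consensus = cons._contig_consensus(snps)
    return comp


class TestMerge:
    def test_single_map(self):
        maps = [make_map([(f"m{i}", "LG1", float(i)) for i in range(5)])]
        coords = make_coords([(f"m{i}", "c1", 10 * i + 1) for i in range(5)])
        comp = cons.merge_compendium(maps, coords)
        assert len(comp.snps) == 5
        assert (comp.snps["n_families"] == 1).all()

    def test_conflicting_assignment_excluded(self):
        maps = [
            make_map([("mA", "LG1", 0.0)], family="f1"),
            make_map([("mA", "LG7", 0.0)], family="f2"),
        ]
        comp = cons.merge_compendium(maps, make_coords([("mA", "c1", 5)]))
        assert len(comp.snps) == 0
        assert comp.conflicts["marker"].tolist() == ["mA"]
        assert comp.size == 1

    def test_duplicate_physical_position_removed(self):
        maps = [make_map([("mA", "LG1", 0.0), ("mB", "LG1", 1.0), ("mC", "LG1", 2.0)])]
        coords = make_coords([("mA", "c1", 5), ("mB", "c1", 5), ("mC", "c1", 9)])
        comp = cons.merge_compendium(maps, coords)
        assert comp.snps["marker"].tolist() == ["mC"]
        assert sorted(comp.duplicates["marker"]) == ["mA", "mB"]

    def test_marker_without_coordinates_listed(self):
        maps = [make_map([("mA", "LG1", 0.0), ("ghost", "LG1", 1.0)])]
        comp = cons.merge_compendium(maps, make_coords([("mA", "c1", 5)]))
        assert comp.missing == ["ghost"]


class TestConsensusLG:
    def test_unanimous(self):
        records = pd.DataFrame({"linkage_group": ["LG3"] * 4})
        assert cons.consensus_lg(records) == ("LG3", False)

    def test_plurality_14_vs_12(self):
        records = pd.DataFrame({"linkage_group": ["LG2"] * 14 + ["LG10"] * 12})
        assert cons.consensus_lg(records) == ("LG2", False)

    def test_tie_is_ambiguous(self):
        records = pd.DataFrame({"linkage_group": ["LG1"] * 5 + ["LG2"] * 5})
        assert cons.consensus_lg(records) == (None, True)


class TestClassify:
    def build(self):
        # contig c1: consensus LG1; m1 multi-family conLG (cat1), m2 single-family
        # conLG (cat2 via m1), m3 single-family non-conLG (low), m4 multi-family
        # non-conLG (cat3).  contig c2: one single-family SNP, no cat1 -> low.
        # contig c3: 1 vs 1 tie -> unclassifiable.
        maps = [
            make_map(
                [("m1", "LG1", 0.0), ("m2", "LG1", 1.0), ("m3", "LG2", 0.0),
                 ("m4", "LG2", 1.0), ("m5", "LG1", 2.0), ("m6", "LG1", 3.0),
                 ("m7", "LG1", 4.0), ("m8", "LG3", 0.0), ("m9", "LG1", 5.0)],
                family="f1",
            ),
            make_map([("m1", "LG1", 0.0), ("m4", "LG2", 1.0)], family="f2"),
        ]
        coords = make_coords(
            [("m1", "c1", 10), ("m2", "c1", 20), ("m3", "c1", 30), ("m4", "c1", 40),
             ("m5", "c1", 50), ("m6", "c1", 60), ("m7", "c1", 70),
             ("m8", "c2", 10), ("m9", "c3", 10)]
        )
        coords.loc[coords["marker"] == "m9", ["contig"]] = "c3"
        extra = make_map([("m10", "LG2", 6.0)], family="f1")
        coords = pd.concat(
            [coords, make_coords([("m10", "c3", 20)])], ignore_index=True
        )
        return cons.merge_compendium(maps + [extra], coords)

    def test_decision_tree_categories(self):
        comp = self.build()
        cats = cons.classify_snps(comp)
        assert cats["m1"] == "cat1"
        assert cats["m2"] == "cat2"
        assert cats["m3"] == "low"
        assert cats["m4"] == "cat3"
        assert cats["m8"] == "low"  # single-family conLG, contig without cat1
        assert cats["m9"] == "unclassifiable" and cats["m10"] == "unclassifiable"

    def test_high_confidence_set(self):
        cats = cons.classify_snps(self.build())
        high = set(cats[cats.isin(cons.HIGH_CONFIDENCE)].index)
        assert high == {"m1", "m2", "m4", "m5", "m6", "m7"}


def snps_table(pattern, families_per_snp=None, contig="c1"):
    """Per-SNP table from an LG pattern string like 'CCXCXXC'
    (C=consensus LG, other letters = non-consensus LGs)."""
    n = len(pattern)
    fams = families_per_snp or [("f1",)] * n
    return pd.DataFrame(
        {
            "marker": [f"m{i}" for i in range(n)],
            "contig": contig,
            "contig_pos": [10 * (i + 1) for i in range(n)],
            "chrom": "chr1",
            "chrom_pos": [10 * (i + 1) for i in range(n)],
            "linkage_group": [f"LG_{ch}" for ch in pattern],
            "n_families": [len(f) for f in fams],
            "families": fams,
            "methods": [("ML",)] * n,
        }
    )


def bruteforce_blocks(pattern):
    """Independent run scan: maximal runs of equal non-consensus letters."""
    runs = []
    i = 0
    while i < len(pattern):
        if pattern[i] == "C":
            i += 1
            continue
        j = i
        while j + 1 < len(pattern) and pattern[j + 1] == pattern[i]:
            j += 1
        runs.append((i, j))
        i = j + 1
    return runs


class TestDetectBlocks:
    def test_no_non_consensus(self):
        blocks = cons.detect_blocks(comp_from_snps(snps_table("CCCCC")))
        assert len(blocks) == 0

    def test_single_exception_and_block(self):
        # pattern C C X C X X C: one single exception + one block of 2
        blocks = cons.detect_blocks(comp_from_snps(snps_table("CCXCXXC")))
        assert sorted(blocks["kind"]) == ["one_family_block", "single_exception"]
        blk = blocks[blocks["kind"] == "one_family_block"].iloc[0]
        assert blk["n_snps"] == 2
        assert blk["length_bp"] == blk["end_bp"] - blk["start_bp"] + 1

    def test_family_support_union_vs_per_snp(self):
        fams = [("f1",), ("f1",), ("f1",), ("f2",), ("f1",)]
        table = snps_table("CCXXC", families_per_snp=fams)
        union = cons.detect_blocks(comp_from_snps(table), support="union")
        strict = cons.detect_blocks(comp_from_snps(table), support="per_snp")
        assert union["kind"].iloc[0] == "multi_family_block"
        assert strict["kind"].iloc[0] == "one_family_block"

    def test_matches_bruteforce_on_random_contigs(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 15))
            letters = rng.choice(list("CCCXY"), size=n)
            # force a consensus majority of C so the plurality is C
            letters[: max(1, n // 2 + 1)] = "C"
            pattern = "".join(rng.permutation(letters))
            if pattern.count("C") <= max(
                pattern.count("X"), pattern.count("Y")
            ):
                continue
            blocks = cons.detect_blocks(comp_from_snps(snps_table(pattern)))
            expected = bruteforce_blocks(pattern)
            got = sorted(
                (row.start_bp // 10 - 1, row.end_bp // 10 - 1)
                for row in blocks.itertuples()
            )
            assert got == expected, pattern

    def test_ambiguous_contig_skipped(self):
        blocks = cons.detect_blocks(comp_from_snps(snps_table("CX")))
        assert len(blocks) == 0


class TestBlockStats:
    def test_zero_blocks(self):
        stats = cons.block_stats(pd.DataFrame(columns=["kind", "contig", "n_snps", "length_bp"]))
        assert stats["n_blocks"] == 0 and stats["total_length_bp"] == 0
        assert np.isnan(stats["median_length_bp"])

    def test_median_and_total(self):
        blocks = pd.DataFrame(
            {
                "contig": ["c1", "c2"],
                "kind": ["multi_family_block"] * 2,
                "n_snps": [2, 3],
                "length_bp": [10, 50],
            }
        )
        stats = cons.block_stats(blocks)
        assert stats["median_length_bp"] == 30
        assert stats["total_length_bp"] == 60
        assert stats["n_chimeric_contigs"] == 2


class TestPartition:
    def test_counts_sum_to_compendium_size(self):
        comp = comp_from_snps(snps_table("CCXCXXCC"))
        blocks = cons.detect_blocks(comp)
        labels = cons.partition(comp, blocks)
        assert len(labels) == comp.size
        counts = labels.value_counts()
        assert counts.get("single_exception", 0) == 1
        assert counts.get("one_family_block", 0) == 2
        assert counts.get("consensus", 0) == 5


class TestContingency:
    def test_unit_table(self):
        res = cons.contingency_2x2(1, 1, 1, 1)
        assert res.odds_ratio == 1.0

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            cons.contingency_2x2(0, 0, 3, 4)

    def test_zero_cell_flagged(self):
        res = cons.contingency_2x2(0, 5, 3, 4)
        assert res.zero_cell and res.odds_ratio == 0.0


class TestLoglinear:
    def test_independence_table_has_no_interactions(self):
        pa, pb, pc = np.array([0.3, 0.7]), np.array([0.6, 0.4]), np.array([0.2, 0.8])
        table = 10000 * np.einsum("i,j,k->ijk", pa, pb, pc)
        res = cons.loglinear_3way(table)
        assert (res.tests["G2"].abs() < 1e-6).all()

    def test_ipf_reproduces_margins(self, rng):
        table = rng.integers(5, 200, size=(2, 2, 2)).astype(float)
        fit = cons.ipf_fit(table, [(0, 1), (0, 2), (1, 2)])
        for axes in [(0, 1), (0, 2), (1, 2)]:
            other = tuple(i for i in range(3) if i not in axes)
            np.testing.assert_allclose(fit.sum(axis=other), table.sum(axis=other), atol=1e-8)

    def test_g2_matches_poisson_glm_oracle(self, rng):
        table = rng.integers(10, 400, size=(2, 2, 2)).astype(float)
        res = cons.loglinear_3way(table)
        # oracle: Poisson loglinear fits via IRLS on dummy-coded designs
        levels = list(itertools.product((0, 1), repeat=3))
        y = np.array([table[i] for i in levels])

        def design(two_ways):
            cols = [np.ones(8)]
            mains = [np.array([lv[a] for lv in levels], dtype=float) for a in range(3)]
            cols += mains
            for a, b in two_ways:
                cols.append(mains[a] * mains[b])
            return np.column_stack(cols)

        all2 = [(0, 1), (0, 2), (1, 2)]
        g2 = {}
        for dropped in [None] + all2:
            kept = [t for t in all2 if t != dropped]
            fit = sm.GLM(y, design(kept), family=sm.families.Poisson()).fit()
            mu = fit.fittedvalues
            g2[dropped] = 2 * np.sum(y * np.log(y / mu))
        tests = res.tests.set_index("term")
        assert tests.loc["A x B x C", "G2"] == pytest.approx(g2[None], abs=1e-4)
        for (a, b), name in zip(all2, ["A x B", "A x C", "B x C"]):
            assert tests.loc[name, "G2"] == pytest.approx(
                g2[(a, b)] - g2[None], abs=1e-4
            )


class TestGroupingTable:
    def test_counts_and_shares(self):
        # two methods; m1 conLG by ML in 2 families, m2 non-conLG by RG in 1
        maps = [
            make_map([("m1", "LG1", 0.0), ("m3", "LG1", 1.0)], family="f1", method="ML"),
            make_map([("m1", "LG1", 0.0)], family="f2", method="ML"),
            make_map([("m2", "LG2", 0.0)], family="f1", method="RG"),
        ]
        coords = make_coords([("m1", "c1", 10), ("m2", "c1", 20), ("m3", "c1", 30)])
        comp = cons.merge_compendium(maps, coords)
        table = cons.grouping_table(comp, ("RG", "ML"))
        assert table.sum() == 3
        assert table[0, 1, 1] == 1  # conLG, ML, >1 family
        assert table[1, 0, 0] == 1  # non-conLG, RG, 1 family
        shares = cons.grouping_shares(table)
        assert shares["consensus_share"] == pytest.approx(2 / 3)
        assert shares["single_family_share"] == pytest.approx(2 / 3)
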