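import itertools

import numpy as np
import pytest

from semkit.align_io import MafRow, QualityAlignmentBlock
from semkit.indel_imputation import (
    IndelRegion,
    call_ls_indels,
    compress_columns,
    event_cost_matrix,
    event_cost_matrix_columnwise,
    extract_indel_regions,
    impute,
    parsimony_states,
)
from semkit.phylo_error import parse_newick

from conftest import brute_force_parsimony


def region_from(matrix, species=None, col_start=1):
    species = species or [f"sp{i}" for i in range(len(matrix))]
    r = IndelRegion(
        block_index=0,
        col_start=col_start,
        col_end=col_start + len(matrix[0]),
        species=list(species),
        matrix=list(matrix),
    )
    return compress_columns(r)


class TestExtractRegions:
    def _block(self, texts, quals=None, names=None):
        names = names or [f"sp{i}" for i in range(len(texts))]
        rows = []
        for i, t in enumerate(texts):
            size = sum(1 for c in t if c != "-")
            q = quals[i] if quals else None
            rows.append(MafRow(f"{names[i]}.c", 0, size, "+", size, t, quality=q))
        return QualityAlignmentBlock(rows=rows)

    def test_simple_region(self):
        block = self._block(["ACGTA", "AC--A", "ACGTA"])
        regions = list(extract_indel_regions([block], ["sp0", "sp1", "sp2"]))
        assert len(regions) == 1
        r = regions[0]
        assert (r.col_start, r.col_end) == (2, 4)
        assert r.matrix == ["11", "00", "11"]
        assert r.n == 1  # identical columns compress

    def test_long_gap_becomes_missing(self):
        t = "A" + "C" * 12 + "A"
        g = "A" + "-" * 12 + "A"
        block = self._block([t, g, t])
        (r,) = extract_indel_regions([block], ["sp0", "sp1", "sp2"])
        assert set(r.matrix[1]) == {"?"}

    def test_gapless_block_has_no_regions(self):
        block = self._block(["ACGTA", "ACGTA"])
        assert list(extract_indel_regions([block], ["sp0", "sp1"])) == []

    def test_absent_species_is_missing(self):
        block = self._block(["ACGTA", "AC-TA"])
        (r,) = extract_indel_regions([block], ["sp0", "sp1", "spX"])
        assert r.matrix[2] == "?"

    def test_wide_region_flagged_skipped(self):
        # alternate gap patterns -> many distinct columns
        rng = np.random.default_rng(0)
        width = 14
        texts = ["A" + "C" * width + "A"]
        for _ in range(4):
            texts.append(
                "A" + "".join(rng.choice(["C", "-"]) for _ in range(width)) + "A"
            )
        block = self._block(texts)
        regions = list(
            extract_indel_regions([block], [f"sp{i}" for i in range(5)])
        )
        assert any(r.skipped for r in regions) or all(r.n <= 10 for r in regions)


class TestCompression:
    def test_merges_adjacent_identical(self):
        r = region_from(["110", "110", "011"])  # columns: (1,1,0),(1,1,1),(0,0,1)
        # column strings per species; columns are (1,1,0),(1,1,1),(0,0,1)
        assert r.n == 3  # none identical here
        r2 = region_from(["1101", "1101", "0110"])
        assert r2.col_map is not None

    def test_identical_columns_compress_to_one(self):
        r = region_from(["111", "000", "111"])
        assert r.n == 1
        assert r.multiplicity == [3]

    def test_example_with_multiplicities(self):
        # species x columns: rows are per-species strings
        # columns: 101, 101, 110 -> compressed [101, 110], mult [2, 1]
        r = region_from(["110", "001", "110"])
        assert r.n == 2
        assert r.multiplicity == [2, 1]

    def test_distinct_columns_are_identity(self):
        r = region_from(["10", "01"])
        assert r.n == 2
        assert r.multiplicity == [1, 1]


class TestCostMatrix:
    def test_width_one(self):
        W = event_cost_matrix(1)
        assert W.tolist() == [[0, 1], [1, 0]]

    def test_single_deletion(self):
        W = event_cost_matrix(3)
        assert W[0b111, 0b101] == 1

    def test_sequence_contiguity_over_interior_gap(self):
        """101 -> 010 takes 2 events: the two 1s of 101 are sequence-adjacent
        (one deletion), then one insertion; per-column counting would say 3."""
        W = event_cost_matrix(3)
        assert W[0b101, 0b010] == 2
        assert event_cost_matrix_columnwise(3)[0b101, 0b010] == 3

    @pytest.mark.parametrize("n", range(1, 7))
    def test_metric_properties(self, n):
        W = event_cost_matrix(n)
        size = 1 << n
        assert np.all(np.diag(W) == 0)
        assert np.array_equal(W, W.T)
        # triangle inequality, exhaustively: W[i, j] <= W[i, k] + W[k, j]
        for i in range(size):
            assert np.all(W[i] <= (W[i][:, None] + W).min(axis=0))


class TestParsimony:
    TREES = [
        "((A:1,B:1):1,(C:1,D:1):1);",
        "(((A:1,B:1):1,C:1):1,(D:1,E:1):1);",
        "(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);",
    ]

    def test_forced_parent_single_deletion(self):
        tree = parse_newick(self.TREES[0])
        r = region_from(["0", "1", "1", "1"], species=list("ABCD"))
        states, cost = parsimony_states(r, tree)
        assert cost == 1
        # A's parent is forced to present
        assert states["node1"] == {1}

    def test_all_identical_is_free(self):
        tree = parse_newick(self.TREES[0])
        r = region_from(["1", "1", "1", "1"], species=list("ABCD"))
        states, cost = parsimony_states(r, tree)
        assert cost == 0
        assert all(s == {1} for s in states.values())

    def test_sister_deletion_is_shared_not_ls(self):
        tree = parse_newick(self.TREES[0])
        r = region_from(["0", "0", "1", "1"], species=list("ABCD"))
        states, cost = parsimony_states(r, tree)
        assert cost == 1
        assert 0 in states["node1"]  # parent admits the shared deletion

    @pytest.mark.parametrize("newick", TREES)
    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_matches_enumeration_oracle(self, newick, n):
        """Message passing equals exhaustive minimization over labelings."""
        tree = parse_newick(newick)
        leaves = tree.leaf_names()
        W = event_cost_matrix(n)
        rng = np.random.default_rng(13 + n)
        for _ in range(12):
            entries = {
                sp: "".join(rng.choice(list("01?"), size=n, p=[0.4, 0.5, 0.1]))
                for sp in leaves
            }
            matrix = [entries[sp] for sp in leaves]
            r = region_from(matrix, species=leaves)
            # compression may reduce the width below n; use the actual width
            states, cost = parsimony_states(r, tree, event_cost_matrix(r.n))
            want_cost, want_states = brute_force_parsimony(
                {sp: "".join(
                    entries[sp][j] for j in _compressed_cols(r)
                ) for sp in leaves},
                tree,
                event_cost_matrix(r.n),
            )
            assert cost == want_cost
            assert states == want_states

    def test_rooting_invariance_of_cost(self):
        """The minimum cost must not depend on where the tree is rooted."""
        r_matrix = ["10", "01", "11", "00"]
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_newick("(A:1,(B:1,(C:1,D:1):1):1);")
        r1 = region_from(r_matrix, species=list("ABCD"))
        r2 = region_from(r_matrix, species=list("ABCD"))
        _, c1 = parsimony_states(r1, t1)
        _, c2 = parsimony_states(r2, t2)
        assert c1 == c2

    def test_wide_region_refused(self):
        tree = parse_newick(self.TREES[0])
        r = region_from(["1", "1", "1", "1"], species=list("ABCD"))
        r.skipped = True
        with pytest.raises(ValueError):
            parsimony_states(r, tree)


def _compressed_cols(region):
    """Indices of one representative original column per compressed column."""
    seen = set()
    out = []
    for j, ci in enumerate(region.col_map):
        if ci not in seen:
            seen.add(ci)
            out.append(j)
    return out


class TestCallsAndImpute:
    def _quartet_block(self):
        # A carries a 2-bp insertion (cols 2-3) and a 1-bp deletion (col 6)
        texts = {
            "A": "ACTTGT-CA",
            "B": "AC--GTTCA",
            "C": "AC--GTTCA",
            "D": "AC--GTTCA",
        }
        rows = []
        for sp, t in texts.items():
            size = sum(1 for c in t if c != "-")
            q = None
            if sp == "A":
                q = "".join("-" if c == "-" else "2" for c in t)
            rows.append(MafRow(f"{sp}.c", 0, size, "+", size, t, quality=q))
        return QualityAlignmentBlock(rows=rows)

    def _calls(self, block, tree):
        calls = []
        for region in extract_indel_regions([block], tree.leaf_names()):
            states, _ = parsimony_states(region, tree)
            calls.extend(call_ls_indels(region, states, tree, block))
        return calls

    def test_ls_insertion_and_deletion_called(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        block = self._quartet_block()
        calls = self._calls(block, tree)
        kinds = {(c.species, c.kind, c.length) for c in calls}
        assert ("A", "insertion", 2) in kinds
        assert ("A", "deletion", 1) in kinds

    def test_ambiguous_parent_gives_no_call(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        r = region_from(["0", "0", "1", "1"], species=list("ABCD"))
        states, _ = parsimony_states(r, tree)
        block = self._quartet_block()
        calls = [
            c for c in call_ls_indels(r, states, tree, block) if c.species in "AB"
        ]
        assert calls == []  # shared deletion, not lineage-specific

    def test_low_quality_insertion_excised(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        block = self._quartet_block()
        calls = [c for c in self._calls(block, tree) if c.kind == "insertion"]
        edited, log = impute([block], calls, threshold=25)
        arow = edited[0].row("A")
        assert arow.size == block.row("A").size - 2
        assert len(log) == 1 and log[0]["action"] == "excise"
        # columns 2-3 became all-gap and were dropped
        assert edited[0].ncols == block.ncols - 2

    def test_low_quality_deletion_filled_with_n(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        block = self._quartet_block()
        calls = [c for c in self._calls(block, tree) if c.kind == "deletion"]
        edited, log = impute([block], calls, threshold=25)
        arow = edited[0].row("A")
        assert arow.text.count("N") == 1
        assert arow.size == block.row("A").size + 1
        assert arow.quality[arow.text.index("N")] == "0"
        assert edited[0].ncols == block.ncols  # geometry unchanged

    def test_high_quality_untouched(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        block = self._quartet_block()
        arow = block.row("A")
        arow.quality = arow.quality.replace("2", "9")
        calls = self._calls(block, tree)
        edited, log = impute([block], calls, threshold=25)
        assert log == []
        assert edited[0].row("A").text == block.row("A").text

    def test_fixed_point_after_imputation(self):
        """Re-extraction after imputation finds no remaining low-quality LS calls."""
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        block = self._quartet_block()
        calls = self._calls(block, tree)
        edited, _ = impute([block], calls, threshold=25)
        remaining = []
        for region in extract_indel_regions(edited, tree.leaf_names()):
            if region.skipped:
                continue
            states, _ = parsimony_states(region, tree)
            remaining.extend(
                c for c in call_ls_indels(region, states, tree, edited[0])
                if c.quality * 5 < 25 and c.species == "A"
            )
        assert remaining == []
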