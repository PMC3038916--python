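import io

import numpy as np
import pytest

from semkit.align_io import MafRow, QualityAlignmentBlock, read_regions
from semkit.error_assessment import (
    ConfusionCounts,
    DifferenceTable,
    IndelCall,
    collect_indel_calls,
    confusion_adjusted,
    exon_error_expectation,
    indel_length_spectrum,
    indel_quality,
    polymorphism_correct,
    roc_sweep,
    tabulate_differences,
)


def pair_block(ref_text, draft_text, draft_qual, ref_name="REF", draft_name="DRAFT"):
    rsize = sum(1 for c in ref_text if c != "-")
    dsize = sum(1 for c in draft_text if c != "-")
    return QualityAlignmentBlock(
        rows=[
            MafRow(f"{ref_name}.c", 0, rsize, "+", rsize, ref_text,
                   quality="".join("-" if c == "-" else "F" for c in ref_text)),
            MafRow(f"{draft_name}.c", 0, dsize, "+", dsize, draft_text,
                   quality=draft_qual),
        ]
    )


class TestTabulate:
    def test_single_mismatch_counted_at_draft_bin(self):
        block = pair_block("ACCTA", "ACGTA", "99999")
        t = tabulate_differences([block], "DRAFT", "REF")
        assert t.sites[9] == 5
        assert t.diffs["basecall"][9] == 1
        assert t.substitutions[("C", "G", 9)] == 1

    def test_gap_run_is_one_insertion_event(self):
        block = pair_block("AC--G", "ACTTG", "99229")
        t = tabulate_differences([block], "DRAFT", "REF")
        assert t.diffs["insertion"].sum() == 1
        # event binned by min over inserted + flanking draft bases
        assert t.diffs["insertion"][2] == 1

    def test_identity_has_no_diffs(self):
        block = pair_block("ACGTA", "ACGTA", "99999")
        t = tabulate_differences([block], "DRAFT", "REF")
        assert t.sites.sum() == 5
        for e in ("basecall", "insertion", "deletion"):
            assert t.diffs[e].sum() == 0

    def test_n_bases_excluded_everywhere(self):
        block = pair_block("ACGTA", "ANGTA", "99999")
        t = tabulate_differences([block], "DRAFT", "REF")
        assert t.sites.sum() == 4
        assert t.diffs["basecall"].sum() == 0

    def test_abutting_indel_runs_are_two_events(self):
        # insertion run (ref gaps) immediately followed by deletion run
        block = pair_block("A--CCG", "ATT--G", "933--9")
        t = tabulate_differences([block], "DRAFT", "REF")
        assert t.diffs["insertion"].sum() == 1
        assert t.diffs["deletion"].sum() == 1

    def test_missing_draft_quality_raises(self):
        block = pair_block("ACG", "ACG", "999")
        block.rows[1].quality = None
        with pytest.raises(ValueError):
            tabulate_differences([block], "DRAFT", "REF")

    def test_region_restriction_uses_reference_coordinates(self):
        block = pair_block("ACGTACGT", "ACGTACGA", "99999999")
        regions = read_regions(io.StringIO("REF.c\t0\t4\n"))
        t = tabulate_differences([block], "DRAFT", "REF", regions)
        assert t.sites.sum() == 4
        assert t.diffs["basecall"].sum() == 0  # mismatch at ref pos 7 is outside


class TestIndelQuality:
    def test_insertion_includes_inserted_bases(self):
        block = pair_block("AC--GTACG", "ACTTGTACG", "994423444")
        # inserted bins [4,4], flanks: left [9,9], right up to 5 -> min 2
        assert indel_quality(block, "DRAFT", 2, 4, "insertion") == 2

    def test_deletion_uses_flanks_only(self):
        block = pair_block("ACGTACG", "AC--ACG", "19--341")
        assert indel_quality(block, "DRAFT", 2, 4, "deletion") == 1

    def test_truncated_flank_at_block_edge(self):
        block = pair_block("TTACGTACG", "--ACGTACG", "--3456789")
        # deletion at columns 0-2: no left flank, right flank bins 3,4,5,6,7
        assert indel_quality(block, "DRAFT", 0, 2, "deletion") == 3


class TestPolymorphismCorrection:
    def test_aggregate_identity_from_published_rates(self):
        t = DifferenceTable.from_aggregate_rates(
            "hedgehog", {"basecall": (25.10, 23.71)}
        )
        corr = polymorphism_correct(t)
        agg = corr.aggregate[corr.aggregate["type"] == "basecall"].iloc[0]
        assert agg["raw"] == pytest.approx(25.10, abs=1e-9)
        assert agg["poly"] == pytest.approx(23.71, abs=1e-9)
        assert agg["corrected"] == pytest.approx(1.39, abs=0.01)

    def test_equal_rates_correct_to_zero(self):
        t = DifferenceTable.from_aggregate_rates("x", {"basecall": (2.0, 2.0)})
        corr = polymorphism_correct(t)
        assert corr.corrected_aggregate("basecall") == pytest.approx(0.0, abs=1e-12)

    def test_negative_rate_clamped_with_warning(self):
        t = DifferenceTable(species="x")
        t.sites[3] = 1000
        t.sites[9] = 1000
        t.diffs["basecall"][3] = 1.0  # 1.0/kb
        t.diffs["basecall"][9] = 1.5  # 1.5/kb
        with pytest.warns(UserWarning):
            corr = polymorphism_correct(t)
        assert corr.per_bin["basecall"][3] == 0.0

    def test_no_bin9_sites_flags_unavailable(self):
        t = DifferenceTable(species="x")
        t.sites[3] = 1000
        t.diffs["basecall"][3] = 5
        corr = polymorphism_correct(t)
        assert "basecall" in corr.unavailable

    def test_corr_equals_raw_minus_poly_on_any_tabulation(self):
        rng = np.random.default_rng(3)
        t = DifferenceTable(species="x")
        t.sites[:] = rng.integers(1000, 50000, 10)
        for e in ("basecall", "insertion", "deletion"):
            t.diffs[e][:] = rng.integers(5, 40, 10)
            t.diffs[e][9] = 0  # keep the aggregate correction positive
        corr = polymorphism_correct(t)
        for _, row in corr.aggregate.iterrows():
            assert row["corrected"] == pytest.approx(
                row["raw"] - row["poly"], abs=0.01
            )


class TestConfusionAdjusted:
    def test_all_masked_stratum(self):
        c = confusion_adjusted([(10, 990, 0, 0, 0.4)])
        assert c.tp == pytest.approx(6.0)
        assert c.fp == pytest.approx(994.0)
        assert c.fn == 0.0 and c.tn == 0.0

    def test_f_zero_reduces_to_raw_counts(self):
        c = confusion_adjusted([(7, 100, 3, 890, 0.0)])
        assert (c.tp, c.fp, c.fn, c.tn) == (7, 100, 3, 890)

    def test_nothing_masked(self):
        c = confusion_adjusted([(0, 0, 10, 990, 0.4)])
        assert c.fn == pytest.approx(6.0)
        assert c.tn == pytest.approx(994.0)

    def test_total_conserved_regardless_of_f(self):
        for f in (0.0, 0.3, 1.0, float("nan")):
            c = confusion_adjusted([(5, 45, 10, 940, f)])
            assert c.total == pytest.approx(1000.0)


class TestRocSweep:
    def _blocks(self):
        rng = np.random.default_rng(9)
        from semkit.synthetic_data import SimulationConfig, simulate_assembly

        cfg = SimulationConfig(seed=17, genome_length=8000)
        return [simulate_assembly(cfg).block]

    def test_extreme_thresholds(self):
        blocks = self._blocks()
        results = roc_sweep(blocks, "DRAFT", "REF", [0, 50], mode="mask")
        t0 = results[0][1]
        t50 = results[1][1]
        assert t0.tpr == pytest.approx(0.0, abs=1e-12)
        assert t0.fpr == pytest.approx(0.0, abs=1e-12)
        assert t50.tpr == pytest.approx(1.0, abs=1e-12)

    def test_tpr_fpr_monotone_in_threshold(self):
        blocks = self._blocks()
        results = roc_sweep(blocks, "DRAFT", "REF", [0, 10, 20, 30, 45], mode="mask")
        tprs = [c.tpr for _, c in results]
        fprs = [c.fpr for _, c in results]
        assert all(b >= a - 1e-12 for a, b in zip(tprs, tprs[1:]))
        assert all(b >= a - 1e-12 for a, b in zip(fprs, fprs[1:]))

    def test_indel_mode_runs_and_is_monotone(self):
        blocks = self._blocks()
        results = roc_sweep(blocks, "DRAFT", "REF", [0, 25, 50], mode="indel")
        tprs = [c.tpr for _, c in results]
        assert all(b >= a - 1e-12 for a, b in zip(tprs, tprs[1:]))

    def test_empty_thresholds_raises(self):
        with pytest.raises(ValueError):
            roc_sweep([], "DRAFT", "REF", [], mode="mask")


class TestExonExpectation:
    def test_uniform_rates_full_coverage(self):
        rates = {f"sp{i}": 1.0 for i in range(14)}
        cov = {sp: 1.0 for sp in rates}
        got = exon_error_expectation(rates, cov, exon_length=120)
        assert got == pytest.approx(0.12 * 14 * (20 / 14))

    def test_zero_rates(self):
        assert exon_error_expectation({"a": 0.0}, {"a": 1.0}) == 0.0

    def test_half_coverage_halves_expectation(self):
        rates = {"a": 2.0, "b": 3.0}
        full = exon_error_expectation(rates, {"a": 1.0, "b": 1.0})
        half = exon_error_expectation(rates, {"a": 0.5, "b": 0.5})
        assert half == pytest.approx(full / 2)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            exon_error_expectation({}, {})


class TestIndelSpectrum:
    def _call(self, length):
        return IndelCall("s", 0, 0, length, "insertion", length, 9)

    def test_periodicity(self):
        spec = indel_length_spectrum([self._call(l) for l in (3, 3, 6, 1)])
        assert spec.periodicity == pytest.approx(0.75)
        assert spec.counts[3] == 2 and spec.counts[6] == 1 and spec.counts[1] == 1

    def test_all_length_one(self):
        spec = indel_length_spectrum([self._call(1)] * 5)
        assert spec.periodicity == 0.0

    def test_empty_is_zero_histogram(self):
        spec = indel_length_spectrum([])
        assert spec.n_total == 0 and spec.periodicity == 0.0
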