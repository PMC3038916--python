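import numpy as np
import pytest
from scipy import stats

from semkit.coverage_model import CoverageModel, QualityDistribution
from semkit.synthetic_data import (
    SimulationConfig,
    default_single_read_profile,
    inject_errors,
    replay_truth,
    simulate_alignment,
    simulate_assembly,
)


class TestSimulateAssembly:
    def test_no_error_no_poly_gives_identical_rows(self):
        cfg = SimulationConfig(
            seed=1, genome_length=3000, polymorphism_rate=0.0,
            insertion_error_ratio=0.0, deletion_error_ratio=0.0,
            p1=QualityDistribution.point_mass(90),  # error prob 1e-9
        )
        sim = simulate_assembly(cfg)
        ref, draft = sim.block.rows
        assert ref.text == draft.text
        assert len(sim.truth) == 0

    def test_fixed_seed_is_bit_identical(self):
        a = simulate_assembly(SimulationConfig(seed=42, genome_length=2000))
        b = simulate_assembly(SimulationConfig(seed=42, genome_length=2000))
        assert a.block.rows[1].text == b.block.rows[1].text
        assert a.block.rows[1].quality == b.block.rows[1].quality
        assert a.truth.equals(b.truth)

    def test_invalid_coverage(self):
        with pytest.raises(ValueError):
            simulate_assembly(SimulationConfig(seed=0, coverage=0.0))

    def test_quality_distribution_matches_model(self):
        """Empirical summed qualities track the truncated-Poisson mixture."""
        cfg = SimulationConfig(
            seed=11, genome_length=100_000,
            insertion_error_ratio=0.0, deletion_error_ratio=0.0,
            polymorphism_rate=0.0,
        )
        sim = simulate_assembly(cfg)
        model = CoverageModel(cfg.p1, cfg.coverage)
        predicted = model.assembly_distribution()
        counts = np.bincount(sim.raw_qualities, minlength=predicted.pmf.size)
        empirical = counts / counts.sum()
        tv = 0.5 * np.abs(
            empirical[: predicted.pmf.size] - predicted.pmf[: empirical.size]
        ).sum()
        assert tv < 0.02

    def test_per_bin_error_rate_tracks_quality(self):
        """Injected error rates per bin follow 10**(-q/10) within 3 SE."""
        cfg = SimulationConfig(
            seed=13, genome_length=150_000, polymorphism_rate=0.0,
            insertion_error_ratio=0.0, deletion_error_ratio=0.0,
        )
        sim = simulate_assembly(cfg)
        q = sim.raw_qualities
        bins = np.minimum(np.minimum(q, 50) // 5, 9)
        errors = sim.truth[sim.truth.kind == "basecall_error"]
        for b in range(10):
            sel = bins == b
            n = int(sel.sum())
            if n < 500:
                continue
            expected_p = float(np.mean(10.0 ** (-q[sel] / 10.0)))
            observed = int((errors["bin"] == b).sum())
            se = np.sqrt(n * expected_p * (1 - expected_p))
            assert abs(observed - n * expected_p) < 3 * se + 3


class TestSimulateAlignment:
    def test_zero_indel_rate_is_gapless(self):
        cfg = SimulationConfig(seed=3, alignment_length=800, indel_sub_ratio=0.0)
        sim = simulate_alignment(cfg)
        assert all("-" not in r.text for r in sim.block.rows)
        assert len(sim.truth) == 0

    def test_zero_branch_lengths_identical_rows(self):
        cfg = SimulationConfig(
            seed=3, alignment_length=500,
            tree_newick="((A:0,B:0):0,(C:0,D:0):0);",
        )
        sim = simulate_alignment(cfg)
        texts = {r.text for r in sim.block.rows}
        assert len(texts) == 1

    def test_branch_indel_counts_near_expectation(self):
        cfg = SimulationConfig(seed=19, alignment_length=20_000, indel_sub_ratio=0.1)
        sim = simulate_alignment(cfg)
        from semkit.phylo_error import parse_newick

        tree = parse_newick(cfg.tree_newick)
        lengths = {l.name: l.length for l in tree.leaves()}
        for leaf, t in lengths.items():
            mean = cfg.indel_sub_ratio * t * cfg.alignment_length
            got = int((sim.truth["branch"] == leaf).sum())
            se = np.sqrt(mean)
            assert abs(got - mean) < 3 * se + 3

    def test_coding_mode_prefers_frame_lengths(self):
        cfg = SimulationConfig(
            seed=23, alignment_length=20_000, indel_sub_ratio=0.1,
            coding_mode=True, frame_fraction=0.9,
        )
        sim = simulate_alignment(cfg)
        lengths = sim.truth["length"].to_numpy()
        frac3 = float((lengths % 3 == 0).mean())
        assert frac3 > 0.7


class TestInjectErrors:
    def test_zero_rates_identity_with_high_qualities(self):
        cfg = SimulationConfig(
            seed=7, polymorphism_rate=0.0,
            insertion_error_ratio=0.0, deletion_error_ratio=0.0,
            p1=QualityDistribution.point_mass(90),
        )
        base = simulate_alignment(SimulationConfig(seed=5, alignment_length=1000))
        res = inject_errors(base.block, ["speciesA"], cfg)
        assert res.block.row("speciesA").text == base.block.row("speciesA").text
        q = res.block.row("speciesA").quality
        assert set(q) <= {"9", "-"}

    def test_truth_replay_restores_input_exactly(self):
        cfg = SimulationConfig(seed=29, alignment_length=3000)
        base = simulate_alignment(SimulationConfig(seed=31, alignment_length=3000))
        res = inject_errors(base.block, ["speciesA", "speciesB"], cfg)
        restored = replay_truth(res, ["speciesA", "speciesB"])
        for orig, back in zip(base.block.rows, restored.rows):
            assert back.text == orig.text
            assert back.size == orig.size
            assert back.quality == orig.quality

    def test_injected_rates_match_design(self):
        """Measured per-bin basecall error rates follow 10**(-q/10)."""
        cfg = SimulationConfig(seed=37, polymorphism_rate=0.0)
        base = simulate_alignment(
            SimulationConfig(seed=41, alignment_length=60_000, indel_sub_ratio=0.0)
        )
        res = inject_errors(base.block, ["speciesA"], cfg)
        truth = res.truth
        row = res.block.row("speciesA")
        bins = np.array([b for b in row.quality_bins() if b is not None])
        n = bins.size
        errors = truth[truth.kind == "basecall_error"]
        # total error count matches the coverage model's expectation
        p = CoverageModel(cfg.p1, cfg.coverage).expected_error()
        se = np.sqrt(n * p * (1 - p))
        assert abs(len(errors) - n * p) < 3 * se
        # and the per-bin error rate is decreasing in quality
        rates = []
        for b in range(10):
            nb = int((bins == b).sum())
            if nb >= 2000:
                rates.append(int((errors["bin"] == b).sum()) / nb)
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_determinism(self):
        base = simulate_alignment(SimulationConfig(seed=5, alignment_length=1500))
        cfg = SimulationConfig(seed=99)
        r1 = inject_errors(base.block, ["speciesA"], cfg)
        r2 = inject_errors(base.block, ["speciesA"], cfg)
        assert r1.block.row("speciesA").text == r2.block.row("speciesA").text
        assert r1.truth.equals(r2.truth)
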