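"""Depth profiles, masked normalization, region estimates, ploidy calls."""
import numpy as np
import pytest

from bitrexkit import depthcn
from bitrexkit.depthcn import (
    chromosome_ploidy,
    compute_depth,
    normalize_depth,
    region_copy_number,
    region_ratio,
)
from bitrexkit.synthetic_data import (
    ArraySpec,
    ReadSimParams,
    build_array_genome,
    inject_rearrangement,
    simulate_reads,
)


def masked_cn_pipeline(genome, depth=30.0, read_length=100, seed=0, bin_size=100):
    """Mask all but the first unit copy, normalize, estimate over the unit."""
    t = genome.truth
    reads = simulate_reads(
        genome,
        ReadSimParams(
            length_distribution="fixed", read_length=read_length, depth=depth, seed=seed
        ),
    )
    first_end = t.unit_intervals[0][1]
    mask = [(t.array_chrom, first_end, t.array_end)] if t.array_end > first_end else []
    excl = [(t.array_chrom, t.left_anchor[0], t.right_anchor[1])]
    profile = compute_depth(genome, reads=reads, bin_size=bin_size, mask_intervals=mask)
    norm = normalize_depth(profile, mask_intervals=mask, background_exclude=excl)
    cn = region_copy_number(norm, (t.array_chrom, *t.unit_intervals[0]))
    return norm, cn


class TestComputeDepth:
    def test_single_placement_covers_its_bases_only(self):
        chroms = [("c1", "A" * 1000)]
        profile = compute_depth(chroms, placements=[("c1", 0, 10)], bin_size=10)
        assert profile.values["c1"][0] == 1.0
        assert np.all(profile.values["c1"][1:] == 0.0)

    def test_empty_input_gives_all_zero_profile(self):
        profile = compute_depth([("c1", "A" * 500)], placements=[], bin_size=100)
        assert np.all(profile.values["c1"] == 0.0)

    def test_off_end_placement_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            profile = compute_depth(
                [("c1", "A" * 100)], placements=[("c1", 80, 150)], bin_size=100
            )
        assert profile.stats["placed_bases"] == 20

    def test_uniform_coverage_near_nominal_depth(self, small_genome):
        reads = simulate_reads(
            small_genome,
            ReadSimParams(length_distribution="fixed", read_length=100, depth=30.0, seed=3),
        )
        profile = compute_depth(small_genome, reads=reads)
        # mean over the extra (repeat-free) chromosome
        assert profile.values["chrB"].mean() == pytest.approx(30.0, rel=0.05)

    def test_binned_counts_conserve_placed_bases(self, small_genome):
        reads = simulate_reads(
            small_genome,
            ReadSimParams(length_distribution="fixed", read_length=73, depth=5.0, seed=4),
        )
        profile = compute_depth(small_genome, reads=reads, bin_size=97)
        total = sum(
            float(np.sum(profile.values[c] * profile.bin_widths(c)))
            for c in profile.values
        )
        assert total == pytest.approx(profile.stats["placed_bases"], abs=1e-6)


class TestNormalize:
    def test_uniform_profile_normalizes_to_one(self):
        chroms = [("c1", "A" * 1000)]
        placements = [("c1", i, i + 100) for i in range(0, 1000, 100)]
        profile = compute_depth(chroms, placements=placements)
        norm = normalize_depth(profile)
        assert np.allclose(norm.values["c1"], 1.0)

    def test_idempotent_within_fp(self, small_genome):
        norm, _ = masked_cn_pipeline(small_genome, depth=10.0, seed=5)
        t = small_genome.truth
        mask = [(t.array_chrom, t.unit_intervals[0][1], t.array_end)]
        excl = [(t.array_chrom, t.left_anchor[0], t.right_anchor[1])]
        again = normalize_depth(norm, mask_intervals=mask, background_exclude=excl)
        for c in norm.values:
            assert np.allclose(again.values[c], norm.values[c], atol=1e-12)

    def test_mask_covering_everything_rejected(self):
        profile = compute_depth([("c1", "A" * 500)], placements=[], bin_size=100)
        with pytest.raises(ValueError):
            normalize_depth(profile, mask_intervals=[("c1", 0, 500)])


class TestRegionEstimates:
    def test_background_region_reads_one(self, small_genome):
        norm, _ = masked_cn_pipeline(small_genome, seed=6)
        cn = region_copy_number(norm, ("chrB", 2000, 12000))
        assert cn.mean == pytest.approx(1.0, rel=0.1)

    def test_identical_regions_ratio_one(self, small_genome):
        norm, _ = masked_cn_pipeline(small_genome, seed=7)
        assert region_ratio(norm, ("chrB", 0, 5000), ("chrB", 0, 5000)) == 1.0

    def test_macrosatellite_style_region_ratio(self):
        """17-copy repeat vs single-copy flank: ratio reads the copy number."""
        g = build_array_genome(
            ArraySpec(n_units=17, unit_length=2000, flank_anchor_length=500),
            45000, seed=30,
        )
        norm, _ = masked_cn_pipeline(g, depth=30.0, seed=8)
        t = g.truth
        unit0 = t.unit_intervals[0]
        flank = (t.array_chrom, 1000, t.left_anchor[0] - 500)
        ratio = region_ratio(norm, (t.array_chrom, *unit0), flank)
        assert ratio == pytest.approx(17.0, rel=0.1)

    def test_single_bin_region_has_undefined_sd(self, small_genome):
        norm, _ = masked_cn_pipeline(small_genome, seed=9)
        cn = region_copy_number(norm, ("chrB", 0, 50))
        assert cn.n_bins == 1 and not cn.sd_defined and np.isnan(cn.sd)

    def test_fully_masked_region_rejected(self, small_genome):
        norm, _ = masked_cn_pipeline(small_genome, seed=10)
        t = small_genome.truth
        with pytest.raises(ValueError):
            region_copy_number(norm, (t.array_chrom, *t.unit_intervals[2]))


class TestMaskedCopyNumber:
    @pytest.mark.parametrize("n_units,seed", [(2, 0), (5, 1), (20, 2)])
    def test_recovers_simulated_copy_number(self, n_units, seed):
        g = build_array_genome(
            ArraySpec(n_units=n_units, unit_length=2000, flank_anchor_length=500),
            20000 + n_units * 2000, seed=40 + n_units,
        )
        _, cn = masked_cn_pipeline(g, depth=30.0, seed=seed)
        assert abs(cn.mean - n_units) / n_units <= 0.1


class TestPloidy:
    def test_clean_simulation_all_euploid(self, small_genome):
        norm, _ = masked_cn_pipeline(small_genome, seed=11)
        t = small_genome.truth
        excl = [(t.array_chrom, t.left_anchor[0], t.right_anchor[1])]
        calls = chromosome_ploidy(norm, excl)
        assert all(c.call == "euploid" for c in calls.values())

    def test_injected_gain_doubles_depth_and_is_called(self):
        # the gained chromosome is a minor fraction of the genome, so the
        # genome-wide normalization factor is only mildly inflated
        g = build_array_genome(
            ArraySpec(n_units=5, unit_length=400, flank_anchor_length=200),
            30000, seed=50, n_extra_chromosomes=1, extra_chromosome_length=5000,
        )
        g2 = inject_rearrangement(g, "chromosome_gain", seed=3)
        reads = simulate_reads(
            g2, ReadSimParams(length_distribution="fixed", read_length=100,
                              depth=30.0, seed=12),
        )
        t = g2.truth
        mask = [(t.array_chrom, t.unit_intervals[0][1], t.array_end)]
        excl = [(t.array_chrom, t.left_anchor[0], t.right_anchor[1])]
        profile = compute_depth(g2, reads=reads, mask_intervals=mask)
        norm = normalize_depth(profile, mask_intervals=mask, background_exclude=excl)
        calls = chromosome_ploidy(norm, excl)
        gained = g2.truth.rearrangements[0].details["chrom"]
        # raw depth on the gained chromosome is ~2x its single-copy value
        raw_gain = profile.values[gained].mean()
        raw_single = np.concatenate(
            [profile.values[t.array_chrom][:10], profile.values[t.array_chrom][-10:]]
        ).mean()
        assert raw_gain / raw_single == pytest.approx(2.0, rel=0.15)
        assert calls[gained].call == "gain"
        assert calls[t.array_chrom].call == "euploid"

    def test_threshold_boundary_is_euploid(self):
        profile = depthcn.DepthProfile(
            bin_size=100, lengths={"c1": 300},
            values={"c1": np.array([1.25, 1.25, 1.25])}, normalized=True,
        )
        assert chromosome_ploidy(profile)["c1"].call == "euploid"
        profile.values["c1"][:] = 1.26
        assert chromosome_ploidy(profile)["c1"].call == "gain"
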