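"""Anchor location, spanning selection, unit counting, bias correction."""
import numpy as np
import pytest

from bitrexkit import spanscan
from bitrexkit._kmer import revcomp
from bitrexkit.spanscan import (
    AscertainmentModel,
    bias_corrected_mean,
    copy_number_distribution,
    count_units,
    export_dotplot,
    hit_count_estimate,
    locate_anchor,
    select_spanning_reads,
)
from bitrexkit.synthetic_data import (
    ArraySpec,
    build_array_genome,
    mutate_substitutions,
    random_sequence,
    simulate_reads,
)

from conftest import spanning_reads_for


def substring_unit_count(read: str, unit: str) -> int:
    """Exhaustive sliding-window oracle: non-overlapping exact unit copies."""
    n, start = 0, 0
    while True:
        i = read.find(unit, start)
        if i < 0:
            return n
        n += 1
        start = i + len(unit)


class TestLocateAnchor:
    def setup_method(self):
        rng = np.random.default_rng(123)
        self.anchor = random_sequence(rng, 400)
        self.flanks = (random_sequence(rng, 300), random_sequence(rng, 350))

    def test_exact_substring_found_at_known_offset(self):
        read = self.flanks[0] + self.anchor + self.flanks[1]
        hit = locate_anchor(read, self.anchor)
        assert (hit.read_start, hit.read_end) == (300, 700)
        assert hit.strand == "+" and hit.identity == 1.0 and hit.complete

    def test_reverse_complement_read_mirrored(self):
        read = revcomp(self.flanks[0] + self.anchor + self.flanks[1])
        hit = locate_anchor(read, self.anchor)
        assert hit.strand == "-"
        assert (hit.read_start, hit.read_end) == (350, 750)
        assert hit.identity == 1.0

    def test_mutated_anchor_identity_tracks_truth(self):
        rng = np.random.default_rng(7)
        mutated = mutate_substitutions(self.anchor, 0.05, rng)
        n_subs = sum(a != b for a, b in zip(mutated, self.anchor))
        read = self.flanks[0] + mutated + self.flanks[1]
        hit = locate_anchor(read, self.anchor)
        assert hit is not None
        assert hit.identity == pytest.approx(1 - n_subs / 400, abs=0.01)

    def test_absent_anchor_returns_none(self):
        rng = np.random.default_rng(9)
        assert locate_anchor(random_sequence(rng, 2000), self.anchor) is None


class TestCountUnits:
    @pytest.mark.parametrize("n_units", [0, 1, 2, 3, 5, 8, 13, 21, 34, 50])
    def test_error_free_counts_match_substring_oracle(self, n_units):
        rng = np.random.default_rng(1000 + n_units)
        unit = random_sequence(rng, 300)
        read = (
            random_sequence(rng, 150) + unit * n_units + random_sequence(rng, 150)
        )
        res = count_units(read, unit)
        assert res.n_units == n_units == substring_unit_count(read, unit)

    def test_partial_terminal_units_follow_min_fraction(self):
        """A read covering 2.5 units counts 2 or 3 depending on the cutoff."""
        rng = np.random.default_rng(5)
        unit = random_sequence(rng, 400)
        read = unit[200:] + unit + unit  # 0.5 + 1 + 1 copies
        assert count_units(read, unit, min_unit_fraction=0.6).n_units == 2
        assert count_units(read, unit, min_unit_fraction=0.4).n_units == 3

    def test_inverted_copy_reported_on_minus_strand(self):
        rng = np.random.default_rng(6)
        unit = random_sequence(rng, 300)
        read = unit + revcomp(unit) + unit
        res = count_units(read, unit)
        strands = [s.strand for s in res.segments if s.accepted]
        assert strands == ["+", "-", "+"]
        assert res.n_units == 3

    def test_interrupted_array_counts_units_only(self):
        rng = np.random.default_rng(8)
        unit = random_sequence(rng, 300)
        spacer = random_sequence(rng, 500)
        read = unit + spacer + unit
        assert count_units(read, unit).n_units == 2

    def test_unit_shorter_than_minimum_rejected(self):
        with pytest.raises(ValueError):
            count_units("ACGT" * 100, "ACGTACGTAC")

    def test_study_scale_reads_with_errors_mostly_exact(self, study_genome):
        """14 x 2.0-kb units at 5% substitutions: >= 95% exact counts."""
        reads = spanning_reads_for(study_genome, 40, seed=71, error_rate=0.05)
        res = spanscan.genotype_spanning_reads(
            reads,
            study_genome.unit_sequence,
            study_genome.left_anchor_sequence,
            study_genome.right_anchor_sequence,
        )
        span = [r for r in res if r.spanning]
        assert len(span) >= 38
        exact = sum(1 for r in span if r.n_units == 14)
        assert exact / len(span) >= 0.95


class TestSelectSpanning:
    def test_selection_equals_truth_on_error_free_simulation(self, small_genome):
        from bitrexkit.synthetic_data import ReadSimParams

        reads = simulate_reads(
            small_genome,
            ReadSimParams(
                length_distribution="lognormal",
                log_mu=float(np.log(3500.0)),
                log_sigma=0.5,
                n_reads=400,
                seed=13,
            ),
        )
        res = select_spanning_reads(
            reads,
            small_genome.left_anchor_sequence,
            small_genome.right_anchor_sequence,
        )
        truth = {r.read_id: r.spans_array for r in reads}
        assert all(r.spanning == truth[r.read_id] for r in res)
        assert sum(r.spanning for r in res) > 10

    def test_read_missing_right_anchor_excluded(self, small_genome):
        chrom = small_genome.sequence("chrA")
        lo = small_genome.truth.left_anchor[0]
        hi = small_genome.truth.right_anchor[1]
        read = chrom[lo - 100 : hi - 150]  # truncates the right anchor
        (res,) = select_spanning_reads(
            [("r", read)],
            small_genome.left_anchor_sequence,
            small_genome.right_anchor_sequence,
        )
        assert not res.spanning

    def test_inverted_anchor_order_flagged_anomalous(self, small_genome):
        left = small_genome.left_anchor_sequence
        right = small_genome.right_anchor_sequence
        rng = np.random.default_rng(3)
        read = (
            random_sequence(rng, 100) + right + random_sequence(rng, 500)
            + left + random_sequence(rng, 100)
        )
        (res,) = select_spanning_reads([("r", read)], left, right)
        assert not res.spanning
        assert res.anomaly == "inverted_order"

    def test_identical_anchors_rejected(self):
        with pytest.raises(ValueError):
            select_spanning_reads([("r", "ACGT" * 100)], "A" * 40, "A" * 40)


class TestDistributionAndHits:
    def test_degenerate_histogram(self, small_genome):
        reads = spanning_reads_for(small_genome, 8, seed=2, margin=500)
        res = spanscan.genotype_spanning_reads(
            reads,
            small_genome.unit_sequence,
            small_genome.left_anchor_sequence,
            small_genome.right_anchor_sequence,
        )
        summary = copy_number_distribution(res)
        assert summary.histogram == {5: 8}
        assert summary.mode == summary.max == 5
        assert summary.n == 8

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            copy_number_distribution([])

    def test_hit_counts_on_partial_reads(self):
        rng = np.random.default_rng(14)
        unit = random_sequence(rng, 400)
        reads = [
            ("spanning", unit * 5),
            ("partial", unit[200:] + unit * 2),  # 2.5 copies
            ("absent", random_sequence(rng, 1500)),
        ]
        agg = hit_count_estimate(reads, unit)
        assert agg.per_read["spanning"] == 5
        assert agg.per_read["partial"] == 2  # the 0.5 terminal copy is below 0.6
        assert (
            hit_count_estimate(reads[:2], unit, min_unit_fraction=0.4).per_read["partial"]
            == 3
        )
        assert "absent" not in agg.per_read
        assert agg.max == 5 and agg.n_dropped == 1

    def test_all_reads_without_unit_rejected(self):
        rng = np.random.default_rng(15)
        unit = random_sequence(rng, 400)
        with pytest.raises(ValueError):
            hit_count_estimate([("x", random_sequence(rng, 1000))], unit)


class TestDotplot:
    def test_three_collinear_segments_and_match_recount(self):
        rng = np.random.default_rng(20)
        unit = random_sequence(rng, 300)
        read = unit * 3
        matches, segments = export_dotplot(read, unit)
        assert (segments["accepted"]).sum() == 3
        assert (segments["strand"] == "+").all()
        # row count equals the total number of k-mer matches found
        k = spanscan.DEFAULT_SEED_K
        from bitrexkit._kmer import KmerIndex, encode_kmers

        codes = encode_kmers(read, k)
        qf, _ = KmerIndex(unit, k).lookup(codes)
        qr, _ = KmerIndex(revcomp(unit), k).lookup(codes)
        assert len(matches) == qf.size + qr.size

    def test_inverted_copy_appears_on_minus_diagonal(self):
        rng = np.random.default_rng(21)
        unit = random_sequence(rng, 300)
        matches, segments = export_dotplot(unit + revcomp(unit), unit)
        assert set(matches["strand"]) == {"+", "-"}
        assert set(segments["strand"]) == {"+", "-"}


class TestAscertainment:
    def test_probability_decreasing_in_array_length(self):
        m = AscertainmentModel(
            genome_length=40000, anchor_length=250, unit_length=500,
            length_distribution="lognormal", log_mu=float(np.log(9000.0)),
            log_sigma=0.5,
        )
        p = [m.p_span_units(n) for n in range(1, 60)]
        assert all(a > b for a, b in zip(p, p[1:]))
        assert all(0 <= x <= 1 for x in p)

    def test_fixed_length_matches_start_enumeration(self):
        m = AscertainmentModel(
            genome_length=100, anchor_length=10, unit_length=10,
            length_distribution="fixed", read_length=50,
        )
        assert m.p_span_units(1) == pytest.approx(21 / 51)
        assert m.spanning_probability(200) == 0.0

    def test_empirical_fraction_matches_model(self, lognormal_reads):
        g = build_array_genome(
            ArraySpec(n_units=10, unit_length=500, flank_anchor_length=250),
            36000, seed=1,
        )
        params = lognormal_reads(12000, n_reads=2000, seed=8)
        reads = simulate_reads(g, params)
        frac = np.mean([r.spans_array for r in reads])
        model = AscertainmentModel.from_read_params(36000, 250, 500, params)
        p = model.p_span_units(10)
        assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / 2000)


class TestBiasCorrection:
    def _mixture_results(self, run, lognormal_reads):
        results = []
        for nu, s in ((10, 100 + run), (20, 200 + run)):
            g = build_array_genome(
                ArraySpec(n_units=nu, unit_length=500, flank_anchor_length=250),
                36000, seed=1000 + nu + run,
            )
            reads = simulate_reads(g, lognormal_reads(12000, n_reads=400, seed=s))
            res = spanscan.genotype_spanning_reads(
                reads, g.unit_sequence, g.left_anchor_sequence, g.right_anchor_sequence
            )
            results += [r for r in res if r.spanning]
        return results

    def test_equal_mixture_recovered_where_naive_is_biased_low(self, lognormal_reads):
        results = self._mixture_results(0, lognormal_reads)
        model = AscertainmentModel(
            genome_length=36000, anchor_length=250, unit_length=500,
            length_distribution="lognormal", log_mu=float(np.log(12000.0)),
            log_sigma=0.5,
        )
        est = bias_corrected_mean(results, model, n_bootstrap=400, seed=0)
        assert est.ci[0] <= 15.0 <= est.ci[1]
        assert est.naive_mean < est.ci[0]
        assert est.n_excluded == 0

    def test_single_allele_correction_is_identity(self, small_genome):
        reads = spanning_reads_for(small_genome, 10, seed=4, margin=400)
        res = spanscan.genotype_spanning_reads(
            reads, small_genome.unit_sequence,
            small_genome.left_anchor_sequence, small_genome.right_anchor_sequence,
        )
        model = AscertainmentModel(
            genome_length=8000, anchor_length=200, unit_length=400,
            length_distribution="fixed", read_length=4000,
        )
        est = bias_corrected_mean(res, model, n_bootstrap=100, seed=1)
        assert est.mean == pytest.approx(est.naive_mean)
        assert est.mean == pytest.approx(5.0)
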