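import numpy as np
import pytest

from bitrexkit.synthetic_data import ArraySpec, ReadSimParams, build_array_genome


@pytest.fixture(scope="session")
def small_genome():
    """5 x 400-bp units, 200-bp anchors, one extra chromosome."""
    spec = ArraySpec(n_units=5, unit_length=400, flank_anchor_length=200)
    return build_array_genome(spec, 8000, seed=11, n_extra_chromosomes=1)


@pytest.fixture(scope="session")
def study_genome():
    """The study geometry: 14 x 2.0-kb units with 1-kb anchors."""
    spec = ArraySpec(n_units=14, unit_length=2000, flank_anchor_length=1000)
    return build_array_genome(spec, 45000, seed=20, n_extra_chromosomes=1)


def spanning_reads_for(genome, n, seed, error_rate=0.0, margin=2000):
    """Slice guaranteed array-spanning reads with random flank margins."""
    rng = np.random.default_rng(seed)
    chrom = genome.sequence(genome.truth.array_chrom)
    lo, hi = genome.truth.left_anchor[0], genome.truth.right_anchor[1]
    from bitrexkit.synthetic_data import mutate_substitutions

    reads = []
    for i in range(n):
        a = int(rng.integers(0, min(margin, lo) + 1))
        b = int(rng.integers(0, min(margin, len(chrom) - hi) + 1))
        seq = mutate_substitutions(chrom[lo - a : hi + b], error_rate, rng)
        reads.append((f"span_{i}", seq))
    return reads


@pytest.fixture
def lognormal_reads():
    def make(median, sigma=0.5, n_reads=500, seed=0, error=0.0):
        return ReadSimParams(
            length_distribution="lognormal",
            log_mu=float(np.log(median)),
            log_sigma=sigma,
            n_reads=n_reads,
            substitution_error_rate=error,
            seed=seed,
        )

    return make
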