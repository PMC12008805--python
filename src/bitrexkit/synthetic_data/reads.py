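"""Long- and short-read simulation with per-read truth.

Emulates ligation-based nanopore sequencing (heavy-tailed lognormal lengths,
substitution errors, both strands) and Illumina-style fixed-length reads on
the same genome.  Reads start uniformly on a linear chromosome: a length-l
read on a length-L chromosome starts uniformly on [0, L-l] (reads longer
than the chromosome are truncated to it), so the number of start positions
yielding a read that spans a region is exactly enumerable — the basis of
the spanning-read ascertainment model.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._kmer import revcomp
from .genome import RepeatArrayGenome, mutate_substitutions

_LENGTH_DISTS = ("fixed", "lognormal")


@dataclass(frozen=True)
class ReadSimParams:
    """Read-length distribution, yield, and error model.

    Exactly one of ``n_reads`` / ``depth`` must be set; ``depth`` is mean
    per-base coverage and is converted using the expected read length.
    """

    length_distribution: str = "lognormal"
    read_length: int = 1000  # fixed mode
    log_mu: float = float(np.log(20000.0))  # lognormal mode, log-bp
    log_sigma: float = 0.6
    n_reads: int | None = None
    depth: float | None = None
    substitution_error_rate: float = 0.0
    both_strands: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.length_distribution not in _LENGTH_DISTS:
            raise ValueError(f"length_distribution must be one of {_LENGTH_DISTS}")
        if not 0.0 <= self.substitution_error_rate <= 1.0:
            raise ValueError("substitution_error_rate must be in [0, 1]")
        if (self.n_reads is None) == (self.depth is None):
            raise ValueError("set exactly one of n_reads / depth")
        if self.n_reads is not None and self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.depth is not None and self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.length_distribution == "fixed" and self.read_length < 1:
            raise ValueError("read_length must be >= 1")

    @property
    def mean_length(self) -> float:
        if self.length_distribution == "fixed":
            return float(self.read_length)
        return float(np.exp(self.log_mu + 0.5 * self.log_sigma**2))


@dataclass
class SimRead:
    """One simulated read plus its truth.

    ``start``/``end`` are the source interval on the forward strand of
    ``chrom``; minus-strand reads store the reverse-complemented sequence.
    ``spans_array`` is True iff the source interval fully contains the array
    and both flank anchors.
    """

    read_id: str
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    spans_array: bool


def _draw_lengths(params: ReadSimParams, n: int, rng: np.random.Generator) -> np.ndarray:
    if params.length_distribution == "fixed":
        return np.full(n, params.read_length, dtype=np.int64)
    lengths = np.rint(rng.lognormal(params.log_mu, params.log_sigma, size=n)).astype(np.int64)
    bad = lengths < 1
    for _ in range(100):
        if not bad.any():
            break
        lengths[bad] = np.rint(
            rng.lognormal(params.log_mu, params.log_sigma, size=int(bad.sum()))
        ).astype(np.int64)
        bad = lengths < 1
    if (lengths < 1).any():
        raise ValueError("length distribution keeps producing non-positive lengths")
    return lengths


def simulate_reads(genome: RepeatArrayGenome, params: ReadSimParams) -> list[SimRead]:
    """Sample reads with uniform starts per chromosome; return reads + truth."""
    chroms = genome.chromosomes
    if not chroms or genome.total_length() == 0:
        raise ValueError("genome is empty")
    rng = np.random.default_rng(params.seed)

    if params.n_reads is not None:
        n = params.n_reads
    else:
        n = int(np.ceil(params.depth * genome.total_length() / params.mean_length))

    lengths = _draw_lengths(params, n, rng)
    clens = np.array([len(s) for _, s in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n, p=clens / clens.sum())
    span_chrom, span_lo, span_hi = genome.spanning_region

    reads: list[SimRead] = []
    for i in range(n):
        name, seq = chroms[chrom_idx[i]]
        L = len(seq)
        ell = int(min(lengths[i], L))
        start = int(rng.integers(0, L - ell + 1))
        end = start + ell
        strand = "+"
        if params.both_strands and rng.random() < 0.5:
            strand = "-"
        spans = name == span_chrom and start <= span_lo and end >= span_hi
        s = seq[start:end]
        if strand == "-":
            s = revcomp(s)
        s = mutate_substitutions(s, params.substitution_error_rate, rng)
        reads.append(SimRead(f"read_{i:06d}", s, name, start, end, strand, spans))
    return reads


def reads_truth_frame(reads: list[SimRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "chrom": [r.chrom for r in reads],
            "start": [r.start for r in reads],
            "end": [r.end for r in reads],
            "strand": [r.strand for r in reads],
            "spans_array": [r.spans_array for r in reads],
        }
    )
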