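"""Synthetic genomes carrying a tandem gene array with unique flank anchors.

The generated locus mimics a gene-sized tandem repeat (e.g. the yeast CUP1
array of ~2.0-kb units, or a two-unit array interrupted by an integrated
plasmid backbone): ``n_units`` identical (or slightly diverged) copies of a
repeat unit, optionally separated by an intervening segment, embedded in
random single-copy background with 1-kb unique anchor sequences immediately
flanking the array.  Every downstream stage (spanning-read genotyping,
masked-depth copy number, rearrangement screening) is validated against the
truth tables emitted here.
"""
from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .._kmer import _CODE
from .. import io as _io

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. per-base substitutions at the given rate (never to self)."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        codes = _CODE[arr[hits]]
        new_codes = (codes + rng.integers(1, 4, size=hits.size)) % 4
        arr[hits] = _BASES[new_codes]
    return arr.tobytes().decode("ascii")


@dataclass(frozen=True)
class ArraySpec:
    """Declarative geometry of a tandem array locus.

    ``realized length = n_units*unit_length + max(n_units-1, 0)*intervening_length``.
    ``locus_offset`` is the 0-based array start on its chromosome; ``None``
    centres the array at build time.
    """

    n_units: int
    unit_length: int = 2000
    intervening_length: int = 0
    flank_anchor_length: int = 1000
    unit_divergence_rate: float = 0.0
    locus_offset: int | None = None

    def __post_init__(self):
        if self.n_units < 0:
            raise ValueError("n_units must be >= 0")
        if self.unit_length < 1:
            raise ValueError("unit_length must be >= 1")
        if self.intervening_length < 0:
            raise ValueError("intervening_length must be >= 0")
        if self.flank_anchor_length < 1:
            raise ValueError("flank_anchor_length must be >= 1")
        if not 0.0 <= self.unit_divergence_rate <= 1.0:
            raise ValueError("unit_divergence_rate must be in [0, 1]")

    @property
    def realized_length(self) -> int:
        return self.n_units * self.unit_length + max(self.n_units - 1, 0) * self.intervening_length


@dataclass
class RearrangementRecord:
    kind: str
    details: dict


@dataclass
class GenomeTruth:
    """Exact construction-time annotations, in clean-reference coordinates."""

    array_chrom: str
    array_start: int
    array_end: int
    unit_intervals: list[tuple[int, int]]
    left_anchor: tuple[int, int]
    right_anchor: tuple[int, int]
    unit_sequence: str
    intervening_sequence: str
    rearrangements: list[RearrangementRecord] = field(default_factory=list)
    gained_chromosomes: list[str] = field(default_factory=list)


@dataclass
class RepeatArrayGenome:
    """A realized genome plus the truth needed to score every estimator.

    ``chromosomes`` is the *simulation* genome (reads are drawn from it);
    :meth:`reference_chromosomes` is the analysis reference, which excludes
    whole-chromosome duplicates introduced by ``chromosome_gain`` so that
    aneuploidy manifests as doubled depth rather than multi-mapping.
    Truth coordinates always refer to the clean (pre-rearrangement) reference.
    """

    chromosomes: list[tuple[str, str]]
    spec: ArraySpec
    truth: GenomeTruth
    seed: int

    def sequence(self, name: str) -> str:
        for n, s in self.chromosomes:
            if n == name:
                return s
        raise KeyError(name)

    @property
    def array_locus(self) -> tuple[str, int, int]:
        return (self.truth.array_chrom, self.truth.array_start, self.truth.array_end)

    @property
    def spanning_region(self) -> tuple[str, int, int]:
        """Array plus both full anchors: what a spanning read must contain."""
        return (
            self.truth.array_chrom,
            self.truth.left_anchor[0],
            self.truth.right_anchor[1],
        )

    @property
    def left_anchor_sequence(self) -> str:
        s, e = self.truth.left_anchor
        return self.sequence(self.truth.array_chrom)[s:e]

    @property
    def right_anchor_sequence(self) -> str:
        s, e = self.truth.right_anchor
        return self.sequence(self.truth.array_chrom)[s:e]

    @property
    def unit_sequence(self) -> str:
        return self.truth.unit_sequence

    def reference_chromosomes(self) -> list[tuple[str, str]]:
        gained = set(self.truth.gained_chromosomes)
        return [(n, s) for n, s in self.chromosomes if n not in gained]

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.chromosomes)

    # ---- persistence -------------------------------------------------
    def write_fasta(self, path) -> None:
        _io.write_fasta(self.chromosomes, path)

    def write_truth_bed(self, path) -> None:
        c = self.truth.array_chrom
        rows = [(c, s, e, f"unit_{i}") for i, (s, e) in enumerate(self.truth.unit_intervals)]
        rows.append((c, *self.truth.left_anchor, "left_anchor"))
        rows.append((c, *self.truth.right_anchor, "right_anchor"))
        _io.write_bed(rows, path)

    def write_truth_json(self, path) -> None:
        payload = {
            "spec": dataclasses.asdict(self.spec),
            "seed": self.seed,
            "truth": {
                "array_chrom": self.truth.array_chrom,
                "array_start": self.truth.array_start,
                "array_end": self.truth.array_end,
                "unit_intervals": self.truth.unit_intervals,
                "left_anchor": self.truth.left_anchor,
                "right_anchor": self.truth.right_anchor,
                "unit_sequence": self.truth.unit_sequence,
                "intervening_sequence": self.truth.intervening_sequence,
                "rearrangements": [dataclasses.asdict(r) for r in self.truth.rearrangements],
                "gained_chromosomes": self.truth.gained_chromosomes,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def load_genome(fasta_path, truth_json_path) -> RepeatArrayGenome:
    """Rebuild a RepeatArrayGenome from its FASTA + truth JSON pair."""
    chroms = _io.read_fasta(fasta_path)
    with open(truth_json_path) as fh:
        payload = json.load(fh)
    t = payload["truth"]
    truth = GenomeTruth(
        array_chrom=t["array_chrom"],
        array_start=t["array_start"],
        array_end=t["array_end"],
        unit_intervals=[tuple(iv) for iv in t["unit_intervals"]],
        left_anchor=tuple(t["left_anchor"]),
        right_anchor=tuple(t["right_anchor"]),
        unit_sequence=t["unit_sequence"],
        intervening_sequence=t["intervening_sequence"],
        rearrangements=[RearrangementRecord(**r) for r in t["rearrangements"]],
        gained_chromosomes=list(t["gained_chromosomes"]),
    )
    return RepeatArrayGenome(
        chromosomes=chroms,
        spec=ArraySpec(**payload["spec"]),
        truth=truth,
        seed=payload["seed"],
    )


def _count_occurrences(haystack: str, needle: str) -> int:
    n, start = 0, 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def build_array_genome(
    spec: ArraySpec,
    background_length: int,
    seed: int,
    *,
    n_extra_chromosomes: int = 0,
    extra_chromosome_length: int = 20000,
    chromosome_name: str = "chrA",
) -> RepeatArrayGenome:
    """Embed a tandem array in random background and return genome + truth.

    The chromosome has length ``background_length`` with the array written
    over ``[offset, offset+realized_length)``; the flank anchors are the
    ``flank_anchor_length`` bases immediately outside the array.  Anchor
    sequences are checked to occur exactly once in the whole genome; the
    construction is re-drawn up to 10 times before raising.
    """
    a = spec.flank_anchor_length
    realized = spec.realized_length
    if background_length <= realized + 2 * a:
        raise ValueError("background_length must exceed realized array length plus both anchors")

    offset = spec.locus_offset
    if offset is None:
        offset = (background_length - realized) // 2
    if offset < a or offset + realized + a > background_length:
        raise ValueError("locus_offset leaves no room for a flank anchor")

    rng = np.random.default_rng(seed)
    for _attempt in range(10):
        unit = random_sequence(rng, spec.unit_length)
        intervening = (
            random_sequence(rng, spec.intervening_length) if spec.intervening_length else ""
        )
        parts, unit_intervals = [], []
        pos = offset
        for i in range(spec.n_units):
            if i > 0 and intervening:
                parts.append(intervening)
                pos += len(intervening)
            copy_seq = mutate_substitutions(unit, spec.unit_divergence_rate, rng)
            parts.append(copy_seq)
            unit_intervals.append((pos, pos + spec.unit_length))
            pos += spec.unit_length
        array_seq = "".join(parts)
        assert len(array_seq) == realized

        background = random_sequence(rng, background_length)
        chrom = background[:offset] + array_seq + background[offset + realized :]
        chromosomes = [(chromosome_name, chrom)]
        for j in range(n_extra_chromosomes):
            chromosomes.append(
                (f"chr{chr(ord('B') + j)}", random_sequence(rng, extra_chromosome_length))
            )

        left_anchor = chrom[offset - a : offset]
        right_anchor = chrom[offset + realized : offset + realized + a]
        hits = sum(_count_occurrences(s, left_anchor) for _, s in chromosomes)
        hits_r = sum(_count_occurrences(s, right_anchor) for _, s in chromosomes)
        if hits == 1 and hits_r == 1 and left_anchor != right_anchor:
            truth = GenomeTruth(
                array_chrom=chromosome_name,
                array_start=offset,
                array_end=offset + realized,
                unit_intervals=unit_intervals,
                left_anchor=(offset - a, offset),
                right_anchor=(offset + realized, offset + realized + a),
                unit_sequence=unit,
                intervening_sequence=intervening,
            )
            return RepeatArrayGenome(
                chromosomes=chromosomes, spec=spec, truth=truth, seed=seed
            )
    raise RuntimeError("could not construct genome with unique flank anchors in 10 draws")


_REARRANGEMENT_KINDS = ("translocation", "ectopic_circle", "chromosome_gain")


def inject_rearrangement(
    genome: RepeatArrayGenome,
    kind: str,
    seed: int,
    *,
    circle_units: int = 2,
    target_chromosome: str | None = None,
) -> RepeatArrayGenome:
    """Engineer a rearrangement into a copy of ``genome``; truth records it.

    translocation     reciprocal exchange at the array 3' end with a partner
                      chromosome, so reads running off the array continue
                      into partner sequence.
    ectopic_circle    a circle of ``circle_units`` repeat units integrated at
                      a random non-array site on a partner chromosome.
    chromosome_gain   whole-chromosome duplication (default: the partner
                      chromosome; the array chromosome if none exists).
    """
    if kind not in _REARRANGEMENT_KINDS:
        raise ValueError(f"unknown rearrangement kind {kind!r}")
    rng = np.random.default_rng(seed)
    g = copy.deepcopy(genome)
    chrom_names = [n for n, _ in g.chromosomes]
    partners = [n for n in chrom_names if n != g.truth.array_chrom]

    if kind in ("translocation", "ectopic_circle") and not partners:
        raise ValueError(f"{kind} requires a genome with >= 2 chromosomes")

    def _set(name: str, seq: str) -> None:
        for i, (n, _) in enumerate(g.chromosomes):
            if n == name:
                g.chromosomes[i] = (n, seq)
                return
        g.chromosomes.append((name, seq))

    if kind == "translocation":
        partner = target_chromosome or partners[0]
        a_seq = g.sequence(g.truth.array_chrom)
        b_seq = g.sequence(partner)
        pos_a = g.truth.array_end
        pos_b = int(rng.integers(len(b_seq) // 4, 3 * len(b_seq) // 4))
        _set(g.truth.array_chrom, a_seq[:pos_a] + b_seq[pos_b:])
        _set(partner, b_seq[:pos_b] + a_seq[pos_a:])
        g.truth.rearrangements.append(
            RearrangementRecord(
                kind="translocation",
                details={
                    "chrom_a": g.truth.array_chrom,
                    "breakpoint_a": pos_a,
                    "chrom_b": partner,
                    "breakpoint_b": pos_b,
                },
            )
        )
    elif kind == "ectopic_circle":
        if circle_units < 1:
            raise ValueError("circle_units must be >= 1")
        partner = target_chromosome or partners[0]
        b_seq = g.sequence(partner)
        margin = min(1000, len(b_seq) // 4)
        pos = int(rng.integers(margin, len(b_seq) - margin))
        circle = g.truth.unit_sequence * circle_units
        _set(partner, b_seq[:pos] + circle + b_seq[pos:])
        g.truth.rearrangements.append(
            RearrangementRecord(
                kind="ectopic_circle",
                details={
                    "chrom": partner,
                    "position": pos,
                    "n_units": circle_units,
                    "length": len(circle),
                },
            )
        )
    else:  # chromosome_gain
        target = target_chromosome or (partners[0] if partners else g.truth.array_chrom)
        dup_name = f"{target}_gain"
        _set(dup_name, g.sequence(target))
        g.truth.gained_chromosomes.append(dup_name)
        g.truth.rearrangements.append(
            RearrangementRecord(
                kind="chromosome_gain", details={"chrom": target, "duplicate": dup_name}
            )
        )
    return g
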