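"""Internal unique-placement read mapper for synthetic genomes.

Seed-and-verify: probe k-mers vote for candidate diagonals, candidates are
verified by exact comparison (then edlib within an edit budget), and a read
is placed only when a single best placement remains — multi-mapping reads
are reported as ambiguous, never silently assigned.  Masked reference
intervals are written as 'N' before indexing, so reads drawn from a masked
duplicate place uniquely on the retained copy, and reads crossing a masked
boundary fail verification and drop out.
"""
from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from ._kmer import KmerIndex, encode_kmers, revcomp


def as_chromosomes(obj) -> list[tuple[str, str]]:
    """Accept RepeatArrayGenome, dict, or (name, seq) list."""
    if hasattr(obj, "reference_chromosomes"):
        return obj.reference_chromosomes()
    if isinstance(obj, dict):
        return list(obj.items())
    return list(obj)


def apply_mask(chromosomes, intervals) -> list[tuple[str, str]]:
    """Replace masked intervals with 'N' (0-based half-open per chromosome)."""
    if not intervals:
        return list(chromosomes)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    out = []
    for name, seq in chromosomes:
        ivs = by_chrom.get(name)
        if not ivs:
            out.append((name, seq))
            continue
        arr = bytearray(seq, "ascii")
        for s, e in ivs:
            s, e = max(0, s), min(len(arr), e)
            arr[s:e] = b"N" * (e - s)
        out.append((name, arr.decode("ascii")))
    return out


@dataclass
class Placement:
    chrom: str
    start: int
    end: int
    strand: str
    edits: int


class GenomeIndex:
    """K-mer index over a concatenated genome for unique best placement."""

    def __init__(self, chromosomes, k: int = 21):
        self.k = k
        self.chromosomes = as_chromosomes(chromosomes)
        self._names = [n for n, _ in self.chromosomes]
        self._seqs = [s for _, s in self.chromosomes]
        sep = "N" * k
        offsets = []
        pos = 0
        parts = []
        for s in self._seqs:
            offsets.append(pos)
            parts.append(s)
            pos += len(s) + len(sep)
            parts.append(sep)
        self._offsets = np.array(offsets, dtype=np.int64)
        self._lengths = np.array([len(s) for s in self._seqs], dtype=np.int64)
        self._index = KmerIndex("".join(parts), k)

    def _locate(self, gpos: int) -> tuple[int, int]:
        ci = int(np.searchsorted(self._offsets, gpos, side="right") - 1)
        return ci, gpos - int(self._offsets[ci])

    def _candidates(self, seq: str, n_probes: int) -> dict[int, int]:
        codes = encode_kmers(seq, self.k)
        if codes.size == 0:
            return {}
        probes = np.unique(np.linspace(0, codes.size - 1, n_probes).astype(np.int64))
        qpos, rpos = self._index.lookup(codes[probes])
        votes: dict[int, int] = {}
        for q, rp in zip(probes[qpos], rpos):
            g = int(rp) - int(q)
            votes[g] = votes.get(g, 0) + 1
        return votes

    def place(
        self,
        seq: str,
        *,
        max_edit_frac: float = 0.1,
        n_probes: int = 8,
        max_candidates: int = 40,
    ) -> tuple[str, Placement | None]:
        """Place a sequence; returns (status, placement).

        status is 'mapped', 'ambiguous' (several equally good placements) or
        'unmapped'.  Verification is exact first, then edlib bounded at
        ``max_edit_frac * len(seq)`` edits.
        """
        max_edits = int(max_edit_frac * len(seq))
        verified: dict[tuple[str, int, str], int] = {}
        for strand in ("+", "-"):
            s = seq if strand == "+" else revcomp(seq)
            votes = self._candidates(s, n_probes)
            ranked = sorted(votes.items(), key=lambda kv: -kv[1])[:max_candidates]
            for g, _v in ranked:
                ci, pos = self._locate(g)
                ref = self._seqs[ci]
                if pos < 0 or pos + len(s) > len(ref):
                    continue
                target = ref[pos : pos + len(s)]
                if target == s:
                    edits = 0
                else:
                    edits = edlib.align(s, target, mode="NW", k=max_edits)["editDistance"]
                    if edits < 0:
                        continue
                key = (self._names[ci], pos, strand)
                if key not in verified or edits < verified[key]:
                    verified[key] = edits
        if not verified:
            return "unmapped", None
        best = min(verified.values())
        winners = [kk for kk, vv in verified.items() if vv == best]
        if len(winners) > 1:
            return "ambiguous", None
        chrom, pos, strand = winners[0]
        return "mapped", Placement(chrom, pos, pos + len(seq), strand, best)
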