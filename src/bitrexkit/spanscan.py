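"""Spanning-read selection and per-read repeat-unit counting.

A long read spans the array when it contains both unique 1-kb flank
anchors; the number of repeat units it carries is then counted from the
collinear diagonal segments formed by exact k-mer matches between the read
and the unit reference — an automated version of counting diagonals on a
read-vs-unit dot plot.  Because longer arrays fit inside fewer reads,
spanning-read histograms under-represent long alleles; the ascertainment
model quantifies P(span | array length) under the read-length distribution
and drives the length-bias-corrected population mean.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from ._kmer import KmerIndex, encode_kmers, revcomp

DEFAULT_SEED_K = 15
_EDGE_PAD = 30


@dataclass
class AnchorHit:
    """Best placement of a flank anchor on a read.

    ``read_start``/``read_end`` are 0-based half-open on the read as given;
    ``strand`` is '-' when the anchor matches the reverse complement.
    ``complete`` marks hits whose alignment is not clipped by a read edge
    (or matches exactly despite abutting one).
    """

    read_start: int
    read_end: int
    ref_offset: int
    strand: str
    identity: float
    chain_score: int
    complete: bool


@dataclass
class UnitSegment:
    """One maximal diagonal: a (partial) unit copy on the read."""

    read_start: int
    read_end: int
    unit_start: int
    unit_end: int
    strand: str
    coverage: float
    accepted: bool


@dataclass
class SpanningReadResult:
    read_id: str
    left: AnchorHit | None = None
    right: AnchorHit | None = None
    segments: list[UnitSegment] = field(default_factory=list)
    n_units: int = 0
    spanning: bool = False
    anomaly: str | None = None


class _MultiRefIndex:
    """One k-mer index over several references joined by 'N' separators."""

    def __init__(self, refs: list[tuple[str, str, str]], k: int):
        # refs: (name, strand, sequence); '-' entries hold the reverse
        # complement so read-forward k-mers match them directly
        self.k = k
        sep = "N" * k
        parts, self.bounds = [], []
        pos = 0
        for name, strand, seq in refs:
            self.bounds.append((pos, pos + len(seq), name, strand, seq))
            parts.append(seq)
            parts.append(sep)
            pos += len(seq) + k
        self.index = KmerIndex("".join(parts), k)

    def lookup_split(self, codes: np.ndarray):
        """Yield (name, strand, ref_seq, read_pos[], ref_pos[]) per reference."""
        qpos, rpos = self.index.lookup(codes)
        for lo, hi, name, strand, seq in self.bounds:
            sel = (rpos >= lo) & (rpos < hi)
            if sel.any():
                yield name, strand, seq, qpos[sel], rpos[sel] - lo


def _refine_anchor(
    read: str,
    qpos: np.ndarray,
    upos: np.ndarray,
    query_seq: str,
    strand: str,
    min_identity: float,
) -> AnchorHit | None:
    """Best-diagonal refinement of anchor seed matches via infix alignment.

    ``query_seq`` is the anchor on the strand that matches the read
    directly, so the refined interval is in raw read coordinates.
    """
    diag = qpos - upos
    vals, counts = np.unique(diag, return_counts=True)
    best = int(vals[np.argmax(counts)])  # max chain score, leftmost tie-break
    score = int(counts.max())
    window_start = max(0, best - _EDGE_PAD)
    window = read[window_start : best + len(query_seq) + _EDGE_PAD]
    res = edlib.align(query_seq, window, mode="HW", task="locations")
    dist = res["editDistance"]
    loc = res["locations"][0]
    rs, re = window_start + loc[0], window_start + loc[1] + 1
    identity = 1.0 - dist / len(query_seq)
    if identity < min_identity:
        return None
    complete = (rs > 0 and re < len(read)) or dist == 0
    return AnchorHit(rs, re, 0, strand, identity, score, complete)


class AnchorPairLocator:
    """Locate a left/right anchor pair on many reads with one index."""

    def __init__(self, left_anchor: str, right_anchor: str, k: int = DEFAULT_SEED_K):
        if len(left_anchor) < k or len(right_anchor) < k:
            raise ValueError("anchors must be at least k bases long")
        self._multi = _MultiRefIndex(
            [
                ("left", "+", left_anchor),
                ("right", "+", right_anchor),
                ("left", "-", revcomp(left_anchor)),
                ("right", "-", revcomp(right_anchor)),
            ],
            k,
        )

    def locate(
        self, read: str, min_identity: float = 0.8, codes: np.ndarray | None = None
    ) -> dict[str, AnchorHit | None]:
        if codes is None:
            codes = encode_kmers(read, self._multi.k)
        best: dict[str, AnchorHit | None] = {"left": None, "right": None}
        for name, strand, seq, qpos, upos in self._multi.lookup_split(codes):
            hit = _refine_anchor(read, qpos, upos, seq, strand, min_identity)
            if hit is None:
                continue
            cur = best[name]
            if cur is None or (hit.chain_score, hit.identity) > (cur.chain_score, cur.identity):
                best[name] = hit
        return best


def locate_anchor(
    read: str, anchor_sequence: str, min_identity: float = 0.8, k: int = DEFAULT_SEED_K
) -> AnchorHit | None:
    """Seed-and-chain placement of an anchor on either strand of a read.

    Exact k-mer seeds vote for diagonals; the best diagonal (highest seed
    count, then leftmost) is refined by an infix edlib alignment of the full
    anchor.  Returns None below ``min_identity``.
    """
    if len(anchor_sequence) < k:
        raise ValueError("anchor must be at least k bases long")
    multi = _MultiRefIndex(
        [("a", "+", anchor_sequence), ("a", "-", revcomp(anchor_sequence))], k
    )
    best: AnchorHit | None = None
    codes = encode_kmers(read, k)
    for _name, strand, seq, qpos, upos in multi.lookup_split(codes):
        hit = _refine_anchor(read, qpos, upos, seq, strand, min_identity)
        if hit is None:
            continue
        if best is None or (hit.chain_score, hit.identity) > (best.chain_score, best.identity):
            best = hit
    return best


def _chain_segments(
    rpos: np.ndarray,
    upos: np.ndarray,
    k: int,
    gap_tol: int,
    chain_slack: int,
) -> tuple[list[tuple[int, int, int, int]], np.ndarray]:
    """Greedy collinear chaining of (read_pos, unit_pos) seed matches.

    Matches extend the open segment while read positions advance by at most
    ``gap_tol`` and the diagonal shift stays within ``chain_slack``; a wrap
    of the unit coordinate (next tandem copy) or a larger gap closes it.
    Returns segments as (r0, r1, u0, u1) half-open intervals and, aligned
    with the input match order, the segment id of every match (-1 for
    matches not used in any chain).
    """
    order = np.lexsort((upos, rpos))
    r = rpos[order]
    u = upos[order]
    n = r.size
    if n == 0:
        return [], np.empty(0, dtype=np.int64)
    inv = np.empty(n, dtype=np.int64)
    inv[order] = np.arange(n)
    if n == 1 or np.all(np.diff(r) > 0):
        # no duplicate read positions: the greedy chain is a vectorized scan
        dr = np.diff(r)
        du = np.diff(u)
        brk = (dr > gap_tol) | (du < 1) | (np.abs(du - dr) > chain_slack)
        cut = np.nonzero(brk)[0]
        starts = np.concatenate(([0], cut + 1))
        ends = np.concatenate((cut, [n - 1]))
        segments = [
            (int(r[s]), int(r[e]) + k, int(u[s]), int(u[e]) + k)
            for s, e in zip(starts, ends)
        ]
        seg_id_sorted = np.concatenate(([0], np.cumsum(brk)))
        return segments, seg_id_sorted[inv]
    seg_id = np.full(n, -1, dtype=np.int64)
    segments = []
    cur = None  # [r0, rlast, u0, ulast]
    i = 0
    while i < n:
        ri = int(r[i])
        j = i
        while j < n and r[j] == ri:
            j += 1
        group = range(i, j)
        extended = False
        if cur is not None:
            dr = ri - cur[1]
            if 0 < dr <= gap_tol:
                best_m, best_dev = -1, None
                for m in group:
                    du = int(u[m]) - cur[3]
                    if du < 1:
                        continue
                    dev = abs(du - dr)
                    if dev <= chain_slack and (best_dev is None or dev < best_dev):
                        best_m, best_dev = m, dev
                if best_m >= 0:
                    cur[1] = ri
                    cur[3] = int(u[best_m])
                    seg_id[best_m] = len(segments)
                    extended = True
        if not extended:
            if cur is not None:
                segments.append((cur[0], cur[1] + k, cur[2], cur[3] + k))
            m0 = min(group, key=lambda m: u[m])
            cur = [ri, ri, int(u[m0]), int(u[m0])]
            seg_id[m0] = len(segments)
        i = j
    if cur is not None:
        segments.append((cur[0], cur[1] + k, cur[2], cur[3] + k))
    return segments, seg_id[inv]


class UnitMatcher:
    """Reusable both-strand matcher of a repeat-unit reference."""

    def __init__(self, unit_reference: str, k: int = DEFAULT_SEED_K):
        if len(unit_reference) < 50:
            raise ValueError("unit reference must be at least 50 bp")
        if len(unit_reference) < k:
            raise ValueError("unit reference shorter than the seed length")
        self.unit_len = len(unit_reference)
        self.k = k
        self._multi = _MultiRefIndex(
            [("unit", "+", unit_reference), ("unit", "-", revcomp(unit_reference))], k
        )

    def segments(
        self,
        read: str,
        min_unit_fraction: float,
        gap_tolerance_frac: float = 0.1,
        chain_slack: int = 20,
        codes: np.ndarray | None = None,
        with_matches: bool = False,
    ):
        if codes is None:
            codes = encode_kmers(read, self.k)
        gap_tol = max(self.k + 5, int(round(gap_tolerance_frac * self.unit_len)))
        out: list[UnitSegment] = []
        tables = []
        for _name, strand, _seq, qpos, upos in self._multi.lookup_split(codes):
            segs, seg_ids = _chain_segments(qpos, upos, self.k, gap_tol, chain_slack)
            base = len(out)
            for r0, r1, u0, u1 in segs:
                cov = (u1 - u0) / self.unit_len
                if strand == "+":
                    us, ue = u0, u1
                else:
                    us, ue = self.unit_len - u1, self.unit_len - u0
                out.append(
                    UnitSegment(r0, r1, us, ue, strand, cov, cov >= min_unit_fraction)
                )
            if with_matches:
                upos_fwd = upos if strand == "+" else self.unit_len - self.k - upos
                tables.append(
                    pd.DataFrame(
                        {
                            "read_pos": qpos,
                            "unit_pos": upos_fwd,
                            "strand": strand,
                            "segment_id": np.where(seg_ids >= 0, seg_ids + base, -1),
                        }
                    )
                )
        out.sort(key=lambda s: s.read_start)
        if not with_matches:
            return out
        matches = (
            pd.concat(tables, ignore_index=True)
            if tables
            else pd.DataFrame(columns=["read_pos", "unit_pos", "strand", "segment_id"])
        )
        return out, matches


def count_units(
    read: str,
    unit_reference: str,
    min_unit_fraction: float = 0.6,
    *,
    k: int = DEFAULT_SEED_K,
    gap_tolerance_frac: float = 0.1,
    chain_slack: int = 20,
    read_id: str = "read",
    matcher: UnitMatcher | None = None,
) -> SpanningReadResult:
    """Count repeat-unit copies on a read by diagonal-segment chaining.

    A segment counts as one unit iff it covers at least ``min_unit_fraction``
    of the unit reference; partial terminal copies below that fraction are
    reported in ``segments`` but not counted.  Pass a prebuilt ``matcher``
    when processing many reads against the same unit.
    """
    if matcher is None:
        matcher = UnitMatcher(unit_reference, k)
    segs = matcher.segments(read, min_unit_fraction, gap_tolerance_frac, chain_slack)
    return SpanningReadResult(
        read_id=read_id,
        segments=segs,
        n_units=sum(1 for s in segs if s.accepted),
    )


def export_dotplot(
    read: str,
    unit_reference: str,
    *,
    k: int = DEFAULT_SEED_K,
    gap_tolerance_frac: float = 0.1,
    chain_slack: int = 20,
    min_unit_fraction: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dot-plot tables: one row per k-mer match, plus segment boundaries.

    Returns ``(matches, segments)``: matches has (read_pos, unit_pos, strand,
    segment_id) suitable for scatter plotting; segments lists the chained
    diagonals with coverage and acceptance.
    """
    matcher = UnitMatcher(unit_reference, k)
    segs, matches = matcher.segments(
        read, min_unit_fraction, gap_tolerance_frac, chain_slack, with_matches=True
    )
    seg_df = pd.DataFrame(
        {
            "segment_id": range(len(segs)),
            "read_start": [s.read_start for s in segs],
            "read_end": [s.read_end for s in segs],
            "unit_start": [s.unit_start for s in segs],
            "unit_end": [s.unit_end for s in segs],
            "strand": [s.strand for s in segs],
            "coverage": [s.coverage for s in segs],
            "accepted": [s.accepted for s in segs],
        }
    )
    return matches, seg_df


def _as_read_pairs(reads) -> list[tuple[str, str]]:
    out = []
    for i, r in enumerate(reads):
        if isinstance(r, str):
            out.append((f"read_{i:06d}", r))
        elif isinstance(r, tuple):
            out.append((r[0], r[1]))
        else:
            out.append((r.read_id, r.sequence))
    return out


def _spanning_decision(res: SpanningReadResult) -> None:
    lh, rh = res.left, res.right
    if lh is None or rh is None:
        return
    if lh.strand != rh.strand:
        res.anomaly = "strand_mismatch"
        return
    ordered = (
        lh.read_end <= rh.read_start if lh.strand == "+" else rh.read_end <= lh.read_start
    )
    if not ordered:
        res.anomaly = "inverted_order"
    elif not (lh.complete and rh.complete):
        res.anomaly = "clipped_anchor"
    else:
        res.spanning = True


def select_spanning_reads(
    reads,
    left_anchor: str,
    right_anchor: str,
    *,
    min_identity: float = 0.8,
    k: int = DEFAULT_SEED_K,
) -> list[SpanningReadResult]:
    """Flag reads containing both anchors, consistently oriented.

    A read spans iff both anchors hit on the same strand, complete (not
    clipped by a read edge), with the left anchor before the right in the
    read's genomic orientation.  Inverted-order and strand-mismatched pairs
    are flagged as anomalous.  Returns one result per input read.
    """
    if left_anchor == right_anchor:
        raise ValueError("left and right anchors must differ")
    locator = AnchorPairLocator(left_anchor, right_anchor, k)
    results = []
    for rid, seq in _as_read_pairs(reads):
        res = SpanningReadResult(read_id=rid)
        hits = locator.locate(seq, min_identity)
        res.left, res.right = hits["left"], hits["right"]
        _spanning_decision(res)
        results.append(res)
    return results


def genotype_spanning_reads(
    reads,
    unit_reference: str,
    left_anchor: str,
    right_anchor: str,
    *,
    min_identity: float = 0.8,
    min_unit_fraction: float = 0.6,
    k: int = DEFAULT_SEED_K,
) -> list[SpanningReadResult]:
    """Select spanning reads and count units on each (canonical strand)."""
    if left_anchor == right_anchor:
        raise ValueError("left and right anchors must differ")
    locator = AnchorPairLocator(left_anchor, right_anchor, k)
    matcher = UnitMatcher(unit_reference, k)
    results = []
    for rid, seq in _as_read_pairs(reads):
        res = SpanningReadResult(read_id=rid)
        codes = encode_kmers(seq, k)
        hits = locator.locate(seq, min_identity, codes=codes)
        res.left, res.right = hits["left"], hits["right"]
        _spanning_decision(res)
        if res.spanning:
            if res.left.strand == "-":
                canonical, canon_codes = revcomp(seq), None
            else:
                canonical, canon_codes = seq, codes
            res.segments = matcher.segments(
                canonical, min_unit_fraction, codes=canon_codes
            )
            res.n_units = sum(1 for s in res.segments if s.accepted)
        results.append(res)
    return results


@dataclass
class CopyNumberSummary:
    histogram: dict[int, int]
    mode: int
    max: int
    n: int


def copy_number_distribution(results: Iterable[SpanningReadResult]) -> CopyNumberSummary:
    """Histogram of per-read unit counts over spanning reads."""
    counts: dict[int, int] = {}
    n = 0
    for r in results:
        if not r.spanning:
            continue
        counts[r.n_units] = counts.get(r.n_units, 0) + 1
        n += 1
    if n == 0:
        raise ValueError("no spanning reads to summarize")
    mode = sorted(counts, key=lambda c: (-counts[c], c))[0]
    return CopyNumberSummary(histogram=dict(sorted(counts.items())), mode=mode, max=max(counts), n=n)


@dataclass
class HitCountAggregate:
    per_read: dict[str, int]
    distribution: dict[int, int]
    max: int
    n_reads: int
    n_dropped: int
    note: str = (
        "per-read local-match counts; aggregation to a single copy number is "
        "ambiguous for non-spanning reads — the distribution and its maximum "
        "are reported"
    )


def hit_count_estimate(
    reads,
    unit_reference: str,
    *,
    min_unit_fraction: float = 0.6,
    k: int = DEFAULT_SEED_K,
) -> HitCountAggregate:
    """Per-read unit-match counts without requiring spanning reads.

    Reads with no unit match are dropped from the aggregate.  Mirrors
    copy-number estimation from the number of unit hits per read; since
    clipped reads undercount, the maximum is the informative statistic.
    """
    pairs = _as_read_pairs(reads)
    if not pairs:
        raise ValueError("no reads given")
    matcher = UnitMatcher(unit_reference, k)
    per_read: dict[str, int] = {}
    dropped = 0
    for rid, seq in pairs:
        n = count_units(
            seq, unit_reference, min_unit_fraction, k=k, read_id=rid, matcher=matcher
        ).n_units
        if n == 0:
            dropped += 1
            continue
        per_read[rid] = n
    if not per_read:
        raise ValueError("no reads contain the unit reference")
    dist: dict[int, int] = {}
    for v in per_read.values():
        dist[v] = dist.get(v, 0) + 1
    return HitCountAggregate(
        per_read=per_read,
        distribution=dict(sorted(dist.items())),
        max=max(per_read.values()),
        n_reads=len(per_read),
        n_dropped=dropped,
    )


@dataclass(frozen=True)
class AscertainmentModel:
    """P(a random read spans an array of given length).

    For a read of length l on a linear chromosome of length L, starts are
    uniform on [0, L-l]; a centrally placed region of length
    S = array + 2 anchors is spanned by min(max(0, l - S + 1), L - l + 1)
    of the L - l + 1 possible starts.  The model averages this over the
    read-length distribution.
    """

    genome_length: int
    anchor_length: int
    unit_length: int
    length_distribution: str = "fixed"
    read_length: int = 0
    log_mu: float = 0.0
    log_sigma: float = 1.0

    @classmethod
    def from_read_params(cls, genome_length: int, anchor_length: int, unit_length: int, params):
        return cls(
            genome_length=genome_length,
            anchor_length=anchor_length,
            unit_length=unit_length,
            length_distribution=params.length_distribution,
            read_length=params.read_length,
            log_mu=params.log_mu,
            log_sigma=params.log_sigma,
        )

    def array_length(self, n_units: int, intervening_length: int = 0) -> int:
        return n_units * self.unit_length + max(n_units - 1, 0) * intervening_length

    def _p_fixed(self, ell: float, span: float) -> float:
        # exact for a centrally placed region; reads longer than the
        # chromosome are truncated to it and always span
        L = self.genome_length
        ell = min(ell, L)
        starts = ell - span + 1.0
        if starts <= 0:
            return 0.0
        total = L - ell + 1.0
        return min(starts, total) / total

    def spanning_probability(self, array_length_bp: float) -> float:
        span = array_length_bp + 2.0 * self.anchor_length
        if span > self.genome_length:
            return 0.0
        if self.length_distribution == "fixed":
            return self._p_fixed(float(self.read_length), span)
        dist = stats.lognorm(s=self.log_sigma, scale=np.exp(self.log_mu))
        hi = min(float(dist.ppf(1 - 1e-9)), float(self.genome_length))
        if hi <= span:
            return float(dist.sf(self.genome_length))  # only full-chromosome reads span
        grid = np.linspace(span, hi, 4096)
        vals = np.array([self._p_fixed(g, span) for g in grid])
        p = float(np.trapezoid(vals * dist.pdf(grid), grid))
        p += float(dist.sf(hi))  # reads truncated to the whole chromosome
        return min(p, 1.0)

    def p_span_units(self, n_units: int, intervening_length: int = 0) -> float:
        return self.spanning_probability(self.array_length(n_units, intervening_length))


@dataclass
class BiasCorrectedEstimate:
    mean: float
    ci: tuple[float, float]
    naive_mean: float
    n_used: int
    n_excluded: int


def bias_corrected_mean(
    results: Sequence[SpanningReadResult],
    model: AscertainmentModel,
    *,
    intervening_length: int = 0,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> BiasCorrectedEstimate:
    """Length-bias-corrected population mean copy number.

    Each spanning read is weighted by 1/P(span | array length of its allele);
    reads whose allele cannot be spanned (P = 0) are excluded with a count.
    CI by case-resampling bootstrap over reads.
    """
    counts = np.array([r.n_units for r in results if r.spanning], dtype=float)
    if counts.size == 0:
        raise ValueError("no spanning reads")
    p = np.array(
        [model.p_span_units(int(c), intervening_length) for c in counts], dtype=float
    )
    keep = p > 0
    n_excluded = int((~keep).sum())
    counts, p = counts[keep], p[keep]
    if counts.size == 0:
        raise ValueError("all observed alleles have zero spanning probability")
    w = 1.0 / p
    est = float(np.sum(w * counts) / np.sum(w))
    naive = float(counts.mean())
    rng = np.random.default_rng(seed)
    boots = []
    n = counts.size
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        boots.append(np.sum(w[idx] * counts[idx]) / np.sum(w[idx]))
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (est, est))
    return BiasCorrectedEstimate(
        mean=est, ci=(float(lo), float(hi)), naive_mean=naive, n_used=n, n_excluded=n_excluded
    )
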