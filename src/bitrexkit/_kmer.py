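"""Exact k-mer seeding primitives shared by the anchor locator, unit counter
and internal read placer.

Sequences are plain Python strings over the DNA alphabet; windows containing
any non-ACGT character (e.g. the ``N`` bases used for masking) encode as -1
and never seed a match.
"""
from __future__ import annotations

import numpy as np

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement; non-ACGTN characters are not supported."""
    return seq.translate(_RC_TABLE)[::-1]


def encode_kmers(seq: str, k: int) -> np.ndarray:
    """Integer codes of every k-mer of ``seq`` (base-4 encoding, A=0..T=3).

    Returns an array of length ``len(seq) - k + 1``; entries covering a
    non-ACGT base are -1.  Requires ``4**k`` to fit in int64 (k <= 31).
    """
    if k < 1 or k > 31:
        raise ValueError("k must be in [1, 31]")
    a = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = a.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(a, k)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win @ weights
    bad = np.lib.stride_tricks.sliding_window_view(a < 0, k).any(axis=1)
    codes[bad] = -1
    return codes


class KmerIndex:
    """Sorted-array index of all valid k-mers of a reference string."""

    def __init__(self, seq: str, k: int):
        self.k = k
        self.length = len(seq)
        codes = encode_kmers(seq, k)
        pos = np.nonzero(codes >= 0)[0]
        order = np.argsort(codes[pos], kind="stable")
        self._codes = codes[pos][order]
        self._pos = pos[order]

    def lookup(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All exact matches of ``query_codes`` against the reference.

        Returns ``(query_pos, ref_pos)`` pairs; invalid query codes (-1)
        never match.  A query k-mer occurring m times in the reference
        produces m pairs.
        """
        valid = np.nonzero(query_codes >= 0)[0]
        if valid.size == 0 or self._codes.size == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        c = query_codes[valid]
        left = np.searchsorted(self._codes, c, side="left")
        # resolve run lengths only for codes actually present
        has = (left < self._codes.size) & (
            self._codes[np.minimum(left, self._codes.size - 1)] == c
        )
        valid, left, c = valid[has], left[has], c[has]
        cnt = np.searchsorted(self._codes, c, side="right") - left
        total = int(cnt.sum())
        if total == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        qpos = np.repeat(valid, cnt)
        run_starts = np.cumsum(cnt) - cnt
        offsets = np.arange(total) - np.repeat(run_starts, cnt)
        rpos = self._pos[np.repeat(left, cnt) + offsets]
        return qpos, rpos
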