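"""Copy-number estimation from read depth with masking and normalization.

The reference keeps a single repeat-unit copy and masks the rest with 'N'
before mapping, so all reads from the array pile onto the retained copy;
after dividing by the mean depth of a single-copy background (defined by an
exclusion list for repetitive regions), the normalized depth over the unit
reads out the array copy number directly, and per-chromosome means expose
aneuploidy.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mapping import GenomeIndex, apply_mask, as_chromosomes


@dataclass
class DepthProfile:
    """Binned mean per-base coverage per chromosome.

    ``values[chrom][i]`` is the mean per-base depth over bin i (the last bin
    may be shorter than ``bin_size``).  ``mask_bins`` (set at normalization)
    marks bins overlapping masked intervals; ``norm_factor`` is the
    background mean the profile was last divided by.
    """

    bin_size: int
    lengths: dict[str, int]
    values: dict[str, np.ndarray]
    normalized: bool = False
    norm_factor: float | None = None
    mask_bins: dict[str, np.ndarray] | None = None
    stats: dict = field(default_factory=dict)

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def bin_widths(self, chrom: str) -> np.ndarray:
        L = self.lengths[chrom]
        n = self.n_bins(chrom)
        w = np.full(n, self.bin_size, dtype=float)
        if n:
            w[-1] = L - (n - 1) * self.bin_size
        return w


@dataclass
class RegionCN:
    region: tuple[str, int, int]
    mean: float
    sd: float
    n_bins: int

    @property
    def sd_defined(self) -> bool:
        return self.n_bins >= 2


@dataclass
class PloidyCall:
    chrom: str
    mean_depth: float
    call: str  # euploid / gain / loss


def _bin_flags(lengths: dict[str, int], bin_size: int, intervals) -> dict[str, np.ndarray]:
    """Boolean per-bin flags: True where the bin overlaps any interval."""
    flags = {
        c: np.zeros(int(np.ceil(L / bin_size)) if L else 0, dtype=bool)
        for c, L in lengths.items()
    }
    for chrom, s, e in intervals or []:
        if chrom not in flags or e <= s:
            continue
        lo = max(0, s // bin_size)
        hi = min(len(flags[chrom]), (e - 1) // bin_size + 1)
        flags[chrom][lo:hi] = True
    return flags


def compute_depth(
    genome,
    reads=None,
    placements: list[tuple[str, int, int]] | None = None,
    *,
    bin_size: int = 100,
    mask_intervals=None,
    max_edit_frac: float = 0.1,
    index_k: int = 21,
) -> DepthProfile:
    """Raw binned depth from reads (internally placed) or explicit placements.

    With reads, the reference is masked ('N') before indexing; multi-mapping
    reads are discarded and counted in ``stats``.  Explicit placements that
    run off a chromosome end are clipped with a warning.
    """
    chroms = as_chromosomes(genome)
    lengths = {n: len(s) for n, s in chroms}
    cov = {n: np.zeros(L, dtype=np.float64) for n, L in lengths.items()}
    stats = {"n_placed": 0, "n_multimapped": 0, "n_unmapped": 0, "placed_bases": 0}

    if (reads is None) == (placements is None):
        raise ValueError("provide exactly one of reads / placements")

    if placements is not None:
        for chrom, s, e in placements:
            if chrom not in cov:
                raise KeyError(f"unknown chromosome {chrom!r}")
            L = lengths[chrom]
            cs, ce = max(0, s), min(L, e)
            if (cs, ce) != (s, e):
                warnings.warn(f"placement [{s},{e}) clipped to chromosome {chrom}")
            if ce > cs:
                cov[chrom][cs:ce] += 1.0
                stats["n_placed"] += 1
                stats["placed_bases"] += ce - cs
    else:
        index = GenomeIndex(apply_mask(chroms, mask_intervals), k=index_k)
        for r in reads:
            if isinstance(r, str):
                seq = r
            elif hasattr(r, "sequence"):
                seq = r.sequence
            else:
                seq = r[1]
            status, pl = index.place(seq, max_edit_frac=max_edit_frac)
            if status == "mapped":
                cov[pl.chrom][pl.start : pl.end] += 1.0
                stats["n_placed"] += 1
                stats["placed_bases"] += pl.end - pl.start
            elif status == "ambiguous":
                stats["n_multimapped"] += 1
            else:
                stats["n_unmapped"] += 1

    values = {}
    for n, arr in cov.items():
        L = lengths[n]
        nb = int(np.ceil(L / bin_size)) if L else 0
        sums = np.add.reduceat(arr, np.arange(0, L, bin_size)) if nb else np.empty(0)
        widths = np.full(nb, bin_size, dtype=float)
        if nb:
            widths[-1] = L - (nb - 1) * bin_size
        values[n] = sums / widths if nb else np.empty(0)
    return DepthProfile(bin_size=bin_size, lengths=lengths, values=values, stats=stats)


def normalize_depth(
    profile: DepthProfile, mask_intervals=None, background_exclude=None
) -> DepthProfile:
    """Divide every bin by the mean depth of the effective background.

    Background = bins overlapping neither the mask nor the exclusion list
    (rRNA/repeat/organelle-style categories).  Masked bins are remembered on
    the returned profile and excluded from region estimates.
    """
    mask_bins = _bin_flags(profile.lengths, profile.bin_size, mask_intervals)
    excl_bins = _bin_flags(profile.lengths, profile.bin_size, background_exclude)
    bg_vals = np.concatenate(
        [
            profile.values[c][~mask_bins[c] & ~excl_bins[c]]
            for c in profile.values
        ]
    ) if profile.values else np.empty(0)
    if bg_vals.size == 0:
        raise ValueError("effective background is empty (mask covers everything)")
    factor = float(bg_vals.mean())
    if factor <= 0:
        raise ValueError("background mean depth is zero; cannot normalize")
    return DepthProfile(
        bin_size=profile.bin_size,
        lengths=dict(profile.lengths),
        values={c: v / factor for c, v in profile.values.items()},
        normalized=True,
        norm_factor=factor,
        mask_bins=mask_bins,
        stats=dict(profile.stats),
    )


def _region_bins(profile: DepthProfile, region) -> np.ndarray:
    chrom, s, e = region
    if chrom not in profile.values:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if e <= s:
        raise ValueError("empty region")
    lo = max(0, s // profile.bin_size)
    hi = min(profile.n_bins(chrom), (e - 1) // profile.bin_size + 1)
    idx = np.arange(lo, hi)
    if profile.mask_bins is not None:
        idx = idx[~profile.mask_bins[chrom][lo:hi]]
    return idx


def region_copy_number(profile: DepthProfile, region) -> RegionCN:
    """Mean +/- SD normalized depth over a region, masked bins excluded."""
    chrom = region[0]
    idx = _region_bins(profile, region)
    if idx.size == 0:
        raise ValueError("region is fully masked or outside the profile")
    vals = profile.values[chrom][idx]
    sd = float(vals.std(ddof=1)) if vals.size >= 2 else float("nan")
    return RegionCN(region=tuple(region), mean=float(vals.mean()), sd=sd, n_bins=int(vals.size))


def region_ratio(profile: DepthProfile, numerator_region, denominator_region) -> float:
    """Ratio of mean normalized depths between two regions."""
    num = region_copy_number(profile, numerator_region)
    den = region_copy_number(profile, denominator_region)
    if den.mean == 0:
        raise ValueError("denominator region has zero mean depth")
    return num.mean / den.mean


def chromosome_ploidy(
    profile: DepthProfile,
    exclude_intervals=None,
    *,
    gain_threshold: float = 1.25,
    loss_threshold: float = 0.75,
) -> dict[str, PloidyCall]:
    """Classify each chromosome as euploid/gain/loss by mean normalized depth.

    Thresholds are strict inequalities: a mean exactly at a threshold is
    euploid.  ``exclude_intervals`` (typically the array locus plus anchors)
    and masked bins are left out of the means.
    """
    excl = _bin_flags(profile.lengths, profile.bin_size, exclude_intervals)
    calls = {}
    for chrom, vals in profile.values.items():
        keep = ~excl[chrom]
        if profile.mask_bins is not None:
            keep &= ~profile.mask_bins[chrom]
        v = vals[keep]
        mean = float(v.mean()) if v.size else float("nan")
        if np.isnan(mean):
            call = "euploid"
        elif mean > gain_threshold:
            call = "gain"
        elif mean < loss_threshold:
            call = "loss"
        else:
            call = "euploid"
        calls[chrom] = PloidyCall(chrom=chrom, mean_depth=mean, call=call)
    return calls
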