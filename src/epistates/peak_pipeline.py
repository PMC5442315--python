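"""Replicate-filtered consensus histone-mark regions.

Per-replicate enrichment regions (signal = FPKM(ChIP)/FPKM(H3)) are first
concordance-filtered — matched region pairs whose replicate signal
difference deviates from the mean difference by more than 2 s.d. are
discarded — and then combined into consensus regions: the union of every
pair of regions that overlap (>= 1 bp) across the two replicates, with
chains of transitively overlapping regions merged into one. Regions
supported by only one replicate do not enter the consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .genome_model import GenomicInterval, overlap_length
from .io_formats import PeakFileRecord

__all__ = [
    "MarkRegion",
    "ReplicateRegionSet",
    "ConsensusMarkSet",
    "ConcordanceResult",
    "downsample_counts",
    "merge_regions",
    "concordance_filter",
    "consensus_regions",
]

MARKS = ("H3K4me3", "H3K27me3")


@dataclass(frozen=True)
class MarkRegion:
    """A histone-mark interval with its normalized signal level."""

    interval: GenomicInterval
    signal: float


@dataclass
class ReplicateRegionSet:
    """All regions of one mark, one timepoint, one biological replicate."""

    mark: str
    timepoint: str
    replicate: int
    regions: list[PeakFileRecord]

    def merged(self) -> "ReplicateRegionSet":
        """Self-overlapping regions merged (length-weighted signal)."""
        merged = [
            PeakFileRecord(r.interval, signal=r.signal)
            for r in merge_regions(self.regions)
        ]
        return ReplicateRegionSet(self.mark, self.timepoint, self.replicate, merged)


@dataclass
class ConsensusMarkSet:
    """Sorted, non-overlapping consensus regions of one mark at one timepoint."""

    mark: str
    timepoint: str
    regions: list[MarkRegion] = field(default_factory=list)


def downsample_counts(
    counts_per_sample: Sequence[int], seed: int
) -> list[np.ndarray]:
    """Index masks reducing every sample to the minimum count.

    Models depth normalization by read down-sampling: each sample keeps a
    uniform random subset (without replacement) of size ``min(counts)``.
    Returns one sorted index array per sample; seeded and reproducible.
    """
    if len(counts_per_sample) == 0:
        raise ValueError("counts_per_sample must be non-empty")
    if any(c <= 0 for c in counts_per_sample):
        raise ValueError("all counts must be > 0")
    target = min(counts_per_sample)
    rng = np.random.default_rng(seed)
    return [
        np.sort(rng.choice(c, size=target, replace=False))
        for c in counts_per_sample
    ]


def merge_regions(regions: Sequence) -> list[MarkRegion]:
    """Merge overlapping (>= 1 bp shared base) intervals within one set.

    Touching half-open intervals ([0,10) and [10,20)) are kept separate.
    Merged signal is the length-weighted mean of the contributors.
    """
    by_chrom: dict[str, list] = {}
    for r in regions:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    out: list[MarkRegion] = []
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.interval.start, r.interval.end))
        cur: list = []
        cur_end = -1
        for r in rs:
            if cur and r.interval.start < cur_end:
                cur.append(r)
                cur_end = max(cur_end, r.interval.end)
            else:
                if cur:
                    out.append(_combine(chrom, cur))
                cur = [r]
                cur_end = r.interval.end
        if cur:
            out.append(_combine(chrom, cur))
    return out


def _combine(chrom: str, members: list) -> MarkRegion:
    start = min(m.interval.start for m in members)
    end = max(m.interval.end for m in members)
    w = np.array([len(m.interval) for m in members], dtype=float)
    s = np.array([m.signal for m in members], dtype=float)
    return MarkRegion(GenomicInterval(chrom, start, end), float(np.sum(w * s) / np.sum(w)))


@dataclass
class ConcordanceResult:
    """Outcome of the 2 s.d. replicate concordance filter."""

    kept_pairs: list[tuple[PeakFileRecord, PeakFileRecord]]
    removed_pairs: list[tuple[PeakFileRecord, PeakFileRecord]]
    sd_estimate: float | None
    rep1_kept: list[PeakFileRecord]
    rep2_kept: list[PeakFileRecord]


def _best_matches(a_regions, b_regions):
    """For each region in *a*, the index of the max-overlap region in *b*.

    Ties broken by larger overlap (the criterion), then smaller start.
    Returns -1 where nothing overlaps.
    """
    by_chrom: dict[str, list[tuple[int, PeakFileRecord]]] = {}
    for j, r in enumerate(b_regions):
        by_chrom.setdefault(r.interval.chrom, []).append((j, r))
    best = []
    for r in a_regions:
        cand = by_chrom.get(r.interval.chrom, [])
        best_j, best_key = -1, None
        for j, s in cand:
            ov = overlap_length(r.interval, s.interval)
            if ov <= 0:
                continue
            key = (-ov, s.interval.start)
            if best_key is None or key < best_key:
                best_key, best_j = key, j
        best.append(best_j)
    return best


def concordance_filter(
    rep1: ReplicateRegionSet,
    rep2: ReplicateRegionSet,
    sd_mult: float = 2.0,
    centered: bool = True,
) -> ConcordanceResult:
    """Remove replicate region pairs with discordant signal levels.

    Regions are matched across replicates by mutual maximal overlap; per
    matched pair the signal difference ``d = signal1 - signal2`` is taken,
    and pairs with ``|d - mean(d)| > sd_mult * sd(d)`` are filtered out
    (``|d| > sd_mult * sd(d)`` with ``centered=False``). Unmatched regions
    pass through unfiltered — the consensus step decides their fate. With
    fewer than 3 matched pairs the s.d. is not estimable: a warning is
    issued and nothing is filtered.
    """
    if (rep1.mark, rep1.timepoint) != (rep2.mark, rep2.timepoint):
        raise ValueError("replicates must share mark and timepoint")
    r1 = rep1.merged().regions
    r2 = rep2.merged().regions
    fwd = _best_matches(r1, r2)
    rev = _best_matches(r2, r1)
    pairs = [(i, j) for i, j in enumerate(fwd) if j >= 0 and rev[j] == i]

    unmatched1 = [r for i, r in enumerate(r1) if not any(i == p[0] for p in pairs)]
    unmatched2 = [r for j, r in enumerate(r2) if not any(j == p[1] for p in pairs)]

    if len(pairs) < 3:
        warnings.warn(
            f"{rep1.mark}/{rep1.timepoint}: only {len(pairs)} matched pairs; "
            "concordance filter disabled (s.d. not estimable)",
            stacklevel=2,
        )
        kept = [(r1[i], r2[j]) for i, j in pairs]
        return ConcordanceResult(kept, [], None, list(r1), list(r2))

    d = np.array([r1[i].signal - r2[j].signal for i, j in pairs])
    sd = float(np.std(d, ddof=1))
    center = float(np.mean(d)) if centered else 0.0
    # sd == 0 degenerates to removing nothing (strict inequality)
    discord = np.abs(d - center) > sd_mult * sd

    kept_pairs, removed_pairs = [], []
    rep1_kept, rep2_kept = list(unmatched1), list(unmatched2)
    for (i, j), bad in zip(pairs, discord):
        pair = (r1[i], r2[j])
        if bad:
            removed_pairs.append(pair)
        else:
            kept_pairs.append(pair)
            rep1_kept.append(r1[i])
            rep2_kept.append(r2[j])
    rep1_kept.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    rep2_kept.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    return ConcordanceResult(kept_pairs, removed_pairs, sd, rep1_kept, rep2_kept)


def consensus_regions(
    rep1: ReplicateRegionSet, rep2: ReplicateRegionSet
) -> ConsensusMarkSet:
    """Union-of-overlapping-pairs consensus of two (filtered) replicates.

    Both replicates are first self-merged. Every chain of transitively
    overlapping regions (>= 1 bp shared base) containing regions from both
    replicates is emitted as its spanning union interval, with signal equal
    to the length-weighted mean of all contributing replicate regions.
    Single-replicate chains are dropped.
    """
    if (rep1.mark, rep1.timepoint) != (rep2.mark, rep2.timepoint):
        raise ValueError("replicates must share mark and timepoint")
    tagged = [
        (r, 1) for r in rep1.merged().regions
    ] + [(r, 2) for r in rep2.merged().regions]
    by_chrom: dict[str, list] = {}
    for r, tag in tagged:
        by_chrom.setdefault(r.interval.chrom, []).append((r, tag))

    out: list[MarkRegion] = []
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda t: (t[0].interval.start, t[0].interval.end))
        component: list = []
        comp_end = -1
        for r, tag in rs:
            if component and r.interval.start < comp_end:
                component.append((r, tag))
                comp_end = max(comp_end, r.interval.end)
            else:
                _emit(chrom, component, out)
                component = [(r, tag)]
                comp_end = r.interval.end
        _emit(chrom, component, out)
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return ConsensusMarkSet(rep1.mark, rep1.timepoint, out)


def _emit(chrom: str, component: list, out: list[MarkRegion]) -> None:
    if not component or len({tag for _, tag in component}) < 2:
        return  # empty or single-replicate chain: no cross-replicate support
    out.append(_combine(chrom, [r for r, _ in component]))
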