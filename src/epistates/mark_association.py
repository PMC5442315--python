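"""Per-gene mark profiles and mark-expression association statistics.

A gene is "marked at the TSS" when any consensus region of that mark
overlaps the TSS +-500 bp window by at least one base. Association
statistics follow the study design: per-timepoint marked proportions in
the expressed (mean FPKM > 1 at that timepoint) and non-expressed strata,
summarized as mean +- s.e. over timepoints, and the Spearman rank
correlation between TSS signal and FPKM among expressed genes, tested via
the t approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genome_model import GeneAnnotation, GenomicInterval, TSSWindow, overlap_length
from .io_formats import ExpressionTable
from .peak_pipeline import ConsensusMarkSet, MarkRegion

__all__ = [
    "MarkProfile",
    "GeneMarkProfile",
    "FractionSummary",
    "AssociationSummary",
    "profile_genes",
    "marked_fraction",
    "spearman_with_t",
    "associate",
]


@dataclass(frozen=True)
class MarkProfile:
    """One gene's view of one mark at one timepoint."""

    regions: tuple[MarkRegion, ...]
    tss_marked: bool
    tss_signal: float  # mean signal of TSS-overlapping regions; 0 if none
    body_signal: float  # length-weighted mean over the gene body (gaps = 0)

    def __post_init__(self) -> None:
        if self.tss_marked and not self.regions:
            raise ValueError("tss_marked requires at least one region")


@dataclass(frozen=True)
class GeneMarkProfile:
    gene_id: str
    timepoint: str
    marks: Mapping[str, MarkProfile]


def profile_genes(
    genes: Sequence[GeneAnnotation],
    consensus: Mapping[str, ConsensusMarkSet],
    window_halfwidth: int = 500,
) -> list[GeneMarkProfile]:
    """Intersect consensus mark sets with genes.

    For every gene and mark, collects the consensus regions overlapping
    the gene body or its TSS window, flags TSS-marked genes, and computes
    the mean TSS signal and the length-weighted body signal. A gene whose
    chromosome carries no regions simply gets an empty profile.
    """
    trees: dict[str, dict[str, IntervalTree]] = {}
    timepoint = ""
    for mark, cset in consensus.items():
        timepoint = cset.timepoint
        per_chrom: dict[str, IntervalTree] = {}
        for r in cset.regions:
            per_chrom.setdefault(r.interval.chrom, IntervalTree()).addi(
                r.interval.start, r.interval.end, r
            )
        trees[mark] = per_chrom

    profiles = []
    for gene in genes:
        body = gene.body
        window = TSSWindow(body.chrom, gene.tss, window_halfwidth).interval
        lo, hi = min(body.start, window.start), max(body.end, window.end)
        marks = {}
        for mark, per_chrom in trees.items():
            tree = per_chrom.get(body.chrom)
            hits = sorted(tree.overlap(lo, hi), key=lambda h: h.begin) if tree else []
            regions = tuple(h.data for h in hits)
            tss_hits = [r for r in regions if overlap_length(r.interval, window) > 0]
            tss_signal = float(np.mean([r.signal for r in tss_hits])) if tss_hits else 0.0
            body_mass = sum(
                overlap_length(r.interval, body) * r.signal for r in regions
            )
            marks[mark] = MarkProfile(
                regions=regions,
                tss_marked=bool(tss_hits),
                tss_signal=tss_signal,
                body_signal=body_mass / len(body),
            )
        profiles.append(GeneMarkProfile(gene.gene_id, timepoint, marks))
    return profiles


@dataclass
class FractionSummary:
    """Per-timepoint marked proportions with their mean and standard error.

    The s.e. is the s.d. of the per-timepoint proportions divided by
    sqrt(T), T the number of timepoints with a defined proportion.
    Empty strata yield NaN proportions and are excluded from the mean.
    """

    per_timepoint: dict[str, float]
    mean: float
    se: float
    n_timepoints: int


def marked_fraction(
    profiles_by_timepoint: Mapping[str, Sequence[GeneMarkProfile]],
    expression: ExpressionTable,
    mark: str,
    stratum: str,
    threshold: float = 1.0,
) -> FractionSummary:
    """Proportion of genes in a stratum with the mark at the TSS.

    *stratum* is ``"expressed"`` (mean FPKM > threshold at that timepoint)
    or ``"non_expressed"``. Proportions are computed per timepoint and
    summarized as mean +- s.e. across timepoints.
    """
    if stratum not in ("expressed", "non_expressed"):
        raise ValueError(f"unknown stratum {stratum!r}")
    fpkm = expression.mean_fpkm()
    per_tp: dict[str, float] = {}
    for tp, profiles in profiles_by_timepoint.items():
        marked = total = 0
        for p in profiles:
            val = fpkm.at[p.gene_id, tp] if p.gene_id in fpkm.index else np.nan
            if np.isnan(val):
                continue
            is_expr = val > threshold
            if (stratum == "expressed") != is_expr:
                continue
            total += 1
            marked += int(p.marks[mark].tss_marked)
        per_tp[tp] = marked / total if total else float("nan")
    vals = np.array([v for v in per_tp.values() if not math.isnan(v)])
    if vals.size == 0:
        return FractionSummary(per_tp, float("nan"), float("nan"), 0)
    se = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return FractionSummary(per_tp, float(np.mean(vals)), se, int(vals.size))


def spearman_with_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with the Student-t significance test.

    rho is the Pearson correlation of mid-ranks (average ranks on ties);
    the p-value is the two-sided tail of ``t = rho * sqrt((n-2)/(1-rho^2))``
    with n-2 degrees of freedom, and exactly 0 when ``|rho| = 1``.
    Constant input yields ``(nan, nan)`` (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, p


@dataclass
class AssociationSummary:
    """The mark-expression association battery for one mark."""

    mark: str
    expressed: FractionSummary
    non_expressed: FractionSummary
    spearman_by_timepoint: dict[str, tuple[float, float]]  # tp -> (rho, p)


def associate(
    profiles_by_timepoint: Mapping[str, Sequence[GeneMarkProfile]],
    expression: ExpressionTable,
    mark: str,
    threshold: float = 1.0,
) -> AssociationSummary:
    """Marked fractions in both strata plus the per-timepoint Spearman
    correlation between TSS signal and FPKM among expressed TSS-marked genes."""
    fpkm = expression.mean_fpkm()
    spearman: dict[str, tuple[float, float]] = {}
    for tp, profiles in profiles_by_timepoint.items():
        xs, ys = [], []
        for p in profiles:
            if p.gene_id not in fpkm.index:
                continue
            val = fpkm.at[p.gene_id, tp]
            mp = p.marks[mark]
            if val > threshold and mp.tss_marked:
                xs.append(mp.tss_signal)
                ys.append(val)
        spearman[tp] = (
            spearman_with_t(xs, ys) if len(xs) >= 3 else (float("nan"), float("nan"))
        )
    return AssociationSummary(
        mark=mark,
        expressed=marked_fraction(profiles_by_timepoint, expression, mark, "expressed", threshold),
        non_expressed=marked_fraction(
            profiles_by_timepoint, expression, mark, "non_expressed", threshold
        ),
        spearman_by_timepoint=spearman,
    )
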