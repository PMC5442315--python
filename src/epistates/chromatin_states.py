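"""TSS-anchored H3K4me3/H3K27me3 chromatin-state classification.

Each gene at each timepoint gets exactly one label describing the joint
configuration of its two marks around the TSS:

* ``H`` — "harbouring": a broad H3K27me3 region contains a narrow
  H3K4me3 peak whose midpoint lies within +-500 bp of the TSS;
* ``E`` — "embedded": the mirror image, a narrow H3K27me3 peak inside a
  broader H3K4me3 domain at the TSS;
* ``K27_gt_K4`` / ``K4_gt_K27`` — both marks overlap partially, with the
  named mark spanning more bases;
* ``Non`` — both marks present on the gene but never overlapping;
* ``K4_only`` / ``K27_only`` / ``Unmarked`` — one or zero marks present.

"Narrow inside broad" is operationalized as interval containment (with
configurable slack) rather than an absolute width cutoff, and the TSS
condition applies to the inner peak's midpoint. Both choices are
parameters of :class:`StateCallParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_model import GeneAnnotation, GenomicInterval, TSSWindow, contains, overlap_length
from .peak_pipeline import ConsensusMarkSet, MarkRegion

__all__ = [
    "STATE_LABELS",
    "StateCallParams",
    "GeneStateCall",
    "TransitionMatrix",
    "classify_gene_state",
    "call_states",
    "transition_matrix",
    "state_set_overlap",
]

STATE_LABELS = (
    "H", "E", "K27_gt_K4", "K4_gt_K27", "Non", "K4_only", "K27_only", "Unmarked",
)


@dataclass(frozen=True)
class StateCallParams:
    """Tunable knobs of the state classifier.

    tss_halfwidth
        Half-width of the TSS window in bases (default 500).
    containment_slack
        Bases of slack allowed when testing whether one mark's interval
        contains the other's (default 0, strict containment).
    narrow_max_span
        Optional absolute width cap on the inner peak; None (default)
        means containment alone decides narrow-vs-broad.
    min_overlap
        Minimum shared bases for two regions to count as overlapping.
    midpoint_at_tss
        If True (default) the H/E TSS condition tests the inner peak's
        midpoint against ``TSS +- halfwidth``; if False, any overlap of
        the inner peak with the TSS window suffices.
    """

    tss_halfwidth: int = 500
    containment_slack: int = 0
    narrow_max_span: int | None = None
    min_overlap: int = 1
    midpoint_at_tss: bool = True

    def __post_init__(self) -> None:
        if min(self.tss_halfwidth, self.containment_slack, self.min_overlap) < 0:
            raise ValueError("parameters must be >= 0")
        if self.narrow_max_span is not None and self.narrow_max_span < 0:
            raise ValueError("narrow_max_span must be >= 0 or None")


@dataclass(frozen=True)
class GeneStateCall:
    """State label for one gene at one timepoint plus the evidence pair."""

    gene_id: str
    timepoint: str
    label: str
    k4_evidence: GenomicInterval | None = None
    k27_evidence: GenomicInterval | None = None
    inner_at_tss: bool = False

    def __post_init__(self) -> None:
        if self.label not in STATE_LABELS:
            raise ValueError(f"unknown state label {self.label!r}")
        if self.label in ("H", "E") and not self.inner_at_tss:
            raise ValueError(f"{self.label}-state requires inner_at_tss")


def _inner_ok(inner: GenomicInterval, tss: int, params: StateCallParams) -> bool:
    if params.narrow_max_span is not None and len(inner) > params.narrow_max_span:
        return False
    if params.midpoint_at_tss:
        return abs(inner.midpoint - tss) <= params.tss_halfwidth
    window = TSSWindow(inner.chrom, tss, params.tss_halfwidth)
    return overlap_length(inner, window.interval) > 0


def classify_gene_state(
    gene: GeneAnnotation,
    k4_regions: Sequence[GenomicInterval],
    k27_regions: Sequence[GenomicInterval],
    params: StateCallParams = StateCallParams(),
    timepoint: str = "",
) -> GeneStateCall:
    """Classify one gene's joint mark configuration (total decision cascade).

    *k4_regions* / *k27_regions* are the consensus intervals overlapping
    the gene (body union TSS window). The cascade:

    1. zero or one mark present -> ``Unmarked`` / ``K4_only`` / ``K27_only``;
    2. both present but no cross-mark pair overlaps by ``min_overlap`` ->
       ``Non``;
    3. among overlapping pairs, pick the maximal-overlap pair whose union
       intersects the TSS window, falling back to the overall
       maximal-overlap pair;
    4. K27 contains K4 (with slack) and the K4 peak sits at the TSS -> ``H``;
    5. K4 contains K27 and the K27 peak sits at the TSS -> ``E``;
    6. otherwise partial: the longer-spanning mark names the label
       (``K27_gt_K4`` on equal spans — documented tie-break).
    """
    tss = gene.tss
    k4s = list(k4_regions)
    k27s = list(k27_regions)
    if not k4s and not k27s:
        return GeneStateCall(gene.gene_id, timepoint, "Unmarked")
    if not k27s:
        return GeneStateCall(gene.gene_id, timepoint, "K4_only",
                             k4_evidence=_nearest(k4s, tss))
    if not k4s:
        return GeneStateCall(gene.gene_id, timepoint, "K27_only",
                             k27_evidence=_nearest(k27s, tss))

    pairs = [
        (a, b, overlap_length(a, b))
        for a in k4s for b in k27s
        if overlap_length(a, b) >= params.min_overlap
    ]
    if not pairs:
        return GeneStateCall(
            gene.gene_id, timepoint, "Non",
            k4_evidence=_nearest(k4s, tss), k27_evidence=_nearest(k27s, tss),
        )

    window = TSSWindow(k4s[0].chrom, tss, params.tss_halfwidth)

    def union_hits_window(p):
        a, b, _ = p
        union = GenomicInterval(a.chrom, min(a.start, b.start), max(a.end, b.end))
        return overlap_length(union, window.interval) > 0

    def pair_key(p):
        a, b, ov = p
        return (-ov, a.start, a.end, b.start, b.end)

    at_tss = [p for p in pairs if union_hits_window(p)]
    k4, k27, _ = min(at_tss or pairs, key=pair_key)

    if contains(k27, k4, params.containment_slack) and _inner_ok(k4, tss, params):
        return GeneStateCall(gene.gene_id, timepoint, "H",
                             k4_evidence=k4, k27_evidence=k27, inner_at_tss=True)
    if contains(k4, k27, params.containment_slack) and _inner_ok(k27, tss, params):
        return GeneStateCall(gene.gene_id, timepoint, "E",
                             k4_evidence=k4, k27_evidence=k27, inner_at_tss=True)
    label = "K4_gt_K27" if len(k4) > len(k27) else "K27_gt_K4"
    return GeneStateCall(gene.gene_id, timepoint, label,
                         k4_evidence=k4, k27_evidence=k27)


def _nearest(regions: Sequence[GenomicInterval], tss: int) -> GenomicInterval:
    return min(regions, key=lambda r: (abs(r.midpoint - tss), r.start))


def _region_tree(regions: Iterable[MarkRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.interval.chrom, IntervalTree()).addi(
            r.interval.start, r.interval.end, r
        )
    return trees


def call_states(
    genes: Sequence[GeneAnnotation],
    k4: ConsensusMarkSet,
    k27: ConsensusMarkSet,
    params: StateCallParams = StateCallParams(),
    timepoint: str | None = None,
) -> list[GeneStateCall]:
    """Classify every gene against two consensus mark sets.

    For each gene, the consensus regions overlapping its body or its TSS
    window are collected and passed to :func:`classify_gene_state`.
    """
    tp = timepoint if timepoint is not None else k4.timepoint
    trees = {"K4": _region_tree(k4.regions), "K27": _region_tree(k27.regions)}
    calls = []
    for gene in genes:
        body = gene.body
        window = TSSWindow(body.chrom, gene.tss, params.tss_halfwidth)
        lo = min(body.start, window.interval.start)
        hi = max(body.end, window.interval.end)
        per_mark = {}
        for mark, tree_map in trees.items():
            tree = tree_map.get(body.chrom)
            hits = sorted(tree.overlap(lo, hi), key=lambda h: h.begin) if tree else []
            per_mark[mark] = [h.data.interval for h in hits]
        calls.append(
            classify_gene_state(gene, per_mark["K4"], per_mark["K27"], params, tp)
        )
    return calls


@dataclass
class TransitionMatrix:
    """Counts and row fractions of genes moving between state labels."""

    from_timepoint: str
    to_timepoint: str
    labels: tuple[str, ...]
    counts: np.ndarray
    excluded_genes: tuple[str, ...] = ()

    @property
    def n_per_row(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def row_fractions(self) -> np.ndarray:
        n = self.n_per_row.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = self.counts / n[:, None]
        frac[n == 0] = np.nan  # empty origin category
        return frac

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))

    def fractions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.row_fractions, index=list(self.labels),
                            columns=list(self.labels))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# transitions {self.from_timepoint} -> {self.to_timepoint}\n")
            fh.write("# counts\n")
            self.counts_frame().to_csv(fh, sep="\t")
            fh.write("# row_fractions\n")
            self.fractions_frame().to_csv(fh, sep="\t", float_format="%.6g")


def transition_matrix(
    calls_t0: Sequence[GeneStateCall],
    calls_t1: Sequence[GeneStateCall],
    labels: Sequence[str] = STATE_LABELS,
) -> TransitionMatrix:
    """Tabulate state transitions between two timepoints.

    ``counts[i, j]`` is the number of genes labelled ``labels[i]`` at the
    first timepoint and ``labels[j]`` at the second. Genes absent from
    either call set (or carrying a label outside *labels*) are excluded
    and reported in ``excluded_genes``; disjoint gene universes raise.
    """
    m0 = {c.gene_id: c for c in calls_t0}
    m1 = {c.gene_id: c for c in calls_t1}
    shared = set(m0) & set(m1)
    if not shared:
        raise ValueError("call sets have disjoint gene universes")
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    excluded = sorted((set(m0) | set(m1)) - shared)
    for g in shared:
        l0, l1 = m0[g].label, m1[g].label
        if l0 in index and l1 in index:
            counts[index[l0], index[l1]] += 1
        else:
            excluded.append(g)
    tp0 = calls_t0[0].timepoint if calls_t0 else ""
    tp1 = calls_t1[0].timepoint if calls_t1 else ""
    return TransitionMatrix(tp0, tp1, tuple(labels), counts, tuple(sorted(excluded)))


def state_set_overlap(set_a: Iterable[str], set_b: Iterable[str]) -> tuple[int, float, float]:
    """(|A&B|, |A&B|/|A|, |A&B|/|B|) for two gene-id sets (0 on empty)."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    return (
        inter,
        inter / len(a) if a else 0.0,
        inter / len(b) if b else 0.0,
    )
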