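"""Readers and writers for the plain-text genomics formats the pipeline touches.

Supported on input: GFF3 and BED6 gene annotations, BED6 / ENCODE
narrowPeak / broadPeak enrichment regions, bedGraph signal tracks,
long-format expression TSV and external significance-call TSV, and
two-column chrom.sizes files. All genomic output is written 0-based
half-open (BED convention); GFF3 1-based coordinates are converted on read.

Every reader/writer pair round-trips exactly on its own output.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_model import GeneAnnotation, GenomicInterval

__all__ = [
    "PeakFileRecord",
    "ExpressionTable",
    "BedGraphTrack",
    "read_genes",
    "read_peaks",
    "read_bedgraph",
    "write_bedgraph",
    "read_regions",
    "write_regions",
    "read_state_calls",
    "write_state_calls",
    "read_significance_calls",
    "write_significance_calls",
    "read_chrom_sizes",
]


class FormatError(ValueError):
    """Malformed record in an input file; message carries the line number."""


@dataclass(frozen=True)
class PeakFileRecord:
    """One enrichment region from a peak file.

    ``signal`` carries the normalized signal level (ChIP/H3 FPKM ratio for
    histone-mark data); for narrowPeak input it is the signalValue column.
    ``summit`` is the narrowPeak point-source offset, or None (broadPeak,
    BED6).
    """

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    signal: float = 0.0
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"peak {self.name!r}: score must be >= 0")


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _gff3_attr(attrs: str, keys: Sequence[str]) -> str | None:
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        k, v = part.split("=", 1)
        if k in keys:
            return v
    return None


def read_genes(path, format: str = "gff3") -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 or BED6.

    GFF3 1-based closed coordinates become internal 0-based half-open
    (``start - 1``); only ``gene``-type features are kept. Duplicate
    gene_ids raise; malformed lines raise with the line number.
    """
    if format not in ("gff3", "bed"):
        raise ValueError(f"unknown gene format {format!r}")
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        try:
            if format == "gff3":
                if len(fields) < 9:
                    raise ValueError("GFF3 requires 9 columns")
                if fields[2] != "gene":
                    continue
                chrom, start, end, strand = fields[0], int(fields[3]) - 1, int(fields[4]), fields[6]
                gene_id = _gff3_attr(fields[8], ("ID", "gene_id", "Name"))
                if gene_id is None:
                    raise ValueError("no ID/gene_id/Name attribute")
            else:
                if len(fields) < 6:
                    raise ValueError("BED6 requires 6 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                gene_id, strand = fields[3], fields[5]
            gene = GeneAnnotation(gene_id, GenomicInterval(chrom, start, end, strand))
        except ValueError as exc:
            raise FormatError(f"{path}, line {lineno}: {exc}") from exc
        if gene.gene_id in seen:
            raise FormatError(f"{path}, line {lineno}: duplicate gene_id {gene.gene_id!r}")
        seen.add(gene.gene_id)
        genes.append(gene)
    return genes


def write_genes_gff3(genes: Iterable[GeneAnnotation], path) -> None:
    """Write gene annotations as GFF3 (1-based closed on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.body.chrom}\tepistates\tgene\t{g.body.start + 1}\t{g.body.end}\t.\t"
                f"{g.body.strand}\t.\tID={g.gene_id};biotype={g.biotype}\n"
            )


_PEAK_NCOLS = {"bed6": 6, "narrowPeak": 10, "broadPeak": 9}


def read_peaks(path, format: str = "narrowPeak") -> list[PeakFileRecord]:
    """Read enrichment regions from BED6, narrowPeak or broadPeak.

    narrowPeak column 7 (signalValue) maps to ``signal``, column 10 to
    ``summit``; BED6 score maps to both score and signal.
    """
    if format not in _PEAK_NCOLS:
        raise ValueError(f"unknown peak format {format!r}")
    ncols = _PEAK_NCOLS[format]
    peaks: list[PeakFileRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < ncols:
            raise FormatError(f"{path}, line {lineno}: expected >= {ncols} columns")
        try:
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[5])
            if format == "bed6":
                score = float(fields[4])
                rec = PeakFileRecord(iv, fields[3], score, score)
            else:
                summit = int(fields[9]) if format == "narrowPeak" else None
                if summit is not None and summit < -1:
                    raise ValueError("summit offset must be >= -1")
                rec = PeakFileRecord(
                    iv, fields[3], float(fields[4]), float(fields[6]),
                    None if summit in (None, -1) else summit,
                )
        except ValueError as exc:
            raise FormatError(f"{path}, line {lineno}: {exc}") from exc
        peaks.append(rec)
    return peaks


def write_peaks(peaks: Iterable[PeakFileRecord], path, format: str = "narrowPeak") -> None:
    """Write peaks in narrowPeak (or broadPeak) layout, 0-based half-open."""
    if format not in ("narrowPeak", "broadPeak"):
        raise ValueError(f"unknown peak output format {format!r}")
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            base = (
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score:g}\t{iv.strand}\t"
                f"{p.signal:.6g}\t-1\t-1"
            )
            if format == "narrowPeak":
                base += f"\t{-1 if p.summit is None else p.summit}"
            fh.write(base + "\n")


class BedGraphTrack:
    """Piecewise-constant signal, one sorted non-overlapping segment list per
    chromosome. Gaps read as signal 0 (coverage semantics)."""

    def __init__(self, segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # segments: chrom -> (starts, ends, values), sorted, non-overlapping
        self._segments = segments

    @property
    def chroms(self) -> list[str]:
        return sorted(self._segments)

    def segments_in(self, chrom: str, start: float, end: float):
        """(starts, ends, values) of stored segments overlapping [start, end)."""
        if chrom not in self._segments:
            z = np.empty(0)
            return z, z, z
        starts, ends, values = self._segments[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        return starts[lo:hi], ends[lo:hi], values[lo:hi]

    def integral(self, chrom: str, start: float, end: float) -> float:
        """Exact integral of the signal over [start, end); gaps contribute 0.

        Summed with math.fsum so the result is independent of segment order.
        """
        if end <= start:
            return 0.0
        s, e, v = self.segments_in(chrom, start, end)
        return math.fsum(
            float(vi) * (min(float(ei), end) - max(float(si), start))
            for si, ei, vi in zip(s, e, v)
        )

    def mean(self, interval: GenomicInterval) -> float:
        """Length-weighted mean signal over *interval* (gaps count as 0)."""
        return self.integral(interval.chrom, interval.start, interval.end) / len(interval)


def read_bedgraph(path) -> BedGraphTrack:
    """Read a bedGraph file into a queryable track.

    Records may arrive unsorted; overlapping records on a chromosome raise.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"{path}, line {lineno}: bedGraph requires 4 columns")
        try:
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
        except ValueError as exc:
            raise FormatError(f"{path}, line {lineno}: {exc}") from exc
        per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, float(fields[3])))
    segments = {}
    for chrom, recs in per_chrom.items():
        recs.sort()
        for (s0, e0, _), (s1, _, _) in zip(recs, recs[1:]):
            if s1 < e0:
                raise FormatError(
                    f"{path}: overlapping bedGraph intervals on {chrom} at {s1} < {e0}"
                )
        arr = np.asarray(recs, dtype=float)
        segments[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return BedGraphTrack(segments)


def write_bedgraph(track: BedGraphTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track._segments[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.6g}\n")


def write_regions(regions, path) -> None:
    """Write mark regions (objects with .interval and .signal) as BED6.

    The signal level goes to the score column; strand defaults to '.'.
    """
    with open(path, "w") as fh:
        for r in regions:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{r.signal:.10g}\t{iv.strand}\n")


def read_regions(path):
    """Read BED6 mark regions written by :func:`write_regions`."""
    from .peak_pipeline import MarkRegion

    regions = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise FormatError(f"{path}, line {lineno}: BED6 requires 6 columns")
        try:
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[5])
        except ValueError as exc:
            raise FormatError(f"{path}, line {lineno}: {exc}") from exc
        regions.append(MarkRegion(iv, float(fields[4])))
    return regions


_CALL_COLUMNS = [
    "gene_id", "timepoint", "state", "inner_at_tss",
    "k4_chrom", "k4_start", "k4_end", "k27_chrom", "k27_start", "k27_end",
]


def write_state_calls(calls, path) -> None:
    """Write per-gene chromatin-state calls as a headered TSV.

    Evidence intervals absent for a mark are encoded as '.'; the file
    round-trips through :func:`read_state_calls`.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            row = [c.gene_id, c.timepoint, c.label, "1" if c.inner_at_tss else "0"]
            for iv in (c.k4_evidence, c.k27_evidence):
                if iv is None:
                    row += [".", ".", "."]
                else:
                    row += [iv.chrom, str(iv.start), str(iv.end)]
            fh.write("\t".join(row) + "\n")


def read_state_calls(path):
    """Read state calls written by :func:`write_state_calls`."""
    from .chromatin_states import GeneStateCall

    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CALL_COLUMNS:
            raise FormatError(f"{path}: unexpected state-call header {header}")
        for lineno, raw in enumerate(fh, start=2):
            f = raw.rstrip("\n").split("\t")
            if len(f) != len(_CALL_COLUMNS):
                raise FormatError(f"{path}, line {lineno}: expected {len(_CALL_COLUMNS)} columns")

            def iv(chrom, start, end):
                if chrom == ".":
                    return None
                return GenomicInterval(chrom, int(start), int(end))

            calls.append(
                GeneStateCall(
                    gene_id=f[0], timepoint=f[1], label=f[2],
                    inner_at_tss=f[3] == "1",
                    k4_evidence=iv(*f[4:7]), k27_evidence=iv(*f[7:10]),
                )
            )
    return calls


class ExpressionTable:
    """Gene x timepoint x replicate FPKM/count table.

    Backed by a long-format DataFrame with columns ``gene_id``,
    ``timepoint``, ``replicate``, ``fpkm``, ``count``. Replicate FPKMs are
    averaged per timepoint for thresholding; a gene is expressed at a
    timepoint when its mean FPKM exceeds the threshold (strictly).
    """

    COLUMNS = ["gene_id", "timepoint", "replicate", "fpkm", "count"]

    def __init__(self, frame: pd.DataFrame, timepoint_order: Sequence[str] | None = None):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"expression table missing columns {missing}")
        if (frame["fpkm"] < 0).any() or (frame["count"] < 0).any():
            raise ValueError("expression values must be non-negative")
        dup = frame.duplicated(subset=["gene_id", "timepoint", "replicate"])
        if dup.any():
            raise ValueError("duplicate (gene_id, timepoint, replicate) rows")
        self.frame = frame.reset_index(drop=True)
        if timepoint_order is None:
            timepoint_order = list(pd.unique(frame["timepoint"]))
        self.timepoints = list(timepoint_order)
        self.genes = list(pd.unique(frame["gene_id"]))

    def mean_fpkm(self) -> pd.DataFrame:
        """Gene x timepoint matrix of replicate-averaged FPKM."""
        wide = self.frame.pivot_table(
            index="gene_id", columns="timepoint", values="fpkm", aggfunc="mean"
        )
        return wide.reindex(index=self.genes, columns=self.timepoints)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, timepoint_order: Sequence[str] | None = None) -> "ExpressionTable":
        frame = pd.read_csv(path, sep="\t", comment="#")
        return cls(frame, timepoint_order)


_SIG_COLUMNS = ["gene_id", "contrast", "direction", "significant"]


def write_significance_calls(frame: pd.DataFrame, path) -> None:
    """Write external differential-significance calls (the DE input contract)."""
    frame[_SIG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_significance_calls(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _SIG_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: significance table missing columns {missing}")
    bad = set(frame["direction"]) - {"up", "down"}
    if bad:
        raise FormatError(f"{path}: unknown direction tokens {sorted(bad)}")
    return frame


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column chrom.sizes file -> {chrom: length}."""
    sizes: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}, line {lineno}: expected 2 columns")
        sizes[fields[0]] = int(fields[1])
    return sizes
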