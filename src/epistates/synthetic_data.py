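"""Synthetic annotation + peak + signal + expression datasets with known truth.

The generator emulates the statistical structure of a nuclear-purified
time-course epigenome study at desk scale: a gene set partitioned into
expressed (FPKM > 1) and silent genes, log-scale expression with a planted
Spearman coupling between TSS H3K4me3 signal and expression (Gaussian
copula on ranks), per-gene joint H3K4me3/H3K27me3 configurations realizing
planted chromatin-state fractions, two noisy replicates per mark with a
planted fraction of discordant regions, and Markov state switching plus
expression trends across the photoperiod-shift time course. Every planted
quantity is recorded in :class:`GroundTruth` for recovery tests.

Replicate noise is antisymmetric and bounded: the two replicates of a
region carry signals ``v + u/2`` and ``v - u/2`` with ``u`` uniform,
calibrated so the replicate difference has standard deviation
``sqrt(2) * replicate_noise_sd`` (what independent Gaussian noise of that
s.d. would give) but bounded support below 2 s.d. of the difference
distribution. Discordant regions instead carry a fixed offset of
``4 * replicate_noise_sd`` on replicate 1. Consequently the 2 s.d.
concordance filter separates planted discordant pairs exactly, and the
consensus (mean) signal recovers the planted region signal exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .genome_model import GeneAnnotation, GenomicInterval
from .io_formats import (
    BedGraphTrack,
    ExpressionTable,
    PeakFileRecord,
    write_bedgraph,
    write_genes_gff3,
    write_peaks,
    write_significance_calls,
)
from .peak_pipeline import ReplicateRegionSet

__all__ = ["SimulationConfig", "GroundTruth", "SimulatedDataset",
           "simulate", "simulate_replicate_pair"]

STATES = ("H", "E", "K27_gt_K4", "K4_gt_K27", "Non", "K4_only", "K27_only", "Unmarked")
K4_STATES = frozenset({"H", "E", "K27_gt_K4", "K4_gt_K27", "Non", "K4_only"})
K27_STATES = frozenset({"H", "E", "K27_gt_K4", "K4_gt_K27", "Non", "K27_only"})

# Default per-stratum state fractions. Expressed genes carry H3K4me3 at the
# TSS with probability 0.66 and silent genes with probability 0.05; 41% of
# silent genes carry a broad H3K27me3 domain only.
_EXPRESSED_FRACTIONS = {
    "H": 0.10, "E": 0.07, "K27_gt_K4": 0.06, "K4_gt_K27": 0.06,
    "Non": 0.07, "K4_only": 0.30, "K27_only": 0.14, "Unmarked": 0.20,
}
_SILENT_FRACTIONS = {
    "H": 0.01, "E": 0.01, "K27_gt_K4": 0.01, "K4_gt_K27": 0.01,
    "Non": 0.01, "K4_only": 0.00, "K27_only": 0.41, "Unmarked": 0.54,
}

# Default Markov switching per one-day step: mass 0.88 stays put.
_TRANSITIONS = {
    "H": {"H": 0.88, "E": 0.02, "K4_only": 0.04, "K27_only": 0.03, "Non": 0.03},
    "E": {"E": 0.88, "H": 0.02, "K4_only": 0.05, "K27_only": 0.02, "Non": 0.03},
    "K27_gt_K4": {"K27_gt_K4": 0.88, "H": 0.04, "K27_only": 0.04, "Non": 0.04},
    "K4_gt_K27": {"K4_gt_K27": 0.88, "E": 0.04, "K4_only": 0.04, "Non": 0.04},
    "Non": {"Non": 0.88, "H": 0.03, "E": 0.03, "K4_only": 0.03, "K27_only": 0.03},
    "K4_only": {"K4_only": 0.88, "Unmarked": 0.06, "H": 0.03, "K4_gt_K27": 0.03},
    "K27_only": {"K27_only": 0.90, "Unmarked": 0.06, "H": 0.02, "K27_gt_K4": 0.02},
    "Unmarked": {"Unmarked": 0.92, "K27_only": 0.05, "K4_only": 0.03},
}

_SLOT = 10_000  # bases reserved per gene; keeps neighbouring regions disjoint
_TSS_OFFSET = 3_000  # TSS position inside the slot (transcription direction)


def _check_fractions(name: str, fr: Mapping[str, float]) -> None:
    if set(fr) - set(STATES):
        raise ValueError(f"{name}: unknown states {sorted(set(fr) - set(STATES))}")
    if any(not (0 <= v <= 1) for v in fr.values()):
        raise ValueError(f"{name}: fractions must lie in [0, 1]")
    if abs(sum(fr.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name}: fractions must sum to 1, got {sum(fr.values())}")


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fixes every draw."""

    seed: int = 0
    n_genes: int = 2000
    n_chroms: int = 5
    chrom_length: int = 20_000_000
    timepoints: tuple[str, ...] = ("0LD", "1LD", "2LD", "3LD")
    frac_expressed: float = 0.6
    expr_logmean: float = 1.5
    expr_logsd: float = 1.2
    expr_rep_noise: float = 0.05  # relative antisymmetric replicate deviation
    target_rho_k4: float = 0.31
    state_fractions_expressed: dict[str, float] = field(
        default_factory=lambda: dict(_EXPRESSED_FRACTIONS))
    state_fractions_silent: dict[str, float] = field(
        default_factory=lambda: dict(_SILENT_FRACTIONS))
    state_fractions_override: dict[str, float] | None = None
    replicate_noise_sd: float = 0.5
    frac_discordant: float = 0.02
    discordant_offset_mult: float = 4.0
    transition_spec: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _TRANSITIONS.items()})
    de_spec: dict[str, float] = field(
        default_factory=lambda: {"up": 0.05, "down": 0.05, "complex": 0.01})
    signal_logmean: float = 1.2
    signal_logsd: float = 0.5

    def __post_init__(self) -> None:
        for name in ("frac_expressed", "frac_discordant"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.state_fractions_override is not None:
            fr = {s: self.state_fractions_override.get(s, 0.0) for s in STATES}
            _check_fractions("state_fractions", fr)
            self.state_fractions_expressed = dict(fr)
            self.state_fractions_silent = dict(fr)
        _check_fractions("state_fractions_expressed", self.state_fractions_expressed)
        _check_fractions("state_fractions_silent", self.state_fractions_silent)
        for state, row in self.transition_spec.items():
            _check_fractions(f"transition_spec[{state}]", row)
        if sum(self.de_spec.values()) > 1.0 + 1e-9:
            raise ValueError("de_spec fractions must sum to <= 1")
        slots = self.n_chroms * (self.chrom_length // _SLOT)
        if self.n_genes > slots:
            raise ValueError(
                f"infeasible geometry: {self.n_genes} genes need {self.n_genes} "
                f"slots of {_SLOT} bp but only {slots} fit on "
                f"{self.n_chroms} x {self.chrom_length} bp chromosomes"
            )

    @property
    def state_fractions(self) -> dict[str, float]:
        """Planted global state mixture (expressed/silent strata combined)."""
        fe, fs = self.frac_expressed, 1.0 - self.frac_expressed
        return {
            s: fe * self.state_fractions_expressed[s] + fs * self.state_fractions_silent[s]
            for s in STATES
        }

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["timepoints"] = list(self.timepoints)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "timepoints" in d:
            d["timepoints"] = tuple(d["timepoints"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted truths, consistent with the emitted files.

    genes: gene_id, chrom, start, end, strand, expressed, de_class
    states: gene_id, timepoint, state, fpkm, k4_tss_signal, expressed_at_tp
    regions: region_id, mark, timepoint, gene_id, chrom, start, end,
             signal, discordant
    """

    genes: pd.DataFrame
    states: pd.DataFrame
    regions: pd.DataFrame

    def write(self, outdir: Path) -> None:
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.states.to_csv(outdir / "truth_states.tsv", sep="\t", index=False,
                           float_format="%.10g")
        self.regions.to_csv(outdir / "truth_regions.tsv", sep="\t", index=False,
                            float_format="%.10g")


@dataclass
class SimulatedDataset:
    """In-memory simulation output plus writers for the on-disk formats."""

    config: SimulationConfig
    genes: list[GeneAnnotation]
    replicates: dict[tuple[str, str, int], ReplicateRegionSet]  # (mark, tp, rep)
    tracks: dict[tuple[str, str], BedGraphTrack]  # (mark, tp)
    expression: ExpressionTable
    significance: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir) -> None:
        """Write the full file set (GFF3, narrowPeak, bedGraph, TSVs).

        Identical configs (including seed) produce byte-identical trees.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(outdir / "config.yaml")
        write_genes_gff3(self.genes, outdir / "genes.gff3")
        for (mark, tp, rep), rrs in sorted(self.replicates.items()):
            write_peaks(rrs.regions, outdir / f"{mark}_{tp}_rep{rep}.narrowPeak")
        for (mark, tp), track in sorted(self.tracks.items()):
            write_bedgraph(track, outdir / f"{mark}_{tp}.bedgraph")
        self.expression.to_tsv(outdir / "expression.tsv")
        write_significance_calls(self.significance, outdir / "significance.tsv")
        self.truth.write(outdir)


def _offsets_to_interval(chrom: str, tss: int, d0: int, d1: int) -> GenomicInterval:
    """Transcription-direction offsets [d0, d1) from the TSS base -> genomic."""
    return GenomicInterval(chrom, tss + d0, tss + d1)


def _region_geometry(state: str, rng: np.random.Generator) -> dict[str, tuple[int, int]]:
    """Offset intervals (transcription direction, relative to TSS) realizing
    *state*. Keys 'K4'/'K27' present where the mark exists."""
    out: dict[str, tuple[int, int]] = {}

    def narrow() -> tuple[int, int]:
        w = int(rng.integers(150, 601))
        c = int(rng.integers(-500 + (w + 1) // 2, 500 - (w + 1) // 2 + 1))
        lo = c - w // 2
        return lo, lo + w

    if state == "Unmarked":
        return out
    if state in ("H", "E"):
        lo, hi = narrow()
        w_in = hi - lo
        w_out = int(rng.integers(max(1500, w_in + 200), 4001))
        a = int(rng.integers(50, min(1500, w_out - w_in - 50) + 1))
        outer = (lo - a, lo - a + w_out)
        if state == "H":
            out["K4"], out["K27"] = (lo, hi), outer
        else:
            out["K27"], out["K4"] = (lo, hi), outer
        return out
    if state in ("K27_gt_K4", "K4_gt_K27"):
        w_n = int(rng.integers(300, 601))
        c = int(rng.integers(-500 + (w_n + 1) // 2, 500 - (w_n + 1) // 2 + 1))
        lo = c - w_n // 2
        shift = int(rng.integers(50, w_n - 50 + 1))
        w_b = int(rng.integers(w_n + 500, 3001))
        longer = (lo + shift, lo + shift + w_b)
        if state == "K27_gt_K4":
            out["K4"], out["K27"] = (lo, lo + w_n), longer
        else:
            out["K27"], out["K4"] = (lo, lo + w_n), longer
        return out
    if state == "Non":
        w4 = int(rng.integers(150, 601))
        c = int(rng.integers(-500 + (w4 + 1) // 2, 500 - (w4 + 1) // 2 + 1))
        lo = c - w4 // 2
        j = int(rng.integers(0, 301))
        w27 = int(rng.integers(1500, 3001))
        out["K4"] = (lo, lo + w4)
        out["K27"] = (700 + j, 700 + j + w27)
        return out
    if state == "K4_only":
        out["K4"] = narrow()
        return out
    if state == "K27_only":
        j = int(rng.integers(0, 401))
        w27 = int(rng.integers(1500, 4001))
        out["K27"] = (-1000 + j, -1000 + j + w27)
        return out
    raise ValueError(f"unknown state {state!r}")


def _draw_states(rng, labels, probs, n):
    return rng.choice(labels, size=n, p=probs)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full synthetic dataset under *config*.

    Genes are placed on non-overlapping fixed slots on both strands, so
    regions of neighbouring genes never merge. See the module docstring
    for the planted statistical structure.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    tps = list(config.timepoints)
    mark_name = {"K4": "H3K4me3", "K27": "H3K27me3"}

    # --- gene placement on fixed slots, both strands -----------------------
    slots_per_chrom = config.chrom_length // _SLOT
    all_slots = [(c, s) for c in range(config.n_chroms) for s in range(slots_per_chrom)]
    chosen = rng.choice(len(all_slots), size=n, replace=False)
    chosen.sort()
    strands = rng.choice(["+", "-"], size=n)
    lengths = rng.integers(1000, 5001, size=n)
    genes: list[GeneAnnotation] = []
    tss_list: list[int] = []
    for i, (slot_idx, strand, L) in enumerate(zip(chosen, strands, lengths)):
        chrom_i, slot = all_slots[slot_idx]
        chrom = f"chr{chrom_i + 1}"
        base = slot * _SLOT
        if strand == "+":
            tss = base + _TSS_OFFSET
            body = GenomicInterval(chrom, tss, tss + int(L), "+")
        else:
            tss = base + _SLOT - _TSS_OFFSET - 1
            body = GenomicInterval(chrom, tss - int(L) + 1, tss + 1, "-")
        genes.append(GeneAnnotation(f"gene{i + 1:05d}", body))
        tss_list.append(tss)

    # --- expression --------------------------------------------------------
    expressed = rng.random(n) < config.frac_expressed
    base_fpkm = np.where(
        expressed,
        1.0 + np.exp(rng.normal(config.expr_logmean, config.expr_logsd, size=n)),
        rng.uniform(0.0, 0.9, size=n),
    )

    de_class = np.full(n, "ns", dtype=object)
    expr_idx = np.flatnonzero(expressed)
    perm = rng.permutation(expr_idx)
    pos = 0
    for cls in ("up", "down", "complex"):
        k = int(round(config.de_spec.get(cls, 0.0) * expr_idx.size))
        de_class[perm[pos:pos + k]] = cls
        pos += k

    # per-timepoint fold factors realizing the DE classes
    factors = {"up": [1.0, 1.6, 2.4, 3.2], "down": [1.0, 0.7, 0.45, 0.3],
               "complex": [1.0, 2.2, 1.6, 0.4], "ns": [1.0] * 4}
    fpkm_t = np.empty((n, len(tps)))
    for ti in range(len(tps)):
        f = np.array([factors[c][min(ti, 3)] for c in de_class])
        fpkm_t[:, ti] = base_fpkm * f

    # --- state chains ------------------------------------------------------
    labels = list(STATES)
    pe = np.array([config.state_fractions_expressed[s] for s in labels])
    ps = np.array([config.state_fractions_silent[s] for s in labels])
    pe, ps = pe / pe.sum(), ps / ps.sum()
    states = np.empty((n, len(tps)), dtype=object)
    for i in range(n):
        states[i, 0] = rng.choice(labels, p=pe if expressed[i] else ps)
    trans = {
        s: (list(row.keys()), np.array(list(row.values())) / sum(row.values()))
        for s, row in config.transition_spec.items()
    }
    for ti in range(1, len(tps)):
        for i in range(n):
            lab, p = trans[states[i, ti - 1]]
            states[i, ti] = rng.choice(lab, p=p)

    # --- region geometry and signals ---------------------------------------
    sigma = config.replicate_noise_sd
    u_bound = math.sqrt(6.0) * sigma  # difference s.d. sqrt(2)*sigma, bounded
    offset = config.discordant_offset_mult * sigma
    rho_r = 2.0 * math.sin(math.pi * config.target_rho_k4 / 6.0)

    region_rows = []
    rep_records: dict[tuple[str, str, int], list[PeakFileRecord]] = {}
    track_segments: dict[tuple[str, str], dict[str, list]] = {}
    k4_tss_signal = np.full((n, len(tps)), np.nan)

    for ti, tp in enumerate(tps):
        geoms = [_region_geometry(states[i, ti], rng) for i in range(n)]
        has_k4 = np.array(["K4" in g for g in geoms])

        # planted TSS H3K4me3 signal: Gaussian copula against FPKM rank
        # among expressed K4-marked genes at this timepoint
        signal_v = np.empty(n)
        eligible = has_k4 & (fpkm_t[:, ti] > 1.0)
        if np.count_nonzero(eligible) < 3:  # too few for a rank coupling
            eligible[:] = False
        idx = np.flatnonzero(eligible)
        if idx.size:
            ranks = stats.rankdata(fpkm_t[idx, ti], method="average")
            zx = stats.norm.ppf((ranks - 0.5) / idx.size)
            eps = rng.standard_normal(idx.size)
            z = rho_r * zx + math.sqrt(1.0 - rho_r**2) * eps
            signal_v[idx] = np.exp(config.signal_logmean + config.signal_logsd * z)
        rest = np.flatnonzero(has_k4 & ~eligible)
        signal_v[rest] = np.exp(
            config.signal_logmean
            + config.signal_logsd * rng.standard_normal(rest.size)
        )
        k4_tss_signal[has_k4, ti] = signal_v[has_k4]

        for i in range(n):
            gene, tss, strand = genes[i], tss_list[i], genes[i].body.strand
            chrom = gene.body.chrom
            for mark_key in ("K4", "K27"):
                if mark_key not in geoms[i]:
                    continue
                d0, d1 = geoms[i][mark_key]
                if strand == "+":
                    iv = _offsets_to_interval(chrom, tss, d0, d1)
                else:
                    iv = GenomicInterval(chrom, tss - d1 + 1, tss - d0 + 1)
                mark = mark_name[mark_key]
                if mark_key == "K4":
                    v = float(signal_v[i])
                else:
                    v = float(np.exp(config.signal_logmean
                                     + config.signal_logsd * rng.standard_normal()))
                discordant = bool(rng.random() < config.frac_discordant)
                if discordant:
                    s1, s2 = v + offset, v
                else:
                    u = float(rng.uniform(-u_bound, u_bound))
                    s1, s2 = v + u / 2.0, v - u / 2.0
                name = f"{mark}_{tp}_{gene.gene_id}"
                for rep, s in ((1, s1), (2, s2)):
                    rep_records.setdefault((mark, tp, rep), []).append(
                        PeakFileRecord(iv, f"{name}_rep{rep}", 0.0, s)
                    )
                track_segments.setdefault((mark, tp), {}).setdefault(chrom, []).append(
                    (iv.start, iv.end, v)
                )
                region_rows.append((name, mark, tp, gene.gene_id, chrom,
                                    iv.start, iv.end, v, discordant))

    replicates = {
        key: ReplicateRegionSet(key[0], key[1], key[2],
                                sorted(recs, key=lambda r: (r.interval.chrom,
                                                            r.interval.start)))
        for key, recs in rep_records.items()
    }
    tracks = {}
    for key, per_chrom in track_segments.items():
        segs = {}
        for chrom, triples in per_chrom.items():
            triples.sort()
            arr = np.asarray(triples, dtype=float)
            segs[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
        tracks[key] = BedGraphTrack(segs)

    # --- expression table (replicates antisymmetric around the mean) --------
    expr_rows = []
    depth_kb = 30.0  # pseudo count depth: counts ~ fpkm * kb * depth
    e_noise = rng.uniform(0.0, config.expr_rep_noise, size=(n, len(tps)))
    for ti, tp in enumerate(tps):
        for i, gene in enumerate(genes):
            m = fpkm_t[i, ti]
            kb = len(gene.body) / 1000.0
            for rep, f in ((1, 1.0 + e_noise[i, ti]), (2, 1.0 - e_noise[i, ti])):
                val = m * f
                expr_rows.append(
                    (gene.gene_id, tp, rep, val, int(round(val * kb * depth_kb)))
                )
    expression = ExpressionTable(
        pd.DataFrame(expr_rows, columns=ExpressionTable.COLUMNS),
        timepoint_order=tps,
    )

    # --- significance calls realizing the DE classes ------------------------
    contrasts = [f"{tps[0]}->{t}" for t in tps[1:]]
    sig_rows = []
    for i, gene in enumerate(genes):
        cls = de_class[i]
        for ci, contrast in enumerate(contrasts):
            fold_dir = "up" if fpkm_t[i, ci + 1] >= fpkm_t[i, 0] else "down"
            if cls == "up":
                direction, sig = "up", 1
            elif cls == "down":
                direction, sig = "down", 1
            elif cls == "complex":
                direction = "up" if ci == 0 else "down"
                sig = 1 if ci in (0, len(contrasts) - 1) else 0
            else:
                direction, sig = fold_dir, 0
            sig_rows.append((gene.gene_id, contrast, direction, sig))
    significance = pd.DataFrame(
        sig_rows, columns=["gene_id", "contrast", "direction", "significant"]
    )

    truth_genes = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.body.chrom for g in genes],
            "start": [g.body.start for g in genes],
            "end": [g.body.end for g in genes],
            "strand": [g.body.strand for g in genes],
            "expressed": expressed.astype(int),
            "de_class": de_class,
        }
    )
    truth_states = pd.DataFrame(
        [
            (genes[i].gene_id, tp, states[i, ti], fpkm_t[i, ti],
             k4_tss_signal[i, ti], int(fpkm_t[i, ti] > 1.0))
            for ti, tp in enumerate(tps)
            for i in range(n)
        ],
        columns=["gene_id", "timepoint", "state", "fpkm",
                 "k4_tss_signal", "expressed_at_tp"],
    )
    truth_regions = pd.DataFrame(
        region_rows,
        columns=["region_id", "mark", "timepoint", "gene_id", "chrom",
                 "start", "end", "signal", "discordant"],
    )
    truth_regions["discordant"] = truth_regions["discordant"].astype(int)

    return SimulatedDataset(
        config=config,
        genes=genes,
        replicates=replicates,
        tracks=tracks,
        expression=expression,
        significance=significance,
        truth=GroundTruth(truth_genes, truth_states, truth_regions),
    )


def simulate_replicate_pair(
    n_regions: int,
    replicate_noise_sd: float = 0.5,
    frac_discordant: float = 0.02,
    seed: int = 0,
    mark: str = "H3K4me3",
    timepoint: str = "0LD",
    discordant_offset_mult: float = 4.0,
    signal_logmean: float = 1.2,
    signal_logsd: float = 0.5,
) -> tuple[ReplicateRegionSet, ReplicateRegionSet, np.ndarray]:
    """A bare replicate pair with planted discordance, for filter studies.

    Regions sit on one chromosome, identical intervals across replicates,
    with the same bounded antisymmetric noise model as :func:`simulate`.
    Returns (rep1, rep2, boolean discordant mask over region index).
    """
    rng = np.random.default_rng(seed)
    sigma = replicate_noise_sd
    u_bound = math.sqrt(6.0) * sigma
    offset = discordant_offset_mult * sigma
    v = np.exp(signal_logmean + signal_logsd * rng.standard_normal(n_regions))
    discordant = rng.random(n_regions) < frac_discordant
    u = rng.uniform(-u_bound, u_bound, size=n_regions)
    s1 = np.where(discordant, v + offset, v + u / 2.0)
    s2 = np.where(discordant, v, v - u / 2.0)
    starts = 2000 * np.arange(n_regions)
    widths = rng.integers(300, 1500, size=n_regions)
    recs1, recs2 = [], []
    for i in range(n_regions):
        iv = GenomicInterval("chr1", int(starts[i]), int(starts[i] + widths[i]))
        recs1.append(PeakFileRecord(iv, f"r{i}_rep1", 0.0, float(s1[i])))
        recs2.append(PeakFileRecord(iv, f"r{i}_rep2", 0.0, float(s2[i])))
    return (
        ReplicateRegionSet(mark, timepoint, 1, recs1),
        ReplicateRegionSet(mark, timepoint, 2, recs2),
        discordant,
    )
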