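import math

import numpy as np
import pytest

from epistates.genome_model import GeneAnnotation, GenomicInterval
from epistates.io_formats import BedGraphTrack
from epistates.metagene import (
    body_normalized_matrix,
    order_rows,
    tss_anchored_matrix,
)


def gene(gene_id, start, end, strand="+", chrom="chr1"):
    return GeneAnnotation(gene_id, GenomicInterval(chrom, start, end, strand))


def track(segments, chrom="chr1"):
    arr = np.asarray(sorted(segments), dtype=float)
    return BedGraphTrack({chrom: (arr[:, 0], arr[:, 1], arr[:, 2])})


def constant_track(value, length=200_000, chrom="chr1"):
    return track([(0, length, value)], chrom)


def mirror_genes_and_track(genes, segs, L):
    """Reverse chromosome coordinates and flip strands."""
    mg = []
    for g in genes:
        flipped = "-" if g.body.strand == "+" else "+"
        mg.append(gene(g.gene_id, L - g.body.end, L - g.body.start, flipped))
    msegs = [(L - e, L - s, v) for s, e, v in segs]
    return mg, track(msegs)


class TestTssAnchored:
    def test_default_bin_count_is_120(self):
        m = tss_anchored_matrix([gene("g", 50_000, 60_000)], constant_track(1.0))
        assert m.frame.shape == (1, 120)

    def test_constant_signal_fills_every_cell_on_both_strands(self):
        genes = [gene("g+", 50_000, 60_000), gene("g-", 80_000, 90_000, "-")]
        m = tss_anchored_matrix(genes, constant_track(2.0))
        assert np.all(m.frame.values == 2.0)

    def test_minus_strand_block_lands_downstream_after_flip(self):
        # block 1000-1100 bases 5' of nothing: put signal just downstream of
        # the minus-strand TSS (i.e. at genomic coordinates below the TSS)
        g = gene("g", 40_000, 50_000, "-")  # TSS at 49_999
        segs = [(48_900, 49_000, 5.0)]
        m = tss_anchored_matrix([g], track(segs))
        vals = m.frame.values[0]
        labels = [int(c) for c in m.frame.columns]
        nonzero = [labels[i] for i in np.flatnonzero(vals)]
        # per-base oracle: bases 48900..48999 lie 1000..1099 transcription-
        # direction bases downstream of the TSS -> exactly the [1000,1100) bin
        assert nonzero == [1000]
        assert vals[labels.index(1000)] == pytest.approx(5.0)

    def test_out_of_chromosome_bins_masked_and_zero(self):
        g = gene("g", 1000, 3000)  # window starts 3000 bases left of 0
        m = tss_anchored_matrix([g], constant_track(1.0),
                                chrom_sizes={"chr1": 200_000})
        vals, mask = m.frame.values[0], m.mask.values[0]
        assert mask[:30].all() and not mask[30:].any()
        assert np.all(vals[:30] == 0.0) and np.all(vals[30:] == 1.0)

    def test_mirror_invariance(self):
        L = 200_000
        rng = np.random.default_rng(1)
        segs = [(int(s), int(s) + 500, float(v))
                for s, v in zip(rng.integers(0, L - 500, 40) // 700 * 700,
                                rng.uniform(0.5, 4, 40))]
        segs = list({(s, e): (s, e, v) for s, e, v in segs}.values())
        genes = [gene("g1", 50_000, 58_000), gene("g2", 90_000, 97_000, "-")]
        m = tss_anchored_matrix(genes, track(segs), chrom_sizes={"chr1": L})
        mg, mt = mirror_genes_and_track(genes, segs, L)
        mm = tss_anchored_matrix(mg, mt, chrom_sizes={"chr1": L})
        assert np.array_equal(m.frame.values, mm.frame.values)


class TestBodyNormalized:
    def test_default_layout_70_columns(self):
        m = body_normalized_matrix([gene("g", 50_000, 52_500)], constant_track(1.0))
        assert m.frame.shape == (1, 70)
        assert list(m.frame.columns[:2]) == ["up1", "up2"]
        assert list(m.frame.columns[-2:]) == ["down9", "down10"]

    def test_body_bin_width_is_length_over_50(self):
        # gene of length 500: body bins are 10 bp; a 10 bp block of signal
        # fills exactly one body bin
        g = gene("g", 10_000, 10_500)
        m = body_normalized_matrix([g], track([(10_200, 10_210, 7.0)]))
        body = m.frame.values[0][10:60]
        assert np.count_nonzero(body) == 1
        assert body[20] == pytest.approx(7.0)

    def test_fractional_weighting_matches_perbase_oracle(self):
        # gene length 55: bin width 1.1 bases; compare against an explicit
        # per-base integral oracle
        g = gene("g", 1000, 1055)
        segs = [(1000, 1020, 2.0), (1030, 1055, 5.0)]
        m = body_normalized_matrix([g], track(segs))
        body = m.frame.values[0][10:60]

        def perbase(lo, hi):  # integral of the step signal over [lo, hi)
            total = 0.0
            for s, e, v in segs:
                total += v * max(0.0, min(e, hi) - max(s, lo))
            return total

        L = 55
        for b in range(50):
            lo, hi = 1000 + b * L / 50, 1000 + (b + 1) * L / 50
            assert body[b] == pytest.approx(perbase(lo, hi) / (L / 50), rel=1e-12)

    def test_mass_conservation_exact(self):
        rng = np.random.default_rng(3)
        g = gene("g", 20_000, 23_777)
        segs = []
        pos = 19_000
        while pos < 25_000:
            w = int(rng.integers(50, 400))
            segs.append((pos, pos + w, float(rng.uniform(0, 5))))
            pos += w + int(rng.integers(0, 200))
        t = track(segs)
        m = body_normalized_matrix([g], t)
        L = len(g.body)
        mass = math.fsum(m.frame.values[0][10:60]) * (L / 50)
        assert mass == pytest.approx(t.integral("chr1", 20_000, 23_777), rel=1e-9)

    def test_short_gene_flagged(self):
        m = body_normalized_matrix([gene("g", 100, 130)], constant_track(1.0))
        assert m.short_genes == ("g",)

    def test_mirror_invariance_bitwise(self):
        L = 60_000
        rng = np.random.default_rng(7)
        segs = []
        pos = 0
        while pos < L - 500:
            w = int(rng.integers(100, 400))
            segs.append((pos, pos + w, float(rng.uniform(0.1, 3))))
            pos += w + int(rng.integers(50, 300))
        genes = [gene("a", 10_000, 13_777), gene("b", 30_000, 34_001, "-")]
        m = body_normalized_matrix(genes, track(segs))
        mg, mt = mirror_genes_and_track(genes, segs, L)
        mm = body_normalized_matrix(mg, mt)
        assert np.array_equal(m.frame.values, mm.frame.values)


class TestOrderRows:
    def make_matrix(self):
        genes = [gene(g, 10_000 * (i + 1), 10_000 * (i + 1) + 2000)
                 for i, g in enumerate("abcde")]
        return body_normalized_matrix(genes, constant_track(1.0))

    def test_expressed_block_first_then_silent_by_signal(self):
        m = self.make_matrix()
        fpkm = {"a": 9.0, "b": 3.0, "c": 20.0, "d": 0.1, "e": 0.5}
        k27 = {"d": 1.0, "e": 7.0}
        ordered = order_rows(m, fpkm, k27)
        assert ordered.gene_ids == ["c", "a", "b", "e", "d"]

    def test_equal_expression_ties_break_by_gene_id(self):
        m = self.make_matrix()
        fpkm = {g: 5.0 for g in "abcde"}
        ordered = order_rows(m, fpkm)
        assert ordered.gene_ids == list("abcde")

    def test_planted_monotone_coupling_sorts_high_signal_first(self):
        genes = [gene(f"g{i}", 10_000 * (i + 1), 10_000 * (i + 1) + 2000)
                 for i in range(6)]
        segs = [(g.body.start, g.body.end, float(i + 1))
                for i, g in enumerate(genes)]
        m = body_normalized_matrix(genes, track(segs))
        fpkm = {g.gene_id: float(i + 2) for i, g in enumerate(genes)}
        ordered = order_rows(m, fpkm)
        row_means = ordered.frame.mean(axis=1).values
        assert np.all(np.diff(row_means) < 0)
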