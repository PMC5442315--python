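# epistates

Joint H3K4me3/H3K27me3 chromatin-state analysis anchored at transcription
start sites, for time-course ChIP-seq + RNA-seq studies of small, hard-to-
sample tissues (the motivating system is the plant shoot apical meristem
across a short-day → long-day photoperiod shift).

Genome-wide maps of the activating mark H3K4me3 and the repressive mark
H3K27me3 frequently co-occur near the TSS of the same gene. `epistates`
classifies each gene's joint mark configuration into one of eight states:

| label | configuration |
|---|---|
| `H` | "harbouring": broad H3K27me3 region containing a narrow H3K4me3 peak whose midpoint lies within ±500 bp of the TSS |
| `E` | "embedded": narrow H3K27me3 peak inside a broader H3K4me3 domain at the TSS |
| `K27_gt_K4` / `K4_gt_K27` | partial overlap, the named mark spanning more bases |
| `Non` | both marks on the gene but never overlapping |
| `K4_only` / `K27_only` / `Unmarked` | one or zero marks present |

Around the classifier the package provides the full analysis pipeline:

* **peak_pipeline** — replicate concordance filtering (matched region pairs
  whose ChIP/H3 signal difference deviates from the mean difference by more
  than 2 s.d. are discarded) and consensus region construction (union of
  every cross-replicate overlapping chain; single-replicate regions drop);
* **chromatin_states** — the state classifier, state-transition matrices
  between timepoints, and cross-tissue state-set overlap;
* **mark_association** — per-gene mark profiles (TSS ±500 bp window),
  marked proportions in expressed (FPKM > 1) vs non-expressed strata with
  mean ± s.e. over timepoints, and Spearman rank correlation between TSS
  signal and expression with the Student-*t* significance approximation
  ρ·√((n−2)/(1−ρ²));
* **metagene** — TSS-anchored (−4 kb…+8 kb, 100 bp bins) and
  length-normalized gene-body (10 + 50 + 10 bins) signal matrices with
  exact signal-mass conservation, rows ordered by expression;
* **expression_analysis** — expressed-gene flags, consistency
  classification of differential-expression directions (up / down /
  complex / ns), the zero-slope regression test of mean expression against
  time, and ΔΔCt qPCR quantification with the undetected-Ct = 40 cap;
* **synthetic_data** — a seeded generator emitting GFF3 + narrowPeak +
  bedGraph + TSV datasets with planted state fractions, planted
  mark–expression Spearman correlation (Gaussian copula), planted replicate
  discordance and planted state transitions, all recorded for recovery
  tests;
* **io_formats** — GFF3/BED6/narrowPeak/broadPeak/bedGraph/TSV readers and
  writers, 0-based half-open internally.

## Worked example

```python
from collections import Counter
from epistates import (SimulationConfig, simulate, StateCallParams,
                       call_states, transition_matrix)
from epistates.peak_pipeline import (concordance_filter, consensus_regions,
                                     ReplicateRegionSet)

ds = simulate(SimulationConfig(seed=42, n_genes=2000))

def consensus(mark, tp):
    r1, r2 = ds.replicates[(mark, tp, 1)], ds.replicates[(mark, tp, 2)]
    res = concordance_filter(r1, r2)
    print(f"{mark}/{tp}: {len(res.removed_pairs)} discordant pairs removed")
    return consensus_regions(ReplicateRegionSet(mark, tp, 1, res.rep1_kept),
                             ReplicateRegionSet(mark, tp, 2, res.rep2_kept))

calls_0 = call_states(ds.genes, consensus("H3K4me3", "0LD"),
                      consensus("H3K27me3", "0LD"), StateCallParams(), "0LD")
print(dict(Counter(c.label for c in calls_0)))
```

prints

```
H3K4me3/0LD: 18 discordant pairs removed
H3K27me3/0LD: 29 discordant pairs removed
{'Unmarked': 649, 'Non': 83, 'K4_gt_K27': 66, 'K27_only': 512,
 'K4_only': 382, 'K27_gt_K4': 83, 'E': 109, 'H': 116}
```

— at day 0, 116 of 2000 genes sit in the harbouring state and 109 in the
embedded state. Tabulating transitions to day 3 with
`transition_matrix(calls_0, calls_3)` gives, for the H-state row, the
fraction of day-0 H genes per day-3 state (row sums to 1 over the 8
labels); with the generator's default switching rates about 61% of H genes
remain H. The association battery
(`epistates.mark_association.associate`) on the same dataset reports
63.2% ± 1.2% (s.e., n = 4 timepoints) of expressed genes marked by
H3K4me3 at the TSS and per-timepoint Spearman ρ between TSS signal and
FPKM of 0.28–0.37 around the planted 0.31.

The same pipeline is available from the shell:

```sh
epistates simulate --seed 42 --out sim/
epistates consensus --mark H3K4me3 --rep1 sim/H3K4me3_0LD_rep1.narrowPeak \
    --rep2 sim/H3K4me3_0LD_rep2.narrowPeak --out k4_0LD.bed
epistates states --genes sim/genes.gff3 --k4 k4_0LD.bed --k27 k27_0LD.bed \
    --out calls_0LD.tsv
epistates transitions --calls-t0 calls_0LD.tsv --calls-t1 calls_3LD.tsv \
    --out transitions.tsv
```

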