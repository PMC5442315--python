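# Methods

## Coordinates and gene anchors

All intervals are 0-based, half-open (BED convention); GFF3 input is
shifted on read (`start − 1`) and restored on write. The TSS is the
gene-body 5′ end: `start` on the plus strand, `end − 1` on the minus
strand. Using the gene body rather than a representative transcript keeps
the anchor well-defined for annotation sets without transcript models; for
annotations where the two differ, callers can pre-project transcripts onto
gene bodies. The TSS window is the symmetric ±`halfwidth` interval
(default 500 bp, clipped at zero), spanning 2·halfwidth + 1 bases.

## Consensus mark regions

Per-replicate enrichment regions carry a normalized signal
(FPKM(ChIP)/FPKM(H3)). Two steps produce consensus regions per mark and
timepoint:

1. **Concordance filter.** Regions are matched across replicates by
   mutual maximal overlap (ties: larger overlap, then smaller start).
   For matched pairs, the signal difference `d = s₁ − s₂` is computed;
   pairs with `|d − mean(d)| > 2·sd(d)` are removed. Centring on
   `mean(d)` makes the rule robust to a global replicate-depth offset; a
   raw `|d|` mode is available. With fewer than 3 matched pairs the s.d.
   is not estimable and the filter disables itself with a warning.
   Unmatched regions pass through; the consensus step decides their fate.
   The threshold is computed per mark per timepoint; whether the original
   analysis pooled further is not recoverable from its description, and
   per-condition estimation is the conservative choice.
2. **Consensus.** Both replicates are self-merged (overlapping regions
   unioned, ≥ 1 shared base; touching half-open intervals stay separate).
   Every chain of transitively overlapping regions containing members of
   both replicates is emitted as its spanning union, with signal the
   length-weighted mean of all members. Chains supported by a single
   replicate are dropped: a "consensus" without cross-replicate support
   would also make the concordance filter vacuous. A per-base oracle
   (base supported iff covered in both replicates, support runs expanded
   over all regions sharing a base) reproduces this construction exactly
   and backs the tests.

Read down-sampling to the minimum library size is represented abstractly
(`downsample_counts`: seeded subsampling of count vectors without
replacement); the package consumes called regions, not reads.

## State classifier

Given the consensus regions overlapping a gene (body ∪ TSS window), the
cascade is total — every gene gets exactly one label:

1. zero/one mark → `Unmarked` / `K4_only` / `K27_only`;
2. both marks, no cross-mark pair overlapping ≥ `min_overlap` (default
   1 bp) → `Non`;
3. evidence pair = the maximal-overlap K4/K27 pair whose union intersects
   the TSS window, else the overall maximal-overlap pair;
4. K27 contains K4 (±`containment_slack`, default 0) and the K4 midpoint
   lies within ±500 bp of the TSS → `H`;
5. the mirror case → `E`;
6. otherwise partial: the longer span names the label; equal spans break
   to `K27_gt_K4` (arbitrary but deterministic and documented).

Two genuinely open design points are parameters rather than hard-coded
guesses. "Narrow peak inside broad domain" is operationalized as interval
containment, not an absolute width cutoff — containment is what
distinguishes the two states, and no width threshold is given by the
descriptions of either state; `narrow_max_span` optionally adds one. The
TSS condition applies to the inner peak's *midpoint* ("a peak around the
TSS" reads as peak location); `midpoint_at_tss=False` switches to
any-overlap. The midpoint test uses `|mid − TSS| ≤ halfwidth` on the
continuous midpoint, which is symmetric on both strands.

Transition matrices count genes per (state at t₀, state at t₁); row
fractions normalize by origin-category size, and row sums equal those
sizes exactly. Genes missing from either call set are excluded and
reported.

## Association statistics

A gene is marked at the TSS when any consensus region overlaps the ±500 bp
window by ≥ 1 base. Marked proportions are computed per timepoint within
the expressed (replicate-mean FPKM > 1 at that timepoint, strict) or
non-expressed stratum and summarized as mean ± s.e. with
s.e. = sd(per-timepoint proportions)/√T. The Spearman correlation between
TSS signal and FPKM among expressed, marked genes uses mid-ranks and the
Student-t approximation `t = ρ·√((n−2)/(1−ρ²))` with n−2 df (p = 0 at
|ρ| = 1; constant input is flagged NaN rather than raised, since silent
strata legitimately produce it).

## Metagene matrices

Two schemes, both oriented 5′→3′ (minus-strand genes flipped):
TSS-anchored fixed windows (default −4 kb…+8 kb in 100 bp bins → 120
columns; the bin width is an assumption, exposed as a parameter) and
length-normalized bodies (10 × 100 bp upstream, 50 equal body bins,
10 × 100 bp downstream → 70 columns). Body bin boundaries at multiples of
L/50 are handled in coordinates scaled by the bin count, where every
boundary is an exact integer; per-bin sums use `math.fsum`. Consequences:
per-gene signal mass is conserved exactly (tested at 1e−9 relative), and
mirroring the genome (reversing coordinates, flipping strands) reproduces
both matrices bit for bit. Bins beyond chromosome bounds read 0 and are
flagged in a mask instead of NaN, keeping downstream averaging defined.
Row ordering puts expressed genes first (descending FPKM), then
non-expressed genes by descending H3K27me3 level, ties by gene_id.

## Expression-side procedures

* Expressed-gene flags: replicate FPKMs averaged per timepoint, then
  strict `> 1` (global flag = any timepoint). Averaging before
  thresholding is the least-surprising replicate handling and is
  configurable.
* DE direction classes from external significance calls: `up`/`down`
  require ≥ 1 significant contrast with all significant directions
  concordant, `complex` requires both directions significant, else `ns`.
  The significance engine itself is an input contract, not part of the
  package.
* Slope test: OLS of mean expression on time, two-sided t-test with T−2
  df; perfect fits report p = 0 by convention.
* ΔΔCt: `2^(−((Ct_t − Ct_ref) − mean ΔCt(calibrators)))`, technical
  replicates averaged, undetected targets entered at Ct = 40 (the cycle
  cap) before differencing — a conservative lower bound on expression
  differences. The procedure is invariant to adding a constant to every
  Ct.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale, with every planted truth recorded.

* **Geometry.** Genes occupy random 10 kb slots (TSS 3 kb into the slot,
  both strands, lengths 1–5 kb uniform), so neighbouring genes' regions
  can never merge and planted states stay unambiguous. Narrow peaks are
  150–600 bp with span inside the TSS ±500 bp window; broad domains
  1.5–4 kb. H/E plant strict containment with ≥ 50 bp margins; partial
  states plant staggered overlaps with span difference ≥ 500 bp; `Non`
  plants a TSS-proximal K4 peak and a disjoint downstream K27 domain.
* **Expression.** A fraction (default 0.6) of genes is expressed with
  FPKM = 1 + lognormal(μ=1.5, σ=1.2) (silent: uniform on [0, 0.9]).
  DE classes (defaults 5% up, 5% down, 1% complex of expressed genes —
  desk-scale fractions chosen so each class is populated at n≈2000)
  apply monotone fold trends over the four timepoints, and the emitted
  per-contrast significance calls realize each class exactly. Replicate
  FPKMs are antisymmetric around the planted mean, so replicate averaging
  recovers it exactly.
* **States.** Initial states draw from per-stratum fractions — expressed
  genes carry H3K4me3 at the TSS with probability 0.66, silent genes
  0.05, and 41% of silent genes carry a broad H3K27me3 domain — because a
  single global state map cannot plant those stratum-level proportions;
  the global mixture is exposed as `state_fractions`, and an override
  sets both strata uniformly. States then evolve by a per-step Markov
  chain (defaults: 0.88–0.92 stay probability, small moves to adjacent
  configurations).
* **Mark–expression coupling.** Among expressed, K4-marked genes at each
  timepoint, TSS H3K4me3 signal follows a Gaussian copula on FPKM ranks
  with latent correlation r = 2·sin(πρ/6), targeting a Spearman of
  ρ = 0.31 by default (the magnitude such studies report).
* **Replicate noise.** The two replicates of a region carry v ± u/2 with
  u uniform, calibrated so the replicate difference has s.d. √2·σ
  (σ = `replicate_noise_sd`, default 0.5) — the dispersion independent
  Gaussian noise of s.d. σ would give — but with support bounded at
  √3 s.d. of the difference. Discordant regions (default 2%) instead get
  a fixed +4σ offset on replicate 1. Bounded concordant differences and
  a 4σ offset straddle the 2 s.d. threshold with margin on both sides,
  so the filter separates planted discordance exactly, and the consensus
  mean recovers the planted signal exactly — which is what makes
  correlation recovery through the full pipeline sharp. This is a
  deliberate idealization: real replicate noise is unbounded, so the
  filter's exactness on synthetic data says nothing about false-removal
  rates on real data, only that the mechanism is implemented correctly.
* **Determinism.** One `numpy` generator seeded from `seed` drives every
  draw; identical configs produce byte-identical file trees.

What the generator does *not* emulate: read-level sampling noise, peak
caller boundary jitter, overlapping or nested genes, chromosome-scale
covariance of marks, antibody efficiency differences between marks, and
unbounded replicate noise. Recovery tests therefore validate the
pipeline's arithmetic and logic, not its robustness to real-data artefacts.

## Problem sizes and numerical choices

Recovery tests run at n = 2000 genes (state/transition fractions,
concordance filter at 2000 regions) and n = 5000 × 10 seeds (Spearman
recovery), sizes at which binomial 99% bounds are decisive for the planted
effects. The classifier is verified exhaustively against an independent
truth table on a 20-point endpoint grid (~10⁵ pair cases), and the
consensus construction against a per-base voting oracle on random 100 kb
replicate sets. Degenerate inputs are defined, not erroneous: sd(d) = 0
filters nothing; empty strata yield flagged NaNs; genes shorter than 50 bp
are body-binned with fractional weighting and flagged.

## Known limitations

Only two replicates are supported in the concordance filter (the design it
models); generalization would need a different dispersion estimate. The
region-pairing rule before differencing (mutual maximal overlap) is a
documented choice — the original procedure's pairing is not specified.
Cross-tissue comparison is plain gene-set overlap; no attempt is made to
model tissue-specific peak-calling sensitivity.
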