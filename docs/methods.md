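# Methods

## Scope and data model

`pol2poise` operates on aligned-read positions (BED6, one record per
read) for a Pol II ChIP library and an IgG mock-IP control, per cell
state, plus gene models (refFlat/BED12/GTF). All coordinates are
0-based half-open internally; refFlat and BED are read natively, GTF is
converted on load. Alignment, duplicate marking and transcript
quantification are upstream of this package: it consumes aligned reads
and FPKM tables.

## Gene filtering and regions

Transcripts are kept when NM-tagged (protein coding) and at least
`min_gene_length` (2 kb) on genomic extent (`tx_end − tx_start`).
Within each cluster of transcripts with overlapping extents on a
chromosome the longest survives. Two deliberate choices where the
procedure is underdetermined: clustering ignores strand (overlap is
overlap), and length ties break by lexicographically smallest gene id,
so the filter is deterministic and idempotent. Clusters are built by a
sweep over start-sorted transcripts, so overlap is transitive (a–b and
b–c overlapping puts a, b, c in one cluster even if a and c are
disjoint).

Regions per gene, strand-aware with TSS = `tx_start` (+) or `tx_end`
(−): promoter `[TSS−100, TSS+500)`, body `[TSS+1000, TTS)`, mirrored
on the reverse strand. Promoters running past position 0 are clipped
and flagged rather than dropped, preserving the gene count; the flag
lets a downstream analysis exclude them. A gene shorter than the body
offset has no body and is a contract violation (the filter prevents it
under defaults).

## Counting and densities

A read is assigned to a region iff its strand-aware 5′ end (start for
+, end−1 for −) lies in the half-open interval. This point-mass
convention means a read straddling the promoter/body boundary counts
exactly once, matching the density-ratio treatment; read strand
relative to gene strand is ignored (Pol II ChIP is not
strand-resolved). Replicates merge by summing counts, and the library
total is the number of retained reads streamed from the input —
reproducible without trusting external headers. Counting uses a sorted
`searchsorted` fast path when a region set is disjoint on a chromosome
and an interval-tree fallback when promoters of adjacent genes overlap;
both paths are checked against a read-by-read brute-force oracle in the
tests.

Densities are RPKM: `count / ((len/1000) · (library/10⁶))`. The poising
index is `prom_rpkm / body_rpkm`; when the body count is zero the body
density is replaced by the RPKM of a single read in that body
(one-read pseudocount) and the value is flagged `body-pseudocounted`,
keeping rank statistics usable without inventing an unflagged number.

## Class calling

Stage 1 (activity): under the assumption that background read counts in
short segments are Poisson, each gene's Pol II promoter count is tested
against `λ = mean IgG promoter RPKM · (prom_len/1000) ·
(polii_library/10⁶)` — the IgG rate rescaled to the Pol II library
depth, without which unequal sequencing depths bias the call. The
p-value is the upper tail P(X ≥ observed); `λ = 0` gives p = 1 for a
zero observation and p = 0 otherwise. BH adjustment runs over all genes
and adjusted p < `active_alpha` (0.01) marks Pol II⁺.

Stage 2 (poising): among Pol II⁺ genes only — the test family is
defined on that subset, and BH runs within it — a one-sided Fisher's
exact test (hypergeometric upper tail, alternative: odds ratio > 1
toward the promoter) on the table `[[polii_prom, polii_body],
[igg_prom, igg_body]]`. The IgG row defaults to genome-average
*expected* counts per region (rounded, floored at 1 when positive
density rounds to 0, since Fisher needs integers); a `per_gene` switch
uses that gene's observed IgG counts instead. Degenerate tables (zero
row or column) carry no evidence and return p = 1. Adjusted
p < `poised_alpha` (0.001) marks poised.

Classes: I (not Pol II⁺), P (Pol II⁺ and poised), NP (the rest). The
partition is exhaustive and exclusive by construction.

## Two-state comparison

The transition matrix counts class pairs over genes present in both
states; rows are state-A classes and row percentages sum to 100.

Fold changes are state-B over state-A with pseudocounts so ratios stay
finite: densities use each state's one-read RPKM for that region,
expression uses 0.01 FPKM. Body-density labels: `similar` for
2/3 < fc < 1.5, `increased` above, `decreased` below; the PI-based
transition flag fires at a ≥ 2-fold PI change in either direction.

Group comparisons pair a two-sided Mann-Whitney U test with Cohen's d.
The U test uses exact enumeration for tie-free samples up to n = 20 per
group and the tie-corrected normal approximation otherwise. Cohen's d
is computed on log₁₀ values for densities and poising indices — these
are heavy-tailed, and an effect size on the raw scale would be
dominated by outliers; the scale is a package choice and is reported as
such. Zero pooled variance yields d = 0, p = 1.

Partial Spearman uses the rank-residual construction: rank all three
vectors, regress the x- and y-ranks on the z-ranks, and correlate the
residuals. Constant inputs are rejected rather than silently returning
NaN.

The IEG screen ranks NP genes by body RPKM, descending, ties by gene
id, returning the top k with a shortfall flag. Expression-ratio
tertiles sort by pseudocounted ratio (ties by gene id); the bottom and
top ⌊n/3⌋ are LO and HI and the remainder sits in MED, keeping the two
extreme groups exactly equal-sized.

## G4 motif scanning

A motif is four maximal runs of ≥ `g4_min_run` (3) guanines whose
inter-run gaps each span 1–7 nt. Runs are maximal — six Gs are one run
of six, never two of three — and windows of four consecutive runs are
enumerated over the run list, then merged per strand into maximal
regions, which makes the greedy/lazy regex distinction immaterial.
Gaps are the nucleotides strictly between runs and may contain N or
sub-threshold G-runs; N never extends a run. Reverse-strand hits come
from scanning the reverse complement and mapping coordinates back.

Windows are transcription-direction-aware: upstream `[TSS−3000, TSS)`
and downstream `[TSS, TSS+500)` in the direction of transcription
(upstream of a reverse-strand gene lies at larger coordinates). A hit
counts in a window when it overlaps it by ≥ 1 bp — containment is not
required, and a hit spanning the TSS counts in both windows. Hits on
the gene's strand are non-template, opposite-strand hits template.
Totals use the cross-strand union of hit intervals re-merged;
strand-resolved counts use the per-strand merged hits, so
template + non-template can exceed the total when opposite-strand hits
overlap. CpG masking removes every hit overlapping an island by
≥ 1 bp. Group comparisons report the two-sided Mann-Whitney p, a
mean-rank direction, and median plus unscaled median absolute
deviation.

The upstream window default is 3000 bp (the operative description);
2000 bp appears as an informal figure elsewhere and both are
configurable via `PipelineConfig.g4_upstream_window`.

## Synthetic data

The generator materializes the statistical assumptions above, so the
pipeline's inference is tested against data that satisfies its model
exactly:

- **Layout** — one chromosome; genes alternate strand, lengths uniform
  in 3–8 kb, separated by 6.5 kb. The gap keeps head-facing
  neighbours' 3 kb upstream G4 windows disjoint (alternating strands
  make gaps alternately tail-to-tail and head-to-head; head-to-head
  needs ≥ 6 kb), so planted per-gene motif counts are exact.
- **Classes** — exact planted counts at proportions 0.45/0.15/0.40
  (I/NP/P), order shuffled. Read counts per region are Poisson at
  `igg_density` (10 RPKM) times the class multiplier: 1 for I, 10 for
  both regions of NP, 20 (promoter) and 2 (body) for P, so the planted
  PI of poised genes is 10. Libraries are 2×10⁶ reads each, giving
  expected IgG promoter counts of 12 (≥ 5, enough for the Fisher
  table). Reads are 36 bp with the sampled position as the 5′ end;
  the library mass not assigned to regions is placed uniformly in the
  complement of all promoter/body intervals, so the streamed library
  total equals the configured size and planted counts stay exact.
- **G4 plants** — a fixed 15-mer (`GGGTGGGTGGGTGGG`, or its complement
  for reverse-strand plants) written into upstream/downstream windows
  at class-dependent rates (defaults: upstream 0.8 for NP vs 0.2
  otherwise, downstream 0.8 for P vs 0.2 otherwise), strand uniform,
  1 bp T flanks so adjacent background cannot extend the runs. The
  background is rejection-resampled until a both-strand scan finds no
  spontaneous motif, so the scan result equals the plant ledger.
- **Expression** — FPKM over rest/30m/3h/24h/72h with multiplicative
  lognormal noise (σ = 0.25): IEG-like genes (10% of NP) burst at 30 m
  from an already-high resting level and decay to a plateau
  (means 8, 24, 6, 2.5, 2); constitutive genes are flat at 5; silent
  genes (class I) sit at 0.05. IEG-like genes also get a 3× Pol II
  rate boost so the body-density screen has planted targets that are
  genuinely the most transcribed NP genes.

Everything derives from one seed; outputs are byte-identical across
runs. What the generator does **not** emulate: fragment-length and GC
bias, mappability, replicate overdispersion beyond Poisson, overlapping
genes, alternative TSSs, realistic G4 sequence diversity, or any
coupling between expression level and Pol II densities beyond the IEG
boost. Passing tests therefore demonstrate correctness of the
inference machinery under its own model, not robustness to real-data
artifacts.

## Numerical choices

- One-sided Fisher p is computed as the hypergeometric survival
  function; it is exact, and the test suite checks it against full
  integer enumeration for every 2×2 table with grand total ≤ 60.
- The Poisson upper tail comes from the survival function; agreement
  with log-space pmf summation is asserted to 1e-12 relative error
  wherever the probability is a normal double (≥ 1e-300); below that
  doubles are subnormal and relative error is undefined.
- BH adjustment is the standard step-up, checked against a hand
  implementation on random vectors; it is permutation-equivariant and
  caps at 1.
- Tie-breaks are always by gene id; merges and sorts use stable
  algorithms; pipeline outputs are byte-identical across reruns on
  identical inputs, recorded with input digests in a manifest.

## Problem sizes

Tests and the acceptance script run at the study defaults scaled for a
desk machine: 2,000 genes (≈ 24 Mb genome, 2×10⁶ reads per library)
for class recovery and transitions, 10,000 genes for null calibration,
800 genes with 0.2/0.4/0.4 proportions for G4 group comparisons (≥ 300
genes per group), and 500 random 200-bp sequences plus 30 hand-crafted
edge cases for scanner/oracle equivalence. These sizes give
Monte-Carlo standard errors well inside the asserted margins.

## Known limitations

ChIP-seq density ratios cannot distinguish paused, docked or melted
Pol II — the package classifies *poising* only. The genome-average IgG
background ignores local chromatin artifacts; the `per_gene` Fisher
variant is available but noisier at low IgG counts. RPKM normalization
assumes library composition is comparable between states; no
input-subtraction or signal-extraction normalization is attempted. GO
enrichment of gene groups is out of scope; the pipeline exports gene
lists for external tools.
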