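# Methods notes

## Scope and model

regulonkit reconstructs a transcription factor's direct regulon from three
ingredients: a genome annotation (GFF3), regulator ChIP peaks (narrowPeak),
and a WT-vs-regulator-null count matrix with a
genotype × condition × replicate sample sheet. It deliberately consumes
the outputs of read-level tools (aligners, counters, peak callers) rather
than reimplementing them; everything downstream of the count matrix and
peak list is specified exactly here and is deterministic.

All intervals are 0-based half-open internally. GFF3 (1-based inclusive)
converts on read and write; narrowPeak is already half-open and passes
through. Classification and assignment operate against features of one
annotation type (default `gene`, configurable), because the biological
contract — "inside an annotated gene or not" — is about gene bodies, not
CDS sub-features.

## Differential expression

The DE step is a transparent two-group analysis chosen for determinism and
auditability, not a replacement for shrinkage-based count models:

- **Size factors**: median-of-ratios over genes with nonzero counts in all
  samples, rescaled to geometric mean 1 so normalized counts keep the raw
  scale. When regulation is predominantly one-directional (this regulator
  mostly represses), the all-gene median absorbs a small library-composition
  bias that attenuates fold changes near a gate; factors are therefore
  re-estimated on an apparent control set (genes with preliminary
  |log2FC| < 1, used only when it covers at least 10% of genes). Under a
  global null the control set is essentially all genes and the two passes
  coincide. If no gene is nonzero everywhere, a library-size-ratio fallback
  applies with a warning.
- **Fold change**: log2 of the ratio of pseudocounted (c = 1) normalized
  group means, mutant over wild type; positive = higher in the mutant.
- **Test**: one-way two-group ANOVA on log2(normalized + 1), computed as
  the equivalent pooled-variance t. Degenerate genes are resolved
  deterministically (identical constant groups → p = 1; zero within-group
  variance with differing means → p = 0, logged). Each group needs ≥ 2
  replicates.
- **Multiplicity**: Benjamini–Hochberg step-up.
- **Gates are inclusive** (|log2FC| ≥ log2 F): published phrasing mixes
  "5-fold" and ">5-fold"; one convention had to be fixed and inclusive was
  chosen and is tested at the exact boundary.

Counts produced by this test on real deposited data will differ from
tables produced with negative-binomial shrinkage tools; the pipeline's
contracts (threshold sets, Venn overlaps, the regulon gate) are what it
guarantees.

### Gate contrast

The design has two conditions (glucose, carbon limitation). Per-condition
WT-vs-mutant contrasts (3 vs 3) drive the Venn reports. For gating the
regulon table on synthetic data the default contrast pools conditions
(6 vs 6), because the generator plants regulon effects as condition-
independent genotype effects. This is a power necessity, not a
convenience: with NB dispersion φ the sampling sd of an estimated log2FC
from n-vs-n groups is bounded below by √(2φ/n)/ln 2 ≈ 0.26 at φ = 0.05,
n = 3 — against a margin of log2 5 − log2 4 ≈ 0.32 that caps per-gene
recovery of a 5-fold effect at a 4-fold gate near 89% no matter how deep
the sequencing. Pooling to n = 6 lifts the ceiling to ~96%. On real data
with condition-specific regulation, users should select the relevant
condition (`--gate-contrast`).

## Peak classification and assignment

- *Intragenic* requires every base of the peak to be covered by the union
  of gene intervals — a peak inside two overlapping genes is intragenic —
  matching the complementary definition of *intergenic* ("entirely outside
  annotated coding regions"). Anything else is *spanning*. The three
  counts partition the peak total by construction, and the summary object
  refuses to build otherwise.
- Distance is measured peak edge to gene edge in half-open coordinates
  (overlap and adjacency are 0), with the published 500-bp radius as
  default. Summit-based distance is available behind a flag
  (`use_summit`); the default follows the stated rule, which is about
  peaks, not summits.
- Strand and upstream/downstream orientation are ignored during
  assignment (the rule makes no distinction); the orientation of every
  peak-gene pair is reported per row so users can filter afterwards.
- A peak may attach to every gated gene within range; a gated gene with no
  peak in range stays in the table flagged `indirect`.
- The original study's published tallies (8 + 200 + 626 = 834 peak
  classes; 35 + 140 = 175 direction calls) are used in the acceptance
  suite as arithmetic identities only; a later passage of the same text
  swaps the intergenic/intragenic counts (184 of 200 intergenic, 5 of 8
  intragenic), an inconsistency this package reports around (unassociated
  peaks are tallied per class) but does not resolve.

## Motif scanning

The consensus is a degenerate pattern over the IUPAC alphabet, matched
position-wise; no position-weight matrix is inferred, since no weights were
ever published for this motif. Windows on the minus strand are scored
against the reverse-complemented consensus and reported at their
forward-strand start. The consensus is its own reverse complement, so every
site yields a coincident +/− mirror pair; both are reported by default
(counts are then well-defined) with the − member flagged, and
`dedupe_mirrors` collapses them. The default reporting cutoff of 17/22
matched positions is the score of the one site with direct experimental
support; no numeric cutoff was ever published, so any genome-wide site
count depends on this user-visible choice.

## qPCR arithmetic

Amplification efficiency defaults to E = 2 (perfect doubling), configurable
per call; none was published. ChIP enrichment uses the mock- and
reference-normalized ΔΔCt form (invariant to plate-wide Ct shifts); the
percent-input alternative is provided (`chip_percent_input`) because the
exact published formula is delegated to earlier work and is not
recoverable. Replicates aggregate on the ratio scale — matching how such
figures are drawn — with SEM = sd/√n.

## Synthetic data: what it emulates, and what it does not

One 100-kb contig holds 120 non-overlapping alternating-strand genes
(400–600 bp, intergenic gaps ≥ 200 bp). Roles partition the genes:
4 direct-activated (one flagship at 238-fold, the study's strongest
activation), 12 direct-repressed (the study's ~1:4 activated:repressed
imbalance), 8 indirect (effect, no nearby binding), 96 null. One null gene
carries a genotype-independent 10-fold condition effect, emulating the
condition-repressed transcript observed alongside the flagship's
induction. Direct effects are 5-fold; counts are NB with gene-constant
dispersion φ = 0.05 (the simplest overdispersion model; no noise model was
published); baseline means are log10-uniform over 10^2.7–10^3.7 so that
both groups of a 5-fold contrast stay at or above ~100 counts, consistent
with a ~4,800-gene bacterial transcriptome sequenced at typical depth;
library sizes are uniform on 0.7–1.4.

Each direct gene gets one concrete consensus instantiation written 60 bp
upstream of its start (inside the 500-bp assignment radius by
construction) and one covering peak (width 150–300 bp, summit at the site
centre ± 10 bp, enrichment scores stochastically above the decoys'). 300
decoy peaks land uniformly, excluded from a 500-bp halo around planted
sites and around indirect genes — otherwise a decoy could silently turn an
"indirect" gene into a direct one and corrupt the ground truth. Planted
peaks may legitimately attach to a neighbouring gated gene (one peak,
several genes), as in real data.

All randomness flows from a single seed through fixed
`SeedSequence(seed, spawn_key=(stage,))` streams, so adding draws to one
stage never perturbs another and every artifact is byte-reproducible.

Not emulated: read-level noise (FASTQ), fragment-size effects and ChIP
coverage shapes, GC/mappability bias, operon structure, overlapping genes,
multi-contig genomes (supported but not defaulted), batch effects, and
condition-specific regulon effects. Passing recovery tests on this
generator therefore demonstrates the integration logic and the statistical
calibration of the DE gate under clean NB noise — not robustness to the
full messiness of deposited sequencing data.

## Problem sizes and tolerances

Recovery and type-I properties are evaluated over five independent
simulations (80 direct-gene trials; 600 null tests) — enough that the
±3·SE acceptance bands are meaningful while the whole suite runs in
seconds. Brute-force oracle equivalence uses 1,000 random peak/annotation
instances and 100 random sequences against exhaustive window scoring.
Floating-point identities (barcode normalization, noise-free qPCR round
trips) are asserted to machine precision; statistical checks use the bands
stated with them.

## Known limitations

- The ANOVA-on-logs test is slightly anti-conservative at 3-replicate
  group sizes with NB counts (raw p < 0.05 rate ~5–6% in the null
  benchmark); BH at α = 0.05 still yields zero discoveries in ≥ 4 of 5
  null simulations.
- Median-of-ratios refinement assumes most genes are unregulated; a
  transcriptome-wide response would defeat it (as it defeats any
  global-scaling normalization).
- Assignment is per gene; operon-aware propagation is out of scope.
- The motif model is a hard degenerate consensus; near-cognate sites with
  compensating positions score no higher than any other mismatch pattern.
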