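# Methods

This note documents the models implemented in `castworks`, the
assumptions behind them, the parameters that matter, and what the
synthetic-data generators do and do not emulate.

## 1. Pooled-screen fitness model (`screenfit`)

### Model

Barcode counts are compared between time zero (T0) and post-selection
samples. Strain fitness is `log2((post + ψ)/(t0 + ψ))` with pseudocount
`ψ` (default 1), centred on the median over strains with adequate T0
counts so that the typical — overwhelmingly null — strain sits at 0.
Gene fitness is the unweighted mean over *usable* strains: T0 count ≥
`min_t0` (default 3) and insertion at fractional gene position inside
`central_window` (default [0.1, 0.9]; insertions near either end of a
gene frequently leave function intact and would dilute the signal).
Replicates are averaged per condition, the CAST-minus-control
differential Δ is formed per screen, and candidates must satisfy
|Δ| > `threshold` (default 1) with a consistent sign in **both**
independent screens. Genes with fewer than `min_strains` (default 1)
usable strains in a screen are `nd` (not determined) and excluded from
calling — the fate of genes bottlenecked out of the starting library.

This is intentionally a compact re-implementation of the standard
RB-TnSeq fitness workflow: the full published pipeline adds
weighted-variance strain averaging and several normalisations
(per-scaffold, GC). Those refinements are not reproduced because the
downstream decision rule consumes only gene-level scores; the
simplification is a documented divergence, not a claim of equivalence.
T0 replicates are summed before ratio formation; `nd` status is decided
per screen before replicate averaging.

### What the generator emulates

`simgen.make_screen_design` / `simulate_barseq` emulate a barcoded
single-gene insertion library screened twice under a CAST and a matched
unrelated-transposase (mariner) condition:

* 3,744 genes × 10 uniquely barcoded strains by default. The emulated
  library carries ~40 insertion mutants per gene; 10 preserves the
  per-gene averaging that gives the real screen its sensitivity while
  staying desk-scale. Strain T0 abundances are lognormal (σ = 0.7),
  insertion positions uniform in [0, 1].
* Every gene draws a *general* fitness effect ~ N(0, `null_effect_sd` =
  0.3) per screen applied equally to both conditions — ordinary growth
  consequences of losing the gene, which the control arm exists to
  cancel. CAST-specific hits add a differential effect to the CAST
  condition only. This separation is what makes the two-screen rule's
  false-positive rate essentially zero at realistic depth; modelling
  null effects as independent per condition would instead leak ~1 false
  candidate per 3,700 genes into every run.
* Post-selection expected shares are T0 shares × 2^effect, renormalised;
  counts are negative-binomial with dispersion `nb_size` (default 50,
  mildly overdispersed relative to Poisson) at `depth` expected reads
  per sample (default 10⁶).
* Per-screen dropout genes receive zero T0 abundance, emulating
  propagation bottlenecks; they surface as `nd` and in the T0 QC report
  (e.g. 107/3,744 → 2.9%).

The planted hit panel (`default_hit_set`) contains 11 activators
(negative differentials, −1.5 to −3.2) and 4 inhibitors (+1.5 to +2.8),
named for the host factors recurrently implicated in type I-F CAST
integration where applicable and synthetic ids otherwise. Recovery of
this panel is exact across independent seeds at the default conditions.

Not emulated: barcode sequencing error and PCR jackpotting, strain
cross-contamination, condition-dependent generation counts, and the
real pipeline's experiment-quality metrics. Passing tests therefore
demonstrate correctness of the decision rule under the stated noise
model, not robustness to library artefacts.

## 2. Long-read insertion profiling (`profiler`)

### Procedure

1. **Filters.** Mean Phred quality strictly above `min_quality` (20) and
   length ≥ `min_length` (150 bp); the analysis subset keeps reads
   longer than `analysis_min_length` (10 kb) so one read can span the
   complete cargo plus genomic flanks. Mean quality is the arithmetic
   mean of per-base scores.
2. **Cargo location.** Local alignment of the read against the
   annotated transposon unit (left end + cargo + right end). Reads
   covering < `min_right_end_cov` (80%) of the annotated right-end
   interval are discarded; the right-end interval is taken from the
   user-supplied annotation, since its biological extent is a property
   of the element. Orientation calling additionally requires the left
   end (≥ 50% covered), otherwise the call is `ambiguous`.
3. **Flank classification.** The read on either side of the cargo is
   aligned to the reference genome and the delivery plasmid; a flank is
   genomic/plasmid when > `min_flank_bp` (100 bp) maps to the
   respective reference, `both` when both do. Only the `max_flank_bp`
   (2.5 kb) adjacent to the cargo is examined — the junction and the
   classification are decided there, and the cap bounds alignment cost.
4. **Call.** The junction is the first genomic base after the
   transposon on the reference; both flanks share that coordinate, and
   the estimate prefers a purely genomic flank because a
   plasmid-involved flank (as in cointegrates) can overshoot the
   junction when the transposon terminus coincidentally matches the
   adjacent genomic bases (junction micro-homology). Orientation is RL
   when the right end is PAM-proximal, derived from the strand geometry
   of the cargo and flank alignments. Offset = junction − protospacer
   3' end (strand-aware); on-target ⇔ offset ∈ [0, `on_target_window`]
   (100 bp, one-sided downstream; a symmetric ±window is available via
   `symmetric_window` since the informal description of the window is
   ambiguous). Cointegrate ⇔ any flank classified plasmid or both.
5. **Summary.** On-target %, orientation fractions, cointegrate %
   (read-level; plus a clone-level majority vote when clone ids are
   supplied — the two estimators agree closely on simulated data, and
   both are reported because colony-PCR-style assays count clones while
   sequencing counts reads), per-bp offset histogram, genome-wide
   junction histogram (`bin_size` 1 kb). Junctions are 0-based
   internally and additionally reported 1-based in the calls table.
   Counts along the filter chain are asserted monotone on every run.

### Recovery characteristics

At 0% read error, orientation, offset, on-target, cointegrate and exact
junction match the simulation truth for 100% of placeable reads. At 5%
per-base error, labels still match truth essentially perfectly; junction
estimates are exact for ~85–90% of reads and off by a few bp otherwise
(trailing errors clip local alignments), so the *modal* offset is exact
while the histogram acquires light ±1–2 bp shoulders.

### Read generator

`simulate_long_reads` builds, per event, the allele around the planted
junction (simple: left end + cargo + right end; cointegrate: unit +
full backbone + duplicated unit), draws a read window fully spanning
the insertion with ≥ `min_margin` (300 bp) genomic sequence on both
sides, a random genome strand, and applies independent per-base errors
(60% substitutions, 20% single-base duplications, 20% deletions of the
`per_base_error` total). Read lengths are normal (mean 15 kb, sd
1.5 kb) or a point mass, floored at insert + 2×margin. Per-base
qualities are normal around `mean_quality`. This is not a calibrated
Nanopore error model: no homopolymer structure, no quality-error
correlation, no chimeras, and every read spans its insertion (no
fragmented reads), so filter-chain attrition in real data will exceed
the simulated one.

## 3. Alignment core (`align`)

A seed-and-extend local aligner: exact `word_size`-mers (default 11)
shared between query and an indexed reference are clustered by
diagonal (clusters need ≥ 3 seeds; genuine alignments > 100 bp carry
dozens), and each cluster is extended with a banded affine-gap
Smith–Waterman (band 100 around the seeded diagonals; numba kernels;
alignment starts recovered by a reverse pass). Scoring is the common
nucleotide default: match +2, mismatch −3, gap open −5, extend −2.
Alignments below `min_score` (40) are rejected. The test suite enforces
agreement of accept/reject decisions *and scores* with an independent
full-matrix Smith–Waterman oracle on random planted instances.

For 32-nt protospacers the scan is exhaustive (full DP, both strands,
no complexity masking) — at word size ≤ 4 seeds saturate every
position, so seeding is vacuous — with traceback for per-base match
information.

Known limitation: within exact score ties, reported coordinates follow
deterministic tie-breaks (leftmost target position; '+' strand first),
and junction micro-homology makes ±1 bp placement inherently
convention-dependent.

## 4. Guide design (`designer`)

Safe sites are intergenic gaps between converging genes (→ ←) of
`min_len`–`max_len` (300–600 nt), excluding gaps that overlap
mobile-element or ncRNA masks or flank essential genes; rejected sites
are retained with audit flags. Masks and essential-gene lists are
user-supplied (BED / id sets): curated-database lookups are out of
scope.

Within each accepted site, every 5'-CN-3' PAM on both strands is
enumerated and the 32 nt immediately 3' of the PAM form a candidate.
Filters: GC ∈ [40, 60]%; the predicted insertion locus — the window
`offset_window` = 45–55 bp downstream of the protospacer 3' end,
reflecting the ~49 bp integration distance with its observed spread —
must lie inside the intergenic region and clear of terminator masks.

Off-target assessment scans the protospacer against the genome (own
locus masked). The report carries the best-hit score, the count of
distinct regions reaching `score_floor` (32 = 16 matched bases), and
`seed_matches`: matching bases within the PAM-proximal `seed_len`
(10 nt) of the *worst offender* among all top-scoring hits — when many
loci tie at a weak best score, the one with the highest seed
complementarity defines the risk. Tied hits are collected from both
orientations of the reference so reports are orientation-independent.
Ranking is (fewest seed matches, lowest best-hit score, leftmost
coordinate), top `k` = 3 per site; shortfalls warn rather than fail.
E-values are not computed: on a single genome with a fixed query
length they are monotone in raw score, so score-based ranking is
equivalent.

Emitted guides are re-audited against every rule as a pipeline
postcondition.

## 5. Efficiency statistics (`effstats`)

**Titers.** A 10-fold dilution series with technical replicate drops
(simulator default 3, following surface-drop plating convention) is
reduced to CFU/ml by pooling: a dilution is countable when the mean
count of its readable (non-lawn) spots lies in `countable_range`
(default 3–300, the classical plate-count window extended down to drop
counts), and all readable spots of countable dilutions are pooled as
total colonies / total plated volume — the Poisson maximum-likelihood
estimate, which for one spot reduces to
`count × dilution_factor × 1000/volume_µl`. Two deliberate choices:
per-*dilution* (not per-spot) selection avoids Poisson truncation bias
when expected counts sit near a window boundary, and a narrow window
such as 3–30 per spot is avoided because it caps a titer's relative
precision at ~18–30%, which would drown the day-to-day spreads this
assay is used to measure. A series with no countable dilution and no
lawn is *below detection*, bounded by `countable_min` colonies at its
least-dilute spot; bounds propagate as censored values (exports can
additionally show the conventional explicit zero with a flag).

**Efficiency and normalisation.** Efficiency = transconjugant/total
titer. Editing efficiencies vary day to day, so treatments are
normalised strictly to same-day controls (multi-control days use the
control mean; a missing same-day control is a hard error, never a
silent cross-day pool). Significance uses a one-sample t test against
the hypothetical normalised mean of 1, one-tailed in the direction
hypothesised a priori (activator/inhibitor); n < 2 or zero variance are
explicit errors. No two-sample tests or multiplicity corrections are
implemented — each treatment is its own paired comparison.

**Plate simulator.** Colony counts are Poisson around
`titer × volume / dilution_factor`; counts above `lawn_threshold` (300)
are flagged as unreadable lawns. Day-to-day biological variation is not
simulated — all scatter in recovered fold changes is counting noise —
and plating efficiency is assumed 1. In recovery runs the simulated
titers (total 2×10⁹ CFU/ml, control efficiency 10⁻³) are chosen so
expected counts land mid-window on the 10-fold grid, as a practitioner
designs a dilution scheme to do; the day-paired fold-change estimator
is then unbiased with ~3 fold-units of spread (sd) on a mean of ~55
over three days.

## 6. Problem sizes and determinism

Default recovery runs use 3,744 genes × 10 strains at depth 10⁶
(screens), 500 reads at 5% error (on-target/offset), 1,000 events with
cointegrates planted at exactly 12% (rate recovery is the question
there, so the planted frequency is assigned in exact proportion via
`exact_counts` rather than left to the generator's own binomial noise;
the default elsewhere remains i.i.d. draws), and 3 simulated days
(fold change); the test
suite exercises the same code paths at smaller sizes. Every generator
accepts a single integer seed; generators fold a domain tag into the
seed material so the same seed never replays one random stream across
different generators (a genome and a vector generated with the same
seed are independent sequences). Fixed seeds give byte-identical
outputs.
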