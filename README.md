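# castworks

Computational toolkit for CRISPR-associated transposase (CAST) genome
editing experiments in bacteria.

CASTs couple an RNA-guided CRISPR effector to a Tn7-like transposase,
inserting a large DNA cargo a fixed distance (~49 bp) downstream of a
32-nt protospacer flanked by a 5'-CN-3' PAM. Their efficiency depends
heavily on host factors, and the experiments that probe this — pooled
loss-of-function screens, long-read sequencing of insertion products,
safe-site guide design, conjugation-based efficiency assays — each need
a dedicated quantitative analysis. `castworks` implements those analyses
as a tested, reusable library with a matched synthetic-data generator,
for researchers running or modelling CAST editing experiments.

## Components

| module | what it computes |
|---|---|
| `castworks.simgen` | synthetic genomes with converging-gene safe sites, planted protospacer targets, insertion outcomes, Nanopore-like long reads, pooled-library BarSeq counts, spot-plate colony counts — all with ground truth |
| `castworks.screenfit` | RB-TnSeq gene fitness from barcode counts; CAST − control differentials; activator/inhibitor calls |
| `castworks.profiler` | long-read insertion outcomes: cargo location, flank typing, orientation (T-RL/T-LR), offset, on-target %, cointegrate rate |
| `castworks.designer` | safe sites between converging genes; 5'-CN-3' PAM scan; 32-nt guides filtered by GC and insertion-locus placement; off-target scoring and ranking |
| `castworks.effstats` | CFU titers from serial dilutions, editing efficiencies with detection limits, day-paired fold changes, one-sample one-tailed t tests |
| `castworks.align` | internal seed-and-extend banded affine Smith–Waterman used by the profiler and designer |

## The statistics at the core

**Gene fitness.** For strain $s$ with time-zero count $n_{s,0}$ and
post-selection count $n_s$, the strain fitness is the median-centred
$\log_2\!\frac{n_s + \psi}{n_{s,0} + \psi}$ (pseudocount $\psi = 1$).
Gene fitness $f_g$ is the unweighted mean over usable strains — those
with adequate time-zero counts whose insertion lies in the central
portion of the gene. Per screen, the differential is
$\Delta_g = \bar f_g^{\text{CAST}} - \bar f_g^{\text{control}}$
(replicate-averaged; an unrelated *mariner* transposase arm cancels
generic growth effects). A gene is called an **inhibitor** when
$\Delta_g > 1$ in both independent screens (losing it helps CAST), an
**activator** when $\Delta_g < -1$ in both, and `nd` when it lacked
time-zero abundance in either screen.

**Insertion outcomes.** Reads pass Q20/150-bp filters and a >10-kb
analysis cut, must cover ≥80% of the annotated transposon right end,
have their flanks classified genomic/plasmid/both by a >100-bp mapped
rule, and are called on-target when the transposon–genome junction lies
within a 100-bp window downstream of the protospacer 3' end. A read
whose cargo is contiguous with plasmid backbone is a cointegrate
(whole-vector integration with duplicated transposon ends).

**Editing efficiency.** Titers pool countable dilutions of a 10-fold
spot series (total colonies / total plated volume); efficiency is
transconjugant CFU/ml over total CFU/ml, censored at the detection
limit rather than imputed; treatments are normalised to the same-day
control and tested with a one-sample, one-tailed t test against a
hypothetical mean of 1.

## Worked example

Simulate a full two-screen host-factor experiment (3,744 genes, 10
barcoded insertion mutants per gene, 15 planted CAST-specific hits,
10⁶ reads per sample) and call candidates:

```python
from castworks import simgen, screenfit

hits = simgen.default_hit_set()                      # 11 activators, 4 inhibitors
design = simgen.make_screen_design(n_genes=3744, hit_effects=hits, seed=7)
counts = simgen.simulate_barseq(design, depth=1_000_000, seed=7)
res = screenfit.analyze_screens(counts, design.meta(), threshold=1.0)
print(res.calls.head(5).to_string(index=False))
print((res.calls.call == "activator").sum(), "activators,",
      (res.calls.call == "inhibitor").sum(), "inhibitors")
```

prints

```
  gene  delta_screen1  delta_screen2      call
  recD           2.72           2.71 inhibitor
  ihfB          -2.64          -2.46 activator
  cspC          -2.30          -2.12 activator
  ynbE          -2.25          -1.81 activator
actH08          -1.93          -1.93 activator
11 activators, 4 inhibitors
```

Every planted hit — and nothing else — is recovered: `recD` (a RecBCD
subunit that suppresses homologous recombination) surfaces as the
strongest inhibitor and `ihfB` (integration host factor β) as the
strongest activator, each consistently in both screens.

The same pattern applies to the other components: simulate with known
truth, analyse, compare. See `castworks simulate --help`,
`castworks screen/profile/design/efficiency --help` for the
command-line equivalents.

## Documentation

`docs/methods.md` describes the models, their assumptions, all tunable
parameters, and known limitations.
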