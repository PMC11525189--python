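# Methods

## The problem and the model

Plant genes carry regulatory information not only upstream of the
transcription start site (TSS) but inside the transcribed region itself,
and some elements act only from one side of the TSS. The quantity at the
centre of this package is the **per-copy motif effect**: a multiplicative
change in expression per occurrence of a short degenerate motif, gated on
the motif's position relative to the TSS. On the log2 scale the model is
linear:

```
log2(expression) = a + b · min(copies, cap) + e
```

where `copies` counts motif occurrences (in a reporter fragment, or in the
window 1–500 bp downstream of a gene's TSS), `b` is the *effect size*
(log2 per copy), and `e` collects everything else. `b` is estimated by
ordinary least squares; the reported p value is the two-sided *t* statistic
for `b = 0`. The cap (default 9) keeps a handful of extreme-count genes
from dominating the fit; fits use the raw truncated counts, not dose-bin
indices, because the target quantity is "expression change per added
motif".

The motif itself is an 8-bp IUPAC consensus, **YVGATCBR** — a literal GATC
core with degenerate flanks (Y=C/T, V=A/C/G, B=C/G/T, R=A/G; 36 concrete
8-mers). It equals its own reverse complement as an expansion set, so
single-strand scanning is lossless; overlapping matches are counted because
no exclusion rule is part of the definition. An occurrence is "in" a
TSS-relative window iff its start offset falls in the window; the default
downstream window [+1, +500] excludes the TSS base itself.

## MPRA quantification

Barcodes are linked to fragments by majority vote over association reads
(retained when total reads ≥ 3 and majority purity ≥ 0.9 — conventional
MPRA thresholds, config-exposed). Expression per barcode is
`log2(CPM_RNA / p_DNA)` with one pseudocount read per barcode before CPM
(the pseudocount's influence vanishes at realistic depth; the scale
invariance of the estimate to per-replicate depth is property-tested).
DNA input proportions are estimated per *fragment* from shotgun DNA
counts; per-barcode DNA normalisation is not attempted. Fragment activity
is the mean of its barcode log-ratios (median by config), requires ≥ 3
barcodes, and replicates are median-centred before averaging so that
depth/efficiency offsets cancel. Activities relative to no-insert controls
subtract the control mean within the library.

## Statistical tests

* **Mann–Whitney U** (k-mer screen, allele associations): the exact mode
  enumerates the permutation null over all assignments of the pooled
  values (tie-aware, U credited 0.5 per tie; two-sided p = 2·min(tails),
  capped at 1) and is used when the pooled size is ≤ 16; larger samples
  use the normal approximation with tie and continuity corrections
  (delegated to scipy; the screen evaluates all 4^k k-mers at once with a
  vectorised rank-sum equivalent of the same approximation).
* **Multiple testing**: Bonferroni at family size 4^k for k-mer screens;
  Bonferroni over tested genes for allele associations (nominal and BH
  available by config). A k-mer enters the screen only when present in at
  least 10 and absent from at least 1 fragment, to avoid vacuous splits.
* **Direction ratios**: per distance bin, (n_higher + 0.5)/(n_lower + 0.5)
  over significant associations, with raw counts reported alongside; the
  0.5 pseudocount makes empty bins well-defined (ratio 1).

## Mutagenesis series

Removal edits destroy *all* occurrences of the motif in a fragment at
once, in three modes: deletion of the 8-bp window (overlapping occurrence
windows are merged and the union deleted; if the deletion junction itself
creates a new occurrence it is deleted too, iteratively), a seeded 8-bp
shuffle redrawn until no GATC remains and the consensus is gone, and a
GATC→GATA point mutation of the core. Every derivative is re-scanned; a
surviving occurrence is an error, never a silent pass. The deep scan over
a mutable region of L nt enumerates (L−9) 10-bp deletions, 3L single-base
substitutions and L single-base deletions — `5L − 9` derivatives, 736 at
L = 149. The default mutable region is the whole fragment; the length is a
parameter because synthesis designs often commit a few terminal bases to
adapters. Motif additions substitute (never insert, preserving length)
1..8 copies of one concrete 8-mer at evenly spaced positions, dithered a
few bases when a placement would collide with or accidentally create an
occurrence.

## The synthetic study

The generator emulates the geometry and noise structure of a
barcoded-reporter study of TSS-proximal fragments:

* **Genes**: one per synthetic chromosome (1,401 bp, TSS centred), random
  strand, TSS-to-ATG distances drawn from bins 0–50/50–100/100–250/250–500 bp.
* **Fragments**: 160 bp, tiled without overlap from [−200, −40) upstream
  and [+40, +360) downstream of the TSS (1 + 2 per gene; the core promoter
  ±40 bp is excluded), read in the direction of transcription.
* **Planted signal**: per fragment, 0–3 motif copies (P = 0.70/0.20/0.08/0.02)
  substituted at random non-overlapping positions; ground-truth copy
  numbers are *re-scanned* from the final sequence so background
  occurrences count honestly. True activity = copies × effect(side) +
  N(0, sd), with effect(downstream) = +0.585 log2 (×1.5) and
  effect(upstream) = 0 — the position gate. An optional ceiling saturates
  very active fragments; it is off by default.
* **Noise**: fragment-level Gaussian sd 0.5 log2 (chosen to give the
  activity spread and replicate reproducibility, r ≈ 0.93, typical of a
  well-powered reporter experiment; no-insert controls have no insert
  sequence, hence no sequence-driven noise — their true activity is
  exactly baseline). Counts are gamma–Poisson with dispersion 0.1
  (variance μ + 0.1 μ²), depth 2×10⁶ per library, DNA mix Dirichlet(10)
  shared across the three replicates; replicates use independent
  sub-seeds.
* **Barcodes**: VNN × 5 (15 nt, V = A/C/G), 8 per construct, globally
  unique; the pattern space holds (3·4·4)⁵ ≈ 2.5×10⁸ barcodes.
* **Gene-level simulators**: downstream motif counts drawn from a
  realistic dose mix (≈ 68/24/6/2 % for 0/1/2/≥3 copies with a geometric
  tail to 9), expression linear in count with Gaussian noise; the
  population allele simulator plants a +0.5 log2 allele effect only for
  motifs at offsets +1..+500 (500 genes × 200 samples, allele frequency
  0.3, noise sd 0.5 — sized so a per-gene rank test retains power at a
  Bonferroni threshold over the tested genes).

Everything is driven by one integer seed through per-stage `numpy`
generators; identical configurations are bit-identical.

What the generator deliberately does **not** emulate: sequencing errors,
splice-site constraints on fragment selection (synthetic genes are
intronless), plasmid backbone context, species differences, and linkage
between neighbouring variants in the population simulator. Passing tests
therefore demonstrate that the estimators recover the planted
position-gated, per-copy multiplicative model under realistic count noise
— not that real libraries are free of the artefacts listed above.

## Numerical choices and degenerate inputs

Problem sizes in the test suite and the reproduction script were chosen to
make Monte-Carlo tolerances comfortable: 1,000 genes (3,000 fragments ×
8 barcodes × 3 replicates) for end-to-end recovery, 15,000 genes for
dose–response fits (slope SE ≈ 0.02 at noise sd 1.5), 100 seeds for null
calibration. OLS on collinear input is exact to machine precision;
zero-variance predictors (a k-mer absent everywhere) yield NA rows rather
than errors in the scan, and errors elsewhere (single dose, < 10 genes,
empty groups, all-zero DNA counts, motif-free fragments) are raised
eagerly with the offending item named. Profile smoothing uses a centred
rolling mean truncated at the grid edges, so constant tracks are fixed
points. Nearest-TSS assignment breaks ties toward the smaller absolute
oriented offset, then lexicographic gene id.

## Known limitations

* The k-mer screen is presence/absence by design; copy-number information
  enters only through the dose–response module.
* Allele associations use a plain rank test: no relatedness or population
  structure correction, so results on real population data would be
  anti-conservative.
* Per-fragment (not per-barcode) DNA normalisation slightly misweights
  barcodes with very uneven representation within a fragment.
* The exact Mann–Whitney mode enumerates C(n, n₁) assignments and is
  intended for n ≤ 16.
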