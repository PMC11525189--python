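# tssreg

Analysis toolkit for **position-dependent regulatory sequences around plant
transcription start sites (TSSs)** — the kind of regulatory grammar in which
a sequence element enhances transcription when it sits *inside the
transcribed region, downstream of the TSS*, but not when the same sequence
sits upstream.

The package implements, as a tested and reusable pipeline:

* **MPRA quantification** (`tssreg.quantify`) — from barcode→fragment
  association reads, DNA-input counts and RNA barcode counts to per-fragment
  log2 expression, with purity/coverage QC, replicate merging and
  no-insert-control normalisation. The activity of a barcode is
  `log2(CPM_RNA / p_DNA)`; fragment activity averages its barcodes, and
  replicates are median-centred before merging.
* **K-mer association screen** (`tssreg.kmer_screen`) — every k-mer's
  presence/absence in the fragment pool tested against activity with a
  two-sided Mann–Whitney *U* test (exact permutation-null enumeration at
  small n, tie/continuity-corrected normal approximation otherwise),
  Bonferroni-corrected at family size 4^k.
* **Degenerate motif machinery** (`tssreg.motifs`) — IUPAC consensus
  construction from core-aligned k-mers, expansion, reverse complement, and
  overlapping-match scanning. The central motif is the 8-bp GATA-factor
  consensus **YVGATCBR** (Y=C/T, V=A/C/G, B=C/G/T, R=A/G; 36 concrete
  8-mers; reverse-complement-closed).
* **Mutagenesis series** (`tssreg.mutagenesis`) — motif removal (deletion /
  seeded 8-bp shuffle / GATC→GATA), the saturation deep scan (every 10-bp
  deletion, every 1-bp substitution and deletion: `5L − 9` derivatives,
  736 at L = 149 nt), incremental 1–8-copy motif additions, and paired
  parent/derivative activity-delta analysis.
* **Positional analyses** (`tssreg.positional`) — TSS-anchored metagene
  profiles with 100-bp rolling smoothing, TSS-to-ATG stratification,
  TF-family profile consolidation, windowed nucleotide diversity (π), and
  the direction ratio of significant motif-allele/expression associations
  by distance bin.
* **Dose–response** (`tssreg.dose_response`) — the *effect size*: the OLS
  slope of log2 expression on the number of motif copies within 500 bp
  downstream of the TSS (two-sided *t* p value), per dataset, per k-mer and
  window, and across expression compendia with 0-motif-normalised dose
  means.
* **Synthetic data with ground truth** (`tssreg.synthio`) — genes with
  TSSs, 160-bp fragments tiled from [−200, −40) and [+40, +360) around each
  TSS, VNN×5 barcodes, a DNA input mix, and gamma–Poisson RNA counts whose
  expectation encodes a planted, *position-gated* per-copy activity effect
  (+0.585 log2 ≈ ×1.5 per copy for downstream insertion, 0 upstream).

## Worked example

```python
from tssreg import SynthConfig, simulate_library, quantify, effect_size, screen

cfg = SynthConfig(n_genes=1000, rng_seed=0)          # 3,000 fragments
lib = simulate_library(cfg, "downstream")

props = quantify.dna_proportions(lib.dna_counts)
act = quantify.quantify_expression(lib.rna_counts, lib.barcode_map, props)

truth = lib.truth.loc[act.index]
real = truth[~truth["is_control"]]
fit = effect_size(act.loc[real.index, "log2_expression"], real["copies"])
print(f"per-copy effect {fit.slope:.3f} log2 (p = {fit.p:.2g}, n = {fit.n})")

seqs = lib.fragment_sequences
res = screen(act.loc[act.index.intersection(list(seqs))], seqs, k=6)
print(res.head(3)[["kmer", "delta_mean", "p", "significant"]])
```

prints (seed 0):

```
per-copy effect 0.573 log2 (p = 2.2e-308, n = 3000)
     kmer  delta_mean             p  significant
0  CAGATC    0.608792  1.044428e-45         True
1  CGGATC    0.599890  2.902572e-41         True
2  GATCCG    0.585193  1.529622e-39         True
```

The recovered per-copy effect (0.573 log2 ≈ +49%) matches the planted
+0.585 log2 (×1.5), and the most activity-associated 6-mers are all
instances of the planted YVGATCBR consensus — the screen rediscovers the
motif from counts alone. The same fragments quantified from an
upstream-insertion library (`simulate_counts(..., library_side="upstream")`)
yield no Bonferroni-significant GATC 6-mer: the effect is position-gated.

A thin CLI mirrors the main steps: `tssreg simulate`, `tssreg quantify`,
`tssreg kmer-screen`, `tssreg motif-count`, `tssreg mutate`, `tssreg dose`.

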