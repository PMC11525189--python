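"""Synthetic genomes, MPRA libraries, barcodes and counts with known ground truth.

Emulates the study design this package analyses: genes with annotated TSSs,
160-bp regulatory fragments tiled from the windows [-200, -40) upstream and
[+40, +360) downstream of each TSS (the core promoter, -40..+40, is excluded),
VNN x 5 barcodes linking fragments to transcripts, a DNA input mix, and
overdispersed (gamma-Poisson) RNA barcode counts whose expectation encodes a
planted, position-gated, per-motif-copy multiplicative activity effect
(default +0.585 log2 per copy, i.e. ~x1.5, when the library is inserted
downstream of the reporter TSS; 0 when inserted upstream).

All randomness flows from ``SynthConfig.rng_seed`` through per-stage
``numpy`` generators, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .motifs import IUPACMotif, expand, scan, oriented_slice, revcomp_seq

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
V_BASES = np.array(list("ACG"))

#: dose distribution over downstream motif counts emulating genome-wide
#: proportions (groups 0/1/2/>=3 at roughly 68/24/6/2 percent, with a
#: geometric tail over 3..9 copies)
DEFAULT_DOSE_PROBS = (0.683, 0.241, 0.056, 0.0125, 0.0045, 0.0017,
                      0.0007, 0.0003, 0.0002, 0.0001)


class ConfigurationError(ValueError):
    """Raised for invalid generator geometry or parameters."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic MPRA study."""

    n_genes: int = 100
    fragment_length: int = 160
    upstream_window: tuple[int, int] = (-200, -40)
    downstream_window: tuple[int, int] = (40, 360)
    core_exclusion: tuple[int, int] = (-40, 40)
    barcode_triplets: int = 5                       # VNN x 5 -> 15 nt
    barcodes_per_fragment: int = 8
    planted_motif: str = "YVGATCBR"
    #: planted copies per fragment: P(0..len-1 copies)
    planted_copy_probs: tuple[float, ...] = (0.70, 0.20, 0.08, 0.02)
    per_copy_log2_effect_downstream: float = 0.585  # ~= log2(1.5): ~50%/copy
    per_copy_log2_effect_upstream: float = 0.0
    fragment_noise_sd: float = 0.5
    activity_cap: float | None = None               # saturation ceiling, log2
    nb_dispersion: float = 0.1
    seq_depth: int = 2_000_000
    n_replicates: int = 3
    n_controls: int = 50                            # no-insert constructs
    tss_flank: int = 700                            # chromosome flank each side of TSS
    tss_to_atg_bins: tuple[tuple[int, int], ...] = ((0, 50), (50, 100), (100, 250), (250, 500))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        for name in ("upstream_window", "downstream_window"):
            lo, hi = getattr(self, name)
            if hi <= lo:
                raise ConfigurationError(f"{name} is empty")
            if (hi - lo) % self.fragment_length != 0:
                raise ConfigurationError(
                    f"fragment_length {self.fragment_length} must divide {name} "
                    f"length {hi - lo} exactly")
            clo, chi = self.core_exclusion
            if lo < chi and clo < hi:
                raise ConfigurationError(f"{name} overlaps core_exclusion")
        if self.barcode_triplets * 3 != 15:
            raise ConfigurationError("barcode pattern must be 15 nt (VNN x 5)")
        if self.barcodes_per_fragment < 1:
            raise ConfigurationError("barcodes_per_fragment must be >= 1")
        if self.seq_depth <= 0:
            raise ConfigurationError("seq_depth must be positive")
        if abs(sum(self.planted_copy_probs) - 1.0) > 1e-9:
            raise ConfigurationError("planted_copy_probs must sum to 1")
        IUPACMotif(self.planted_motif)  # validates the consensus

    def effect(self, library_side: str) -> float:
        if library_side == "downstream":
            return self.per_copy_log2_effect_downstream
        if library_side == "upstream":
            return self.per_copy_log2_effect_upstream
        raise ConfigurationError(f"unknown library side {library_side!r}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss_pos: int            # 0-based; the TSS base itself
    strand: str             # '+' or '-'
    tss_to_atg: int


@dataclass
class FragmentDesign:
    """A tested fragment: oriented sequence plus its TSS-relative origin."""

    fragment_id: str
    gene_id: str
    side: str               # 'upstream' or 'downstream' (origin relative to native TSS)
    offset: int             # TSS-relative start of the oriented window
    sequence: str


def _rng(config: SynthConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, config.rng_seed])


# ---------------------------------------------------------------------------
# genes and genome

def generate_genes(config: SynthConfig) -> tuple[list[GeneModel], dict[str, str]]:
    """Random intronless genes, one per synthetic chromosome.

    Returns the gene models and the genome (chrom -> sequence).  Strands are
    drawn 50/50; TSS-to-ATG distances are drawn uniformly within uniformly
    chosen configured bins.
    """
    rng = _rng(config, 1)
    genes: list[GeneModel] = []
    genome: dict[str, str] = {}
    chrom_len = 2 * config.tss_flank + 1
    bins = np.asarray(config.tss_to_atg_bins)
    for i in range(config.n_genes):
        gid = f"g{i:05d}"
        chrom = f"chr_{gid}"
        seq = "".join(rng.choice(BASES, size=chrom_len))
        strand = "+" if rng.random() < 0.5 else "-"
        b = rng.integers(len(bins))
        tss_to_atg = int(rng.integers(bins[b, 0], bins[b, 1]))
        genes.append(GeneModel(gid, chrom, config.tss_flank, strand, tss_to_atg))
        genome[chrom] = seq
    return genes, genome


def plant_motifs(
    genes: list[GeneModel],
    genome: dict[str, str],
    config: SynthConfig,
) -> dict[str, str]:
    """Substitute motif instances into fragment windows of the genome.

    Per fragment window, the number of planted copies is drawn from
    ``planted_copy_probs``; each copy is a random concrete expansion of the
    planted consensus, substituted at a random non-overlapping position.
    Returns a new genome; the input genome is not modified.
    """
    rng = _rng(config, 2)
    instances = sorted(expand(config.planted_motif))
    mlen = len(config.planted_motif)
    L = config.fragment_length
    genome = dict(genome)
    copy_values = np.arange(len(config.planted_copy_probs))
    for gene in genes:
        for lo, hi in (config.upstream_window, config.downstream_window):
            for off in range(lo, hi, L):
                n_plant = int(rng.choice(copy_values, p=config.planted_copy_probs))
                if n_plant == 0:
                    continue
                window = oriented_slice(genome[gene.chrom], gene.tss_pos, gene.strand,
                                        off, off + L - 1)
                window = _substitute_copies(window, n_plant, instances, mlen, rng)
                genome[gene.chrom] = _write_oriented(
                    genome[gene.chrom], gene.tss_pos, gene.strand, off, window)
    return genome


def _substitute_copies(seq: str, n: int, instances: list[str], mlen: int,
                       rng: np.random.Generator) -> str:
    starts: list[int] = []
    for _ in range(n):
        for _attempt in range(100):
            s = int(rng.integers(0, len(seq) - mlen + 1))
            if all(abs(s - t) >= mlen for t in starts):
                starts.append(s)
                break
    out = list(seq)
    for s in starts:
        inst = instances[int(rng.integers(len(instances)))]
        out[s:s + mlen] = inst
    return "".join(out)


def _write_oriented(chrom_seq: str, tss_pos: int, strand: str, off: int, window: str) -> str:
    if strand == "+":
        start = tss_pos + off
        piece = window
    else:
        start = tss_pos - off - len(window) + 1
        piece = revcomp_seq(window)
    return chrom_seq[:start] + piece + chrom_seq[start + len(piece):]


# ---------------------------------------------------------------------------
# fragments

def design_fragments(
    genes: list[GeneModel],
    genome: dict[str, str],
    config: SynthConfig,
) -> list[FragmentDesign]:
    """Tile each gene's upstream and downstream windows into fragments.

    Default geometry yields 1 upstream- and 2 downstream-derived fragments
    per gene, in original orientation (minus-strand genes read on the
    reverse complement).  Fragments running past a chromosome end are
    skipped with a warning.
    """
    L = config.fragment_length
    fragments: list[FragmentDesign] = []
    i = 0
    for gene in genes:
        for side, (lo, hi) in (("upstream", config.upstream_window),
                               ("downstream", config.downstream_window)):
            for off in range(lo, hi, L):
                seq = oriented_slice(genome[gene.chrom], gene.tss_pos, gene.strand,
                                     off, off + L - 1)
                if len(seq) < L:
                    logger.warning("fragment at %s%+d of %s extends beyond chromosome; skipped",
                                   gene.strand, off, gene.gene_id)
                    continue
                fragments.append(FragmentDesign(f"f{i:06d}", gene.gene_id, side, off, seq))
                i += 1
    return fragments


# ---------------------------------------------------------------------------
# ground truth

def ground_truth(
    fragments: list[FragmentDesign],
    config: SynthConfig,
    library_sides: tuple[str, ...] = ("downstream", "upstream"),
) -> pd.DataFrame:
    """True activities: baseline 0 + copies x per-copy effect(side) + noise.

    Copy counts are re-scanned from the final fragment sequences (background
    occurrences count too).  One independent Gaussian noise draw per fragment
    per library; the optional ``activity_cap`` saturates high activities.
    No-insert controls have no insert sequence to drive activity, so their
    true activity is the baseline exactly (count noise still applies).
    """
    rng = _rng(config, 3)
    rows = []
    for f in fragments:
        rows.append({"fragment_id": f.fragment_id, "gene_id": f.gene_id,
                     "side": f.side, "offset": f.offset,
                     "copies": len(scan(f.sequence, config.planted_motif)),
                     "is_control": False})
    for j in range(config.n_controls):
        rows.append({"fragment_id": f"ctrl{j:04d}", "gene_id": "",
                     "side": "control", "offset": 0, "copies": 0, "is_control": True})
    gt = pd.DataFrame(rows).set_index("fragment_id")
    for side in library_sides:
        noise = rng.normal(0.0, config.fragment_noise_sd, size=len(gt))
        noise[gt["is_control"].to_numpy()] = 0.0
        act = gt["copies"].to_numpy() * config.effect(side) + noise
        if config.activity_cap is not None:
            act = np.minimum(act, config.activity_cap)
        gt[f"activity_{side}"] = act
    gt.attrs["per_copy_log2_effect_downstream"] = config.per_copy_log2_effect_downstream
    gt.attrs["per_copy_log2_effect_upstream"] = config.per_copy_log2_effect_upstream
    return gt


# ---------------------------------------------------------------------------
# barcodes

def assign_barcodes(fragment_ids: list[str], config: SynthConfig) -> pd.DataFrame:
    """Unique VNN x 5 barcodes (V = A/C/G), ``barcodes_per_fragment`` each.

    Returns a DataFrame with columns barcode, fragment_id.
    """
    n_needed = len(fragment_ids) * config.barcodes_per_fragment
    space = (3 * 4 * 4) ** config.barcode_triplets
    if n_needed > space:
        raise ConfigurationError(f"{n_needed} barcodes exceed VNN^{config.barcode_triplets} "
                                 f"space of {space}")
    rng = _rng(config, 4)
    seen: set[str] = set()
    barcodes: list[str] = []
    while len(barcodes) < n_needed:
        k = n_needed - len(barcodes)
        vs = rng.choice(V_BASES, size=(k, config.barcode_triplets, 1))
        ns = rng.choice(BASES, size=(k, config.barcode_triplets, 2))
        batch = np.concatenate([vs, ns], axis=2).reshape(k, -1)
        for row in batch:
            bc = "".join(row)
            if bc not in seen:
                seen.add(bc)
                barcodes.append(bc)
                if len(barcodes) == n_needed:
                    break
    fid = np.repeat(fragment_ids, config.barcodes_per_fragment)
    return pd.DataFrame({"barcode": barcodes, "fragment_id": fid})


BARCODE_PATTERN = tuple("VNN" * 5)


def barcode_is_valid(barcode: str) -> bool:
    if len(barcode) != 15:
        return False
    return all((b in "ACG") if p == "V" else (b in "ACGT")
               for b, p in zip(barcode, BARCODE_PATTERN))


# ---------------------------------------------------------------------------
# counts

def simulate_counts(
    barcode_map: pd.DataFrame,
    truth: pd.DataFrame,
    config: SynthConfig,
    library_side: str = "downstream",
) -> tuple[pd.Series, pd.DataFrame]:
    """DNA input counts and per-replicate RNA barcode counts.

    The DNA mix is a Dirichlet draw over constructs (one mix, shared by all
    replicates); DNA counts are multinomial reads of that mix.  The RNA
    count of barcode b is gamma-Poisson (negative binomial, variance
    mu + dispersion x mu^2) with mean proportional to
    dna_prop(fragment) x 2^activity(fragment), normalised to the
    sequencing depth.  Replicates use independent sub-seeds.
    """
    if config.seq_depth <= 0:
        raise ConfigurationError("zero sequencing depth")
    rng = _rng(config, 5)
    frag_ids = truth.index.to_numpy()
    props = pd.Series(rng.dirichlet(np.full(len(frag_ids), 10.0)), index=frag_ids)
    dna_counts = pd.Series(
        rng.multinomial(config.seq_depth, props.to_numpy()), index=frag_ids,
        name="dna_count")

    frag_of_bc = barcode_map["fragment_id"].to_numpy()
    n_bc = barcode_map["fragment_id"].map(barcode_map["fragment_id"].value_counts())
    activity = truth[f"activity_{library_side}"]
    w = (props[frag_of_bc].to_numpy() / n_bc.to_numpy()
         * np.exp2(activity[frag_of_bc].to_numpy()))
    mu = config.seq_depth * w / w.sum()

    reps = {}
    side_id = {"downstream": 0, "upstream": 1}[library_side]
    for r in range(config.n_replicates):
        rep_rng = np.random.default_rng([6, side_id, r, config.rng_seed])
        if config.nb_dispersion <= 1e-12:
            counts = rep_rng.poisson(mu)
        else:
            shape = 1.0 / config.nb_dispersion
            lam = rep_rng.gamma(shape, mu * config.nb_dispersion)
            counts = rep_rng.poisson(lam)
        reps[f"rep{r + 1}"] = counts
    rna = pd.DataFrame(reps, index=pd.Index(barcode_map["barcode"], name="barcode"))
    return dna_counts, rna


# ---------------------------------------------------------------------------
# gene-level simulators (expression matrices, allele associations)

def simulate_motif_counts(
    n_genes: int,
    seed: int,
    probs: tuple[float, ...] = DEFAULT_DOSE_PROBS,
) -> pd.Series:
    """Downstream motif copy counts per gene, drawn from a realistic dose mix."""
    rng = np.random.default_rng([7, seed])
    p = np.asarray(probs) / np.sum(probs)
    counts = rng.choice(np.arange(len(p)), size=n_genes, p=p)
    return pd.Series(counts, index=[f"g{i:05d}" for i in range(n_genes)],
                     name="motif_count")


def simulate_expression(
    motif_counts: pd.Series,
    slope: float,
    noise_sd: float,
    seed: int,
    intercept: float = 0.0,
) -> pd.Series:
    """log2 expression per gene with mean linear in downstream motif count."""
    rng = np.random.default_rng([8, seed])
    vals = intercept + slope * motif_counts.to_numpy() + rng.normal(0, noise_sd, len(motif_counts))
    return pd.Series(vals, index=motif_counts.index, name="log2_expression")


def simulate_allele_data(
    n_genes: int = 500,
    n_samples: int = 200,
    effect: float = 0.5,
    noise_sd: float = 0.5,
    allele_freq: float = 0.3,
    effect_window: tuple[int, int] = (1, 500),
    offset_range: tuple[int, int] = (-2000, 2000),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Population expression with motif-gain alleles effective only in a window.

    Each gene carries a motif allele at a TSS-relative offset; samples with
    the motif allele express ``effect`` log2 higher iff the offset falls in
    ``effect_window``.  Returns (expression genes x samples, binary allele
    matrix, per-gene motif offsets).
    """
    rng = np.random.default_rng([9, seed])
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    sample_ids = [f"s{j:04d}" for j in range(n_samples)]
    offsets = pd.Series(rng.integers(offset_range[0], offset_range[1], n_genes),
                        index=gene_ids, name="motif_offset")
    alleles = rng.random((n_genes, n_samples)) < allele_freq
    in_win = ((offsets.to_numpy() >= effect_window[0])
              & (offsets.to_numpy() <= effect_window[1]))
    expr = (effect * alleles * in_win[:, None]
            + rng.normal(0, noise_sd, (n_genes, n_samples)))
    return (pd.DataFrame(expr, index=gene_ids, columns=sample_ids),
            pd.DataFrame(alleles.astype(int), index=gene_ids, columns=sample_ids),
            offsets)


# ---------------------------------------------------------------------------
# one-call library bundle and file output

@dataclass
class SimulatedLibrary:
    config: SynthConfig
    genes: list[GeneModel]
    genome: dict[str, str]
    fragments: list[FragmentDesign]
    truth: pd.DataFrame
    barcode_map: pd.DataFrame
    dna_counts: pd.Series
    rna_counts: pd.DataFrame
    library_side: str

    @property
    def tss_annotation(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"gene_id": g.gene_id, "chrom": g.chrom, "tss_pos": g.tss_pos,
              "strand": g.strand, "tss_to_atg": g.tss_to_atg} for g in self.genes])

    @property
    def fragment_sequences(self) -> dict[str, str]:
        return {f.fragment_id: f.sequence for f in self.fragments}


def simulate_library(config: SynthConfig, library_side: str = "downstream") -> SimulatedLibrary:
    """Run the whole generator: genes -> planting -> fragments -> counts."""
    genes, genome = generate_genes(config)
    genome = plant_motifs(genes, genome, config)
    fragments = design_fragments(genes, genome, config)
    truth = ground_truth(fragments, config)
    barcode_map = assign_barcodes(list(truth.index), config)
    dna_counts, rna_counts = simulate_counts(barcode_map, truth, config, library_side)
    return SimulatedLibrary(config, genes, genome, fragments, truth,
                            barcode_map, dna_counts, rna_counts, library_side)


def write_library(lib: SimulatedLibrary, outdir) -> None:
    """Write fragments FASTA, barcode-map/count/ground-truth TSVs, config YAML."""
    from pathlib import Path
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    recs = [SeqRecord(Seq(f.sequence), id=f.fragment_id,
                      description=f"{f.gene_id} {f.side} {f.offset:+d}")
            for f in lib.fragments]
    SeqIO.write(recs, out / "fragments.fasta", "fasta")
    bm = lib.barcode_map.copy()
    bm["library_id"] = lib.library_side
    bm.to_csv(out / "barcode_map.tsv", sep="\t", index=False)
    lib.dna_counts.to_csv(out / "dna_counts.tsv", sep="\t")
    lib.rna_counts.to_csv(out / "rna_counts.tsv", sep="\t")
    lib.truth.to_csv(out / "ground_truth.tsv", sep="\t")
    lib.tss_annotation.to_csv(out / "tss.tsv", sep="\t", index=False)
    lib.config.to_yaml(out / "config.yaml")
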