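"""TSS-relative positional analyses.

Feature positions (variant sites, TF-binding peak centers, motif starts)
are mapped to strand-oriented offsets from the nearest annotated TSS and
summarised as metagene-style enrichment profiles with rolling smoothing.
Also here: TSS-to-ATG distance stratification, TF-family consolidation,
windowed nucleotide diversity (pi) and the direction ratio of significant
motif-allele/expression associations by distance bin.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kmer_screen import mann_whitney_u

DEFAULT_TSS_ATG_BINS = ((0, 50), (50, 100), (100, 250), (250, 500))
DEFAULT_DISTANCE_BINS = ((-2000, -500), (-500, 0), (0, 500), (500, 2000))


@dataclass
class Profile:
    """A TSS-anchored positional track (raw and rolling-mean smoothed)."""

    positions: np.ndarray   # uniform grid of TSS-relative offsets, bp
    raw: np.ndarray
    smoothed: np.ndarray
    smooth_window: int
    n_features: int         # features assigned to the grid


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    return (pd.Series(values.astype(float))
            .rolling(window, center=True, min_periods=1).mean().to_numpy())


def assign_offsets(
    points: pd.DataFrame,
    tss_annotation: pd.DataFrame,
    half_width: int,
) -> pd.DataFrame:
    """Strand-oriented offset of each point from its nearest TSS.

    Each point goes to the single nearest TSS within ``half_width``; ties
    are broken toward the smaller absolute oriented offset, then by
    lexicographic gene id.  Points with no TSS in range are dropped.
    """
    out_rows = []
    by_chrom = dict(tuple(tss_annotation.groupby("chrom")))
    for row in points.itertuples(index=False):
        genes = by_chrom.get(row.chrom)
        if genes is None:
            continue
        sign = np.where(genes["strand"].to_numpy() == "+", 1, -1)
        offs = (row.pos - genes["tss_pos"].to_numpy()) * sign
        order = np.lexsort((genes["gene_id"].to_numpy(), np.abs(offs)))
        best = order[0]
        if abs(offs[best]) <= half_width:
            out_rows.append({"chrom": row.chrom, "pos": row.pos,
                             "gene_id": genes["gene_id"].iloc[best],
                             "offset": int(offs[best])})
    return pd.DataFrame(out_rows, columns=["chrom", "pos", "gene_id", "offset"])


def tss_relative_profile(
    points: pd.DataFrame,
    tss_annotation: pd.DataFrame,
    half_width: int = 2000,
    smooth: int = 100,
    as_proportion: bool = False,
) -> Profile:
    """Positional enrichment profile of features around TSSs.

    ``points`` needs columns chrom, pos; ``tss_annotation`` needs gene_id,
    chrom, tss_pos, strand.  Per-offset feature counts (or, with
    ``as_proportion``, the fraction of annotated genes with a feature at
    that offset) are smoothed with a centered rolling mean, truncated at
    the grid edges.
    """
    if len(points) == 0:
        raise ValueError("no feature points given")
    assigned = assign_offsets(points, tss_annotation, half_width)
    grid = np.arange(-half_width, half_width + 1)
    raw = np.zeros(grid.size)
    if len(assigned):
        offs, counts = np.unique(assigned["offset"].to_numpy(), return_counts=True)
        raw[offs + half_width] = counts
    if as_proportion:
        raw = raw / len(tss_annotation)
    return Profile(grid, raw, _smooth(raw, smooth), smooth, int(len(assigned)))


def stratify_by_tss_atg(
    points: pd.DataFrame,
    tss_annotation: pd.DataFrame,
    bins: tuple[tuple[int, int], ...] = DEFAULT_TSS_ATG_BINS,
    half_width: int = 2000,
    smooth: int = 100,
) -> tuple[dict[tuple[int, int], Profile], dict[tuple[int, int], int], int]:
    """One profile per TSS-to-ATG distance bin (half-open [lo, hi)).

    Genes without a tss_to_atg annotation are excluded and counted.
    Returns (profiles per bin, gene counts per bin, n excluded genes).
    """
    dist = tss_annotation["tss_to_atg"]
    excluded = int(dist.isna().sum())
    profiles: dict[tuple[int, int], Profile] = {}
    sizes: dict[tuple[int, int], int] = {}
    for lo, hi in bins:
        genes = tss_annotation[(dist >= lo) & (dist < hi)]
        sizes[(lo, hi)] = len(genes)
        if len(genes) == 0:
            continue
        sub_points = points[points["chrom"].isin(set(genes["chrom"]))]
        if len(sub_points) == 0:
            continue
        profiles[(lo, hi)] = tss_relative_profile(sub_points, genes, half_width, smooth)
    return profiles, sizes, excluded


def family_consolidate(
    per_tf_profiles: dict[str, np.ndarray],
    family_map: dict[str, str],
) -> dict[str, np.ndarray]:
    """Average member profiles per TF family, then scale each to max 100."""
    members: dict[str, list[np.ndarray]] = {}
    for tf, profile in per_tf_profiles.items():
        fam = family_map.get(tf)
        if fam is not None:
            members.setdefault(fam, []).append(np.asarray(profile, dtype=float))
    out = {}
    for fam, profs in members.items():
        if not profs:
            raise ValueError(f"family {fam} has no member profiles")
        mean = np.mean(profs, axis=0)
        peak = mean.max()
        if peak <= 0:
            raise ValueError(f"family {fam} profile has no positive signal to scale")
        out[fam] = mean * (100.0 / peak)
    if not out:
        raise ValueError("no family had any member profile")
    return out


def nucleotide_diversity(
    haplotypes: list[str],
    windows: list[tuple[int, int]] | int,
) -> pd.DataFrame:
    """Windowed nucleotide diversity pi over aligned equal-length haplotypes.

    Per window (half-open [start, end)), pi is the mean over haplotype
    pairs of (differing sites / comparable sites), where sites with a gap
    or N in either member of the pair are excluded from both numerator and
    denominator.  ``windows`` may be explicit intervals or a window size to
    tile the alignment with.
    """
    if len(haplotypes) < 2:
        raise ValueError("need >= 2 haplotypes")
    length = len(haplotypes[0])
    if any(len(h) != length for h in haplotypes):
        raise ValueError("haplotypes must be aligned to equal length")
    if isinstance(windows, int):
        windows = [(s, min(s + windows, length)) for s in range(0, length, windows)]
    arr = np.array([list(h.upper()) for h in haplotypes])
    valid = (arr != "-") & (arr != "N")
    rows = []
    for lo, hi in windows:
        pis = []
        for i, j in itertools.combinations(range(len(haplotypes)), 2):
            ok = valid[i, lo:hi] & valid[j, lo:hi]
            n_sites = int(ok.sum())
            if n_sites == 0:
                continue
            diffs = int(((arr[i, lo:hi] != arr[j, lo:hi]) & ok).sum())
            pis.append(diffs / n_sites)
        rows.append({"start": lo, "end": hi,
                     "pi": float(np.mean(pis)) if pis else float("nan")})
    return pd.DataFrame(rows)


def allele_direction_ratio(
    expression: pd.DataFrame,
    motif_alleles: pd.DataFrame,
    motif_offsets: pd.Series,
    distance_bins: tuple[tuple[int, int], ...] = DEFAULT_DISTANCE_BINS,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Ratio of higher- vs lower-expressing significant motif alleles per bin.

    Per gene, expression is compared between samples with and without the
    motif allele by a two-sided rank test; significance defaults to
    Bonferroni over the genes tested (``nominal`` and ``bh`` available).
    Direction is the sign of the with-minus-without median difference.
    Per distance bin (half-open, on the motif's TSS-relative offset) the
    ratio (n_higher + 0.5) / (n_lower + 0.5) is reported alongside the raw
    counts and the number of monomorphic (skipped) genes.
    """
    results = []
    n_skipped = 0
    for gene in expression.index:
        alleles = motif_alleles.loc[gene]
        expr = expression.loc[gene]
        with_vals = expr[alleles == 1].to_numpy()
        without_vals = expr[alleles == 0].to_numpy()
        if with_vals.size == 0 or without_vals.size == 0:
            n_skipped += 1
            continue
        res = mann_whitney_u(with_vals, without_vals, mode="approx")
        results.append({"gene_id": gene, "p": res.p,
                        "direction": float(np.median(with_vals) - np.median(without_vals)),
                        "offset": int(motif_offsets[gene])})
    tested = pd.DataFrame(results)
    if tested.empty:
        raise ValueError("no polymorphic gene to test")
    if correction == "bonferroni":
        sig = tested["p"] <= alpha / len(tested)
    elif correction == "nominal":
        sig = tested["p"] <= alpha
    elif correction == "bh":
        order = tested["p"].rank(method="first")
        sig = tested["p"] <= alpha * order / len(tested)
        # step-up: everything below the largest passing rank is significant
        if sig.any():
            sig = tested["p"] <= tested.loc[sig, "p"].max()
    else:
        raise ValueError(f"unknown correction {correction!r}")
    rows = []
    for lo, hi in distance_bins:
        in_bin = (tested["offset"] >= lo) & (tested["offset"] < hi)
        n_higher = int((sig & in_bin & (tested["direction"] > 0)).sum())
        n_lower = int((sig & in_bin & (tested["direction"] < 0)).sum())
        rows.append({"bin_lo": lo, "bin_hi": hi, "n_higher": n_higher,
                     "n_lower": n_lower, "n_genes": int(in_bin.sum()),
                     "ratio": (n_higher + 0.5) / (n_lower + 0.5)})
    out = pd.DataFrame(rows)
    out.attrs["n_monomorphic_skipped"] = n_skipped
    out.attrs["n_tested"] = len(tested)
    return out
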