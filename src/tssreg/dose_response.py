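"""Motif dose-response: per-copy effect sizes of motif count on expression.

The effect size is the OLS slope of log2 expression on the number of motif
copies in a TSS-anchored window (counts truncated at a cap, default 9),
with a two-sided t-statistic p value for slope = 0.  Applied per dataset
(tissues, cell types, species) and, in the k-mer scan, to every k-mer in
upstream and downstream windows at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import oriented_slice


@dataclass
class EffectSizeResult:
    """OLS slope of expression on motif count with its t-test p value."""

    dataset_id: str
    slope: float
    intercept: float
    t: float
    p: float
    n: int
    n_per_dose: dict[int, int] = field(default_factory=dict)
    dose_cap: int = 9


def _dose_labels(counts: np.ndarray, cap: int) -> np.ndarray:
    counts = counts.astype(int)
    labels = counts.astype(object)
    labels[counts >= cap] = f"{cap}+"
    return labels.astype(str)


def group_by_dose(
    expression: pd.Series,
    motif_counts: pd.Series,
    cap: int = 4,
) -> pd.DataFrame:
    """Box-plot statistics of expression per motif-dose group.

    Doses >= ``cap`` are pooled into a top "{cap}+" bin.  Reports n, mean,
    sd, median, quartiles and 1.5-IQR whiskers per group.
    """
    shared = expression.index.intersection(motif_counts.index)
    if len(shared) == 0:
        raise ValueError("expression and motif counts share no genes")
    expr = expression.loc[shared].to_numpy(dtype=float)
    doses = _dose_labels(motif_counts.loc[shared].to_numpy(), cap)
    rows = []
    for dose in sorted(set(doses), key=lambda d: int(d.rstrip("+"))):
        vals = expr[doses == dose]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        in_fence = vals[(vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)]
        rows.append({"dose": dose, "n": vals.size, "mean": vals.mean(),
                     "sd": vals.std(ddof=1) if vals.size > 1 else float("nan"),
                     "median": med, "q1": q1, "q3": q3,
                     "whisker_lo": in_fence.min(), "whisker_hi": in_fence.max()})
    return pd.DataFrame(rows).set_index("dose")


def effect_size(
    expression: pd.Series,
    motif_counts: pd.Series,
    dataset_id: str = "",
    count_cap: int = 9,
    min_genes: int = 10,
) -> EffectSizeResult:
    """Per-copy effect: OLS of expression on (cap-truncated) motif count."""
    shared = expression.index.intersection(motif_counts.index)
    if len(shared) < min_genes:
        raise ValueError(f"need >= {min_genes} genes, got {len(shared)}")
    y = expression.loc[shared].to_numpy(dtype=float)
    x = np.minimum(motif_counts.loc[shared].to_numpy(dtype=float), count_cap)
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct motif-count doses")
    slope, t, p, intercept = _ols(x, y)
    doses, sizes = np.unique(x.astype(int), return_counts=True)
    return EffectSizeResult(dataset_id, slope, intercept, t, p, y.size,
                            dict(zip(doses.tolist(), sizes.tolist())), count_cap)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = yc - slope * xc
    s2 = float(resid @ resid) / max(n - 2, 1)
    se = np.sqrt(s2 / sxx)
    if se == 0:
        return slope, float("inf") if slope else 0.0, 0.0 if slope else 1.0, intercept
    t = slope / se
    p = float(min(1.0, 2 * stats.t.sf(abs(t), n - 2)))
    return slope, float(t), max(p, np.finfo(float).tiny), intercept


def _ols_many(X: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Slope/t/p of y on each column of X (zero-variance columns -> NaN)."""
    n = y.size
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (Xc ** 2).sum(axis=0)
    sxy = Xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        rss = float(yc @ yc) - slope * sxy
        s2 = rss / (n - 2)
        t = slope / np.sqrt(s2 / sxx)
    p = np.minimum(1.0, 2 * stats.t.sf(np.abs(t), n - 2))
    out = pd.DataFrame({"slope": slope, "t": t, "p": p})
    out.loc[sxx == 0, ["slope", "t", "p"]] = np.nan
    return out


def count_kmers_in_windows(
    genome: dict[str, str],
    tss_annotation: pd.DataFrame,
    k: int = 6,
    windows: dict[str, tuple[int, int]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-gene occurrence counts of every k-mer in TSS-relative windows.

    Windows are inclusive offset intervals on the transcribed strand
    (default upstream [-500, -1] and downstream [+1, +500]); overlapping
    occurrences count, windows containing N contribute nothing.
    Returns, per window name, a genes x 4^k count matrix.
    """
    if windows is None:
        windows = {"upstream": (-500, -1), "downstream": (1, 500)}
    from itertools import product
    kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    col = {km: i for i, km in enumerate(kmers)}
    out: dict[str, pd.DataFrame] = {}
    for name, (lo, hi) in windows.items():
        mat = np.zeros((len(tss_annotation), 4 ** k), dtype=np.int32)
        for gi, row in enumerate(tss_annotation.itertuples(index=False)):
            seq = oriented_slice(genome[row.chrom], row.tss_pos, row.strand,
                                 lo, hi + k - 1)
            limit = hi - lo
            for i in range(min(len(seq) - k, limit) + 1):
                j = col.get(seq[i:i + k])
                if j is not None:
                    mat[gi, j] += 1
        out[name] = pd.DataFrame(mat, index=tss_annotation["gene_id"].to_numpy(),
                                 columns=kmers)
    return out


def kmer_effect_scan(
    expression: pd.Series,
    genome: dict[str, str],
    tss_annotation: pd.DataFrame,
    k: int = 6,
    windows: dict[str, tuple[int, int]] | None = None,
    count_cap: int = 9,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Effect size of every k-mer's windowed count, upstream and downstream.

    Per (k-mer, window): OLS slope of expression on the gene's occurrence
    count, two-sided t p value, and a Bonferroni flag at ``alpha`` over all
    fitted tests.  K-mers absent everywhere in a window are reported NaN.
    """
    counts = count_kmers_in_windows(genome, tss_annotation, k, windows)
    frames = []
    for name, mat in counts.items():
        shared = expression.index.intersection(mat.index)
        y = expression.loc[shared].to_numpy(dtype=float)
        X = np.minimum(mat.loc[shared].to_numpy(dtype=float), count_cap)
        res = _ols_many(X, y)
        res.insert(0, "kmer", mat.columns)
        res.insert(1, "window", name)
        res["n_genes_with"] = (mat.loc[shared].to_numpy() > 0).sum(axis=0)
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    n_tests = int(out["p"].notna().sum())
    out["significant"] = out["p"] <= alpha / max(n_tests, 1)
    out["significant"] = out["significant"].fillna(False)
    return out.sort_values("p", na_position="last").reset_index(drop=True)


def compendium_effects(
    datasets: dict[str, pd.Series],
    motif_counts: pd.Series | dict[str, pd.Series],
    cap: int = 4,
    count_cap: int = 9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Effect sizes across many expression datasets + 0-dose-normalised means.

    ``motif_counts`` may be shared or per-dataset (e.g. per species).
    Returns (effect table with an NA row + reason where a dataset fails the
    fit preconditions, heatmap matrix of per-dose mean expression minus the
    dose-0 mean: the dose-0 column is 0 in every row).
    """
    eff_rows, heat_rows = [], []
    for ds_id, expr in datasets.items():
        counts = motif_counts[ds_id] if isinstance(motif_counts, dict) else motif_counts
        try:
            res = effect_size(expr, counts, dataset_id=ds_id, count_cap=count_cap)
            eff_rows.append({"dataset_id": ds_id, "slope": res.slope, "t": res.t,
                             "p": res.p, "n": res.n, "reason": ""})
            g = group_by_dose(expr, counts, cap=cap)["mean"]
            base = g.get("0", np.nan)
            heat_rows.append(pd.Series(g - base, name=ds_id))
        except ValueError as exc:
            eff_rows.append({"dataset_id": ds_id, "slope": np.nan, "t": np.nan,
                             "p": np.nan, "n": 0, "reason": str(exc)})
    effects = pd.DataFrame(eff_rows).set_index("dataset_id").sort_values("slope")
    heatmap = pd.DataFrame(heat_rows) if heat_rows else pd.DataFrame()
    return effects, heatmap


def response_by_dose(
    treatment: pd.Series,
    control: pd.Series,
    motif_counts: pd.Series,
    cap: int = 4,
) -> tuple[pd.DataFrame, int]:
    """Treatment-minus-control log2 response summarised by motif dose.

    Returns the dose summary and the number of genes missing from either
    vector (excluded).
    """
    shared = treatment.index.intersection(control.index)
    if len(shared) == 0:
        raise ValueError("treatment and control share no genes")
    n_excluded = len(treatment.index.union(control.index)) - len(shared)
    response = treatment.loc[shared] - control.loc[shared]
    return group_by_dose(response, motif_counts, cap=cap), n_excluded
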