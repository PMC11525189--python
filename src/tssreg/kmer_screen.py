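"""K-mer association screen: which k-mers' presence tracks fragment activity.

Fragments are split into with/without groups per k-mer (presence, not
count; as-written strand only, since fragments are assayed in their
original orientation) and compared by a two-sided Mann-Whitney U test with
Bonferroni correction at family size 4^k.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats


class MannWhitneyResult(NamedTuple):
    U: float
    p: float


def kmer_presence(sequence: str, k: int) -> set[str]:
    """All length-k substrings over ACGT (windows containing N are skipped)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = sequence.upper()
    return {seq[i:i + k] for i in range(len(seq) - k + 1)
            if "N" not in seq[i:i + k]}


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    # pairs where x wins, half credit for ties
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_u(x, y, mode: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test; U is the statistic of group x.

    ``exact`` mode enumerates the permutation null over all assignments of
    the pooled values to the two groups (tie-aware; used automatically when
    the pooled size is <= 16).  ``approx`` uses the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode == "auto":
        mode = "exact" if x.size + y.size <= 16 else "approx"
    if mode == "exact":
        u_obs = _u_statistic(x, y)
        pooled = np.concatenate([x, y])
        n = pooled.size
        us = []
        for idx in itertools.combinations(range(n), x.size):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            us.append(_u_statistic(pooled[mask], pooled[~mask]))
        us = np.asarray(us)
        eps = 1e-9
        p_lo = np.mean(us <= u_obs + eps)
        p_hi = np.mean(us >= u_obs - eps)
        return MannWhitneyResult(U=u_obs, p=float(min(1.0, 2 * min(p_lo, p_hi))))
    if mode == "approx":
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        return MannWhitneyResult(U=float(res.statistic), p=float(res.pvalue))
    raise ValueError(f"unknown mode {mode!r}")


def _ranksum_test(ranks: np.ndarray, presence: np.ndarray,
                  tie_term: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised normal-approximation U test for many with/without splits.

    ``presence`` is a boolean matrix (k-mers x fragments) over the shared
    fragment order of ``ranks``.  Returns (U, two-sided p) per row.
    """
    n = ranks.size
    n1 = presence.sum(axis=1).astype(float)
    n2 = n - n1
    rank_sum = presence @ ranks
    U = rank_sum - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(U - mu) - 0.5) / sigma
    z = np.where(sigma > 0, np.maximum(z, 0.0), 0.0)
    p = np.minimum(1.0, 2 * stats.norm.sf(z))
    return U, p


def screen(
    table: pd.DataFrame,
    fragment_sequences: dict[str, str],
    k: int = 6,
    alpha: float = 0.05,
    min_group: int = 10,
) -> pd.DataFrame:
    """Test every k-mer's presence against fragment activity.

    One row per k-mer present in >= ``min_group`` and absent from >= 1 of
    the fragments: difference of group means (with - without), Mann-Whitney
    U (of the with-group) and two-sided p, with a Bonferroni significance
    flag at family size 4^k.  Sorted by p, then by |delta_mean| descending.
    """
    frag_ids = [f for f in table.index if f in fragment_sequences]
    missing = set(table.index) - set(frag_ids)
    if missing:
        raise KeyError(f"fragments without sequence: {sorted(missing)[:5]}")
    act = table.loc[frag_ids, "log2_expression"].to_numpy()
    n = len(frag_ids)

    kmer_to_frags: dict[str, list[int]] = defaultdict(list)
    for i, fid in enumerate(frag_ids):
        for km in kmer_presence(fragment_sequences[fid], k):
            kmer_to_frags[km].append(i)
    kmers = sorted(km for km, idx in kmer_to_frags.items()
                   if min_group <= len(idx) <= n - 1)
    if not kmers:
        raise ValueError("no k-mer passes the with/without grouping")

    presence = np.zeros((len(kmers), n), dtype=bool)
    for row, km in enumerate(kmers):
        presence[row, kmer_to_frags[km]] = True

    ranks = stats.rankdata(act)
    _, tie_counts = np.unique(act, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    U, p = _ranksum_test(ranks, presence, tie_term)

    n_with = presence.sum(axis=1)
    sums = presence @ act
    delta = sums / n_with - (act.sum() - sums) / (n - n_with)
    out = pd.DataFrame({
        "kmer": kmers,
        "delta_mean": delta,
        "U": U,
        "p": p,
        "n_with": n_with,
        "n_without": n - n_with,
        "significant": p <= alpha / (4 ** k),
    })
    out = out.sort_values(["p", "delta_mean"],
                          key=lambda s: s if s.name == "p" else -s.abs(),
                          kind="mergesort").reset_index(drop=True)
    return out


def group_by_presence(
    table: pd.DataFrame,
    kmer: str,
    fragment_sequences: dict[str, str],
) -> dict:
    """Partition fragments by k-mer presence with per-group mean +- 1 s.d."""
    with_ids, without_ids = [], []
    for fid in table.index:
        seq = fragment_sequences[fid].upper()
        (with_ids if kmer.upper() in seq else without_ids).append(fid)

    def _summ(ids):
        vals = table.loc[ids, "log2_expression"]
        return {"n": len(ids),
                "mean": float(vals.mean()) if len(ids) else float("nan"),
                "sd": float(vals.std(ddof=1)) if len(ids) > 1 else float("nan")}

    return {"with": with_ids, "without": without_ids,
            "summary": {"with": _summ(with_ids), "without": _summ(without_ids)},
            "degenerate": not with_ids or not without_ids}
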