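"""Barcode-level MPRA quantification: linking, normalisation, expression, QC.

Turns barcode-association reads, DNA input counts and RNA barcode counts
into per-fragment log2 expression per library.  The expression of a barcode
is the log2 ratio of its RNA abundance (counts per million, pseudocounted)
to the DNA input proportion of its fragment; fragment activity averages the
barcode ratios, and replicates are median-centred before merging so that
depth and transformation-efficiency offsets cancel.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class CorrelationResult(NamedTuple):
    r: float
    n: int


def link_barcodes(
    association_records: Iterable[tuple[str, str]],
    fragment_sequences: dict[str, str],
    min_reads: int = 3,
    min_purity: float = 0.9,
    anchor_length: int = 30,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign barcodes to fragments from (barcode, fragment_read) pairs.

    A fragment read is matched by exact identity of its first
    ``anchor_length`` bases to a designed fragment.  A barcode is retained
    and assigned to its majority fragment when its total matched reads are
    >= ``min_reads`` and the majority fraction (purity) is >= ``min_purity``.

    Returns the barcode map (barcode, fragment_id, n_reads, purity) and a
    tally of drop reasons; retained + dropped_purity + dropped_min_reads
    equals the number of distinct barcodes with matched reads.
    """
    anchors: dict[str, str] = {}
    for fid, seq in fragment_sequences.items():
        anchors[seq[:anchor_length]] = fid
    votes: dict[str, Counter] = defaultdict(Counter)
    tally = {"unmatched_reads": 0, "dropped_purity": 0, "dropped_min_reads": 0, "retained": 0}
    n_records = 0
    for barcode, frag_read in association_records:
        n_records += 1
        fid = anchors.get(frag_read[:anchor_length])
        if fid is None:
            tally["unmatched_reads"] += 1
            continue
        votes[barcode][fid] += 1
    if n_records == 0:
        raise ValueError("empty association input")
    rows = []
    for barcode, counter in votes.items():
        total = sum(counter.values())
        (fid, top), = counter.most_common(1)
        purity = top / total
        if total < min_reads:
            tally["dropped_min_reads"] += 1
        elif purity < min_purity:
            tally["dropped_purity"] += 1
        else:
            tally["retained"] += 1
            rows.append({"barcode": barcode, "fragment_id": fid,
                         "n_reads": total, "purity": purity})
    return pd.DataFrame(rows, columns=["barcode", "fragment_id", "n_reads", "purity"]), tally


def dna_proportions(dna_counts: pd.Series, pseudocount: float = 0.0) -> pd.Series:
    """Fragment DNA-input proportions, pseudocounted and normalised to 1."""
    shifted = dna_counts.astype(float) + pseudocount
    total = shifted.sum()
    if total <= 0:
        raise ValueError("all-zero DNA counts (and zero pseudocount)")
    return shifted / total


def quantify_expression(
    rna_counts: pd.DataFrame,
    barcode_map: pd.DataFrame,
    dna_props: pd.Series,
    min_barcodes: int = 3,
    pseudocount: float = 1.0,
    cpm_scale: float = 1e6,
    aggregate: str = "mean",
    center_replicates: bool = True,
) -> pd.DataFrame:
    """Per-fragment log2 expression from RNA barcode counts.

    ``rna_counts`` is barcodes x replicates.  Per replicate: each barcode's
    count is converted to pseudocounted CPM, divided by the DNA proportion
    of its fragment and log2-transformed; fragment activity aggregates the
    barcode log-ratios (mean by default, median by config).  Replicates are
    median-centred (optional) and averaged into ``log2_expression``.
    Fragments supported by fewer than ``min_barcodes`` barcodes are omitted.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    bm = barcode_map.set_index("barcode")["fragment_id"]
    shared = rna_counts.index.intersection(bm.index)
    counts = rna_counts.loc[shared]
    frags = bm.loc[shared]
    missing = set(frags.unique()) - set(dna_props.index)
    if missing:
        raise KeyError(f"fragment(s) missing from DNA proportions: {sorted(missing)[:5]}")
    props = dna_props.loc[frags].to_numpy()[:, None]

    c = counts.to_numpy(dtype=float) + pseudocount
    totals = counts.sum(axis=0).to_numpy(dtype=float) + pseudocount * len(counts)
    cpm = cpm_scale * c / totals
    log_ratio = pd.DataFrame(np.log2(cpm / props), index=counts.index,
                             columns=counts.columns)
    grouped = log_ratio.groupby(frags)
    per_rep = grouped.mean() if aggregate == "mean" else grouped.median()
    n_bc = grouped.size()
    per_rep = per_rep.loc[n_bc >= min_barcodes]
    n_bc = n_bc.loc[per_rep.index]
    if center_replicates:
        per_rep = per_rep - per_rep.median(axis=0)
    out = per_rep.copy()
    out.columns = [f"log2_{c}" for c in per_rep.columns]
    out["log2_expression"] = per_rep.mean(axis=1)
    out["n_barcodes"] = n_bc
    out.index.name = "fragment_id"
    return out


def replicate_correlation(a, b) -> CorrelationResult:
    """Pearson correlation between two activity tables over shared fragments."""
    sa = a["log2_expression"] if isinstance(a, pd.DataFrame) else a
    sb = b["log2_expression"] if isinstance(b, pd.DataFrame) else b
    shared = sa.index.intersection(sb.index)
    if len(shared) < 2:
        raise ValueError(f"need >= 2 shared fragments, got {len(shared)}")
    r = float(np.corrcoef(sa.loc[shared], sb.loc[shared])[0, 1])
    return CorrelationResult(r=r, n=len(shared))


def relative_activity(table: pd.DataFrame, control_ids: Iterable[str]) -> pd.Series:
    """Activity relative to no-insert controls: delta log2 vs the control mean."""
    controls = table.index.intersection(pd.Index(control_ids))
    if len(controls) == 0:
        raise ValueError("no no-insert control entries in the table")
    baseline = table.loc[controls, "log2_expression"].mean()
    return table["log2_expression"] - baseline
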