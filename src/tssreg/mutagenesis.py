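"""Mutagenesis series: motif removal, deep mutational scan, motif addition.

Three families of derivatives are designed from a parent fragment, mirroring
a motif-perturbation reporter experiment:

* removal — every motif occurrence is destroyed at once, by deletion of the
  8-bp window, by a seeded 8-bp shuffle (redrawn until the GATC core is
  gone), or by a GATC-to-GATA point mutation of the core;
* deep scan — every 10-bp window deleted, every base substituted to its
  three alternatives, and every base deleted: 5L - 9 derivatives for a
  mutable region of L nt (736 at L = 149);
* addition — 1..n motif copies substituted in at evenly spaced positions,
  preserving length.

``paired_effect`` analyses matched parent/derivative activities as
activity deltas grouped by edit kind, position or copies added.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import IUPACMotif, scan

logger = logging.getLogger(__name__)

REMOVAL_MODES = ("motif_delete", "motif_shuffle8", "gatc_to_gata")


@dataclass(frozen=True)
class Derivative:
    derivative_id: str
    parent_fragment_id: str
    op_kind: str            # motif_delete | motif_shuffle8 | gatc_to_gata | del10 | sub1 | del1 | add_motifs
    positions: tuple[int, ...]
    payload: str            # replacement bases, or copies added as str
    sequence: str


def _merge_windows(starts: list[int], width: int) -> list[tuple[int, int]]:
    """Merge overlapping [s, s+width) windows into disjoint intervals."""
    merged: list[tuple[int, int]] = []
    for s in sorted(starts):
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], s + width))
        else:
            merged.append((s, s + width))
    return merged


def remove_motifs(
    fragment_id: str,
    sequence: str,
    motif: IUPACMotif | str = "YVGATCBR",
    mode: str | None = None,
    seed: int = 0,
    max_tries: int = 1000,
) -> dict[str, Derivative] | Derivative:
    """Destroy every motif occurrence in the fragment, per removal mode.

    All occurrences are edited simultaneously.  ``mode=None`` returns all
    three derivatives keyed by mode.  Post-edit sequences are re-scanned;
    the shuffle is redrawn (seeded) until no GATC remains in the edited
    windows and the motif is gone from the derivative.
    """
    consensus = motif.consensus if isinstance(motif, IUPACMotif) else motif
    width = len(consensus)
    starts = scan(sequence, consensus)
    if not starts:
        raise ValueError(f"fragment {fragment_id} contains no {consensus} occurrence")
    windows = _merge_windows(starts, width)
    core_off = consensus.find("GATC")

    def _build(kind: str) -> Derivative:
        if kind == "motif_delete":
            # a deletion junction can itself form a new occurrence; re-scan
            # and keep deleting until the derivative is motif-free
            out = sequence
            pending = windows
            for _ in range(max_tries):
                for lo, hi in reversed(pending):
                    out = out[:lo] + out[hi:]
                new_starts = scan(out, consensus)
                if not new_starts:
                    break
                pending = _merge_windows(new_starts, width)
            payload = ""
        elif kind == "gatc_to_gata":
            if core_off < 0:
                raise ValueError(f"motif {consensus} has no literal GATC core")
            chars = list(sequence)
            for s in starts:
                chars[s + core_off + 3] = "A"     # ...GATC -> ...GATA
            out = "".join(chars)
            payload = "A"
        elif kind == "motif_shuffle8":
            rng = np.random.default_rng([zlib.crc32(fragment_id.encode()), seed])
            for _ in range(max_tries):
                chars = list(sequence)
                for lo, hi in windows:
                    piece = list(sequence[lo:hi])
                    rng.shuffle(piece)
                    chars[lo:hi] = piece
                out = "".join(chars)
                edited_ok = all("GATC" not in out[lo:hi] for lo, hi in windows)
                if edited_ok and not scan(out, consensus):
                    break
            else:
                raise RuntimeError(f"shuffle failed to remove motif in {fragment_id}")
            payload = "".join(out[lo:hi] for lo, hi in windows)
        else:
            raise ValueError(f"unknown removal mode {kind!r}")
        if scan(out, consensus):
            raise RuntimeError(f"{kind} left a {consensus} occurrence in {fragment_id}")
        return Derivative(f"{fragment_id}:{kind}", fragment_id, kind,
                          tuple(starts), payload, out)

    if mode is not None:
        return _build(mode)
    return {m: _build(m) for m in REMOVAL_MODES}


def deep_scan(
    fragment_id: str,
    sequence: str,
    window_len: int = 10,
    mutable_region: tuple[int, int] | None = None,
) -> list[Derivative]:
    """Enumerate the saturation series over the mutable region.

    (L - window_len + 1) sliding-window deletions, 3L single-base
    substitutions and L single-base deletions: 5L - 9 derivatives at the
    default window length, duplicates not collapsed.
    """
    lo, hi = mutable_region if mutable_region is not None else (0, len(sequence))
    region = sequence[lo:hi]
    L = len(region)
    if L < window_len:
        raise ValueError(f"mutable region length {L} < window length {window_len}")
    derivs: list[Derivative] = []

    def _emit(kind: str, pos: int, payload: str, new_region: str) -> None:
        derivs.append(Derivative(
            f"{fragment_id}:{kind}:{pos}" + (f":{payload}" if payload else ""),
            fragment_id, kind, (lo + pos,), payload,
            sequence[:lo] + new_region + sequence[hi:]))

    for i in range(L - window_len + 1):
        _emit("del10", i, "", region[:i] + region[i + window_len:])
    for i in range(L):
        for alt in "ACGT":
            if alt != region[i]:
                _emit("sub1", i, alt, region[:i] + alt + region[i + 1:])
    for i in range(L):
        _emit("del1", i, "", region[:i] + region[i + 1:])
    return derivs


def add_motifs(
    fragment_id: str,
    sequence: str,
    motif_instance: str,
    n_copies: int | range = range(1, 9),
    motif: IUPACMotif | str = "YVGATCBR",
    max_dither: int = 12,
) -> list[Derivative]:
    """Substitute 1..n motif copies at evenly spaced positions.

    Length is preserved (8-bp windows are overwritten, not inserted);
    placements avoid existing motif occurrences, and each derivative is
    re-scanned to confirm it carries exactly (original + k) occurrences —
    positions are dithered a few bases if a substitution would collide with
    or accidentally create an occurrence.
    """
    consensus = motif.consensus if isinstance(motif, IUPACMotif) else motif
    if motif_instance not in IUPACMotif(consensus).expansion:
        raise ValueError(f"{motif_instance} is not an expansion of {consensus}")
    width = len(motif_instance)
    base_count = len(scan(sequence, consensus))
    occupied = _merge_windows(scan(sequence, consensus), width)
    copies = [n_copies] if isinstance(n_copies, int) else list(n_copies)
    out: list[Derivative] = []
    for k in copies:
        if k * width > len(sequence):
            raise ValueError(f"cannot host {k} copies of {width} bp in {len(sequence)} bp")
        for dither in range(max_dither + 1):
            slots = []
            ok = True
            for j in range(k):
                s = round((j + 1) * (len(sequence) - width) / (k + 1)) + dither
                s = min(max(s, 0), len(sequence) - width)
                if any(s < hi and lo < s + width for lo, hi in occupied) or \
                   any(abs(s - t) < width for t in slots):
                    ok = False
                    break
                slots.append(s)
            if not ok:
                continue
            chars = list(sequence)
            for s in slots:
                chars[s:s + width] = motif_instance
            derived = "".join(chars)
            if len(scan(derived, consensus)) == base_count + k:
                out.append(Derivative(f"{fragment_id}:add{k}", fragment_id,
                                      "add_motifs", tuple(slots), str(k), derived))
                break
        else:
            raise ValueError(f"no valid placement for {k} copies in {fragment_id}")
    return out


def paired_effect(
    parent_activity: pd.Series,
    derivatives: list[Derivative],
    derivative_activity: pd.Series,
    group_by: str = "op_kind",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Activity deltas of derivatives vs their parents, with group summaries.

    delta = activity(derivative) - activity(parent).  ``group_by`` is
    ``op_kind`` (removal/scan kinds), ``position`` (per-position deep-scan
    track) or ``copies`` (addition series).  Unmatched derivatives are
    skipped with a warning.  Returns (per-derivative table, summary with
    mean/sd/n per group).
    """
    rows = []
    for d in derivatives:
        if d.derivative_id not in derivative_activity.index or \
           d.parent_fragment_id not in parent_activity.index:
            logger.warning("derivative %s unmatched; skipped", d.derivative_id)
            continue
        rows.append({
            "derivative_id": d.derivative_id,
            "parent_fragment_id": d.parent_fragment_id,
            "op_kind": d.op_kind,
            "position": d.positions[0] if d.positions else -1,
            "copies": int(d.payload) if d.op_kind == "add_motifs" else len(d.positions),
            "delta": float(derivative_activity[d.derivative_id]
                           - parent_activity[d.parent_fragment_id]),
        })
    per_derivative = pd.DataFrame(
        rows, columns=["derivative_id", "parent_fragment_id", "op_kind",
                       "position", "copies", "delta"])
    if per_derivative.empty:
        summary = pd.DataFrame(columns=["mean", "sd", "n"])
    else:
        g = per_derivative.groupby(group_by)["delta"]
        summary = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()})
    return per_derivative, summary
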