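"""Degenerate (IUPAC) consensus motifs: construction, expansion and scanning.

The central object is the 8-bp consensus YVGATCBR (Y = C/T, V = A/C/G,
B = C/G/T, R = A/G), built by aligning the activity-associated 6-mers on
their shared GATC core.  Scanning is as-written-strand only and counts
overlapping matches; for reverse-complement-closed consensi such as
YVGATCBR and GATC this loses no occurrences.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import pandas as pd

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# base-set -> minimal IUPAC code
_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

DEFAULT_CONSENSUS = "YVGATCBR"


def revcomp_seq(seq: str) -> str:
    """Reverse complement of a plain or IUPAC-degenerate sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IUPACMotif:
    """A degenerate consensus with its concrete expansion set."""

    consensus: str
    expansion: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        bad = [c for c in self.consensus if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC character(s) {bad!r} in {self.consensus!r}")
        if not self.consensus:
            raise ValueError("empty consensus")
        object.__setattr__(self, "expansion", frozenset(expand(self.consensus)))

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def degeneracy(self) -> int:
        return len(self.expansion)


def expand(motif: IUPACMotif | str) -> set[str]:
    """All concrete sequences matching the consensus (Cartesian product)."""
    consensus = motif.consensus if isinstance(motif, IUPACMotif) else motif
    if not consensus:
        raise ValueError("empty consensus")
    alphabets = []
    for c in consensus:
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC character {c!r}")
        alphabets.append(sorted(IUPAC[c]))
    return {"".join(p) for p in itertools.product(*alphabets)}


def revcomp(motif: IUPACMotif | str) -> IUPACMotif:
    """Reverse-complement a degenerate motif via the IUPAC complement table."""
    consensus = motif.consensus if isinstance(motif, IUPACMotif) else motif
    return IUPACMotif(revcomp_seq(consensus))


def build_consensus(kmers: list[str], core: str, width: int) -> IUPACMotif:
    """Combine k-mers sharing a literal core into one degenerate consensus.

    K-mers are aligned on the (unique) core occurrence; at each aligned
    position the consensus code is the minimal IUPAC code covering the union
    of observed bases.  Positions covered by no k-mer are N; the core stays
    literal.  If ``width`` exceeds the aligned span the consensus is padded
    with N on the right.
    """
    if not kmers:
        raise ValueError("no k-mers given")
    offsets = []
    for km in kmers:
        n = km.count(core)
        if n != 1:
            raise ValueError(f"k-mer {km!r} must contain core {core!r} exactly once (found {n})")
        offsets.append(km.index(core))
    left = max(offsets)
    right = max(len(km) - o - len(core) for km, o in zip(kmers, offsets))
    span = left + len(core) + right
    if width < span:
        raise ValueError(f"width {width} smaller than aligned span {span}")
    sets: list[set[str]] = [set() for _ in range(span)]
    for km, o in zip(kmers, offsets):
        start = left - o
        for i, base in enumerate(km):
            sets[start + i].add(base)
    codes = []
    for i, s in enumerate(sets):
        if left <= i < left + len(core):
            codes.append(core[i - left])
        elif not s:
            codes.append("N")
        else:
            codes.append(_SET_TO_CODE[frozenset(s)])
    codes.extend("N" * (width - span))
    return IUPACMotif("".join(codes))


def _pattern(consensus: str) -> re.Pattern[str]:
    # character classes over ACGT only, so N in the subject never matches
    parts = []
    for c in consensus:
        bases = "".join(sorted(IUPAC[c]))
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile(r"(?=" + "".join(parts) + r")")  # lookahead: overlaps allowed


def scan(sequence: str, motif: IUPACMotif | str) -> list[int]:
    """0-based start positions of all (overlapping) matches, as-written strand."""
    consensus = motif.consensus if isinstance(motif, IUPACMotif) else motif
    if any(c not in IUPAC for c in consensus):
        raise ValueError(f"invalid consensus {consensus!r}")
    return [m.start() for m in _pattern(consensus).finditer(sequence.upper())]


def count_in_window(
    genome: dict[str, str],
    tss_annotation: pd.DataFrame,
    motif: IUPACMotif | str = DEFAULT_CONSENSUS,
    window: tuple[int, int] = (1, 500),
) -> pd.Series:
    """Per-gene motif occurrence count in a strand-oriented TSS-relative window.

    ``tss_annotation`` needs columns gene_id, chrom, tss_pos, strand.  The
    window is inclusive on both ends in TSS-relative coordinates (default
    [+1, +500], excluding the TSS base itself); an occurrence is in the
    window iff its start offset lies in it.  Minus-strand genes are scanned
    on the reverse complement; windows are truncated at chromosome ends.
    """
    consensus = motif.consensus if isinstance(motif, IUPACMotif) else motif
    lo, hi = window
    mlen = len(consensus)
    counts: dict[str, int] = {}
    for row in tss_annotation.itertuples(index=False):
        if row.chrom not in genome:
            raise KeyError(f"gene {row.gene_id}: chromosome {row.chrom!r} not in genome")
        chrom_seq = genome[row.chrom]
        # oriented slice covering offsets lo .. hi+mlen-1 so matches starting at hi fit
        oriented = oriented_slice(chrom_seq, row.tss_pos, row.strand, lo, hi + mlen - 1)
        starts = scan(oriented, consensus)
        counts[row.gene_id] = sum(1 for s in starts if s <= hi - lo)
    out = pd.Series(counts, name="motif_count")
    out.index.name = "gene_id"
    return out


def oriented_slice(chrom_seq: str, tss_pos: int, strand: str, lo: int, hi: int) -> str:
    """Sequence at TSS-relative offsets [lo, hi] along the transcribed strand.

    Offset 0 is the TSS base; positive offsets run in the direction of
    transcription.  Out-of-chromosome positions are truncated.
    """
    n = len(chrom_seq)
    if strand == "+":
        start, stop = tss_pos + lo, tss_pos + hi + 1
        return chrom_seq[max(0, start):max(0, min(n, stop))]
    if strand == "-":
        start, stop = tss_pos - hi, tss_pos - lo + 1
        return revcomp_seq(chrom_seq[max(0, start):max(0, min(n, stop))])
    raise ValueError(f"bad strand {strand!r}")
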