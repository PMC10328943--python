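"""In-silico restriction digestion and the capturable-CpG background.

Reduced-representation bisulfite sequencing only observes CpGs close to the
restriction sites of the digesting enzyme (MspI by default, cutting C^CGG).
Representation tests for differentially methylated cytosines must therefore
be run against the set of CpGs the protocol could have captured, not the
whole genome.  This module enumerates that background: find every motif
occurrence, take ``flank`` bp on both sides of each cleavage point, merge
overlapping windows, and collect the CpG positions inside.

Because CCGG is its own reverse complement, + and − strand sites coincide
and the digest is applied to the + strand only.  CpG positions are keyed by
the + strand C of the CG dinucleotide throughout; a CG whose C lies inside a
window is counted even when its G falls just outside the window edge.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .types import GenomeSequence


@dataclass(frozen=True)
class CutSite:
    """One cleavage point: the 0-based position between motif offset-1 and offset."""

    contig: str
    cut_pos: int


@dataclass
class BackgroundCpGSet:
    """Digest-capturable CpG cytosine positions, the urn for representation tests."""

    positions: set[tuple[str, int]] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.positions)

    def sorted_positions(self) -> list[tuple[str, int]]:
        return sorted(self.positions)


def find_cut_sites(seq: GenomeSequence, motif: str = "CCGG", cut_offset: int = 1) -> list[CutSite]:
    """Locate every motif occurrence (including overlapping ones) and return
    the cleavage points at ``occurrence_start + cut_offset``."""
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} must be over {{A,C,G,T}}")
    if not (0 <= cut_offset <= len(motif)):
        raise ValueError(f"cut_offset {cut_offset} outside [0, {len(motif)}]")
    sites = []
    s = seq.sequence
    start = s.find(motif)
    while start != -1:
        sites.append(CutSite(seq.contig_name, start + cut_offset))
        start = s.find(motif, start + 1)  # step 1 so overlapping occurrences count
    return sites


def collect_windows(
    cuts: Sequence[CutSite], flank: int = 100, contig_len: int | None = None
) -> list[tuple[int, int]]:
    """Per cut site, the interval [cut − flank, cut + flank) clipped to the
    contig; overlapping or touching windows are merged so downstream CpG
    enumeration counts each position once."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    raw = []
    for c in cuts:
        lo = max(0, c.cut_pos - flank)
        hi = c.cut_pos + flank
        if contig_len is not None:
            hi = min(hi, contig_len)
        if lo < hi:
            raw.append((lo, hi))
    raw.sort()
    merged: list[list[int]] = []
    for lo, hi in raw:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def enumerate_background_cpgs(
    genome: Iterable[GenomeSequence],
    windows: Mapping[str, Sequence[tuple[int, int]]],
) -> BackgroundCpGSet:
    """Collect CpG cytosine positions inside the digest windows.

    A position p qualifies when genome[p] == 'C', genome[p+1] == 'G' and p is
    inside a window; N bases never match.  Windows are assumed merged, so the
    result is deduplicated by construction.
    """
    background = BackgroundCpGSet()
    for seq in genome:
        s = seq.sequence
        n = len(s)
        for lo, hi in windows.get(seq.contig_name, ()):
            for p in range(lo, min(hi, n - 1)):
                if s[p] == "C" and s[p + 1] == "G":
                    background.positions.add((seq.contig_name, p))
    return background


def digest_genome(
    genome: Iterable[GenomeSequence],
    motif: str = "CCGG",
    cut_offset: int = 1,
    flank: int = 100,
) -> BackgroundCpGSet:
    """Convenience: cut sites → merged windows → background CpGs, per contig."""
    genome = list(genome)
    windows = {
        seq.contig_name: collect_windows(
            find_cut_sites(seq, motif, cut_offset), flank, len(seq)
        )
        for seq in genome
    }
    return enumerate_background_cpgs(genome, windows)


def background_feature_distribution(background: BackgroundCpGSet, annot_index) -> Counter:
    """Assign each background CpG exactly one feature label; counts sum to the
    background size."""
    counts: Counter = Counter()
    for contig, pos in background.sorted_positions():
        label, _gene = annot_index.annotate_position(contig, pos)
        counts[label] += 1
    return counts
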