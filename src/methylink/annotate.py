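"""Single-label genomic feature annotation with promoter / gene-body windows.

Definitions (strand-aware, all 0-based half-open on the genomic axis):

* promoter — the 2000 bp immediately upstream of the TSS, excluding the TSS
  base itself (set ``include_tss`` to include it);
* gene body — TSS through TTS (exons and the introns between them);
* TTS region — the 1000 bp immediately downstream of the TTS;
* intergenic — everything else.

Every position receives exactly one label through the fixed precedence
promoter > exon > intron > tts_region > intergenic.  When several genes
claim a position at the same precedence level, the gene with the nearest
TSS wins, then lexicographic gene id — the assignment is deterministic.

For expression–methylation pairing, :meth:`AnnotationIndex.assign_dmc_region`
collapses labels to {promoter, gene_body, other}, where the gene body spans
TSS to 1000 bp past the TTS (the downstream tail can be switched off).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .types import GeneModel


class FeatureLabel(str, enum.Enum):
    PROMOTER = "promoter"
    EXON = "exon"
    INTRON = "intron"
    TTS_REGION = "tts_region"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # keep TSV output plain
        return self.value


_PRECEDENCE = {
    FeatureLabel.PROMOTER: 0,
    FeatureLabel.EXON: 1,
    FeatureLabel.INTRON: 2,
    FeatureLabel.TTS_REGION: 3,
}


@dataclass
class _GeneWindows:
    gene_id: str
    tss: int
    promoter: tuple[int, int] | None
    body: tuple[int, int]           # TSS..TTS span on the genomic axis
    body_with_tail: tuple[int, int]  # body extended 1000 bp past the TTS


class AnnotationIndex:
    """Interval index over gene-derived feature windows on each contig."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        promoter_up: int = 2000,
        tts_down: int = 1000,
        include_tss: bool = False,
        contig_lengths: Mapping[str, int] | None = None,
    ) -> None:
        self.promoter_up = promoter_up
        self.tts_down = tts_down
        self.include_tss = include_tss
        self._trees: dict[str, IntervalTree] = {}
        self._region_trees: dict[str, IntervalTree] = {}
        self._contig_lengths = dict(contig_lengths) if contig_lengths is not None else None
        if self._contig_lengths is not None:
            self._known = set(self._contig_lengths)
        else:
            self._known = {g.contig for g in genes}

        for g in genes:
            if self._contig_lengths is not None and g.contig not in self._contig_lengths:
                raise KeyError(f"gene {g.gene_id} on unknown contig {g.contig!r}")
            clen = None if self._contig_lengths is None else self._contig_lengths[g.contig]
            w = self._windows(g, clen)
            tree = self._trees.setdefault(g.contig, IntervalTree())
            rtree = self._region_trees.setdefault(g.contig, IntervalTree())
            if w.promoter is not None:
                tree.addi(*w.promoter, (FeatureLabel.PROMOTER, g.gene_id, w.tss))
                rtree.addi(*w.promoter, ("promoter", g.gene_id, w.tss))
            for s, e in g.exons:
                tree.addi(s, e, (FeatureLabel.EXON, g.gene_id, w.tss))
            for s, e in _gaps(g.start, g.end, g.exons):
                tree.addi(s, e, (FeatureLabel.INTRON, g.gene_id, w.tss))
            tts_iv = self._tts_interval(g, clen)
            if tts_iv is not None:
                tree.addi(*tts_iv, (FeatureLabel.TTS_REGION, g.gene_id, w.tss))
            rtree.addi(*w.body_with_tail, ("gene_body", g.gene_id, w.tss))
            rtree.addi(*w.body, ("gene_body_core", g.gene_id, w.tss))

    # -- window construction -------------------------------------------------

    def _windows(self, g: GeneModel, clen: int | None) -> _GeneWindows:
        shift = 1 if self.include_tss else 0
        if g.strand == "+":
            prom = (g.start - self.promoter_up, g.start + shift)
            tail = (g.start, min(g.end + self.tts_down, clen) if clen else g.end + self.tts_down)
            body = (g.start, g.end)
        else:
            prom = (g.end - shift, g.end + self.promoter_up)
            tail = (max(0, g.start - self.tts_down), g.end)
            body = (g.start, g.end)
        lo = max(0, prom[0])
        hi = prom[1] if clen is None else min(prom[1], clen)
        promoter = (lo, hi) if lo < hi else None
        return _GeneWindows(g.gene_id, g.tss, promoter, body, tail)

    def _tts_interval(self, g: GeneModel, clen: int | None) -> tuple[int, int] | None:
        if g.strand == "+":
            lo, hi = g.end, g.end + self.tts_down
        else:
            lo, hi = g.start - self.tts_down, g.start
        lo = max(0, lo)
        if clen is not None:
            hi = min(hi, clen)
        return (lo, hi) if lo < hi else None

    # -- queries -------------------------------------------------------------

    def _check_contig(self, contig: str) -> None:
        if contig not in self._known:
            raise KeyError(f"unknown contig {contig!r}")

    def annotate_position(self, contig: str, pos: int) -> tuple[FeatureLabel, str | None]:
        """Exactly one feature label per position, ties broken deterministically."""
        self._check_contig(contig)
        tree = self._trees.get(contig)
        hits = tree[pos] if tree is not None else ()
        best = None
        for iv in hits:
            label, gene_id, tss = iv.data
            key = (_PRECEDENCE[label], abs(pos - tss), gene_id)
            if best is None or key < best[0]:
                best = (key, label, gene_id)
        if best is None:
            return (FeatureLabel.INTERGENIC, None)
        return (best[1], best[2])

    def assign_dmc_region(
        self, contig: str, pos: int, body_includes_tail: bool = True
    ) -> tuple[str, str | None]:
        """Collapse to {promoter, gene_body, other} for expression pairing.

        Promoter wins over gene body; within a category the nearest TSS wins.
        """
        self._check_contig(contig)
        tree = self._region_trees.get(contig)
        hits = tree[pos] if tree is not None else ()
        body_kind = "gene_body" if body_includes_tail else "gene_body_core"
        best_prom = best_body = None
        for iv in hits:
            kind, gene_id, tss = iv.data
            key = (abs(pos - tss), gene_id)
            if kind == "promoter" and (best_prom is None or key < best_prom[0]):
                best_prom = (key, gene_id)
            elif kind == body_kind and (best_body is None or key < best_body[0]):
                best_body = (key, gene_id)
        if best_prom is not None:
            return ("promoter", best_prom[1])
        if best_body is not None:
            return ("gene_body", best_body[1])
        return ("other", None)


def _gaps(start: int, end: int, exons: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intron intervals: the gene span minus its exons."""
    out = []
    cursor = start
    for s, e in exons:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < end:
        out.append((cursor, end))
    return out


def build_index(
    genes: Sequence[GeneModel],
    promoter_up: int = 2000,
    tts_down: int = 1000,
    include_tss: bool = False,
    contig_lengths: Mapping[str, int] | None = None,
) -> AnnotationIndex:
    """Build the feature index from gene models (promoter 2 kb, TTS tail 1 kb)."""
    return AnnotationIndex(genes, promoter_up, tts_down, include_tss, contig_lengths)
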