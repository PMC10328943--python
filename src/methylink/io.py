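"""Readers and writers for the standard formats the pipeline touches.

Conventions enforced here, once, at the boundary:

* FASTA sequences are uppercased; the alphabet is {A,C,G,T,N}.
* GTF coordinates (1-based inclusive) become internal 0-based half-open.
* Bismark-style coverage positions (1-based) become 0-based; the percent
  column is ignored in favour of the counts.
* BED is 0-based half-open and passes through unchanged.

All readers accept gzip-compressed files (by ``.gz`` suffix or magic bytes).
"""

from __future__ import annotations

import gzip
import logging
import shutil
import tempfile
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    CountMatrix,
    FormatError,
    GeneModel,
    GeneSetCollection,
    GenomeSequence,
)

log = logging.getLogger(__name__)


def _is_gzip(path: str | Path) -> bool:
    path = Path(path)
    if path.suffix == ".gz":
        return True
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def _open_text(path: str | Path):
    if _is_gzip(path):
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _prescan_fasta(path: str | Path) -> None:
    """Light pass over the raw lines so format errors can name a line number."""
    seen: dict[str, int] = {}
    header_line = None
    has_seq = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if header_line is not None and not has_seq:
                    raise FormatError(f"{path}: empty sequence for header at line {header_line}")
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FormatError(f"{path}: malformed FASTA header at line {lineno}")
                if name in seen:
                    raise FormatError(
                        f"{path}: duplicate FASTA header {name!r} at line {lineno} "
                        f"(first seen at line {seen[name]})"
                    )
                seen[name] = lineno
                header_line = lineno
                has_seq = False
            else:
                if header_line is None:
                    raise FormatError(f"{path}: sequence before any header at line {lineno}")
                has_seq = True
    if header_line is not None and not has_seq:
        raise FormatError(f"{path}: empty sequence for header at line {header_line}")
    if header_line is None:
        raise FormatError(f"{path}: no FASTA records found")


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (possibly gzipped) FASTA file into :class:`GenomeSequence` records.

    Sequences are uppercased (soft-masked lowercase bases are folded to their
    uppercase counterparts).
    """
    _prescan_fasta(path)
    records = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            records.append(GenomeSequence(rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.contig_name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path, strict: bool = True) -> list[GeneModel]:
    """Read gene and exon features from a GTF file into :class:`GeneModel` s.

    GTF is 1-based inclusive; output coordinates are 0-based half-open.
    Genes without exon children get a single exon covering the whole span.
    Overlapping exons within one gene raise when ``strict`` is true and are
    merged otherwise.
    """
    src = Path(path)
    tmp = None
    if _is_gzip(src):
        tmp = tempfile.NamedTemporaryFile(suffix=".gtf", delete=False)
        with gzip.open(src, "rb") as fin:
            shutil.copyfileobj(fin, tmp)
        tmp.close()
        src = Path(tmp.name)
    try:
        db = gffutils.create_db(
            str(src),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
        genes: list[GeneModel] = []
        for g in db.features_of_type("gene"):
            if g.strand not in ("+", "-"):
                raise FormatError(f"{path}: gene {g.id}: unknown strand {g.strand!r}")
            start, end = g.start - 1, g.end  # 1-based inclusive -> 0-based half-open
            exons = sorted(
                (e.start - 1, e.end)
                for e in db.children(g, featuretype="exon")
            )
            for s, e in exons:
                if not (start <= s < e <= end):
                    raise FormatError(f"{path}: gene {g.id}: exon [{s},{e}) outside gene span")
            merged: list[list[int]] = []
            for s, e in exons:
                if merged and s < merged[-1][1]:
                    if strict:
                        raise FormatError(f"{path}: gene {g.id}: overlapping exons")
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            if not merged:
                merged = [[start, end]]
            genes.append(
                GeneModel(
                    gene_id=g.id,
                    contig=g.seqid,
                    strand=g.strand,
                    start=start,
                    end=end,
                    exons=tuple((s, e) for s, e in merged),
                )
            )
        return genes
    finally:
        if tmp is not None:
            Path(tmp.name).unlink(missing_ok=True)


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "methylink") -> None:
    """Write gene models as GTF2.2 (1-based inclusive coordinates)."""
    with open(path, "wt") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.contig}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Bismark-style coverage
# ---------------------------------------------------------------------------

_COV_COLS = ["contig", "start", "end", "percent_meth", "n_meth", "n_unmeth"]


def read_meth_coverage(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read one sample's Bismark-coverage-dialect TSV.

    Columns: contig, start (1-based), end, percent methylation, methylated
    count, unmethylated count.  Returns a long-format frame with 0-based
    positions; the percent column is checked against the counts (0.5 %
    tolerance) and then discarded.
    """
    df = pd.read_csv(_open_text(path), sep="\t", header=None, names=_COV_COLS,
                     dtype={"contig": str})
    if df[["n_meth", "n_unmeth"]].lt(0).to_numpy().any():
        raise FormatError(f"{path}: negative methylation counts")
    total = df["n_meth"] + df["n_unmeth"]
    covered = total > 0
    pct = df.loc[covered, "n_meth"] / total[covered] * 100.0
    off = (pct - df.loc[covered, "percent_meth"]).abs() > 0.5
    if off.any():
        warnings.warn(
            f"{path}: {int(off.sum())} rows with percent column inconsistent with "
            "counts beyond 0.5% tolerance; counts take precedence"
        )
    n_zero = int((~covered).sum())
    if n_zero:
        log.info("%s: %d zero-coverage rows retained", path, n_zero)
    out = pd.DataFrame(
        {
            "contig": df["contig"],
            "pos": df["start"].astype(int) - 1,  # 1-based -> 0-based
            "sample_id": sample_id,
            "n_meth": df["n_meth"].astype(int),
            "n_unmeth": df["n_unmeth"].astype(int),
        }
    )
    return out


def write_meth_coverage(records: pd.DataFrame, path: str | Path) -> None:
    """Write one sample's long-format records back to the coverage dialect."""
    total = (records["n_meth"] + records["n_unmeth"]).to_numpy()
    with pd.option_context("mode.chained_assignment", None):
        pct = pd.Series(0.0, index=records.index)
        nz = total > 0
        pct[nz] = records["n_meth"][nz] / total[nz] * 100.0
    out = pd.DataFrame(
        {
            "contig": records["contig"],
            "start": records["pos"] + 1,
            "end": records["pos"] + 1,
            "percent_meth": pct.round(6),
            "n_meth": records["n_meth"],
            "n_unmeth": records["n_unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GMT / BED / counts TSV / group table
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT rows need >=3 columns")
            set_id, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}: line {lineno}: gene set {set_id!r} has no members")
            if set_id in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set id {set_id!r}")
            sets[set_id] = (desc, frozenset(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for set_id, (desc, members) in collection:
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED intervals (0-based half-open) as (contig, start, end, name)."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: BED rows need >=3 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0 or end < start:
                raise FormatError(f"{path}: line {lineno}: invalid interval")
            name = parts[3] if len(parts) > 3 else "."
            out.append((contig, start, end, name))
    return out


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (contig, start, end[, name]) tuples as BED."""
    with open(path, "wt") as fh:
        for iv in intervals:
            contig, start, end = iv[0], iv[1], iv[2]
            name = iv[3] if len(iv) > 3 else "."
            fh.write(f"{contig}\t{start}\t{end}\t{name}\n")


def read_counts(path: str | Path, group_of: Mapping[str, str]) -> CountMatrix:
    """Read a TSV count matrix (first column gene ids, header row sample ids)."""
    df = pd.read_csv(_open_text(path), sep="\t", index_col=0)
    if df.isna().to_numpy().any():
        raise FormatError(f"{path}: ragged rows or missing values in count matrix")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise FormatError(f"{path}: non-integer counts")
        df = df.astype(int)
    return CountMatrix(df, dict(group_of))


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_group_table(path: str | Path) -> dict[str, str]:
    """Read a two-column sample→group TSV (no header)."""
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected two columns")
            sample, group = parts
            if sample in out:
                raise FormatError(f"{path}: line {lineno}: duplicate sample {sample!r}")
            out[sample] = group
    return out


def read_ortholog_table(path: str | Path) -> dict[str, str]:
    """Read a two-column source→target ortholog mapping TSV (no header)."""
    return read_group_table(path)
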