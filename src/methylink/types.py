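"""Core in-memory containers shared across the pipeline.

All genomic coordinates held by these types are 0-based half-open on the
forward strand of the reference.  Conversions from 1-based external formats
(GTF, Bismark coverage) happen at the I/O boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DNA_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GenomeSequence:
    """One reference contig: a name and an uppercase DNA string over {A,C,G,T,N}."""

    contig_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"contig {self.contig_name!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"contig {self.contig_name!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """One gene's strand-aware coordinates.

    ``start``/``end`` delimit the gene span as a 0-based half-open interval;
    ``exons`` are disjoint sub-intervals of the span sorted by start.  The
    transcription start site (TSS) is ``start`` on the + strand and ``end - 1``
    on the − strand; the termination site (TTS) is the opposite extremity.
    """

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(f"gene {self.gene_id}: invalid span [{self.start},{self.end})")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise FormatError(f"gene {self.gene_id}: exon [{s},{e}) outside gene span")
            if prev_end is not None and s < prev_end:
                raise FormatError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def _check_groups(sample_ids: Sequence[str], group_of: Mapping[str, str]) -> dict[str, str]:
    missing = [s for s in sample_ids if s not in group_of]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    return {s: group_of[s] for s in sample_ids}


@dataclass
class CountMatrix:
    """Gene-level integer counts (genes × samples) plus a sample→group map."""

    counts: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        self.group_of = _check_groups(list(self.counts.columns), self.group_of)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]

    def drop_samples(self, samples: Sequence[str]) -> "CountMatrix":
        keep = [s for s in self.sample_ids if s not in set(samples)]
        return CountMatrix(self.counts[keep].copy(), {s: self.group_of[s] for s in keep})

    def cpm(self) -> pd.DataFrame:
        """Counts per million using raw library sizes."""
        lib = self.counts.sum(axis=0).astype(float)
        return self.counts.div(lib, axis=1) * 1e6


#: columns of the long-format methylation count table
METH_COLUMNS = ("contig", "pos", "sample_id", "n_meth", "n_unmeth")


@dataclass
class MethCountTable:
    """Per-sample per-CpG methylated/unmethylated read counts (long format).

    ``pos`` is the 0-based position of the CpG cytosine on the + strand.
    """

    records: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(METH_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"methylation table missing columns: {sorted(missing)}")
        rec = self.records
        if (rec["n_meth"] < 0).any() or (rec["n_unmeth"] < 0).any():
            raise ValueError("negative methylation counts")
        if rec.duplicated(subset=["contig", "pos", "sample_id"]).any():
            raise ValueError("duplicate (contig, pos, sample) records")
        self.group_of = _check_groups(sorted(rec["sample_id"].unique()), self.group_of)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): set id → (description, member ids)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {set_id!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]
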