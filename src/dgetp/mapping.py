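"""Exact mapping of 20-mer tags to a genome.

The assay produces genomic-contiguous tags, so mapping is exact substring
search on both strands — no gaps, no mismatches.  A tag is kept only when
it has exactly one match over the whole genome, counting (position,
strand) pairs; anything matching twice (including a perfect-palindrome
tag that matches the same window on both strands) is discarded as
``multi``.  Tags containing non-ACGT symbols are never searched
(``ambiguous_base``), and genome windows containing N are never indexed.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Literal, Mapping

import pandas as pd
from Bio.Seq import reverse_complement

from .counting import TagCountTable
from .digestion import TAG_LENGTH

logger = logging.getLogger(__name__)

GenomeSequence = Mapping[str, str]

MapStatus = Literal["unique", "multi", "unmapped", "ambiguous_base"]

_VALID = frozenset("ACGT")


@dataclass
class MappedTag:
    """A tag with its mapping outcome and per-library counts.

    For ``unique`` tags, ``start`` is the leftmost (0-based) genome
    position of the 20-mer window regardless of strand; ``strand`` records
    which strand carries the tag in sense orientation.
    """

    tag: str
    status: MapStatus
    counts: dict[str, int] = field(default_factory=dict)
    supercontig: str | None = None
    start: int | None = None
    strand: str | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def end(self) -> int:
        """0-based exclusive end of the window (unique tags only)."""
        if self.start is None:
            raise ValueError("tag is not uniquely mapped")
        return self.start + TAG_LENGTH


class GenomeIndex:
    """Hash index of every clean 20-mer window of the forward strand.

    Occurrences on the minus strand are found by looking up the reverse
    complement of the query, so only forward windows are stored.
    """

    def __init__(self, genome: GenomeSequence):
        if not genome:
            raise ValueError("empty genome")
        for name, seq in genome.items():
            if not seq:
                raise ValueError(f"supercontig {name!r} has empty sequence")
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        self.contig_lengths = {name: len(seq) for name, seq in genome.items()}
        for name, seq in genome.items():
            seq = seq.upper()
            for i in range(len(seq) - TAG_LENGTH + 1):
                window = seq[i : i + TAG_LENGTH]
                if set(window) <= _VALID:
                    self._index[window].append((name, i))

    def occurrences(self, tag: str) -> list[tuple[str, int, str]]:
        """All (supercontig, start, strand) exact matches of ``tag``."""
        hits = [(c, p, "+") for c, p in self._index.get(tag, ())]
        hits += [(c, p, "-") for c, p in self._index.get(reverse_complement(tag), ())]
        return hits


def build_index(genome: GenomeSequence) -> GenomeIndex:
    return GenomeIndex(genome)


def map_all(table: TagCountTable, index: GenomeIndex) -> list[MappedTag]:
    """Classify every tag of the table against the genome index.

    Status is exhaustive and mutually exclusive: ``ambiguous_base`` (tag
    has a non-ACGT symbol), ``unmapped`` (no exact match), ``unique``
    (exactly one (position, strand) match) or ``multi``.  Only unique
    tags flow into clustering and gene assignment.
    """
    out: list[MappedTag] = []
    status_counts: dict[str, int] = defaultdict(int)
    for tag, row in table.counts.iterrows():
        counts = {lib: int(v) for lib, v in row.items()}
        if not set(tag) <= _VALID:
            mt = MappedTag(tag=tag, status="ambiguous_base", counts=counts)
        else:
            hits = index.occurrences(tag)
            if len(hits) == 0:
                mt = MappedTag(tag=tag, status="unmapped", counts=counts)
            elif len(hits) == 1:
                contig, start, strand = hits[0]
                mt = MappedTag(
                    tag=tag, status="unique", counts=counts,
                    supercontig=contig, start=start, strand=strand,
                )
            else:
                mt = MappedTag(tag=tag, status="multi", counts=counts)
        status_counts[mt.status] += 1
        out.append(mt)
    logger.info("mapping: %s", dict(status_counts))
    return out


def unique_tags(mapped: list[MappedTag]) -> list[MappedTag]:
    return [m for m in mapped if m.status == "unique"]


def scan_with_mismatches(
    genome: GenomeSequence, tag: str, max_mismatches: int = 1
) -> list[tuple[str, int, str, int]]:
    """Diagnostic Hamming-distance scan (not part of the default pipeline).

    Returns (supercontig, start, strand, mismatches) for every window
    within ``max_mismatches`` of the tag on either strand.
    """
    rc = reverse_complement(tag)
    hits = []
    for name, seq in genome.items():
        seq = seq.upper()
        for i in range(len(seq) - TAG_LENGTH + 1):
            window = seq[i : i + TAG_LENGTH]
            for query, strand in ((tag, "+"), (rc, "-")):
                d = sum(a != b for a, b in zip(window, query))
                if d <= max_mismatches:
                    hits.append((name, i, strand, d))
    return hits


def mapped_to_frame(mapped: list[MappedTag], libraries: list[str]) -> pd.DataFrame:
    """Tabular view of mapping results (1-based starts for export)."""
    rows = []
    for m in mapped:
        rows.append({
            "tag": m.tag,
            "status": m.status,
            "supercontig": m.supercontig or ".",
            "start": (m.start + 1) if m.start is not None else 0,
            "strand": m.strand or ".",
            **{lib: m.counts.get(lib, 0) for lib in libraries},
        })
    return pd.DataFrame(rows)


def write_unique_bed(mapped: list[MappedTag], path) -> None:
    """BED6 track of uniquely mapped tags (score = total reads, capped)."""
    with open(path, "w") as fh:
        for m in unique_tags(mapped):
            score = min(m.total, 1000)
            fh.write(
                f"{m.supercontig}\t{m.start}\t{m.end}\t{m.tag}\t{score}\t{m.strand}\n"
            )
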