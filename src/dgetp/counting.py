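"""Tag counting and background filtering.

Reads are fixed-length 20-mers; counting collapses them into a table of
distinct tags x libraries.  Sequencing noise is removed by a background
filter on the *total* read count of a tag across all libraries: singleton
and near-singleton tags are overwhelmingly sequencing errors, so only tags
seen at least ``min_total_reads`` times in the whole experiment are kept.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .digestion import TAG_LENGTH

logger = logging.getLogger(__name__)


@dataclass
class TagCountTable:
    """Distinct tags x libraries matrix of non-negative read counts.

    ``counts`` is indexed by tag sequence (lexicographically sorted,
    unique) with one integer column per library.  ``rejected_reads``
    records, per library, how many input reads were discarded for not
    being 20 nt long.
    """

    counts: pd.DataFrame
    rejected_reads: dict[str, int] = field(default_factory=dict)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tags(self) -> pd.Index:
        return self.counts.index

    @property
    def totals(self) -> pd.Series:
        """Per-library total reads (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def tag_totals(self) -> pd.Series:
        """Per-tag total reads across all libraries."""
        return self.counts.sum(axis=1)

    def __len__(self) -> int:
        return len(self.counts)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.rename_axis("tag").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TagCountTable":
        df = pd.read_csv(path, sep="\t", index_col="tag", dtype={"tag": str})
        df.index = df.index.astype(str)
        return cls(counts=df.astype(int).sort_index())


@dataclass(frozen=True)
class FilterConfig:
    """Background-filter settings.

    ``min_total_reads`` is the threshold on a tag's total reads across all
    libraries (default 20); ``keep_equal`` selects the comparator: True
    keeps tags with total >= threshold, False keeps strictly greater.
    """

    min_total_reads: int = 20
    keep_equal: bool = True

    def __post_init__(self) -> None:
        if self.min_total_reads < 0:
            raise ValueError("min_total_reads must be >= 0")


def count_tags(reads_by_library: Mapping[str, Iterable[str]]) -> TagCountTable:
    """Count distinct 20-mers per library.

    Reads that are not exactly 20 nt are rejected and tallied per library
    in ``rejected_reads`` (and logged).  The output table is sorted by tag
    so the result is deterministic regardless of input order.
    """
    counters: dict[str, Counter] = {}
    rejected: dict[str, int] = {}
    for lib, reads in reads_by_library.items():
        c: Counter = Counter()
        bad = 0
        for r in reads:
            if len(r) != TAG_LENGTH:
                bad += 1
            else:
                c[r] += 1
        counters[lib] = c
        rejected[lib] = bad
        if bad:
            logger.warning("library %s: rejected %d reads of length != %d", lib, bad, TAG_LENGTH)
    df = pd.DataFrame(counters).fillna(0).astype(int)
    if df.empty:
        df = pd.DataFrame(columns=list(reads_by_library), dtype=int)
    df = df.reindex(columns=list(reads_by_library)).fillna(0).astype(int).sort_index()
    return TagCountTable(counts=df, rejected_reads=rejected)


def filter_background(table: TagCountTable, cfg: FilterConfig | None = None) -> TagCountTable:
    """Keep tags whose total reads across libraries clear the threshold.

    Idempotent; library totals downstream are recomputed on the filtered
    table (they are the ``totals`` property of the result).
    """
    cfg = cfg or FilterConfig()
    totals = table.tag_totals
    if cfg.keep_equal:
        keep = totals >= cfg.min_total_reads
    else:
        keep = totals > cfg.min_total_reads
    kept = table.counts.loc[keep]
    logger.info(
        "background filter: kept %d / %d tags (threshold %s%d)",
        len(kept), len(table), ">=" if cfg.keep_equal else ">", cfg.min_total_reads,
    )
    return TagCountTable(counts=kept.copy(), rejected_reads=dict(table.rejected_reads))
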