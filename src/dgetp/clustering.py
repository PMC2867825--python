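"""Clustering of mapped tags into genomic transcription units.

Partial DpnII digestion leaves several tags on one transcript, with read
counts decreasing toward the 5' end.  Tags are therefore chained into a
cluster when, for every consecutive pair in transcription order, (i) both
lie on the same supercontig and strand, (ii) they are separated by less
than ``max_separation`` bp, and (iii) the downstream (3') tag has a
strictly higher all-library read total than the upstream (5') one.
Clusters are the maximal runs under this pairwise predicate; a tag that
chains with nothing forms a singleton cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .digestion import TAG_LENGTH
from .mapping import MappedTag

#: library-count key order is taken from the tags themselves


@dataclass(frozen=True)
class ClusterConfig:
    max_separation: int = 500  # strict: gap must be < this
    require_increasing_3prime: bool = True

    def __post_init__(self) -> None:
        if self.max_separation <= 0:
            raise ValueError("max_separation must be > 0")


@dataclass
class TagCluster:
    """A maximal chain of same-strand tags ordered 5'->3'."""

    cluster_id: str
    supercontig: str
    strand: str
    members: list[MappedTag]
    gene_associated: bool = False

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (leftmost start, rightmost end) over member windows."""
        starts = [m.start for m in self.members]
        return min(starts), max(starts) + TAG_LENGTH

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.members:
            for lib, v in m.counts.items():
                out[lib] = out.get(lib, 0) + v
        return out

    @property
    def total(self) -> int:
        return sum(m.total for m in self.members)


def _gap(upstream: MappedTag, downstream: MappedTag) -> int:
    """Separation between adjacent tags in transcription order.

    Gap between nearest window ends; overlapping windows count as 0.
    """
    if upstream.strand == "+":
        g = downstream.start - upstream.end
    else:
        g = upstream.start - downstream.end
    return max(g, 0)


def chainable(upstream: MappedTag, downstream: MappedTag, cfg: ClusterConfig) -> bool:
    """Pairwise rule for consecutive tags in transcription order."""
    if upstream.supercontig != downstream.supercontig or upstream.strand != downstream.strand:
        return False
    if _gap(upstream, downstream) >= cfg.max_separation:
        return False
    if cfg.require_increasing_3prime and not (downstream.total > upstream.total):
        return False
    return True


def cluster_tags(mapped: Iterable[MappedTag], cfg: ClusterConfig | None = None) -> list[TagCluster]:
    """Partition unique-mapped tags into maximal chains.

    Within each (supercontig, strand) group tags are sorted in
    transcription order (ascending start on +, descending on -) and the
    group is split wherever an adjacent pair violates the chain rule.
    Cluster ids are assigned in (supercontig, leftmost coordinate) order,
    so the result is independent of input order.
    """
    cfg = cfg or ClusterConfig()
    groups: dict[tuple[str, str], list[MappedTag]] = {}
    for m in mapped:
        if m.status != "unique":
            raise ValueError(f"tag {m.tag} is not uniquely mapped")
        groups.setdefault((m.supercontig, m.strand), []).append(m)

    clusters: list[TagCluster] = []
    for (contig, strand), tags in groups.items():
        tags.sort(key=lambda m: m.start, reverse=(strand == "-"))
        run: list[MappedTag] = [tags[0]]
        for prev, cur in zip(tags, tags[1:]):
            if chainable(prev, cur, cfg):
                run.append(cur)
            else:
                clusters.append(TagCluster("", contig, strand, run))
                run = [cur]
        clusters.append(TagCluster("", contig, strand, run))

    clusters.sort(key=lambda c: (c.supercontig, c.span[0], c.strand))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"CL{i:05d}"
    return clusters


def classify_clusters(
    clusters: Iterable[TagCluster], gene_associated_tags: set[str]
) -> list[TagCluster]:
    """Flag clusters containing any gene-assigned (or gene-ambiguous) tag.

    The complementary, non-gene-associated clusters are the additional
    features ("clusters not mapped within predicted genes") carried into
    differential testing alongside genes.
    """
    out = []
    for c in clusters:
        c.gene_associated = any(m.tag in gene_associated_tags for m in c.members)
        out.append(c)
    return out


def cluster_count_matrix(clusters: Iterable[TagCluster], libraries: list[str]) -> pd.DataFrame:
    """Per-cluster, per-library aggregated counts (sorted by cluster id)."""
    rows = {
        c.cluster_id: {lib: c.counts.get(lib, 0) for lib in libraries}
        for c in clusters
    }
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    if df.empty:
        return pd.DataFrame(columns=libraries, dtype=int)
    return df.reindex(columns=libraries).fillna(0).astype(int).sort_index()


def write_cluster_bed(clusters: Iterable[TagCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            lo, hi = c.span
            fh.write(
                f"{c.supercontig}\t{lo}\t{hi}\t{c.cluster_id}\t"
                f"{min(c.total, 1000)}\t{c.strand}\n"
            )
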