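"""Gene models and assignment of mapped tags to genes.

Because the assay anchors tags toward the 3' end of transcripts and 3'
UTR annotation is frequently incomplete, a tag counts as "within" a gene
when its full 20 bp window lies between the gene's 5' boundary and its
3' boundary extended by a fixed distance (default 300 bp) downstream in
the gene's transcription direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .mapping import MappedTag

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """A gene span on a supercontig; coordinates 0-based half-open."""

    gene_id: str
    supercontig: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval for {self.gene_id}: [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AssignmentConfig:
    three_prime_extension: int = 300
    ambiguous_policy: str = "exclude"  # or "assign_all"
    require_same_strand: bool = False

    def __post_init__(self) -> None:
        if self.three_prime_extension < 0:
            raise ValueError("three_prime_extension must be >= 0")
        if self.ambiguous_policy not in ("exclude", "assign_all"):
            raise ValueError(f"unknown ambiguous_policy {self.ambiguous_policy!r}")


def extend_gene_interval(
    gene: GeneModel, cfg: AssignmentConfig, contig_length: int | None = None
) -> tuple[int, int]:
    """The gene span with its 3' boundary pushed downstream.

    On the + strand the 3' end is ``end``; on the - strand it is
    ``start``.  The result is clipped to [0, contig_length).
    """
    if gene.strand == "+":
        lo, hi = gene.start, gene.end + cfg.three_prime_extension
    else:
        lo, hi = gene.start - cfg.three_prime_extension, gene.end
    lo = max(lo, 0)
    if contig_length is not None:
        hi = min(hi, contig_length)
    return lo, hi


@dataclass
class AssignmentResult:
    """Partition of unique tags into gene / ambiguous / unassigned sets."""

    gene_to_tags: dict[str, list[MappedTag]]
    ambiguous: list[tuple[MappedTag, list[str]]]
    unassigned: list[MappedTag]
    config: AssignmentConfig = field(default_factory=AssignmentConfig)

    def tag_gene_map(self) -> dict[str, str]:
        """tag sequence -> gene id for unambiguously assigned tags."""
        return {
            m.tag: g for g, tags in self.gene_to_tags.items() for m in tags
        }

    def gene_associated_tag_set(self) -> set[str]:
        """Tags assigned to, or ambiguous between, genes."""
        s = {m.tag for tags in self.gene_to_tags.values() for m in tags}
        s |= {m.tag for m, _ in self.ambiguous}
        return s


def assign_tags(
    mapped: Iterable[MappedTag],
    genes: Iterable[GeneModel],
    cfg: AssignmentConfig | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> AssignmentResult:
    """Assign uniquely mapped tags to genes by full window containment.

    A tag is within gene g iff its 20 bp window is entirely inside g's
    3'-extended interval on the same supercontig (tag strand is not
    required to match gene strand unless ``require_same_strand``).
    Tags falling in >= 2 genes follow ``ambiguous_policy``: ``exclude``
    (default) keeps them out of per-gene aggregation; ``assign_all``
    credits every covering gene.
    """
    cfg = cfg or AssignmentConfig()
    genes = list(genes)
    by_contig: dict[str, list[tuple[int, int, GeneModel]]] = {}
    for g in genes:
        clen = contig_lengths.get(g.supercontig) if contig_lengths else None
        lo, hi = extend_gene_interval(g, cfg, clen)
        by_contig.setdefault(g.supercontig, []).append((lo, hi, g))

    gene_to_tags: dict[str, list[MappedTag]] = {}
    ambiguous: list[tuple[MappedTag, list[str]]] = []
    unassigned: list[MappedTag] = []
    for m in mapped:
        if m.status != "unique":
            raise ValueError(f"tag {m.tag} is not uniquely mapped (status {m.status})")
        hits = []
        for lo, hi, g in by_contig.get(m.supercontig, ()):
            if lo <= m.start and m.end <= hi:
                if cfg.require_same_strand and m.strand != g.strand:
                    continue
                hits.append(g.gene_id)
        if not hits:
            unassigned.append(m)
        elif len(hits) == 1:
            gene_to_tags.setdefault(hits[0], []).append(m)
        else:
            ambiguous.append((m, sorted(hits)))
            if cfg.ambiguous_policy == "assign_all":
                for gid in hits:
                    gene_to_tags.setdefault(gid, []).append(m)
    if ambiguous:
        logger.info("assignment: %d tags ambiguous between genes (policy=%s)",
                    len(ambiguous), cfg.ambiguous_policy)
    return AssignmentResult(
        gene_to_tags=gene_to_tags, ambiguous=ambiguous,
        unassigned=unassigned, config=cfg,
    )


def aggregate_gene_counts(assignment: AssignmentResult, libraries: list[str]) -> pd.DataFrame:
    """Per-gene count matrix: sum of member-tag counts per library.

    Genes without any assigned tag are absent.  Row order is sorted by
    gene id for determinism.
    """
    rows = {}
    for gid, tags in assignment.gene_to_tags.items():
        if not tags:
            continue
        rows[gid] = {
            lib: sum(m.counts.get(lib, 0) for m in tags) for lib in libraries
        }
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    if df.empty:
        return pd.DataFrame(columns=libraries, dtype=int)
    return df.reindex(columns=libraries).fillna(0).astype(int).sort_index()


# ---------------------------------------------------------------------------
# GFF3 I/O: `gene` features only, ID attribute, 1-based inclusive on disk.

def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID")
            if gid is None:
                raise ValueError(f"gene feature without ID attribute: {line!r}")
            genes.append(GeneModel(
                gene_id=gid, supercontig=parts[0], strand=parts[6],
                start=int(parts[3]) - 1, end=int(parts[4]),
            ))
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.supercontig}\tdgetp\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_assignment_bed(assignment: AssignmentResult, path: str | Path) -> None:
    """BED6 of assigned tags, gene id in the name field."""
    with open(path, "w") as fh:
        for gid in sorted(assignment.gene_to_tags):
            for m in assignment.gene_to_tags[gid]:
                fh.write(
                    f"{m.supercontig}\t{m.start}\t{m.end}\t{gid}\t"
                    f"{min(m.total, 1000)}\t{m.strand}\n"
                )
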