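"""End-to-end orchestration: count -> filter -> map -> assign -> cluster
-> differential test -> multivariate summary.

The run produces a stage-accounting table in the style of a sequencing
statistics report (reads and distinct tags surviving each stage, per
library and total, with percentages of sequenced reads) and a
per-condition summary of differentially transcribed features split into
genes vs non-gene clusters and over- vs under-transcribed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import (AssignmentConfig, AssignmentResult, GeneModel,
                         aggregate_gene_counts, assign_tags)
from .clustering import (ClusterConfig, TagCluster, classify_clusters,
                         cluster_count_matrix, cluster_tags, write_cluster_bed)
from .counting import FilterConfig, TagCountTable, count_tags, filter_background
from .differential import DifferentialConfig, FeatureCountMatrix, run_differential
from .mapping import MappedTag, build_index, map_all, unique_tags
from .multivariate import hierarchical_cluster, pca_varimax

logger = logging.getLogger(__name__)

STAGES = (
    "Sequenced",
    "Filtered from background",
    "Mapped to genome",
    "Mapped to genes",
)


@dataclass(frozen=True)
class PipelineConfig:
    control: str = "Ctrl"
    filter: FilterConfig = field(default_factory=FilterConfig)
    assignment: AssignmentConfig = field(default_factory=AssignmentConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)
    n_pca_axes: int = 5


@dataclass
class PipelineResult:
    accounting: pd.DataFrame
    differential: pd.DataFrame
    summary: pd.DataFrame
    table: TagCountTable
    filtered: TagCountTable
    mapped: list[MappedTag]
    assignment: AssignmentResult
    clusters: list[TagCluster]
    feature_counts: FeatureCountMatrix

    def report_text(self) -> str:
        lines = ["# Stage accounting", self.accounting.to_string(float_format=lambda v: f"{v:.1f}"),
                 "", "# Differentially transcribed features per condition",
                 self.summary.to_string()]
        return "\n".join(lines) + "\n"


def _stage_row(counts: pd.Series, sequenced_total: int, n_tags: int, libraries: list[str]) -> dict:
    total = int(counts.sum())
    row = {lib: int(counts.get(lib, 0)) for lib in libraries}
    row["Total"] = total
    row["pct_of_sequenced"] = 100.0 * total / sequenced_total if sequenced_total else 0.0
    row["distinct_tags"] = n_tags
    return row


def run_pipeline(
    reads_by_library: dict[str, list[str]],
    genome: dict[str, str],
    genes: list[GeneModel],
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute every stage on in-memory inputs.

    ``reads_by_library`` must contain ``cfg.control``.  When ``outdir``
    is given, all intermediate tables plus the final report are written
    there.
    """
    cfg = cfg or PipelineConfig()
    libraries = list(reads_by_library)
    if cfg.control not in libraries:
        raise ValueError(f"control library {cfg.control!r} not among {libraries}")

    logger.info("stage count: %d libraries", len(libraries))
    table = count_tags(reads_by_library)
    filtered = filter_background(table, cfg.filter)

    logger.info("stage map: %d filtered tags", len(filtered))
    index = build_index(genome)
    mapped = map_all(filtered, index)
    uniq = unique_tags(mapped)

    logger.info("stage assign: %d unique tags vs %d genes", len(uniq), len(genes))
    contig_lengths = {name: len(seq) for name, seq in genome.items()}
    assignment = assign_tags(uniq, genes, cfg.assignment, contig_lengths)
    gene_counts = aggregate_gene_counts(assignment, libraries)

    logger.info("stage cluster")
    clusters = cluster_tags(uniq, cfg.clustering) if uniq else []
    clusters = classify_clusters(clusters, assignment.gene_associated_tag_set())
    nongene = [c for c in clusters if not c.gene_associated]
    nongene_counts = cluster_count_matrix(nongene, libraries)

    # features = genes + clusters not associated with genes
    feature_df = pd.concat([gene_counts, nongene_counts])
    norm_totals = filtered.totals.astype(float)
    if feature_df.empty:
        feature_df = pd.DataFrame(columns=libraries, dtype=int)
    feature_counts = FeatureCountMatrix(
        counts=feature_df,
        norm_totals=norm_totals if (norm_totals > 0).all() else norm_totals + 1.0,
    )

    logger.info("stage differential: %d features", len(feature_df))
    if len(feature_df) and (filtered.totals > 0).all():
        diff = run_differential(feature_counts, cfg.control, cfg.differential)
    else:
        diff = _empty_differential()

    accounting = _accounting(table, filtered, mapped, assignment, libraries)
    summary = _summarize(diff, set(gene_counts.index))

    result = PipelineResult(
        accounting=accounting, differential=diff, summary=summary,
        table=table, filtered=filtered, mapped=mapped,
        assignment=assignment, clusters=clusters, feature_counts=feature_counts,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _empty_differential() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "feature", "condition", "count_treated", "count_control",
        "rpm_treated", "rpm_control", "tr", "log10_tr", "p_raw",
        "direction", "p_adj", "significant",
    ])


def _accounting(
    table: TagCountTable,
    filtered: TagCountTable,
    mapped: list[MappedTag],
    assignment: AssignmentResult,
    libraries: list[str],
) -> pd.DataFrame:
    sequenced_total = int(table.totals.sum())
    uniq = unique_tags(mapped)
    mapped_counts = pd.Series(
        {lib: sum(m.counts.get(lib, 0) for m in uniq) for lib in libraries}, dtype=int
    )
    assigned_tags = [m for tags in assignment.gene_to_tags.values() for m in tags]
    gene_counts = pd.Series(
        {lib: sum(m.counts.get(lib, 0) for m in assigned_tags) for lib in libraries},
        dtype=int,
    )
    n_gene_tags = len({m.tag for m in assigned_tags})
    rows = {
        STAGES[0]: _stage_row(table.totals, sequenced_total, len(table), libraries),
        STAGES[1]: _stage_row(filtered.totals, sequenced_total, len(filtered), libraries),
        STAGES[2]: _stage_row(mapped_counts, sequenced_total, len(uniq), libraries),
        STAGES[3]: _stage_row(gene_counts, sequenced_total, n_gene_tags, libraries),
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def _summarize(diff: pd.DataFrame, gene_ids: set[str]) -> pd.DataFrame:
    """Per-condition counts of significant features, split gene/cluster
    and over/under."""
    if diff.empty:
        return pd.DataFrame(columns=[
            "condition", "genes_over", "genes_under", "clusters_over",
            "clusters_under", "total",
        ])
    sig = diff[diff["significant"]]
    rows = []
    for cond in sorted(diff["condition"].unique()):
        s = sig[sig["condition"] == cond]
        is_gene = s["feature"].isin(gene_ids)
        rows.append({
            "condition": cond,
            "genes_over": int(((s["direction"] == "over") & is_gene).sum()),
            "genes_under": int(((s["direction"] == "under") & is_gene).sum()),
            "clusters_over": int(((s["direction"] == "over") & ~is_gene).sum()),
            "clusters_under": int(((s["direction"] == "under") & ~is_gene).sum()),
            "total": int(len(s)),
        })
    return pd.DataFrame(rows)


def significant_ratio_matrix(diff: pd.DataFrame) -> pd.DataFrame:
    """log10 TR matrix (features x conditions) of features significant in
    at least one condition — the input to the multivariate stage."""
    if diff.empty:
        return pd.DataFrame()
    keep = diff.loc[diff["significant"], "feature"].unique()
    sub = diff[diff["feature"].isin(keep)]
    return sub.pivot(index="feature", columns="condition", values="log10_tr").fillna(0.0)


def run_multivariate(diff: pd.DataFrame, n_axes: int = 5):
    """PCA + varimax and feature/condition trees on significant features.

    Returns (PcaResult | None, feature Dendrogram | None, condition
    Dendrogram | None); components are None when the significant set is
    too small to support them.
    """
    m = significant_ratio_matrix(diff)
    pca = trees_f = trees_c = None
    if m.shape[0] >= 2 and m.shape[1] >= 2:
        axes = min(n_axes, min(m.shape))
        try:
            pca = pca_varimax(m, n_axes=axes)
        except ValueError:
            pca = None
        try:
            trees_f = hierarchical_cluster(m, axis="features")
            trees_c = hierarchical_cluster(m, axis="conditions")
        except ValueError:
            trees_f = trees_c = None
    return pca, trees_f, trees_c


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.table.to_tsv(outdir / "tag_counts.tsv")
    result.filtered.to_tsv(outdir / "tag_counts.filtered.tsv")
    from .mapping import mapped_to_frame, write_unique_bed

    libraries = result.table.libraries
    mapped_to_frame(result.mapped, libraries).to_csv(
        outdir / "mapped_tags.tsv", sep="\t", index=False)
    write_unique_bed(result.mapped, outdir / "unique_tags.bed")
    write_cluster_bed(result.clusters, outdir / "clusters.bed")
    cluster_count_matrix(result.clusters, libraries).rename_axis("cluster").to_csv(
        outdir / "cluster_counts.tsv", sep="\t")
    result.feature_counts.counts.rename_axis("feature").to_csv(
        outdir / "feature_counts.tsv", sep="\t")
    result.differential.to_csv(outdir / "differential.tsv", sep="\t", index=False,
                               float_format="%.6g")
    result.accounting.rename_axis("stage").to_csv(outdir / "accounting.tsv", sep="\t",
                                                  float_format="%.4f")
    result.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    (outdir / "report.txt").write_text(result.report_text())
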