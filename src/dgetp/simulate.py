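"""Synthetic tag-profiling experiments with known ground truth.

The generator emulates the structure of a multi-library tag-profiling
study — one control plus several treatment libraries sequenced from the
same gene set — on a toy genome small enough for exhaustive testing:

* a genome of a few supercontigs with configurable GC content;
* non-overlapping genes whose transcripts are genomic subsequences
  (reverse-complemented on the minus strand) plus a fixed 3' poly(A)
  tail, each guaranteed to carry at least one usable DpnII tag site;
* per-gene baseline abundances drawn log-normally (spanning orders of
  magnitude, as real tag counts do);
* a known subset of genes spiked with true fold changes in the
  treatment libraries;
* partial digestion: within a gene, tag sites are sampled with weight
  decaying geometrically from the 3'-most (canonical) site toward 5';
* fixed per-library sequencing depth (multinomial sampling, mirroring a
  fixed flow-cell lane yield) and independent per-base sequencing error.

Every downstream stage can therefore be scored against exact truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

from .annotation import GeneModel, write_gff3_genes
from .digestion import TAG_LENGTH, enumerate_tags

logger = logging.getLogger(__name__)

#: treatment names of the default seven-library design
DEFAULT_TREATMENTS = ("Copper", "Fluo", "Atraz", "Propo", "Perm", "Imida")
CONTROL_NAME = "Ctrl"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a synthetic experiment.

    The defaults describe a scaled-down version of a seven-library
    xenobiotic-exposure design: 1 control + 6 treatments, AT-rich
    genome, log-normal abundances spanning several orders of magnitude,
    10% of genes spiked at folds between 4-fold down and 10-fold up,
    geometric partial-digestion decay of 0.5 per site toward 5', and a
    0.2% per-base sequencing error rate.
    """

    n_supercontigs: int = 4
    supercontig_length: int = 100_000
    n_genes: int = 150
    transcript_length_range: tuple[int, int] = (400, 1500)
    gc_content: float = 0.38
    n_treatment_libraries: int = 6
    reads_per_library: int = 200_000
    abundance_log_mean: float = 0.0
    abundance_log_sd: float = 1.5
    spike_fraction: float = 0.10
    spike_folds: tuple[float, ...] = (0.25, 0.5, 2.0, 4.0, 10.0)
    digestion_decay: float = 0.5
    sequencing_error_rate: float = 0.002
    random_seed: int = 0
    polya_length: int = 30
    min_intergenic_gap: int = 600
    max_retries: int = 500

    def __post_init__(self) -> None:
        for name in ("n_supercontigs", "supercontig_length", "n_treatment_libraries",
                     "reads_per_library", "polya_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise ValueError("spike_fraction must be in [0, 1]")
        if not 0.0 < self.digestion_decay <= 1.0:
            raise ValueError("digestion_decay must be in (0, 1]")
        if not 0.0 <= self.sequencing_error_rate < 1.0:
            raise ValueError("sequencing_error_rate must be in [0, 1)")
        lo, hi = self.transcript_length_range
        if not TAG_LENGTH + 4 <= lo <= hi:
            raise ValueError("transcript_length_range must satisfy 24 <= lo <= hi")
        if any(f <= 0 or f == 1.0 for f in self.spike_folds):
            raise ValueError("spike_folds must be positive and != 1")

    @property
    def library_names(self) -> list[str]:
        if self.n_treatment_libraries == len(DEFAULT_TREATMENTS):
            return [CONTROL_NAME, *DEFAULT_TREATMENTS]
        return [CONTROL_NAME] + [f"T{i + 1}" for i in range(self.n_treatment_libraries)]

    @property
    def treatment_names(self) -> list[str]:
        return self.library_names[1:]


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated experiment.

    ``folds`` holds the true fold change per (gene, treatment); unspiked
    genes are exactly 1.0 everywhere.
    """

    genes: list[GeneModel]
    transcripts: dict[str, str]
    abundances: pd.Series
    folds: pd.DataFrame
    spiked_genes: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for g in self.genes:
            for cond in self.folds.columns:
                rows.append({
                    "gene": g.gene_id, "supercontig": g.supercontig,
                    "strand": g.strand, "start": g.start + 1, "end": g.end,
                    "treatment": cond,
                    "fold": self.folds.loc[g.gene_id, cond],
                    "abundance": self.abundances[g.gene_id],
                })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _usable_body(body: str, polya: int) -> bool:
    """A gene body is usable when its transcript (body + poly(A)) has at
    least one tag site and every usable site lies fully inside the body,
    so that every emitted tag is genomic and mapping truth is exact."""
    sites = enumerate_tags(body + "A" * polya)
    if not sites:
        return False
    return all(s.offset + TAG_LENGTH <= len(body) for s in sites)


def generate_genome_and_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], SyntheticTruth]:
    """Build a toy genome, gene annotation and ground truth.

    Deterministic given ``config.random_seed``.  Genes are placed
    non-overlapping with a minimum intergenic gap (so 3'-extended gene
    intervals cannot swallow a neighbour's tags); each transcript is the
    genomic subsequence plus a poly(A) tail and is redrawn (bounded
    retries) until it carries a usable, fully genomic DpnII tag site.
    """
    rng = np.random.default_rng(config.random_seed)
    contig_names = [f"supercont{i + 1}" for i in range(config.n_supercontigs)]
    contigs = {
        name: _random_sequence(rng, config.supercontig_length, config.gc_content)
        for name in contig_names
    }

    lo, hi = config.transcript_length_range
    gap = config.min_intergenic_gap
    # assign genes to supercontigs under a capacity constraint, then lay
    # each contig out left-to-right with random integer gaps >= the
    # minimum intergenic distance (so 3'-extended intervals of
    # neighbouring genes cannot swallow each other's tags)
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_genes)]
    per_contig: dict[str, list[int]] = {name: [] for name in contig_names}  # gene indices
    load: dict[str, int] = {name: 0 for name in contig_names}
    for i, length in enumerate(lengths):
        candidates = [
            name for name in contig_names
            if load[name] + length + gap * (len(per_contig[name]) + 2) <= config.supercontig_length
        ]
        if not candidates:
            raise RuntimeError(
                "genes do not fit on the supercontigs: reduce n_genes, "
                "transcript_length_range or min_intergenic_gap, or increase "
                "supercontig_length/n_supercontigs"
            )
        name = candidates[rng.integers(len(candidates))]
        per_contig[name].append(i)
        load[name] += length

    starts: dict[int, tuple[str, int]] = {}
    for name in contig_names:
        idx = per_contig[name]
        if not idx:
            continue
        slack = config.supercontig_length - load[name] - gap * (len(idx) + 1)
        extra = rng.multinomial(slack, np.full(len(idx) + 1, 1.0 / (len(idx) + 1)))
        pos = 0
        for j, i in enumerate(idx):
            pos += gap + int(extra[j])
            starts[i] = (name, pos)
            pos += lengths[i]

    genes: list[GeneModel] = []
    transcripts: dict[str, str] = {}
    for i in range(config.n_genes):
        gid = f"gene{i + 1:04d}"
        length = lengths[i]
        contig, start = starts[i]
        end = start + length
        # draw a gene body with a usable, fully genomic canonical tag site
        for _ in range(config.max_retries):
            body_codes = _random_sequence(rng, length, config.gc_content)
            body = _decode(body_codes)
            if _usable_body(body, config.polya_length):
                break
        else:
            raise RuntimeError(
                "could not draw a transcript with a usable DpnII site: "
                "check gc_content and transcript_length_range"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        genomic = body if strand == "+" else reverse_complement(body)
        contigs[contig][start:end] = np.searchsorted(
            _BASES, np.frombuffer(genomic.encode(), np.uint8)
        ).astype(np.uint8)
        genes.append(GeneModel(gene_id=gid, supercontig=contig, strand=strand,
                               start=start, end=end))
        transcripts[gid] = body + "A" * config.polya_length

    genome = {name: _decode(codes) for name, codes in contigs.items()}

    gene_ids = [g.gene_id for g in genes]
    abundances = pd.Series(
        rng.lognormal(config.abundance_log_mean, config.abundance_log_sd, size=len(genes)),
        index=gene_ids, name="abundance",
    )
    treatments = config.treatment_names
    folds = pd.DataFrame(1.0, index=gene_ids, columns=treatments)
    n_spiked = int(round(config.spike_fraction * len(genes)))
    spiked = sorted(str(g) for g in rng.choice(gene_ids, size=n_spiked, replace=False)) if n_spiked else []
    for gid in spiked:
        folds.loc[gid, :] = rng.choice(config.spike_folds, size=len(treatments))
    truth = SyntheticTruth(
        genes=genes, transcripts=transcripts, abundances=abundances,
        folds=folds, spiked_genes=list(spiked),
    )
    return genome, genes, truth


def expected_tag_weights(truth: SyntheticTruth, config: SimulationConfig) -> pd.DataFrame:
    """Per-library expected sampling probability of every (gene, tag).

    Within a gene, site weights decay geometrically with rank
    (``digestion_decay ** rank``, rank 0 = 3'-most); across genes,
    weight is abundance x fold.  One row per tag site, columns: gene,
    tag, rank, offset, plus one probability column per library.
    """
    rows = []
    decay = config.digestion_decay
    for g in truth.genes:
        sites = enumerate_tags(truth.transcripts[g.gene_id])
        site_w = np.array([decay ** s.rank for s in sites])
        site_w = site_w / site_w.sum()
        for s, w in zip(sites, site_w):
            rows.append({
                "gene": g.gene_id, "tag": s.sequence, "rank": s.rank,
                "offset": s.offset, "site_weight": w,
            })
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no tag sites: empty gene set or no usable transcripts")
    for lib in [CONTROL_NAME, *truth.folds.columns]:
        if lib == CONTROL_NAME:
            gene_w = truth.abundances.copy()
        else:
            gene_w = truth.abundances * truth.folds[lib]
        total = gene_w.sum()
        if total <= 0:
            raise ValueError(f"zero total abundance in library {lib}")
        df[lib] = df["site_weight"].to_numpy() * (gene_w / total).loc[df["gene"]].to_numpy()
    return df


def generate_tag_libraries(
    genome: dict[str, str],
    genes: list[GeneModel],
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Sample sequencing reads for every library.

    Each library draws exactly ``reads_per_library`` 20-mer reads
    multinomially over (gene, tag site) with the probabilities of
    :func:`expected_tag_weights`; each read is then corrupted
    independently at ``sequencing_error_rate`` per base.  Deterministic
    given ``config.random_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.random_seed, 1)))
    manifest = expected_tag_weights(truth, config)
    tag_codes = np.array(
        [np.searchsorted(_BASES, np.frombuffer(t.encode(), np.uint8)) for t in manifest["tag"]],
        dtype=np.uint8,
    )
    reads: dict[str, list[str]] = {}
    for lib in [CONTROL_NAME, *truth.folds.columns]:
        p = manifest[lib].to_numpy()
        counts = rng.multinomial(config.reads_per_library, p / p.sum())
        codes = np.repeat(tag_codes, counts, axis=0)
        if config.sequencing_error_rate > 0:
            mask = rng.random(codes.shape) < config.sequencing_error_rate
            shift = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
            codes = np.where(mask, (codes + shift) % 4, codes)
        raw = _BASES[codes].tobytes()
        reads[lib] = [
            raw[i * TAG_LENGTH:(i + 1) * TAG_LENGTH].decode()
            for i in range(len(codes))
        ]
    return reads, manifest


# ---------------------------------------------------------------------------
# file output

def write_genome_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_reads_fastq(reads: list[str], path: str | Path, prefix: str = "read") -> None:
    records = []
    for i, seq in enumerate(reads):
        rec = SeqRecord(Seq(seq), id=f"{prefix}{i + 1}", description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_reads_fastq(path: str | Path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_simulation(
    outdir: str | Path, config: SimulationConfig
) -> tuple[dict[str, str], list[GeneModel], SyntheticTruth, dict[str, list[str]]]:
    """Run the full generator and write FASTA/GFF3/FASTQ/TSV outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = generate_genome_and_annotation(config)
    reads, manifest = generate_tag_libraries(genome, genes, truth, config)
    write_genome_fasta(genome, outdir / "genome.fasta")
    write_gff3_genes(genes, outdir / "genes.gff3")
    truth.to_tsv(outdir / "truth.tsv")
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    for lib, lib_reads in reads.items():
        write_reads_fastq(lib_reads, outdir / f"{lib}.fastq", prefix=f"{lib}_")
    logger.info("simulation written to %s (%d genes, %d libraries)",
                outdir, len(genes), len(reads))
    return genome, genes, truth, reads
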