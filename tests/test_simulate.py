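"""Synthetic-data generator: determinism, layout guarantees, sampling law."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dgetp.annotation import GeneModel
from dgetp.digestion import enumerate_tags
from dgetp.simulate import (SimulationConfig, SyntheticTruth,
                            expected_tag_weights,
                            generate_genome_and_annotation,
                            generate_tag_libraries)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(gc_content=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(digestion_decay=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(spike_folds=(1.0, 2.0))
    with pytest.raises(ValueError):
        SimulationConfig(reads_per_library=0)


def test_deterministic_given_seed(small_config):
    g1 = generate_genome_and_annotation(small_config)
    g2 = generate_genome_and_annotation(small_config)
    assert g1[1] == g2[1]                       # identical gene intervals
    assert g1[0] == g2[0]                       # identical genome
    assert g1[2].folds.equals(g2[2].folds)
    r1, _ = generate_tag_libraries(*g1, small_config)
    r2, _ = generate_tag_libraries(*g2, small_config)
    assert r1 == r2


def test_zero_genes_yield_empty_annotation():
    cfg = SimulationConfig(n_genes=0, n_supercontigs=1, supercontig_length=5000)
    genome, genes, truth = generate_genome_and_annotation(cfg)
    assert genes == [] and truth.abundances.empty and truth.folds.empty
    with pytest.raises(ValueError):
        generate_tag_libraries(genome, genes, truth, cfg)


def test_genes_non_overlapping_with_minimum_gap(small_simulation):
    cfg = small_simulation["config"]
    by_contig = {}
    for g in small_simulation["genes"]:
        by_contig.setdefault(g.supercontig, []).append((g.start, g.end))
    for intervals in by_contig.values():
        intervals.sort()
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert s2 - e1 >= cfg.min_intergenic_gap


def test_transcript_matches_genome_and_has_genomic_tag_sites(small_simulation):
    from Bio.Seq import reverse_complement

    genome = small_simulation["genome"]
    cfg = small_simulation["config"]
    for g in small_simulation["genes"][:10]:
        t = small_simulation["truth"].transcripts[g.gene_id]
        body = t[: -cfg.polya_length]
        assert t.endswith("A" * cfg.polya_length)
        segment = genome[g.supercontig][g.start : g.end]
        assert body == (segment if g.strand == "+" else reverse_complement(segment))
        sites = enumerate_tags(t)
        assert sites
        assert all(s.offset + 20 <= len(body) for s in sites)


def test_fold_invariants(small_simulation):
    truth = small_simulation["truth"]
    cfg = small_simulation["config"]
    spiked = set(truth.spiked_genes)
    for gid in truth.folds.index:
        folds = set(truth.folds.loc[gid])
        if gid in spiked:
            assert folds <= set(cfg.spike_folds)
        else:
            assert folds == {1.0}


def test_reads_per_library_exact(small_simulation):
    cfg = small_simulation["config"]
    for lib, reads in small_simulation["reads"].items():
        assert len(reads) == cfg.reads_per_library
        assert all(len(r) == 20 for r in reads[:100])


def test_error_free_reads_all_in_manifest(clean_simulation):
    expected = set(clean_simulation["manifest"]["tag"])
    for reads in clean_simulation["reads"].values():
        assert set(reads) <= expected


def _toy_truth(transcript, abundances=None, treatments=("Trt",)):
    genes = [GeneModel(gene_id="g1", supercontig="sc1", strand="+",
                       start=0, end=len(transcript) - 30)]
    ab = pd.Series(abundances or {"g1": 1.0})
    folds = pd.DataFrame(1.0, index=list(ab.index), columns=list(treatments))
    return SyntheticTruth(genes=genes, transcripts={"g1": transcript},
                          abundances=ab, folds=folds)


def _three_site_transcript():
    block = "C" * 16
    return "GATC" + block + "GATC" + block + "GATC" + block + "A" * 30


def test_partial_digestion_weights_decay_toward_five_prime():
    truth = _toy_truth(_three_site_transcript())
    cfg = SimulationConfig(n_treatment_libraries=1, digestion_decay=0.5)
    manifest = expected_tag_weights(truth, cfg)
    # ranks 0,1,2 from the 3' end weigh 1, .5, .25 -> 4/7, 2/7, 1/7
    w = manifest.sort_values("rank")["site_weight"].to_numpy()
    np.testing.assert_allclose(w, [4 / 7, 2 / 7, 1 / 7], atol=1e-12)


def test_uniform_limit_at_decay_one():
    truth = _toy_truth(_three_site_transcript())
    cfg = SimulationConfig(n_treatment_libraries=1, digestion_decay=1.0)
    manifest = expected_tag_weights(truth, cfg)
    np.testing.assert_allclose(manifest["site_weight"], [1 / 3] * 3, atol=1e-12)


def test_zero_abundance_gene_emits_no_reads():
    t1 = _three_site_transcript()
    t2 = "GATC" + "G" * 16 + "A" * 30
    genes = [
        GeneModel(gene_id="g1", supercontig="sc1", strand="+", start=0, end=len(t1) - 30),
        GeneModel(gene_id="g2", supercontig="sc1", strand="+", start=700, end=700 + len(t2) - 30),
    ]
    truth = SyntheticTruth(
        genes=genes, transcripts={"g1": t1, "g2": t2},
        abundances=pd.Series({"g1": 0.0, "g2": 5.0}),
        folds=pd.DataFrame(1.0, index=["g1", "g2"], columns=["Trt"]),
    )
    cfg = SimulationConfig(n_treatment_libraries=1, reads_per_library=2000,
                           sequencing_error_rate=0.0, random_seed=3)
    reads, manifest = generate_tag_libraries({}, genes, truth, cfg)
    g1_tags = set(manifest.loc[manifest["gene"] == "g1", "tag"])
    for lib_reads in reads.values():
        assert not (set(lib_reads) & g1_tags)


def test_read_shares_follow_abundance_times_fold():
    """Chi-square goodness of fit of per-gene read counts at 1e5 reads."""
    cfg = SimulationConfig(
        random_seed=19, n_supercontigs=1, supercontig_length=40_000,
        n_genes=12, reads_per_library=100_000, sequencing_error_rate=0.0,
        n_treatment_libraries=2, spike_fraction=0.5,
    )
    genome, genes, truth = generate_genome_and_annotation(cfg)
    reads, manifest = generate_tag_libraries(genome, genes, truth, cfg)
    tag_to_gene = dict(zip(manifest["tag"], manifest["gene"]))
    for lib in cfg.library_names:
        fold = 1.0 if lib == "Ctrl" else truth.folds[lib]
        weight = truth.abundances * fold
        expected = weight / weight.sum() * cfg.reads_per_library
        observed = pd.Series(0, index=weight.index, dtype=int)
        counted = pd.Series(reads[lib]).map(tag_to_gene).value_counts()
        observed.loc[counted.index] = counted
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01
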