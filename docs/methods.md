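# Methods

## The assay and its in-silico model

Tag profiling represents each polyadenylated transcript by short cDNA
fragments anchored at restriction sites. mRNA is captured at its
poly(A) tail, double-stranded cDNA is cut at every DpnII site
(5'-GATC-3'), and a type IIS enzyme (MmeI) ligated at the cut releases
a fixed 20 bp fragment starting with the GATC motif. Digestion is
partial, so one transcript yields one tag per site, with the 3'-most
("canonical") tag dominating and counts decaying toward 5'. The package
models only the sequence arithmetic of this chemistry
(`dgetp.digestion`): a tag site is any GATC with at least 16 bases
downstream within the transcript; sites closer to the 3' end would
yield sub-20-mers, which are assumed lost during size selection and are
skipped. Site ranks count 0, 1, 2, … from the 3'-most usable site.

MmeI's staggered cut and 2-nt overhangs, adapter ligation, and PCR
enrichment are not modeled: only the released 20-mer matters
downstream.

## Statistical model of differential transcription

The design is one pooled library per condition — there are no
replicates, so the test is an exact two-library comparison. Feature
counts x_t (treated) and x_c (control) out of library totals N_t, N_c
are conditioned on all margins; under an odds ratio ψ the treated count
follows Fisher's noncentral hypergeometric distribution

    pmf(x) ∝ C(N_t, x) · C(N_c, k − x) · ψ^x,   k = x_t + x_c,

on the support [max(0, k − N_c), min(k, N_t)]. Because feature counts
are orders of magnitude below the library totals, the odds ratio is
effectively the RPM ratio, so "changed more than ψ₀-fold" is tested by
two one-sided boundary tails: p_over = P(X ≥ x_t | ψ = ψ₀) and
p_under = P(X ≤ x_t | ψ = 1/ψ₀), with ψ₀ = 2 by default. The raw
p-value is min(p_over, p_under): under any null fold inside
[1/ψ₀, ψ₀] at most one directional tail can be small, so the minimum is
a valid level-α test at the boundary (the worst case). A Bonferroni
`double_min` combination is available for users who prefer strict
conservatism; the boundary calibration run in `scripts/acceptance.py`
shows the default is already slightly conservative (rejection fraction
≈ 0.04 at nominal 0.05) because of the discreteness of the exact test.

Holm's step-down correction is applied over all features tested within
one condition (per-condition families match reporting significance "in
at least one condition"; a pooled family is available by flag).
Significance is adjusted p < 10⁻³.

Effect sizes are transcription ratios of reads-per-million with a
pseudocount: TR = (RPM_t + x)/(RPM_c + x), x = 0.2 RPM — roughly one
read in a few-million-read library — which bounds TRs away from 0 and ∞
for features absent in one library. Normalization totals default to the
post-background-filter library totals: the pseudocount's "about one
read per million" reading matches filtered, not mapped, library sizes;
mapped totals can be supplied instead.

### Numerical evaluation

Tails are computed in log space with the pmf ratio recurrence
pmf(x+1)/pmf(x) = ψ(N_t − x)(k − x) / ((x+1)(N_c − k + x + 1)),
anchored at the mode and normalized by compensated summation
(`math.fsum`). No factorial of a library-sized number is ever formed;
cost is O(k) per tail. Agreement with exact rational-arithmetic
enumeration is at the 10⁻¹² level for k ≤ 10⁴ (tested), and with
`scipy.stats.nchypergeom_fisher` at 10⁻⁹ (scipy is used only as an
independent cross-check, never as the implementation). Features with
k = 0 are skipped — the conditional test is undefined with an empty
margin. Direction ties (p_over = p_under) resolve to `over`.

## Pipeline rules and their edge cases

* **Background filter**: keep tags with total reads across all
  libraries ≥ 20 (comparator configurable to strict >). The filter is
  idempotent and read-conserving.
* **Mapping**: exact matching of the 20-mer on both strands via a hash
  index of every clean forward window; windows containing N are never
  indexed, tags containing non-ACGT symbols are never searched. "Unique"
  means exactly one (position, strand) pair; a reverse-complement
  palindromic 20-mer matching one window matches it on both strands and
  is therefore `multi`. Reported coordinates are leftmost, 0-based
  internally, 1-based in exports.
* **Gene assignment**: full containment of the 20 bp window in the
  gene interval extended 300 bp past its 3' boundary (strand-aware,
  clipped to contig bounds). Containment avoids double-counting windows
  that straddle boundaries. Tag strand is *not* required to match gene
  strand by default — the positional rule alone defines "within", and
  antisense tags are genuine transcription signal; a
  `--require-same-strand` flag inverts this. Tags inside ≥ 2 extended
  intervals are ambiguous and excluded from gene aggregation by default
  (preventing double counting), or credited to all genes under
  `assign_all`.
* **Clustering**: within a (supercontig, strand) group sorted in
  transcription order, adjacent tags chain when their gap (nearest
  window ends; overlap counts as 0) is < 500 bp *and* the downstream
  tag's all-library total is strictly greater. Clusters are maximal
  runs of chaining pairs; both rules are direction-invariant under this
  construction so no processing-order ambiguity exists; ties in totals
  break the chain. Clustering runs over all unique tags; clusters with
  no gene-assigned (or gene-ambiguous) member become the non-gene
  features tested alongside genes.
* **Multivariate**: PCA input is the log₁₀ TR matrix of features
  significant in ≥ 1 condition; columns are centered, not scaled
  (unit scaling available). The leading axes are varimax-rotated
  (delegated to `statsmodels`); rotation preserves the captured
  variance and the orthonormality of loadings; axis signs are fixed by
  making each axis' largest-magnitude loading positive. Feature and
  condition trees use uncentered Pearson distance
  (1 − cosine similarity, undefined for zero profiles → error),
  complete linkage, and scipy's exact optimal leaf ordering; items are
  pre-sorted by label for deterministic tie-breaking.
* **qPCR**: ratio = E_t^ΔCt_t normalized by the *geometric* mean of
  E_r^ΔCt_r over the reference genes — the standard combination for
  efficiency-corrected relative quantification with multiple reference
  genes.

## The synthetic data generator

`dgetp.simulate` emulates the structure of a seven-library
xenobiotic-exposure design at a scale suited to exhaustive testing.
Defaults (all configurable through `SimulationConfig`):

| parameter | default | meaning |
| --- | --- | --- |
| n_supercontigs × supercontig_length | 4 × 100 kb | toy assembly |
| n_genes | 150 | non-overlapping gene spans |
| transcript_length_range | 400–1500 bp | uniform |
| gc_content | 0.38 | AT-rich, insect-like |
| n_treatment_libraries | 6 | plus one control |
| reads_per_library | 200,000 | fixed lane yield, multinomial |
| abundance_log_mean / sd | 0.0 / 1.5 | log-normal; ~4 decades of expression |
| spike_fraction | 0.10 | genes with a true fold change |
| spike_folds | 0.25, 0.5, 2, 4, 10 | drawn per (gene, treatment) |
| digestion_decay | 0.5 | site weight ∝ decay^rank toward 5' |
| sequencing_error_rate | 0.002 /base | independent substitutions |
| polya_length | 30 nt | appended 3' tail |
| min_intergenic_gap | 600 bp | see below |

Design choices worth stating:

* **Placement** assigns genes to supercontigs under a capacity
  constraint and lays each contig out left-to-right with random
  multinomial gaps of at least `min_intergenic_gap`. The 600 bp minimum
  guarantees a 300 bp 3' extension can never reach into a neighbouring
  gene, so assignment truth is unambiguous by construction.
* **Gene bodies are redrawn** (bounded retries, explicit failure naming
  the offending parameters) until the transcript has ≥ 1 usable DpnII
  site *and* every usable site lies fully inside the genomic body — no
  tag spans the poly(A) junction, so every emitted tag has a well
  defined genomic source locus. The 30 nt tail mirrors oligo(dT)
  capture and guarantees any within-body site has ≥ 16 downstream
  bases.
* **Sampling** is multinomial per library with probability
  ∝ abundance × fold across genes and ∝ decay^rank within a gene
  (fixed total per library, matching fixed flow-cell lane depth),
  rather than per-gene Poisson.
* Spiked genes draw an independent fold per treatment from
  `spike_folds`; unspiked genes are exactly 1.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: biological replicate variance
(the real design pooled 3 replicates per treatment before library
prep; the generator produces one pooled library per condition),
PCR-enrichment and ligation biases, base-quality structure, repetitive
genomic sequence (multi-mapping is exercised only via constructed
cases), allelic variation between the sequenced strain and the
reference (real data lose a large read fraction there; here only
sequencing errors are rejected at mapping), and intergenic
transcription (non-gene clusters arise in tests by hiding a subset of
genes from the annotation, emulating unannotated transcription units).

## Problem sizes

The test suite and acceptance script deliberately run scaled-down
instances chosen to exercise every code path with exact oracles:
simulations of 30–150 genes at 10⁴–2×10⁵ reads per library, exact
rational-arithmetic tail enumeration up to k = 200 at N ≤ 10⁴,
calibration and spike-recovery simulations of 10³–10⁴ features at
N = 10⁶ margins, and brute-force mapping/clustering oracles on ≤ 100 kb
genomes and ≤ 100-tag strand groups. These sizes are the package's own
test design; all stages scale linearly in reads and tags and have been
run at the multi-million-read scale of a real lane.

## Known limitations

* The two-library exact test ignores biological dispersion; with
  replicated designs a negative-binomial framework (e.g. DESeq2/edgeR)
  is the right tool, and this package intentionally does not duplicate
  it.
* Gene assignment is span-based (no exon/UTR structure, no isoform
  resolution).
* The mismatch-tolerant mapper is a diagnostic scan, not an aligner;
  the pipeline path is exact-match only.
* Cluster calling does not assemble transcript models; non-gene
  clusters are features, not gene predictions.
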