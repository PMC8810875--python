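# Methods

This note states precisely what `cleftscan` computes, the conventions and
defaults it adopts, and how the synthetic-data generator is constructed. All
genomic coordinates are 0-based half-open (BED convention); VCF and GWAS
positions are 1-based and converted at the boundary (`pos − 1`).

## 1. High-confidence peak derivation (`cleftscan.intervals`)

**Quality filter** (applied to each replicate's narrowPeak calls
independently):

* fold enrichment `FE ∈ [fe_min, fe_max]`, inclusive at both ends
  (default 5–50; the upper bound removes pile-up artifacts),
* FDR `q < fdr_max`, strict (default 0.05),
* zero base-pair overlap with the blacklist,
* chromosome in the allowed set (default chr1–chr22, chrX, chrY).

narrowPeak parsing follows the ENCODE dialect: column 7 is fold enrichment,
column 9 is `−log10 q` (stored as `q = 10^(−col9)`), column 10 the summit
offset. Parse errors name the offending line number.

**Intersection rule.** For each filtered replicate-1 peak, the hc regions are
the non-empty intersections with the *union* of its overlapping replicate-2
peaks; abutting intersection pieces are merged. Each hc-peak carries a
provenance name `rep1_name|rep2a,rep2b` and inherits the anchor (rep-1)
peak's statistics. Counting is therefore region-based on the replicate-1
side: one rep-1 peak overlapping two disjoint rep-2 peaks yields two hc
regions unless they abut. Per-base, the result equals the set intersection of
the two filtered peak sets (verified against brute-force oracles and
`bedtools intersect` in the test suite).

`GenomeCover` maintains merged per-chromosome interval arrays; covered base
pairs for query batches are computed vectorially with `searchsorted` over
cumulative covered lengths (O(log n) per query).

## 2. Expression classification (`cleftscan.expression`)

A gene is **expressed** if its mean raw count across replicates is
≥ `mean_min` (default 5). The **strongly expressed** cut is the 75th
percentile of the means of *expressed* genes, computed by the nearest-rank
(type-1) method — the ⌈0.75·n⌉-th smallest value — and applied inclusively
(mean ≥ cut). Nearest-rank is chosen over linear interpolation so the cut is
always an attained data value; a `quartile_method="linear"` option is
provided. `candidate_tf_report` summarizes a candidate gene list against
these classes and a TF universe.

## 3. Overlap classification and enrichment (`cleftscan.overlap`)

Two membership rules:

* `min_bp`: covered bases ≥ threshold (integer ≥ 1),
* `fraction_of_query`: covered bases / peak length ≥ threshold, inclusive.

Coverage is always against the **union** of the reference intervals, so
overlapping reference regions are never double-counted. Membership across
several references yields a Venn partition; named classes are boolean
expressions over the reference labels
(e.g. `dnase & h3k27ac & ~hela_tf`). Cell counts sum to the number of query
peaks; peaks in no set are reported as the outside-union count
(total − union).

**Enrichment null.** Expected overlap comes from placing length-preserved
copies of the query peaks uniformly at random — by default within each
peak's own chromosome, optionally genome-wide with chromosomes drawn
proportionally to length — `n_perm` times (≥ 100 enforced; pipeline default
200), rejecting blacklist hits. The expected overlapping count is the mean
over permutations. Observed vs expected `(overlapping, non-overlapping)`
pairs are compared with a Pearson **goodness-of-fit** chi-square
`Σ (O−E)²/E` on 1 df, upper-tail p. We deliberately do *not* form a
two-sample 2×2 table of observed and expected columns: that halves the
statistic (for large `n_perm` the expected column has vanishing sampling
noise) and produces conservative, non-uniform null p-values; the
goodness-of-fit form is calibrated (KS-uniform under the null, type-I rate
≈ α — both verified in the test suite and the acceptance script). If an
expected cell is zero (e.g. the reference covers the whole genome), the
result is flagged `degenerate` and reported as `chi2 = 0, p = 1`.

## 4. Regulatory domains and gene assignment (`cleftscan.domains`)

GREAT-style basal-plus-extension. The basal domain is
`[TSS − up, TSS + down)` in the gene's orientation (defaults
up = 5000, down = 1000; for a minus-strand gene the TSS is `end − 1` and the
interval is mirrored). Each side extends to the nearest neighbouring basal
domain edge or at most `max_ext` (default 1 Mb), clipped to the chromosome;
when neighbouring basal domains already overlap the gene's own basal start,
no extension is added on that side. A peak is assigned to every gene whose
extended domain it overlaps (≥ 1 bp); unassigned peaks appear as rows with
missing `gene_id`. The signed distance to the TSS is measured from the peak
midpoint by default (`distance_anchor="summit"` optional), negative =
upstream in gene orientation.

## 5. Allele-specific binding (`cleftscan.asb`)

SNPs are located in hc-peaks via `pos − 1 ∈ [start, end)`. Only biallelic
heterozygous SNVs are tested (indels and missing genotypes are tallied and
dropped). For each SNP, ref/alt read counts are **pooled across ChIP
replicates** and tested two-sided against `Binomial(n, 0.5)` (scipy
`binomtest`, minlike method). A call additionally requires:

* pooled depth ≥ `min_total` (default 10),
* direction consistency: every replicate with a non-zero ref−alt difference
  skews the same way, and at least one replicate is informative,
* `p < alpha` (default 0.05).

Pooling maximizes power at moderate depth; a conservative
`per_replicate=True` mode instead takes the maximum of per-replicate p-values
(requiring each replicate to be independently significant). The pooled test
with the consistency filter is the default because replicate counts share the
same underlying allele and pooling is the standard practice; calibration
under the null (call rate ≤ α over 10⁴ simulated het sites) is verified.

## 6. GWAS, TADs and LD (`cleftscan.gwas`)

GWAS summary statistics require columns
`snp, chrom, pos, a1, a2, p, info`; records are dropped unless
`info > info_min` (strict; default 0.8). Risk loci are scoped to the **first
TAD containing the lead SNP** (TADs may be nested in real data; first-match
in file order is deterministic and documented); peaks overlapping that TAD by
≥ 1 bp are reported per locus. SNP-in-peak tables flag p-values below each
configured threshold (defaults 0.01 and 0.001) and optionally add a
Bonferroni column `min(1, p·n)`.

LD between a peak SNP and its locus lead SNP is computed from phased
haplotype matrices with the classical formulas:
`D = p_AB − p_A p_B`;
`D′ = |D| / D_max` where `D_max = min(p_A p_b, p_a p_B)` if `D > 0` else
`min(p_A p_B, p_a p_b)`; `r² = D² / (p_A p_a p_B p_b)`. Monomorphic sites
yield `defined = False` rather than a value.

## 7. Synthetic-data generator (`cleftscan.simulate`)

The generator emulates the *file formats and statistical structure* of a
two-replicate TF ChIP-seq study with genotypes and GWAS context — not any
particular genome. Default problem sizes (2 chromosomes × 5 Mb, 400 peaks,
300 genes, 1000 SNPs, 200 haplotypes, …) are the package's own choice,
selected so the full pipeline runs in ~1 s while every downstream count is
large enough to exercise the statistics.

Design points:

* **Slot-based placement.** Each chromosome is divided into fixed slots
  (3.6 kb); at most one planted peak pair per slot, with replicate-2 partners
  jittered by ±25% of peak length — guaranteed to overlap their replicate-1
  anchor but never to touch a neighbouring pair. Ground-truth hc regions are
  therefore exactly the pairwise intersections, written to
  `truth/true_hc_peaks.bed`.
* **Concordance.** A fraction `concordance` (default 0.7) of replicate-1
  peaks receives a replicate-2 partner; at `concordance = 1.0` the per-base
  union of true hc regions is recovered exactly (asserted in tests).
* **QC decoys.** Low-FE, high-q, blacklisted and non-standard-chromosome
  (`chrUn_synth`) peaks are planted and must be removed by the filter.
* **Reference sets** are random covers with configurable per-label genomic
  coverage (defaults 0.94 / 0.57 / 0.47) plus background intervals.
* **ASB truth.** Among het SNPs in peaks, a fraction (default 10%) is planted
  with allelic ratio `p_true = 0.9` at mean depth 50 per replicate; the rest
  are balanced. Truth goes to `truth/asb_truth.tsv`.
* **Haplotypes** are drawn in LD blocks (50 kb, within-block correlation
  0.9), giving realistic `r²` decay for the LD table.
* **Determinism.** All randomness flows from one master seed through named
  `SeedSequence.spawn` child streams (`peaks`, `references`, `expression`,
  `genotypes`, `allele_counts`, `gwas`, `tads_loci`, `haplotypes`), so output
  files are byte-identical across runs and insensitive to component
  reordering.

Not emulated: read-level data (only counts), mappability structure, copy
number, population structure in genotypes, and overlapping/nested gene
models beyond what the domain rules require.

## 8. Pipeline and error handling (`cleftscan.pipeline`, CLI)

`run_pipeline` executes hcpeaks → classify → expression → assign → asb → gwas
from a YAML config (`inputs`, optional `params`, `seed`), writing one table
per product and a `report.json` whose counts equal the row counts of the
written tables, plus per-stage wall time, the parameter set, seed and package
version. Any stage failure raises `PipelineError` naming the stage, and all
files newly created by the failed run are removed (pre-existing files are
untouched). The `cleftscan` CLI exposes `simulate` (which also writes a
ready-made `pipeline_config.yaml`), one subcommand per stage, and `all`.

## 9. Numerical choices

* Exact binomial p-values via `scipy.stats.binomtest` (minlike), never a
  normal approximation.
* Interval arithmetic in integer numpy arrays; no floating-point
  coordinates.
* Percentages are rounded only at the reporting layer
  (`percent_overlap`, default 1 digit).
* Derived seeds are reduced mod 2³¹ so they remain valid for any RNG
  consumer.
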