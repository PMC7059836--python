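# Methods

## The problem

Joint variant calling on a cohort typically runs several callers (here the
mix emulates GATK UnifiedGenotyper, Freebayes, and bcftools on low-coverage
whole-genome and whole-exome data) and integrates their outputs into one
consensus call set. Integration is only meaningful after the call sets are
made comparable: different callers describe the same edit differently
(INDELs placed anywhere in a repeat, adjacent SNVs fused into MNPs,
co-located alleles merged into multiallelic records). `consvar` implements
the full integration chain — normalization, annotation hard-filtering,
union consensus with provenance, genotype reconciliation — together with
the evaluation suite used to judge such a call set against a gold standard,
and a synthetic-data generator that makes the whole pipeline testable with
known truth.

## Normalization

`left_align_trim` implements the standard trim/extend loop (the
`bcftools norm` / `vt normalize` convention): right-trim shared trailing
bases across all alleles, extending to the left with reference sequence
whenever an allele would become empty, then trim shared leading bases while
all alleles are longer than one base. The result is the unique minimal
left-most representation; the operation is idempotent and edit-preserving
(checked against a string-rewrite oracle that applies the variant to the
contig).

`decompose_primitives` emits allelic primitives from a biallelic record.
MNPs yield one SNV per mismatching column. For complex substitutions (both
alleles longer than one base, unequal lengths) the alignment is prefix-first:
SNVs from the shared columns plus a single INDEL carrying the length
difference, anchored on the last shared column. Jointly applying the
children (INDEL before SNV where they share the anchor) reproduces the
parent edit. This tie-break is a deliberate design choice: the upstream
protocol delegates decomposition to external tools whose tie behaviour is
unspecified, and a deterministic, oracle-checkable rule was preferred.

`normalize_callset` chains split → left-align → decompose → sort →
deduplicate (highest QUAL wins, ties keep input order) → re-merge
co-located rows → biallelic selection. Distinct alleles sharing a position
become multiallelic on re-merge and are then discarded, mirroring the
production protocol's `-m2 -M2` step. The chain is idempotent and its
output is unique by `(contig, pos, ref, alt)` site key, the identity under
which all downstream set operations work.

Region exclusion removes centromere-style intervals, all chrY sites, and
chrX sites outside the pseudo-autosomal regions (the calling ploidy model
makes non-PAR sex-chromosome calls unreliable, so they are dropped rather
than carried as haploid).

## Hard filtering

A `FilterProfile` is a disjunction of threshold rules over QUAL and INFO
annotations; any rule firing soft-filters the site with the profile's label
(`GIABFILTER` / `QUALFILTER`), never removing it. The five shipped profiles
transcribe the production cutoffs exactly (see
`src/consvar/data/profiles/*.json`); comparisons are strict (`>` / `<`),
matching the filter expressions they came from. The Freebayes rule rejects
QUAL strictly below 1: the production command says `QUAL<1` while the
accompanying prose says "less than or equal to 1"; the command is taken as
authoritative. A missing annotation passes by default (mirroring expression
short-circuiting when a tag is absent) and increments a logged counter;
`missing_policy="fail"` is available per rule.

`derive_cutoffs` reconstructs such cutoffs from a gold-standard comparison.
The production thresholds were chosen by inspecting TP vs FP annotation
distributions without a stated rule; this package defines the procedure as:
threshold = the `tp_retention` empirical quantile of the TP distribution on
the rejecting side (`method="higher"`/`"lower"` so the quantile guarantee
is exact: at most `(1 − tp_retention)·|TP| + 1` true positives rejected per
rule). Thresholds are marginal per annotation; joint thresholding is out of
scope. The default retention is 0.99.

## Consensus

`union_sites` takes the union of normalized biallelic site keys and records
per-caller provenance; `contribution_counts` reports exact-subset
intersection sizes (UpSet semantics: subset counts sum to the consensus
size, marginals are per-caller totals). Consensus site fields are resolved
conservatively: QUAL = max across supporters, filters reset (final
filtering happens downstream of the union in the production protocol), and
INFO restricted to keys identical across supporters. Genotypes are filled
by `reconcile_genotypes`, a deterministic priority lookup (first
non-missing call in priority order, default gatk → freebayes → lc_bcftools
→ ex_bcftools) standing in for likelihood-based joint re-genotyping, which
is out of scope.

## Evaluation

All evaluations are site-level, matched by normalized site key, reported
per contig with an unweighted-mean AVG row. chrX is excluded from averages
by default: it is evaluated on pseudo-autosomal regions only and is not
comparable to autosomes. The AVG row is the mean of per-contig values, not
the pooled ratio — this matches the published tables' arithmetic and is
verified against them.

* **Concordance** restricts query and gold to high-confidence regions and
  counts TP (shared), FN (gold only), FP (query only); percentages are
  relative to the gold total (TP, FN) and the query total (FP).
* **Switch error** assesses sites present in both call sets where the
  sample is heterozygous with the same unphased genotype and phased in
  both. Each site has a relative orientation; a switch is an orientation
  change between consecutive assessable sites; the rate is
  `100·switches/(assessable−1)` per contig. Phase is relative, so a global
  haplotype flip costs nothing. Sites het in truth but homozygous or
  missing in the prediction are genotype errors, not phase errors, and are
  excluded. A single isolated flip between two same-orientation neighbours
  counts as two switches (orientation-transition counting); comparators
  that count "flip errors" separately would report one.
* **FN attribution** looks FN sites up in the pre-selection call set that
  still carries soft-filter labels and tallies the labels; `% explained` is
  the attributed fraction of FNs per contig.
* **Stratification** counts each call set's sites inside/outside novel
  regions and reports each call set's share of the class total, optionally
  with per-contig TP percentages within the novel class against a gold
  standard.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
sequencing itself (no reads, no error model, no linkage disequilibrium).

* **Reference and truth.** Random contigs (defaults: four autosome-like
  contigs plus chrX, chrY and one designated novel contig, 430 kb total).
  Truth sites sit on a 16 bp slot grid so planted features never collide:
  4,000 biallelic canonical sites by default — 12% INDELs (single-copy
  insertions/deletions of a planted 3–5 bp homopolymer run, left-aligned),
  8% MNP-source and 6% merge-source sites (adjacent same-genotype SNV
  pairs), the rest SNVs. Allele frequencies follow Beta(0.8, 0.8) and
  genotypes are drawn haplotype-wise, hence Hardy–Weinberg by construction;
  phasing is exact.
* **Callers.** Each simulated caller includes truth sites independently at
  its sensitivity (zero on contigs it is declared blind to, emulating a
  lift-over's novel-contig blindness), adds false sites at free grid slots
  so the expected false fraction equals its FDR, rewrites representation
  per style (right-shifted INDELs within their runs; MNP joins; padded
  multiallelic merges of adjacent pairs), and draws QUAL plus the
  filterable annotations from Gaussian TP/FP laws. Default laws separate
  TP from FP (e.g. MQ 55±3 vs 30±5, DP 300±60 vs 900±300) so cutoff
  derivation has learnable signal; the laws are configuration, not code.
* **Phasing.** `simulate_phasing` swaps the haplotypes of each het call
  independently with probability p (default 0.02), giving an expected
  orientation-transition rate of 2p(1−p).
* **Gold standard.** A downsampled/augmented copy of the truth; with
  sensitivity 1 and no false sites it equals the truth, so concordance of a
  simulated caller has closed-form expectations (pct_shared → 100·s,
  pct_query_only → 100·f).

What passing tests show — and what they do not: the pipeline provably
preserves site identity under the representation rewrites the simulator
generates, and the evaluation statistics recover injected parameters within
their sampling intervals. Real caller output contains representation
pathologies the simulator does not generate (nested complex alleles,
half-calls, spanning deletions), misaligned reads, and LD structure; results
here say nothing about those.

## Numerical and statistical choices

* Coordinates: VCF 1-based inclusive, BED 0-based half-open; conversion in
  exactly one place (`RegionSet.contains`).
* Contig order follows the reference FASTA; call sets on unknown contigs
  raise.
* Fractional QUAL/INFO values round-trip through VCF at float32 fidelity
  (htslib storage); integral values and everything else round-trip exactly.
* Percentages carry full precision internally; TSV writers round to two
  decimals (rates) to match the conventional table layout.
* Statistical tests on seeded simulations use 99% intervals. For switch
  counts over overlapping consecutive pairs, adjacent transitions share a
  flip, so the count is over-dispersed relative to a binomial
  (Var = nq(1−q) + 2(n−1)(p(1−p)−q²), roughly 2× binomial); tests use this
  corrected interval for the full count and the exact binomial on disjoint
  pairs.
* Problem sizes (4,000-site studies, 7,000 sites for phasing recovery,
  pooled over 3–5 seeds) were chosen to keep every interval tight enough to
  detect estimator bias while the full suite stays interactive.

## Known limitations

* Genotype-level concordance, phasing block structure (N50), and
  likelihood-based re-genotyping are out of scope by design.
* `merge_multiallelics` assumes inputs normalized against one reference
  (each REF must be a prefix of the longest at its position).
* The multiallelic-merge representation style encodes a haplotype carrying
  both alternates of a pair lossily (alt 1 wins); site-key analyses are
  unaffected.
* INFO handling is scalar-only; Number=A/R/G semantics are not modelled.
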