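# Methods

## Scope and model

The package identifies two complementary classes of tumor-vaccine
targets from sequencing-derived inputs and supports the downstream
panel production and immune monitoring steps:

1. **Neoantigens** — peptides created by somatic SNVs and indels.
   Variants are applied to annotated coding transcripts codon-aware,
   candidate peptide windows are enumerated over the altered residues,
   and candidates pass a stepwise filter chain.
2. **Tumor-associated antigens (TAAs)** — non-mutated transcripts
   aberrantly overexpressed in tumor relative to a panel of normal
   tissues, called by a dual transcript/gene TPM rule.
3. **Capture-panel design and QC** — tiling hybridization probes over
   selected antigen transcripts, and validation of an enriched library
   against its pre-enrichment pool.
4. **Immune monitoring** — ELISA reactivity calls, TCR clone-size
   binning, Chao1 richness, and Vβ-family composition.

## Variant consequences

Internal coordinates are 0-based half-open; VCF and GTF coordinates are
converted at the parsing boundary. Variants are edited into the
plus-strand spliced CDS (VCF alleles are plus-strand) and the mutant
CDS is re-translated:

- SNV → single-codon substitution; synonymous outcomes are flagged
  non-antigenic and produce no candidates.
- In-frame indel → residue insertion/deletion. The altered span is
  computed by common prefix/suffix trimming; a pure deletion that
  leaves no novel residue marks the junction residue, so the span is
  never empty for an accepted variant.
- Frameshift indel → re-translation from the shift through the first
  new stop; the whole novel tail is the altered span. When a
  transcript carries 3' UTR sequence, stop-loss and late frameshifts
  read through into it.
- Stop-gain and start-loss create no novel peptide and are rejected;
  a ref-allele/genome mismatch is a hard error.

Translation uses the standard genetic code; any codon containing N
yields `X` rather than being resolved through wobble ambiguity, so an
uncertain base never silently produces a confident residue.
Transcripts with a CDS that is not a multiple of three or lacks an ATG
start are excluded at load time with a warning rather than patched.

## Epitope enumeration and the filter chain

MHC class I candidates are all 8–11-mers and class II candidates all
15-mers of the mutant protein that overlap the altered span; windows
identical to any wild-type substring are dropped, since they cannot be
neoantigens. Filtering is stepwise, in the order **affinity → VAF →
expression**, and each rejected candidate records the first step it
failed:

| step       | rule                                     | boundary |
|------------|------------------------------------------|----------|
| affinity   | class I < 500 nM, class II < 1000 nM     | strict   |
| VAF        | tumor variant allele fraction > 0.6      | strict   |
| expression | tumor gene expression > 1 TPM            | strict   |

All three printed cutoffs are read literally as strict inequalities, so
boundary values (500 nM, VAF 0.6, 1 TPM) fail. Upstream of prediction,
"RNA-expressed" is operationalized as at least `min_rna_alt_reads`
RNA-seq reads supporting the alt allele (default 1, inclusive,
configurable down to 0 for users whose RNA confirmation is
expression-only). Gene expression is the mean over tumor replicates of
the isoform-summed gene TPM. Candidates from different transcripts of
the same gene with the same peptide and allele are merged; TAA-derived
candidates carry no VAF and skip that step.

## Binding affinity

Affinity prediction is a contract: deterministic
`predict(peptide, allele) -> nM` on the conventional 1–50000 nM scale.
External predictors are integrated only through a TSV adapter
(`peptide, allele, affinity_nm`; conflicting duplicates and malformed
rows are errors naming the line). For self-contained testing the
package ships a surrogate scorer: per-allele position weight matrices
(`toy-Kb` at lengths 8–11, `toy-IAb` at 15) with calibration
`nM = 50000^(1 − s/s_max)` clipped to [1, 50000]. The calibration is
strictly decreasing in the raw score, so the per-position-argmax
consensus peptide attains the 1 nM floor and moving any residue toward
the consensus never weakens the prediction. The surrogate is a test
stand-in by design and makes no claim to biological accuracy.

## Peptide uniqueness

Tumor specificity is enforced by exact string matching against a k-mer
index of the reference proteome (all substrings of length 8–15 of
every protein, mapped to their carrying gene/transcript). A mutant
epitope is removed if it occurs anywhere in the proteome. A TAA epitope
is removed if an *expressed* transcript of another gene contains it;
occurrences in non-expressed transcripts are reported but only reject
in strict mode. Exact matching is the conservative, reproducible
choice; the `occurrences` hook accepts a fuzzy matcher should one be
wanted. The expression context defaults to tumor-expressed transcripts
(TPM > 1), since normal-tissue silence is already enforced gene-level
by the TAA caller.

## TAA calling

Gene TPM is defined as the sum of isoform TPM. A transcript is called
iff its tumor TPM exceeds 1 (strict) and its gene's TPM stays below 1
(strict) in **every** normal sample — the max over the panel, not the
mean, which is the strictest reading of "below threshold across normal
tissues". Tumor replicates aggregate by mean by default; a union mode
(any replicate over threshold) is available and the per-replicate pass
pattern is always reported, because the replicate-aggregation rule is
genuinely open. The rule is a deterministic filter; no test statistic
or multiple-testing correction applies.

## Probe tiling and enrichment QC

Probes default to 120 nt every 60 nt (a common half-overlap
hybrid-capture design; fully configurable), starting at 0 and stepping
until the transcript end, with a final probe anchored to end exactly at
the 3' end whenever the last regular probe falls short — guaranteeing
every base is covered. Transcripts shorter than one probe yield a
single whole-transcript probe flagged short.

Enrichment QC quantifies the target gene set's share of the expression
pool, TPM-weighted: `100 × (target TPM sum) / (total TPM)`, which is
invariant under uniform rescaling. Fold enrichment is the post/pre
share ratio (infinite with a warning when the pre share is zero). The
per-gene table reports `log2((post + c)/(pre + c))` with pseudocount
c = 0.01 TPM; with replicates on both sides an unpaired t-statistic on
log-TPM and Benjamini–Hochberg adjusted p-values are added. A
read-count-weighted share would differ only by length weighting and is
out of scope; TPM share is the default interpretation.

## Immune-monitoring statistics

- Reactivity: positive iff IFN-γ > 100 pg/ml (strict) AND ≥ 2-fold the
  irrelevant-peptide response (inclusive) — the concentration clause is
  worded "over", the fold clause "at least", and both are read
  literally.
- Clone-size bins, inclusive at each boundary: hyperexpanded ≥ 1%,
  large ≥ 0.1%, medium ≥ 0.01%, small ≥ 0.001% of reads, rare below.
  Bin read-shares partition the repertoire and sum to 1.
- Richness: bias-corrected Chao1,
  `S_obs + f1(f1−1)/(2(f2+1))` over singleton/doubleton clone counts.
  Upstream toolchains label their diversity output "Chao E mean"
  without defining the estimator; this package computes the standard
  bias-corrected Chao1 (cross-checked against scikit-bio in tests) and
  a per-group mean of per-sample estimates.
- Vβ composition: read share per V family; MiXCR-style V-hit strings
  are trimmed to the family and empty labels grouped as "unassigned".

## Synthetic cohorts

The fixture generator is a pure function of its spec (seed included):
identical specs give byte-identical files. Defaults mirror the study
design the pipeline assumes — 3 tumor replicates, a 95-tissue normal
panel, 20 genes × 2 isoforms with CDS lengths 150–270 nt (kept small so
the whole suite runs in seconds), capture efficiency 0.95 vs off-target
0.002.

Spiked variants carry designed outcomes recorded in a truth table. The
wild-type context of a "pass" SNV is one substitution away from the
surrogate consensus 9-mer and the variant completes it, so at least one
enumerated window scores the 1 nM floor; in-frame insertions insert
the missing consensus residue, and frameshifts use a searched downstream
sequence that encodes the consensus in the shifted frame while
translating cleanly in the original frame. Designed failures flip
exactly one step (VAF 0.5; gene expression 0.4 TPM; zero RNA support; a
verified weak-binding missense; a synonymous change). Construction-time
checks run the real variant/enumeration/scoring machinery and reject
any draw that does not behave as designed, so truth labels are
guaranteed, not probabilistic. Spiked TAA transcripts exceed 1 TPM in
tumor while both isoforms of their gene stay below 1 TPM summed in all
normals; decoys violate exactly one clause (tumor 0.8 TPM; an
isoform-sum of 1.2 TPM in one normal with each isoform individually
below 1). Background transcripts absorb the remaining mass so every
sample sums to 10^6.

Capture enrichment is simulated noise-free: target TPM scaled by e,
off-target by o, renormalized; the post share then equals
`100·e·S/(e·S + o·(10^6 − S))` exactly, which the QC layer is tested
against to 1e-9, and o can be inverted in closed form to hit a desired
post share.

What the fixtures do **not** emulate: read-level sequencing (no
FASTQs, error models, or mapping artifacts), splice-aware variant
effects across exon junctions, phased multi-variant haplotypes,
realistic tissue-specific expression correlation, and real pMHC
binding chemistry. Passing tests therefore demonstrate the correctness
of the filtering logic, coordinate arithmetic, and bookkeeping — not
predictive performance on real tumors, which depends on the external
predictors and upstream callers the adapters integrate.

## Numerical and design notes

- Thresholds are compared exactly as documented (strict vs inclusive);
  no epsilon is applied anywhere.
- Output TSVs are sorted (gene, peptide, allele) so reruns are
  byte-identical.
- Multi-allelic VCF records are skipped with a warning — splitting
  belongs upstream (`bcftools norm`).
- VAF comes from the first sample's `AF` format field, falling back to
  `AD`-derived alt/(ref+alt); RNA support from a configurable INFO key
  (default `RNAD`).
- The acceptance script (`scripts/acceptance.py`) runs 5 generated
  cohorts per invocation and the test suite 20; sizes chosen so both
  finish in seconds while exercising every spike class.

## Known limitations

- No phasing: nearby somatic variants are evaluated independently, so
  a haplotype carrying two mutations in one epitope is not modeled.
- Splice-site, fusion, and intronic neoantigens are out of scope.
- The uniqueness screen is exact-match; a single-mismatch self peptide
  will not be flagged.
- Probe design is purely geometric (no Tm/GC balancing or
  cross-hybridization screening).
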