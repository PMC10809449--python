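# oran

Tumor antigen discovery and vaccine-panel tooling: a tested library +
CLI that calls **neoantigens** (mutant peptides from somatic SNVs and
indels) and **tumor-associated antigens** (TAAs — non-mutated
transcripts aberrantly overexpressed in tumor versus a normal-tissue
panel), screens every candidate epitope for tumor specificity against
the reference proteome, designs tiling hybrid-capture probes over the
selected transcripts, validates capture enrichment, and computes the
immune-monitoring statistics used to evaluate the resulting therapy
(ELISA reactivity, TCR clone-size bins, Chao1 diversity, Vβ usage).

It is aimed at computational immunologists prototyping antigen-
selection rules and at engineers who need a transparent, fully
offline-testable re-implementation of a stepwise epitope filter chain:
every stage works on synthetic cohorts with known ground truth, and
external binding predictors plug in through a plain TSV adapter.

## The core rules

**Neoantigen arm.** Somatic variants with RNA support are applied to
coding transcripts; 8–11-mer (MHC I) and 15-mer (MHC II) windows over
the altered residues are filtered stepwise, each rejection recording
its first failed step:

    affinity:    IC50 < 500 nM (class I), < 1000 nM (class II)
    VAF:         tumor variant allele fraction > 0.6
    expression:  tumor gene expression > 1 TPM

followed by a proteome-uniqueness screen (exact match against all
8–15-mers of the reference proteome). All cutoffs are strict.

**TAA arm.** With gene TPM defined as the sum over isoforms, a
transcript is called iff

    tumor transcript TPM > 1   AND   gene TPM < 1 in every normal tissue

(default panel size: 95 tissues; tumor replicates aggregate by mean).

**Capture QC.** The target set's pool share is
`100·Σ target TPM / Σ TPM`; fold enrichment is the post/pre share
ratio, and a noise-free capture with efficiencies (e, o) satisfies
`post share = 100·e·S/(e·S + o·(10⁶ − S))` for pre-enrichment target
mass S — the QC layer is tested against this closed form.

**Repertoire statistics.** Clone bins (hyperexpanded ≥ 1%, large
≥ 0.1%, medium ≥ 0.01%, small ≥ 0.001% of reads, rare below), bias-
corrected Chao1 `S_obs + f1(f1−1)/(2(f2+1))`, and per-family Vβ read
shares. Reactivity: IFN-γ > 100 pg/ml and ≥ 2-fold over the
irrelevant-peptide control.

See `docs/methods.md` for assumptions, parameter rationale, and
limitations.

## Worked example

Generate a toy cohort (toy genome + GTF, spiked VCF, tumor/normal
expression, capture pair) and run the pipeline:

    $ oran fixtures make --out demo --seed 11
    $ oran neo --genome demo/genome.fa --annotation demo/annotation.gtf \
          --vcf demo/variants.vcf --expression demo/expression.tsv \
          --samples demo/samples.tsv --out demo/neo
    retained 4 neoantigen candidates (4 genes) -> demo/neo

    $ oran taa --expression demo/expression.tsv --samples demo/samples.tsv \
          --proteome demo/proteome.fa --out demo/taa
    3 TAA transcripts called -> demo/taa

    $ oran panel qc --pre demo/pre_enrichment.tsv \
          --post demo/post_enrichment.tsv --targets demo/targets.txt \
          --out demo/qc
    target share 0.02% -> 10.42% (425.6-fold)

The fixture spikes four variants designed to survive every filter
(an SNV on each strand, an in-frame insertion, a frameshift) and five
designed to fail exactly one step; the neoantigen table lists exactly
the four designed genes:

    $ head -3 demo/neo/neoantigens.tsv | cut -f1-9
    peptide    length  class  allele  affinity_nm  gene  transcript  variant        vaf
    GRGNTWGFT  9       I      toy-Kb  1.0          G000  T000.1      chr1:162:C>A   0.7976
    GRGNTWGFT  9       I      toy-Kb  1.0          G001  T001.1      chr1:692:G>T   0.7887

`GRGNTWGFT` is the consensus peptide of the packaged surrogate binding
matrix (1 nM floor); each spiked variant completes it from a wild-type
context one substitution away. The 4 retained candidates pass
affinity (< 500 nM), VAF (> 0.6), expression (> 1 TPM) and are absent
from the reference proteome; `demo/neo/rejections.tsv` names the first
failed step of every rejected window. The three TAA calls are the
transcripts constructed to exceed 1 TPM in tumor while their genes stay
silent (< 1 TPM summed) in all 95 normals — the two decoys violating
one clause each are rejected. The capture report shows the target
share rising from 0.02% to 10.42% of the pool under the default
simulated efficiencies (e = 0.95, o = 0.002), a 425.6-fold enrichment.

Affinities from a real predictor can be supplied with
`--predictor table:affinities.tsv` (columns
`peptide, allele, affinity_nm`).

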