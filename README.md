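# ighvhaplo

Strain-specific germline IGHV inference from long-read VDJ-C repertoires of
F1 hybrid mice.

Laboratory mouse strains other than C57BL/6 lack curated germline
immunoglobulin references, which corrupts every downstream repertoire
analysis. `ighvhaplo` implements the F1-hybrid strategy for building such
references: sequence VDJ rearrangements *together with their spliced
constant region* (VDJ-C) from F1 offspring of two homozygous strains, type
exonic constant-region SNPs (the IGHM CH1 SNP rs29176517, and four IGHG2B
SNPs) to anchor every read to a parental chromosome, and use the anchors to

- call the F1 **genotype** (which germline V alleles are present),
- discover **novel alleles** missing from the starting database via
  mutation-load regression (carrier fraction vs. total V mutations; a
  germline polymorphism has y-intercept ≥ 0.125, hypermutation ≈ 0),
- **haplotype** every V allele onto a parental chromosome (per-allele
  binomial likelihood ratio between a single-chromosome leak model,
  ε = 0.01, and a both-chromosomes p = 0.5 model, with kThreDel = 0.1),
- quantify residual **PCR chimerism** (anchor-discordant records),
- **curate** the resulting reference sets (truncated-record extension,
  evidence-based 3'-end confirmation, per-strain FASTA export) and measure
  reference completeness via read-mismatch histograms and assembly search.

Because real strain repertoires are not bundled, the package ships a
first-class synthetic F1 repertoire generator (molecules, UMIs, PCR
duplicates, CCS-grade substitution + homopolymer-indel noise, exonuclease
trimming, and two template-switch channels) with complete planted truth, so
every inference stage is validated by parameter recovery. See
`docs/methods.md` for the models and numerical choices.

## Worked example

```bash
python examples/genotype_and_haplotype.py
```

runs the full pipeline on the standard synthetic study (50,000 reads,
2×100 V alleles, four shared, a planted novel variant, 14% template
switching; about a minute) and prints, among other lines:

```
reads annotated:            50000
unique VDJ sequences:       34552
prepared for haplotyping:   3952
genotype: 162 alleles present
genotype sensitivity (usage >= 0.05%): 100.0% (143/143); false alleles: 0
novel 1-SNP variant rediscovered: True (['IGHV8-6*01_G151C'])
planted shared alleles:  ['IGHV12-12*01', 'IGHV3-3*01', 'IGHV4-15*01', 'IGHV6-15*01']
called on both chromosomes: ['IGHV12-12*01', 'IGHV3-3*01', 'IGHV4-15*01', 'IGHV6-15*01']
residual chimerism: estimated 1.11%, planted 1.14%
pre-filter IGHJ1/SNP concordance: B6=81.1%, BALB=85.8%
```

Reading the numbers: every allele called present is genuinely planted
(zero false positives); the four alleles shared between the parental
haplotypes — and only those — are detected on both chromosomes; the
planted novel allele is rediscovered from rearrangements alone and named
by its substitution; and the anchor-discordance estimates bracket the
planted template-switch rates (~86% concordance is the pre-filter regime,
~1% the residual after the duplicate/ambiguity/UMI filters). The other
example scripts demonstrate dataset simulation
(`simulate_dataset.py`), annotation and SNP typing with the
indel-correction contrast (`annotate_and_type.py`), and reference curation
(`curate_reference.py`).

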