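# Methods

`ighvhaplo` infers strain-specific germline IGHV reference sets from
long-read VDJ-C amplicon repertoires of F1 hybrid mice. This note documents
the model behind each stage, the parameters that matter, what the synthetic
data generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## The inference problem

Inbred mouse strains differ so extensively across the IGH locus that alleles
often cannot be matched between strains, and germline reference sets exist
essentially only for C57BL/6. Germline inference from repertoire data can
fill the gap, but rarely-used genes (utilization down to ~0.01%) are hard to
distinguish from PCR artefacts. The F1-hybrid design resolves this: cross
two homozygous strains, amplify VDJ rearrangements together with the spliced
constant region (VDJ-C), and use exonic constant-region SNPs — one in the
IGHM CH1 (rs29176517: g on the BALB/c chromosome, a on C57BL/6), four across
the IGHG2B CH1/CH2 — to anchor every read to a parental chromosome. Because
VDJ recombination is a chromosomal event, the anchor phases every V gene:
alleles observed (essentially) only with one anchor belong to that strain,
and anchor-discordant reads expose PCR template switching.

## Synthetic repertoire generator

The generator is first-class, tested code: it defines the study conditions
under which the pipeline's recovery guarantees are demonstrated.

**Germline structure.** Two parental haplotypes carry `n_v_alleles` (default
100) V alleles each, organised into families (founders ~291–306 nt; members
2–8 substitutions apart, minimum pairwise distance 2). A configurable
fraction of V sequences (default 4%, i.e. four alleles) is shared between
the haplotypes, mirroring the near-disjoint strain repertoires with a
handful of common sequences. Family mutations avoid the conserved FR3
cysteine codon and the final 12 nt, so alleles remain identifiable under 3'
exonuclease trimming (alleles distinguishable only in the trimmed tail would
be genuinely unidentifiable in rearrangements — a deliberate generator
restriction, stated here). Twelve D genes and four J genes are shared;
IGHJ1 carries two alleles one substitution apart (*01 on strain A, *03 on
strain B). The IgM CH1 exons are the published strain pair (reconstructed
under the single-SNP statement); the remaining exons and IgG subclass genes
(IgG2a/IgG2b on strain A, IgG2b/IgG2c on strain B, with the four IGHG2B
SNPs planted at documented offsets) are synthetic stand-ins.

**Usage.** Per-haplotype V usage is log-uniform on [1e-4, 5e-2] (the
0.01%–5% range the inference must cope with), normalised to 1; shared
alleles draw independently per haplotype from [5e-3, 2e-2]. J usage gives
IGHJ1 25% (its real utilization is comparatively low).

**Molecules and reads.** Reads are PCR/sequencing copies of *molecules*:
each molecule has one chromosome (50/50), one rearrangement (geometric 3'
V-trim and 5' J-trim, mean 2 nt; D trimmed both sides; N-inserts uniform
0–8 nt), one UMI, and a geometric number of read copies (mean 2.5).
IgM molecules are unmutated with probability 0.8, else lightly mutated
(0.5%/base); IgG always 2%/base. 5% of molecules are 5'-truncated by
20–80 nt (the filtered class). Per read, sequencing noise applies
substitutions at 0.001/base and, at each homopolymer run (length ≥ 2), an
insertion or deletion of one copy with probability 0.003/run — the
homopolymer bias of long-read platforms at CCS quality.

**Chimeras.** Template switching is modelled in two channels:

* *Late-cycle, per-read* (`chimera_rate`, default 0.14): a read is replaced
  by donor A's VDJ joined to donor B's constant region, donors drawn from
  opposite chromosomes, breakpoint uniform between the end of J and the
  IGHM CH1 SNP. The rate is therefore directly the pre-filter IGHJ1-vs-SNP
  discordance scale (the regime with ~86% concordance). These products
  carry the host molecule's UMI as singletons and are removed by the
  duplicate/ambiguity/UMI-confirmation filters.
* *Early-cycle, per-molecule* (`chimera_molecule_rate`, default 0.01):
  a whole molecule is chimeric, so all its copies share the artefact and
  one UMI. These survive the filters and set the residual post-filter
  chimerism (~1%, the quantity the haplotype-stage estimator measures).

A `v_region` breakpoint mode (hybrid V products) is available; it is not
the default because breakpoints upstream of J cannot produce the J-vs-C
discordance that the anchored design actually observes.

Determinism: a single 64-bit seed drives one generator; identical
configurations produce byte-identical outputs.

**What the generator does not emulate:** base-quality variation, chemistry-
specific error profiles, clonal lineage structure, light chains, biased
N-nucleotide composition, cross-family gene conversion. Passing recovery
tests therefore demonstrate correctness of the inference machinery under
the stated statistical structure, not performance on any particular real
instrument run.

## Annotation

Reads are UMI/primer-trimmed (primers located with ≤ 2 mismatches), then V
and J segments are called against germline references.

* `align_segment` is unit-cost semi-global alignment (allele as an infix of
  the read, free end gaps on the read) via edlib; ties are reported
  comma-joined in ascending name order. This is the reference behaviour and
  is verified against an exhaustive DP oracle.
* The bulk V caller exploits the anchored geometry (the V 5' end starts the
  trimmed read) with a banded extension alignment (match +1, mismatch −2,
  gap −3, band ±12) anchored at the 5' ends and free at both 3' ends, so
  mismatches are counted only over the germline span the read actually
  covers — exonuclease trimming is not charged as error. An exact
  prefix-index plus a substitution-only vectorised path handles the common
  indel-free case (the score-maximising germline end is computed in closed
  form and equals the DP answer when no indel is present); reads with
  indels, heavy mutation or 5' truncation fall back to the gapped kernel
  and an exhaustive edlib scan. Call sets are independent of reference
  ordering. One documented artefact: when a deep 3' trim is followed by
  junction bases that happen to match the germline tail, the extension can
  overrun by a few bases and report ~2 spurious mismatches; this affects
  <1% of reads and only removes them from "unmutated" subsets.
* Junctions run from the annotated V cysteine codon to the J tryptophan
  (`tgggg`) anchor; `complete_vdj` requires the V alignment to start within
  the first 5 germline positions. D calls (unused downstream) require ≥ 5
  consecutive matching bases in the junction.

## Constant-region typing

The constant segment is the read from one base past the final J nucleotide
to the primer end. It is globally aligned (unit-cost, via edlib) to the
canonical spliced exon reference of the best-matching isotype; read
insertions are removed and deletions are filled with the reference base and
flagged low-confidence. The affine-gap scoring named in early design notes
was dropped: unit costs resolve single homopolymer indels in 300-nt exons
identically, as the alignment-oracle tests verify. SNP bases are then read
positionally; deletion-filled positions give no-call. A strain call
requires all called SNPs to agree on one strain (IgM: one SNP; IGHG2B: all
four). "Highly confident" adds ≥ 90% alignment identity and no no-calls.

Indel correction is what makes positional extraction work at all: at
platform noise rates (0.002 subst/base, 0.01 indel/run) naive positional
typing drops to ~80% accuracy while corrected typing exceeds 99.8%.

## Genotype inference and novel alleles

After removing 5'-truncated reads and those lacking a junction or J call,
reads collapse to unique VDJ nucleotide sequences (the collapse key excludes
the constant region). Member strain calls aggregate per unique sequence;
a sequence observed with both anchors is ambiguous and excluded from
haplotyping, and an anchor call counts as *confirmed* only when ≥ 2
identically-typed member reads share one UMI — independent chimeras
coinciding on the same acceptor VDJ carry distinct UMIs and cannot fake
molecule-level replication. This is the package's rendering of the original
study's "highly confident" SNP-call filter.

**Novel alleles** are found by mutation-load regression: for each reference
allele with ≥ 50 (`germline_min`) assigned unique sequences, the fraction of
sequences carrying a given substitution is regressed (weighted by bin
count) against total V mutation load over loads 1–10. A germline
polymorphism is carried at high frequency even by otherwise-unmutated
sequences, so its fitted y-intercept is large; hypermutation extrapolates
to ~0. Substitutions with intercept ≥ 0.125 supported by ≥ 10 (`min_seqs`)
otherwise-unmutated sequences become candidate alleles (reference plus that
substitution), deduplicated against the starting set. Bins with positional
coverage < 10 sequences are excluded from the fit.

**Genotype.** An allele is present when ≥ 2 unique unmutated sequences have
it as a (tied-)best match; single-sequence alleles are kept on a separate
provisional list rather than in the genotype. After novel alleles join the
reference, records are incrementally re-scored (only records with ≥ 1
mismatch can improve) and finally restricted to the present set.

## Haplotype assignment

Prepared records (unmutated, duplicate count > 1, confirmed unambiguous
anchor, single V call) give per-allele anchor counts (nA, nB). Two models
are compared per allele, independently (no pooling across a gene's alleles;
symmetric p = 0.5 rather than usage-weighted priors):

* single chromosome with leak ε = 0.01 (absorbing residual chimerism and
  typing error): likelihood (1−ε)^major · ε^minor;
* both chromosomes: 0.5^n.

`certainty = log10` of their ratio. Presence on **both** chromosomes
requires minor/n ≥ kThreDel (0.1), minor ≥ 2 unique sequences, and
certainty ≤ −2. Otherwise the allele is assigned to its major anchor — a
gene observed on a chromosome sits on that chromosome — with the *deletion*
of the minor anchor recorded only when certainty ≥ +2, mirroring how
Bayes-factor certainty levels attach to deletion calls in chromosome
haplotyping practice; ties and alleles with fewer than 2 records stay
unknown. The minimum-minor-count rule exists because a single leaked
chimeric record must not flag a gene as shared; the thresholds' behaviour
is verified exhaustively against a direct binomial-likelihood oracle.

**Chimerism estimate.** Records whose V allele is single-anchor assigned
but whose own anchor is the opposite chromosome; the fraction over prepared
records recovers the planted surviving-chimera fraction to within a few
hundredths of a percentage point.

**Per-chromosome usage** weights unique sequences by duplicate count within
each anchor; shared alleles appear in both columns.

## Reference curation and evaluation

* **Truncated-record extension:** the truncated sequence is located inside
  each longer donor (≥ 95% identity over ≥ 100 nt); the best donor's flanks
  are copied, the record keeps its own bases, and provenance/donor/flank
  lengths are recorded. Trimming the recorded flanks restores the original
  (round-trip identity).
* **3' end confirmation:** under geometric trimming, genuine terminal
  positions are reached by ≥ P(trim = 0) ≈ 0.33 of assigned unmutated
  reads, while phantom positions are reached only by chance matches into
  the junction (~0.08–0.11 measured). Trailing positions reached by < 0.20
  of reads are trimmed. For extension, reads consuming the full reference
  vote on the next base; a dominant fraction ≥ 0.55 extends by one
  (iterated). The closed form for a 1-nt-short reference at trim mean 2 is
  (P0 + P1/4)/(P0 + P1) ≈ 0.70 against a ~0.25–0.35 null, which fixes the
  threshold between the two distributions; the widely-quoted 0.8 cut-off
  cannot fire under realistic trimming and was rejected. These thresholds
  assume trim means ≲ 4; the verdicts degrade to `inconclusive`/`confirmed`
  beyond that.
* **Mismatch histogram:** best-V mismatch counts (bins 0–30 and 30+),
  duplicate-count weighted. Deleting an allele moves its reads to a spike
  at its nearest-neighbour distance with mass equal to the allele's usage;
  adding alleles can only grow bin 0 (supersets never fit worse).
* **Assembly search:** exact full-length match (default) on either strand
  of any contig, with a near-match mode (`max_mismatches`).

## Problem sizes and defaults

The standard recovery study uses 50,000 reads per replicate (≈ 20,000
molecules), 2×100 V alleles with 4 shared, a planted novel 1-SNP variant at
~0.5% usage whose ancestral sequence sits in the starting reference, 20
decoy database alleles ≥ 3 substitutions from every planted sequence, and
ten seeds; the SNP-typing contrast uses 8,000 reads at (0.002, 0.01) noise;
the reference-completeness study uses 6,000 noise-free reads with an
isolated allele pair at distance 15. Under these conditions the pipeline
achieves pooled genotype sensitivity ≥ 0.95 for alleles at ≥ 0.05% usage
with zero false alleles, ≥ 98% haplotype assignment accuracy at n ≥ 8,
exact recovery of the four shared alleles, and chimerism recovery within
0.5 percentage points — the quantities `scripts/acceptance.py` recomputes.

## Known limitations

* The annotator assumes primer-anchored reads whose V region begins at the
  read start; it is not a general-purpose aligner (no CDR1/2 delineation,
  frame analysis, or species models).
* Novel-allele discovery is restricted to single-substitution V variants;
  multi-SNP phasing within one allele and D/J novelty are out of scope.
* The Bayesian genotype posterior of the published tooling is replaced by
  an explicit support-count contract (≥ 2 unique unmutated sequences),
  which is simpler and oracle-checkable but not a posterior.
* Strain labels are configuration, not biology: the pipeline is agnostic
  to which inbred strains are crossed as long as anchor SNPs exist.
* IgG1/IgG3 are not modelled (the underlying amplification was not
  optimised for them); IgG machinery covers subclass discovery and the
  IGHG2B SNPs only.
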