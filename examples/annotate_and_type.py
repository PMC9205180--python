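"""Annotate simulated reads and type their constant-region strain SNPs.

Each read is primer/UMI-trimmed, its V and J segments are called against the
germline reference, the constant region downstream of J is extracted,
indel-corrected against the reference exons and typed at the strain SNP;
the IGHJ1-vs-SNP concordance then measures pre-filter chimerism.
"""

import numpy as np

from ighvhaplo import (
    SimulationConfig,
    annotate_reads,
    build_parental_haplotypes,
    j_anchor_concordance,
    simulate_repertoire,
    trim_primer_umi,
    type_constant_regions,
)
from ighvhaplo.references import ReferenceSet
from ighvhaplo.simulate import PRIMER_3P, PRIMER_5P, planted_v_reference

config = SimulationConfig(n_reads=3000, n_v_alleles=30, seed=13)
hap_a, hap_b, c_refs, snps = build_parental_haplotypes(
    config, 0.0, np.random.default_rng(13)
)
dataset = simulate_repertoire(hap_a, hap_b, config, c_refs, snps)

trimmed, umis = [], {}
for read in dataset.reads:
    res = trim_primer_umi(
        read.raw_sequence(), PRIMER_5P, PRIMER_3P[read.isotype], config.umi_length
    )
    if res.ok:
        trimmed.append((read.read_id, res.sequence))
        umis[read.read_id] = res.umi
print(f"primer-trimmed {len(trimmed)}/{len(dataset.reads)} reads")

v_refs = planted_v_reference(hap_a, hap_b)
j_refs = ReferenceSet(
    {a.name: a for hap in (hap_a, hap_b) for a in hap.j_alleles}.values()
)
records = annotate_reads(trimmed, v_refs, j_refs, None, umis=umis, call_d=False)
records = type_constant_regions(records, dataset.c_references)

print(records[["sequence_id", "v_call", "j_call", "c_call", "x_v_mismatches"]].head(5))

called = (records["c_call"] != "").mean()
print(f"\nconstant-region strain call made for {called:.1%} of reads")

conc = j_anchor_concordance(records, {"IGHJ1*01": "BALB", "IGHJ1*03": "B6"})
for strain, v in conc.items():
    print(f"IGHJ1 vs IGHM-SNP concordance, {strain}: {v:.2%}")
print("One minus the concordance approximates the pre-filter template-switch")
print(f"rate (planted: {config.chimera_rate:.0%} on IgM reads).")
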