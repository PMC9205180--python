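"""End-to-end F1 germline-inference pipeline.

Chains the stages: primer/UMI trimming -> VDJ annotation -> constant-region
SNP typing -> filtering and unique-sequence collapsing -> novel-allele
discovery -> genotype calling -> allele reassignment -> anchor haplotyping
-> chimerism and per-chromosome usage estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import VSegmentCaller
from .annotate import annotate_reads, trim_primer_umi
from .constant import j_anchor_concordance, type_constant_regions
from .genotype import (
    InferenceParams,
    collapse_unique,
    filter_rearrangements,
    find_novel_alleles,
    infer_genotype,
)
from .haplotype import (
    HaplotypeParams,
    estimate_chimerism,
    infer_haplotype,
    prepare_haplotype_input,
    usage_by_chromosome,
)
from .references import ReferenceSet


@dataclass
class F1PipelineResult:
    records: pd.DataFrame  # per-read annotated + C-typed table
    collapsed: pd.DataFrame  # unique VDJ sequences (final allele calls)
    novel_alleles: list
    genotype: pd.DataFrame
    final_refs: ReferenceSet  # starting refs + accepted novel alleles
    prepared: pd.DataFrame
    haplotype: pd.DataFrame
    chimerism_fraction: float
    chimerism_count: int
    usage: pd.DataFrame
    concordance: dict
    n_raw: int = 0
    n_trimmed: int = 0
    logs: dict = field(default_factory=dict)


def _merge_novel_calls(df: pd.DataFrame, novels: list) -> pd.DataFrame:
    """Incremental re-annotation after adding novel alleles.

    Only records with at least one mismatch can improve; they are re-scored
    against the novel alleles alone and updated when a novel allele aligns
    strictly better (or ties the current best).
    """
    if not novels:
        return df
    caller = VSegmentCaller(novels)
    out = df.copy()
    mask = out["x_v_mismatches"] != 0
    for idx in out.index[mask]:
        seq = out.at[idx, "sequence"]
        cur = out.at[idx, "x_v_mismatches"]
        v = caller.call(seq)
        if not v.called:
            continue
        if cur < 0 or v.mismatches < cur:
            out.at[idx, "v_call"] = v.call_string
            out.at[idx, "x_v_mismatches"] = v.mismatches
            out.at[idx, "x_v_germline_start"] = v.germline_start + 1
            out.at[idx, "x_v_germline_end"] = v.germline_end
            lead = caller.alleles[caller.names.index(v.names[0])]
            out.at[idx, "x_v_mutations"] = ",".join(
                f"{lead.sequence[p]}{p + 1}{b}" for p, b in v.substitutions
            )
        elif v.mismatches == cur:
            names = sorted(set(out.at[idx, "v_call"].split(",")) | set(v.names))
            out.at[idx, "v_call"] = ",".join(names)
    return out


def _restrict_to_present(df: pd.DataFrame, present: ReferenceSet) -> pd.DataFrame:
    """Reassign records so that only genotype-present alleles are called."""
    out = df.copy()
    present_names = set(present.names)
    caller = None
    for idx in out.index:
        calls = out.at[idx, "v_call"]
        if not calls:
            continue
        names = calls.split(",")
        kept = [n for n in names if n in present_names]
        if len(kept) == len(names):
            continue
        if kept and names[0] in kept:
            out.at[idx, "v_call"] = ",".join(sorted(kept))
            continue
        if caller is None:
            caller = VSegmentCaller(present)
        v = caller.call(out.at[idx, "sequence"])
        if v.called:
            out.at[idx, "v_call"] = v.call_string
            out.at[idx, "x_v_mismatches"] = v.mismatches
            out.at[idx, "x_v_germline_start"] = v.germline_start + 1
            out.at[idx, "x_v_germline_end"] = v.germline_end
        else:
            out.at[idx, "v_call"] = ""
            out.at[idx, "x_v_mismatches"] = -1
    return out


def run_f1_pipeline(
    raw_reads,
    v_refs: ReferenceSet,
    j_refs: ReferenceSet,
    d_refs: ReferenceSet | None,
    c_references: dict,
    anchor_a: str,
    anchor_b: str,
    j_anchor_map: dict | None = None,
    primer_5p: str | None = None,
    primer_3p: list | None = None,
    umi_length: int = 16,
    params: InferenceParams | None = None,
    hap_params: HaplotypeParams | None = None,
    detect_novel: bool = True,
    call_d: bool = True,
) -> F1PipelineResult:
    """Run the complete inference on raw (id, sequence) reads.

    ``primer_3p`` may list several reverse primers (one per isotype library);
    each read is trimmed with the first primer pair that locates.  When
    ``primer_5p`` is None the reads are assumed already primer-trimmed and
    UMI-free.
    """
    params = params or InferenceParams()
    hap_params = hap_params or HaplotypeParams()
    raw_reads = list(raw_reads)

    trimmed = []
    umis = {}
    n_excluded = 0
    if primer_5p is None:
        trimmed = [(rid, seq.lower()) for rid, seq in raw_reads]
    else:
        for rid, seq in raw_reads:
            res = None
            for p3 in primer_3p or []:
                r = trim_primer_umi(seq, primer_5p, p3, umi_length)
                if r.ok:
                    res = r
                    break
            if res is None:
                n_excluded += 1
                continue
            trimmed.append((rid, res.sequence))
            umis[rid] = res.umi

    records = annotate_reads(trimmed, v_refs, j_refs, d_refs, umis=umis, call_d=call_d)
    records = type_constant_regions(records, c_references)
    concordance = {}
    if j_anchor_map:
        try:
            concordance = j_anchor_concordance(records, j_anchor_map)
        except ValueError:
            concordance = {}

    filtered = filter_rearrangements(records)
    collapsed = collapse_unique(filtered)

    novels = []
    if detect_novel:
        novels = find_novel_alleles(collapsed, v_refs, params)
    final_refs = ReferenceSet(list(v_refs), label=v_refs.label or "final")
    for a in novels:
        final_refs.add(a)
    collapsed = _merge_novel_calls(collapsed, novels)

    genotype = infer_genotype(collapsed, final_refs, params)
    present_names = [n for n in genotype.loc[genotype["present"], "allele"]]
    present = final_refs.subset(present_names, label="genotype")
    if len(present):
        collapsed = _restrict_to_present(collapsed, present)

    prepared = prepare_haplotype_input(collapsed, anchor_a, anchor_b)
    haplotype = infer_haplotype(prepared, anchor_a, anchor_b, hap_params)
    chim_frac, chim_count = estimate_chimerism(prepared, haplotype, anchor_a, anchor_b)
    usage = usage_by_chromosome(prepared, haplotype, anchor_a, anchor_b)

    return F1PipelineResult(
        records=records,
        collapsed=collapsed,
        novel_alleles=novels,
        genotype=genotype,
        final_refs=final_refs,
        prepared=prepared,
        haplotype=haplotype,
        chimerism_fraction=chim_frac,
        chimerism_count=chim_count,
        usage=usage,
        concordance=concordance,
        n_raw=len(raw_reads),
        n_trimmed=len(trimmed),
        logs={"n_primer_excluded": n_excluded},
    )
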