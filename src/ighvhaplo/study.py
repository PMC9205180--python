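"""Parameter-recovery studies on synthetic F1 repertoires.

These functions set up the standard synthetic study conditions (two parental
haplotypes of 100 V alleles with four shared, usage 0.01%-5%, one planted
novel 1-SNP variant absent from the starting reference, 14% template-switch
rate, CCS-like noise), run the full inference pipeline, and score every
stage against the planted truth.  They are the substrate for the acceptance
checks and for the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constant import type_uncorrected
from .curation import mismatch_distribution
from .genotype import filter_rearrangements
from .pipeline import F1PipelineResult, run_f1_pipeline
from .references import GermlineAllele, ReferenceSet
from .simulate import (
    PRIMER_3P,
    PRIMER_5P,
    SimulationConfig,
    build_annotation_reference,
    build_parental_haplotypes,
    planted_v_reference,
    simulate_repertoire,
)


@dataclass
class StudyResult:
    seed: int
    sensitivity: float
    n_recoverable: int
    n_recovered: int
    n_false_alleles: int
    haplotype_accuracy: float
    n_haplotype_scored: int
    both_called: list
    shared_planted: list
    novel_detected: bool
    chimerism_estimate: float
    chimerism_truth: float
    concordance: dict
    snp_accuracy_corrected: float
    snp_accuracy_uncorrected: float
    n_prepared: int
    pipeline: F1PipelineResult | None = None
    extras: dict = field(default_factory=dict)


def _plant_novel_variant(hap, rng, target_usage=0.005):
    """Swap one strain-private allele for a 1-SNP variant of itself.

    The variant becomes the expressed (planted) allele; the original
    sequence is returned for inclusion in the starting reference, so the
    pipeline must rediscover the variant as a novel allele.
    """
    shared_names = {
        a.name for a in hap.v_alleles if "," in (a.metadata.get("strain") or "")
    }
    private = [a for a in hap.v_alleles if a.name not in shared_names]
    pick = min(private, key=lambda a: abs(hap.usage_weights[a.name] - target_usage))
    cys = pick.cys_position or (len(pick.sequence) - 15)
    pos = 150
    while cys <= pos < cys + 3:
        pos += 3
    alts = [b for b in "acgt" if b != pick.sequence[pos]]
    newb = alts[int(rng.integers(3))]
    variant_seq = pick.sequence[:pos] + newb + pick.sequence[pos + 1 :]
    variant = GermlineAllele(
        name=f"{pick.name}_planted_variant",
        segment="V",
        sequence=variant_seq,
        metadata=dict(pick.metadata),
    )
    idx = hap.v_alleles.index(pick)
    hap.v_alleles[idx] = variant
    hap.usage_weights[variant.name] = hap.usage_weights.pop(pick.name)
    return pick, variant


def build_study(
    seed: int, n_reads: int = 50_000, plant_novel: bool = True, **config_overrides
):
    """Standard study setup: haplotypes, dataset, references, anchors."""
    config = SimulationConfig(seed=seed, n_reads=n_reads, **config_overrides)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9151]))
    hap_a, hap_b, crefs, snps = build_parental_haplotypes(config, 0.04, rng)
    if plant_novel:
        parent, variant = _plant_novel_variant(hap_a, rng)
        hold_out, extra = [variant.name], [parent]
    else:
        parent = variant = None
        hold_out, extra = [], []
    refs = build_annotation_reference(
        hap_a,
        hap_b,
        rng,
        hold_out=hold_out,
        add_sequences=extra,
        n_decoys=20,
    )
    dataset = simulate_repertoire(hap_a, hap_b, config, crefs, snps)
    meta = {
        "parent": parent,
        "variant": variant,
        "refs": refs,
        "crefs": crefs,
        "snps": snps,
    }
    return dataset, meta


def _j_refs(dataset) -> ReferenceSet:
    refs = ReferenceSet(label="J")
    for hap in (dataset.hap_a, dataset.hap_b):
        for a in hap.j_alleles:
            if a.name not in refs:
                refs.add(a)
    return refs


def _d_refs(dataset) -> ReferenceSet:
    refs = ReferenceSet(label="D")
    for a in dataset.hap_a.d_alleles:
        refs.add(a)
    return refs


def run_f1_study(
    seed: int,
    n_reads: int = 50_000,
    usage_threshold: float = 5e-4,
    min_haplotype_records: int = 8,
    keep_pipeline: bool = False,
    plant_novel: bool = True,
    **config_overrides,
) -> StudyResult:
    """Simulate one F1 dataset and score full-pipeline recovery."""
    dataset, meta = build_study(seed, n_reads, plant_novel=plant_novel, **config_overrides)
    hap_a, hap_b = dataset.hap_a, dataset.hap_b
    sa, sb = dataset.config.strain_labels
    anchor_a, anchor_b = f"IgM*{sa}", f"IgM*{sb}"
    j_map = {"IGHJ1*01": sa, "IGHJ1*03": sb}

    raw = [(r.read_id, r.raw_sequence()) for r in dataset.reads]
    result = run_f1_pipeline(
        raw,
        meta["refs"],
        _j_refs(dataset),
        _d_refs(dataset),
        dataset.c_references,
        anchor_a,
        anchor_b,
        j_anchor_map=j_map,
        primer_5p=PRIMER_5P,
        primer_3p=list(PRIMER_3P.values()),
        umi_length=dataset.config.umi_length,
        call_d=False,
    )

    # ---- truth maps -------------------------------------------------
    planted_seq_to_name = {}
    planted_strains: dict[str, set] = {}
    usage: dict[str, float] = {}
    for hap in (hap_a, hap_b):
        for a in hap.v_alleles:
            planted_seq_to_name[a.sequence] = a.name
            planted_strains.setdefault(a.name, set()).add(hap.strain_label)
            usage[a.name] = max(usage.get(a.name, 0.0), hap.usage_weights[a.name])
    shared_planted = sorted(n for n, s in planted_strains.items() if len(s) == 2)

    ref_seq = {a.name: a.sequence for a in result.final_refs}

    # ---- genotype recovery -----------------------------------------
    present = result.genotype.loc[result.genotype["present"], "allele"]
    present_seqs = {ref_seq[n] for n in present}
    planted_seqs = set(planted_seq_to_name)
    recoverable = [
        n for n, u in usage.items() if u >= usage_threshold
    ]
    seq_of = {n: a.sequence for hap in (hap_a, hap_b) for a in hap.v_alleles for n in [a.name]}
    recovered = [n for n in recoverable if seq_of[n] in present_seqs]
    n_false = len(present_seqs - planted_seqs)

    # ---- haplotype scoring -----------------------------------------
    anchor_of_strain = {sa: anchor_a, sb: anchor_b}
    n_scored = 0
    n_correct = 0
    both_called = []
    for _, row in result.haplotype.iterrows():
        name = row["v_allele"]
        seq = ref_seq.get(name)
        truth_name = planted_seq_to_name.get(seq)
        if row["assignment"] == "both":
            both_called.append(name)
        if truth_name is None:
            continue
        if row["count_a"] + row["count_b"] < min_haplotype_records:
            continue
        n_scored += 1
        strains = planted_strains[truth_name]
        if len(strains) == 2:
            n_correct += int(row["assignment"] == "both")
        else:
            expected = f"{anchor_of_strain[next(iter(strains))]}_only"
            n_correct += int(row["assignment"] == expected)

    # ---- chimerism truth -------------------------------------------
    chim_truth = _chimerism_truth(
        result.prepared, planted_seq_to_name, planted_strains, ref_seq, anchor_a, anchor_b, sa, sb
    )

    # ---- SNP typing accuracy ---------------------------------------
    corr_acc, uncorr_acc = _snp_accuracies(result.records, dataset)

    novel_detected = meta["variant"] is not None and any(
        a.sequence == meta["variant"].sequence for a in result.novel_alleles
    )
    both_named_as_planted = sorted(
        planted_seq_to_name.get(ref_seq.get(n, ""), n) for n in both_called
    )

    return StudyResult(
        seed=seed,
        sensitivity=len(recovered) / len(recoverable) if recoverable else float("nan"),
        n_recoverable=len(recoverable),
        n_recovered=len(recovered),
        n_false_alleles=n_false,
        haplotype_accuracy=n_correct / n_scored if n_scored else float("nan"),
        n_haplotype_scored=n_scored,
        both_called=both_named_as_planted,
        shared_planted=shared_planted,
        novel_detected=novel_detected,
        chimerism_estimate=result.chimerism_fraction,
        chimerism_truth=chim_truth,
        concordance=result.concordance,
        snp_accuracy_corrected=corr_acc,
        snp_accuracy_uncorrected=uncorr_acc,
        n_prepared=len(result.prepared),
        pipeline=result if keep_pipeline else None,
        extras={"n_novel_candidates": len(result.novel_alleles)},
    )


def _chimerism_truth(
    prepared, planted_seq_to_name, planted_strains, ref_seq, anchor_a, anchor_b, sa, sb
) -> float:
    """Fraction of prepared records whose anchor call contradicts the
    planted chromosome of their V allele (i.e. surviving chimeras)."""
    if prepared.empty:
        return 0.0
    strain_of_anchor = {anchor_a: sa, anchor_b: sb}
    n_bad = 0
    for v, c in zip(prepared["v_call"], prepared["c_call"]):
        seq = ref_seq.get(v)
        truth_name = planted_seq_to_name.get(seq)
        if truth_name is None:
            continue
        strains = planted_strains[truth_name]
        if len(strains) == 1 and strain_of_anchor.get(c) not in strains:
            n_bad += 1
    return n_bad / len(prepared)


def _snp_accuracies(records: pd.DataFrame, dataset) -> tuple[float, float]:
    """Strain-call accuracy (among calls made) on non-chimeric IgM reads,
    with and without indel correction."""
    truth = dataset.truth_by_id()
    uncorr = type_uncorrected(records, dataset.c_references)
    n_c = n_c_ok = n_u = n_u_ok = 0
    for rid, c_call, u_call in zip(records["sequence_id"], records["c_call"], uncorr):
        t = truth.get(rid)
        if t is None or t.is_chimera or t.isotype != "IgM":
            continue
        expected = f"IgM*{t.chromosome}"
        if c_call:
            n_c += 1
            n_c_ok += int(c_call == expected)
        if u_call:
            n_u += 1
            n_u_ok += int(u_call == expected)
    return (
        n_c_ok / n_c if n_c else float("nan"),
        n_u_ok / n_u if n_u else float("nan"),
    )


# ---------------------------------------------------------------------------
# reference-completeness (mismatch-histogram) study


@dataclass
class ReferenceEvaluationResult:
    removed_allele: str
    neighbor_distance: int
    spike_mass: float
    expected_mass: float
    se: float
    bin0_with: float
    bin0_without: float
    spike_with: float


def run_reference_evaluation_study(
    seed: int, n_reads: int = 6000, distance: int = 15, target_usage: float = 0.02
) -> ReferenceEvaluationResult:
    """Delete one planted allele from the reference and measure the
    mismatch-histogram spike at its nearest-neighbor distance.

    Run under noise-free conditions so every read of the deleted allele
    lands exactly at the planted pairwise distance.
    """
    config = SimulationConfig(
        seed=seed,
        n_reads=n_reads,
        n_v_alleles=20,
        chimera_rate=0.0,
        subst_error_rate=0.0,
        homopolymer_indel_rate=0.0,
        p_unmutated_igm=1.0,
        p_truncate_5p=0.0,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 40923]))
    hap_a, hap_b, crefs, snps = build_parental_haplotypes(config, 0.0, rng)

    # craft an isolated target/neighbor pair at the requested distance: the
    # target is scrambled far away from every family so its nearest
    # neighbor is the crafted variant
    base = hap_a.v_alleles[0]
    cys = base.cys_position or (len(base.sequence) - 15)
    safe = [p for p in range(0, len(base.sequence) - 12) if not cys <= p < cys + 3]

    def _mutate_at(seq, positions):
        seq = list(seq)
        for p in positions:
            alts = [b for b in "acgt" if b != seq[p]]
            seq[p] = alts[int(rng.integers(3))]
        return "".join(seq)

    target_seq = _mutate_at(
        base.sequence, rng.choice(safe, size=len(safe) // 2, replace=False)
    )
    target = GermlineAllele(
        name="IGHVtgt-1*01", segment="V", sequence=target_seq,
        metadata=dict(base.metadata),
    )
    hap_a.v_alleles[0] = target
    hap_a.usage_weights[target.name] = hap_a.usage_weights.pop(base.name)
    inner = [p for p in safe if p >= 20]
    neighbor = GermlineAllele(
        name="IGHVnbr-1*01",
        segment="V",
        sequence=_mutate_at(target_seq, rng.choice(inner, size=distance, replace=False)),
        metadata=dict(base.metadata),
    )
    displaced = hap_a.v_alleles[1]
    hap_a.v_alleles[1] = neighbor
    hap_a.usage_weights.pop(displaced.name)
    hap_a.usage_weights[neighbor.name] = target_usage
    hap_a.usage_weights[target.name] = target_usage
    v_names = [a.name for a in hap_a.v_alleles]
    tot = sum(hap_a.usage_weights[n] for n in v_names)
    for n in v_names:
        hap_a.usage_weights[n] /= tot

    dataset = simulate_repertoire(hap_a, hap_b, config, crefs, snps)
    refs = planted_v_reference(hap_a, hap_b)
    raw = [(r.read_id, r.raw_sequence()) for r in dataset.reads]

    from .annotate import annotate_reads, trim_primer_umi

    trimmed = []
    for rid, s in raw:
        res = trim_primer_umi(s, PRIMER_5P, PRIMER_3P["IgM"], config.umi_length)
        if res.ok:
            trimmed.append((rid, res.sequence))
    records = annotate_reads(trimmed, refs, _j_refs(dataset), None, call_d=False)
    records = filter_rearrangements(records)

    hist_with = mismatch_distribution(records, refs)
    reduced = ReferenceSet(
        [a for a in refs if a.name != target.name], label="reduced"
    )
    hist_without = mismatch_distribution(records, reduced)

    truth = dataset.truth_by_id()
    n_target = sum(
        1 for rid in records["sequence_id"] if truth[rid].v_call == target.name
    )
    expected = n_target / len(records)
    se = np.sqrt(expected * (1 - expected) / len(records))
    return ReferenceEvaluationResult(
        removed_allele=target.name,
        neighbor_distance=distance,
        spike_mass=float(hist_without.fractions[distance]),
        expected_mass=float(expected),
        se=float(se),
        bin0_with=hist_with.bin0,
        bin0_without=hist_without.bin0,
        spike_with=float(hist_with.fractions[distance]),
    )


# ---------------------------------------------------------------------------
# constant-region SNP-typing study


def run_snp_typing_study(
    seed: int,
    n_reads: int = 8000,
    subst_error_rate: float = 0.002,
    homopolymer_indel_rate: float = 0.01,
) -> tuple[float, float]:
    """Strain-call accuracy with vs without indel correction.

    Simulates an IgM dataset at the given platform noise rates, annotates
    it, and types the constant-region SNP two ways: positionally on the
    corrected segment, and positionally on the raw segment.  Returns the
    (corrected, uncorrected) accuracies among calls made on non-chimeric
    reads; the gap measures what homopolymer indels do to naive positional
    extraction.
    """
    from .annotate import annotate_reads, trim_primer_umi

    config = SimulationConfig(
        seed=seed,
        n_reads=n_reads,
        n_v_alleles=30,
        subst_error_rate=subst_error_rate,
        homopolymer_indel_rate=homopolymer_indel_rate,
        chimera_rate=0.0,
        chimera_molecule_rate=0.0,
        p_truncate_5p=0.0,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 777]))
    hap_a, hap_b, crefs, snps = build_parental_haplotypes(config, 0.0, rng)
    dataset = simulate_repertoire(hap_a, hap_b, config, crefs, snps)
    trimmed = []
    for r in dataset.reads:
        res = trim_primer_umi(
            r.raw_sequence(), PRIMER_5P, PRIMER_3P[r.isotype], config.umi_length
        )
        if res.ok:
            trimmed.append((r.read_id, res.sequence))
    refs = planted_v_reference(hap_a, hap_b)
    j_refs = _j_refs(dataset)
    records = annotate_reads(trimmed, refs, j_refs, None, call_d=False)
    from .constant import type_constant_regions

    records = type_constant_regions(records, dataset.c_references)
    return _snp_accuracies(records, dataset)
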