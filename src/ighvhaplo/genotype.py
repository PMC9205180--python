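"""Genotype inference: filtering, unique-sequence collapsing, novel-allele
discovery and presence/absence calling.

Novel V alleles are detected with a mutation-load regression: for a candidate
substitution that is really a germline polymorphism, the fraction of an
allele's sequences carrying it is high even among sequences with no other
mutations, so a straight-line fit of carrier fraction against total mutation
load has a large y-intercept; somatic hypermutation instead accumulates with
load and extrapolates to ~0 at zero mutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import VSegmentCaller
from .references import GermlineAllele, ReferenceSet


@dataclass
class InferenceParams:
    germline_min: int = 50
    min_seqs: int = 10
    intercept_threshold: float = 0.125
    genotype_min_support: int = 2
    unmutated_max_mismatches: int = 0
    max_load: int = 10
    min_position_coverage: int = 10

    def __post_init__(self):
        if min(self.germline_min, self.min_seqs, self.genotype_min_support) < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 < self.intercept_threshold < 1.0:
            raise ValueError("intercept_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# record-level filters


def filter_rearrangements(df: pd.DataFrame) -> pd.DataFrame:
    """Drop 5'-truncated records and those lacking a junction or a J call."""
    keep = (
        df["x_complete_vdj"].astype(bool)
        & (df["junction"] != "")
        & (df["j_call"] != "")
    )
    return df[keep].reset_index(drop=True)


def collapse_unique(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse to unique VDJ nucleotide sequences.

    The collapse key is the read portion from the V start through the final
    J nucleotide (the constant region is excluded, so identical
    rearrangements expressed with either constant allele collapse together).
    ``duplicate_count`` sums member counts; the representative keeps the
    lexicographically smallest sequence_id; member constant-region strain
    calls are aggregated into ``x_c_calls`` (ambiguous when both anchors
    were observed for one VDJ sequence).
    """
    if df.empty:
        out = df.copy()
        out["x_vdj"] = pd.Series(dtype=str)
        out["x_c_calls"] = pd.Series(dtype=str)
        out["x_c_call_count"] = pd.Series(dtype=int)
        return out
    work = df.copy()
    work["x_vdj"] = [
        s[:je] if je and je > 0 else s
        for s, je in zip(work["sequence"], work["j_sequence_end"])
    ]
    if "duplicate_count" not in work.columns:
        work["duplicate_count"] = 1
    if "c_call" not in work.columns:
        work["c_call"] = ""
    work = work.sort_values("sequence_id", kind="mergesort")
    reps = work.drop_duplicates("x_vdj", keep="first").set_index("x_vdj")
    reps["duplicate_count"] = work.groupby("x_vdj")["duplicate_count"].sum()
    # member constant-region call tally per unique VDJ sequence
    called = work[work["c_call"] != ""]
    if called.empty:
        reps["x_c_calls"] = ""
        reps["c_call"] = ""
        reps["x_c_call_count"] = 0
    else:
        tally = pd.crosstab(called["x_vdj"], called["c_call"])
        n_kinds = (tally > 0).sum(axis=1)
        joined = tally.apply(
            lambda row: ";".join(sorted(c for c in row.index if row[c] > 0)), axis=1
        )
        unique_call = tally.idxmax(axis=1).where(n_kinds == 1, "")
        # anchor-call confirmation: the largest number of identically-typed
        # member reads sharing one UMI, i.e. independent re-reads of the
        # same molecule.  Two PCR chimeras that happen to coincide on the
        # same VDJ sequence carry different UMIs and cannot fake this.
        if "x_umi" in called.columns and called["x_umi"].ne("").any():
            per_umi = (
                called.groupby(["x_vdj", "c_call", "x_umi"], sort=False)
                .size()
                .groupby(level=[0, 1])
                .max()
                .groupby(level=0)
                .max()
            )
        else:
            per_umi = tally.max(axis=1)
        counts = per_umi.where(n_kinds == 1, 0)
        reps["x_c_calls"] = joined.reindex(reps.index, fill_value="")
        reps["c_call"] = unique_call.reindex(reps.index, fill_value="")
        reps["x_c_call_count"] = (
            counts.reindex(reps.index, fill_value=0).astype(int)
        )
    out = reps.reset_index()
    cols = [c for c in out.columns if c != "x_vdj"] + ["x_vdj"]
    return out[cols].sort_values("sequence_id").reset_index(drop=True)


def select_unmutated(df: pd.DataFrame, params: InferenceParams | None = None) -> pd.DataFrame:
    params = params or InferenceParams()
    return df[
        (df["x_v_mismatches"] >= 0)
        & (df["x_v_mismatches"] <= params.unmutated_max_mismatches)
    ].reset_index(drop=True)


# ---------------------------------------------------------------------------
# novel allele discovery


def _parse_mutations(s: str):
    """'a100g,c150t' -> [(99, 'a', 'g'), (149, 'c', 't')] (0-based)."""
    if not s:
        return []
    out = []
    for tok in s.split(","):
        ref = tok[0]
        new = tok[-1]
        pos = int(tok[1:-1]) - 1
        out.append((pos, ref, new))
    return out


def find_novel_alleles(
    df: pd.DataFrame, refs: ReferenceSet, params: InferenceParams | None = None
) -> list[GermlineAllele]:
    """Candidate unreported germline V alleles from mutation-load regression.

    For each reference allele with >= ``germline_min`` assigned unique
    sequences, each recurrent substitution's carrier fraction is regressed
    against total V mutation load over loads 1..``max_load``; substitutions
    with fitted intercept >= ``intercept_threshold`` that are carried by >=
    ``min_seqs`` otherwise-unmutated sequences become candidate alleles
    (the reference with that substitution applied), deduplicated against the
    reference set.
    """
    params = params or InferenceParams()
    # unambiguous single-allele assignments only
    sub = df[(~df["v_call"].str.contains(",")) & (df["v_call"] != "")]
    known = {a.sequence for a in refs}
    candidates: list[GermlineAllele] = []
    skipped = []
    for allele_name, grp in sub.groupby("v_call"):
        if allele_name not in refs:
            continue
        if len(grp) < params.germline_min:
            skipped.append(allele_name)
            continue
        ref = refs[allele_name]
        fit = grp[(grp["x_v_mismatches"] >= 1) & (grp["x_v_mismatches"] <= params.max_load)]
        if fit.empty:
            continue
        loads = fit["x_v_mismatches"].to_numpy()
        # per-load sequence counts and per-(position,base) carrier counts
        n_by_load = pd.Series(loads).value_counts().to_dict()
        carriers: dict[tuple, dict] = {}
        carrier_load1: dict[tuple, int] = {}
        for load, muts, gend in zip(
            loads, fit["x_v_mutations"], fit["x_v_germline_end"]
        ):
            for pos, refb, newb in _parse_mutations(muts):
                key = (pos, refb, newb)
                carriers.setdefault(key, {})
                carriers[key][load] = carriers[key].get(load, 0) + 1
                if load == 1:
                    carrier_load1[key] = carrier_load1.get(key, 0) + 1
        # coverage per load bin at each position: sequences must reach it
        gends = fit["x_v_germline_end"].to_numpy()
        for (pos, refb, newb), by_load in carriers.items():
            n_l1 = carrier_load1.get((pos, refb, newb), 0)
            if n_l1 < params.min_seqs:
                continue
            xs, ys, ws = [], [], []
            for load in sorted(n_by_load):
                cov = int(np.sum((loads == load) & (gends > pos)))
                if cov < params.min_position_coverage:
                    continue
                xs.append(load)
                ys.append(by_load.get(load, 0) / cov)
                ws.append(cov)
            if len(xs) < 1:
                continue
            if len(xs) == 1:
                intercept = ys[0]  # single informative bin: use it directly
            else:
                slope, intercept = np.polyfit(xs, ys, 1, w=np.sqrt(ws))
            if intercept < params.intercept_threshold:
                continue
            if ref.sequence[pos] != refb:
                continue
            seq = ref.sequence[:pos] + newb + ref.sequence[pos + 1 :]
            if seq in known:
                continue
            known.add(seq)
            candidates.append(
                GermlineAllele(
                    name=f"{allele_name}_{refb.upper()}{pos + 1}{newb.upper()}",
                    segment="V",
                    sequence=seq,
                    provenance="inferred",
                    metadata=dict(ref.metadata),
                )
            )
    return candidates


# ---------------------------------------------------------------------------
# genotype calling and reassignment


def infer_genotype(
    df: pd.DataFrame, refs: ReferenceSet, params: InferenceParams | None = None
) -> pd.DataFrame:
    """Presence/absence genotype over a candidate allele set.

    An allele is present when supported by >= ``genotype_min_support``
    unique unmutated sequences for which it is a (tied-)best match.
    Single-sequence alleles are retained as provisional entries with
    ``present=False``.
    """
    params = params or InferenceParams()
    support: dict[str, int] = {}
    total: dict[str, int] = {}
    freq: dict[str, float] = {}
    total_reads = float(df["duplicate_count"].sum()) or 1.0
    for calls, mm, dup in zip(
        df["v_call"], df["x_v_mismatches"], df["duplicate_count"]
    ):
        if not calls:
            continue
        names = calls.split(",")
        for n in names:
            total[n] = total.get(n, 0) + 1
            freq[n] = freq.get(n, 0.0) + dup / total_reads
            if mm == 0:
                support[n] = support.get(n, 0) + 1
    rows = []
    for name in refs.names:
        s = support.get(name, 0)
        if s == 0:
            continue
        rows.append(
            {
                "allele": name,
                "unmutated_support": s,
                "total_support": total.get(name, 0),
                "frequency": freq.get(name, 0.0),
                "present": s >= params.genotype_min_support,
                "note": "" if s >= params.genotype_min_support else "provisional_single_sequence",
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "allele",
            "unmutated_support",
            "total_support",
            "frequency",
            "present",
            "note",
        ],
    )
    return out.sort_values("frequency", ascending=False).reset_index(drop=True)


def reassign_alleles(
    df: pd.DataFrame, alleles: ReferenceSet, caller: VSegmentCaller | None = None
) -> pd.DataFrame:
    """Re-annotate V calls against a restricted allele set.

    Records keep their row identity; ``v_call``, mismatch counts, germline
    coordinates and mutation strings are recomputed against the given set.
    """
    if caller is None:
        caller = VSegmentCaller(alleles)
    out = df.copy()
    v_calls, mms, gstarts, gends, muts = [], [], [], [], []
    for seq in out["sequence"]:
        v = caller.call(seq)
        if not v.called:
            v_calls.append("")
            mms.append(-1)
            gstarts.append(0)
            gends.append(0)
            muts.append("")
            continue
        v_calls.append(v.call_string)
        mms.append(v.mismatches)
        gstarts.append(v.germline_start + 1)
        gends.append(v.germline_end)
        lead = caller.alleles[caller.names.index(v.names[0])]
        muts.append(
            ",".join(f"{lead.sequence[p]}{p + 1}{b}" for p, b in v.substitutions)
        )
    out["v_call"] = v_calls
    out["x_v_mismatches"] = mms
    out["x_v_germline_start"] = gstarts
    out["x_v_germline_end"] = gends
    out["x_v_mutations"] = muts
    return out
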