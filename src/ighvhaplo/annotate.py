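"""Germline-guided annotation of primer-trimmed long reads.

Produces AIRR-style rearrangement records (a pandas DataFrame with AIRR
Rearrangement column names; tool-specific columns carry an ``x_`` prefix).
File coordinates are 1-based inclusive per the AIRR standard; everything
internal is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import pandas as pd

from .align import SegmentCall, VSegmentCaller, align_segment, call_d_segment
from .references import ReferenceSet
from .simulate import revcomp

AIRR_COLUMNS = [
    "sequence_id",
    "sequence",
    "v_call",
    "d_call",
    "j_call",
    "c_call",
    "junction",
    "v_sequence_start",
    "v_sequence_end",
    "j_sequence_start",
    "j_sequence_end",
    "duplicate_count",
    "x_umi",
    "x_v_mismatches",
    "x_v_germline_start",
    "x_v_germline_end",
    "x_v_mutations",
    "x_complete_vdj",
]

MANDATORY_COLUMNS = [
    "sequence_id",
    "sequence",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "v_sequence_start",
    "v_sequence_end",
    "j_sequence_start",
    "j_sequence_end",
]


@dataclass
class TrimResult:
    sequence: str
    umi: str
    status: str  # "ok" | "too_short" | "primer_not_found"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _locate(pattern: str, seq: str, max_mismatches: int) -> tuple[int, int] | None:
    res = edlib.align(pattern, seq, mode="HW", task="locations")
    if res["editDistance"] > max_mismatches:
        return None
    s, e = res["locations"][0]
    return s, e + 1


def trim_primer_umi(
    raw: str,
    primer_5p: str,
    primer_3p: str,
    umi_length: int,
    max_mismatches: int = 2,
) -> TrimResult:
    """Strip the UMI and locate/remove both primers (<=2 mismatches).

    The read layout is ``UMI + primer_5p + insert + revcomp(primer_3p)``.
    Reads too short to contain both primers plus the UMI, or in which a
    primer cannot be located, are flagged and excluded downstream.
    """
    if not primer_5p or not primer_3p:
        raise ValueError("primers must be non-empty")
    raw = raw.lower()
    if len(raw) < umi_length + len(primer_5p) + len(primer_3p):
        return TrimResult("", "", "too_short")
    umi = raw[:umi_length]
    body = raw[umi_length:]
    loc5 = _locate(primer_5p, body[: len(primer_5p) + 16], max_mismatches)
    if loc5 is None:
        return TrimResult("", umi, "primer_not_found")
    tail_window = len(primer_3p) + 16
    loc3 = _locate(revcomp(primer_3p), body[-tail_window:], max_mismatches)
    if loc3 is None:
        return TrimResult("", umi, "primer_not_found")
    start = loc5[1]
    end = len(body) - tail_window + loc3[0]
    if end <= start:
        return TrimResult("", umi, "too_short")
    return TrimResult(body[start:end], umi, "ok")


# ---------------------------------------------------------------------------


def annotate_read(
    seq: str,
    v_caller: VSegmentCaller,
    j_refs: ReferenceSet,
    d_refs: ReferenceSet | None,
    j_window: int = 160,
    call_d: bool = True,
) -> dict:
    """Annotate one primer-trimmed read; returns an AIRR-style record dict."""
    rec = {
        "sequence": seq,
        "v_call": "",
        "d_call": "",
        "j_call": "",
        "c_call": "",
        "junction": "",
        "v_sequence_start": 0,
        "v_sequence_end": 0,
        "j_sequence_start": 0,
        "j_sequence_end": 0,
        "duplicate_count": 1,
        "x_v_mismatches": -1,
        "x_v_germline_start": 0,
        "x_v_germline_end": 0,
        "x_v_mutations": "",
        "x_complete_vdj": False,
    }
    v = v_caller.call(seq)
    if not v.called:
        return rec
    rec["v_call"] = v.call_string
    rec["v_sequence_start"] = v.read_start + 1
    rec["v_sequence_end"] = v.read_end
    rec["x_v_mismatches"] = v.mismatches
    rec["x_v_germline_start"] = v.germline_start + 1
    rec["x_v_germline_end"] = v.germline_end
    rec["x_v_mutations"] = ",".join(
        f"{v_caller.alleles[v_caller.names.index(v.names[0])].sequence[p]}{p + 1}{b}"
        for p, b in v.substitutions
    )

    window_start = v.read_end
    window = seq[window_start : window_start + j_window]
    if len(window) >= 20:
        j = align_segment(window, j_refs, segment="J")
    else:
        j = SegmentCall()
    if not j.called:
        return rec
    j_start = window_start + j.read_start
    j_end = window_start + j.read_end
    rec["j_call"] = j.call_string
    rec["j_sequence_start"] = j_start + 1
    rec["j_sequence_end"] = j_end

    # junction: conserved V cysteine codon .. the J tryptophan (tgggg) anchor
    lead = v_caller.alleles[v_caller.names.index(v.names[0])]
    cys = lead.cys_position
    junction = ""
    if cys is not None and cys < v.germline_end and v.germline_start <= cys:
        if v.q2t is None:
            cys_read = cys - v.germline_start
        else:
            cys_read = int(v.q2t[cys]) if v.q2t[cys] >= 0 else -1
        j_lead = j_refs[j.names[0]]
        motif = j_lead.metadata.get("motif")
        motif_off = int(motif) if motif is not None else j_lead.sequence.find("tgggg")
        if cys_read >= 0 and motif_off >= 0:
            jn_end = j_start + motif_off + 3
            if 0 <= cys_read < jn_end <= len(seq):
                junction = seq[cys_read:jn_end]
    rec["junction"] = junction
    rec["x_complete_vdj"] = bool(v.germline_start <= 4 and v.called and j.called)

    if call_d and d_refs is not None and junction:
        core = junction[3:-3] if len(junction) > 10 else junction
        rec["d_call"] = call_d_segment(core, d_refs)
    return rec


def annotate_reads(
    reads,
    v_refs: ReferenceSet,
    j_refs: ReferenceSet,
    d_refs: ReferenceSet | None = None,
    umis: dict | None = None,
    call_d: bool = True,
) -> pd.DataFrame:
    """Annotate (id, sequence) pairs into an AIRR rearrangement table."""
    v_caller = VSegmentCaller(v_refs)
    j_only = j_refs.of_segment("J") if isinstance(j_refs, ReferenceSet) else j_refs
    rows = []
    for read_id, seq in reads:
        rec = annotate_read(seq, v_caller, j_only, d_refs, call_d=call_d)
        rec["sequence_id"] = read_id
        rec["x_umi"] = umis.get(read_id, "") if umis else ""
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df[[c for c in AIRR_COLUMNS if c in df.columns]]


# ---------------------------------------------------------------------------
# AIRR TSV I/O


def write_airr(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "x_complete_vdj" in out.columns:
        out["x_complete_vdj"] = out["x_complete_vdj"].map({True: "T", False: "F"})
    out.to_csv(path, sep="\t", index=False)


def read_airr(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str}, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory AIRR columns: {', '.join(missing)}")
    if "x_complete_vdj" in df.columns:
        df["x_complete_vdj"] = df["x_complete_vdj"].map(
            {"T": True, "F": False, True: True, False: False}
        )
    for col in (
        "v_sequence_start",
        "v_sequence_end",
        "j_sequence_start",
        "j_sequence_end",
        "duplicate_count",
        "x_v_mismatches",
    ):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col]).astype(int)
    return df
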