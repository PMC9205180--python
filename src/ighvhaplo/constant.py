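"""Constant-region extraction, indel correction and strain SNP typing.

Long-read VDJ-C amplicons carry the spliced constant-region exons downstream
of the rearrangement.  In an F1 hybrid the parental chromosomes are
distinguishable by exonic SNPs (one in the IGHM CH1, four across the IGHG2B
CH1/CH2), so after correcting platform indels against reference exons the
base observed at each SNP offset anchors the read to a parental chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StrainSNP:
    """A strain-defining constant-region polymorphism."""

    snp_id: str
    gene: str
    exon: str
    offset: int  # 0-based within the (corrected) exon
    base_by_strain: dict

    def __post_init__(self):
        bases = list(self.base_by_strain.values())
        if len(bases) != 2 or bases[0] == bases[1]:
            raise ValueError(f"{self.snp_id}: strain bases must differ")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


@dataclass
class CRegionReference:
    """Canonical spliced constant-region exons for one isotype/gene."""

    gene: str
    isotype: str
    exon_names: list
    exon_seqs: list
    snps: list = field(default_factory=list)

    def __post_init__(self):
        for s in self.snps:
            i = self.exon_names.index(s.exon)
            if s.offset >= len(self.exon_seqs[i]):
                raise ValueError(f"{s.snp_id}: offset beyond exon {s.exon}")

    @property
    def concat(self) -> str:
        return "".join(self.exon_seqs)

    def global_offset(self, snp: StrainSNP) -> int:
        i = self.exon_names.index(snp.exon)
        return sum(len(e) for e in self.exon_seqs[:i]) + snp.offset


@dataclass
class ConstantCall:
    isotype: str
    snp_bases: dict
    strain_call: str  # strain label or "uncalled"
    confidence: str  # "high" | "low"

    @property
    def c_call(self) -> str:
        if self.strain_call == "uncalled":
            return ""
        return f"{self.isotype}*{self.strain_call}"


@dataclass
class CorrectionResult:
    corrected: str
    low_confidence: np.ndarray  # deletion-filled positions
    edits: list  # (kind, ref_pos, base)
    identity: float
    status: str  # "ok" | "unalignable" | "empty"


# ---------------------------------------------------------------------------


def extract_ighc(sequence: str, j_sequence_end: int) -> str:
    """Constant-region portion of a read: one base past the final IGHJ
    nucleotide through the end of the primer-trimmed read.

    ``j_sequence_end`` is 1-based inclusive (AIRR convention).
    """
    if j_sequence_end is None or j_sequence_end <= 0:
        raise ValueError("no_j_call")
    if j_sequence_end > len(sequence):
        raise ValueError("j_sequence_end beyond read")
    return sequence[j_sequence_end:]


def indel_correct(c_seq: str, ref_exons: list | str, min_identity: float = 0.70) -> CorrectionResult:
    """Correct read indels against concatenated reference exons.

    Global alignment; read insertions are removed, read deletions are filled
    with the reference base and marked low-confidence, substitutions are
    preserved.  Reads whose alignment identity falls below ``min_identity``
    are returned uncorrected with status ``"unalignable"``.
    """
    ref = ref_exons if isinstance(ref_exons, str) else "".join(ref_exons)
    if len(ref) < 50:
        raise ValueError("reference exons too short (<50 nt)")
    if not c_seq:
        return CorrectionResult("", np.zeros(0, bool), [], 0.0, "empty")
    res = edlib.align(c_seq, ref, mode="NW", task="path")
    identity = 1.0 - res["editDistance"] / max(len(ref), len(c_seq))
    if identity < min_identity:
        return CorrectionResult(c_seq, np.zeros(len(c_seq), bool), [], identity, "unalignable")
    out = []
    low = []
    edits = []
    qi = 0  # read
    ri = 0  # reference
    for n, op in _cigar_ops(res["cigar"]):
        if op == "=" or op == "M" or op == "X":
            out.append(c_seq[qi : qi + n])
            low.extend([False] * n)
            qi += n
            ri += n
        elif op == "I":  # insertion in the read: drop
            edits.append(("ins", ri, c_seq[qi : qi + n]))
            qi += n
        elif op == "D":  # deletion in the read: fill from reference
            out.append(ref[ri : ri + n])
            low.extend([True] * n)
            edits.append(("del", ri, ref[ri : ri + n]))
            ri += n
    corrected = "".join(out)
    return CorrectionResult(corrected, np.array(low, dtype=bool), edits, identity, "ok")


def _cigar_ops(cigar: str):
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            yield n, ch
            n = 0


def type_snps(correction: CorrectionResult, cref: CRegionReference) -> dict:
    """Base observed at each SNP offset; deletion-filled positions and
    offsets beyond the corrected span give no-call (None)."""
    bases = {}
    for snp in cref.snps:
        off = cref.global_offset(snp)
        if correction.status != "ok" or off >= len(correction.corrected):
            bases[snp.snp_id] = None
        elif correction.low_confidence[off]:
            bases[snp.snp_id] = None
        else:
            bases[snp.snp_id] = correction.corrected[off]
    return bases


def assign_c_call(snp_bases: dict, snps: list, isotype: str) -> ConstantCall:
    """Strain call from typed SNP bases.

    The call is the unique strain consistent with every called base; any
    inconsistency, any base matching neither strain, or all-no-call yields
    ``uncalled``.  Confidence is high only when every SNP is called.
    """
    by_id = {s.snp_id: s for s in snps}
    candidates = None
    n_called = 0
    for sid, base in snp_bases.items():
        if base is None or sid not in by_id:
            continue
        n_called += 1
        match = {st for st, b in by_id[sid].base_by_strain.items() if b == base}
        candidates = match if candidates is None else (candidates & match)
    if not candidates or n_called == 0 or len(candidates) != 1:
        return ConstantCall(isotype, snp_bases, "uncalled", "low")
    conf = "high" if n_called == len(snps) else "low"
    return ConstantCall(isotype, snp_bases, next(iter(candidates)), conf)


# ---------------------------------------------------------------------------
# dataframe-level pipeline step


def type_constant_regions(
    df: pd.DataFrame,
    c_references: dict,
    min_identity: float = 0.70,
    confident_identity: float = 0.90,
) -> pd.DataFrame:
    """Add ``c_call``, ``x_snp_bases``, ``x_c_identity`` and ``x_c_confident``
    columns to an annotated rearrangement table.

    Each read's extracted constant segment is indel-corrected against the
    best-matching isotype reference, the strain SNPs are read off, and the
    "highly confident" flag requires all SNPs called (none deletion-filled)
    with exon alignment identity >= ``confident_identity``.
    """
    crefs = list(c_references.values())
    c_calls = []
    snp_strings = []
    idents = []
    confident = []
    for seq, j_end in zip(df["sequence"], df["j_sequence_end"]):
        if not j_end or j_end <= 0 or j_end >= len(seq):
            c_calls.append("")
            snp_strings.append("")
            idents.append(np.nan)
            confident.append(False)
            continue
        c_seq = extract_ighc(seq, int(j_end))
        # choose the isotype reference by edit distance, correct once
        if len(crefs) == 1:
            pick = (0, crefs[0])
        else:
            pick = None
            for cref in crefs:
                ref = cref.concat
                if abs(len(c_seq) - len(ref)) > 0.3 * len(ref):
                    continue
                d = edlib.align(c_seq, ref, mode="NW", task="distance")["editDistance"]
                if pick is None or d < pick[0]:
                    pick = (d, cref)
        best = None
        if pick is not None:
            corr = indel_correct(c_seq, pick[1].concat, min_identity)
            best = (corr, pick[1])
        if best is None or best[0].status != "ok":
            c_calls.append("")
            snp_strings.append("")
            idents.append(best[0].identity if best else np.nan)
            confident.append(False)
            continue
        corr, cref = best
        bases = type_snps(corr, cref)
        call = assign_c_call(bases, cref.snps, cref.isotype)
        c_calls.append(call.c_call)
        snp_strings.append(
            ";".join(f"{k}={v or '.'}" for k, v in sorted(bases.items()))
        )
        idents.append(corr.identity)
        confident.append(
            call.strain_call != "uncalled"
            and call.confidence == "high"
            and corr.identity >= confident_identity
        )
    out = df.copy()
    out["c_call"] = c_calls
    out["x_snp_bases"] = snp_strings
    out["x_c_identity"] = idents
    out["x_c_confident"] = confident
    return out


def type_uncorrected(df: pd.DataFrame, c_references: dict) -> list:
    """Naive positional SNP typing without indel correction (for contrast).

    Reads the base at each SNP's fixed offset directly off the raw extracted
    constant segment; platform indels upstream of the SNP shift the
    coordinate and corrupt the call.
    """
    crefs = list(c_references.values())
    calls = []
    for seq, j_end in zip(df["sequence"], df["j_sequence_end"]):
        if not j_end or j_end <= 0 or j_end >= len(seq):
            calls.append("")
            continue
        c_seq = extract_ighc(seq, int(j_end))
        cref = min(crefs, key=lambda cr: abs(len(c_seq) - len(cr.concat)))
        bases = {}
        for snp in cref.snps:
            off = cref.global_offset(snp)
            bases[snp.snp_id] = c_seq[off] if off < len(c_seq) else None
        calls.append(assign_c_call(bases, cref.snps, cref.isotype).c_call)
    return calls


# ---------------------------------------------------------------------------
# IGHJ1-anchored discovery and concordance


def discover_c_alleles_by_j_anchor(
    df: pd.DataFrame, anchor_map: dict, top_n: int = 1
) -> dict:
    """Most frequent raw constant segments per IGHJ1 anchor allele.

    ``anchor_map`` maps IGHJ1 allele name -> strain label.  Reads are
    restricted to unambiguous IGHJ1 users; for each anchor the unique raw
    constant segments are ranked by frequency and the top ``top_n`` returned
    (1 recovers the IgM gene per strain, 2 the two IgG subclasses).
    """
    result = {a: [] for a in anchor_map}
    sub = df[df["j_call"].isin(anchor_map.keys())]
    if sub.empty:
        warnings.warn("no IGHJ1-annotated reads; C-allele discovery is empty")
        return result
    for anchor, grp in sub.groupby("j_call"):
        segs = []
        for seq, j_end in zip(grp["sequence"], grp["j_sequence_end"]):
            if j_end and 0 < j_end < len(seq):
                segs.append(extract_ighc(seq, int(j_end)))
        counts = pd.Series(segs).value_counts()
        result[anchor] = list(counts.head(top_n).items())
    return result


def j_anchor_concordance(df: pd.DataFrame, anchor_map: dict) -> dict:
    """Fraction of constant-region strain calls agreeing with the IGHJ1 anchor.

    One minus the concordance is the pre-filter proxy for PCR chimerism plus
    typing error.  Returns per-strain fractions (None where an anchor allele
    is absent from the data).
    """
    sub = df[(df["j_call"].isin(anchor_map.keys())) & (df["c_call"] != "")]
    if sub.empty:
        raise ValueError("no reads with both an IGHJ1 call and a C strain call")
    out = {}
    strain_of_c = sub["c_call"].str.split("*").str[1]
    anchor_strain = sub["j_call"].map(anchor_map)
    for strain in sorted(set(anchor_map.values())):
        mask = strain_of_c == strain
        if not mask.any():
            out[strain] = None
            continue
        out[strain] = float((anchor_strain[mask] == strain).mean())
    return out
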