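"""Reference-set curation and completeness evaluation.

Covers: extending truncated database records from their closest full-length
relatives, confirming germline 3' gene ends from the terminal-nucleotide
profile of assigned rearrangements, labelling pairwise variants, exporting
per-strain reference sets, exact/near-match searching of genome assemblies,
and measuring reference completeness via the read-mismatch distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from .align import VSegmentCaller
from .references import GermlineAllele, ReferenceSet, write_reference_fasta
from .simulate import revcomp


# ---------------------------------------------------------------------------
# truncated-record extension


def extend_truncated_reference(
    truncated: GermlineAllele,
    donors: ReferenceSet,
    min_overlap: int = 100,
    min_identity: float = 0.95,
) -> GermlineAllele:
    """Extend a truncated germline record using its most similar
    full-length relative.

    The truncated sequence is located inside each candidate donor; the donor
    with the fewest mismatches over the overlap supplies the missing flanks.
    The extended record keeps the truncated record's own bases and gains
    ``extended`` provenance with the donor and flank lengths recorded.
    """
    if len(truncated.sequence) < min_overlap:
        raise ValueError("truncated sequence shorter than min_overlap")
    best = None
    for donor in donors:
        if donor.name == truncated.name or len(donor.sequence) <= len(truncated.sequence):
            continue
        res = edlib.align(
            truncated.sequence, donor.sequence, mode="HW", task="locations"
        )
        if best is None or res["editDistance"] < best[0]:
            best = (res["editDistance"], donor, res["locations"][0])
    if best is None:
        raise ValueError("no_suitable_donor")
    dist, donor, (start, end) = best
    identity = 1.0 - dist / len(truncated.sequence)
    if identity < min_identity:
        raise ValueError("no_suitable_donor")
    extended_seq = (
        donor.sequence[:start] + truncated.sequence + donor.sequence[end + 1 :]
    )
    meta = dict(truncated.metadata)
    meta["extension_donor"] = donor.name
    meta["extension_5p"] = str(start)
    meta["extension_3p"] = str(len(donor.sequence) - end - 1)
    if donor.cys_position is not None:
        meta["cys"] = str(donor.cys_position)
    return truncated.with_sequence(extended_seq, provenance="extended", metadata=meta)


# ---------------------------------------------------------------------------
# 3' gene-end confirmation


@dataclass
class EndProfile:
    """Terminal-nucleotide evidence for one V allele's 3' end."""

    v_allele: str
    verdict: str  # confirmed | trim_by_k | extend_by_k | inconclusive
    k: int = 0
    n_records: int = 0
    extension_bases: str = ""
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def confirm_3prime_ends(
    allele: GermlineAllele,
    assigned: pd.DataFrame,
    min_depth: int = 20,
    dominant_threshold: float = 0.55,
    reach_threshold: float = 0.20,
    min_extend_support: int = 10,
    max_scan: int = 6,
) -> EndProfile:
    """Confirm, trim or extend a germline 3' end from rearrangement evidence.

    Exonuclease trimming removes a geometric-tailed number of terminal
    germline nucleotides, so the fraction of reads whose alignment reaches a
    genuine germline position decays smoothly and never collapses; positions
    present in the reference but absent from the genome are reached only by
    chance matches into the junction.  Conversely, if the reference is too
    short, reads that consume the whole reference show a strongly biased
    next nucleotide (the missing germline base) where random N-region
    sequence would be near-uniform.

    ``assigned`` must hold unmutated records assigned to this allele with
    ``x_v_germline_end`` / ``v_sequence_end`` columns.
    """
    n = len(assigned)
    if n < min_depth:
        return EndProfile(allele.name, "inconclusive", n_records=n)
    L = len(allele.sequence)
    gends = assigned["x_v_germline_end"].to_numpy()
    # reach profile over the terminal window
    rows = []
    for p in range(max(1, L - max_scan + 1), L + 1):
        rows.append({"position": p, "reach_fraction": float(np.mean(gends >= p))})
    table = pd.DataFrame(rows)

    # --- extension: follow reads past the current reference end
    ext = ""
    sub = assigned[gends >= L]
    while len(sub) >= min_extend_support:
        nxt = []
        for _, row in sub.iterrows():
            seq = row["sequence"]
            pos = int(row["v_sequence_end"]) + len(ext)  # 0-based next base
            if pos < len(seq) and (
                len(ext) == 0
                or seq[int(row["v_sequence_end"]) : pos] == ext
            ):
                nxt.append(seq[pos])
        if len(nxt) < min_extend_support:
            break
        counts = pd.Series(nxt).value_counts()
        if counts.iloc[0] / len(nxt) < dominant_threshold:
            break
        ext += counts.index[0]
    if ext:
        return EndProfile(
            allele.name,
            f"extend_by_{len(ext)}",
            k=len(ext),
            n_records=n,
            extension_bases=ext,
            table=table,
        )

    # --- trimming: trailing reference positions that reads fail to reach
    k = 0
    for p in range(L, max(0, L - max_scan), -1):
        if float(np.mean(gends >= p)) < reach_threshold:
            k += 1
        else:
            break
    if k > 0:
        return EndProfile(allele.name, f"trim_by_{k}", k=k, n_records=n, table=table)
    return EndProfile(allele.name, "confirmed", n_records=n, table=table)


# ---------------------------------------------------------------------------
# pairwise variant labels


def pairwise_diff(seq_a: str, seq_b: str) -> list[str]:
    """1-based substitution labels (``C100T`` style) between equal-length
    sequences; raises on length mismatch (align first)."""
    a = seq_a.lower()
    b = seq_b.lower()
    if len(a) != len(b):
        raise ValueError(
            "sequences differ in length; align them before calling pairwise_diff"
        )
    return [
        f"{x.upper()}{i + 1}{y.upper()}"
        for i, (x, y) in enumerate(zip(a, b))
        if x != y
    ]


# ---------------------------------------------------------------------------
# export


def export_reference_set(
    genotype: pd.DataFrame,
    haplotype: pd.DataFrame,
    refs: ReferenceSet,
    anchor_to_strain: dict,
    out_dir: str | Path,
    end_profiles: dict | None = None,
) -> dict:
    """Write per-strain germline FASTA sets plus a metadata table.

    Alleles assigned to a single chromosome go to that strain's set, shared
    alleles to both; unhaplotyped genotype alleles are listed separately.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    present = set(genotype.loc[genotype["present"], "allele"])
    hap = haplotype.set_index("v_allele")
    strains = sorted(set(anchor_to_strain.values()))
    per_strain: dict[str, list] = {s: [] for s in strains}
    unassigned = []
    meta_rows = []
    end_profiles = end_profiles or {}
    for name in sorted(present):
        if name in hap.index:
            row = hap.loc[name]
            assignment = row["assignment"]
        else:
            assignment = "unknown"
            row = None
        targets = []
        if assignment == "both":
            targets = strains
        elif assignment.endswith("_only"):
            anchor = assignment[: -len("_only")]
            targets = [anchor_to_strain[anchor]]
        allele = refs[name] if name in refs else None
        if allele is None:
            continue
        verdict = (
            end_profiles[name].verdict if name in end_profiles else "not_assessed"
        )
        if targets:
            for s in targets:
                per_strain[s].append(
                    allele.with_sequence(allele.sequence, strain=s)
                )
        else:
            unassigned.append(allele)
        meta_rows.append(
            {
                "allele": name,
                "assignment": assignment,
                "count_a": 0 if row is None else int(row["count_a"]),
                "count_b": 0 if row is None else int(row["count_b"]),
                "strains": ",".join(targets),
                "end_verdict": verdict,
                "provenance": allele.provenance,
            }
        )
    paths = {}
    for s in strains:
        p = out_dir / f"ighv_{s}.fasta"
        write_reference_fasta(per_strain[s], p)
        paths[s] = p
    p_un = out_dir / "ighv_unassigned.fasta"
    write_reference_fasta(unassigned, p_un)
    paths["unassigned"] = p_un
    meta_path = out_dir / "reference_metadata.tsv"
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)
    paths["metadata"] = meta_path
    return paths


# ---------------------------------------------------------------------------
# assembly search and mismatch histograms


def search_assembly(
    refs: ReferenceSet, assembly: dict | list, max_mismatches: int = 0
) -> pd.DataFrame:
    """Presence/absence of each allele in a genome assembly.

    An allele is present when a full-length match with <= ``max_mismatches``
    edits exists on either strand of any contig.  ``assembly`` is a mapping
    of contig name to sequence (or a list of (name, sequence) pairs).
    """
    contigs = list(assembly.items()) if isinstance(assembly, dict) else list(assembly)
    if not contigs:
        raise ValueError("assembly is empty")
    rows = []
    for a in refs:
        best = None
        where = ""
        for cname, cseq in contigs:
            for strand, seq in (("+", cseq.lower()), ("-", revcomp(cseq.lower()))):
                res = edlib.align(a.sequence, seq, mode="HW", task="distance")
                d = res["editDistance"]
                if best is None or d < best:
                    best = d
                    where = f"{cname}{strand}"
        rows.append(
            {
                "allele": a.name,
                "best_mismatches": best,
                "present": best is not None and best <= max_mismatches,
                "contig": where,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_present"] = int(df["present"].sum())
    df.attrs["fraction_present"] = float(df["present"].mean())
    return df


@dataclass
class MismatchHistogram:
    reference_label: str
    fractions: np.ndarray  # bins 0..30 plus a final 30+ bin

    @property
    def bin0(self) -> float:
        return float(self.fractions[0])

    def as_series(self) -> pd.Series:
        idx = [str(i) for i in range(31)] + ["30+"]
        return pd.Series(self.fractions, index=idx)


def mismatch_distribution(
    df: pd.DataFrame, refs: ReferenceSet, max_bin: int = 30
) -> MismatchHistogram:
    """Histogram of best-V-alignment mismatch counts against a reference set.

    Records are (re-)aligned against ``refs``; fractions are weighted by
    ``duplicate_count`` so the histogram reflects reads, not unique
    sequences.  Bin 0 is the unmutated (perfect-alignment) fraction.
    """
    caller = VSegmentCaller(refs)
    weights = (
        df["duplicate_count"].to_numpy(dtype=float)
        if "duplicate_count" in df.columns
        else np.ones(len(df))
    )
    bins = np.zeros(max_bin + 2)
    for seq, w in zip(df["sequence"], weights):
        call = caller.call(seq)
        mm = call.mismatches if call.called else max_bin + 1
        bins[min(mm, max_bin + 1)] += w
    total = bins.sum()
    if total > 0:
        bins = bins / total
    return MismatchHistogram(refs.label, bins)
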