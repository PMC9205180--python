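"""Chromosome assignment of V alleles via constant-region anchors.

Each prepared unique sequence carries a constant-region strain call that
anchors it to one parental chromosome.  Per V allele, the unique-sequence
counts on the two anchors are compared under two models: present on a single
chromosome with a small leak rate (chimerism/typing error), or present on
both with symmetric usage.  A log10 likelihood ratio scores the decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class HaplotypeParams:
    k_thre_del: float = 0.1  # minor-fraction threshold for a deletion call
    epsilon: float = 0.01  # leak rate of the single-chromosome model
    certainty_min: float = 2.0  # log10 likelihood-ratio threshold
    min_both_count: int = 2  # unique sequences required on the minor anchor
    # to call presence on both chromosomes
    min_assign_count: int = 2  # total unique sequences below which an
    # allele stays unknown

    def __post_init__(self):
        if not 0.0 < self.k_thre_del < 0.5:
            raise ValueError("k_thre_del must be in (0, 0.5)")
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")


def prepare_haplotype_input(
    df: pd.DataFrame, anchor_a: str, anchor_b: str, min_c_support: int = 2
) -> pd.DataFrame:
    """Filter collapsed records for haplotype analysis.

    Keeps unmutated unique sequences with read counts > 1 and a highly
    confident single-anchor constant-region call: no member read typed to
    the other anchor (the ambiguity rule) and at least ``min_c_support``
    member reads supporting the anchor, so a single chimeric or mistyped
    copy cannot anchor a sequence on its own.  Records with multi-allele
    (tied) V calls are excluded.
    """
    keep = (
        df["c_call"].isin([anchor_a, anchor_b])
        & (df["x_v_mismatches"] == 0)
        & (df["duplicate_count"] > 1)
        & (~df["x_c_calls"].str.contains(";"))
        & (df["v_call"] != "")
        & (~df["v_call"].str.contains(","))
    )
    if "x_c_call_count" in df.columns and min_c_support > 1:
        keep &= df["x_c_call_count"] >= min_c_support
    return df[keep].reset_index(drop=True)


def _single_anchor_certainty(
    major: int, minor: int, params: HaplotypeParams
) -> float:
    """log10 L(single chromosome, leak eps) / L(both chromosomes, p=0.5)."""
    eps = params.epsilon
    return major * math.log10((1 - eps) / 0.5) + minor * math.log10(eps / 0.5)


def infer_haplotype(
    prepared: pd.DataFrame,
    anchor_a: str,
    anchor_b: str,
    params: HaplotypeParams | None = None,
) -> pd.DataFrame:
    """Per-allele chromosome assignment table.

    Decision per V allele with anchor counts (nA, nB), n = nA + nB:

    * n = 0 -> unknown;
    * minor/n >= k_thre_del with minor >= min_both_count -> both;
    * otherwise the single-chromosome model is scored against the
      both-chromosomes model; assignments below ``certainty_min`` stay
      unknown, otherwise the major anchor wins and the minor anchor is
      recorded as deleted.

    Each allele is scored independently (no pooling across alleles of a
    gene) with a symmetric p = 0.5 both-model, i.e. no usage-weighted prior.
    """
    params = params or HaplotypeParams()
    counts = {}
    for v, c in zip(prepared["v_call"], prepared["c_call"]):
        a, b = counts.get(v, (0, 0))
        if c == anchor_a:
            counts[v] = (a + 1, b)
        elif c == anchor_b:
            counts[v] = (a, b + 1)
    rows = []
    for v in sorted(counts):
        na, nb = counts[v]
        assignment, deleted_on, certainty = decide_assignment(
            na, nb, anchor_a, anchor_b, params
        )
        rows.append(
            {
                "v_allele": v,
                "count_a": na,
                "count_b": nb,
                "assignment": assignment,
                "deleted_on": deleted_on,
                "certainty": certainty,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["v_allele", "count_a", "count_b", "assignment", "deleted_on", "certainty"],
    )


def decide_assignment(
    na: int, nb: int, anchor_a: str, anchor_b: str, params: HaplotypeParams
) -> tuple[str, str, float]:
    """Assignment decision for one allele's anchor counts.

    The log10 likelihood ratio ``certainty`` compares the single-chromosome
    leak model against the both-chromosomes p=0.5 model.  Presence on both
    chromosomes requires an above-threshold minor fraction, the minimum
    minor count, and a strongly negative ratio.  Otherwise the allele is
    assigned to its major anchor (a gene observed on a chromosome sits on
    that chromosome); the *deletion* of the minor anchor is only recorded
    when the ratio clears ``certainty_min``, mirroring Bayes-factor
    certainty levels of chromosome deletion calls.  Alleles with fewer than
    ``min_assign_count`` records stay unknown.
    """
    n = na + nb
    if n == 0:
        return "unknown", "", 0.0
    minor = min(na, nb)
    certainty = _single_anchor_certainty(max(na, nb), minor, params)
    if (
        minor / n >= params.k_thre_del
        and minor >= params.min_both_count
        and certainty <= -params.certainty_min
    ):
        return "both", "", certainty
    if n < params.min_assign_count or na == nb:
        return "unknown", "", certainty
    deleted = ""
    if certainty >= params.certainty_min:
        deleted = anchor_b if na >= nb else anchor_a
    if na >= nb:
        return f"{anchor_a}_only", deleted, certainty
    return f"{anchor_b}_only", deleted, certainty


def estimate_chimerism(
    prepared: pd.DataFrame, haplotype: pd.DataFrame, anchor_a: str, anchor_b: str
) -> tuple[float, int]:
    """Residual chimerism: records whose V allele sits on one chromosome but
    whose own constant-region call names the other.

    Returns (fraction over all prepared records, count).
    """
    if prepared.empty:
        return 0.0, 0
    side = {}
    for _, row in haplotype.iterrows():
        if row["assignment"] == f"{anchor_a}_only":
            side[row["v_allele"]] = anchor_a
        elif row["assignment"] == f"{anchor_b}_only":
            side[row["v_allele"]] = anchor_b
    n_bad = 0
    for v, c in zip(prepared["v_call"], prepared["c_call"]):
        expected = side.get(v)
        if expected is not None and c != expected:
            n_bad += 1
    return n_bad / len(prepared), n_bad


def usage_by_chromosome(
    prepared: pd.DataFrame, haplotype: pd.DataFrame, anchor_a: str, anchor_b: str
) -> pd.DataFrame:
    """Per-anchor allele usage frequencies (weighted by duplicate_count).

    For each anchor chromosome, the frequency of each V allele among that
    anchor's records; per-anchor frequencies sum to 1 and shared alleles
    appear in both columns.
    """
    out = {}
    for anchor, col in ((anchor_a, "freq_a"), (anchor_b, "freq_b")):
        sub = prepared[prepared["c_call"] == anchor]
        tot = float(sub["duplicate_count"].sum())
        freqs = (
            sub.groupby("v_call")["duplicate_count"].sum() / tot
            if tot > 0
            else pd.Series(dtype=float)
        )
        out[col] = freqs
    table = pd.DataFrame(out).fillna(0.0)
    table.index.name = "v_allele"
    table = table.reset_index()
    return table.merge(
        haplotype[["v_allele", "assignment"]], on="v_allele", how="left"
    )
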