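"""Segment alignment against germline reference sets.

Two alignment flavours are used:

* :func:`align_segment` — unit-cost semi-global alignment (the reference
  allele as an infix of the read, free end gaps on the read) via edlib.
  This is the generic segment caller used for J genes and as the reference
  behaviour checked against an exhaustive dynamic-programming oracle.

* a banded *extension* alignment (score-based, anchored at the 5' end of
  both read and allele, free at both 3' ends) used by the bulk V caller.
  V genes are exonuclease-trimmed at their 3' end in rearrangements, so the
  number of germline positions a read actually covers is unknown a priori;
  the extension alignment stops where similarity ends and reports mismatches
  only within the covered span, which is what mutation counting needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from numba import njit

from .references import GermlineAllele, ReferenceSet

# extension-alignment scoring: unit match bonus, heavy mismatch/gap penalties
# chosen so that a random-sequence tail (25% identity) always scores downhill
MATCH = 1
MISMATCH = -2
GAP = -3
BAND = 12

_PREFIX_K = 24


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.int8)


@dataclass
class SegmentCall:
    """Result of aligning one read region against a reference set.

    Coordinates are 0-based half-open within the sequence that was aligned.
    ``names`` lists all tied best alleles in ascending name order.
    """

    names: list[str] = field(default_factory=list)
    mismatches: int = -1
    read_start: int = -1
    read_end: int = -1
    germline_start: int = -1
    germline_end: int = -1
    substitutions: list[tuple[int, str]] = field(default_factory=list)
    q2t: np.ndarray | None = None  # germline pos -> read pos map (best allele)

    @property
    def called(self) -> bool:
        return bool(self.names)

    @property
    def call_string(self) -> str:
        return ",".join(self.names)


def align_segment(
    seq: str,
    refs: ReferenceSet | list[GermlineAllele],
    segment: str = "V",
    min_overlap: int | None = None,
) -> SegmentCall:
    """Best semi-global alignment of each reference allele within ``seq``.

    Every allele is aligned as an infix of the read (free end gaps on the
    read); the allele(s) with minimum edit distance are reported, ties in
    ascending name order.  Mismatch count is the edit distance of the best
    alignment (end gaps on the read are free and not counted).
    """
    alleles = [a for a in refs if a.segment == segment] if isinstance(refs, ReferenceSet) else list(refs)
    if not alleles:
        raise ValueError("empty reference set")
    if min_overlap is None:
        min_overlap = 50 if segment == "V" else 20

    best = None
    dists = []
    for a in alleles:
        res = edlib.align(a.sequence, seq, mode="HW", task="distance")
        dists.append(res["editDistance"])
        if best is None or res["editDistance"] < best:
            best = res["editDistance"]

    names = sorted(a.name for a, d in zip(alleles, dists) if d == best)
    by_name = {a.name: a for a in alleles}
    loc = edlib.align(by_name[names[0]].sequence, seq, mode="HW", task="locations")
    start, end = loc["locations"][0]
    call = SegmentCall(
        names=names,
        mismatches=best,
        read_start=start,
        read_end=end + 1,
        germline_start=0,
        germline_end=len(by_name[names[0]].sequence),
    )
    if call.read_end - call.read_start < min_overlap:
        return SegmentCall()
    return call


# ---------------------------------------------------------------------------
# banded extension alignment (numba kernel)


@njit(cache=False)
def _ext_align(q, t, B, m, x, g):  # pragma: no cover - exercised via wrapper
    lq = q.shape[0]
    lt = t.shape[0]
    W = 2 * B + 1
    NEG = np.int32(-1000000)
    S = np.full((lq + 1, W), NEG, dtype=np.int32)
    P = np.zeros((lq + 1, W), dtype=np.int8)
    S[0, B] = 0
    for k in range(B + 1, W):
        j = k - B
        if j <= lt:
            S[0, k] = S[0, k - 1] + g
            P[0, k] = 3
    best = np.int32(0)
    bi = 0
    bk = B
    for i in range(1, lq + 1):
        for k in range(W):
            j = i + k - B
            if j < 0 or j > lt:
                continue
            s = NEG
            p = np.int8(0)
            if j >= 1 and S[i - 1, k] > NEG:
                sc = S[i - 1, k] + (m if q[i - 1] == t[j - 1] else x)
                if sc > s:
                    s = sc
                    p = 1
            if k + 1 < W and S[i - 1, k + 1] > NEG and S[i - 1, k + 1] + g > s:
                s = S[i - 1, k + 1] + g
                p = 2
            if k - 1 >= 0 and S[i, k - 1] > NEG and S[i, k - 1] + g > s:
                s = S[i, k - 1] + g
                p = 3
            S[i, k] = s
            P[i, k] = p
            if s > best:
                best = s
                bi = i
                bk = k
    q2t = np.full(lq, -1, np.int32)
    sub_q = np.empty(64, np.int32)
    sub_b = np.empty(64, np.int8)
    nsub = 0
    ngap = 0
    i = bi
    k = bk
    while not (i == 0 and k == B):
        p = P[i, k]
        j = i + k - B
        if p == 1:
            if q[i - 1] != t[j - 1]:
                if nsub < 64:
                    sub_q[nsub] = i - 1
                    sub_b[nsub] = t[j - 1]
                nsub += 1
            q2t[i - 1] = j - 1
            i -= 1
        elif p == 2:
            ngap += 1
            i -= 1
            k += 1
        elif p == 3:
            ngap += 1
            k -= 1
        else:
            break
    bj = bi + bk - B
    return best, bi, bj, nsub, ngap, sub_q, sub_b, q2t


def extension_align(
    allele_seq: str, read: str, band: int = BAND
) -> tuple[int, int, int, int, list[tuple[int, str]], np.ndarray]:
    """Anchored 5'-to-5' extension alignment of an allele against a read.

    Returns ``(score, germline_end, read_end, mismatches, substitutions,
    q2t)`` where coordinates are 0-based half-open and ``mismatches``
    counts substitutions plus gaps inside the extension.
    """
    q = _encode(allele_seq)
    t = _encode(read)
    score, gi, rj, nsub, ngap, sub_q, sub_b, q2t = _ext_align(
        q, t, band, MATCH, MISMATCH, GAP
    )
    nrec = min(nsub, 64)
    subs = [(int(sub_q[i]), chr(sub_b[i])) for i in range(nrec)]
    subs.reverse()
    return int(score), int(gi), int(rj), int(nsub + ngap), subs, q2t


# ---------------------------------------------------------------------------
# bulk V caller


class VSegmentCaller:
    """Fast V-allele caller for reads whose V region starts at position 0.

    Candidate alleles are looked up by exact 5'-prefix; a numpy
    substitution-only comparison handles the common indel-free case and the
    banded extension alignment resolves reads with indels.  Reads matching
    no prefix fall back to an exhaustive edlib scan, so call sets never
    depend on reference ordering.
    """

    def __init__(self, refs: ReferenceSet | list[GermlineAllele], band: int = BAND):
        alleles = (
            [a for a in refs if a.segment == "V"]
            if isinstance(refs, ReferenceSet)
            else list(refs)
        )
        if not alleles:
            raise ValueError("no V alleles")
        self.alleles = sorted(alleles, key=lambda a: a.name)
        self.seqs = [a.sequence for a in self.alleles]
        self.arrs = [_encode(s) for s in self.seqs]
        self.names = [a.name for a in self.alleles]
        self.band = band
        self.prefix: dict[str, list[int]] = {}
        self.prefix2: dict[str, list[int]] = {}
        for i, s in enumerate(self.seqs):
            self.prefix.setdefault(s[:_PREFIX_K], []).append(i)
            self.prefix2.setdefault(s[_PREFIX_K : 2 * _PREFIX_K], []).append(i)
        self.max_len = max(len(s) for s in self.seqs)

    # -- candidate evaluation -------------------------------------------

    def _numpy_eval(self, read_arr: np.ndarray, idx: int):
        """Substitution-only comparison (valid when the read carries no
        indel within the compared span)."""
        a = self.arrs[idx]
        L = min(len(a), len(read_arr))
        if L < 30:
            return None
        eq = read_arr[:L] == a[:L]
        # germline end maximising the extension score (matches + penalties),
        # exactly as the gapped DP would place it for an indel-free read
        cum_mm = np.cumsum(~eq)
        scores = np.arange(1, L + 1) + (MISMATCH - MATCH) * cum_mm
        bi = int(np.argmax(scores))
        if scores[bi] <= 0:
            return None
        end = bi + 1
        mm = int(cum_mm[bi])
        mism = np.nonzero(~eq[:end])[0]
        return int(scores[bi]), end, mm, mism

    def _dp_eval(self, read: str, idx: int):
        score, gend, rend, mm, subs, q2t = extension_align(
            self.seqs[idx], read, self.band
        )
        return score, gend, rend, mm, subs, q2t

    def call(self, read: str) -> SegmentCall:
        read_win = read[: self.max_len + 40]
        read_arr = _encode(read_win)
        cands = self.prefix.get(read[:_PREFIX_K])
        if cands is None:
            cands = self.prefix2.get(read[_PREFIX_K : 2 * _PREFIX_K])
        if cands is None:
            cands = self._edlib_candidates(read_win)

        np_results = {}
        for i in cands:
            r = self._numpy_eval(read_arr, i)
            if r is not None:
                np_results[i] = r
        best_np = max(np_results.items(), default=None, key=lambda kv: kv[1][0])
        # alleles of one locus differ by substitutions, so when the best
        # candidate matches near-full-length without indels the
        # substitution-only ranking is exact and no DP is needed
        if best_np is not None:
            bi, (bscore, bend, bmm, bmism) = best_np
            clean = bmm <= 6 and bend >= len(self.seqs[bi]) - 25
            if clean:
                tied = sorted(i for i, r in np_results.items() if r[0] == bscore)
                lead = tied[0]
                _, end, mm, mism = np_results[lead]
                subs = [(int(p), chr(read_arr[p])) for p in mism]
                return SegmentCall(
                    names=[self.names[i] for i in tied],
                    mismatches=mm,
                    read_start=0,
                    read_end=end,
                    germline_start=0,
                    germline_end=end,
                    substitutions=subs,
                    q2t=None,
                )

        results = {}
        for i in cands:
            results[i] = self._dp_eval(read_win, i)[:4]
        if not results:
            return self._truncated_rescue(read_win, results)
        best_score = max(r[0] for r in results.values())
        if best_score < 60:
            # poor everywhere: exhaustive rescan, then 5'-truncation rescue
            cands2 = self._edlib_candidates(read_win)
            for i in cands2:
                if i not in results:
                    results[i] = self._dp_eval(read_win, i)[:4]
            best_score = max(r[0] for r in results.values())
            if best_score < 60:
                return self._truncated_rescue(read_win, results)
        tied = sorted(i for i, r in results.items() if r[0] == best_score)
        lead = tied[0]
        score, gend, rend, mm, subs, q2t = self._dp_eval(read_win, lead)
        return SegmentCall(
            names=[self.names[i] for i in tied],
            mismatches=mm,
            read_start=0,
            read_end=rend,
            germline_start=0,
            germline_end=gend,
            substitutions=subs,
            q2t=q2t,
        )

    def _edlib_candidates(
        self, read_win: str, keep: int = 2, max_dist: int = 60
    ) -> list[int]:
        # the distance cap lets edlib reject distant alleles cheaply; reads
        # beating it nowhere (deep 5' truncations) go to the rescue path
        dists = np.empty(len(self.seqs), dtype=np.int32)
        for i, s in enumerate(self.seqs):
            d = edlib.align(s, read_win, mode="HW", task="distance", k=max_dist)[
                "editDistance"
            ]
            dists[i] = d if d >= 0 else max_dist + 1
        best = int(dists.min())
        if best > max_dist:
            return []
        return [i for i in range(len(self.seqs)) if dists[i] <= best + keep]

    def _truncated_rescue(self, read_win: str, results: dict) -> SegmentCall:
        """Handle reads missing their V 5' end (library truncation)."""
        probe = read_win[:80]
        best = None
        for i, s in enumerate(self.seqs):
            if len(s) < 90:
                continue
            res = edlib.align(probe, s, mode="HW", task="locations", k=12)
            if res["editDistance"] < 0:
                continue
            if best is None or res["editDistance"] < best[0]:
                best = (res["editDistance"], i, res["locations"][0][0])
        if best is None:
            return SegmentCall()
        dist, i, gstart = best
        tail = self.seqs[i][gstart:]
        score, gend, rend, mm, subs, q2t = self._dp_eval_seq(tail, read_win)
        return SegmentCall(
            names=[self.names[i]],
            mismatches=mm,
            read_start=0,
            read_end=rend,
            germline_start=gstart,
            germline_end=gstart + gend,
            substitutions=[(p + gstart, b) for p, b in subs],
            q2t=None,
        )

    def _dp_eval_seq(self, seq: str, read: str):
        return extension_align(seq, read, self.band)


# ---------------------------------------------------------------------------
# D segment calling (ungapped exact-substring match inside the junction)


def call_d_segment(
    junction: str,
    d_refs: ReferenceSet | list[GermlineAllele],
    min_match: int = 5,
    max_probe: int = 15,
) -> str:
    """Longest exact D-gene substring found in the junction (>= min_match nt).

    D segments are trimmed at both ends during rearrangement, so only an
    internal fragment survives.  Returns a comma-joined sorted call string,
    empty when no D fragment of sufficient length is found.
    """
    alleles = (
        [a for a in d_refs if a.segment == "D"]
        if isinstance(d_refs, ReferenceSet)
        else list(d_refs)
    )
    if not junction or len(junction) < min_match:
        return ""
    subs: dict[str, set[str]] = {}
    for a in alleles:
        s = a.sequence
        for L in range(min_match, min(len(s), max_probe) + 1):
            for i in range(len(s) - L + 1):
                subs.setdefault(s[i : i + L], set()).add(a.name)
    top = min(len(junction), max_probe)
    for L in range(top, min_match - 1, -1):
        hits: set[str] = set()
        for i in range(len(junction) - L + 1):
            hit = subs.get(junction[i : i + L])
            if hit:
                hits |= hit
        if hits:
            return ",".join(sorted(hits))
    return ""
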