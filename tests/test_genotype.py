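import numpy as np
import pandas as pd

from ighvhaplo.genotype import (
    InferenceParams,
    collapse_unique,
    filter_rearrangements,
    find_novel_alleles,
    infer_genotype,
    reassign_alleles,
    select_unmutated,
)
from ighvhaplo.references import GermlineAllele, ReferenceSet


def _rec(i, seq="acgtacgt", v="V1*01", mm=0, junction="tgtgcatgg", j="IGHJ1*01",
         complete=True, dup=1, c_call="", umi=""):
    return {
        "sequence_id": f"r{i:03d}",
        "sequence": seq + "cccc",
        "v_call": v,
        "d_call": "",
        "j_call": j,
        "c_call": c_call,
        "junction": junction,
        "v_sequence_start": 1,
        "v_sequence_end": 4,
        "j_sequence_start": 5,
        "j_sequence_end": len(seq),
        "duplicate_count": dup,
        "x_umi": umi,
        "x_v_mismatches": mm,
        "x_v_germline_start": 1,
        "x_v_germline_end": len(seq),
        "x_v_mutations": "",
        "x_complete_vdj": complete,
    }


class TestFilters:
    def test_drop_rules(self):
        df = pd.DataFrame(
            [
                _rec(0),
                _rec(1, junction=""),
                _rec(2, j=""),
                _rec(3, complete=False),
            ]
        )
        out = filter_rearrangements(df)
        assert list(out["sequence_id"]) == ["r000"]

    def test_empty_input(self):
        df = pd.DataFrame([_rec(0)]).iloc[:0]
        assert len(filter_rearrangements(df)) == 0

    def test_retained_fraction_tracks_planted_truncations(self):
        from tests.conftest import make_clean_config, simulate_with_refs, trim_dataset
        from ighvhaplo.annotate import annotate_reads

        config = make_clean_config(n_reads=1200, seed=91, p_truncate_5p=0.10)
        dataset, refs, j_refs, _ = simulate_with_refs(config)
        trimmed, umis = trim_dataset(dataset)
        records = annotate_reads(trimmed, refs, j_refs, None, umis=umis, call_d=False)
        kept = len(filter_rearrangements(records)) / len(records)
        se = np.sqrt(0.9 * 0.1 / len(records))
        assert abs(kept - 0.9) <= 3 * se + 0.01


class TestCollapse:
    def test_identical_copies_collapse_with_count(self):
        df = pd.DataFrame([_rec(i, seq="aaaacgtt") for i in range(5)])
        out = collapse_unique(df)
        assert len(out) == 1
        assert out.loc[0, "duplicate_count"] == 5
        assert out.loc[0, "sequence_id"] == "r000"

    def test_all_distinct_identity(self):
        df = pd.DataFrame(
            [_rec(i, seq="aaaacgtt"[:-1] + b) for i, b in enumerate("acgt")]
        )
        out = collapse_unique(df)
        assert len(out) == 4
        assert (out["duplicate_count"] == 1).all()

    def test_duplicate_count_conserved(self):
        rng = np.random.default_rng(1)
        seqs = ["aaaacgtt", "ccccgggg", "aaaacgtt", "ttttaaaa", "ccccgggg"]
        df = pd.DataFrame(
            [_rec(i, seq=s, dup=int(rng.integers(1, 4))) for i, s in enumerate(seqs)]
        )
        out = collapse_unique(df)
        assert out["duplicate_count"].sum() == df["duplicate_count"].sum()

    def test_anchor_ambiguity_and_umi_confirmation(self):
        df = pd.DataFrame(
            [
                _rec(0, seq="aaaacgtt", c_call="IgM*BALB", umi="u1"),
                _rec(1, seq="aaaacgtt", c_call="IgM*BALB", umi="u1"),
                _rec(2, seq="ccccgggg", c_call="IgM*BALB", umi="u2"),
                _rec(3, seq="ccccgggg", c_call="IgM*B6", umi="u3"),
                _rec(4, seq="ttttaaaa", c_call="IgM*B6", umi="u4"),
                _rec(5, seq="ttttaaaa", c_call="IgM*B6", umi="u5"),
            ]
        )
        out = collapse_unique(df).set_index("sequence_id")
        # same-UMI pair: confirmed call with support 2
        assert out.loc["r000", "c_call"] == "IgM*BALB"
        assert out.loc["r000", "x_c_call_count"] == 2
        # both anchors seen for one VDJ: ambiguous, no call
        assert out.loc["r002", "c_call"] == ""
        assert "IgM*B6" in out.loc["r002", "x_c_calls"]
        # two different UMIs: call retained but unconfirmed (support 1)
        assert out.loc["r004", "c_call"] == "IgM*B6"
        assert out.loc["r004", "x_c_call_count"] == 1


class TestUnmutatedSelection:
    def test_threshold(self):
        df = pd.DataFrame([_rec(0, mm=0), _rec(1, mm=1), _rec(2, mm=-1)])
        out = select_unmutated(df)
        assert list(out["sequence_id"]) == ["r000"]
        out2 = select_unmutated(df, InferenceParams(unmutated_max_mismatches=1))
        assert list(out2["sequence_id"]) == ["r000", "r001"]


def _novel_frame(rng, ref_seq, n_clean=60, n_variant_frac=0.5, variant_pos=100,
                 shm_rate=0.002):
    """Unique-sequence table for one allele with a planted 1-SNP variant."""
    rows = []
    alt = "t" if ref_seq[variant_pos] != "t" else "g"
    for i in range(n_clean):
        is_var = rng.random() < n_variant_frac
        muts = []
        if is_var:
            muts.append((variant_pos, ref_seq[variant_pos], alt))
        n_shm = rng.poisson(3 * shm_rate * 100)
        for _ in range(n_shm):
            p = int(rng.integers(0, len(ref_seq)))
            if p == variant_pos:
                continue
            b = "acgt"[(("acgt".index(ref_seq[p])) + 1) % 4]
            muts.append((p, ref_seq[p], b))
        rec = _rec(i, seq=ref_seq)
        rec["x_v_mismatches"] = len(muts)
        rec["x_v_mutations"] = ",".join(f"{r}{p + 1}{b}" for p, r, b in muts)
        rec["x_v_germline_end"] = len(ref_seq)
        rows.append(rec)
    return pd.DataFrame(rows)


class TestNovelAlleles:
    def setup_method(self):
        rng = np.random.default_rng(10)
        self.ref_seq = "".join(rng.choice(list("acgt"), size=250))
        self.refs = ReferenceSet([GermlineAllele("V1*01", "V", self.ref_seq)])
        self.rng = rng

    def test_planted_half_frequency_variant_found(self):
        df = _novel_frame(self.rng, self.ref_seq, n_clean=120, n_variant_frac=0.5)
        params = InferenceParams(germline_min=50, min_seqs=10)
        out = find_novel_alleles(df, self.refs, params)
        assert len(out) == 1
        expected = self.ref_seq[:100] + ("t" if self.ref_seq[100] != "t" else "g") + self.ref_seq[101:]
        assert out[0].sequence == expected
        assert out[0].provenance == "inferred"

    def test_no_variant_no_candidates(self):
        df = _novel_frame(self.rng, self.ref_seq, n_clean=120, n_variant_frac=0.0,
                          shm_rate=0.05)
        out = find_novel_alleles(df, self.refs, InferenceParams())
        assert out == []

    def test_below_min_seqs_not_reported(self):
        df = _novel_frame(self.rng, self.ref_seq, n_clean=120, n_variant_frac=0.05)
        n_l1 = sum(
            1
            for mm, muts in zip(df["x_v_mismatches"], df["x_v_mutations"])
            if mm == 1 and "101" in muts
        )
        params = InferenceParams(germline_min=50, min_seqs=n_l1 + 1)
        assert find_novel_alleles(df, self.refs, params) == []

    def test_below_germline_min_skipped(self):
        df = _novel_frame(self.rng, self.ref_seq, n_clean=30, n_variant_frac=0.5)
        assert find_novel_alleles(df, self.refs, InferenceParams()) == []


class TestGenotype:
    def test_support_thresholds(self):
        refs = ReferenceSet(
            [
                GermlineAllele("V1*01", "V", "acgt" * 20),
                GermlineAllele("V2*01", "V", "tgca" * 20),
                GermlineAllele("V3*01", "V", "ggcc" * 20),
            ]
        )
        df = pd.DataFrame(
            [
                _rec(0, v="V1*01", mm=0, dup=5),
                _rec(1, v="V1*01", mm=0, dup=2),
                _rec(2, v="V2*01", mm=0, dup=1),
                _rec(3, v="V2*01", mm=2, dup=1),
                _rec(4, v="V3*01", mm=3, dup=1),
            ]
        )
        gt = infer_genotype(df, refs, InferenceParams())
        gt = gt.set_index("allele")
        assert bool(gt.loc["V1*01", "present"])
        assert not bool(gt.loc["V2*01", "present"])
        assert gt.loc["V2*01", "note"] == "provisional_single_sequence"
        assert "V3*01" not in gt.index  # zero unmutated support: absent
        # sorted by frequency, weighted by duplicate_count
        assert gt.index[0] == "V1*01"

    def test_reassignment_migrates_to_nearest_neighbor(self):
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("acgt"), size=260))
        a = GermlineAllele("VA*01", "V", base)
        bseq = list(base)
        for p in (30, 90, 150):
            bseq[p] = "acgt"[("acgt".index(base[p]) + 1) % 4]
        b = GermlineAllele("VB*01", "V", "".join(bseq))
        df = pd.DataFrame([_rec(0, seq=base, v="VA*01", mm=0)])
        df["sequence"] = base + "gggg"
        out = reassign_alleles(df, ReferenceSet([a, b]))
        assert out.loc[0, "v_call"] == "VA*01"
        assert out.loc[0, "x_v_mismatches"] == 0
        out2 = reassign_alleles(df, ReferenceSet([b]))
        assert out2.loc[0, "v_call"] == "VB*01"
        assert out2.loc[0, "x_v_mismatches"] == 3

    def test_reassignment_never_worsens_present_calls(self):
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list("acgt"), size=260))
        a = GermlineAllele("VA*01", "V", base)
        refs = ReferenceSet([a])
        df = pd.DataFrame([_rec(0, seq=base, v="VA*01", mm=0)])
        df["sequence"] = base + "gggg"
        out = reassign_alleles(df, refs)
        assert out.loc[0, "x_v_mismatches"] <= 0 + df.loc[0, "x_v_mismatches"]
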