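import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ighvhaplo.align import VSegmentCaller
from ighvhaplo.curation import (
    confirm_3prime_ends,
    export_reference_set,
    extend_truncated_reference,
    mismatch_distribution,
    pairwise_diff,
    search_assembly,
)
from ighvhaplo.references import (
    GermlineAllele,
    ReferenceSet,
    load_novel_ighv_table,
    read_reference_fasta,
)
from ighvhaplo.simulate import revcomp


def _rand_dna(rng, n):
    return "".join(rng.choice(list("acgt"), size=n))


class TestExtension:
    def setup_method(self):
        rng = np.random.default_rng(21)
        self.full = GermlineAllele("FULL*01", "V", _rand_dna(rng, 300))
        decoy = GermlineAllele("FAR*01", "V", _rand_dna(rng, 300))
        self.donors = ReferenceSet([self.full, decoy])

    def test_restore_missing_3prime(self):
        trunc = GermlineAllele("T*01", "V", self.full.sequence[:-3])
        ext = extend_truncated_reference(trunc, self.donors)
        assert ext.sequence == self.full.sequence
        assert ext.provenance == "extended"
        assert ext.metadata["extension_donor"] == "FULL*01"
        assert ext.metadata["extension_3p"] == "3"

    def test_restore_57_missing_5prime(self):
        trunc = GermlineAllele("T*01", "V", self.full.sequence[57:])
        ext = extend_truncated_reference(trunc, self.donors)
        assert ext.sequence == self.full.sequence
        assert ext.metadata["extension_5p"] == "57"

    def test_round_trip_identity(self):
        trunc = GermlineAllele("T*01", "V", self.full.sequence[10:-5])
        ext = extend_truncated_reference(trunc, self.donors)
        i5 = int(ext.metadata["extension_5p"])
        i3 = int(ext.metadata["extension_3p"])
        assert ext.sequence[i5 : len(ext.sequence) - i3] == trunc.sequence

    def test_no_suitable_donor(self):
        rng = np.random.default_rng(5)
        trunc = GermlineAllele("T*01", "V", _rand_dna(rng, 150))
        with pytest.raises(ValueError, match="no_suitable_donor"):
            extend_truncated_reference(trunc, self.donors)


def _assigned_frame(allele_ref: GermlineAllele, true_seq: str, n: int, rng, trim_mean=2.0):
    """Annotate synthetic unmutated reads of ``true_seq`` against a
    (possibly wrong-ended) reference allele."""
    caller = VSegmentCaller([allele_ref])
    rows = []
    p = 1.0 / (trim_mean + 1.0)
    for i in range(n):
        t = int(rng.geometric(p)) - 1
        t = min(t, 30)
        read = true_seq[: len(true_seq) - t] + _rand_dna(rng, 40)
        call = caller.call(read)
        rows.append(
            {
                "sequence_id": f"r{i}",
                "sequence": read,
                "v_call": call.call_string,
                "x_v_germline_end": call.germline_end,
                "v_sequence_end": call.read_end,
                "x_v_mismatches": call.mismatches,
            }
        )
    return pd.DataFrame(rows)


class TestEndConfirmation:
    def test_correct_end_confirmed(self):
        rng = np.random.default_rng(31)
        true = _rand_dna(rng, 290)
        ref = GermlineAllele("V*01", "V", true)
        df = _assigned_frame(ref, true, 120, rng)
        prof = confirm_3prime_ends(ref, df)
        assert prof.verdict == "confirmed"

    def test_reference_two_nt_too_long_trimmed(self):
        rng = np.random.default_rng(32)
        true = _rand_dna(rng, 290)
        ref = GermlineAllele("V*01", "V", true + "ag")  # phantom 3' bases
        df = _assigned_frame(ref, true, 150, rng)
        prof = confirm_3prime_ends(ref, df)
        assert prof.verdict == "trim_by_2"

    def test_reference_one_nt_too_short_extended(self):
        rng = np.random.default_rng(33)
        true = _rand_dna(rng, 290)
        ref = GermlineAllele("V*01", "V", true[:-1])  # missing final base
        df = _assigned_frame(ref, true, 150, rng)
        prof = confirm_3prime_ends(ref, df)
        assert prof.verdict == "extend_by_1"
        assert prof.extension_bases == true[-1]

    def test_false_revision_rate_low_across_replicates(self):
        """A correct reference end is confirmed in >= 95% of replicates."""
        confirmed = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            true = _rand_dna(rng, 290)
            ref = GermlineAllele("V*01", "V", true)
            df = _assigned_frame(ref, true, 100, rng)
            confirmed += confirm_3prime_ends(ref, df).verdict == "confirmed"
        assert confirmed >= 19

    def test_insufficient_depth_inconclusive(self):
        rng = np.random.default_rng(34)
        true = _rand_dna(rng, 290)
        ref = GermlineAllele("V*01", "V", true)
        df = _assigned_frame(ref, true, 10, rng)
        assert confirm_3prime_ends(ref, df).verdict == "inconclusive"


class TestPairwiseDiff:
    def test_published_variant_pair_single_c_to_t(self):
        t1 = load_novel_ighv_table()
        diffs = pairwise_diff(
            t1["b6IGHV040"].sequence, t1["balbIGHV041"].sequence
        )
        assert len(diffs) == 1
        assert diffs[0].startswith("C") and diffs[0].endswith("T")

    def test_identical_empty(self):
        assert pairwise_diff("acgt", "acgt") == []

    def test_length_mismatch_suggests_alignment(self):
        with pytest.raises(ValueError, match="align"):
            pairwise_diff("acgt", "acg")

    @given(st.integers(0, 2**31 - 1))
    def test_matches_positionwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = _rand_dna(rng, 60)
        b = _rand_dna(rng, 60)
        labels = pairwise_diff(a, b)
        expected = [
            f"{x.upper()}{i + 1}{y.upper()}"
            for i, (x, y) in enumerate(zip(a, b))
            if x != y
        ]
        assert labels == expected


class TestAssemblySearch:
    def setup_method(self):
        rng = np.random.default_rng(41)
        self.allele = GermlineAllele("V*01", "V", _rand_dna(rng, 120))
        self.rng = rng

    def _flank(self, core):
        return _rand_dna(self.rng, 200) + core + _rand_dna(self.rng, 200)

    def test_verbatim_and_revcomp_found(self):
        contigs = {
            "c1": self._flank(self.allele.sequence),
            "c2": self._flank(revcomp(self.allele.sequence)),
        }
        refs = ReferenceSet([self.allele])
        out1 = search_assembly(refs, {"c1": contigs["c1"]})
        out2 = search_assembly(refs, {"c2": contigs["c2"]})
        assert bool(out1.loc[0, "present"]) and bool(out2.loc[0, "present"])

    def test_mismatch_threshold_semantics(self):
        seq = self.allele.sequence
        mutated = seq[:60] + ("a" if seq[60] != "a" else "c") + seq[61:]
        contig = {"c": self._flank(mutated)}
        refs = ReferenceSet([self.allele])
        assert not search_assembly(refs, contig, max_mismatches=0).loc[0, "present"]
        assert bool(search_assembly(refs, contig, max_mismatches=1).loc[0, "present"])

    def test_contig_order_invariant(self):
        c1 = self._flank(self.allele.sequence)
        c2 = _rand_dna(self.rng, 300)
        refs = ReferenceSet([self.allele])
        a = search_assembly(refs, [("c1", c1), ("c2", c2)])
        b = search_assembly(refs, [("c2", c2), ("c1", c1)])
        assert bool(a.loc[0, "present"]) == bool(b.loc[0, "present"]) is True

    def test_empty_assembly_rejected(self):
        with pytest.raises(ValueError):
            search_assembly(ReferenceSet([self.allele]), {})


class TestMismatchHistogram:
    def test_germline_identical_reads_all_bin0(self):
        rng = np.random.default_rng(51)
        alleles = [GermlineAllele(f"V{i}*01", "V", _rand_dna(rng, 250)) for i in range(3)]
        refs = ReferenceSet(alleles, label="full")
        df = pd.DataFrame(
            {
                "sequence": [a.sequence + _rand_dna(rng, 50) for a in alleles] * 5,
                "duplicate_count": 1,
            }
        )
        hist = mismatch_distribution(df, refs)
        assert hist.bin0 == pytest.approx(1.0)
        assert hist.fractions.sum() == pytest.approx(1.0)

    def test_bin0_monotone_under_reference_supersets(self):
        rng = np.random.default_rng(52)
        alleles = [GermlineAllele(f"V{i}*01", "V", _rand_dna(rng, 250)) for i in range(4)]
        df = pd.DataFrame(
            {
                "sequence": [a.sequence + _rand_dna(rng, 50) for a in alleles] * 3,
                "duplicate_count": 1,
            }
        )
        subset = ReferenceSet(alleles[:2], label="subset")
        superset = ReferenceSet(alleles, label="superset")
        assert (
            mismatch_distribution(df, superset).bin0
            >= mismatch_distribution(df, subset).bin0
        )


class TestExport:
    def test_per_strain_sets_and_unassigned(self, tmp_path):
        rng = np.random.default_rng(61)
        names = ["VA*01", "VB*01", "VS*01", "VU*01"]
        refs = ReferenceSet(
            [GermlineAllele(n, "V", _rand_dna(rng, 100)) for n in names]
        )
        genotype = pd.DataFrame(
            {
                "allele": names,
                "unmutated_support": [5, 5, 5, 5],
                "total_support": [6, 6, 6, 6],
                "frequency": [0.3, 0.3, 0.3, 0.1],
                "present": [True, True, True, True],
                "note": "",
            }
        )
        haplotype = pd.DataFrame(
            {
                "v_allele": ["VA*01", "VB*01", "VS*01"],
                "count_a": [9, 0, 6],
                "count_b": [0, 8, 7],
                "assignment": ["IgM*BALB_only", "IgM*B6_only", "both"],
                "deleted_on": ["IgM*B6", "IgM*BALB", ""],
                "certainty": [2.6, 2.3, -9.0],
            }
        )
        paths = export_reference_set(
            genotype,
            haplotype,
            refs,
            {"IgM*BALB": "BALB", "IgM*B6": "B6"},
            tmp_path,
        )
        balb = read_reference_fasta(paths["BALB"])
        b6 = read_reference_fasta(paths["B6"])
        un = read_reference_fasta(paths["unassigned"])
        assert set(balb.names) == {"VA*01", "VS*01"}
        assert set(b6.names) == {"VB*01", "VS*01"}
        assert un.names == ["VU*01"]
        assert balb["VS*01"].sequence == refs["VS*01"].sequence
        meta = pd.read_csv(paths["metadata"], sep="\t")
        assert len(meta) == 4
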