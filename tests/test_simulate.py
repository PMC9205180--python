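import filecmp

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ighvhaplo.simulate import (
    SimulationConfig,
    apply_sequencing_errors,
    apply_shm,
    build_parental_haplotypes,
    inject_chimeras,
    read_fastq,
    simulate_rearrangement,
    simulate_repertoire,
    write_dataset,
)


@pytest.fixture(scope="module")
def haplotypes():
    config = SimulationConfig(n_v_alleles=50, seed=3)
    rng = np.random.default_rng(3)
    return build_parental_haplotypes(config, 0.04, rng), config


class TestParentalHaplotypes:
    def test_shared_allele_count(self, haplotypes):
        (hap_a, hap_b, crefs, snps), config = haplotypes
        names_a = {a.name for a in hap_a.v_alleles}
        names_b = {a.name for a in hap_b.v_alleles}
        assert len(names_a) == len(names_b) == 50
        assert len(names_a & names_b) == round(0.04 * 50)

    def test_disjoint_when_shared_fraction_zero(self):
        config = SimulationConfig(n_v_alleles=20, seed=4)
        hap_a, hap_b, _, _ = build_parental_haplotypes(
            config, 0.0, np.random.default_rng(4)
        )
        assert not {a.name for a in hap_a.v_alleles} & {
            b.name for b in hap_b.v_alleles
        }

    def test_ighm_ch1_differs_only_at_snp(self, haplotypes):
        (hap_a, hap_b, crefs, snps), config = haplotypes
        ch1_a = hap_a.c_genes["IgM"][0]
        ch1_b = hap_b.c_genes["IgM"][0]
        diffs = [i for i, (x, y) in enumerate(zip(ch1_a, ch1_b)) if x != y]
        ighm = [s for s in snps if s.gene == "IGHM"][0]
        assert diffs == [ighm.offset]
        assert ch1_a[ighm.offset] == ighm.base_by_strain[hap_a.strain_label]

    def test_ighj1_alleles_differ_by_one_base(self, haplotypes):
        (hap_a, hap_b, _, _), config = haplotypes
        j1_a = next(a for a in hap_a.j_alleles if a.name.startswith("IGHJ1"))
        j1_b = next(a for a in hap_b.j_alleles if a.name.startswith("IGHJ1"))
        assert sum(x != y for x, y in zip(j1_a.sequence, j1_b.sequence)) == 1

    def test_usage_weights_normalised(self, haplotypes):
        (hap_a, _, _, _), config = haplotypes
        tot = sum(hap_a.usage_weights[a.name] for a in hap_a.v_alleles)
        assert abs(tot - 1.0) < 1e-9

    def test_excessive_shared_fraction_rejected(self):
        config = SimulationConfig(n_v_alleles=10, seed=5)
        with pytest.raises(ValueError):
            build_parental_haplotypes(config, 1.5, np.random.default_rng(5))


class TestRearrangement:
    def test_identity_configuration_is_pure_concatenation(self, haplotypes):
        (hap_a, _, _, _), _ = haplotypes
        config = SimulationConfig(
            trim_mean_v3=0, trim_mean_j5=0, trim_mean_d=0, n_insert_max=0
        )
        rng = np.random.default_rng(8)
        seq, tr = simulate_rearrangement(hap_a, "IgM", rng, config)
        v = next(a for a in hap_a.v_alleles if a.name == tr["v_call"])
        d = next(a for a in hap_a.d_alleles if a.name == tr["d_call"])
        j = next(a for a in hap_a.j_alleles if a.name == tr["j_call"])
        expect = v.sequence + d.sequence + j.sequence + "".join(hap_a.c_genes["IgM"])
        assert seq == expect

    def test_unknown_isotype_rejected(self, haplotypes):
        (hap_a, _, _, _), _ = haplotypes
        with pytest.raises(ValueError):
            simulate_rearrangement(hap_a, "IgZ", np.random.default_rng(0))

    def test_v_usage_matches_multinomial_oracle(self, haplotypes):
        (hap_a, _, _, _), _ = haplotypes
        config = SimulationConfig()
        rng = np.random.default_rng(12)
        n = 10_000
        counts = {}
        for _ in range(n):
            _, tr = simulate_rearrangement(hap_a, "IgM", rng, config)
            counts[tr["v_call"]] = counts.get(tr["v_call"], 0) + 1
        for a in hap_a.v_alleles:
            p = hap_a.usage_weights[a.name]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts.get(a.name, 0) / n - p) <= 3 * se + 1e-9


class TestSHM:
    def test_rate_zero_identity(self):
        seq = "acgt" * 50
        out, pos = apply_shm(seq, 0.0, np.random.default_rng(0))
        assert out == seq and pos == []

    def test_mean_mutation_load_matches_binomial(self):
        rng = np.random.default_rng(42)
        n_mut = [
            len(apply_shm("acgt" * 75, 0.02, rng)[1]) for _ in range(1000)
        ]
        mean = np.mean(n_mut)
        se = np.sqrt(300 * 0.02 * 0.98 / 1000)
        assert abs(mean - 6.0) <= 3 * se

    @given(st.integers(0, 2**31 - 1))
    def test_mutated_base_always_differs(self, seed):
        rng = np.random.default_rng(seed)
        seq = "acgtgggtttaaacccgtgacgtacgtacc"
        out, pos = apply_shm(seq, 0.3, rng)
        assert len(out) == len(seq)
        for p in pos:
            assert out[p] != seq[p]
        for i in range(len(seq)):
            if i not in pos:
                assert out[i] == seq[i]


class TestSequencingErrors:
    def test_all_rates_zero_identity(self):
        config = SimulationConfig(subst_error_rate=0.0, homopolymer_indel_rate=0.0)
        out, log = apply_sequencing_errors("acgtaaagttc", config, np.random.default_rng(1))
        assert out == "acgtaaagttc" and log == []

    def test_forced_homopolymer_indels(self):
        config = SimulationConfig(subst_error_rate=0.0, homopolymer_indel_rate=0.999999)
        lengths = set()
        for seed in range(40):
            out, log = apply_sequencing_errors("aaaa", config, np.random.default_rng(seed))
            assert out in ("aaaaa", "aaa")
            lengths.add(out)
        assert lengths == {"aaaaa", "aaa"}

    def test_error_counts_match_binomial_oracle(self):
        config = SimulationConfig(subst_error_rate=0.002, homopolymer_indel_rate=0.01)
        rng = np.random.default_rng(77)
        seq = "".join(rng.choice(list("acgt"), size=10_000))
        from ighvhaplo.simulate import _homopolymer_runs

        n_runs = len(_homopolymer_runs(seq))
        out, log = apply_sequencing_errors(seq, config, rng)
        n_sub = sum(1 for op in log if op[0] == "sub")
        n_indel = len(log) - n_sub
        se_sub = np.sqrt(10_000 * 0.002 * 0.998)
        se_ind = np.sqrt(n_runs * 0.01 * 0.99)
        assert abs(n_sub - 20) <= 3 * se_sub
        assert abs(n_indel - 0.01 * n_runs) <= 3 * se_ind


class TestChimeras:
    def _dataset(self, rate, n=2000, molecule_rate=0.0, seed=19):
        config = SimulationConfig(
            n_reads=n,
            n_v_alleles=20,
            chimera_rate=rate,
            chimera_molecule_rate=molecule_rate,
            seed=seed,
        )
        rng = np.random.default_rng(seed)
        hap_a, hap_b, crefs, snps = build_parental_haplotypes(config, 0.0, rng)
        return simulate_repertoire(hap_a, hap_b, config, crefs, snps)

    def test_rate_zero_no_flags(self):
        ds = self._dataset(0.0)
        assert not any(t.is_chimera for t in ds.truth)

    def test_flagged_fraction_tracks_rate(self):
        ds = self._dataset(0.14, n=10_000)
        frac = np.mean([t.is_chimera for t in ds.truth])
        se = np.sqrt(0.14 * 0.86 / 10_000)
        assert abs(frac - 0.14) <= 3 * se

    def test_chimera_truth_chromosome_and_donors(self):
        ds = self._dataset(0.2, n=3000)
        chims = [t for t in ds.truth if t.is_chimera]
        assert chims
        for t in chims:
            assert t.chromosome == "chimera"
            assert t.donor_a and t.donor_b and t.donor_a != t.donor_b

    def test_standalone_injector_flags_and_warns(self):
        ds = self._dataset(0.0, n=400)
        rng = np.random.default_rng(5)
        reads, truth = inject_chimeras(ds.reads, ds.truth, 0.1, rng)
        frac = np.mean([t.is_chimera for t in truth])
        assert 0.02 < frac < 0.25
        with pytest.warns(UserWarning):
            inject_chimeras(ds.reads[:1], ds.truth[:1], 0.5, rng)


class TestDatasetFiles:
    def test_round_trip_and_counts(self, tmp_path):
        ds = TestChimeras()._dataset(0.05, n=300)
        paths = write_dataset(ds, tmp_path / "out")
        back = read_fastq(paths["reads"])
        assert len(back) == len(ds.reads) == 300
        for (rid, seq), r in zip(back, ds.reads):
            assert rid == r.read_id
            assert seq == r.raw_sequence()
        truth_lines = (tmp_path / "out" / "truth.tsv").read_text().splitlines()
        assert len(truth_lines) == 301  # header + one row per read

    def test_same_seed_byte_identical(self, tmp_path):
        for sub in ("a", "b"):
            ds = TestChimeras()._dataset(0.05, n=300)
            write_dataset(ds, tmp_path / sub)
        for name in ("reads.fastq", "truth.tsv", "haplotypes.fasta", "config.echo"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_path_collision_rejected(self, tmp_path):
        ds = TestChimeras()._dataset(0.0, n=50)
        write_dataset(ds, tmp_path / "out")
        with pytest.raises(FileExistsError):
            write_dataset(ds, tmp_path / "out")
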