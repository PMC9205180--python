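import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from ighvhaplo.annotate import annotate_reads, trim_primer_umi
from ighvhaplo.references import ReferenceSet
from ighvhaplo.simulate import (
    PRIMER_3P,
    PRIMER_5P,
    SimulationConfig,
    build_parental_haplotypes,
    planted_v_reference,
    simulate_repertoire,
)


def make_clean_config(n_reads=400, **kw):
    """Noise-free study conditions: no errors, no SHM, no chimeras."""
    defaults = dict(
        n_reads=n_reads,
        n_v_alleles=30,
        subst_error_rate=0.0,
        homopolymer_indel_rate=0.0,
        chimera_rate=0.0,
        chimera_molecule_rate=0.0,
        p_unmutated_igm=1.0,
        p_truncate_5p=0.0,
        seed=11,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def simulate_with_refs(config, shared_fraction=0.0):
    rng = np.random.default_rng(config.seed)
    hap_a, hap_b, crefs, snps = build_parental_haplotypes(
        config, shared_fraction, rng
    )
    dataset = simulate_repertoire(hap_a, hap_b, config, crefs, snps)
    refs = planted_v_reference(hap_a, hap_b)
    j_refs = ReferenceSet(label="J")
    for hap in (hap_a, hap_b):
        for a in hap.j_alleles:
            if a.name not in j_refs:
                j_refs.add(a)
    d_refs = ReferenceSet(dataset.hap_a.d_alleles, label="D")
    return dataset, refs, j_refs, d_refs


def trim_dataset(dataset):
    out = []
    umis = {}
    for r in dataset.reads:
        res = trim_primer_umi(
            r.raw_sequence(),
            PRIMER_5P,
            PRIMER_3P[r.isotype],
            dataset.config.umi_length,
        )
        if res.ok:
            out.append((r.read_id, res.sequence))
            umis[r.read_id] = res.umi
    return out, umis


@pytest.fixture(scope="session")
def clean_world():
    """Small noise-free dataset with planted references and annotations."""
    config = make_clean_config()
    dataset, refs, j_refs, d_refs = simulate_with_refs(config)
    trimmed, umis = trim_dataset(dataset)
    records = annotate_reads(trimmed, refs, j_refs, d_refs, umis=umis)
    return {
        "dataset": dataset,
        "refs": refs,
        "j_refs": j_refs,
        "d_refs": d_refs,
        "records": records,
        "truth": dataset.truth_by_id(),
    }


@pytest.fixture(scope="session")
def noisy_world():
    """Default-noise dataset (errors, SHM, chimeras) at moderate depth."""
    config = SimulationConfig(n_reads=4000, n_v_alleles=30, seed=23)
    dataset, refs, j_refs, d_refs = simulate_with_refs(config, shared_fraction=0.0)
    trimmed, umis = trim_dataset(dataset)
    records = annotate_reads(trimmed, refs, j_refs, d_refs, umis=umis, call_d=False)
    return {
        "dataset": dataset,
        "refs": refs,
        "j_refs": j_refs,
        "records": records,
        "truth": dataset.truth_by_id(),
    }
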