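"""Synthetic F1-hybrid VDJ-C long-read repertoire generator.

The generator emulates an IgM/IgG CH3-primed long-read amplicon experiment on
F1 offspring of two fully homozygous inbred strains: every B-cell molecule
derives from exactly one parental chromosome, V/D/J segments are drawn with
strongly skewed per-allele usage (spanning roughly 0.01%-5%), junctions carry
exonuclease trims and N insertions, IgM molecules are mostly unmutated, the
constant region carries the strain-defining SNPs, and reads are PCR/sequencing
copies of molecules with substitution and homopolymer-indel noise plus
template-switch (chimeric) artefacts.

Ground truth (molecule of origin, chromosome, planted segments, trims,
mutations, error operations and chimera donors) is recorded per read so that
every downstream inference step can be scored by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constant import CRegionReference, StrainSNP
from .references import GermlineAllele, ReferenceSet, load_c_exon_table

BASES = np.frombuffer(b"acgt", dtype=np.int8)
_COMPLEMENT = str.maketrans("acgt", "tgca")

# CH3 primer sequences of the amplification protocol (universal forward +
# isotype-specific reverse)
PRIMER_5P = "aagcagtggtatcaacgcagagt"
PRIMER_3P = {
    "IgM": "cagatccctgtgagtcacagtacac",
    "IgG": "atgaagtaagaaccatcagagtccaggac",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def _geometric(rng: np.random.Generator, mean: float) -> int:
    """Geometric draw on {0, 1, 2, ...} with the given mean."""
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (mean + 1.0))) - 1


# ---------------------------------------------------------------------------
# configuration and haplotypes


@dataclass
class SimulationConfig:
    """Study conditions for one simulated F1 dataset.

    The defaults are the regime the inference pipeline is designed for:
    50,000 CCS-grade reads, IgM-dominated, per-allele usage 0.01%-5%,
    a 14% template-switch rate (the pre-filter anchor-discordance scale),
    low substitution noise and homopolymer-biased indels.
    """

    n_reads: int = 50_000
    isotype_mix: dict = field(default_factory=lambda: {"IgM": 1.0})
    chimera_rate: float = 0.14
    # early-cycle (pre-UMI) template switches: whole molecules, and hence all
    # their read copies, are chimeric; these survive UMI-level confidence
    # filters and set the residual post-filter chimerism scale
    chimera_molecule_rate: float = 0.01
    shm_rate_igm: float = 0.005
    shm_rate_igg: float = 0.02
    p_unmutated_igm: float = 0.8
    trim_mean_v3: float = 2.0
    trim_mean_j5: float = 2.0
    trim_mean_d: float = 1.5
    n_insert_max: int = 8
    subst_error_rate: float = 0.001
    homopolymer_indel_rate: float = 0.003
    umi_length: int = 16
    reads_per_molecule_mean: float = 2.5
    p_truncate_5p: float = 0.05
    n_v_alleles: int = 100
    chimera_breakpoint: str = "c_region"  # or "v_region"
    strain_labels: tuple = ("BALB", "B6")
    seed: int = 0

    def validate(self) -> None:
        rates = [
            self.chimera_rate,
            self.chimera_molecule_rate,
            self.shm_rate_igm,
            self.shm_rate_igg,
            self.subst_error_rate,
            self.homopolymer_indel_rate,
            self.p_truncate_5p,
        ]
        if any(not (0.0 <= p < 1.0) for p in rates):
            raise ValueError("rates must lie in [0, 1)")
        if not 0.0 <= self.p_unmutated_igm <= 1.0:
            raise ValueError("p_unmutated_igm must lie in [0, 1]")
        if abs(sum(self.isotype_mix.values()) - 1.0) > 1e-9:
            raise ValueError("isotype_mix must sum to 1")
        if self.chimera_breakpoint not in ("c_region", "v_region"):
            raise ValueError("chimera_breakpoint must be c_region or v_region")

    def as_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            d[k] = v
        return d


@dataclass
class ParentalHaplotype:
    """One parental chromosome: germline segments plus usage profile."""

    strain_label: str
    v_alleles: list
    d_alleles: list
    j_alleles: list
    c_genes: dict  # isotype/subclass label -> ordered exon sequences
    usage_weights: dict  # allele name -> probability (per segment type)

    def validate(self) -> None:
        for group in (self.v_alleles, self.d_alleles, self.j_alleles):
            names = [a.name for a in group]
            if len(set(names)) != len(names):
                raise ValueError("duplicate allele names within haplotype")
            tot = sum(self.usage_weights[n] for n in names)
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"usage weights sum to {tot}, expected 1")

    def weights_for(self, alleles: Sequence[GermlineAllele]) -> np.ndarray:
        w = np.array([self.usage_weights[a.name] for a in alleles])
        return w / w.sum()


@dataclass
class TruthRecord:
    """Planted origin of one emitted read."""

    read_id: str
    molecule_id: str
    chromosome: str  # strain label or "chimera"
    isotype: str
    c_gene: str
    v_call: str
    d_call: str
    j_call: str
    v_trim_3p: int
    d_trim_5p: int
    d_trim_3p: int
    j_trim_5p: int
    n1: str
    n2: str
    shm_positions: tuple
    error_ops: tuple
    vdj_length: int
    truncated_5p: int
    is_chimera: bool
    donor_a: str = ""
    donor_b: str = ""
    shm_free: bool = True


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str  # amplicon after UMI/primer removal (V..CH3-primer site)
    umi: str
    isotype: str

    def raw_sequence(self) -> str:
        """Full library read: UMI + forward primer + amplicon + rev primer."""
        return (
            self.umi + PRIMER_5P + self.sequence + revcomp(PRIMER_3P[self.isotype])
        )


@dataclass
class SimulatedDataset:
    reads: list
    truth: list
    hap_a: ParentalHaplotype
    hap_b: ParentalHaplotype
    config: SimulationConfig
    c_references: dict  # isotype -> CRegionReference (canonical strain A)
    snps: list

    def truth_by_id(self) -> dict:
        return {t.read_id: t for t in self.truth}

    def truth_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            d = dict(t.__dict__)
            d["shm_positions"] = ",".join(map(str, t.shm_positions))
            d["error_ops"] = ",".join(":".join(map(str, op)) for op in t.error_ops)
            rows.append(d)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# germline construction

_CYS_MOTIF = "tattactgt"  # FR3 end; cys codon is the final tgt
_J_MOTIF = "ctggggt"  # contains the J-TRP anchor tgggg


def _make_v_family(
    rng: np.random.Generator, family: int, n_members: int, existing: set
) -> list[GermlineAllele]:
    length = int(rng.integers(291, 306))
    cys = length - 15
    founder = random_dna(rng, cys - len(_CYS_MOTIF) + 3) + _CYS_MOTIF + random_dna(
        rng, length - cys - 3
    )
    assert founder[cys : cys + 3] == "tgt"
    members = []
    seqs = {founder} | existing
    attempt = 0
    while len(members) < n_members and attempt < 200:
        attempt += 1
        n_mut = int(rng.integers(2, 9))
        seq = list(founder)
        # keep the last 12 nt and the cysteine codon untouched so alleles stay
        # distinguishable under 3' exonuclease trimming
        positions = rng.choice(
            [p for p in range(len(founder) - 12) if not cys <= p < cys + 3],
            size=n_mut,
            replace=False,
        )
        for p in positions:
            alts = [b for b in "acgt" if b != founder[p]]
            seq[p] = alts[int(rng.integers(3))]
        s = "".join(seq)
        if s in seqs:
            continue
        if any(
            sum(x != y for x, y in zip(s, m.sequence)) < 2
            for m in members
            if len(m.sequence) == len(s)
        ):
            continue
        seqs.add(s)
        members.append(
            GermlineAllele(
                name=f"IGHV{family}-{len(members) + 1}*01",
                segment="V",
                sequence=s,
                metadata={"cys": str(cys)},
            )
        )
    return members


def _make_j_alleles(rng: np.random.Generator) -> tuple[list, list]:
    """Four J genes; IGHJ1 has two alleles differing at a single SNP."""
    shared = []
    for g in (2, 3, 4):
        length = int(rng.integers(46, 54))
        pos = int(rng.integers(12, 20))
        seq = (
            random_dna(rng, pos)
            + _J_MOTIF
            + random_dna(rng, length - pos - len(_J_MOTIF))
        )
        shared.append(
            GermlineAllele(
                name=f"IGHJ{g}*01",
                segment="J",
                sequence=seq,
                metadata={"motif": str(pos + 1)},
            )
        )
    length = 50
    pos = 15
    base = (
        random_dna(rng, pos) + _J_MOTIF + random_dna(rng, length - pos - len(_J_MOTIF))
    )
    snp_pos = 5
    alt = [b for b in "acgt" if b != base[snp_pos]][int(rng.integers(3))]
    j1_01 = GermlineAllele(
        name="IGHJ1*01", segment="J", sequence=base, metadata={"motif": str(pos + 1)}
    )
    j1_03 = GermlineAllele(
        name="IGHJ1*03",
        segment="J",
        sequence=base[:snp_pos] + alt + base[snp_pos + 1 :],
        metadata={"motif": str(pos + 1)},
    )
    return [j1_01] + shared, [j1_03] + shared


def _make_d_alleles(rng: np.random.Generator, n: int = 12) -> list:
    out = []
    for i in range(n):
        out.append(
            GermlineAllele(
                name=f"IGHD{i + 1}*01",
                segment="D",
                sequence=random_dna(rng, int(rng.integers(12, 19))),
            )
        )
    return out


def _log_uniform(rng, low, high, size):
    return np.exp(rng.uniform(np.log(low), np.log(high), size=size))


def _build_c_genes(rng: np.random.Generator, strains: tuple) -> tuple[dict, dict, dict, list]:
    """Constant-region genes per strain plus typing metadata.

    IGHM CH1 exons are the published strain pair (single-SNP rule);
    the remaining exons and the IGHG genes are synthetic stand-ins with the
    named SNPs planted at documented offsets.
    """
    table2 = load_c_exon_table()
    ighm_balb = table2["IGHM_CH1_BALB"]
    ighm_b6 = table2["IGHM_CH1_B6"]
    m_off = int(ighm_balb.metadata["snp_offset"])

    m_ch2 = random_dna(rng, 220)
    m_ch3 = random_dna(rng, 120)

    g2b_ch1_a = table2["IGHG2B_CH1_BALB"].sequence
    g_off1 = 100
    while g2b_ch1_a[g_off1] != "c":
        g_off1 += 1
    g2b_ch1_b = g2b_ch1_a[:g_off1] + "t" + g2b_ch1_a[g_off1 + 1 :]
    hinge = random_dna(rng, 35)
    g2b_ch2_a = random_dna(rng, 200)
    ch2_offsets = [40, 95, 150]
    g2b_ch2_b = list(g2b_ch2_a)
    ch2_alt = []
    for off in ch2_offsets:
        alt = [b for b in "acgt" if b != g2b_ch2_a[off]][int(rng.integers(3))]
        g2b_ch2_b[off] = alt
        ch2_alt.append(alt)
    g2b_ch2_b = "".join(g2b_ch2_b)
    g_ch3 = random_dna(rng, 110)

    g2a = [random_dna(rng, n) for n in (290, 35, 200, 110)]
    g2c = [random_dna(rng, n) for n in (290, 35, 200, 110)]

    sa, sb = strains
    c_a = {
        "IgM": [ighm_balb.sequence, m_ch2, m_ch3],
        "IgG2a": g2a,
        "IgG2b": [g2b_ch1_a, hinge, g2b_ch2_a, g_ch3],
    }
    c_b = {
        "IgM": [ighm_b6.sequence, m_ch2, m_ch3],
        "IgG2b": [g2b_ch1_b, hinge, g2b_ch2_b, g_ch3],
        "IgG2c": g2c,
    }
    snps = [
        StrainSNP("rs29176517", "IGHM", "CH1", m_off, {sa: "g", sb: "a"}),
        StrainSNP("rs45969375", "IGHG2B", "CH1", g_off1, {sa: "c", sb: "t"}),
        StrainSNP(
            "rs49934817", "IGHG2B", "CH2", ch2_offsets[0], {sa: g2b_ch2_a[40], sb: ch2_alt[0]}
        ),
        StrainSNP(
            "rs45822066", "IGHG2B", "CH2", ch2_offsets[1], {sa: g2b_ch2_a[95], sb: ch2_alt[1]}
        ),
        StrainSNP(
            "rs46899601", "IGHG2B", "CH2", ch2_offsets[2], {sa: g2b_ch2_a[150], sb: ch2_alt[2]}
        ),
    ]
    crefs = {
        "IgM": CRegionReference(
            gene="IGHM",
            isotype="IgM",
            exon_names=["CH1", "CH2", "CH3"],
            exon_seqs=c_a["IgM"],
            snps=[snps[0]],
        ),
        "IgG2b": CRegionReference(
            gene="IGHG2B",
            isotype="IgG",
            exon_names=["CH1", "H", "CH2", "CH3"],
            exon_seqs=c_a["IgG2b"],
            snps=snps[1:],
        ),
    }
    return c_a, c_b, crefs, snps


def build_parental_haplotypes(
    config: SimulationConfig,
    shared_fraction: float = 0.04,
    rng: np.random.Generator | None = None,
):
    """Construct two homozygous parental IGH haplotypes.

    The V sets overlap by exactly ``round(shared_fraction * n_v)`` alleles,
    the constant-region genes differ at every configured strain SNP, and the
    IGHJ1 alleles differ by a single base.  Returns ``(hap_a, hap_b,
    c_references, snps)``; the C references are the canonical (strain A)
    exon sets used for indel correction and SNP extraction.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_v = config.n_v_alleles
    n_shared = round(shared_fraction * n_v)
    if n_shared > n_v:
        raise ValueError("shared count exceeds V set size")

    n_total = 2 * n_v - n_shared
    members: list[GermlineAllele] = []
    fam = 0
    existing: set[str] = set()
    while len(members) < n_total:
        fam += 1
        got = _make_v_family(rng, fam, min(16, n_total - len(members)), existing)
        existing |= {m.sequence for m in got}
        members.extend(got)
    order = rng.permutation(len(members))
    members = [members[i] for i in order]
    shared = members[:n_shared]
    only_a = members[n_shared : n_shared + (n_v - n_shared)]
    only_b = members[n_shared + (n_v - n_shared) :]

    d_alleles = _make_d_alleles(rng)
    j_a, j_b = _make_j_alleles(rng)
    c_a, c_b, crefs, snps = _build_c_genes(rng, config.strain_labels)

    def usage(v_list, shared_list):
        w = _log_uniform(rng, 1e-4, 5e-2, len(v_list))
        ws = _log_uniform(rng, 5e-3, 2e-2, len(shared_list))
        names = [a.name for a in v_list] + [a.name for a in shared_list]
        vals = np.concatenate([w, ws])
        vals = vals / vals.sum()
        return dict(zip(names, vals))

    def seg_usage(alleles, low, high):
        w = _log_uniform(rng, low, high, len(alleles))
        w = w / w.sum()
        return dict(zip([a.name for a in alleles], w))

    d_usage = seg_usage(d_alleles, 0.02, 0.2)
    j_usage = {"IGHJ1*01": 0.25, "IGHJ2*01": 0.30, "IGHJ3*01": 0.25, "IGHJ4*01": 0.20}
    j_usage_b = {"IGHJ1*03": 0.25, "IGHJ2*01": 0.30, "IGHJ3*01": 0.25, "IGHJ4*01": 0.20}

    sa, sb = config.strain_labels
    hap_a = ParentalHaplotype(
        strain_label=sa,
        v_alleles=only_a + shared,
        d_alleles=d_alleles,
        j_alleles=j_a,
        c_genes=c_a,
        usage_weights={**usage(only_a, shared), **d_usage, **j_usage},
    )
    hap_b = ParentalHaplotype(
        strain_label=sb,
        v_alleles=only_b + shared,
        d_alleles=d_alleles,
        j_alleles=j_b,
        c_genes=c_b,
        usage_weights={**usage(only_b, shared), **d_usage, **j_usage_b},
    )
    for a in hap_a.v_alleles:
        a.metadata.setdefault("strain", sa)
    for b in hap_b.v_alleles:
        b.metadata["strain"] = (
            f"{sa},{sb}" if b in set(shared) else sb
        )
    hap_a.validate()
    hap_b.validate()
    return hap_a, hap_b, crefs, snps


# ---------------------------------------------------------------------------
# molecular events


def apply_shm(
    sequence: str, rate: float, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Independent per-base substitutions, never to the same base."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0 or not sequence:
        return sequence, []
    hits = np.nonzero(rng.random(len(sequence)) < rate)[0]
    if len(hits) == 0:
        return sequence, []
    seq = list(sequence)
    for p in hits:
        alts = [b for b in "acgt" if b != seq[p]]
        seq[p] = alts[int(rng.integers(3))]
    return "".join(seq), [int(p) for p in hits]


def _homopolymer_runs(seq: str) -> list[tuple[int, int]]:
    """(start, length) of maximal runs of identical bases with length >= 2."""
    n = len(seq)
    if n < 2:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.int8)
    change = np.nonzero(arr[1:] != arr[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    lens = ends - starts
    keep = lens >= 2
    return list(zip(starts[keep].tolist(), lens[keep].tolist()))


def apply_sequencing_errors(
    sequence: str, config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, list[tuple]]:
    """CCS-like noise: rare substitutions plus homopolymer-run indels.

    Each maximal homopolymer run (length >= 2) gains or loses one copy of
    its base with probability ``homopolymer_indel_rate``.  The error log
    holds ``(kind, position, base)`` tuples with positions in the input
    coordinate system.
    """
    log = []
    seq = list(sequence)
    subs = np.nonzero(rng.random(len(seq)) < config.subst_error_rate)[0]
    for p in subs:
        alts = [b for b in "acgt" if b != seq[p]]
        b = alts[int(rng.integers(3))]
        log.append(("sub", int(p), b))
        seq[p] = b
    runs = _homopolymer_runs(sequence)
    if runs:
        hit = np.nonzero(rng.random(len(runs)) < config.homopolymer_indel_rate)[0]
        # apply right-to-left so earlier positions stay valid
        for ri in hit[::-1]:
            start, length = runs[ri]
            if rng.random() < 0.5:
                seq.insert(start, sequence[start])
                log.append(("ins", start, sequence[start]))
            else:
                del seq[start]
                log.append(("del", start, sequence[start]))
    return "".join(seq), log


def simulate_rearrangement(
    hap: ParentalHaplotype,
    isotype: str,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
) -> tuple[str, dict]:
    """One germline VDJ-C molecule (before SHM and sequencing noise)."""
    if config is None:
        config = SimulationConfig()
    if isotype not in hap.c_genes:
        raise ValueError(f"isotype {isotype!r} not in haplotype C genes")
    v = hap.v_alleles[
        rng.choice(len(hap.v_alleles), p=hap.weights_for(hap.v_alleles))
    ]
    d = hap.d_alleles[
        rng.choice(len(hap.d_alleles), p=hap.weights_for(hap.d_alleles))
    ]
    j = hap.j_alleles[
        rng.choice(len(hap.j_alleles), p=hap.weights_for(hap.j_alleles))
    ]
    while True:
        vt = _geometric(rng, config.trim_mean_v3)
        if vt < len(v.sequence):
            break
    while True:
        dt5 = _geometric(rng, config.trim_mean_d)
        dt3 = _geometric(rng, config.trim_mean_d)
        if dt5 + dt3 < len(d.sequence):
            break
    while True:
        jt = _geometric(rng, config.trim_mean_j5)
        if jt < len(j.sequence):
            break
    n1 = random_dna(rng, int(rng.integers(0, config.n_insert_max + 1)))
    n2 = random_dna(rng, int(rng.integers(0, config.n_insert_max + 1)))
    vdj = (
        v.sequence[: len(v.sequence) - vt]
        + n1
        + d.sequence[dt5 : len(d.sequence) - dt3]
        + n2
        + j.sequence[jt:]
    )
    c = "".join(hap.c_genes[isotype])
    truth = dict(
        chromosome=hap.strain_label,
        isotype="IgG" if isotype.startswith("IgG") else isotype,
        c_gene=isotype,
        v_call=v.name,
        d_call=d.name,
        j_call=j.name,
        v_trim_3p=vt,
        d_trim_5p=dt5,
        d_trim_3p=dt3,
        j_trim_5p=jt,
        n1=n1,
        n2=n2,
        vdj_length=len(vdj),
    )
    return vdj + c, truth


# ---------------------------------------------------------------------------
# repertoire assembly


def simulate_repertoire(
    hap_a: ParentalHaplotype,
    hap_b: ParentalHaplotype,
    config: SimulationConfig,
    c_references: dict | None = None,
    snps: list | None = None,
) -> SimulatedDataset:
    """Full read-level dataset with molecule duplication and artefacts."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    haps = (hap_a, hap_b)
    iso_names = list(config.isotype_mix)
    iso_probs = np.array([config.isotype_mix[k] for k in iso_names])

    molecules = []  # (mol_id, seq, vdj_len, truth-dict, umi, isotype-class)
    n_assigned = 0
    mi = 0
    while n_assigned < config.n_reads:
        hap = haps[int(rng.integers(2))]
        iso = iso_names[int(rng.choice(len(iso_names), p=iso_probs))]
        if iso == "IgG":
            subclasses = sorted(k for k in hap.c_genes if k.startswith("IgG"))
            gene = subclasses[int(rng.integers(len(subclasses)))]
        else:
            gene = iso
        seq, tr = simulate_rearrangement(hap, gene, rng, config)
        # somatic hypermutation on the VDJ portion, at the molecule level
        if tr["isotype"] == "IgM":
            mutate = rng.random() >= config.p_unmutated_igm
            rate = config.shm_rate_igm if mutate else 0.0
        else:
            rate = config.shm_rate_igg
        vdj_part, shm_pos = apply_shm(seq[: tr["vdj_length"]], rate, rng)
        seq = vdj_part + seq[tr["vdj_length"] :]
        trunc = 0
        if config.p_truncate_5p > 0 and rng.random() < config.p_truncate_5p:
            trunc = int(rng.integers(20, 81))
            seq = seq[trunc:]
        tr["shm_positions"] = tuple(shm_pos)
        tr["truncated_5p"] = trunc
        tr["shm_free"] = len(shm_pos) == 0
        umi = random_dna(rng, config.umi_length)
        n_copies = int(rng.geometric(1.0 / config.reads_per_molecule_mean))
        n_copies = min(n_copies, config.n_reads - n_assigned)
        mol_id = f"mol{mi:06d}"
        molecules.append((mol_id, seq, tr, umi, n_copies))
        n_assigned += n_copies
        mi += 1

    # chromosome pools for chimera donor lookup
    pool = {}
    for k, (mol_id, seq, tr, umi, n_copies) in enumerate(molecules):
        if n_copies == 0:
            continue
        pool.setdefault((tr["chromosome"], tr["isotype"]), []).append(k)

    snp_off = None
    if c_references and "IgM" in c_references:
        snp_off = c_references["IgM"].global_offset(c_references["IgM"].snps[0])

    # early-cycle template switches: convert whole molecules into chimeras
    # (VDJ from the molecule itself, constant region from the other strain)
    other_c = {hap_a.strain_label: hap_b, hap_b.strain_label: hap_a}
    if config.chimera_molecule_rate > 0:
        for k, (mol_id, seq, tr, umi, n_copies) in enumerate(molecules):
            if tr["isotype"] != "IgM" or n_copies == 0:
                continue
            donor_hap = other_c[tr["chromosome"]]
            key = (donor_hap.strain_label, "IgM")
            if key not in pool:
                continue
            if rng.random() >= config.chimera_molecule_rate:
                continue
            donor_k = pool[key][int(rng.integers(len(pool[key])))]
            chim_seq = seq[: tr["vdj_length"] - tr["truncated_5p"]] + "".join(
                donor_hap.c_genes["IgM"]
            )
            tr = dict(tr)
            tr["chromosome"] = "chimera"
            tr["_donor_a"] = mol_id
            tr["_donor_b"] = molecules[donor_k][0]
            molecules[k] = (mol_id, chim_seq, tr, umi, n_copies)

    reads = []
    truth = []
    ri = 0
    for mol_id, seq, tr, umi, n_copies in molecules:
        for _ in range(n_copies):
            read_id = f"read{ri:06d}"
            ri += 1
            is_chim = (
                config.chimera_rate > 0
                and tr["isotype"] == "IgM"
                and rng.random() < config.chimera_rate
            )
            if is_chim:
                rec, sr = _make_chimera(
                    molecules, pool, tr["isotype"], rng, config, snp_off, read_id, umi
                )
                if rec is not None:
                    truth.append(rec)
                    reads.append(sr)
                    continue
            noisy, log = apply_sequencing_errors(seq, config, rng)
            reads.append(SimulatedRead(read_id, noisy, umi, tr["isotype"]))
            base = {k: v for k, v in tr.items() if not k.startswith("_")}
            truth.append(
                TruthRecord(
                    read_id=read_id,
                    molecule_id=mol_id,
                    error_ops=tuple(log),
                    is_chimera="_donor_a" in tr,
                    donor_a=tr.get("_donor_a", ""),
                    donor_b=tr.get("_donor_b", ""),
                    **base,
                )
            )
    return SimulatedDataset(
        reads=reads,
        truth=truth,
        hap_a=hap_a,
        hap_b=hap_b,
        config=config,
        c_references=c_references or {},
        snps=snps or [],
    )


def _make_chimera(molecules, pool, isotype, rng, config, snp_off, read_id, umi):
    """Template-switch product between molecules of opposite chromosomes."""
    chroms = sorted({c for (c, i) in pool if i == isotype})
    if len(chroms) < 2:
        return None, None
    ca = chroms[int(rng.integers(2))]
    cb = [c for c in chroms if c != ca][0]
    ka = pool[(ca, isotype)][int(rng.integers(len(pool[(ca, isotype)])))]
    kb = pool[(cb, isotype)][int(rng.integers(len(pool[(cb, isotype)])))]
    ma, mb = molecules[ka], molecules[kb]
    seq_a, tr_a = ma[1], ma[2]
    seq_b, tr_b = mb[1], mb[2]
    vlen_a = tr_a["vdj_length"] - tr_a["truncated_5p"]
    vlen_b = tr_b["vdj_length"] - tr_b["truncated_5p"]
    if config.chimera_breakpoint == "v_region":
        hi = min(vlen_a, vlen_b, 280)
        bp = int(rng.integers(30, max(31, hi)))
        product = seq_a[:bp] + seq_b[bp:]
    else:
        # switch between the end of J and the CH1 strain SNP: the VDJ travels
        # with template A, the typable constant region with template B
        hi = snp_off if snp_off is not None else 290
        bp = int(rng.integers(0, hi + 1))
        product = seq_a[: vlen_a + bp] + seq_b[vlen_b + bp :]
    noisy, log = apply_sequencing_errors(product, config, rng)
    rec = TruthRecord(
        read_id=read_id,
        molecule_id=ma[0],
        chromosome="chimera",
        isotype=isotype,
        c_gene=tr_b["c_gene"],
        v_call=tr_a["v_call"],
        d_call=tr_a["d_call"],
        j_call=tr_a["j_call"],
        v_trim_3p=tr_a["v_trim_3p"],
        d_trim_5p=tr_a["d_trim_5p"],
        d_trim_3p=tr_a["d_trim_3p"],
        j_trim_5p=tr_a["j_trim_5p"],
        n1=tr_a["n1"],
        n2=tr_a["n2"],
        shm_positions=tuple(tr_a["shm_positions"]),
        error_ops=tuple(log),
        vdj_length=tr_a["vdj_length"],
        truncated_5p=tr_a["truncated_5p"],
        is_chimera=True,
        donor_a=ma[0],
        donor_b=mb[0],
        shm_free=tr_a["shm_free"],
    )
    return rec, SimulatedRead(read_id, noisy, umi, isotype)


def inject_chimeras(
    reads: list,
    truth: list,
    rate: float,
    rng: np.random.Generator,
    breakpoint_mode: str = "v_region",
) -> tuple[list, list]:
    """Replace a fraction of reads with template-switch products.

    Standalone variant operating on an already-emitted read list (the
    repertoire simulator injects chimeras inline); breakpoints fall inside
    the V region on homologous coordinates.  Donor reads are drawn from
    distinct molecules; replaced reads are flagged ``is_chimera`` with
    chromosome ``"chimera"``.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if len(reads) < 2:
        import warnings

        warnings.warn("fewer than 2 reads; chimera injection is a no-op")
        return reads, truth
    reads = list(reads)
    truth = list(truth)
    flags = np.nonzero(rng.random(len(reads)) < rate)[0]
    for idx in flags:
        ia, ib = rng.choice(len(reads), size=2, replace=False)
        ta, tb = truth[ia], truth[ib]
        hi = min(ta.vdj_length, tb.vdj_length, 280)
        if hi <= 31:
            continue
        bp = int(rng.integers(30, hi))
        product = reads[ia].sequence[:bp] + reads[ib].sequence[bp:]
        reads[idx] = SimulatedRead(
            truth[idx].read_id, product, reads[idx].umi, ta.isotype
        )
        truth[idx] = replace(
            ta,
            read_id=truth[idx].read_id,
            chromosome="chimera",
            is_chimera=True,
            donor_a=ta.molecule_id,
            donor_b=tb.molecule_id,
            c_gene=tb.c_gene,
        )
    return reads, truth


# ---------------------------------------------------------------------------
# reference construction for annotation studies


def planted_v_reference(hap_a, hap_b, label="planted") -> ReferenceSet:
    refs = ReferenceSet(label=label)
    for hap in (hap_a, hap_b):
        for a in hap.v_alleles:
            if a.name not in refs:
                refs.add(a)
    return refs


def build_annotation_reference(
    hap_a: ParentalHaplotype,
    hap_b: ParentalHaplotype,
    rng: np.random.Generator,
    hold_out: Sequence[str] = (),
    add_sequences: Sequence[GermlineAllele] = (),
    n_decoys: int = 20,
    min_decoy_distance: int = 3,
) -> ReferenceSet:
    """Starting V reference for inference studies.

    The union of both parental V sets, minus ``hold_out`` (alleles the
    genotype pipeline must rediscover), plus ``add_sequences`` (e.g. the
    ancestral variant of a planted novel allele) and random decoy alleles at
    >= ``min_decoy_distance`` substitutions from every planted sequence
    (database entries absent from this genotype).
    """
    refs = ReferenceSet(label="annotation")
    planted = []
    for hap in (hap_a, hap_b):
        for a in hap.v_alleles:
            if a.name in hold_out:
                planted.append(a.sequence)
                continue
            if a.name not in refs:
                refs.add(a)
                planted.append(a.sequence)
    for a in add_sequences:
        refs.add(a)
        planted.append(a.sequence)
    base_pool = [a for a in refs if a.segment == "V"]
    made = 0
    attempts = 0
    while made < n_decoys and attempts < 50 * n_decoys:
        attempts += 1
        src = base_pool[int(rng.integers(len(base_pool)))]
        seq = list(src.sequence)
        n_mut = min_decoy_distance + int(rng.integers(0, 3))
        positions = rng.choice(len(seq) - 12, size=n_mut, replace=False)
        for p in positions:
            alts = [b for b in "acgt" if b != seq[p]]
            seq[p] = alts[int(rng.integers(3))]
        s = "".join(seq)
        if any(
            len(p) == len(s) and sum(x != y for x, y in zip(s, p)) < min_decoy_distance
            for p in planted
        ):
            continue
        made += 1
        refs.add(
            GermlineAllele(
                name=f"decoyIGHV{made:03d}*01",
                segment="V",
                sequence=s,
                metadata=dict(src.metadata),
            )
        )
    return refs


# ---------------------------------------------------------------------------
# dataset files


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict:
    """Write reads.fastq, truth.tsv, haplotypes.fasta and config.echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": out / "reads.fastq",
        "truth": out / "truth.tsv",
        "haplotypes": out / "haplotypes.fasta",
        "config": out / "config.echo",
    }
    for p in paths.values():
        if p.exists():
            raise FileExistsError(f"refusing to overwrite {p}")
    if len(dataset.reads) != len(dataset.truth):
        raise ValueError("one truth record required per read")
    with open(paths["reads"], "w") as fh:
        for r in dataset.reads:
            raw = r.raw_sequence()
            fh.write(f"@{r.read_id}\n{raw}\n+\n{'?' * len(raw)}\n")
    dataset.truth_dataframe().to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["haplotypes"], "w") as fh:
        for hap in (dataset.hap_a, dataset.hap_b):
            for group in (hap.v_alleles, hap.d_alleles, hap.j_alleles):
                for a in group:
                    fh.write(
                        f">{a.name}|strain={hap.strain_label}|segment={a.segment}"
                    )
                    for k, v in a.metadata.items():
                        if k != "strain":
                            fh.write(f"|{k}={v}")
                    fh.write(f"\n{a.sequence}\n")
            for gene, exons in hap.c_genes.items():
                fh.write(
                    f">{gene}|strain={hap.strain_label}|segment=C-exon\n"
                    + "".join(exons)
                    + "\n"
                )
    with open(paths["config"], "w") as fh:
        for k, v in dataset.config.as_dict().items():
            fh.write(f"{k}={v}\n")
    return paths


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTQ file."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).lower()) for rec in SeqIO.parse(str(path), "fastq")]
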