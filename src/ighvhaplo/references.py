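"""Germline reference containers and FASTA I/O.

A germline reference set is a named collection of V, D, J or C-exon alleles.
FASTA headers may carry ``|key=value`` metadata fields after the allele name,
e.g. ``>IGHV1-2*01|strain=C57BL/6|cys=279``; these are preserved on round trip
and used by the annotator (conserved-cysteine position) and the haplotyper
(strain tags).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

VALID_ALPHABET = frozenset("acgtn")

SEGMENT_TYPES = ("V", "D", "J", "C-exon")
FUNCTIONALITY = ("functional", "ORF", "pseudogene", "unknown")
PROVENANCE = ("reported", "extended", "inferred")


@dataclass(frozen=True)
class GermlineAllele:
    """A named germline gene segment sequence.

    ``metadata`` holds free-form ``key=value`` pairs from the FASTA header;
    recognised keys include ``strain``, ``cys`` (0-based position of the
    conserved FR3 cysteine codon, V alleles only), ``snp_offset`` and
    ``snp_base`` (C exons).
    """

    name: str
    segment: str
    sequence: str
    functionality: str = "functional"
    strain: str | None = None
    provenance: str = "reported"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not self.name:
            raise ValueError("allele name must be non-empty")
        if self.segment not in SEGMENT_TYPES:
            raise ValueError(f"unknown segment type {self.segment!r}")
        if not self.sequence:
            raise ValueError(f"{self.name}: sequence must be non-empty")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(f"{self.name}: invalid characters {sorted(bad)}")
        if self.functionality not in FUNCTIONALITY:
            raise ValueError(f"unknown functionality {self.functionality!r}")
        if self.provenance not in PROVENANCE:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cys_position(self) -> int | None:
        """0-based start of the conserved cysteine codon, if annotated."""
        v = self.metadata.get("cys")
        return int(v) if v is not None else None

    def with_sequence(self, sequence: str, **changes) -> "GermlineAllele":
        return replace(self, sequence=sequence, **changes)


class ReferenceSet:
    """An ordered, name-unique collection of germline alleles."""

    def __init__(self, alleles: Iterable[GermlineAllele] = (), label: str = ""):
        self.label = label
        self._alleles: dict[str, GermlineAllele] = {}
        for a in alleles:
            self.add(a)

    def add(self, allele: GermlineAllele) -> None:
        if allele.name in self._alleles:
            raise ValueError(f"duplicate allele name {allele.name!r}")
        self._alleles[allele.name] = allele

    def remove(self, name: str) -> None:
        del self._alleles[name]

    def __contains__(self, name: str) -> bool:
        return name in self._alleles

    def __getitem__(self, name: str) -> GermlineAllele:
        return self._alleles[name]

    def __iter__(self) -> Iterator[GermlineAllele]:
        return iter(self._alleles.values())

    def __len__(self) -> int:
        return len(self._alleles)

    @property
    def names(self) -> list[str]:
        return list(self._alleles)

    def subset(self, names: Iterable[str], label: str | None = None) -> "ReferenceSet":
        return ReferenceSet(
            (self._alleles[n] for n in names),
            label=label if label is not None else self.label,
        )

    def of_segment(self, segment: str) -> "ReferenceSet":
        return ReferenceSet(
            (a for a in self if a.segment == segment), label=self.label
        )

    def identical_sequence_groups(self) -> list[list[str]]:
        """Groups of allele names sharing an identical sequence.

        Duplicate sequences under different names are legitimate (identical
        genes at different loci), so this reports rather than fails.
        """
        by_seq: dict[str, list[str]] = {}
        for a in self:
            by_seq.setdefault(a.sequence, []).append(a.name)
        return [names for names in by_seq.values() if len(names) > 1]


# ---------------------------------------------------------------------------
# FASTA I/O with |key=value header metadata


def _parse_header(header: str) -> tuple[str, dict]:
    fields = header.split("|")
    name = fields[0].strip()
    meta = {}
    for f in fields[1:]:
        if "=" in f:
            k, v = f.split("=", 1)
            meta[k.strip()] = v.strip()
    return name, meta


def read_reference_fasta(
    path: str | Path, segment: str = "V", label: str = ""
) -> ReferenceSet:
    """Read a germline FASTA with optional ``|key=value`` header metadata."""
    refs = ReferenceSet(label=label or str(path))
    name, meta, chunks = None, {}, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    refs.add(_make_allele(name, meta, "".join(chunks), segment))
                name, meta = _parse_header(line[1:])
                chunks = []
            else:
                chunks.append(line.lower())
    if name is not None:
        refs.add(_make_allele(name, meta, "".join(chunks), segment))
    return refs


def _make_allele(name: str, meta: dict, seq: str, segment: str) -> GermlineAllele:
    return GermlineAllele(
        name=name,
        segment=meta.get("segment", segment),
        sequence=seq.replace("-", ""),
        functionality=meta.get("functionality", "functional"),
        strain=meta.get("strain"),
        provenance=meta.get("provenance", "reported"),
        metadata={
            k: v
            for k, v in meta.items()
            if k not in ("segment", "functionality", "strain", "provenance")
        },
    )


def write_reference_fasta(refs: Iterable[GermlineAllele], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in refs:
            parts = [a.name]
            if a.strain:
                parts.append(f"strain={a.strain}")
            if a.segment != "V":
                parts.append(f"segment={a.segment}")
            if a.functionality != "functional":
                parts.append(f"functionality={a.functionality}")
            if a.provenance != "reported":
                parts.append(f"provenance={a.provenance}")
            parts.extend(f"{k}={v}" for k, v in a.metadata.items())
            fh.write(">" + "|".join(parts) + "\n" + a.sequence + "\n")


# ---------------------------------------------------------------------------
# Bundled worked-example fixtures (published novel IGHV and C-exon sequences)


def _data_path(fname: str) -> Path:
    return Path(importlib.resources.files("ighvhaplo.data") / fname)


def load_novel_ighv_table() -> ReferenceSet:
    """Six newly inferred BALB/c / C57BL/6 IGHV sequences (worked examples)."""
    return read_reference_fasta(
        _data_path("table1_novel_ighv.fasta"), segment="V", label="novel-ighv"
    )


def load_c_exon_table() -> ReferenceSet:
    """Published strain constant-region CH1 exons carrying the typing SNPs."""
    return read_reference_fasta(
        _data_path("table2_c_exons.fasta"), segment="C-exon", label="c-exons"
    )
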