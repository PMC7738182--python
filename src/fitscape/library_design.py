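"""Degenerate-codon library design statistics.

Tools for the design stage of a combinatorial active-site mutagenesis
library: expanding IUPAC degenerate codons into their concrete triplets,
tabulating the amino-acid repertoire each codon encodes, counting the gene-
and protein-level diversity of a multi-site design, and estimating how many
distinct variants a given number of transformants is expected to sample.

The canonical example is an eight-site nitroreductase library built from
NDT codons (12 amino acids, one codon each) at six positions, an NHT codon
(12 amino acids) and a VNG codon (11 amino acids, arginine twice), giving
12^8 ~ 4.3e8 gene variants encoding 12^7 x 11 ~ 3.9e8 proteins.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
from Bio.Data import CodonTable, IUPACData

__all__ = [
    "GeneticCode",
    "DegenerateCodon",
    "Site",
    "LibraryDesign",
    "CoverageModel",
    "expand_degenerate_codon",
    "amino_acid_repertoire",
    "gene_variant_count",
    "protein_variant_count",
    "includes_wild_type",
    "expected_distinct_variants",
    "side_chain_category",
    "nfsa_design",
    "STOP",
    "AMINO_ACIDS",
    "SIDE_CHAIN_CATEGORIES",
]

STOP = "STOP"

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: IUPAC nucleotide ambiguity alphabet accepted in degenerate codons.
IUPAC_NUCLEOTIDES: Mapping[str, str] = {
    k: v for k, v in IUPACData.ambiguous_dna_values.items() if k != "X"
}

#: The five textbook side-chain categories partitioning the 20 amino acids.
SIDE_CHAIN_CATEGORIES: Mapping[str, frozenset[str]] = {
    "nonpolar aliphatic": frozenset("GAVLIMP"),
    "aromatic": frozenset("FYW"),
    "polar uncharged": frozenset("STCNQ"),
    "positively charged": frozenset("KRH"),
    "negatively charged": frozenset("DE"),
}

_AA_TO_CATEGORY = {
    aa: cat for cat, members in SIDE_CHAIN_CATEGORIES.items() for aa in members
}


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table: 64 DNA triplets -> one-letter amino acid or STOP.

    The default is the standard nuclear code. Alternative tables can be
    loaded from a two-column CSV (``codon,amino_acid`` with ``*`` or
    ``STOP`` marking stop codons).
    """

    table: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must have 64 entries, got {len(self.table)}")
        values = set(self.table.values())
        missing = (AMINO_ACIDS | {STOP}) - values
        if missing:
            raise ValueError(f"genetic code is missing values: {sorted(missing)}")

    @classmethod
    def standard(cls) -> "GeneticCode":
        ncbi = CodonTable.unambiguous_dna_by_id[1]
        table = dict(ncbi.forward_table)
        for codon in ncbi.stop_codons:
            table[codon] = STOP
        return cls(table=table)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneticCode":
        table: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#") or row[0].lower() == "codon":
                    continue
                codon, aa = row[0].strip().upper(), row[1].strip().upper()
                table[codon] = STOP if aa in ("*", STOP) else aa
        return cls(table=table)

    def translate(self, codon: str) -> str:
        try:
            return self.table[codon.upper().replace("U", "T")]
        except KeyError:
            raise ValueError(f"not a concrete DNA triplet: {codon!r}") from None


_STANDARD_CODE = GeneticCode.standard()


@dataclass(frozen=True)
class DegenerateCodon:
    """A codon written in IUPAC ambiguity characters, e.g. ``NDT`` or ``VNG``."""

    symbols: str

    def __post_init__(self) -> None:
        s = self.symbols.upper().replace("U", "T")
        object.__setattr__(self, "symbols", s)
        if len(s) != 3:
            raise ValueError(f"degenerate codon must have 3 characters, got {s!r}")
        for ch in s:
            if ch not in IUPAC_NUCLEOTIDES:
                raise ValueError(f"invalid IUPAC nucleotide symbol {ch!r} in {s!r}")

    @property
    def size(self) -> int:
        """Number of concrete triplets (product of per-position set sizes)."""
        return math.prod(len(IUPAC_NUCLEOTIDES[ch]) for ch in self.symbols)

    def expand(self) -> frozenset[str]:
        return frozenset(
            "".join(t) for t in product(*(IUPAC_NUCLEOTIDES[ch] for ch in self.symbols))
        )

    def __str__(self) -> str:
        return self.symbols


@dataclass(frozen=True)
class Site:
    """One randomised position: residue index (1-based), wild-type residue, codon."""

    position: int
    wild_type: str
    codon: DegenerateCodon

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be 1-based positive, got {self.position}")
        if self.wild_type not in AMINO_ACIDS:
            raise ValueError(f"wild-type residue {self.wild_type!r} is not a standard amino acid")


@dataclass(frozen=True)
class LibraryDesign:
    """An ordered multi-site degenerate design (positions strictly increasing)."""

    sites: tuple[Site, ...]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("a library design needs at least one site")
        object.__setattr__(self, "sites", tuple(self.sites))
        positions = [s.position for s in self.sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"site positions must be strictly increasing, got {positions}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LibraryDesign":
        """Read a design from CSV with header ``position,wild_type,codon``."""
        sites = []
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh), start=2):
                try:
                    sites.append(
                        Site(
                            position=int(row["position"]),
                            wild_type=row["wild_type"].strip().upper(),
                            codon=DegenerateCodon(row["codon"].strip()),
                        )
                    )
                except (KeyError, ValueError) as exc:
                    raise ValueError(f"{path}, row {i}: {exc}") from exc
        return cls(sites=tuple(sites))


def expand_degenerate_codon(codon: DegenerateCodon | str) -> frozenset[str]:
    """All concrete DNA triplets matched by a degenerate codon."""
    if isinstance(codon, str):
        codon = DegenerateCodon(codon)
    return codon.expand()


def amino_acid_repertoire(
    codon: DegenerateCodon | str, code: GeneticCode = _STANDARD_CODE
) -> dict[str, int]:
    """Amino acid -> number of concrete codons encoding it.

    Stop codons, if any, are tallied under the distinct key ``"STOP"``.
    Multiplicities sum to the codon's expansion size.
    """
    if isinstance(codon, str):
        codon = DegenerateCodon(codon)
    counts: Counter[str] = Counter(code.translate(c) for c in codon.expand())
    return dict(counts)


def gene_variant_count(design: LibraryDesign) -> int:
    """Number of distinct DNA sequences the design encodes (product of codon counts)."""
    return math.prod(site.codon.size for site in design.sites)


def protein_variant_count(
    design: LibraryDesign, code: GeneticCode = _STANDARD_CODE
) -> int:
    """Number of distinct protein sequences (stop codons excluded).

    Always <= :func:`gene_variant_count` because synonymous codons collapse.
    A site whose repertoire is stop-only cannot encode any protein and is
    rejected.
    """
    total = 1
    for site in design.sites:
        n_aa = len(set(amino_acid_repertoire(site.codon, code)) - {STOP})
        if n_aa == 0:
            raise ValueError(
                f"site {site.position}: codon {site.codon} encodes only stop codons"
            )
        total *= n_aa
    return total


def includes_wild_type(
    design: LibraryDesign, code: GeneticCode = _STANDARD_CODE
) -> dict[int, bool]:
    """Per-site: does the codon's repertoire contain the wild-type residue?

    A ``False`` site forces substitution — e.g. NDT at a threonine position
    cannot retain threonine, which is why such sites get NHT instead.
    """
    return {
        site.position: site.wild_type in amino_acid_repertoire(site.codon, code)
        for site in design.sites
    }


def _multiplicity_classes(
    design: LibraryDesign, code: GeneticCode = _STANDARD_CODE
) -> dict[int, int]:
    """Group protein variants into classes by codon multiplicity.

    Returns {m: number of protein variants encoded by exactly m DNA
    sequences}. Computed by convolving per-site multiplicity tallies, so
    1e8-scale libraries are handled without enumerating variants.
    """
    classes: Counter[int] = Counter({1: 1})
    for site in design.sites:
        rep = amino_acid_repertoire(site.codon, code)
        site_counts = Counter()
        for aa, mult in rep.items():
            if aa != STOP:
                site_counts[mult] += 1
        merged: Counter[int] = Counter()
        for m1, c1 in classes.items():
            for m2, c2 in site_counts.items():
                merged[m1 * m2] += c1 * c2
        classes = merged
    return dict(classes)


@dataclass(frozen=True)
class CoverageModel:
    """Sampling model for library completeness.

    Protein variants are grouped into probability classes: a variant encoded
    by m of the library's M possible DNA sequences is drawn with probability
    m/M per transformant (stop-containing sequences waste the draw, which
    matches how a transformant carrying a truncated ORF contributes nothing).
    """

    classes: Mapping[int, int]  # multiplicity -> number of variants
    total_gene: int  # M, total DNA sequences including stop-containing ones
    method: Literal["exact", "poisson"] = "exact"

    def __post_init__(self) -> None:
        if self.total_gene < 1 or not self.classes:
            raise ValueError("coverage model needs a nonempty design")

    @classmethod
    def from_design(
        cls,
        design: LibraryDesign,
        method: Literal["exact", "poisson"] = "exact",
        code: GeneticCode = _STANDARD_CODE,
    ) -> "CoverageModel":
        return cls(
            classes=_multiplicity_classes(design, code),
            total_gene=gene_variant_count(design),
            method=method,
        )

    @property
    def num_variants(self) -> int:
        return sum(self.classes.values())

    def expected_distinct(self, num_transformants: int) -> float:
        """Expected number of distinct protein variants among L transformants.

        exact:   sum_m count_m * (1 - (1 - m/M)^L)
        poisson: sum_m count_m * (1 - exp(-L m/M))
        Both are nondecreasing in L and bounded by the variant count.
        """
        if num_transformants < 0:
            raise ValueError("num_transformants must be >= 0")
        L = float(num_transformants)
        total = 0.0
        for m, count in self.classes.items():
            p = m / self.total_gene
            if self.method == "exact":
                # log1p keeps (1-p)^L accurate for p ~ 1e-9, L ~ 1e8
                miss = math.exp(L * math.log1p(-p)) if p < 1.0 else (0.0 if L > 0 else 1.0)
            elif self.method == "poisson":
                miss = math.exp(-L * p)
            else:
                raise ValueError(f"unknown method {self.method!r}")
            total += count * (1.0 - miss)
        return total


def expected_distinct_variants(
    design: LibraryDesign,
    num_transformants: int,
    method: Literal["exact", "poisson"] = "exact",
    code: GeneticCode = _STANDARD_CODE,
) -> float:
    """Expected distinct protein variants recovered from L transformants."""
    return CoverageModel.from_design(design, method, code).expected_distinct(num_transformants)


def side_chain_category(aa: str) -> str:
    """The side-chain category of a standard amino acid (five-way partition)."""
    aa = aa.upper()
    try:
        return _AA_TO_CATEGORY[aa]
    except KeyError:
        raise ValueError(f"unknown amino acid {aa!r}") from None


def nfsa_design() -> LibraryDesign:
    """The eight-site NfsA active-site design: NDT at six positions, NHT at
    T219, VNG at K222."""
    codons = {
        41: ("S", "NDT"),
        43: ("L", "NDT"),
        215: ("H", "NDT"),
        219: ("T", "NHT"),
        222: ("K", "VNG"),
        224: ("S", "NDT"),
        225: ("R", "NDT"),
        227: ("F", "NDT"),
    }
    return LibraryDesign(
        sites=tuple(
            Site(position=pos, wild_type=wt, codon=DegenerateCodon(cod))
            for pos, (wt, cod) in sorted(codons.items())
        )
    )
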