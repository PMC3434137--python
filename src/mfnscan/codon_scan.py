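"""Exhaustive enumeration of single-nucleotide substitutions in a coding region.

Every codon admits exactly nine single-nucleotide substitutions (three
positions x three alternate bases).  Classifying each against the standard
genetic code yields the synonymous / missense / nonsense partition that
downstream damage-potential scoring consumes.  Coordinates are 1-based
protein residue numbers throughout, so a domain scan can be anchored at an
arbitrary offset (e.g. residue 391 for the first heptad repeat of human
mitofusin-2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "NUCLEOTIDES",
    "GENETIC_CODE",
    "SENSE_CODONS",
    "STOP_CODONS",
    "InvalidCodonError",
    "InvalidRegionError",
    "CodingRegion",
    "CodonSnv",
    "translate_codon",
    "enumerate_snvs",
    "snv_frame",
    "consequence_counts",
]

NUCLEOTIDES = ("A", "C", "G", "T")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino-acid letter, with '*' for the three stop codons
GENETIC_CODE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
GENETIC_CODE.update({c: "*" for c in _STANDARD_TABLE.stop_codons})

STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(set(GENETIC_CODE) - STOP_CODONS))


class InvalidCodonError(ValueError):
    """Codon is not three characters over {A, C, G, T}."""


class InvalidRegionError(ValueError):
    """Coding region violates its invariants (length, alphabet, internal stop)."""


def translate_codon(codon: str) -> str:
    """Translate a codon with the standard genetic code.

    Returns the one-letter amino acid, or ``'*'`` for TAA/TAG/TGA.
    Raises :class:`InvalidCodonError` for anything that is not three
    uppercase-able ACGT characters.
    """
    if not isinstance(codon, str) or len(codon) != 3:
        raise InvalidCodonError(f"codon must be a 3-character string, got {codon!r}")
    codon = codon.upper()
    if any(nt not in NUCLEOTIDES for nt in codon):
        raise InvalidCodonError(f"codon contains non-ACGT characters: {codon!r}")
    return GENETIC_CODE[codon]


@dataclass(frozen=True)
class CodingRegion:
    """A protein-coding nucleotide stretch with a residue-numbering offset.

    Parameters
    ----------
    name
        Free-text label (FASTA header or scenario name).
    sequence
        Nucleotide string over ACGT; length must be a multiple of three and
        no codon may be a stop codon (the scan targets an internal domain).
    first_residue_number
        1-based protein coordinate of the first codon, e.g. 391 when the
        region covers mitofusin-2 residues 391 onwards.
    """

    name: str
    sequence: str
    first_residue_number: int = 1

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise InvalidRegionError("sequence is empty")
        if len(seq) % 3 != 0:
            raise InvalidRegionError(
                f"sequence length {len(seq)} is not a multiple of 3"
            )
        for i, nt in enumerate(seq):
            if nt not in NUCLEOTIDES:
                raise InvalidRegionError(
                    f"non-ACGT character {nt!r} at position {i + 1}"
                )
        if self.first_residue_number < 1:
            raise InvalidRegionError(
                f"first_residue_number must be >= 1, got {self.first_residue_number}"
            )
        for i, codon in enumerate(self.codons):
            if codon in STOP_CODONS:
                raise InvalidRegionError(
                    f"reference stop codon {codon} at residue "
                    f"{self.first_residue_number + i}"
                )

    @property
    def codons(self) -> list[str]:
        return [self.sequence[i : i + 3] for i in range(0, len(self.sequence), 3)]

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    @property
    def residue_numbers(self) -> range:
        return range(
            self.first_residue_number, self.first_residue_number + self.n_codons
        )


@dataclass(frozen=True)
class CodonSnv:
    """One single-nucleotide substitution within a codon and its consequence."""

    residue_number: int
    ref_codon: str
    pos_in_codon: int  # 1..3
    ref_nt: str
    alt_nt: str
    ref_aa: str
    alt_aa: str
    consequence: str = field(init=False)  # synonymous | missense | nonsense

    def __post_init__(self) -> None:
        if self.alt_aa == "*":
            cons = "nonsense"
        elif self.alt_aa == self.ref_aa:
            cons = "synonymous"
        else:
            cons = "missense"
        object.__setattr__(self, "consequence", cons)

    @property
    def alt_codon(self) -> str:
        i = self.pos_in_codon - 1
        return self.ref_codon[:i] + self.alt_nt + self.ref_codon[i + 1 :]


def _iter_snvs(region: CodingRegion) -> Iterator[CodonSnv]:
    for i, codon in enumerate(region.codons):
        residue = region.first_residue_number + i
        ref_aa = GENETIC_CODE[codon]
        for pos in (1, 2, 3):
            ref_nt = codon[pos - 1]
            for alt_nt in NUCLEOTIDES:  # alphabetical by construction
                if alt_nt == ref_nt:
                    continue
                alt_codon = codon[: pos - 1] + alt_nt + codon[pos:]
                yield CodonSnv(
                    residue_number=residue,
                    ref_codon=codon,
                    pos_in_codon=pos,
                    ref_nt=ref_nt,
                    alt_nt=alt_nt,
                    ref_aa=ref_aa,
                    alt_aa=GENETIC_CODE[alt_codon],
                )


def enumerate_snvs(region: CodingRegion) -> list[CodonSnv]:
    """Enumerate all nine single-nucleotide substitutions per codon.

    The output is deterministically ordered by (residue_number, pos_in_codon,
    alphabetical alt_nt) so joins against external score tables are
    reproducible.  Exactly ``9 * region.n_codons`` records are returned.
    """
    return list(_iter_snvs(region))


def snv_frame(snvs: list[CodonSnv]) -> pd.DataFrame:
    """Tabulate SNV records (the TSV dialect written by the CLI)."""
    return pd.DataFrame(
        [
            {
                "residue_number": s.residue_number,
                "ref_codon": s.ref_codon,
                "pos_in_codon": s.pos_in_codon,
                "ref_nt": s.ref_nt,
                "alt_nt": s.alt_nt,
                "ref_aa": s.ref_aa,
                "alt_aa": s.alt_aa,
                "consequence": s.consequence,
            }
            for s in snvs
        ]
    )


def consequence_counts(
    region: CodingRegion, include_stop_gains: bool = True
) -> dict[str, int]:
    """Count substitutions by consequence class over a whole region.

    Returns a dict with keys ``synonymous``, ``missense``, ``nonsense`` and
    ``nonsynonymous_total``.  Stop-gain (nonsense) substitutions count toward
    the non-synonymous total by default, matching a damage scoring scheme in
    which truncating changes carry the maximal category; set
    ``include_stop_gains=False`` for a missense-only total.
    """
    counts = {"synonymous": 0, "missense": 0, "nonsense": 0}
    for snv in _iter_snvs(region):
        counts[snv.consequence] += 1
    counts["nonsynonymous_total"] = counts["missense"] + (
        counts["nonsense"] if include_stop_gains else 0
    )
    return counts
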