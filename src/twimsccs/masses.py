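"""Average molecular masses, charge states, and reduced masses.

Everything native mass spectrometry needs around an ion's mass: average
(chemical) neutral masses of protein/RNA/DNA sequences computed from
elemental composition, m/z of a protonated or deprotonated charge state,
and the ion–gas reduced mass that enters the mobility calibration.

Mass conventions
----------------
* Atomic masses are IUPAC 2021 conventional average weights, so sequence
  masses are average (not monoisotopic) masses, matching how intact masses
  of large biomolecules are reported.
* Nucleic acids are summed as free 5'-monophosphate nucleotides minus one
  condensation water per phosphodiester bond. The default termini are
  5'-hydroxyl / 3'-hydroxyl — the synthetic-oligonucleotide convention —
  implemented by removing one HPO₃ (79.980 Da) from the polymer sum; a
  5'-phosphate terminus can be requested instead.
* Proteins are summed as free amino acids minus one water per peptide bond
  (free N- and C-termini, no modifications).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "Sequence",
    "IonSpecies",
    "sequence_mass",
    "mz_from_mass",
    "reduced_mass",
    "formula_mass",
    "read_fasta",
    "PROTON_MASS",
    "WATER_MASS",
    "HPO3_MASS",
    "GAS_MASS_N2",
    "GAS_MASS_HE",
    "ALPHABETS",
]

#: IUPAC 2021 conventional atomic weights (Da) for the elements occurring in
#: unmodified biopolymers.
ATOMIC_WEIGHTS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973761998,
    "S": 32.06,
}

PROTON_MASS = 1.00728  # Da, charge carrier in both polarities

GAS_MASS_N2 = 28.0134  # Da, nitrogen drift gas (default for protein runs)
GAS_MASS_HE = 4.0026   # Da, helium

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str) -> float:
    """Average mass in Da of a Hill-notation elemental formula like C2H5NO2."""
    mass = 0.0
    for element, count in _FORMULA_RE.findall(formula):
        if not element:
            continue
        try:
            mass += ATOMIC_WEIGHTS[element] * (int(count) if count else 1)
        except KeyError:
            raise ValueError(f"element {element!r} not in atomic-weight table")
    return mass


WATER_MASS = formula_mass("H2O")    # 18.015
HPO3_MASS = formula_mass("HPO3")    # 79.980 (metaphosphate removed for 5'-OH)

# Free monomer elemental formulas. Polymer mass = sum(monomers) - (n-1) * water,
# then for nucleic acids - HPO3 when the 5' end is a hydroxyl.
_RNA_NMP = {  # ribonucleoside 5'-monophosphates
    "A": "C10H14N5O7P",
    "C": "C9H14N3O8P",
    "G": "C10H14N5O8P",
    "U": "C9H13N2O9P",
}
_DNA_NMP = {  # 2'-deoxyribonucleoside 5'-monophosphates
    "A": "C10H14N5O6P",
    "C": "C9H14N3O7P",
    "G": "C10H14N5O7P",
    "T": "C10H15N2O8P",
}
_AMINO_ACID = {  # free amino acids
    "A": "C3H7NO2",  "R": "C6H14N4O2", "N": "C4H8N2O3",  "D": "C4H7NO4",
    "C": "C3H7NO2S", "E": "C5H9NO4",   "Q": "C5H10N2O3", "G": "C2H5NO2",
    "H": "C6H9N3O2", "I": "C6H13NO2",  "L": "C6H13NO2",  "K": "C6H14N2O2",
    "M": "C5H11NO2S", "F": "C9H11NO2", "P": "C5H9NO2",   "S": "C3H7NO3",
    "T": "C4H9NO3",  "W": "C11H12N2O2", "Y": "C9H11NO3", "V": "C5H11NO2",
}

_MONOMER_MASS = {
    "rna": {k: formula_mass(v) for k, v in _RNA_NMP.items()},
    "dna": {k: formula_mass(v) for k, v in _DNA_NMP.items()},
    "protein": {k: formula_mass(v) for k, v in _AMINO_ACID.items()},
}

ALPHABETS = {kind: frozenset(table) for kind, table in _MONOMER_MASS.items()}

SequenceKind = Literal["protein", "rna", "dna"]
FivePrimeGroup = Literal["hydroxyl", "phosphate"]


@dataclass(frozen=True)
class Sequence:
    """A biopolymer sequence in one-letter code.

    ``five_prime_group`` applies to nucleic acids only: ``"hydroxyl"``
    (synthetic-oligo default) or ``"phosphate"``.
    """

    kind: SequenceKind
    residues: str
    five_prime_group: FivePrimeGroup = "hydroxyl"

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues",
                           re.sub(r"\s", "", self.residues).upper())
        if self.kind not in _MONOMER_MASS:
            raise ValueError(f"unknown sequence kind {self.kind!r}")
        if not self.residues:
            raise ValueError("sequence must be non-empty")
        if self.five_prime_group not in ("hydroxyl", "phosphate"):
            raise ValueError(f"unknown 5' group {self.five_prime_group!r}")
        alphabet = ALPHABETS[self.kind]
        for pos, symbol in enumerate(self.residues):
            if symbol not in alphabet:
                raise ValueError(
                    f"invalid {self.kind} symbol {symbol!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def sequence_mass(seq: Sequence) -> float:
    """Average neutral mass of a sequence in Da.

    Nucleic acids: sum of free 5'-monophosphate masses, minus (n−1)
    condensation waters, minus one HPO₃ when the 5' end is a hydroxyl
    (3' end is always a hydroxyl). Proteins: sum of free amino-acid masses
    minus (n−1) waters, i.e. residue masses plus one water.
    """
    table = _MONOMER_MASS[seq.kind]
    n = len(seq)
    mass = sum(table[s] for s in seq.residues) - (n - 1) * WATER_MASS
    if seq.kind in ("rna", "dna") and seq.five_prime_group == "hydroxyl":
        mass -= HPO3_MASS
    return mass


def mz_from_mass(
    neutral_mass: float,
    z: int,
    polarity: Literal["positive", "negative"] = "positive",
) -> float:
    """m/z (Th) of a protonated (+) or deprotonated (−) charge state.

    positive: (M + z·m_H)/z;  negative: (M − z·m_H)/z with m_H = 1.00728 Da.
    """
    if z < 1:
        raise ValueError("charge state z must be >= 1")
    if polarity == "positive":
        return (neutral_mass + z * PROTON_MASS) / z
    if polarity == "negative":
        mz = (neutral_mass - z * PROTON_MASS) / z
        if mz <= 0:
            raise ValueError(
                f"negative-mode m/z non-positive for M={neutral_mass}, z={z}"
            )
        return mz
    raise ValueError(f"unknown polarity {polarity!r}")


def reduced_mass(ion_mass: float, gas_mass: float) -> float:
    """Reduced mass μ = m_ion·m_gas/(m_ion + m_gas) of the ion/gas pair, Da."""
    if ion_mass <= 0 or gas_mass <= 0:
        raise ValueError("masses must be positive")
    return ion_mass * gas_mass / (ion_mass + gas_mass)


@dataclass(frozen=True)
class IonSpecies:
    """A charge state of a neutral species, with its derived m/z."""

    neutral_mass: float
    z: int
    polarity: Literal["positive", "negative"] = "positive"

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError("z must be >= 1")
        if self.neutral_mass <= 0:
            raise ValueError("neutral mass must be positive")

    @property
    def mz(self) -> float:
        return mz_from_mass(self.neutral_mass, self.z, self.polarity)


def read_fasta(source, kind: SequenceKind,
               five_prime_group: FivePrimeGroup = "hydroxyl") -> list[Sequence]:
    """Read sequences from a FASTA path or handle (Biopython SeqIO backend)."""
    from Bio import SeqIO

    return [
        Sequence(kind, str(record.seq), five_prime_group)
        for record in SeqIO.parse(source, "fasta")
    ]
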