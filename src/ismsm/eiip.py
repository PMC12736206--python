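"""Electron-ion interaction potential (EIIP) encoding.

Proteins and small molecules are rendered as ordered series of EIIP values
(in Rydbergs), the numerical representation underlying the informational
spectrum method. Residue EIIP values come from the classical tabulated set;
small-molecule values are computed from the average quasi-valence number
(AQVN) of each atomic group:

    Z* = (1/N) * sum_i n_i Z_i          (AQVN; Z_i = valence-electron count)
    W  = 0.25 * Z* * sin(1.04 pi Z*) / (2 pi)   (EIIP, Ry)
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # unparseable SMILES raise; no console spam

__all__ = [
    "VALENCE_ELECTRONS",
    "AtomComposition",
    "EiipTable",
    "EncodedSequence",
    "compute_aqvn",
    "compute_eiip",
    "load_amino_acid_table",
    "computed_amino_acid_table",
    "encode_protein",
    "encode_smiles",
]

# Valence-ELECTRON counts (not bonding valences): the AQVN convention.
VALENCE_ELECTRONS: Mapping[str, int] = {
    "H": 1,
    "B": 3,
    "C": 4,
    "N": 5,
    "O": 6,
    "F": 7,
    "Si": 4,
    "P": 5,
    "S": 6,
    "Cl": 7,
    "Se": 6,
    "Br": 7,
    "I": 7,
}

# Atomic composition of the 20 standard amino-acid residues (free amino acid
# minus water, i.e. the peptide-bonded residue), used by the "computed" table.
_RESIDUE_COMPOSITION: Mapping[str, Mapping[str, int]] = {
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
}

STANDARD_RESIDUES = frozenset(_RESIDUE_COMPOSITION)


class UnknownElementError(ValueError):
    """Raised when an atom composition names an element without a tabulated
    valence-electron count."""


class EncodingError(ValueError):
    """Raised when a sequence or SMILES string cannot be encoded."""


@dataclass(frozen=True)
class AtomComposition:
    """Element-symbol -> atom-count map for one molecule or atomic group."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("empty atom composition")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative atom count")
        if sum(self.counts.values()) < 1:
            raise ValueError("total atom count must be >= 1")

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class EiipTable:
    """Token (residue one-letter code or group key) -> EIIP value (Ry)."""

    entries: Mapping[str, float]
    provenance: Literal["tabulated", "computed"] = "tabulated"

    def __post_init__(self) -> None:
        for tok, val in self.entries.items():
            if not math.isfinite(val):
                raise ValueError(f"non-finite EIIP value for token {tok!r}")

    def __getitem__(self, token: str) -> float:
        return self.entries[token]

    def __contains__(self, token: str) -> bool:
        return token in self.entries


@dataclass(frozen=True)
class EncodedSequence:
    """A biomolecule as an ordered EIIP series."""

    id: str
    kind: Literal["protein", "ligand"]
    values: tuple[float, ...]
    source_tokens: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise EncodingError(
                f"{self.id!r}: EIIP series must have length >= 2 "
                f"(got {len(self.values)})"
            )
        if self.source_tokens and len(self.source_tokens) != len(self.values):
            raise ValueError("values and source_tokens lengths differ")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError(f"{self.id!r}: non-finite EIIP value")

    def __len__(self) -> int:
        return len(self.values)


def compute_aqvn(composition: AtomComposition) -> float:
    """Average quasi-valence number Z* = (sum n_i Z_i) / N."""
    total = 0
    for element, count in composition.counts.items():
        if element not in VALENCE_ELECTRONS:
            raise UnknownElementError(
                f"no valence-electron count tabulated for element {element!r}"
            )
        total += count * VALENCE_ELECTRONS[element]
    return total / composition.n_atoms


def compute_eiip(aqvn: float) -> float:
    """EIIP W = 0.25 * Z* * sin(1.04 pi Z*) / (2 pi), in Rydbergs."""
    if not math.isfinite(aqvn):
        raise ValueError("AQVN must be finite")
    return 0.25 * aqvn * math.sin(1.04 * math.pi * aqvn) / (2.0 * math.pi)


def load_amino_acid_table() -> EiipTable:
    """The classical tabulated amino-acid EIIP set (Ry), shipped as data."""
    with resources.files("ismsm.data").joinpath("amino_acid_eiip.csv").open() as fh:
        rows = list(csv.DictReader(fh))
    return EiipTable(
        entries={r["token"]: float(r["value"]) for r in rows},
        provenance="tabulated",
    )


def computed_amino_acid_table() -> EiipTable:
    """Amino-acid EIIP derived from residue atomic composition via the AQVN
    formula. Does NOT coincide with the classical tabulated set; provided for
    comparison and clearly labeled by provenance."""
    entries = {
        aa: compute_eiip(compute_aqvn(AtomComposition(comp)))
        for aa, comp in _RESIDUE_COMPOSITION.items()
    }
    return EiipTable(entries=entries, provenance="computed")


def encode_protein(
    sequence: str,
    table: EiipTable | None = None,
    *,
    id: str = "protein",
    on_unknown: Literal["strict", "skip"] = "strict",
) -> EncodedSequence:
    """Map each residue to its EIIP value, preserving order.

    ``on_unknown`` controls nonstandard residues (X, B, Z, ...): "strict"
    raises naming the first offending position (1-based); "skip" drops them.
    """
    if table is None:
        table = load_amino_acid_table()
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise EncodingError(f"{id!r}: protein sequence must have length >= 2")
    values: list[float] = []
    tokens: list[str] = []
    for pos, residue in enumerate(sequence, start=1):
        if residue not in table:
            if on_unknown == "strict":
                raise EncodingError(
                    f"{id!r}: unknown residue {residue!r} at position {pos}"
                )
            continue
        values.append(table[residue])
        tokens.append(residue)
    if len(values) < 2:
        raise EncodingError(f"{id!r}: fewer than 2 encodable residues")
    return EncodedSequence(
        id=id, kind="protein", values=tuple(values), source_tokens=tuple(tokens)
    )


def _canonical_mol(smiles: str, id: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise EncodingError(f"{id!r}: unparseable SMILES {smiles!r}")
    # Re-parse the canonical SMILES so atom order is the canonical traversal,
    # independent of input atom numbering.
    return Chem.MolFromSmiles(Chem.MolToSmiles(mol))


def encode_smiles(
    smiles: str,
    mode: Literal["per-group", "per-atom"] = "per-group",
    *,
    id: str = "ligand",
) -> EncodedSequence:
    """Encode a molecule as an EIIP series.

    per-group: one element per heavy atom (canonical SMILES order); its value
    is the EIIP of the heavy atom plus its bonded hydrogens, i.e. the group
    AQVN fed through the EIIP formula (explicit-hydrogen treatment folded into
    each group).

    per-atom: explicit-hydrogen expansion; one element per atom, valued at the
    EIIP of that atom's own valence-electron count.
    """
    mol = _canonical_mol(smiles, id)
    if mol.GetNumHeavyAtoms() < 2:
        raise EncodingError(
            f"{id!r}: molecule has fewer than 2 heavy atoms; series too short"
        )
    values: list[float] = []
    tokens: list[str] = []
    if mode == "per-group":
        for atom in mol.GetAtoms():
            symbol = atom.GetSymbol()
            n_h = atom.GetTotalNumHs()
            comp = {symbol: 1}
            if n_h:
                comp["H"] = n_h
            values.append(compute_eiip(compute_aqvn(AtomComposition(comp))))
            tokens.append(f"{symbol}H{n_h}" if n_h else symbol)
    elif mode == "per-atom":
        molh = Chem.AddHs(mol)
        for atom in molh.GetAtoms():
            symbol = atom.GetSymbol()
            if symbol not in VALENCE_ELECTRONS:
                raise UnknownElementError(
                    f"{id!r}: no valence-electron count for element {symbol!r}"
                )
            values.append(compute_eiip(float(VALENCE_ELECTRONS[symbol])))
            tokens.append(symbol)
    else:
        raise ValueError(f"unknown encoding mode {mode!r}")
    return EncodedSequence(
        id=id, kind="ligand", values=tuple(values), source_tokens=tuple(tokens)
    )
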