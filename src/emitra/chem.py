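"""Molecular structures, formulas, fingerprints and Tanimoto similarity.

This module is the numeric substrate for analogue selection: it parses
SMILES into canonical :class:`Structure` objects, computes molecular
formulas and weights from a fixed table of conventional atomic weights
(so results are bit-reproducible across platforms), and generates hashed
substructure fingerprints whose Tanimoto coefficient quantifies
structural similarity between a target chemical and candidate source
chemicals.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator

from rdkit import Chem
from rdkit import rdBase
from rdkit.Chem import rdFingerprintGenerator

rdBase.DisableLog("rdApp.error")

# Conventional atomic weights (IUPAC 2021 abridged values), amu.
# A fixed internal table keeps molecular weights bit-reproducible.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.003, "Li": 6.94, "Be": 9.012, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.098, "Ca": 40.078,
    "Fe": 55.845, "Cu": 63.546, "Zn": 65.38, "Br": 79.904, "I": 126.904,
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass(frozen=True)
class Structure:
    """A parsed molecule in canonical form.

    Attributes
    ----------
    smiles:
        Canonical SMILES as produced by RDKit; canonicalization is
        idempotent, so re-parsing ``smiles`` yields an equal Structure.
    formula:
        Element symbol -> atom count, including implicit hydrogens.
    """

    smiles: str
    formula: dict[str, int] = field(compare=False)

    @property
    def heavy_atom_count(self) -> int:
        return sum(n for el, n in self.formula.items() if el != "H")

    @property
    def carbon_count(self) -> int:
        return self.formula.get("C", 0)

    def __hash__(self) -> int:  # formula dict is unhashable
        return hash(self.smiles)


@dataclass(frozen=True)
class FingerprintParams:
    """Parameters of a fingerprint generation scheme.

    ``kind`` selects the algorithm: ``"atompair"`` (default) hashes all
    heavy-atom pairs annotated with their topological distance, which is
    sensitive to overall molecular size and shape; ``"morgan"`` hashes
    circular substructures of the given ``radius``. Scores are only
    comparable between fingerprints generated under an identical scheme,
    so the scheme is stamped into every fingerprint's ``scheme_id``.
    """

    kind: str = "atompair"
    radius: int = 2
    n_bits: int = 2048

    @property
    def scheme_id(self) -> str:
        if self.kind == "morgan":
            return f"morgan-r{self.radius}-{self.n_bits}"
        return f"{self.kind}-{self.n_bits}"


@dataclass(frozen=True)
class Fingerprint:
    """A hashed binary substructure fingerprint."""

    bits: frozenset[int]
    scheme_id: str

    def __post_init__(self) -> None:
        if any(b < 0 for b in self.bits):
            raise ValueError("fingerprint bit positions must be non-negative")


@dataclass(frozen=True)
class SimilarityScore:
    """A Tanimoto similarity in [0, 1]; 1 means identical bitsets."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"similarity {self.value} outside [0, 1]")

    def __float__(self) -> float:
        return self.value


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        # Locate the offending token for the error message.
        for end in range(1, len(smiles) + 1):
            if Chem.MolFromSmiles(smiles[:end], sanitize=False) is None:
                raise SmilesParseError(
                    f"invalid SMILES {smiles!r}: cannot parse at position "
                    f"{end - 1} ({smiles[end - 1]!r})"
                )
        raise SmilesParseError(f"invalid SMILES {smiles!r}")
    return mol


def _formula_of(mol: Chem.Mol) -> dict[str, int]:
    counts: Counter[str] = Counter()
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] += 1
        counts["H"] += atom.GetTotalNumHs()
    if counts["H"] == 0:
        del counts["H"]
    return dict(counts)


def parse_structure(smiles: str) -> Structure:
    """Parse a SMILES string into a canonical :class:`Structure`.

    The molecular formula is derived by atom counting, with implicit
    hydrogens made explicit in the count.

    Raises
    ------
    SmilesParseError
        If the SMILES is syntactically invalid; the message names the
        offending token and position.
    """
    mol = _mol_from_smiles(smiles)
    return Structure(smiles=Chem.MolToSmiles(mol), formula=_formula_of(mol))


def formula_string(s: Structure) -> str:
    """Hill-order formula string, e.g. ``C9H12``."""
    parts = []
    for el in ["C", "H"] + sorted(k for k in s.formula if k not in ("C", "H")):
        n = s.formula.get(el, 0)
        if n:
            parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


def molecular_weight(s: Structure) -> float:
    """Molecular weight in amu from the internal atomic-weight table.

    Sums count x conventional atomic weight over the formula. Rounding
    (e.g. to 1 decimal place in reports) is the caller's concern.
    """
    try:
        return sum(ATOMIC_WEIGHTS[el] * n for el, n in s.formula.items())
    except KeyError as exc:
        raise ValueError(f"unknown element symbol {exc.args[0]!r}") from exc


def fingerprint(s: Structure, params: FingerprintParams | None = None) -> Fingerprint:
    """Generate the hashed substructure fingerprint of ``s``.

    Deterministic for fixed ``params``; the resulting ``scheme_id``
    records the scheme so that similarity scores are only computed
    within one scheme.
    """
    params = params or FingerprintParams()
    mol = _mol_from_smiles(s.smiles)
    if params.kind == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=params.radius, fpSize=params.n_bits
        )
    elif params.kind == "atompair":
        gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=params.n_bits)
    elif params.kind == "rdkit":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=params.n_bits)
    else:
        raise ValueError(f"unknown fingerprint kind {params.kind!r}")
    bits = frozenset(gen.GetFingerprint(mol).GetOnBits())
    return Fingerprint(bits=bits, scheme_id=params.scheme_id)


def tanimoto(a: Fingerprint, b: Fingerprint) -> SimilarityScore:
    """Tanimoto coefficient |A∩B| / |A∪B| of two fingerprints.

    1 indicates identical bitsets (identical molecules under the
    scheme); 0 indicates no common substructure bits. Two empty bitsets
    score 1 by convention (identity of empty molecules).

    Raises
    ------
    ValueError
        If the fingerprints were generated under different schemes —
        cross-scheme scores are meaningless.
    """
    if a.scheme_id != b.scheme_id:
        raise ValueError(
            f"fingerprint scheme mismatch: {a.scheme_id!r} vs {b.scheme_id!r}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        return SimilarityScore(1.0)
    return SimilarityScore(len(a.bits & b.bits) / union)


_SMILES_LINE = re.compile(r"^(?P<smiles>\S+)(?:\t(?P<name>.*))?$")


def read_smiles_file(path: str) -> Iterator[tuple[str, str]]:
    """Iterate ``(smiles, name)`` records from a SMILES file.

    One record per line, ``SMILES<tab>name``; the name defaults to the
    SMILES itself when absent. Blank lines and ``#`` comments skipped.
    """
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            m = _SMILES_LINE.match(line)
            if m is None:
                raise SmilesParseError(f"{path}:{lineno}: malformed SMILES line")
            yield m.group("smiles"), (m.group("name") or m.group("smiles")).strip()


def read_sdf(path: str) -> Iterator[tuple[str, str]]:
    """Iterate ``(canonical_smiles, name)`` records from a V2000 SDF."""
    supplier = Chem.SDMolSupplier(path)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise SmilesParseError(f"{path}: unreadable molecule at record {i}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        yield Chem.MolToSmiles(mol), name or f"mol{i}"
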