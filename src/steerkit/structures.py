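"""Data model for biomolecular complexes and tokenization.

The toolkit operates on a flat, explicit representation: an ordered list of
atoms grouped into chains, an optional bond list, and a token list derived
from the atoms. Tokens are amino acids for protein chains, nucleic-acid
bases for RNA/DNA, and individual heavy atoms for everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .elements import vdw_radius

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL", "UNK",
}
RNA_RESIDUES = {"A", "C", "G", "U", "N"}
DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DN"}

ENTITY_TYPES = ("protein", "rna", "dna", "nonpolymer")
POCKET_FEATURES = ("UNSPECIFIED", "BINDER", "POCKET", "UNSELECTED")

_CENTER_ATOM_BY_ENTITY = {"protein": "CA", "rna": "C1'", "dna": "C1'"}


@dataclass
class AtomRecord:
    """One atom: identity, position (Å), and the radius used by clash terms."""

    atom_id: str
    name: str
    element: str
    coords: np.ndarray
    chain_id: str
    res_idx: int
    res_name: str = ""
    vdw_radius: float = 0.0
    is_resolved: bool = True
    is_heavy: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if self.is_resolved and not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_id}")
        if self.vdw_radius <= 0.0:
            self.vdw_radius = vdw_radius(self.element)


@dataclass
class ChainInfo:
    """Chain metadata: entity classification and symmetric-copy grouping.

    Chains sharing ``entity_id`` are identical copies of the same molecular
    entity (the symmetry groups used by chain-overlap potentials and by
    symmetry-corrected scoring).
    """

    chain_id: str
    entity_type: str
    sequence: str = ""
    entity_id: str = ""

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.entity_type!r}")
        if not self.entity_id:
            self.entity_id = self.chain_id


@dataclass
class TokenRecord:
    token_idx: int
    asym_id: str
    res_idx: int
    entity_type: str
    center_atom: int  # index into ComplexStructure.atoms
    atom_ids: list[int] = field(default_factory=list)
    is_resolved: bool = True
    pocket_feature: str = "UNSPECIFIED"


@dataclass
class ComplexStructure:
    """A biomolecular complex: ordered atoms, chain metadata, bonds."""

    atoms: list[AtomRecord]
    chains: dict[str, ChainInfo]
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) references a missing atom")
        for atom in self.atoms:
            if atom.chain_id not in self.chains:
                raise ValueError(f"atom {atom.atom_id} references unknown chain {atom.chain_id}")

    @property
    def coords_matrix(self) -> np.ndarray:
        """N×3 coordinate matrix in Å (a copy)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate matrix shape mismatch")
        for atom, xyz in zip(self.atoms, coords):
            atom.coords = xyz.copy()

    def chain_atom_indices(self, chain_id: str) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.chain_id == chain_id]

    def resolved_heavy_mask(self) -> np.ndarray:
        return np.array([a.is_resolved and a.is_heavy for a in self.atoms], dtype=bool)

    def copy(self) -> "ComplexStructure":
        return ComplexStructure(
            atoms=[replace(a, coords=a.coords.copy()) for a in self.atoms],
            chains={k: replace(v) for k, v in self.chains.items()},
            bonds=list(self.bonds),
        )


def classify_residue(res_name: str) -> str:
    name = res_name.strip().upper()
    if name in PROTEIN_RESIDUES:
        return "protein"
    if name in RNA_RESIDUES:
        return "rna"
    if name in DNA_RESIDUES:
        return "dna"
    return "nonpolymer"


def tokenize(complex_: ComplexStructure) -> list[TokenRecord]:
    """Tokenize a complex: one token per polymer residue/base, one per
    nonpolymer heavy atom.

    Token order is chain order (as stored) then sequence order. A polymer
    residue with no resolved heavy atom still yields a token, flagged
    unresolved, whose center atom is its first heavy atom.
    """
    tokens: list[TokenRecord] = []
    for chain_id, chain in complex_.chains.items():
        idxs = complex_.chain_atom_indices(chain_id)
        if chain.entity_type == "nonpolymer":
            for i in idxs:
                atom = complex_.atoms[i]
                if not atom.is_heavy:
                    continue
                tokens.append(TokenRecord(
                    token_idx=len(tokens), asym_id=chain_id, res_idx=atom.res_idx,
                    entity_type=chain.entity_type, center_atom=i, atom_ids=[i],
                    is_resolved=atom.is_resolved,
                ))
        else:
            by_res: dict[int, list[int]] = {}
            for i in idxs:
                by_res.setdefault(complex_.atoms[i].res_idx, []).append(i)
            center_name = _CENTER_ATOM_BY_ENTITY[chain.entity_type]
            for res_idx in sorted(by_res):
                heavy = [i for i in by_res[res_idx] if complex_.atoms[i].is_heavy]
                if not heavy:
                    continue
                center = next(
                    (i for i in heavy if complex_.atoms[i].name == center_name), heavy[0]
                )
                resolved = any(complex_.atoms[i].is_resolved for i in heavy)
                tokens.append(TokenRecord(
                    token_idx=len(tokens), asym_id=chain_id, res_idx=res_idx,
                    entity_type=chain.entity_type, center_atom=center, atom_ids=heavy,
                    is_resolved=resolved and complex_.atoms[center].is_resolved,
                ))
    return tokens
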