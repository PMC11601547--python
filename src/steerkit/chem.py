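"""Cheminformatics-backed ligand annotation (optional, requires rdkit).

Derives the constraint annotation for a ligand straight from an SDF file:
the distance-geometry bounds matrix, bonded/1-3 pair classes, tetrahedral
chirality quadruples in CIP priority order, and double-bond stereo
quadruples. Hydrogens are dropped; atom indices refer to the heavy atoms in
file order, offset into the complex by ``offset``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def annotation_from_sdf(path: str | Path, chain_id: str, offset: int = 0) -> dict:
    """Build a ligand annotation dict (as consumed by ``build_constraints``)
    from the first molecule of an SDF file."""
    try:
        from rdkit import Chem
        from rdkit.Chem import rdDistGeom
    except ImportError as exc:  # pragma: no cover
        raise ImportError("annotation_from_sdf requires the rdkit extra") from exc

    supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=True)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise ValueError(f"{path}: no parsable molecule")
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    n = mol.GetNumAtoms()

    bm = np.array(rdDistGeom.GetMoleculeBoundsMatrix(mol))
    upper = np.triu(bm, k=1)
    lower = np.tril(bm, k=-1).T
    upper = upper + upper.T
    lower = lower + lower.T

    bond_pairs = {tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx())))
                  for b in mol.GetBonds()}
    angle_pairs = set()
    for atom in mol.GetAtoms():
        nbrs = [a.GetIdx() for a in atom.GetNeighbors()]
        for i, a in enumerate(nbrs):
            for b in nbrs[i + 1:]:
                pair = tuple(sorted((a, b)))
                if pair not in bond_pairs:
                    angle_pairs.add(pair)

    ann: dict = {
        "chain_id": chain_id,
        "bounds": {
            "atom_indices": [offset + i for i in range(n)],
            "lower": lower,
            "upper": upper,
            "bond_pairs": sorted(bond_pairs),
            "angle_pairs": sorted(angle_pairs),
        },
    }

    # tetrahedral chirality: quadruple (A, B, C, Z) over the three
    # highest-CIP substituents; R centers have a positive improper dihedral
    ranks = {a.GetIdx(): int(a.GetPropsAsDict().get("_CIPRank", 0))
             for a in mol.GetAtoms()}
    for idx, label in Chem.FindMolChiralCenters(mol, includeUnassigned=False):
        nbrs = sorted((a.GetIdx() for a in mol.GetAtomWithIdx(idx).GetNeighbors()),
                      key=lambda i: -ranks[i])
        if len(nbrs) < 3:
            continue
        quad = (offset + nbrs[0], offset + nbrs[1], offset + nbrs[2], offset + idx)
        ann.setdefault("chiral_R" if label == "R" else "chiral_S", []).append(quad)

    # double-bond stereochemistry: torsions over the declared stereo atoms
    # (and, when present, the complementary substituents, which share the
    # same cis/trans relation)
    for bond in mol.GetBonds():
        stereo = bond.GetStereo()
        if stereo not in (Chem.BondStereo.STEREOE, Chem.BondStereo.STEREOZ):
            continue
        z1, z2 = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        sa1, sa2 = bond.GetStereoAtoms()
        key = "stereo_E" if stereo == Chem.BondStereo.STEREOE else "stereo_Z"
        ann.setdefault(key, []).append(
            (offset + sa1, offset + z1, offset + z2, offset + sa2))
        other1 = [a.GetIdx() for a in mol.GetAtomWithIdx(z1).GetNeighbors()
                  if a.GetIdx() not in (z2, sa1)]
        other2 = [a.GetIdx() for a in mol.GetAtomWithIdx(z2).GetNeighbors()
                  if a.GetIdx() not in (z1, sa2)]
        if other1 and other2:
            ann[key].append((offset + other1[0], offset + z1,
                             offset + z2, offset + other2[0]))
    return ann


def complex_from_sdf(path: str | Path, chain_id: str = "L"):
    """Read the first SDF molecule as a one-chain nonpolymer complex plus
    its annotation (conformer coordinates required)."""
    from rdkit import Chem

    from .structures import AtomRecord, ChainInfo, ComplexStructure

    supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=True)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise ValueError(f"{path}: no parsable molecule")
    if mol.GetNumConformers() == 0:
        raise ValueError(f"{path}: molecule has no 3D coordinates")
    coords = mol.GetConformer().GetPositions()
    atoms = [
        AtomRecord(atom_id=f"{chain_id}:1:{a.GetSymbol()}{i + 1}",
                   name=f"{a.GetSymbol()}{i + 1}", element=a.GetSymbol(),
                   coords=coords[i], chain_id=chain_id, res_idx=1,
                   res_name="LIG")
        for i, a in enumerate(mol.GetAtoms())
    ]
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    complex_ = ComplexStructure(
        atoms=atoms, chains={chain_id: ChainInfo(chain_id, "nonpolymer")},
        bonds=bonds)
    return complex_, annotation_from_sdf(path, chain_id)
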