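"""Synthetic toy complexes, violation injection, and toy denoisers.

Everything in the toolkit is exercisable without downloads: this module
builds small complexes (idealized Cα helices, one-atom-per-base nucleic
strands, hand-built ligand templates with annotated chirality/stereo/
planarity and distance-geometry bounds) whose generated pose satisfies
every constraint of its own constraint set, plus surgical coordinate edits
that make exactly one energy component positive.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import dihedral_angle, kabsch_align
from .potentials import ConstraintSet, build_constraints
from .structures import AtomRecord, ChainInfo, ComplexStructure
from .io import assign_entity_groups

VIOLATION_KINDS = ("chiral_flip", "stereo_flip", "nonplanar", "bond_stretch",
                   "internal_clash", "interchain_clash", "chain_overlap",
                   "covalent_break")


@dataclass
class ChainSpec:
    entity_type: str          # protein | rna | dna | nonpolymer
    length: int = 0           # residues/bases (polymers)
    template: str = ""        # ligand template name (nonpolymers)
    copies: int = 1


@dataclass
class ToySpec:
    chains: list[ChainSpec]
    separation: float = 20.0  # Å between successive chain centroids
    links: list[tuple[int, int]] = field(default_factory=list)  # covalent chain links
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("need at least one chain")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")


# ---------------------------------------------------------------------------
# ligand templates

_T = 1.54 / np.sqrt(3)  # tetrahedral C-X bond component


def _tetrahedral(bond: float = 1.8) -> np.ndarray:
    d = bond / np.sqrt(3)
    return np.array([
        [0.0, 0.0, 0.0],
        [d, d, d],
        [d, -d, -d],
        [-d, d, -d],
        [-d, -d, d],
    ])


def _ethylene_frame(e_config: bool) -> np.ndarray:
    # C1, C2 along x; substituents in the xy plane at ~120°
    c1 = np.array([0.0, 0.0, 0.0])
    c2 = np.array([1.33, 0.0, 0.0])
    a1 = c1 + np.array([-0.75, 1.30, 0.0])
    b1 = c1 + np.array([-0.75, -1.30, 0.0])
    if e_config:
        a2 = c2 + np.array([0.75, -1.30, 0.0])
        b2 = c2 + np.array([0.75, 1.30, 0.0])
    else:
        a2 = c2 + np.array([0.75, 1.30, 0.0])
        b2 = c2 + np.array([0.75, -1.30, 0.0])
    return np.stack([c1, c2, a1, b1, a2, b2])


def _butane() -> np.ndarray:
    # planar trans zigzag with 111° bond angles and a π central torsion
    b = 1.54
    phi = 0.5 * np.arccos(-np.cos(np.deg2rad(111.0)))
    up = b * np.array([np.cos(phi), np.sin(phi), 0.0])
    dn = b * np.array([np.cos(phi), -np.sin(phi), 0.0])
    c1 = np.zeros(3)
    c2 = c1 + up
    c3 = c2 + dn
    c4 = c3 + up
    return np.stack([c1, c2, c3, c4])


#: name -> (atom specs [(name, element)], coords, bonds, kind, loose_others)
_LIGAND_TEMPLATES: dict[str, dict] = {
    "chiral": {
        "atoms": [("C1", "C"), ("BR1", "BR"), ("CL1", "CL"), ("F1", "F"), ("N1", "N")],
        "coords": _tetrahedral(),
        "bonds": [(0, 1), (0, 2), (0, 3), (0, 4)],
        "kind": "chiral",
        "loose_others": False,
    },
    "stereo_e": {
        "atoms": [("C1", "C"), ("C2", "C"), ("BR1", "BR"), ("F1", "F"),
                  ("CL1", "CL"), ("N1", "N")],
        "coords": _ethylene_frame(e_config=True),
        "bonds": [(0, 1), (0, 2), (0, 3), (1, 4), (1, 5)],
        "kind": "stereo_e",
        "loose_others": True,
    },
    "stereo_z": {
        "atoms": [("C1", "C"), ("C2", "C"), ("BR1", "BR"), ("F1", "F"),
                  ("CL1", "CL"), ("N1", "N")],
        "coords": _ethylene_frame(e_config=False),
        "bonds": [(0, 1), (0, 2), (0, 3), (1, 4), (1, 5)],
        "kind": "stereo_z",
        "loose_others": True,
    },
    "planar": {
        "atoms": [("C1", "C"), ("C2", "C"), ("C3", "C"), ("O1", "O"),
                  ("C4", "C"), ("O2", "O")],
        "coords": _ethylene_frame(e_config=True),
        "bonds": [(0, 1), (0, 2), (0, 3), (1, 4), (1, 5)],
        "kind": "planar",
        "loose_others": True,
    },
    "butane": {
        "atoms": [("C1", "C"), ("C2", "C"), ("C3", "C"), ("C4", "C")],
        "coords": _butane(),
        "bonds": [(0, 1), (1, 2), (2, 3)],
        "kind": "plain",
        "loose_others": False,
    },
    "diatomic": {
        "atoms": [("C1", "C"), ("C2", "C")],
        "coords": np.array([[0.0, 0.0, 0.0], [1.54, 0.0, 0.0]]),
        "bonds": [(0, 1)],
        "kind": "plain",
        "loose_others": False,
    },
    "co2": {
        "atoms": [("C1", "C"), ("O1", "O"), ("O2", "O")],
        "coords": np.array([[0.0, 0.0, 0.0], [1.16, 0.0, 0.0], [-1.16, 0.0, 0.0]]),
        "bonds": [(0, 1), (0, 2)],
        "kind": "plain",
        "loose_others": False,
    },
    "ring": {
        "atoms": [(f"C{i+1}", "C") for i in range(6)],
        "coords": np.array([
            [1.39 * np.cos(k * np.pi / 3), 1.39 * np.sin(k * np.pi / 3), 0.0]
            for k in range(6)
        ]),
        "bonds": [(k, (k + 1) % 6) for k in range(6)],
        "kind": "plain",
        "loose_others": False,
    },
}

LIGAND_TEMPLATE_NAMES = tuple(_LIGAND_TEMPLATES)


def _helix_coords(n: int) -> np.ndarray:
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    xyz = np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i], axis=1)
    return xyz - xyz.mean(axis=0)


def _strand_coords(n: int) -> np.ndarray:
    i = np.arange(n)
    theta = np.deg2rad(34.0) * i
    xyz = np.stack([4.0 * np.cos(theta), 4.0 * np.sin(theta), 3.4 * i], axis=1)
    return xyz - xyz.mean(axis=0)


def _angle_pairs(n_atoms: int, bonds: list[tuple[int, int]]) -> set[frozenset]:
    adj: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    bond_set = {frozenset(b) for b in bonds}
    out = set()
    for k in range(n_atoms):
        nb = sorted(adj[k])
        for a_pos, a in enumerate(nb):
            for b in nb[a_pos + 1:]:
                if frozenset((a, b)) not in bond_set:
                    out.add(frozenset((a, b)))
    return out


def _template_annotation(name: str, global_offset: int, chain_id: str) -> dict:
    """Ligand annotation (quadruples + bounds) for one placed template."""
    tpl = _LIGAND_TEMPLATES[name]
    coords = tpl["coords"]
    n = len(coords)
    bonds = tpl["bonds"]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    bond_pairs = {frozenset(b) for b in bonds}
    angle_pairs = _angle_pairs(n, bonds)
    lower = d.copy()
    upper = d.copy()
    if tpl["loose_others"]:
        for a in range(n):
            for b in range(a + 1, n):
                if frozenset((a, b)) not in bond_pairs | angle_pairs:
                    lower[a, b] = lower[b, a] = 0.7 * d[a, b]
                    upper[a, b] = upper[b, a] = 1.43 * d[a, b]
    ann: dict = {
        "chain_id": chain_id,
        "bounds": {
            "atom_indices": list(range(global_offset, global_offset + n)),
            "lower": lower,
            "upper": upper,
            "bond_pairs": [tuple(sorted(p)) for p in bond_pairs],
            "angle_pairs": [tuple(sorted(p)) for p in angle_pairs],
        },
    }
    g = global_offset
    kind = tpl["kind"]
    if kind == "chiral":
        quad = (g + 1, g + 2, g + 3, g + 0)  # (A, B, C, Z) by CIP order
        angle = dihedral_angle(*(coords[i - g] for i in quad))
        # convention: R centers have a positive improper dihedral
        ann["chiral_R" if angle > 0 else "chiral_S"] = [quad]
    elif kind in ("stereo_e", "stereo_z"):
        quads = [(g + 2, g + 0, g + 1, g + 4), (g + 3, g + 0, g + 1, g + 5)]
        ann["stereo_E" if kind == "stereo_e" else "stereo_Z"] = quads
    elif kind == "planar":
        quads = []
        for a1, b1, cfar, cnear in ((2, 3, 1, 0), (4, 5, 0, 1)):
            if abs(dihedral_angle(coords[a1], coords[b1], coords[cfar], coords[cnear])) > np.pi / 2:
                a1, b1 = b1, a1  # pick the ordering whose planar improper is 0
            quads.append((g + a1, g + b1, g + cfar, g + cnear))
        ann["planar"] = quads
    return ann


def make_toy_complex(spec: ToySpec) -> tuple[ComplexStructure, ConstraintSet, dict]:
    """Build a toy complex from a spec; the returned pose satisfies every
    constraint in the returned :class:`ConstraintSet`. The manifest records
    the ground-truth labels (chain ids, entities, templates, links)."""
    atoms: list[AtomRecord] = []
    chains: dict[str, ChainInfo] = {}
    bonds: list[tuple[int, int]] = []
    annotations: list[dict] = []
    manifest: dict = {"chains": [], "links": [], "seed": spec.seed}

    chain_letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    expanded: list[ChainSpec] = []
    for cs in spec.chains:
        expanded.extend([cs] * cs.copies)
    if len(expanded) > len(chain_letters):
        raise ValueError("too many chains for single-letter ids")

    chain_first_atom: list[int] = []
    chain_last_atom: list[int] = []
    for k, cs in enumerate(expanded):
        cid = chain_letters[k]
        offset = len(atoms)
        shift = np.array([k * spec.separation, 0.0, 0.0])
        if cs.entity_type == "nonpolymer":
            if cs.template not in _LIGAND_TEMPLATES:
                raise ValueError(f"unknown ligand template {cs.template!r}")
            tpl = _LIGAND_TEMPLATES[cs.template]
            coords = tpl["coords"] - tpl["coords"].mean(axis=0) + shift
            for (name, element), xyz in zip(tpl["atoms"], coords):
                atoms.append(AtomRecord(
                    atom_id=f"{cid}:1:{name}", name=name, element=element,
                    coords=xyz, chain_id=cid, res_idx=1, res_name="LIG"))
            bonds.extend((offset + i, offset + j) for i, j in tpl["bonds"])
            chains[cid] = ChainInfo(chain_id=cid, entity_type="nonpolymer")
            annotations.append(_template_annotation(cs.template, offset, cid))
            manifest["chains"].append({"chain_id": cid, "entity_type": "nonpolymer",
                                       "template": cs.template})
        else:
            if cs.length < 1:
                raise ValueError("polymer chain needs a positive length")
            if cs.entity_type == "protein":
                coords = _helix_coords(cs.length) + shift
                atom_name, res_name, element = "CA", "GLY", "C"
                seq = "G" * cs.length
            else:
                coords = _strand_coords(cs.length) + shift
                atom_name, element = "C1'", "C"
                res_name = "DA" if cs.entity_type == "dna" else "A"
                seq = "A" * cs.length
            for i, xyz in enumerate(coords):
                atoms.append(AtomRecord(
                    atom_id=f"{cid}:{i + 1}:{atom_name}", name=atom_name,
                    element=element, coords=xyz, chain_id=cid, res_idx=i + 1,
                    res_name=res_name))
            for i in range(cs.length - 1):
                bonds.append((offset + i, offset + i + 1))
            chains[cid] = ChainInfo(chain_id=cid, entity_type=cs.entity_type,
                                    sequence=seq)
            manifest["chains"].append({"chain_id": cid, "entity_type": cs.entity_type,
                                       "length": cs.length})
        chain_first_atom.append(offset)
        chain_last_atom.append(len(atoms) - 1)

    complex_ = ComplexStructure(atoms=atoms, chains=chains, bonds=bonds)

    for ci, cj in spec.links:
        i = chain_last_atom[ci]
        j = chain_first_atom[cj]
        # pull chain cj so the linked atoms sit 1.5 Å apart
        direction = complex_.atoms[j].coords - complex_.atoms[i].coords
        dist = np.linalg.norm(direction)
        if dist > 1e-9:
            delta = (dist - 1.5) * direction / dist
            for idx in complex_.chain_atom_indices(complex_.atoms[j].chain_id):
                complex_.atoms[idx].coords = complex_.atoms[idx].coords - delta
        complex_.bonds.append((i, j))
        manifest["links"].append([i, j])

    assign_entity_groups(complex_)
    for record, cid in zip(manifest["chains"], chains):
        record["entity_id"] = complex_.chains[cid].entity_id
    constraints = build_constraints(complex_, annotations)
    manifest["annotations"] = [
        {k: (v if k != "bounds" else "bounds") for k, v in ann.items()}
        for ann in annotations
    ]
    return complex_, constraints, manifest


# ---------------------------------------------------------------------------
# violation injection

def _rotate_about_axis(points: np.ndarray, origin: np.ndarray, axis: np.ndarray,
                       angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    return (points - origin) @ R.T + origin


def _ligand_side(bonds: list[tuple[int, int]], cut: tuple[int, int],
                 start: int) -> set[int]:
    """Atoms reachable from ``start`` without crossing the cut bond."""
    adj: dict[int, set[int]] = {}
    for i, j in bonds:
        if {i, j} == set(cut):
            continue
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    seen = {start}
    stack = [start]
    while stack:
        for nb in adj.get(stack.pop(), ()):
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


def inject_violation(complex_: ComplexStructure, constraints: ConstraintSet,
                     kind: str, magnitude: float | None = None,
                     seed: int = 0) -> ComplexStructure:
    """Return a copy of ``complex_`` where exactly the targeted energy
    component is violated. Raises if no constraint of the kind exists."""
    if kind not in VIOLATION_KINDS:
        raise ValueError(f"unknown violation kind {kind!r}")
    out = complex_.copy()
    x = out.coords_matrix

    if kind == "chiral_flip":
        quads = constraints.chiral_R + constraints.chiral_S
        if not quads:
            raise ValueError("no chiral constraint to flip")
        chain = out.atoms[quads[0][3]].chain_id
        idx = out.chain_atom_indices(chain)
        center = x[idx].mean(axis=0)
        x[idx, 2] = 2 * center[2] - x[idx, 2]  # mirror through z-plane

    elif kind == "stereo_flip":
        quads = constraints.stereo_E + constraints.stereo_Z
        if not quads:
            raise ValueError("no stereo constraint to flip")
        a1, c1, c2, a2 = quads[0]
        chain = out.atoms[c1].chain_id
        chain_bonds = [(i, j) for i, j in out.bonds
                       if out.atoms[i].chain_id == chain and out.atoms[j].chain_id == chain]
        side = _ligand_side(chain_bonds, (c1, c2), c2) - {c2}
        side_idx = sorted(side)
        x[side_idx] = _rotate_about_axis(x[side_idx], x[c1], x[c2] - x[c1], np.pi)

    elif kind == "nonplanar":
        if not constraints.planar:
            raise ValueError("no planar constraint")
        a1, b1, cfar, cnear = constraints.planar[0]
        angle = 0.6 if magnitude is None else magnitude
        x[[a1]] = _rotate_about_axis(x[[a1]], x[cnear], x[cfar] - x[cnear], angle)

    elif kind == "bond_stretch":
        if not constraints.ligand_bounds or not constraints.ligand_bounds[0].bond_pairs:
            raise ValueError("no ligand bond to stretch")
        lig = constraints.ligand_bounds[0]
        pair = sorted(sorted(p) for p in lig.bond_pairs)[0]
        i, j = (lig.atom_indices[pair[0]], lig.atom_indices[pair[1]])
        factor = 1.5 if magnitude is None else magnitude
        x[j] = x[i] + factor * (x[j] - x[i])

    elif kind == "internal_clash":
        if not constraints.ligand_bounds:
            raise ValueError("no ligand bounds")
        lig = constraints.ligand_bounds[0]
        idx = lig.atom_indices
        chain = out.atoms[idx[0]].chain_id
        chain_bonds = [(i, j) for i, j in out.bonds
                       if out.atoms[i].chain_id == chain and out.atoms[j].chain_id == chain]
        # rotate about a torsion bond (both sides ≥ 2 atoms): bonds and 1-3
        # distances are untouched, only "other" pairs move
        cut = None
        for bond in chain_bonds:
            side = _ligand_side(chain_bonds, bond, bond[1]) - {bond[1]}
            if len(side) >= 1 and len(set(idx) - side - set(bond)) >= 1 \
                    and len(side | {bond[1]}) >= 2 and len(set(idx) - side) >= 3:
                cut = bond
                break
        if cut is None:
            raise ValueError("ligand has no rotatable bond for an internal clash")
        side_idx = sorted(_ligand_side(chain_bonds, cut, cut[1]) - {cut[1]})
        angle = np.pi if magnitude is None else magnitude
        x[side_idx] = _rotate_about_axis(x[side_idx], x[cut[0]],
                                         x[cut[1]] - x[cut[0]], angle)

    elif kind == "interchain_clash":
        if not constraints.cross_chain_pairs:
            raise ValueError("no cross-chain pairs")
        dists = [(float(np.linalg.norm(x[i] - x[j])), i, j, rsum)
                 for i, j, rsum in constraints.cross_chain_pairs]
        _, i, j, rsum = min(dists)
        s = 0.5 if magnitude is None else magnitude
        target = s * rsum
        direction = x[j] - x[i]
        d = float(np.linalg.norm(direction))
        shift = (d - target) * direction / d
        for idx2 in out.chain_atom_indices(out.atoms[j].chain_id):
            x[idx2] -= shift

    elif kind == "chain_overlap":
        if not constraints.symmetric_chain_pairs:
            raise ValueError("no symmetric chain pair")
        ia, ib = constraints.symmetric_chain_pairs[0]
        target = 3.0 if magnitude is None else magnitude
        ca, cb = x[ia].mean(axis=0), x[ib].mean(axis=0)
        # place B's centroid straight "above" A's (out of the placement
        # plane) so only the centroid term, not atom-pair clashes, reacts
        new_cb = ca + np.array([0.0, 0.0, target])
        shift = new_cb - cb
        chain_b = out.atoms[ib[0]].chain_id
        for idx2 in out.chain_atom_indices(chain_b):
            x[idx2] += shift

    elif kind == "covalent_break":
        if not constraints.covalent_cross_bonds:
            raise ValueError("no inter-chain covalent bond")
        i, j = constraints.covalent_cross_bonds[0]
        excess = 1.0 if magnitude is None else magnitude
        direction = x[j] - x[i]
        d = float(np.linalg.norm(direction))
        shift = (2.0 + excess - d) * direction / d
        for idx2 in out.chain_atom_indices(out.atoms[j].chain_id):
            x[idx2] += shift

    out.set_coords(x)
    return out


# ---------------------------------------------------------------------------
# toy denoisers

def make_denoiser(kind: str, target: np.ndarray, delta: float = 10.0,
                  noise_scale: float = 0.1, seed: int = 0):
    """Toy denoiser contracts for exercising the sampler and steering.

    ``ideal`` always returns the target; ``dirac_pathological`` returns the
    target only while the per-atom RMS displacement from the best rigid
    alignment of the target stays below ``delta·σ`` (the zero structure
    otherwise) — a model with near-zero aligned training loss that still
    fails under unaligned interpolation; ``noisy_ideal`` adds deterministic
    pseudo-random jitter derived from the input coordinates.
    """
    target = np.asarray(target, dtype=float)
    if not np.all(np.isfinite(target)):
        raise ValueError("target must be finite")

    if kind == "ideal":
        def denoiser(x, sigma):
            return target.copy()
    elif kind == "dirac_pathological":
        def denoiser(x, sigma):
            try:
                _, _, rms = kabsch_align(target, np.asarray(x, dtype=float))
            except ValueError:
                return np.zeros_like(target)
            return target.copy() if rms < delta * sigma else np.zeros_like(target)
    elif kind == "noisy_ideal":
        def denoiser(x, sigma):
            x = np.asarray(x, dtype=float)
            h = zlib.crc32(np.ascontiguousarray(x).tobytes())
            rng = np.random.default_rng([seed, h])
            return target + noise_scale * rng.standard_normal(target.shape)
    else:
        raise ValueError(f"unknown denoiser kind {kind!r}")
    return denoiser
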