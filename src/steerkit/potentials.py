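"""Flat-bottom constraint potentials over biomolecular coordinates.

Seven hinge-shaped ("flat-bottom") energies penalize the physically
implausible features a structure generator can produce: wrong tetrahedral
chirality, wrong double-bond stereochemistry, non-planar sp² centers,
ligand internal geometry outside distance-geometry bounds, inter-chain
steric clashes, coincident symmetric chains, and broken inter-chain
covalent links. Each energy is exactly zero on any conformer satisfying its
constraint and grows linearly with the violation magnitude, so the summed
potential is cheap to differentiate and safe to switch on anywhere in a
diffusion trajectory.

Sign conventions
----------------
Chirality uses the *signed* improper dihedral over the CIP-ordered
quadruple (X1, X2, X3, Z): an R center is feasible at angle ≥ +π/6, an S
center at ≤ −π/6. Stereochemistry and planarity use the dihedral magnitude
|θ| ∈ [0, π]: an E bond is feasible at |θ| ≥ 5π/6, a Z bond at |θ| ≤ π/6,
and a planar improper at |θ| ≤ π/12.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import dihedral_angle, dihedral_gradient
from .structures import ComplexStructure

COMPONENTS = ("chiral", "stereo", "planar", "geom", "clash", "overlap", "covalent")

CHIRAL_THRESHOLD = np.pi / 6
STEREO_E_THRESHOLD = 5 * np.pi / 6
STEREO_Z_THRESHOLD = np.pi / 6
PLANAR_THRESHOLD = np.pi / 12
CLASH_FACTOR = 0.725
GEOM_UPPER_FACTOR = 1.2
GEOM_LOWER_FACTOR = 0.8
COVALENT_MAX_DISTANCE = 2.0  # Å


def overlap_schedule(t: float) -> float:
    """Minimum centroid distance b_t (Å) for the chain-overlap potential.

    ``b_t = 1 + 4·(exp(−2(1−t)) − 1)/(exp(−2) − 1)`` for diffusion time
    t ∈ [0, 1]; the closed form runs smoothly between 5.0 Å and 1.0 Å and is
    monotone in t.
    """
    t = float(t)
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"diffusion time must lie in [0, 1], got {t}")
    return float(1.0 + 4.0 * (np.exp(-2.0 * (1.0 - t)) - 1.0) / (np.exp(-2.0) - 1.0))


@dataclass
class LigandBounds:
    """Distance-geometry bounds for one ligand.

    ``atom_indices`` are global atom indices (length N); ``lower``/``upper``
    are symmetric N×N matrices in Å; ``bond_pairs`` and ``angle_pairs`` are
    sets of local unordered index pairs (1–2 and 1–3 neighbours in the
    bonded graph). All remaining pairs form the third hinge class.
    """

    chain_id: str
    atom_indices: list[int]
    lower: np.ndarray
    upper: np.ndarray
    bond_pairs: frozenset = frozenset()
    angle_pairs: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        n = len(self.atom_indices)
        if self.lower.shape != (n, n) or self.upper.shape != (n, n):
            raise ValueError("bounds matrices must be N×N over the ligand atoms")
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("lower bound exceeds upper bound")
        self.bond_pairs = frozenset(frozenset(p) for p in self.bond_pairs)
        self.angle_pairs = frozenset(frozenset(p) for p in self.angle_pairs)

    def pair_class(self, i: int, j: int) -> str:
        key = frozenset((i, j))
        if key in self.bond_pairs:
            return "bond"
        if key in self.angle_pairs:
            return "angle"
        return "other"


@dataclass
class ConstraintSet:
    """All constraints the potentials evaluate on one complex.

    Quadruples are global atom-index 4-tuples; ``cross_chain_pairs`` carries
    the summed Van der Waals radii alongside each pair; symmetric chain
    pairs store the atom-index lists whose centroids are compared.
    """

    n_atoms: int
    chiral_R: list[tuple[int, int, int, int]] = field(default_factory=list)
    chiral_S: list[tuple[int, int, int, int]] = field(default_factory=list)
    stereo_E: list[tuple[int, int, int, int]] = field(default_factory=list)
    stereo_Z: list[tuple[int, int, int, int]] = field(default_factory=list)
    planar: list[tuple[int, int, int, int]] = field(default_factory=list)
    ligand_bounds: list[LigandBounds] = field(default_factory=list)
    cross_chain_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    symmetric_chain_pairs: list[tuple[list[int], list[int]]] = field(default_factory=list)
    covalent_cross_bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for quad in (*self.chiral_R, *self.chiral_S, *self.stereo_E,
                     *self.stereo_Z, *self.planar):
            if len(quad) != 4 or any(not 0 <= i < self.n_atoms for i in quad):
                raise ValueError(f"quadruple {quad} references a missing atom")
        for i, j, _ in self.cross_chain_pairs:
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ValueError(f"cross-chain pair ({i}, {j}) references a missing atom")


@dataclass
class PotentialWeights:
    """Weights of the summed potential and the clash time gate."""

    alpha_chiral: float = 1.0
    alpha_stereo: float = 1.0
    alpha_planar: float = 1.0
    alpha_geom: float = 1.0
    alpha_clash: float = 1.0
    alpha_overlap: float = 1.0
    alpha_covalent: float = 1.0
    t_clash: float = 0.5
    lambda_: float = 2.0

    def __post_init__(self) -> None:
        for name in ("alpha_chiral", "alpha_stereo", "alpha_planar", "alpha_geom",
                     "alpha_clash", "alpha_overlap", "alpha_covalent", "lambda_"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def alpha(self, component: str) -> float:
        return getattr(self, f"alpha_{component}")


def build_constraints(complex_: ComplexStructure,
                      ligand_annotations: list[dict] | None = None) -> ConstraintSet:
    """Derive a :class:`ConstraintSet` from a complex plus per-ligand
    annotations.

    Each annotation is a mapping with optional keys ``chain_id``,
    ``chiral_R``/``chiral_S``/``stereo_E``/``stereo_Z``/``planar``
    (lists of global atom-index quadruples), and ``bounds`` (a dict with
    ``atom_indices``, ``lower``, ``upper``, ``bond_pairs``, ``angle_pairs``).
    Cross-chain pairs are all resolved heavy inter-chain pairs between
    chains not covalently linked to each other; symmetric pairs group
    chains of identical entity with more than one atom.
    """
    n = len(complex_.atoms)
    quads = {k: [] for k in ("chiral_R", "chiral_S", "stereo_E", "stereo_Z", "planar")}
    ligand_bounds = []
    for ann in ligand_annotations or []:
        for key in quads:
            quads[key].extend(tuple(q) for q in ann.get(key, []))
        if "bounds" in ann:
            b = ann["bounds"]
            ligand_bounds.append(LigandBounds(
                chain_id=ann.get("chain_id", ""),
                atom_indices=list(b["atom_indices"]),
                lower=np.asarray(b["lower"], dtype=float),
                upper=np.asarray(b["upper"], dtype=float),
                bond_pairs=frozenset(tuple(p) for p in b.get("bond_pairs", [])),
                angle_pairs=frozenset(tuple(p) for p in b.get("angle_pairs", [])),
            ))
    cs = ConstraintSet(n_atoms=n, ligand_bounds=ligand_bounds, **quads)

    bonded_pairs = {frozenset(b) for b in complex_.bonds}
    linked_chains = set()
    for i, j in complex_.bonds:
        ci, cj = complex_.atoms[i].chain_id, complex_.atoms[j].chain_id
        if ci != cj:
            linked_chains.add(frozenset((ci, cj)))
            cs.covalent_cross_bonds.append((i, j))

    chain_ids = list(complex_.chains)
    atom_idx_by_chain = {cid: [k for k in complex_.chain_atom_indices(cid)
                               if complex_.atoms[k].is_resolved and complex_.atoms[k].is_heavy]
                         for cid in chain_ids}
    for a_pos, ca in enumerate(chain_ids):
        for cb in chain_ids[a_pos + 1:]:
            if frozenset((ca, cb)) in linked_chains:
                continue
            for i in atom_idx_by_chain[ca]:
                for j in atom_idx_by_chain[cb]:
                    if frozenset((i, j)) in bonded_pairs:
                        continue
                    rsum = complex_.atoms[i].vdw_radius + complex_.atoms[j].vdw_radius
                    cs.cross_chain_pairs.append((i, j, rsum))

    for a_pos, ca in enumerate(chain_ids):
        for cb in chain_ids[a_pos + 1:]:
            if complex_.chains[ca].entity_id != complex_.chains[cb].entity_id:
                continue
            ia, ib = atom_idx_by_chain[ca], atom_idx_by_chain[cb]
            if len(ia) > 1 and len(ib) > 1:
                cs.symmetric_chain_pairs.append((ia, ib))
    return cs


def constraints_to_dict(cs: ConstraintSet) -> dict:
    """JSON-serializable form of a constraint set (inverse of
    :func:`constraints_from_dict`)."""
    return {
        "n_atoms": cs.n_atoms,
        "chiral_R": [list(q) for q in cs.chiral_R],
        "chiral_S": [list(q) for q in cs.chiral_S],
        "stereo_E": [list(q) for q in cs.stereo_E],
        "stereo_Z": [list(q) for q in cs.stereo_Z],
        "planar": [list(q) for q in cs.planar],
        "ligand_bounds": [
            {
                "chain_id": lb.chain_id,
                "atom_indices": list(lb.atom_indices),
                "lower": lb.lower.tolist(),
                "upper": lb.upper.tolist(),
                "bond_pairs": [sorted(p) for p in lb.bond_pairs],
                "angle_pairs": [sorted(p) for p in lb.angle_pairs],
            }
            for lb in cs.ligand_bounds
        ],
        "cross_chain_pairs": [[i, j, rsum] for i, j, rsum in cs.cross_chain_pairs],
        "symmetric_chain_pairs": [[list(a), list(b)] for a, b in cs.symmetric_chain_pairs],
        "covalent_cross_bonds": [list(p) for p in cs.covalent_cross_bonds],
    }


def constraints_from_dict(data: dict) -> ConstraintSet:
    return ConstraintSet(
        n_atoms=int(data["n_atoms"]),
        chiral_R=[tuple(q) for q in data.get("chiral_R", [])],
        chiral_S=[tuple(q) for q in data.get("chiral_S", [])],
        stereo_E=[tuple(q) for q in data.get("stereo_E", [])],
        stereo_Z=[tuple(q) for q in data.get("stereo_Z", [])],
        planar=[tuple(q) for q in data.get("planar", [])],
        ligand_bounds=[
            LigandBounds(
                chain_id=d.get("chain_id", ""),
                atom_indices=list(d["atom_indices"]),
                lower=np.asarray(d["lower"], dtype=float),
                upper=np.asarray(d["upper"], dtype=float),
                bond_pairs=frozenset(tuple(p) for p in d.get("bond_pairs", [])),
                angle_pairs=frozenset(tuple(p) for p in d.get("angle_pairs", [])),
            )
            for d in data.get("ligand_bounds", [])
        ],
        cross_chain_pairs=[(int(i), int(j), float(r))
                           for i, j, r in data.get("cross_chain_pairs", [])],
        symmetric_chain_pairs=[(list(a), list(b))
                               for a, b in data.get("symmetric_chain_pairs", [])],
        covalent_cross_bonds=[tuple(p) for p in data.get("covalent_cross_bonds", [])],
    )


def _hinge(v: float) -> float:
    return v if v > 0 else 0.0


def energy_components(x: np.ndarray, constraints: ConstraintSet,
                      t: float) -> dict[str, float]:
    """Evaluate the seven component energies at coordinates ``x`` (N×3 Å).

    All components are reported ungated; the clash time gate and the α
    weights are applied by :func:`total_energy`.
    """
    x = np.asarray(x, dtype=float)
    e = {name: 0.0 for name in COMPONENTS}

    def angle(quad):
        return dihedral_angle(*(x[i] for i in quad))

    for quad in constraints.chiral_R:
        e["chiral"] += _hinge(CHIRAL_THRESHOLD - angle(quad))
    for quad in constraints.chiral_S:
        e["chiral"] += _hinge(CHIRAL_THRESHOLD + angle(quad))
    for quad in constraints.stereo_E:
        e["stereo"] += _hinge(STEREO_E_THRESHOLD - abs(angle(quad)))
    for quad in constraints.stereo_Z:
        e["stereo"] += _hinge(abs(angle(quad)) - STEREO_Z_THRESHOLD)
    for quad in constraints.planar:
        e["planar"] += _hinge(abs(angle(quad)) - PLANAR_THRESHOLD)

    for lig in constraints.ligand_bounds:
        idx = np.asarray(lig.atom_indices)
        pos = x[idx]
        n = len(idx)
        for a in range(n):
            for b in range(a + 1, n):
                d = float(np.linalg.norm(pos[a] - pos[b]))
                e["geom"] += _hinge(d - GEOM_UPPER_FACTOR * lig.upper[a, b])
                e["geom"] += _hinge(GEOM_LOWER_FACTOR * lig.lower[a, b] - d)

    for i, j, rsum in constraints.cross_chain_pairs:
        d = float(np.linalg.norm(x[i] - x[j]))
        e["clash"] += _hinge(CLASH_FACTOR * rsum - d)

    b_t = overlap_schedule(t)
    for ia, ib in constraints.symmetric_chain_pairs:
        d = float(np.linalg.norm(x[ia].mean(axis=0) - x[ib].mean(axis=0)))
        e["overlap"] += _hinge(b_t - d)

    for i, j in constraints.covalent_cross_bonds:
        d = float(np.linalg.norm(x[i] - x[j]))
        e["covalent"] += _hinge(d - COVALENT_MAX_DISTANCE)
    return {k: float(v) for k, v in e.items()}


def total_energy(x: np.ndarray, constraints: ConstraintSet,
                 weights: PotentialWeights, t: float) -> float:
    """Weighted sum of components; the clash term only applies for
    t < ``weights.t_clash``."""
    e = energy_components(x, constraints, t)
    total = 0.0
    for name in COMPONENTS:
        if name == "clash" and not t < weights.t_clash:
            continue
        total += weights.alpha(name) * e[name]
    return total


def grad_total_energy(x: np.ndarray, constraints: ConstraintSet,
                      weights: PotentialWeights, t: float) -> np.ndarray:
    """Analytic gradient of :func:`total_energy` (zero inside the feasible
    region; subgradient 0 exactly at hinge kinks)."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)

    def add_dihedral(quad, outer):
        # outer = dE/dθ when the hinge is active
        angle, dangle = dihedral_gradient(*(x[i] for i in quad))
        for k, i in enumerate(quad):
            g[i] += outer(angle) * dangle[k]

    a = weights.alpha("chiral")
    if a > 0:
        for quad in constraints.chiral_R:
            if dihedral_angle(*(x[i] for i in quad)) < CHIRAL_THRESHOLD:
                add_dihedral(quad, lambda _: -a)
        for quad in constraints.chiral_S:
            if dihedral_angle(*(x[i] for i in quad)) > -CHIRAL_THRESHOLD:
                add_dihedral(quad, lambda _: a)
    a = weights.alpha("stereo")
    if a > 0:
        for quad in constraints.stereo_E:
            if abs(dihedral_angle(*(x[i] for i in quad))) < STEREO_E_THRESHOLD:
                add_dihedral(quad, lambda ang: -a * np.sign(ang))
        for quad in constraints.stereo_Z:
            if abs(dihedral_angle(*(x[i] for i in quad))) > STEREO_Z_THRESHOLD:
                add_dihedral(quad, lambda ang: a * np.sign(ang))
    a = weights.alpha("planar")
    if a > 0:
        for quad in constraints.planar:
            if abs(dihedral_angle(*(x[i] for i in quad))) > PLANAR_THRESHOLD:
                add_dihedral(quad, lambda ang: a * np.sign(ang))

    a = weights.alpha("geom")
    if a > 0:
        for lig in constraints.ligand_bounds:
            idx = lig.atom_indices
            n = len(idx)
            for p in range(n):
                for q in range(p + 1, n):
                    i, j = idx[p], idx[q]
                    diff = x[i] - x[j]
                    d = float(np.linalg.norm(diff))
                    if d < 1e-12:
                        continue
                    u = diff / d
                    if d > GEOM_UPPER_FACTOR * lig.upper[p, q]:
                        g[i] += a * u
                        g[j] -= a * u
                    elif d < GEOM_LOWER_FACTOR * lig.lower[p, q]:
                        g[i] -= a * u
                        g[j] += a * u

    a = weights.alpha("clash")
    if a > 0 and t < weights.t_clash:
        for i, j, rsum in constraints.cross_chain_pairs:
            diff = x[i] - x[j]
            d = float(np.linalg.norm(diff))
            if 1e-12 < d < CLASH_FACTOR * rsum:
                u = diff / d
                g[i] -= a * u
                g[j] += a * u

    a = weights.alpha("overlap")
    if a > 0:
        b_t = overlap_schedule(t)
        for ia, ib in constraints.symmetric_chain_pairs:
            diff = x[ia].mean(axis=0) - x[ib].mean(axis=0)
            d = float(np.linalg.norm(diff))
            if 1e-12 < d < b_t:
                u = diff / d
                g[ia] -= a * u / len(ia)
                g[ib] += a * u / len(ib)

    a = weights.alpha("covalent")
    if a > 0:
        for i, j in constraints.covalent_cross_bonds:
            diff = x[i] - x[j]
            d = float(np.linalg.norm(diff))
            if d > COVALENT_MAX_DISTANCE:
                u = diff / d
                g[i] += a * u
                g[j] -= a * u
    return g
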