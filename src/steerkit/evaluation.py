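"""Symmetry-aware structure scoring and physical-quality checks.

LDDT (local distance difference test) scores how well a prediction
preserves the reference's inter-atomic distances, without superposition.
Identical chains and internally symmetric ligands make the atom
correspondence ambiguous, so scoring first searches chain assignments
within symmetry groups and then greedily applies per-ligand graph
automorphisms, evaluating candidates incrementally on only the distance
rows they touch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import islice, permutations, product

import networkx as nx
import numpy as np

from .geometry import dihedral_angle, kabsch_align, apply_rigid
from .potentials import (
    ConstraintSet, GEOM_LOWER_FACTOR, GEOM_UPPER_FACTOR,
)
from .structures import ComplexStructure

DEFAULT_INCLUSION_RADIUS = 15.0  # Å
DEFAULT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)  # Å
QUALITY_CLASH_FACTOR = 0.75
BACKBONE_ATOM_NAMES = {"N", "CA", "C", "O", "P", "O5'", "C5'", "C4'", "C3'", "O3'", "C1'"}


class LddtScorer:
    """Global all-atom LDDT against a fixed reference, with incremental
    re-scoring under partial reassignments of the predicted atoms.

    Pairs counted: reference distance < ``inclusion_radius`` and the two
    atoms belong to different residues. The score is the mean over
    thresholds of the fraction of counted pairs whose distance is preserved
    within that threshold.
    """

    def __init__(self, ref_coords: np.ndarray, residue_keys: list[tuple],
                 inclusion_radius: float = DEFAULT_INCLUSION_RADIUS,
                 thresholds: tuple = DEFAULT_THRESHOLDS):
        self.ref = np.asarray(ref_coords, dtype=float)
        n = len(self.ref)
        self.thresholds = np.asarray(thresholds, dtype=float)
        d_ref = np.linalg.norm(self.ref[:, None, :] - self.ref[None, :, :], axis=-1)
        keys = np.array([hash(k) for k in residue_keys])
        same_res = keys[:, None] == keys[None, :]
        self.mask = (d_ref < inclusion_radius) & ~same_res
        self.mask &= ~np.eye(n, dtype=bool)
        self.d_ref = d_ref
        if not self.mask.any():
            raise ValueError("no qualifying atom pairs for LDDT")
        self.n_pairs = int(self.mask.sum())  # ordered pairs, 2× unordered

    def score(self, pred_coords: np.ndarray, perm: np.ndarray | None = None) -> float:
        """Full recomputation. ``perm[i]`` is the predicted atom assigned to
        reference atom i (identity when None)."""
        pred = np.asarray(pred_coords, dtype=float)
        if perm is not None:
            pred = pred[np.asarray(perm)]
        d_pred = np.linalg.norm(pred[:, None, :] - pred[None, :, :], axis=-1)
        diff = np.abs(d_pred - self.d_ref)[self.mask]
        return float(np.mean([(diff < t).mean() for t in self.thresholds]))

    def preserved_counts(self, pred: np.ndarray) -> np.ndarray:
        d_pred = np.linalg.norm(pred[:, None, :] - pred[None, :, :], axis=-1)
        diff = np.abs(d_pred - self.d_ref)
        return np.array([int(((diff < t) & self.mask).sum()) for t in self.thresholds])

    def score_update(self, pred_coords: np.ndarray, perm: np.ndarray,
                     counts: np.ndarray, new_perm: np.ndarray,
                     affected: np.ndarray) -> tuple[float, np.ndarray]:
        """Score of ``new_perm`` given cached per-threshold preserved counts
        for ``perm``, touching only the distance rows of ``affected``
        reference atoms. Returns (score, new_counts)."""
        pred = np.asarray(pred_coords, dtype=float)
        affected = np.asarray(affected)
        old = pred[perm]
        new = pred[new_perm]
        delta = np.zeros_like(counts)
        for cur, sign in ((old, -1), (new, +1)):
            rows = np.linalg.norm(cur[affected][:, None, :] - cur[None, :, :], axis=-1)
            diff = np.abs(rows - self.d_ref[affected])
            m = self.mask[affected]
            # ordered-pair counts: rows cover (a, j) and (j, a) symmetrically
            for k, t in enumerate(self.thresholds):
                hits = ((diff < t) & m)
                inner = hits[:, affected].sum()  # pairs with both ends affected
                delta[k] += sign * (2 * hits.sum() - inner)
        new_counts = counts + delta
        score = float(np.mean(new_counts / self.n_pairs))
        return score, new_counts


def lddt(pred: np.ndarray, ref: np.ndarray, residue_keys: list[tuple],
         inclusion_radius: float = DEFAULT_INCLUSION_RADIUS,
         thresholds: tuple = DEFAULT_THRESHOLDS) -> float:
    """All-atom LDDT of ``pred`` against ``ref`` with a given atom
    correspondence; ``residue_keys[i]`` identifies atom i's residue."""
    return LddtScorer(ref, residue_keys, inclusion_radius, thresholds).score(pred)


def residue_keys_of(complex_: ComplexStructure) -> list[tuple]:
    return [(a.chain_id, a.res_idx) for a in complex_.atoms]


def ligand_automorphisms(complex_: ComplexStructure, chain_id: str,
                         cap: int = 1000) -> list[np.ndarray]:
    """Element-preserving automorphisms of a ligand's bonded graph, as local
    permutations over the chain's atoms, identity first, capped at ``cap``."""
    idx = complex_.chain_atom_indices(chain_id)
    local = {g: l for l, g in enumerate(idx)}
    G = nx.Graph()
    for l, g in enumerate(idx):
        G.add_node(l, element=complex_.atoms[g].element)
    for i, j in complex_.bonds:
        if i in local and j in local:
            G.add_edge(local[i], local[j])
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        G, G, node_match=lambda a, b: a["element"] == b["element"])
    perms = []
    seen = set()
    identity = tuple(range(len(idx)))
    for mapping in islice(matcher.isomorphisms_iter(), cap * 4):
        perm = tuple(mapping[l] for l in range(len(idx)))
        if perm not in seen:
            seen.add(perm)
            perms.append(perm)
        if len(perms) >= cap:
            break
    if identity in seen:
        perms.remove(identity)
    perms.sort()
    return [np.array(identity)] + [np.array(p) for p in perms]


@dataclass
class SymmetryAssignment:
    chain_map: dict[str, str]
    atom_permutations: dict[str, np.ndarray] = field(default_factory=dict)
    achieved_lddt: float = 0.0
    global_perm: np.ndarray | None = None


def _chain_assignment_candidates(groups: list[list[str]], cap: int):
    """Products of within-group permutations, lexicographic, identity first."""
    per_group = [list(permutations(range(len(g)))) for g in groups]
    count = 0
    for combo in product(*per_group):
        mapping = {}
        for group, perm in zip(groups, combo):
            for a, b in zip(group, (group[i] for i in perm)):
                mapping[a] = b
        yield mapping
        count += 1
        if count >= cap:
            return


def greedy_symmetry_correction(pred: ComplexStructure, ref: ComplexStructure,
                               chain_cap: int = 100, atom_cap: int = 1000,
                               inclusion_radius: float = DEFAULT_INCLUSION_RADIUS,
                               thresholds: tuple = DEFAULT_THRESHOLDS
                               ) -> SymmetryAssignment:
    """Two-stage search for the atom correspondence maximizing global LDDT.

    Stage 1 scores up to ``chain_cap`` chain assignments (permutations
    within symmetry groups, inner atom order fixed) and keeps the best.
    Stage 2 visits each ligand in turn and greedily applies the bonded-graph
    automorphism (≤ ``atom_cap`` per ligand) that most improves the score,
    re-evaluating only the affected distance rows.
    """
    if chain_cap < 1 or atom_cap < 1:
        raise ValueError("caps must be ≥ 1")
    scorer = LddtScorer(ref.coords_matrix, residue_keys_of(ref),
                        inclusion_radius, thresholds)
    pred_coords = pred.coords_matrix

    chain_atoms = {cid: np.array(ref.chain_atom_indices(cid)) for cid in ref.chains}
    groups = {}
    for cid, chain in ref.chains.items():
        groups.setdefault(chain.entity_id, []).append(cid)
    sym_groups = [g for g in groups.values() if len(g) > 1]

    best_map = {cid: cid for cid in ref.chains}
    identity_perm = np.arange(len(ref.atoms))
    best_perm = identity_perm
    best_score = scorer.score(pred_coords)
    for mapping in _chain_assignment_candidates(sym_groups, chain_cap):
        perm = identity_perm.copy()
        for ref_chain, pred_chain in mapping.items():
            perm[chain_atoms[ref_chain]] = chain_atoms[pred_chain]
        score = scorer.score(pred_coords, perm)
        if score > best_score + 1e-12:
            best_score = score
            best_perm = perm
            best_map = {cid: mapping.get(cid, cid) for cid in ref.chains}

    atom_perms: dict[str, np.ndarray] = {}
    counts = scorer.preserved_counts(pred_coords[best_perm])
    for cid, chain in ref.chains.items():
        if chain.entity_type != "nonpolymer":
            continue
        autos = ligand_automorphisms(ref, cid, cap=atom_cap)
        if len(autos) <= 1:
            continue
        idx = chain_atoms[cid]
        chosen = autos[0]
        chosen_counts = counts
        chosen_score = float(np.mean(counts / scorer.n_pairs))
        for auto in autos[1:]:
            new_perm = best_perm.copy()
            new_perm[idx] = best_perm[idx][auto]
            score, new_counts = scorer.score_update(
                pred_coords, best_perm, counts, new_perm, idx)
            if score > chosen_score + 1e-12:
                chosen_score, chosen_counts, chosen = score, new_counts, auto
        if not np.array_equal(chosen, autos[0]):
            best_perm = best_perm.copy()
            best_perm[idx] = best_perm[idx][chosen]
            counts = chosen_counts
            best_score = chosen_score
            atom_perms[cid] = chosen
    return SymmetryAssignment(chain_map=best_map, atom_permutations=atom_perms,
                              achieved_lddt=best_score, global_perm=best_perm)


@dataclass
class QualityReport:
    """Six physical-validity booleans; ``None`` marks a check that could not
    be evaluated (e.g. no bounds for a ligand) — distinct from a failure.
    ``overall_pass`` is the conjunction over the evaluated checks."""

    bond_lengths_ok: bool | None = None
    bond_angles_ok: bool | None = None
    internal_clash_ok: bool | None = None
    chirality_ok: bool | None = None
    stereo_ok: bool | None = None
    interchain_clash_ok: bool | None = None

    @property
    def checks(self) -> dict[str, bool | None]:
        return {
            "bond_lengths_ok": self.bond_lengths_ok,
            "bond_angles_ok": self.bond_angles_ok,
            "internal_clash_ok": self.internal_clash_ok,
            "chirality_ok": self.chirality_ok,
            "stereo_ok": self.stereo_ok,
            "interchain_clash_ok": self.interchain_clash_ok,
        }

    @property
    def overall_pass(self) -> bool:
        return all(v is not False for v in self.checks.values())

    def to_dict(self) -> dict:
        out = dict(self.checks)
        out["overall_pass"] = self.overall_pass
        return out


def quality_report(complex_: ComplexStructure,
                   constraints: ConstraintSet) -> QualityReport:
    """Physical-validity checks on a structure.

    Ligand bond lengths and 1–3 distances must lie inside the
    distance-geometry envelope [0.8L, 1.2U]; all other intra-ligand pairs
    must respect the 0.8L lower bound; chirality and stereochemistry are
    checked by the sign/magnitude of their torsions; an inter-chain clash is
    any non-bonded cross-chain pair between chains of more than one atom
    closer than 0.75·(r_i + r_j).
    """
    x = complex_.coords_matrix
    report = QualityReport()

    has_ligand = any(c.entity_type == "nonpolymer" for c in complex_.chains.values())
    if constraints.ligand_bounds:
        bonds_ok = angles_ok = clash_ok = True
        for lig in constraints.ligand_bounds:
            idx = lig.atom_indices
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    d = float(np.linalg.norm(x[idx[a]] - x[idx[b]]))
                    cls = lig.pair_class(a, b)
                    low = GEOM_LOWER_FACTOR * lig.lower[a, b]
                    high = GEOM_UPPER_FACTOR * lig.upper[a, b]
                    if cls == "bond":
                        bonds_ok &= low <= d <= high
                    elif cls == "angle":
                        angles_ok &= low <= d <= high
                    else:
                        clash_ok &= d >= low
        report.bond_lengths_ok = bool(bonds_ok)
        report.bond_angles_ok = bool(angles_ok)
        report.internal_clash_ok = bool(clash_ok)
    elif not has_ligand:
        report.bond_lengths_ok = True
        report.bond_angles_ok = True
        report.internal_clash_ok = True

    if constraints.chiral_R or constraints.chiral_S:
        ok = all(dihedral_angle(*(x[i] for i in q)) > 0 for q in constraints.chiral_R)
        ok &= all(dihedral_angle(*(x[i] for i in q)) < 0 for q in constraints.chiral_S)
        report.chirality_ok = bool(ok)
    else:
        report.chirality_ok = True
    if constraints.stereo_E or constraints.stereo_Z:
        ok = all(abs(dihedral_angle(*(x[i] for i in q))) > np.pi / 2
                 for q in constraints.stereo_E)
        ok &= all(abs(dihedral_angle(*(x[i] for i in q))) < np.pi / 2
                  for q in constraints.stereo_Z)
        report.stereo_ok = bool(ok)
    else:
        report.stereo_ok = True

    chain_of = [a.chain_id for a in complex_.atoms]
    heavy_counts: dict[str, int] = {}
    for a in complex_.atoms:
        if a.is_heavy and a.is_resolved:
            heavy_counts[a.chain_id] = heavy_counts.get(a.chain_id, 0) + 1
    clash_free = True
    for i, j, rsum in constraints.cross_chain_pairs:
        if heavy_counts.get(chain_of[i], 0) <= 1 or heavy_counts.get(chain_of[j], 0) <= 1:
            continue
        d = float(np.linalg.norm(x[i] - x[j]))
        if d < QUALITY_CLASH_FACTOR * rsum:
            clash_free = False
            break
    report.interchain_clash_ok = clash_free
    return report


def pocket_aligned_rmsd(pred: ComplexStructure, ref: ComplexStructure,
                        ligand_chain_id: str, pocket_radius: float = 10.0,
                        atom_cap: int = 1000) -> float:
    """Heavy-atom ligand RMSD after rigid alignment on the reference pocket.

    The pocket is every non-ligand residue with a heavy atom within
    ``pocket_radius`` Å of the ligand in the reference; alignment uses the
    pocket's backbone atoms. The RMSD is minimized over the ligand's
    bonded-graph automorphisms.
    """
    if ligand_chain_id not in ref.chains:
        raise KeyError(f"unknown ligand chain {ligand_chain_id!r}")
    lig_idx = [i for i in ref.chain_atom_indices(ligand_chain_id)
               if ref.atoms[i].is_heavy and ref.atoms[i].is_resolved]
    lig_coords_ref = ref.coords_matrix[lig_idx]

    pocket_residues = set()
    for i, atom in enumerate(ref.atoms):
        if atom.chain_id == ligand_chain_id or not (atom.is_heavy and atom.is_resolved):
            continue
        d = np.linalg.norm(lig_coords_ref - atom.coords, axis=1).min()
        if d < pocket_radius:
            pocket_residues.add((atom.chain_id, atom.res_idx))
    if not pocket_residues:
        raise ValueError("empty pocket: no residues within radius of the ligand")

    pocket_idx = [i for i, a in enumerate(ref.atoms)
                  if (a.chain_id, a.res_idx) in pocket_residues
                  and a.name in BACKBONE_ATOM_NAMES and a.is_heavy and a.is_resolved]
    if len(pocket_idx) < 3:
        pocket_idx = [i for i, a in enumerate(ref.atoms)
                      if (a.chain_id, a.res_idx) in pocket_residues
                      and a.is_heavy and a.is_resolved]
    pred_x = pred.coords_matrix
    ref_x = ref.coords_matrix
    R, t, _ = kabsch_align(pred_x[pocket_idx], ref_x[pocket_idx])
    pred_aligned = apply_rigid(pred_x, R, t)

    best = np.inf
    for auto in ligand_automorphisms(ref, ligand_chain_id, cap=atom_cap):
        permuted = pred_aligned[np.array(lig_idx)][auto]
        rmsd = float(np.sqrt(np.mean(np.sum((permuted - lig_coords_ref) ** 2, axis=1))))
        best = min(best, rmsd)
    return best
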