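"""Robust pocket conditioning.

At training time the featurizer reveals a partial binding pocket to the
model in a fixed fraction of iterations: a binder chain is chosen (a random
ligand, falling back to any chain), candidate pocket tokens are those of
other chains within a distance cutoff of the binder, and a geometrically
distributed number of them is revealed. At inference time a user-specified
binder and residue list bypass the sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .structures import ComplexStructure, TokenRecord

#: One-hot encoding order for the pocket token feature.
FEATURE_ORDER = ("UNSPECIFIED", "BINDER", "POCKET", "UNSELECTED")


@dataclass
class PocketConfig:
    pocket_conditioned_prop: float = 0.3
    pocket_cutoff: float = 6.0  # Å
    pocket_geometric_p: float = 0.3

    def __post_init__(self) -> None:
        for p in (self.pocket_conditioned_prop, self.pocket_geometric_p):
            if not 0.0 < p <= 1.0:
                raise ValueError("probabilities must lie in (0, 1]")
        if self.pocket_cutoff <= 0:
            raise ValueError("cutoff must be positive")


def _min_distance_to_binder(token: TokenRecord, complex_: ComplexStructure,
                            binder_coords: np.ndarray) -> float:
    coords = [complex_.atoms[i].coords for i in token.atom_ids
              if complex_.atoms[i].is_resolved and complex_.atoms[i].is_heavy]
    if not coords or binder_coords.size == 0:
        return np.inf
    d = np.linalg.norm(np.asarray(coords)[:, None, :] - binder_coords[None, :, :], axis=-1)
    return float(d.min())


def pocket_candidates(tokens: list[TokenRecord], complex_: ComplexStructure,
                      binder_asym_id: str, cutoff: float) -> list[TokenRecord]:
    """Tokens of other chains whose closest resolved heavy atom lies strictly
    within ``cutoff`` Å of the binder's resolved heavy atoms."""
    binder_coords = np.array([
        a.coords for a in complex_.atoms
        if a.chain_id == binder_asym_id and a.is_resolved and a.is_heavy
    ])
    return [
        t for t in tokens
        if t.asym_id != binder_asym_id
        and _min_distance_to_binder(t, complex_, binder_coords) < cutoff
    ]


def featurize_pocket(tokens: list[TokenRecord], complex_: ComplexStructure,
                     config: PocketConfig, seed: int) -> list[TokenRecord]:
    """Training-time pocket featurization (returns new token records).

    With probability ``1 - pocket_conditioned_prop`` every token keeps the
    UNSPECIFIED feature. Otherwise a binder chain is drawn uniformly among
    ligand chains (all chains if there is no ligand), N = min(|candidates|,
    1 + M) pocket tokens are revealed with M ~ Geometric(p) on {1, 2, ...},
    and the remaining tokens are marked UNSELECTED.
    """
    if not tokens:
        raise ValueError("empty token list")
    rng = np.random.default_rng(seed)
    tokens = [replace(t) for t in tokens]
    for t in tokens:
        t.pocket_feature = "UNSPECIFIED"
    if rng.random() >= config.pocket_conditioned_prop:
        return tokens

    ligand_asyms = sorted({t.asym_id for t in tokens if t.entity_type == "nonpolymer"})
    binder_asyms = ligand_asyms or sorted({t.asym_id for t in tokens})
    binder = binder_asyms[int(rng.integers(len(binder_asyms)))]

    candidates = pocket_candidates(tokens, complex_, binder, config.pocket_cutoff)
    if candidates:
        m = int(rng.geometric(config.pocket_geometric_p))
        n = min(len(candidates), 1 + m)
        chosen = rng.choice(len(candidates), size=n, replace=False)
        chosen_ids = {candidates[i].token_idx for i in chosen}
        for t in tokens:
            if t.asym_id == binder:
                t.pocket_feature = "BINDER"
            elif t.token_idx in chosen_ids:
                t.pocket_feature = "POCKET"
            else:
                t.pocket_feature = "UNSELECTED"
    return tokens


def featurize_pocket_manual(tokens: list[TokenRecord], binder_asym_id: str,
                            pocket_residues: list[tuple[str, int]]) -> list[TokenRecord]:
    """Inference-time variant: the user names the binder chain and the known
    pocket residues as ``(chain_id, res_idx)`` pairs; no sampling."""
    tokens = [replace(t) for t in tokens]
    if binder_asym_id not in {t.asym_id for t in tokens}:
        raise KeyError(f"unknown binder chain {binder_asym_id!r}")
    wanted = set(pocket_residues)
    for t in tokens:
        if t.asym_id == binder_asym_id:
            t.pocket_feature = "BINDER"
        elif (t.asym_id, t.res_idx) in wanted:
            t.pocket_feature = "POCKET"
        else:
            t.pocket_feature = "UNSELECTED"
    return tokens


def one_hot_features(tokens: list[TokenRecord]) -> np.ndarray:
    """(n_tokens, 4) one-hot matrix in :data:`FEATURE_ORDER` order."""
    idx = {name: i for i, name in enumerate(FEATURE_ORDER)}
    out = np.zeros((len(tokens), len(FEATURE_ORDER)))
    for row, t in enumerate(tokens):
        out[row, idx[t.pocket_feature]] = 1.0
    return out
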