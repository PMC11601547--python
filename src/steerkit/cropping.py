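"""Unified spatial↔contiguous cropping of token lists.

A crop grows outward from a center token in order of center-atom distance,
but each visited token pulls in its whole *neighborhood*: a contiguous
same-chain residue window of a requested size (or the entire chain/entity
when smaller). Neighborhood size 0 reduces to pure spatial cropping; a size
of half the token budget on a single chain reduces to contiguous cropping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import ComplexStructure, TokenRecord


@dataclass
class CropConfig:
    max_tokens: int = 384
    max_atoms: int = 3456
    neighborhood_sizes: list[int] = field(default_factory=lambda: list(range(0, 41, 2)))

    def __post_init__(self) -> None:
        if self.max_tokens <= 0 or self.max_atoms <= 0:
            raise ValueError("budgets must be positive")
        if any(s < 0 for s in self.neighborhood_sizes):
            raise ValueError("neighborhood sizes must be non-negative")


def _center_coords(tokens: list[TokenRecord], complex_: ComplexStructure) -> np.ndarray:
    return np.array([complex_.atoms[t.center_atom].coords for t in tokens])


def unified_crop(tokens: list[TokenRecord], complex_: ComplexStructure,
                 center_token: TokenRecord, neighborhood_size: int,
                 config: CropConfig) -> list[TokenRecord]:
    """Crop ``tokens`` around ``center_token`` with a given neighborhood size.

    Tokens are visited in ascending distance of their center atom from the
    center token's (ties broken by token index; unresolved tokens are not
    visited but can enter through a window). Each visit atomically adds the
    visited token's neighborhood; an addition that would exceed the token or
    atom budget stops the crop.
    """
    if not tokens:
        raise ValueError("empty token list")
    center_atom = complex_.atoms[center_token.center_atom]
    if not center_atom.is_resolved:
        raise ValueError("center token has no resolved center atom")

    coords = _center_coords(tokens, complex_)
    center = center_atom.coords
    dists = np.linalg.norm(coords - center, axis=1)
    resolved = np.array([t.is_resolved for t in tokens], dtype=bool)
    order = sorted(np.nonzero(resolved)[0],
                   key=lambda i: (dists[i], tokens[i].token_idx))

    by_chain: dict[str, list[TokenRecord]] = {}
    for t in tokens:
        by_chain.setdefault(t.asym_id, []).append(t)

    cropped: dict[int, TokenRecord] = {}
    n_atoms = 0
    for i in order:
        token = tokens[i]
        chain_tokens = by_chain[token.asym_id]
        if len(chain_tokens) <= neighborhood_size:
            selected = chain_tokens
        else:
            min_idx = max_idx = token.res_idx
            selected = [t for t in chain_tokens if t.res_idx == token.res_idx]
            chain_span = (min(t.res_idx for t in chain_tokens),
                          max(t.res_idx for t in chain_tokens))
            while len(selected) < neighborhood_size:
                min_idx -= 1
                max_idx += 1
                selected = [t for t in chain_tokens if min_idx <= t.res_idx <= max_idx]
                if min_idx <= chain_span[0] and max_idx >= chain_span[1]:
                    break
        new_tokens = [t for t in selected if t.token_idx not in cropped]
        new_atoms = sum(len(t.atom_ids) for t in new_tokens)
        if len(cropped) + len(new_tokens) > config.max_tokens \
                or n_atoms + new_atoms > config.max_atoms:
            break
        for t in new_tokens:
            cropped[t.token_idx] = t
        n_atoms += new_atoms
    return sorted(cropped.values(), key=lambda t: t.token_idx)


def _interface_tokens(tokens: list[TokenRecord], complex_: ComplexStructure,
                      chain_a: str, chain_b: str, contact_cutoff: float = 15.0
                      ) -> list[TokenRecord]:
    """Tokens of either chain whose center atom lies within ``contact_cutoff``
    Å of the other chain's center atoms."""
    a = [t for t in tokens if t.asym_id == chain_a and t.is_resolved]
    b = [t for t in tokens if t.asym_id == chain_b and t.is_resolved]
    if not a or not b:
        return []
    ca = _center_coords(a, complex_)
    cb = _center_coords(b, complex_)
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    out = [t for t, keep in zip(a, d.min(axis=1) < contact_cutoff) if keep]
    out += [t for t, keep in zip(b, d.min(axis=0) < contact_cutoff) if keep]
    return out


def sample_crop_params(tokens: list[TokenRecord], complex_: ComplexStructure,
                       chain_or_interface_id: str, config: CropConfig,
                       seed: int) -> tuple[int, TokenRecord]:
    """Draw the random crop parameters: neighborhood size uniform over
    ``config.neighborhood_sizes``, center token uniform within the named
    chain (``"A"``) or interface (``"A|B"``)."""
    rng = np.random.default_rng(seed)
    size = int(rng.choice(config.neighborhood_sizes))
    if "|" in chain_or_interface_id:
        chain_a, chain_b = chain_or_interface_id.split("|", 1)
        for cid in (chain_a, chain_b):
            if cid not in complex_.chains:
                raise KeyError(f"unknown chain {cid!r}")
        pool = _interface_tokens(tokens, complex_, chain_a, chain_b)
    else:
        if chain_or_interface_id not in complex_.chains:
            raise KeyError(f"unknown chain {chain_or_interface_id!r}")
        pool = [t for t in tokens
                if t.asym_id == chain_or_interface_id and t.is_resolved]
    if not pool:
        raise ValueError(f"no tokens for {chain_or_interface_id!r}")
    center = pool[int(rng.integers(len(pool)))]
    return size, center


def sample_crop(tokens: list[TokenRecord], complex_: ComplexStructure,
                chain_or_interface_id: str, config: CropConfig,
                seed: int) -> list[TokenRecord]:
    """Random crop with parameters from :func:`sample_crop_params`;
    deterministic under ``seed``."""
    size, center = sample_crop_params(tokens, complex_, chain_or_interface_id,
                                      config, seed)
    return unified_crop(tokens, complex_, center, size, config)
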