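"""Readers and writers: mmCIF/PDB structures (via gemmi), A3M alignments,
and tab-separated taxonomy maps."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .structures import AtomRecord, ChainInfo, ComplexStructure, classify_residue


class StructureParseError(ValueError):
    pass


@dataclass
class MsaRow:
    sequence: str
    chain_id: str
    taxonomy_id: str | None = None


@dataclass
class MSA:
    """Unpaired alignment rows for one chain; row 0 is the query."""

    rows: list[MsaRow]

    def __post_init__(self) -> None:
        lengths = {len(r.sequence) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"aligned sequences have unequal lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.rows)


def _entity_signature(chain: ChainInfo, res_names: list[str]) -> tuple:
    if chain.entity_type == "nonpolymer":
        return ("nonpolymer", tuple(res_names))
    return (chain.entity_type, chain.sequence)


def assign_entity_groups(complex_: ComplexStructure) -> None:
    """Group chains into symmetric-copy entities by identical type+sequence
    (polymers) or identical residue composition (nonpolymers)."""
    signatures: dict[tuple, str] = {}
    for chain_id, chain in complex_.chains.items():
        res_names = sorted(
            a.res_name for a in complex_.atoms if a.chain_id == chain_id
        )
        sig = _entity_signature(chain, res_names)
        if sig not in signatures:
            signatures[sig] = f"E{len(signatures) + 1}"
        chain.entity_id = signatures[sig]


def parse_structure(path: str | Path, format: str | None = None) -> ComplexStructure:
    """Read an mmCIF or PDB file into a :class:`ComplexStructure`.

    Keeps the first alternate location only; atoms with zero occupancy are
    flagged unresolved. Chain entity types are classified from residue names
    and symmetric-copy groups assigned from identical sequences.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {None: gemmi.CoorFormat.Detect, "mmcif": gemmi.CoorFormat.Mmcif,
           "pdb": gemmi.CoorFormat.Pdb}[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")

    atoms: list[AtomRecord] = []
    chains: dict[str, ChainInfo] = {}
    model = st[0]
    for chain in model:
        res_types = []
        seq_parts = []
        for residue in chain:
            rtype = classify_residue(residue.name)
            res_types.append(rtype)
            if rtype == "protein":
                seq_parts.append(gemmi.find_tabulated_residue(residue.name).one_letter_code.upper()
                                 if gemmi.find_tabulated_residue(residue.name) else "X")
            elif rtype in ("rna", "dna"):
                seq_parts.append(residue.name[-1])
            seen_names: set[str] = set()
            for atom in residue:
                if atom.altloc not in ("", "\x00", "A"):
                    continue
                if atom.name in seen_names:
                    continue
                seen_names.add(atom.name)
                element = atom.element.name
                if element in ("", "X"):
                    raise StructureParseError(
                        f"{path}: unknown element for atom {chain.name}/{residue.seqid.num}/{atom.name}"
                    )
                atoms.append(AtomRecord(
                    atom_id=f"{chain.name}:{residue.seqid.num}:{atom.name}",
                    name=atom.name,
                    element=element,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    chain_id=chain.name,
                    res_idx=residue.seqid.num,
                    res_name=residue.name,
                    is_resolved=atom.occ > 0.0,
                    is_heavy=atom.element.name.upper() not in ("H", "D"),
                ))
        if not res_types:
            continue
        # majority vote over residues decides the chain's entity class
        entity_type = max(set(res_types), key=res_types.count)
        chains[chain.name] = ChainInfo(
            chain_id=chain.name, entity_type=entity_type, sequence="".join(seq_parts)
        )
    if not atoms:
        raise StructureParseError(f"{path}: no atoms parsed")
    complex_ = ComplexStructure(atoms=atoms, chains=chains)
    assign_entity_groups(complex_)
    return complex_


def write_structure(complex_: ComplexStructure, path: str | Path,
                    format: str | None = None) -> None:
    """Write a complex to mmCIF or PDB (inferred from the extension when
    ``format`` is None). Unresolved atoms are written with zero occupancy."""
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = gemmi.Structure()
    st.name = "steerkit"
    model = gemmi.Model("1")
    for chain_id in complex_.chains:
        chain = gemmi.Chain(chain_id)
        current_res = None
        for atom in complex_.atoms:
            if atom.chain_id != chain_id:
                continue
            if current_res is None or current_res.seqid.num != atom.res_idx \
                    or current_res.name != atom.res_name:
                current_res = gemmi.Residue()
                current_res.name = atom.res_name or "UNK"
                current_res.seqid = gemmi.SeqId(atom.res_idx, " ")
                chain.add_residue(current_res)
                current_res = chain[-1]
            g_atom = gemmi.Atom()
            g_atom.name = atom.name
            g_atom.element = gemmi.Element(atom.element)
            g_atom.pos = gemmi.Position(*atom.coords)
            g_atom.occ = 1.0 if atom.is_resolved else 0.0
            current_res.add_atom(g_atom)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(str(path))
    else:
        doc = st.make_mmcif_document()
        doc.write_file(str(path))


def read_taxonomy_map(path: str | Path) -> dict[str, str]:
    """Tab-separated ``sequence_id<TAB>taxonomy_id`` table."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed taxonomy line: {line!r}")
        mapping[parts[0]] = parts[1]
    return mapping


def _strip_insertions(seq: str) -> str:
    # a3m convention: lowercase letters and '.' are insertions relative to
    # the query columns and are removed to recover the aligned frame
    return "".join(c for c in seq if not (c.islower() or c == "."))


def read_msa(path: str | Path, chain_id: str,
             taxonomy_map: dict[str, str] | None = None) -> MSA:
    """Read an A3M alignment for one chain.

    Sequence ids (first whitespace-separated token of each header, without
    the leading ``>``) are looked up in ``taxonomy_map``; unmapped rows get a
    null taxonomy.
    """
    taxonomy_map = taxonomy_map or {}
    text = Path(path).read_text()
    rows: list[MsaRow] = []
    header: str | None = None
    seq_parts: list[str] = []

    def flush() -> None:
        if header is None:
            if seq_parts:
                raise ValueError(f"{path}: sequence data before first header")
            return
        seq = _strip_insertions("".join(seq_parts))
        seq_id = header.split()[0] if header.split() else header
        rows.append(MsaRow(sequence=seq, chain_id=chain_id,
                           taxonomy_id=taxonomy_map.get(seq_id)))

    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            header = line[1:]
            seq_parts = []
        else:
            seq_parts.append(line)
    flush()
    if not rows:
        raise ValueError(f"{path}: empty A3M")
    try:
        return MSA(rows=rows)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
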