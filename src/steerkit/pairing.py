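"""Dense taxonomy-based pairing of per-chain MSAs.

Pairing joins alignment rows across the chains of a complex by shared
taxonomy so inter-chain coevolution is visible to a downstream model, while
keeping the alignment dense: rows are never left empty for a chain while
unpaired sequences remain for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import MSA

#: Default cap on output rows (query row included).
DEFAULT_MAX_ROWS = 16384


@dataclass
class PairedMSA:
    """Result of pairing: per-row chain→sequence maps and paired flags.

    Row 0 is always the query complex (all flags 1). An empty string marks a
    chain with no sequence in that row; writers render it as all-gaps.
    """

    chain_ids: list[str]
    pairing: list[dict[str, str]] = field(default_factory=list)
    is_paired: list[dict[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.pairing) != len(self.is_paired):
            raise ValueError("pairing and is_paired must be parallel")
        for row, flags in zip(self.pairing, self.is_paired):
            if set(row) != set(self.chain_ids) or set(flags) != set(self.chain_ids):
                raise ValueError("every row must contain every chain_id")
        if self.pairing and any(f != 1 for f in self.is_paired[0].values()):
            raise ValueError("query row must be fully paired")

    def __len__(self) -> int:
        return len(self.pairing)

    def column(self, chain_id: str) -> list[str]:
        return [row[chain_id] for row in self.pairing]


def pair_msas(query: list[tuple[str, str]], msas: dict[str, MSA],
              max_rows: int = DEFAULT_MAX_ROWS) -> PairedMSA:
    """Pair per-chain MSAs by taxonomy.

    Parameters
    ----------
    query
        ``(sequence, chain_id)`` pairs for the complex; each chain needs an
        entry in ``msas`` (an empty MSA is legal).
    msas
        ``chain_id -> MSA``. If a chain's first row equals its query
        sequence it is dropped (the query row is re-added explicitly).
    max_rows
        Cap on emitted rows, query row included.

    Taxonomies seen in ≥2 distinct chains are processed in descending order
    of their unique-chain count (ties broken by taxonomy id); inside one
    taxonomy, chains with fewer sequences cycle via ``i mod len``. Chains
    missing from a taxonomy are filled from their unpaired queue with a
    paired-flag of 0, and leftover unpaired rows are appended until the
    queues or the row budget are exhausted.
    """
    chain_ids = [cid for _, cid in query]
    if len(set(chain_ids)) != len(chain_ids):
        raise ValueError("duplicate chain_id in query")
    for cid in chain_ids:
        if cid not in msas:
            raise ValueError(f"no MSA supplied for chain {cid!r}")

    out = PairedMSA(chain_ids=chain_ids)
    out.pairing.append({cid: seq for seq, cid in query})
    out.is_paired.append({cid: 1 for cid in chain_ids})

    # collect (sequence, chain_id, taxonomy_id) entries in file order
    entries: list[tuple[str, str, str | None]] = []
    query_seq = {cid: seq for seq, cid in query}
    for cid in chain_ids:
        rows = list(msas[cid].rows)
        if rows and rows[0].sequence == query_seq[cid]:
            rows = rows[1:]
        for row in rows:
            entries.append((row.sequence, cid, row.taxonomy_id))

    by_taxonomy: dict[str, list[tuple[str, str]]] = {}
    for seq, cid, tax in entries:
        if tax is not None:
            by_taxonomy.setdefault(tax, []).append((seq, cid))

    kept = [tax for tax, ent in by_taxonomy.items()
            if len({cid for _, cid in ent}) >= 2]
    kept.sort(key=lambda tax: (-len({cid for _, cid in by_taxonomy[tax]}), tax))
    kept_set = set(kept)

    available: dict[str, list[str]] = {cid: [] for cid in chain_ids}
    for seq, cid, tax in entries:
        if tax is None or tax not in kept_set:
            available[cid].append(seq)

    full = False
    for tax in kept:
        by_chain: dict[str, list[str]] = {}
        for seq, cid in by_taxonomy[tax]:
            by_chain.setdefault(cid, []).append(seq)
        depth = max(len(seqs) for seqs in by_chain.values())
        for i in range(depth):
            row: dict[str, str] = {}
            flags: dict[str, int] = {}
            for cid, seqs in by_chain.items():
                row[cid] = seqs[i % len(seqs)]
                flags[cid] = 1
            for cid in chain_ids:
                if cid not in row:
                    row[cid] = available[cid].pop(0) if available[cid] else ""
                    flags[cid] = 0
            out.pairing.append(row)
            out.is_paired.append(flags)
            if len(out.pairing) >= max_rows:
                full = True
                break
        if full:
            break

    while not full and any(available[cid] for cid in chain_ids):
        row = {}
        flags = {}
        for cid in chain_ids:
            row[cid] = available[cid].pop(0) if available[cid] else ""
            flags[cid] = 0
        out.pairing.append(row)
        out.is_paired.append(flags)
        if len(out.pairing) >= max_rows:
            full = True
    return out


def write_paired_a3m(paired: PairedMSA, out_prefix, query_lengths: dict[str, int]) -> list:
    """Write one paired A3M per chain plus a paired-flag TSV sidecar.

    Empty rows are rendered as all-gap sequences of the chain's query
    length, keeping every chain file row-aligned with the others.
    """
    from pathlib import Path

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for cid in paired.chain_ids:
        path = Path(f"{out_prefix}_{cid}.a3m")
        lines = []
        for i, row in enumerate(paired.pairing):
            seq = row[cid] or "-" * query_lengths[cid]
            flag = paired.is_paired[i][cid]
            lines.append(f">row{i} paired={flag}")
            lines.append(seq)
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    tsv = Path(f"{out_prefix}_paired_flags.tsv")
    header = "row\t" + "\t".join(paired.chain_ids)
    rows = [
        f"{i}\t" + "\t".join(str(paired.is_paired[i][cid]) for cid in paired.chain_ids)
        for i in range(len(paired.pairing))
    ]
    tsv.write_text("\n".join([header, *rows]) + "\n")
    written.append(tsv)
    return written
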