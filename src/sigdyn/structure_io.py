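"""Cα-level structure and metadata I/O.

Structures are read from PDB-format text (``ATOM`` records only, one chain at
a time) into lightweight :class:`StructureRecord` objects that hold author
residue numbering (insertion codes appended), one-letter residue codes and
Cα coordinates.  A metadata table keyed by member id carries the chain used
for mapping, the species, and the functional-state label (active / inactive /
none) of each ensemble member.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STATE_LABELS = ("active", "inactive", "none")

#: standard three-letter → one-letter amino-acid codes; anything else is 'X'
AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

METADATA_COLUMNS = ("member_id", "chain_id", "species", "state_label", "gene_code")


@dataclass
class StructureRecord:
    """One parsed chain: residue identifiers, one-letter codes, Cα coordinates.

    ``residue_ids`` are author residue numbers with any insertion code
    appended as text (e.g. ``"45"``, ``"45A"``), which keeps identifiers
    unique without renumbering.
    """

    member_id: str
    chain_id: str
    residue_ids: list[str]
    residue_codes: str
    ca_coords: np.ndarray  # (N, 3) Å
    species: str = ""
    state_label: str = "none"
    segments: list[str] = field(default_factory=list)  # optional helix/loop annotation

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float).reshape(-1, 3)
        n = len(self.residue_ids)
        if not (len(self.residue_codes) == n == len(self.ca_coords)):
            raise ValueError(
                f"{self.member_id}: residue ids ({n}), codes "
                f"({len(self.residue_codes)}) and coordinates "
                f"({len(self.ca_coords)}) must have equal length"
            )
        if len(set(self.residue_ids)) != n:
            raise ValueError(f"{self.member_id}: residue identifiers not unique")
        if self.state_label not in STATE_LABELS:
            raise ValueError(
                f"{self.member_id}: state_label {self.state_label!r} not in {STATE_LABELS}"
            )

    def __len__(self) -> int:
        return len(self.residue_ids)


def parse_ca_structure(pdb_text: str, chain_id: str, member_id: str = "") -> StructureRecord:
    """Parse one chain's Cα trace from PDB-format text.

    Keeps, per residue, the CA atom of the highest-occupancy alternate
    location (ties broken by alphabetically first altloc id); residues with
    no CA atom are skipped with a warning; HETATM records are excluded.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise ValueError("no model in PDB text")
    model = structure[0]
    available = [ch.name for ch in model]
    chain = None
    for ch in model:
        if ch.name == chain_id:
            chain = ch
            break
    if chain is None:
        raise ValueError(
            f"chain {chain_id!r} not found; available chains: {sorted(set(available))}"
        )

    residue_ids: list[str] = []
    codes: list[str] = []
    coords: list[list[float]] = []
    for res in chain:
        if res.het_flag != "A":  # ATOM records only
            continue
        cas = [a for a in res if a.name == "CA" and a.element.name != "Ca"]
        if not cas:
            log.warning(
                "%s chain %s residue %s %s: no CA atom, residue skipped",
                member_id or "structure", chain_id, res.seqid.num, res.name,
            )
            continue
        # altloc rule: highest occupancy wins, ties go to the first altloc id
        ca = min(cas, key=lambda a: (-a.occ, a.altloc or "A"))
        icode = res.seqid.icode.strip()
        rid = f"{res.seqid.num}{icode}"
        if rid in residue_ids:
            continue  # duplicate author id (e.g. repeated altloc residue entry)
        residue_ids.append(rid)
        codes.append(AA3TO1.get(res.name.upper(), "X"))
        pos = ca.pos
        coords.append([pos.x, pos.y, pos.z])

    if not residue_ids:
        raise ValueError(f"chain {chain_id!r} has no CA atoms")
    return StructureRecord(
        member_id=member_id or (structure.name or "unknown").strip() or "unknown",
        chain_id=chain_id,
        residue_ids=residue_ids,
        residue_codes="".join(codes),
        ca_coords=np.array(coords),
    )


def record_sequence(record: StructureRecord) -> str:
    """One-letter sequence of the record (residue codes in chain order)."""
    if len(record) == 0:
        raise ValueError("empty record has no sequence")
    return record.residue_codes


_ONE2THREE = {v: k for k, v in AA3TO1.items()}


def write_ca_pdb(record: StructureRecord) -> str:
    """Serialize a record as minimal PDB text (CA ATOM records only)."""
    lines = []
    for i, (rid, code, xyz) in enumerate(
        zip(record.residue_ids, record.residue_codes, record.ca_coords), start=1
    ):
        num, icode = (rid[:-1], rid[-1]) if rid and rid[-1].isalpha() else (rid, " ")
        resname = _ONE2THREE.get(code, "UNK")
        lines.append(
            f"ATOM  {i:5d}  CA  {resname:>3s} {record.chain_id[:1]}{int(num):4d}{icode}"
            f"   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def records_to_fasta(records: list[StructureRecord]) -> str:
    """FASTA text of the records' sequences, one entry per member."""
    chunks = []
    for rec in records:
        seq = record_sequence(rec)
        body = "\n".join(seq[i : i + 60] for i in range(0, len(seq), 60))
        chunks.append(f">{rec.member_id}\n{body}")
    return "\n".join(chunks) + "\n"


@dataclass
class MetadataTable:
    """Validated per-member metadata (chain, species, state label, gene code)."""

    rows: pd.DataFrame

    def __len__(self) -> int:
        return len(self.rows)

    def get(self, member_id: str) -> pd.Series:
        return self.rows.loc[member_id]


def load_metadata(table_text: str) -> MetadataTable:
    """Load and validate the member metadata CSV.

    Required columns: ``member_id, chain_id, species, state_label, gene_code``.
    Unknown state strings are mapped to ``none`` with a warning; duplicate
    member ids or missing columns are errors.
    """
    df = pd.read_csv(io.StringIO(table_text), dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if df["member_id"].duplicated().any():
        dups = df.loc[df["member_id"].duplicated(), "member_id"].tolist()
        raise ValueError(f"duplicate member_id entries: {dups}")
    if (df["chain_id"].str.len() == 0).any():
        raise ValueError("every row must have a nonempty chain_id")
    state = df["state_label"].str.strip().str.lower()
    unknown = ~state.isin(STATE_LABELS)
    if unknown.any():
        for mid, raw in zip(df.loc[unknown, "member_id"], df.loc[unknown, "state_label"]):
            log.warning("member %s: unknown state label %r mapped to 'none'", mid, raw)
        state[unknown] = "none"
    df = df.assign(state_label=state).set_index("member_id", drop=False)
    return MetadataTable(rows=df)
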