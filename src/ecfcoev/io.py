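"""Format readers and writers shared by all pipeline stages.

All user-facing coordinates are 1-based inclusive (matching residue numbering
in structural biology); conversions from 0-based library conventions happen
here and nowhere else.  TSV is the universal inter-stage format; XLSX is
read-only (supplementary-table ingestion).
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SearchIO, SeqIO
from Bio.PDB import PDBParser
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file violates the dialect this pipeline consumes.

    The message names the offending file and, where determinable, the line.
    """


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (plain or aligned) FASTA file into an ordered id -> sequence map."""
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def read_tsv(path: str | Path, columns: Iterable[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if columns is not None:
        missing = set(columns) - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# HMMER3 per-domain hit tables (hmmscan --domtblout dialect)
# ---------------------------------------------------------------------------

#: number of whitespace-separated fields before the free-text description
_DOMTBL_FIELDS = 22


def _validate_domtblout(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_FIELDS + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_FIELDS + 1} "
                    f"domtblout columns, found {len(fields)}"
                )
            try:
                float(fields[13])   # this-domain bit score
                float(fields[12])   # this-domain i-Evalue
                int(fields[19])     # env from
                int(fields[20])     # env to
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparsable numeric field ({exc})") from exc


def parse_domtblout(path: str | Path) -> list["HmmHit"]:
    """Parse an hmmscan per-domain table into :class:`~ecfcoev.retrieval.HmmHit` records.

    Only the hmmscan domtblout column order is accepted; other dialects are
    rejected with the offending line number.  Envelope coordinates are
    returned 1-based inclusive.
    """
    from .retrieval import HmmHit  # local import avoids a cycle

    path = Path(path)
    _validate_domtblout(path)
    hits: list[HmmHit] = []
    with open(path) as fh:
        for qresult in SearchIO.parse(fh, "hmmscan3-domtab"):
            for hit in qresult:
                for hsp in hit:
                    hits.append(
                        HmmHit(
                            protein_id=qresult.id,
                            model_id=hit.id,
                            bit_score=float(hsp.bitscore),
                            evalue=float(hsp.evalue),
                            env_start=int(hsp.env_start) + 1,
                            env_end=int(hsp.env_end),
                        )
                    )
    return hits


# ---------------------------------------------------------------------------
# Newick trees (scikit-bio TreeNode)
# ---------------------------------------------------------------------------

def read_newick(path: str | Path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")


def write_newick(tree, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# PDB coordinate files
# ---------------------------------------------------------------------------

def parse_pdb_ca_coordinates(
    path: str | Path, chains: Iterable[str] | None = None
) -> dict[tuple[str, int], dict[str, np.ndarray]]:
    """Read ATOM records of the first model into ``(chain, resnum) -> {atom: xyz}``.

    Policy: only the first model is used; disordered atoms resolve to the
    highest-occupancy altloc; residues carrying insertion codes are skipped
    with a warning (the reference-numbering maps this pipeline consumes do
    not address them); hydrogens and HETATM records are ignored.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    model = next(structure.get_models())
    wanted = set(chains) if chains is not None else None
    coords: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for chain in model:
        if wanted is not None and chain.id not in wanted:
            continue
        for residue in chain:
            hetflag, resnum, icode = residue.id
            if hetflag.strip():
                continue
            if icode.strip():
                warnings.warn(
                    f"{path}: skipping residue {chain.id}{resnum}{icode} with insertion code"
                )
                continue
            atoms: dict[str, np.ndarray] = {}
            for atom in residue:
                if atom.element == "H":
                    continue
                if atom.is_disordered():
                    atom = max(atom.disordered_get_list(), key=lambda a: a.get_occupancy() or 0.0)
                atoms[atom.get_name()] = np.asarray(atom.get_coord(), dtype=float)
            if atoms:
                coords[(chain.id, int(resnum))] = atoms
    if not coords:
        raise FormatError(f"{path}: no ATOM coordinates parsed")
    return coords


# ---------------------------------------------------------------------------
# Supplementary anti-sigma table (XLSX or TSV, fixed schema)
# ---------------------------------------------------------------------------

#: canonical column names of the full anti-sigma factor list
TABLE_S1_COLUMNS = [
    "anti_sigma_id",
    "as_group",
    "as_subgroup",
    "sequence",
    "ecf_id",
    "ecf_group",
    "ecf_subgroup",
    "organism",
    "phylum",
]


def read_anti_sigma_table(path: str | Path) -> pd.DataFrame:
    """Read the full anti-sigma factor list (XLSX or TSV) in its fixed schema.

    Column matching is positional-tolerant: the file must carry at least the
    canonical columns (case-insensitive fuzzy match on header names).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t")
    rename: dict[str, str] = {}
    lowered = {c: str(c).strip().lower().replace(" ", "_").replace("-", "_") for c in df.columns}
    for canon in TABLE_S1_COLUMNS:
        for orig, low in lowered.items():
            if canon == low or canon in low:
                rename[orig] = canon
                break
    df = df.rename(columns=rename)
    missing = set(TABLE_S1_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: anti-sigma table lacks columns {sorted(missing)}")
    return df[TABLE_S1_COLUMNS]


# ---------------------------------------------------------------------------
# Region annotation and packaged common-contact fixture
# ---------------------------------------------------------------------------

def read_region_table(path: str | Path) -> dict[tuple[str, int], str]:
    """Read a region annotation TSV: columns protein (ecf|asdi), position, region."""
    df = read_tsv(path, columns=["protein", "position", "region"])
    out: dict[tuple[str, int], str] = {}
    for row in df.itertuples(index=False):
        side = str(row.protein).lower()
        if side not in ("ecf", "asdi"):
            raise FormatError(f"{path}: protein column must be 'ecf' or 'asdi', got {row.protein!r}")
        out[(side, int(row.position))] = str(row.region)
    return out


def load_common_contact_table() -> pd.DataFrame:
    """Load the packaged table of contacts shared by all four cocrystal structures.

    Columns: ecf_residue, asdi_residue (RpoE/RseA reference numbering),
    ecf_region, asdi_region, dca_rank (empty if the contact was not among the
    ranked covariation predictions), is_sdp (Y/N).
    """
    with resources.files("ecfcoev.data").joinpath("common_contacts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"dca_rank": "Int64"})
    return df
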