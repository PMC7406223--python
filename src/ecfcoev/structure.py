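"""Validation of contact predictions against ECF/anti-sigma cocrystal structures.

Predictions (in RpoE/RseA reference numbering) are checked for alpha-carbon
proximity (<15 A) in each complex; a prediction counts as a true interaction
when it is proximal in a strict majority of the structures where both
residues are mapped.  Per-structure residue contact sets - either ingested
from an external Voronoi-tessellation run or recomputed with a heavy-atom
distance surrogate - are intersected across all complexes to give the common
contacts, which are then cross-checked against the prediction ranks and the
specificity-determining positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dca import ContactPrediction
from . import io as _io

#: label vocabulary for proximity_label
TRUE_INTERACTION = "true interaction"
NOT_SUPPORTED = "not supported"
UNASSESSABLE = "unassessable"


@dataclass
class StructureComplex:
    """One cocrystal structure with maps into reference numbering.

    ``to_reference`` maps each chain's structure residue numbers to the
    RpoE/RseA reference numbering; the inverse maps are derived lazily.
    """

    structure_id: str
    ecf_chain: str
    asdi_chain: str
    coordinates: Mapping[tuple[str, int], Mapping[str, np.ndarray]]
    to_reference: Mapping[str, Mapping[int, int]]

    def __post_init__(self) -> None:
        for chain, mapping in self.to_reference.items():
            for resnum in mapping:
                if (chain, resnum) not in self.coordinates:
                    raise ValueError(
                        f"{self.structure_id}: mapped residue {chain}{resnum} "
                        "absent from the coordinate set"
                    )
        self._from_reference = {
            chain: {ref: res for res, ref in mapping.items()}
            for chain, mapping in self.to_reference.items()
        }

    @classmethod
    def from_pdb(
        cls,
        path,
        structure_id: str,
        ecf_chain: str,
        asdi_chain: str,
        to_reference: Mapping[str, Mapping[int, int]],
    ) -> "StructureComplex":
        coords = _io.parse_pdb_ca_coordinates(path, chains=(ecf_chain, asdi_chain))
        return cls(structure_id, ecf_chain, asdi_chain, coords, to_reference)

    def _lookup(self, chain: str, ref_pos: int) -> Mapping[str, np.ndarray] | None:
        res = self._from_reference.get(chain, {}).get(ref_pos)
        if res is None:
            return None
        return self.coordinates.get((chain, res))


def ca_distance(
    complex_: StructureComplex, ecf_ref_pos: int, asdi_ref_pos: int
) -> float | None:
    """Alpha-carbon distance (A) between two reference residues, or None when
    either residue is unmapped or lacks a CA atom."""
    a = complex_._lookup(complex_.ecf_chain, ecf_ref_pos)
    b = complex_._lookup(complex_.asdi_chain, asdi_ref_pos)
    if a is None or b is None or "CA" not in a or "CA" not in b:
        return None
    return float(np.linalg.norm(a["CA"] - b["CA"]))


def proximity_label(
    predictions: Sequence[ContactPrediction],
    complexes: Sequence[StructureComplex],
    cutoff: float = 15.0,
) -> pd.DataFrame:
    """Label each prediction by CA proximity across the cocrystal structures.

    "true interaction" iff the distance is < cutoff in strictly more than
    half of the complexes where both residues are mapped; "unassessable" when
    mapped in none.  Per-structure distances are retained in the report.
    """
    if not complexes:
        raise ValueError("need at least one structure")
    rows = []
    for p in predictions:
        dists = {
            c.structure_id: (
                ca_distance(c, p.ecf_residue, p.asdi_residue) if p.mapped else None
            )
            for c in complexes
        }
        assessed = [d for d in dists.values() if d is not None]
        if not assessed:
            label = UNASSESSABLE
        elif sum(d < cutoff for d in assessed) * 2 > len(assessed):
            label = TRUE_INTERACTION
        else:
            label = NOT_SUPPORTED
        rows.append(
            {
                "rank": p.rank,
                "ecf_residue": p.ecf_residue,
                "asdi_residue": p.asdi_residue,
                "label": label,
                **{f"d_{sid}": d for sid, d in dists.items()},
            }
        )
    return pd.DataFrame(rows)


def residue_contact_set(
    complex_: StructureComplex,
    method: str = "distance",
    heavy_cutoff: float = 5.0,
    contact_pairs: Iterable[tuple[str, int, str, int]] | None = None,
) -> set[tuple[int, int]]:
    """Inter-chain residue contacts in reference numbering.

    method="ingest" consumes an externally computed contact list (e.g. from a
    Voronoi tessellation), given as (chain, resnum, chain, resnum) tuples in
    structure numbering.  method="distance" is a documented surrogate: any
    heavy-atom pair within ``heavy_cutoff`` A.  Pairs whose residues have no
    reference mapping are dropped.
    """
    ref = complex_.to_reference
    out: set[tuple[int, int]] = set()
    if method == "ingest":
        if contact_pairs is None:
            raise ValueError("ingest mode requires contact_pairs")
        unknown = []
        for c1, r1, c2, r2 in contact_pairs:
            for c, r in ((c1, r1), (c2, r2)):
                if (c, r) not in complex_.coordinates:
                    unknown.append(f"{c}{r}")
            if unknown:
                continue
            if c1 == complex_.ecf_chain and c2 == complex_.asdi_chain:
                e, a = (c1, r1), (c2, r2)
            elif c2 == complex_.ecf_chain and c1 == complex_.asdi_chain:
                e, a = (c2, r2), (c1, r1)
            else:
                continue
            e_ref = ref.get(e[0], {}).get(e[1])
            a_ref = ref.get(a[0], {}).get(a[1])
            if e_ref is not None and a_ref is not None:
                out.add((e_ref, a_ref))
        if unknown:
            raise ValueError(
                f"{complex_.structure_id}: contact list references unknown residues "
                + ", ".join(sorted(set(unknown)))
            )
        return out
    if method != "distance":
        raise ValueError("method must be 'ingest' or 'distance'")
    ecf_res = [(r, complex_.coordinates[(complex_.ecf_chain, r)]) for r in ref.get(complex_.ecf_chain, {})]
    asdi_res = [(r, complex_.coordinates[(complex_.asdi_chain, r)]) for r in ref.get(complex_.asdi_chain, {})]
    for re_, atoms_e in ecf_res:
        xyz_e = np.array(list(atoms_e.values()))
        for ra, atoms_a in asdi_res:
            xyz_a = np.array(list(atoms_a.values()))
            d = np.linalg.norm(xyz_e[:, None, :] - xyz_a[None, :, :], axis=-1)
            if d.min() <= heavy_cutoff:
                out.add(
                    (
                        ref[complex_.ecf_chain][re_],
                        ref[complex_.asdi_chain][ra],
                    )
                )
    return out


def common_contacts(
    sets: Sequence[set[tuple[int, int]]],
    regions: Mapping[tuple[str, int], str] | None = None,
) -> pd.DataFrame:
    """Intersection of per-structure contact sets, sorted by residue pair."""
    if not sets:
        raise ValueError("no contact sets supplied")
    shared = set.intersection(*map(set, sets))
    rows = [
        {
            "ecf_residue": e,
            "asdi_residue": a,
            "ecf_region": regions.get(("ecf", e)) if regions else None,
            "asdi_region": regions.get(("asdi", a)) if regions else None,
        }
        for e, a in sorted(shared)
    ]
    return pd.DataFrame(rows, columns=["ecf_residue", "asdi_residue", "ecf_region", "asdi_region"])


def crosscheck_dca(
    common: pd.DataFrame, predictions: Sequence[ContactPrediction]
) -> tuple[int, int, pd.DataFrame]:
    """Annotate common contacts with matching prediction ranks.

    Returns (n_predicted, n_unpredicted, annotated table); a common contact
    matches a prediction on exact (ecf_residue, asdi_residue) equality.
    """
    by_pair = {
        (p.ecf_residue, p.asdi_residue): p.rank for p in predictions if p.mapped
    }
    annotated = common.copy()
    annotated["dca_rank"] = [
        by_pair.get((int(r.ecf_residue), int(r.asdi_residue)))
        for r in common.itertuples(index=False)
    ]
    annotated["dca_rank"] = annotated["dca_rank"].astype("Int64")
    n_pred = int(annotated["dca_rank"].notna().sum())
    return n_pred, len(annotated) - n_pred, annotated


def load_reference_common_contacts() -> pd.DataFrame:
    """The packaged transcription of the four-structure common-contact table."""
    return _io.load_common_contact_table()
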