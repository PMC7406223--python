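"""Mirror-tree coevolution test.

Two protein families that interact over evolutionary time accumulate
correlated sequence divergence: the Pearson correlation coefficient (PCC)
between their flattened pairwise-distance matrices, computed over matched
organisms, quantifies this.  Significance is argued by exceedance over
negative-control families (a housekeeping sigma factor and a non-cognate
anti-sigma kinase) that share the organisms but not the interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import pearsonr


@dataclass
class FamilyDistanceMatrix:
    """Pairwise distances of one protein family, one protein per organism."""

    organism_ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        m = len(self.organism_ids)
        if self.D.shape != (m, m):
            raise ValueError("distance matrix shape does not match organism count")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0):
            raise ValueError("distance matrix diagonal must be zero")


@dataclass
class CoevolutionResult:
    pcc: float
    n_pairs: int
    control_pccs: dict[str, float] = field(default_factory=dict)
    significant: bool | None = None


def distance_matrix_from_msa(
    msa: Mapping[str, str], organism_map: Mapping[str, str] | None = None
) -> FamilyDistanceMatrix:
    """Fractional-mismatch distances over mutually ungapped columns.

    ``organism_map`` maps sequence id -> organism; by default sequence ids are
    the organisms.  When several sequences map to one organism the first by
    protein-id sort order is kept.  A pair of rows with no mutually ungapped
    column is an error.
    """
    if organism_map is None:
        organism_map = {sid: sid for sid in msa}
    chosen: dict[str, str] = {}
    for sid in sorted(msa):
        org = organism_map[sid]
        if org not in chosen:
            chosen[org] = sid
        # duplicates resolved by protein-id sort: first wins
    organisms = list(chosen.keys())
    rows = [msa[chosen[o]] for o in organisms]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("alignment rows differ in length")
    X = np.array([list(r) for r in rows])
    gap = (X == "-") | (X == ".")
    m = len(organisms)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ok = ~(gap[i] | gap[j])
            n_ok = int(ok.sum())
            if n_ok == 0:
                raise ValueError(
                    f"zero comparable columns between {organisms[i]!r} and {organisms[j]!r}"
                )
            D[i, j] = D[j, i] = float((X[i, ok] != X[j, ok]).sum()) / n_ok
    return FamilyDistanceMatrix(organisms, D)


def mirror_tree_pcc(Da: FamilyDistanceMatrix, Db: FamilyDistanceMatrix) -> CoevolutionResult:
    """Pearson correlation of the two upper-triangle distance vectors."""
    if Da.organism_ids != Db.organism_ids:
        raise ValueError("organism sets (and order) must match between families")
    m = len(Da.organism_ids)
    if m < 3:
        raise ValueError("need at least 3 organisms")
    iu = np.triu_indices(m, k=1)
    va, vb = Da.D[iu], Db.D[iu]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("degenerate distances: zero variance in a family")
    r, _ = pearsonr(va, vb)
    return CoevolutionResult(pcc=float(r), n_pairs=len(va))


def control_panel(
    families: Mapping[str, FamilyDistanceMatrix],
    interacting_pair: tuple[str, str],
) -> CoevolutionResult:
    """PCC of the designated pair plus every pairing involving a control family.

    The designated pair is flagged significant iff its PCC strictly exceeds
    the maximum control PCC.
    """
    a, b = interacting_pair
    if a not in families or b not in families:
        raise ValueError("designated families missing from the panel")
    controls = [f for f in families if f not in interacting_pair]
    if not controls:
        raise ValueError("need at least one control family")
    main = mirror_tree_pcc(families[a], families[b])
    control_pccs: dict[str, float] = {}
    names = list(families)
    for i, fa in enumerate(names):
        for fb in names[i + 1 :]:
            if {fa, fb} == {a, b}:
                continue
            if fa in controls or fb in controls:
                control_pccs[f"{fa}~{fb}"] = mirror_tree_pcc(families[fa], families[fb]).pcc
    main.control_pccs = control_pccs
    main.significant = main.pcc > max(control_pccs.values())
    return main
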