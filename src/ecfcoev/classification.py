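"""Phylogenetic classification of anti-sigma domains.

ASDI domains are clustered bottom-up-free: a divisive 2-medoid bisection runs
until every cluster's diameter (maximum pairwise k-tuple distance) falls below
a threshold (default 0.6).  Subgroup consensus sequences are then placed on a
neighbor-joining tree rooted on a class II anti-sigma outgroup, and maximal
monophyletic clades whose members regulate the same ECF group become the named
AS groups (AS<ecf-number>, with -1/-2 suffixes when one ECF group maps to
several clades).  Zinc-binding status is read from the Hx3Cx2C signature that
spans helices 2-3 of the domain.

The k-tuple distance is an alignment-free k-mer distance:
``d(a, b) = 1 - S / (min(|a|,|b|) - k + 1)`` where S is the number of shared
k-tuples counted with multiplicity.  It approximates the quick pairwise
distance of common progressive aligners; k defaults to 1.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

Interval = tuple[int, int]

#: zinc-coordination signature spanning ASDI helices 2-3
ZINC_MOTIF = re.compile(r"H.{3}C.{2}C")


@dataclass(frozen=True)
class DistanceParams:
    k: int = 1
    diameter_threshold: float = 0.6

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0.0 < self.diameter_threshold <= 1.0):
            raise ValueError("diameter_threshold must lie in (0, 1]")


@dataclass
class Subgroup:
    subgroup_id: str
    member_ids: list[str]
    diameter: float
    consensus: str = ""
    zinc_fraction: float = float("nan")
    tmh_mode: int | None = None
    conserved_domains: list[tuple[str, float, float]] = field(default_factory=list)


@dataclass
class GroupAssignment:
    group_name: str
    subgroup_ids: list[str]
    cognate_ecf_group: str


# ---------------------------------------------------------------------------
# k-tuple distance
# ---------------------------------------------------------------------------

def ktuple_distance(a: str, b: str, params: DistanceParams = DistanceParams()) -> float:
    """Alignment-free k-mer distance in [0, 1]; 0 for identical sequences."""
    k = params.k
    if len(a) < k or len(b) < k:
        raise ValueError(f"sequences must be at least k={k} long")
    ca = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    shared = sum(min(ca[t], cb[t]) for t in ca.keys() & cb.keys())
    denom = min(len(a), len(b)) - k + 1
    return 1.0 - shared / denom


def distance_matrix(seqs: Sequence[str], params: DistanceParams = DistanceParams()) -> np.ndarray:
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = ktuple_distance(seqs[i], seqs[j], params)
    return D


# ---------------------------------------------------------------------------
# Divisive diameter-bounded clustering
# ---------------------------------------------------------------------------

def _two_medoid_split(D: np.ndarray, members: list[int]) -> tuple[list[int], list[int]]:
    """Deterministic 2-medoid bisection of one cluster on a distance submatrix.

    Medoids are initialized at the two most distant members and the
    assign/update loop iterates to convergence; ties resolve to the
    lower-index medoid / member.
    """
    sub = D[np.ix_(members, members)]
    n = len(members)
    i, j = divmod(int(np.argmax(sub)), n)
    m1, m2 = min(i, j), max(i, j)
    assign = None
    for _ in range(100):
        new_assign = np.where(sub[:, m1] <= sub[:, m2], 0, 1)
        new_assign[m1], new_assign[m2] = 0, 1
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        side0 = np.flatnonzero(assign == 0)
        side1 = np.flatnonzero(assign == 1)
        m1 = side0[int(np.argmin(sub[np.ix_(side0, side0)].sum(axis=1)))]
        m2 = side1[int(np.argmin(sub[np.ix_(side1, side1)].sum(axis=1)))]
    left = [members[x] for x in np.flatnonzero(assign == 0)]
    right = [members[x] for x in np.flatnonzero(assign == 1)]
    return left, right


def bisect_cluster(
    domain_seqs: Mapping[str, str],
    params: DistanceParams = DistanceParams(),
    seed: int = 0,
) -> tuple[list[Subgroup], list[str]]:
    """Divisive bisection until every cluster's diameter is below the threshold.

    Returns the emitted subgroups plus the ids of size-1 terminal clusters
    ("ungrouped").  The procedure is deterministic given the input order; the
    seed parameter is accepted for interface stability but unused because the
    initialization (two most distant members) is itself deterministic.
    """
    del seed
    ids = list(domain_seqs.keys())
    if not ids:
        raise ValueError("no sequences supplied")
    seqs = [domain_seqs[i] for i in ids]
    D = distance_matrix(seqs, params)
    tau = params.diameter_threshold

    def diameter(members: list[int]) -> float:
        if len(members) < 2:
            return 0.0
        return float(D[np.ix_(members, members)].max())

    # split largest-diameter cluster first
    pending: list[list[int]] = [list(range(len(ids)))]
    done: list[tuple[list[int], float]] = []
    ungrouped: list[int] = []
    while pending:
        pending.sort(key=lambda m: (-diameter(m), m[0]))
        members = pending.pop(0)
        d = diameter(members)
        if len(members) == 1:
            ungrouped.append(members[0])
        elif d < tau:
            done.append((members, d))
        else:
            left, right = _two_medoid_split(D, members)
            pending.extend([left, right])

    done.sort(key=lambda md: md[0][0])
    subgroups = [
        Subgroup(subgroup_id=f"SG{n + 1:04d}", member_ids=[ids[i] for i in m], diameter=d)
        for n, (m, d) in enumerate(done)
    ]
    return subgroups, [ids[i] for i in sorted(ungrouped)]


# ---------------------------------------------------------------------------
# Consensus and annotations
# ---------------------------------------------------------------------------

def consensus_sequence(aligned_members: Sequence[str], gap: str = "-") -> str:
    """Column-majority consensus: gap-heavy columns (>= 50% gaps) are dropped,
    else the most frequent residue wins with alphabetical tie-break."""
    if not aligned_members:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in aligned_members}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    n = len(aligned_members)
    out: list[str] = []
    for col in zip(*aligned_members):
        gaps = sum(1 for c in col if c == gap)
        if gaps / n >= 0.5:
            continue
        counts = Counter(c for c in col if c != gap)
        best = min(counts, key=lambda c: (-counts[c], c))
        out.append(best)
    return "".join(out)


def zinc_motif_scan(domain_seq: str, window: Interval | None = None) -> bool:
    """True iff the 8-residue H-x3-C-x2-C signature starts inside the window
    (whole sequence when no window is given; 1-based inclusive)."""
    for m in ZINC_MOTIF.finditer(domain_seq):
        start = m.start() + 1
        if window is None or window[0] <= start <= window[1]:
            return True
    return False


def summarize_subgroup_annotations(
    subgroup: Subgroup,
    domain_seqs: Mapping[str, str],
    tmh_counts: Mapping[str, int] | None = None,
    pfam_hits: Mapping[str, list[tuple[str, int, int]]] | None = None,
    aligned_members: Sequence[str] | None = None,
) -> Subgroup:
    """Fill consensus, zinc fraction, TMH mode, and conserved Pfam domains.

    tmh_mode is the modal transmembrane-helix count (ties to the smaller
    count); conserved domains are those hit in strictly more than half of the
    members, reported with mean start/end.
    """
    members = subgroup.member_ids
    if not members:
        raise ValueError("subgroup has no members")
    if aligned_members is not None:
        subgroup.consensus = consensus_sequence(aligned_members)
    else:
        rows = [domain_seqs[m] for m in members]
        if len({len(r) for r in rows}) == 1:
            subgroup.consensus = consensus_sequence(rows)
    subgroup.zinc_fraction = float(
        np.mean([zinc_motif_scan(domain_seqs[m]) for m in members])
    )
    if tmh_counts is not None:
        counts = Counter(tmh_counts.get(m, 0) for m in members)
        subgroup.tmh_mode = min(counts, key=lambda c: (-counts[c], c))
    if pfam_hits is not None:
        per_domain: dict[str, list[tuple[int, int]]] = {}
        for m in members:
            for name, s, e in pfam_hits.get(m, []):
                per_domain.setdefault(name, []).append((s, e))
        conserved = []
        for name, spans in sorted(per_domain.items()):
            carriers = sum(
                1 for m in members if any(h[0] == name for h in pfam_hits.get(m, []))
            )
            if carriers > len(members) / 2:
                starts, ends = zip(*spans)
                conserved.append((name, float(np.mean(starts)), float(np.mean(ends))))
        subgroup.conserved_domains = conserved
    return subgroup


# ---------------------------------------------------------------------------
# Tree building and group assignment
# ---------------------------------------------------------------------------

def nj_tree_from_matrix(D: np.ndarray, ids: Sequence[str]):
    """Unrooted neighbor joining on a distance matrix (scikit-bio TreeNode);
    negative branch lengths are clamped to zero."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(np.asarray(D, dtype=float), list(ids)))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def build_nj_tree(
    consensus_seqs: Mapping[str, str],
    outgroup_id: str,
    params: DistanceParams = DistanceParams(),
    external_tree=None,
):
    """Neighbor-joining tree of subgroup consensus sequences, rooted on the
    outgroup leaf's branch.

    When an externally inferred tree (e.g. a maximum-likelihood tree) is
    supplied as a scikit-bio TreeNode, only outgroup rooting is performed.
    """
    if external_tree is None:
        ids = list(consensus_seqs.keys())
        if outgroup_id not in ids:
            raise ValueError(f"outgroup {outgroup_id!r} absent from the consensus set")
        if len(ids) < 3:
            raise ValueError("need at least 3 sequences including the outgroup")
        D = distance_matrix([consensus_seqs[i] for i in ids], params)
        tree = nj_tree_from_matrix(D, ids)
    else:
        tree = external_tree
    try:
        tip = tree.find(outgroup_id)
    except Exception as exc:
        raise ValueError(f"outgroup {outgroup_id!r} absent from the tree") from exc
    return tree.root_at(tip, above=True)


def _ecf_group_number(label: str) -> str:
    m = re.match(r"(?i)ECF\s*(.+)", label)
    return m.group(1) if m else label


def assign_groups(
    tree,
    leaf_cognate_map: Mapping[str, str],
    outgroup_id: str | None = None,
) -> list[GroupAssignment]:
    """Split a rooted tree into maximal monophyletic clades of one ECF group.

    Every leaf must carry a cognate ECF group label (the outgroup leaf, if
    named, is ignored).  Clades are named AS<ecf-number>; when one ECF group
    yields several clades, suffixes -1, -2, ... follow preorder traversal.
    """
    def leaf_labels(node) -> set[str]:
        labels = set()
        for tip in node.tips() if not node.is_tip() else [node]:
            if tip.name == outgroup_id:
                continue
            if tip.name not in leaf_cognate_map:
                raise ValueError(f"unlabeled leaf {tip.name!r}")
            labels.add(leaf_cognate_map[tip.name])
        return labels

    clades: list[tuple[str, list[str]]] = []

    def walk(node) -> None:
        labels = leaf_labels(node)
        if not labels:
            return
        if len(labels) == 1:
            members = [
                t.name
                for t in (node.tips() if not node.is_tip() else [node])
                if t.name != outgroup_id
            ]
            clades.append((labels.pop(), members))
            return
        for child in node.children:
            walk(child)

    walk(tree)
    per_group = Counter(g for g, _ in clades)
    seen: Counter = Counter()
    out: list[GroupAssignment] = []
    for ecf_group, members in clades:
        base = f"AS{_ecf_group_number(ecf_group)}"
        if per_group[ecf_group] > 1:
            seen[ecf_group] += 1
            name = f"{base}-{seen[ecf_group]}"
        else:
            name = base
        out.append(GroupAssignment(name, members, ecf_group))
    return out
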