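"""Synthetic paired protein families with known ground truth.

The generator emulates the data regime the pipeline assumes: each organism
carries one ECF/ASDI pair; the two families evolve along a shared phylogeny
(or along independent phylogenies, for null comparisons); a set of planted
column pairs coevolves by compensatory substitution; organisms fall into
groups with divergent root (consensus) sequences; and a configurable
fraction of groups carries a substitution-protected zinc-binding motif in
the ASDI.

Evolution model: Yule pure-birth trees rescaled to unit root-to-tip height;
every site substitutes as a Poisson process at rate mu (expected
substitutions per site over the root-to-tip path = mu), with uniform
replacement over the 19 other residues.  When a site of a planted pair
substitutes to residue a, its partner is immediately set to phi(a) with
probability rho, where phi is a fixed involution of the alphabet swapping
charge partners (D<->R, E<->K) and leaving all other residues in place -
mimicking the charged and hydrophobic-identity contact types seen at real
coevolving interfaces.  No indels, so rows are trivially aligned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .dca import AMINO_ACIDS, PairedFamilyAlignment

#: compensatory substitution map: an involution over the 20 residues
COMPENSATORY_MAP = {a: a for a in AMINO_ACIDS} | {"D": "R", "R": "D", "E": "K", "K": "E"}

#: 1-based ASDI positions of the planted H-x3-C-x2-C anchors (H, C, C)
ZINC_ANCHORS = (11, 15, 18)
_ZINC_RESIDUES = dict(zip(ZINC_ANCHORS, "HCC"))


@dataclass
class SimulationConfig:
    n_taxa: int = 100
    birth_rate: float = 1.0
    len_ecf: int = 60
    len_asdi: int = 40
    mu: float = 0.5
    coupled_pairs: tuple[tuple[int, int], ...] = ()  # 1-based (ecf_col, asdi_col)
    coupling_prob: float = 0.9
    n_groups: int = 1
    zinc_fraction: float = 0.0
    independent_trees: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 * self.n_groups:
            raise ValueError("need at least 2 taxa per group")
        if not (0.0 <= self.coupling_prob <= 1.0):
            raise ValueError("coupling_prob must lie in [0, 1]")
        ecf_cols = [e for e, _ in self.coupled_pairs]
        asdi_cols = [a for _, a in self.coupled_pairs]
        if len(set(ecf_cols)) != len(ecf_cols) or len(set(asdi_cols)) != len(asdi_cols):
            raise ValueError("each column may appear in at most one coupled pair")
        for e, a in self.coupled_pairs:
            if not (1 <= e <= self.len_ecf and 1 <= a <= self.len_asdi):
                raise ValueError(f"coupled pair ({e}, {a}) out of bounds")
        if self.zinc_fraction and set(asdi_cols) & set(ZINC_ANCHORS):
            raise ValueError("coupled pair spans the protected zinc motif")
        if self.zinc_fraction and self.len_asdi < max(ZINC_ANCHORS):
            raise ValueError("len_asdi too short to carry the zinc motif")
        if self.independent_trees and self.coupled_pairs:
            raise ValueError("planted couplings require a shared tree")


@dataclass
class GroundTruth:
    trees: dict[str, str]  # group -> Newick (";"-terminated); ASDI trees keyed group+"/asdi"
    group_labels: dict[str, str]
    planted_contacts: list[tuple[int, int]]  # 1-based (ecf_col, asdi_col) per protein
    zinc_rows: list[str]

    def planted_global_pairs(self, len_ecf: int) -> list[tuple[int, int]]:
        """Planted pairs as 1-based columns of the concatenated alignment."""
        return [(e, len_ecf + a) for e, a in self.planted_contacts]


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(
    n_taxa: int, birth_rate: float = 1.0, seed: int = 0, height: float = 1.0
) -> dendropy.Tree:
    """Yule pure-birth tree with ``n_taxa`` leaves, rescaled so the maximum
    root-to-tip path equals ``height`` (branch lengths are then in expected
    substitutions per site per unit of mu)."""
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    import random as _random

    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=_random.Random(int(seed)),
    )
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    scale = height / depth if depth > 0 else 1.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return tree


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _substitute(residue: str, rng: np.random.Generator) -> str:
    choices = AMINO_ACIDS.replace(residue, "") if residue in AMINO_ACIDS else AMINO_ACIDS
    return choices[rng.integers(len(choices))]


def _evolve_pair_on_tree(
    tree: dendropy.Tree,
    root_ecf: list[str],
    root_asdi: list[str],
    mu: float,
    rho: float,
    coupled: Mapping[tuple[str, int], tuple[str, int]],
    protected_asdi: frozenset[int],
    rng: np.random.Generator,
) -> dict[str, tuple[str, str]]:
    """Evolve a concatenable ECF/ASDI pair down one tree.

    ``coupled`` maps ("ecf", col0) <-> ("asdi", col0) both ways (0-based).
    Within a branch the ASDI sites mutate first and the ECF sites second, so
    an ECF-driven compensatory overwrite takes precedence on conflicts.
    """
    seqs: dict[int, tuple[list[str], list[str]]] = {id(tree.seed_node): (root_ecf, root_asdi)}
    leaves: dict[str, tuple[str, str]] = {}
    for node in tree.preorder_node_iter():
        ecf, asdi = seqs.pop(id(node))
        if node.is_leaf():
            leaves[node.taxon.label] = ("".join(ecf), "".join(asdi))
            continue
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            ce, ca = ecf.copy(), asdi.copy()
            for side, seq, other in (("asdi", ca, ce), ("ecf", ce, ca)):
                n_sites = len(seq)
                n_events = rng.poisson(mu * t, size=n_sites)
                for col in np.flatnonzero(n_events):
                    if side == "asdi" and (col + 1) in protected_asdi:
                        continue
                    for _ in range(int(n_events[col])):
                        new = _substitute(seq[col], rng)
                        seq[col] = new
                        partner = coupled.get((side, col))
                        if partner is not None and rng.random() < rho:
                            other[partner[1]] = COMPENSATORY_MAP[new]
            seqs[id(child)] = (ce, ca)
    return leaves


def _random_seq(
    length: int, rng: np.random.Generator, alphabet: str = AMINO_ACIDS
) -> list[str]:
    return [alphabet[i] for i in rng.integers(len(alphabet), size=length)]


def _group_alphabet(group: int, n_groups: int) -> str:
    """Disjoint residue alphabets for group roots (round-robin partition),
    giving clades distinct consensus compositions; substitutions still draw
    from the full alphabet."""
    return AMINO_ACIDS[group::n_groups]


def evolve_paired_alignment(
    config: SimulationConfig,
) -> tuple[PairedFamilyAlignment, GroundTruth]:
    """Simulate the paired alignment and its full ground truth."""
    rng = np.random.default_rng(config.seed)
    sizes = [
        config.n_taxa // config.n_groups + (g < config.n_taxa % config.n_groups)
        for g in range(config.n_groups)
    ]
    n_zinc = int(round(config.zinc_fraction * config.n_groups))
    zinc_groups = set(rng.permutation(config.n_groups)[:n_zinc])

    coupled: dict[tuple[str, int], tuple[str, int]] = {}
    for e, a in config.coupled_pairs:
        coupled[("ecf", e - 1)] = ("asdi", a - 1)
        coupled[("asdi", a - 1)] = ("ecf", e - 1)

    ids: list[str] = []
    rows: list[str] = []
    trees: dict[str, str] = {}
    group_labels: dict[str, str] = {}
    zinc_rows: list[str] = []
    for g, size in enumerate(sizes):
        gname = f"G{g + 1}"
        tree_seed = int(rng.integers(2**31))
        tree = simulate_tree(size, config.birth_rate, seed=tree_seed)
        trees[gname] = tree.as_string(schema="newick", suppress_rooting=True).strip()
        alphabet = _group_alphabet(g, config.n_groups)
        root_ecf = _random_seq(config.len_ecf, rng, alphabet)
        root_asdi = _random_seq(config.len_asdi, rng, alphabet)
        protected: frozenset[int] = frozenset()
        if g in zinc_groups:
            for pos, res in _ZINC_RESIDUES.items():
                root_asdi[pos - 1] = res
            protected = frozenset(ZINC_ANCHORS)
        if config.independent_trees:
            asdi_seed = int(rng.integers(2**31))
            asdi_tree = simulate_tree(size, config.birth_rate, seed=asdi_seed)
            trees[gname + "/asdi"] = asdi_tree.as_string(
                schema="newick", suppress_rooting=True
            ).strip()
            ecf_leaves = _evolve_pair_on_tree(
                tree, root_ecf, [], config.mu, 0.0, {}, frozenset(), rng
            )
            asdi_leaves = _evolve_pair_on_tree(
                asdi_tree, [], root_asdi, config.mu, 0.0, {}, protected, rng
            )
            labels_e = sorted(ecf_leaves)
            labels_a = sorted(asdi_leaves)
            leaves = {
                le: (ecf_leaves[le][0], asdi_leaves[la][1])
                for le, la in zip(labels_e, labels_a)
            }
        else:
            leaves = _evolve_pair_on_tree(
                tree,
                root_ecf,
                root_asdi,
                config.mu,
                config.coupling_prob,
                coupled,
                protected,
                rng,
            )
        for label in sorted(leaves):
            org = f"{gname}_{label}"
            ecf_seq, asdi_seq = leaves[label]
            ids.append(org)
            rows.append(ecf_seq + asdi_seq)
            group_labels[org] = gname
            if g in zinc_groups:
                zinc_rows.append(org)

    alignment = PairedFamilyAlignment(ids=ids, rows=rows, n_ecf=config.len_ecf)
    truth = GroundTruth(
        trees=trees,
        group_labels=group_labels,
        planted_contacts=list(config.coupled_pairs),
        zinc_rows=zinc_rows,
    )
    return alignment, truth


def default_coupled_pairs(
    config: SimulationConfig, n_pairs: int = 8, seed: int | None = None
) -> tuple[tuple[int, int], ...]:
    """Draw ``n_pairs`` distinct inter-protein column pairs compatible with the
    config (avoiding the protected zinc anchors)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ecf_cols = rng.permutation(np.arange(1, config.len_ecf + 1))[:n_pairs]
    asdi_avail = [
        a
        for a in range(1, config.len_asdi + 1)
        if not (config.zinc_fraction and a in ZINC_ANCHORS)
    ]
    asdi_cols = rng.permutation(asdi_avail)[:n_pairs]
    if len(ecf_cols) < n_pairs or len(asdi_cols) < n_pairs:
        raise ValueError("alignment too short for the requested number of pairs")
    return tuple((int(e), int(a)) for e, a in zip(ecf_cols, asdi_cols))


def planted_sdp_alignment(
    n_groups: int = 12,
    rows_per_group: int = 100,
    n_cols: int = 30,
    noise: float = 0.1,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], dict[str, int]]:
    """Aligned family with one planted specificity-determining column per group.

    All groups share a noisy column-wise consensus; at each group's planted
    column that group carries a distinctive residue while every other group
    carries a common alternative.  Returns (msa, labels, planted) where
    ``planted`` maps group name to its 1-based specificity column.
    """
    if n_cols < n_groups:
        raise ValueError("need at least one column per group")
    rng = np.random.default_rng(seed)
    planted_cols = rng.permutation(n_cols)[:n_groups]
    background = _random_seq(n_cols, rng)
    msa: dict[str, str] = {}
    labels: dict[str, str] = {}
    planted: dict[str, int] = {}
    specific: dict[int, tuple[str, str]] = {}
    for g in range(n_groups):
        col = int(planted_cols[g])
        own, others = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
        specific[col] = (str(own), str(others))
        planted[f"G{g + 1}"] = col + 1
    for g in range(n_groups):
        gname = f"G{g + 1}"
        for r in range(rows_per_group):
            row = list(background)
            for col, (own, others) in specific.items():
                row[col] = own if planted[gname] == col + 1 else others
            noisy = rng.random(n_cols) < noise
            for col in np.flatnonzero(noisy):
                row[col] = _substitute(row[col], rng)
            rid = f"{gname}_r{r}"
            msa[rid] = "".join(row)
            labels[rid] = gname
    return msa, labels, planted


# ---------------------------------------------------------------------------
# family views and fixture emission
# ---------------------------------------------------------------------------

def family_halves(alignment: PairedFamilyAlignment) -> tuple[dict[str, str], dict[str, str]]:
    """Split the concatenated rows back into per-family MSAs keyed by organism."""
    B = alignment.n_ecf
    ecf = {i: r[:B] for i, r in zip(alignment.ids, alignment.rows)}
    asdi = {i: r[B:] for i, r in zip(alignment.ids, alignment.rows)}
    return ecf, asdi


def emit_fixture_bundle(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the simulated bundle (FASTA pair, pairing and group TSVs,
    ground-truth JSON, Newick trees); bit-identical given the same config."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alignment, truth = evolve_paired_alignment(config)
    ecf, asdi = family_halves(alignment)
    paths = {
        "ecf_fasta": outdir / "ecf_aln.fasta",
        "asdi_fasta": outdir / "asdi_aln.fasta",
        "pairs": outdir / "pairs.tsv",
        "groups": outdir / "groups.tsv",
        "truth": outdir / "ground_truth.json",
        "trees": outdir / "trees.nwk",
    }
    _io.write_fasta({f"{o}|ecf": s for o, s in ecf.items()}, paths["ecf_fasta"])
    _io.write_fasta({f"{o}|asdi": s for o, s in asdi.items()}, paths["asdi_fasta"])
    with open(paths["pairs"], "w") as fh:
        fh.write("organism\tecf_id\tasdi_id\n")
        for o in alignment.ids:
            fh.write(f"{o}\t{o}|ecf\t{o}|asdi\n")
    with open(paths["groups"], "w") as fh:
        fh.write("organism\tgroup\n")
        for o in alignment.ids:
            fh.write(f"{o}\t{truth.group_labels[o]}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "config": asdict(config),
                "planted_contacts": truth.planted_contacts,
                "zinc_rows": truth.zinc_rows,
                "group_labels": truth.group_labels,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    with open(paths["trees"], "w") as fh:
        for name in sorted(truth.trees):
            fh.write(truth.trees[name] + "\n")
    return paths
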