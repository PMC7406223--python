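"""Specificity-determining positions (SDPs) of anti-sigma / ECF groups.

For every pair of large groups, alignment columns are ranked by how strongly
they discriminate the two groups; ranks are then aggregated per group by the
sum of inverse ranks across all pairwise runs involving that group, and the
top-scoring column per group is the group's SDP.

The per-pair ranking uses the Jensen-Shannon divergence between the two
groups' pseudocounted residue distributions (gap counted as a 21st state) as
the group-specificity statistic; externally computed rank lists (e.g. from a
multiple-correspondence-analysis tool) can be ingested in place of the
internal statistic and aggregate identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon

from .dca import AMINO_ACIDS

_STATES = AMINO_ACIDS + "-"


@dataclass
class SDPRun:
    """Ranked specificity columns for one pair of groups (rank 1 = best)."""

    group_a: str
    group_b: str
    ranked_positions: list[int]  # 1-based alignment columns

    def __post_init__(self) -> None:
        if len(set(self.ranked_positions)) != len(self.ranked_positions):
            raise ValueError("duplicate positions in a run")

    @property
    def groups(self) -> tuple[str, str]:
        return (self.group_a, self.group_b)


@dataclass
class SDPScoreTable:
    scores: dict[tuple[str, int], float]
    selected: dict[str, int | None] = field(default_factory=dict)


def _column_distribution(column: Sequence[str], pseudocount: float) -> np.ndarray:
    counts = np.full(len(_STATES), pseudocount, dtype=float)
    for c in column:
        idx = _STATES.find(c)
        counts[idx if idx >= 0 else len(_STATES) - 1] += 1.0
    return counts / counts.sum()


def group_specificity_ranks(
    msa: Mapping[str, str],
    labels: Mapping[str, str],
    group_a: str,
    group_b: str,
    pseudocount: float = 0.5,
) -> SDPRun:
    """Rank columns by Jensen-Shannon divergence between two groups.

    Columns with zero divergence (identically distributed residues) are
    excluded; ties break by column index.
    """
    rows_a = [msa[i] for i in sorted(msa) if labels.get(i) == group_a]
    rows_b = [msa[i] for i in sorted(msa) if labels.get(i) == group_b]
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise ValueError("both groups need at least 2 rows")
    if len({len(r) for r in rows_a + rows_b}) != 1:
        raise ValueError("alignment rows differ in length")
    n_cols = len(rows_a[0])
    jsd = np.zeros(n_cols)
    for c in range(n_cols):
        pa = _column_distribution([r[c] for r in rows_a], pseudocount)
        pb = _column_distribution([r[c] for r in rows_b], pseudocount)
        jsd[c] = jensenshannon(pa, pb, base=2) ** 2
    order = sorted(range(n_cols), key=lambda c: (-jsd[c], c))
    ranked = [c + 1 for c in order if jsd[c] > 1e-12]
    return SDPRun(group_a, group_b, ranked)


def aggregate_sdp_scores(runs: Sequence[SDPRun], groups: Sequence[str]) -> SDPScoreTable:
    """Sum-of-inverse-rank aggregation and top-SDP selection per group.

    score(g, p) = sum over runs involving g of 1/rank(p); the selected SDP of
    a group is the argmax position (ties to the smallest column index).
    """
    scores: dict[tuple[str, int], float] = {}
    for run in runs:
        for rank, pos in enumerate(run.ranked_positions, start=1):
            for g in run.groups:
                if g in groups:
                    scores[(g, pos)] = scores.get((g, pos), 0.0) + 1.0 / rank
    selected: dict[str, int | None] = {}
    for g in groups:
        cand = [(p, s) for (gg, p), s in scores.items() if gg == g]
        if cand:
            selected[g] = min(cand, key=lambda ps: (-ps[1], ps[0]))[0]
        else:
            selected[g] = None
    return SDPScoreTable(scores=scores, selected=selected)


def ingest_external_ranks(
    rank_lists: Mapping[tuple[str, str], Sequence[tuple[int, int]]],
) -> list[SDPRun]:
    """Build runs from externally computed (position, rank) lists per group pair."""
    runs = []
    for (ga, gb), pairs in rank_lists.items():
        ordered = sorted(pairs, key=lambda pr: pr[1])
        expected = list(range(1, len(ordered) + 1))
        if [r for _, r in ordered] != expected:
            raise ValueError(f"ranks for ({ga}, {gb}) are not 1..n without repeats")
        runs.append(SDPRun(ga, gb, [p for p, _ in ordered]))
    return runs


def run_pairwise_sdp(
    msa: Mapping[str, str],
    labels: Mapping[str, str],
    min_group_size: int = 100,
    pseudocount: float = 0.5,
    max_gap_fraction: float = 0.5,
) -> tuple[SDPScoreTable, list[SDPRun]]:
    """All-pairs driver over the groups large enough to carry a signal.

    Groups whose mean gap fraction exceeds ``max_gap_fraction`` fit the shared
    alignment poorly; they stay in the analysis but trigger a warning, since
    their SDPs are dominated by gap columns and resist interpretation.
    """
    sizes: dict[str, int] = {}
    for i in msa:
        g = labels.get(i)
        if g is not None:
            sizes[g] = sizes.get(g, 0) + 1
    big = sorted(g for g, n in sizes.items() if n >= min_group_size)
    if len(big) < 2:
        raise ValueError(f"need >= 2 groups with >= {min_group_size} members")
    for g in big:
        rows = [msa[i] for i in msa if labels.get(i) == g]
        gap_frac = float(np.mean([r.count("-") / len(r) for r in rows]))
        if gap_frac > max_gap_fraction:
            warnings.warn(
                f"group {g} has mean gap fraction {gap_frac:.2f}; its members "
                "do not fit the shared alignment well"
            )
    runs = [
        group_specificity_ranks(msa, labels, ga, gb, pseudocount)
        for ga, gb in combinations(big, 2)
    ]
    return aggregate_sdp_scores(runs, big), runs
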