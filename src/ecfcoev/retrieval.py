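"""Curation of anti-sigma domain (ASDI) records from profile-HMM hit tables.

Turns hmmscan per-domain hits into a deduplicated set of ASDI domain records
paired with the cognate ECF sigma factor from the same genetic neighborhood.
Score thresholds are chosen on a receiver-operator-characteristic curve over
labeled training scores; the operating point maximizes Youden's J = TPR - FPR,
preferring the smallest (recall-favoring) threshold among ties.  Profile-HMM
construction and genome scanning are external; this module consumes their
tabular output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

Interval = tuple[int, int]


@dataclass(frozen=True)
class HmmHit:
    """One per-domain profile-HMM hit (1-based inclusive envelope)."""

    protein_id: str
    model_id: str
    bit_score: float
    evalue: float
    env_start: int
    env_end: int

    def __post_init__(self) -> None:
        if self.env_start < 1 or self.env_end < self.env_start:
            raise ValueError(
                f"invalid envelope [{self.env_start}, {self.env_end}] for {self.protein_id}"
            )
        if not np.isfinite(self.bit_score):
            raise ValueError(f"non-finite bit score for {self.protein_id}")


@dataclass(frozen=True)
class RetrievalConfig:
    """Score thresholds and curation filters.

    Defaults are the calibrated operating points for the three domain models
    (non-zinc-binding, zinc-binding, and the extended family model) together
    with the class-II exclusion length and the neighborhood radius used for
    cognate pairing.
    """

    bit_threshold_non_zn: float = 0.4
    bit_threshold_zn: float = 14.2
    bit_threshold_extended: float = 0.2
    min_domain_length: int = 50
    neighborhood_radius: int = 10

    def __post_init__(self) -> None:
        for t in (self.bit_threshold_non_zn, self.bit_threshold_zn, self.bit_threshold_extended):
            if not np.isfinite(t):
                raise ValueError("bit score thresholds must be finite")
        if self.min_domain_length <= 0:
            raise ValueError("min_domain_length must be positive")
        if self.neighborhood_radius < 0:
            raise ValueError("neighborhood_radius must be >= 0")


@dataclass
class AsdiRecord:
    """A curated anti-sigma domain paired with its cognate ECF."""

    protein_id: str
    organism: str
    full_sequence: str
    domain_interval: Interval
    cognate_ecf_id: str = ""
    cognate_ecf_group: str = ""
    taxon_phylum: str | None = None
    domain_sequence: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        start, end = self.domain_interval
        sliced = self.full_sequence[start - 1 : end]
        if not self.domain_sequence:
            self.domain_sequence = sliced
        elif self.domain_sequence != sliced:
            raise ValueError(
                f"{self.protein_id}: domain_sequence does not equal the "
                f"full-sequence slice at {self.domain_interval}"
            )


# ---------------------------------------------------------------------------
# ROC threshold optimization
# ---------------------------------------------------------------------------

def optimize_bit_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Pick the bit-score cutoff maximizing Youden's J on a labeled score set.

    The decision rule is "keep iff score >= t" with t restricted to observed
    scores; among J ties the smallest threshold (highest recall) wins.

    Parameters
    ----------
    scores : bit scores of known positives and negatives.
    labels : 1 for a true family member, 0 for a non-member.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1 or len(scores) == 0:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if len(np.unique(labels)) < 2:
        raise ValueError("degenerate labels: need at least one positive and one negative")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    j = tpr - fpr
    observed = np.isin(thresholds, scores)  # roc_curve prepends an unreachable sentinel
    j[~observed] = -np.inf
    best = j.max()
    # thresholds are sorted descending; the last index with max J is the smallest
    idx = np.flatnonzero(j == best)[-1]
    return float(thresholds[idx])


# ---------------------------------------------------------------------------
# Envelope extraction
# ---------------------------------------------------------------------------

def _subtract_intervals(interval: Interval, excluded: Iterable[Interval]) -> list[Interval]:
    pieces = [interval]
    for xs, xe in excluded:
        nxt: list[Interval] = []
        for s, e in pieces:
            if xe < s or xs > e:  # disjoint
                nxt.append((s, e))
                continue
            if xs > s:
                nxt.append((s, min(e, xs - 1)))
            if xe < e:
                nxt.append((max(s, xe + 1), e))
        pieces = nxt
    return pieces


def extract_domain_region(
    hits: Sequence[HmmHit], excluded_segments: Iterable[Interval] = ()
) -> Interval:
    """Domain interval = envelope of the best hit minus excluded segments.

    The highest-scoring hit is chosen (tie-break: smallest envelope start);
    transmembrane/extracellular segments are subtracted and the longest
    remaining contiguous stretch is returned.
    """
    if not hits:
        raise ValueError("no hits supplied")
    best = min(hits, key=lambda h: (-h.bit_score, h.env_start))
    pieces = _subtract_intervals((best.env_start, best.env_end), excluded_segments)
    if not pieces:
        raise ValueError(f"empty domain: envelope of {best.protein_id} fully excluded")
    return max(pieces, key=lambda p: (p[1] - p[0], -p[0]))


# ---------------------------------------------------------------------------
# Curation filters
# ---------------------------------------------------------------------------

def filter_min_length(
    records: Sequence[AsdiRecord], config: RetrievalConfig = RetrievalConfig()
) -> list[AsdiRecord]:
    """Drop records whose domain is shorter than the class-II exclusion length."""
    return [r for r in records if len(r.domain_sequence) >= config.min_domain_length]


def deduplicate_domains(records: Sequence[AsdiRecord]) -> list[AsdiRecord]:
    """Keep the first record per distinct domain sequence (exact string match)."""
    seen: set[str] = set()
    out: list[AsdiRecord] = []
    for r in records:
        if r.domain_sequence not in seen:
            seen.add(r.domain_sequence)
            out.append(r)
    return out


def pair_with_cognate_ecf(
    asdi_locus: int,
    ecf_loci: Sequence[tuple[str, int]],
    config: RetrievalConfig = RetrievalConfig(),
) -> str:
    """Pair an ASDI with the nearest ECF (by CDS ordinal) within the neighborhood.

    Coordinates are CDS ordinal indices on one replicon.  Ties resolve to the
    downstream (larger-coordinate) partner.
    """
    radius = config.neighborhood_radius
    in_range = [(eid, pos) for eid, pos in ecf_loci if abs(pos - asdi_locus) <= radius]
    if not in_range:
        raise ValueError(f"orphan ASDI: no ECF within +/-{radius} CDS of index {asdi_locus}")
    best = min(in_range, key=lambda ep: (abs(ep[1] - asdi_locus), -ep[1]))
    return best[0]


# ---------------------------------------------------------------------------
# Hit-table driver
# ---------------------------------------------------------------------------

def curate_asdi_records(
    hits: Sequence[HmmHit],
    sequences: dict[str, str],
    neighborhood: pd.DataFrame,
    config: RetrievalConfig = RetrievalConfig(),
    excluded_segments: dict[str, list[Interval]] | None = None,
) -> list[AsdiRecord]:
    """Full curation: threshold, extract, length-filter, deduplicate, pair.

    ``neighborhood`` carries the genomic context with columns
    protein_id, replicon, cds_index, is_ecf, ecf_group (and optionally
    organism, phylum).
    """
    required = {"protein_id", "replicon", "cds_index", "is_ecf", "ecf_group"}
    if not required <= set(neighborhood.columns):
        raise ValueError(f"neighborhood table lacks columns {sorted(required - set(neighborhood.columns))}")
    excluded_segments = excluded_segments or {}
    ctx = neighborhood.set_index("protein_id")
    by_protein: dict[str, list[HmmHit]] = {}
    for h in hits:
        if h.bit_score >= config.bit_threshold_extended:
            by_protein.setdefault(h.protein_id, []).append(h)

    records: list[AsdiRecord] = []
    for pid, phits in by_protein.items():
        if pid not in sequences or pid not in ctx.index:
            continue
        row = ctx.loc[pid]
        if bool(row["is_ecf"]):
            continue
        try:
            interval = extract_domain_region(phits, excluded_segments.get(pid, ()))
        except ValueError:
            continue
        replicon = ctx[ctx["replicon"] == row["replicon"]]
        ecf_loci = [
            (str(r.Index), int(r.cds_index))
            for r in replicon.itertuples()
            if bool(r.is_ecf)
        ]
        try:
            ecf_id = pair_with_cognate_ecf(int(row["cds_index"]), ecf_loci, config)
        except ValueError:
            continue
        ecf_group = str(ctx.loc[ecf_id, "ecf_group"])
        records.append(
            AsdiRecord(
                protein_id=pid,
                organism=str(row.get("organism", "")),
                full_sequence=sequences[pid],
                domain_interval=interval,
                cognate_ecf_id=ecf_id,
                cognate_ecf_group=ecf_group,
                taxon_phylum=str(row["phylum"]) if "phylum" in row else None,
            )
        )
    records.sort(key=lambda r: r.protein_id)
    records = filter_min_length(records, config)
    return deduplicate_domains(records)


def records_to_frame(records: Sequence[AsdiRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "organism": [r.organism for r in records],
            "domain_start": [r.domain_interval[0] for r in records],
            "domain_end": [r.domain_interval[1] for r in records],
            "domain_sequence": [r.domain_sequence for r in records],
            "cognate_ecf_id": [r.cognate_ecf_id for r in records],
            "cognate_ecf_group": [r.cognate_ecf_group for r in records],
            "phylum": [r.taxon_phylum for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Anti-sigma table summary (recomputable census of the curated family)
# ---------------------------------------------------------------------------

def anti_sigma_table_summary(df: pd.DataFrame) -> dict[str, float]:
    """Recompute the family census from the full anti-sigma list.

    Returns distinct subgroup/group counts, subgroup size median and standard
    deviation, the nonredundant-domain count, the count of groups with more
    than 100 proteins, and the zinc-motif fraction of the domain sequences.
    """
    from .classification import zinc_motif_scan

    grouped = df[df["as_subgroup"].notna() & (df["as_subgroup"] != "ungrouped")]
    sizes = grouped.groupby("as_subgroup").size()
    group_sizes = grouped.groupby("as_group").size()
    seqs = df["sequence"].astype(str)
    return {
        "n_records": int(len(df)),
        "n_nonredundant_domains": int(seqs.nunique()),
        "n_subgroups": int(sizes.shape[0]),
        "subgroup_size_median": float(sizes.median()) if len(sizes) else float("nan"),
        "subgroup_size_sd": float(sizes.std(ddof=1)) if len(sizes) > 1 else float("nan"),
        "n_groups": int(group_sizes.shape[0]),
        "n_groups_gt100": int((group_sizes > 100).sum()),
        "zinc_fraction": float(np.mean([zinc_motif_scan(s) for s in seqs])),
    }
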