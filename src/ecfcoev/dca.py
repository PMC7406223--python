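"""Gaussian direct coupling analysis of a concatenated paired alignment.

The alignment stacks, per organism, an ECF sigma-factor sequence and its
cognate anti-sigma domain (ASDI).  The model treats residue identities as a
multivariate Gaussian over one-hot-encoded columns: after similarity-based
sequence reweighting (threshold ``theta``) and pseudocount regularization
(weight ``alpha`` toward the uniform distribution), the coupling matrix is
the negated inverse of the q-1-state covariance matrix.  Pair scores are
Frobenius norms of the zero-sum-gauge couplings with the average product
correction (APC), and inter-protein pairs - one column on each side of the
concatenation boundary - are ranked as contact predictions in the coordinates
of a reference sequence pair (RpoE/RseA of E. coli on real data).

Steps, in the order they run:

1. ``sequence_weights``  - w_m = 1 / #{m' : hamming(m, m')/N < theta}
2. ``weighted_frequencies`` - pseudocounted one- and two-site frequencies
3. ``couplings``         - J = -C^{-1} over q-1 = 20 states (gap dropped)
4. ``frobenius_apc``     - F_ij and APC-corrected S_ij
5. ``extract_interprotein_contacts`` - ranked, reference-mapped predictions
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform

#: 20 amino acids; the gap (and any unknown character) is the 21st state
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_STATE = len(AMINO_ACIDS)  # dropped before inversion
N_STATES = len(AMINO_ACIDS) + 1  # q = 21

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class PairedFamilyAlignment:
    """Concatenated ECF+ASDI alignment with per-row organism linkage.

    ``n_ecf`` is the concatenation boundary B: columns 1..B belong to the ECF
    family, B+1..N to the ASDI family (1-based).  ``reference_row_id`` names
    the row whose residue numbering labels the predictions.
    """

    ids: list[str]
    rows: list[str]
    n_ecf: int
    reference_row_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows) or not self.rows:
            raise ValueError("ids and rows must be equal-length and nonempty")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError("alignment rows differ in length")
        n = widths.pop()
        if not (1 <= self.n_ecf < n):
            raise ValueError("concatenation boundary must leave >= 1 column per family")
        if self.reference_row_id is None:
            self.reference_row_id = self.ids[0]
        if self.reference_row_id not in self.ids:
            raise ValueError(f"reference row {self.reference_row_id!r} absent")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def encoded(self) -> np.ndarray:
        """Integer matrix (M, N): 0..19 amino acids, 20 gap/unknown."""
        return np.array(
            [[_AA_INDEX.get(c, GAP_STATE) for c in row.upper()] for row in self.rows],
            dtype=np.int8,
        )

    def reference_positions(self) -> list[tuple[int | None, int | None]]:
        """Per column: (ecf_residue, asdi_residue) in the reference pair's
        1-based ungapped numbering; both None on the off side, the mapped side
        None where the reference row is gapped."""
        ref = self.rows[self.ids.index(self.reference_row_id)].upper()
        out: list[tuple[int | None, int | None]] = []
        ecf_pos = asdi_pos = 0
        for col, c in enumerate(ref):
            is_res = c in _AA_INDEX
            if col < self.n_ecf:
                ecf_pos += is_res
                out.append((ecf_pos if is_res else None, None))
            else:
                asdi_pos += is_res
                out.append((None, asdi_pos if is_res else None))
        return out


@dataclass
class ContactPrediction:
    col_i: int  # 1-based alignment columns, col_i on the ECF side
    col_j: int
    score: float
    rank: int
    ecf_residue: int | None
    asdi_residue: int | None
    ecf_region: str | None = None
    asdi_region: str | None = None
    interprotein: bool = True

    @property
    def mapped(self) -> bool:
        return self.ecf_residue is not None and self.asdi_residue is not None


@dataclass
class DCAModel:
    theta: float
    alpha: float
    weights: np.ndarray
    meff: float
    fi: np.ndarray  # (N, 20)
    fij: np.ndarray  # (N, N, 20, 20)
    J: np.ndarray = field(repr=False)  # (N*20, N*20)
    F: np.ndarray = field(repr=False)  # (N, N)
    S: np.ndarray = field(repr=False)  # (N, N)


# ---------------------------------------------------------------------------
# 1. reweighting
# ---------------------------------------------------------------------------

def sequence_weights(X: np.ndarray, theta: float) -> tuple[np.ndarray, float]:
    """Down-weight redundant rows: w_m = 1 / (number of rows within normalized
    Hamming distance < theta of row m, itself included).  Meff = sum(w)."""
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie in (0, 1)")
    M = X.shape[0]
    if M == 1:
        return np.ones(1), 1.0
    dist = squareform(pdist(X, metric="hamming"))
    neighbors = (dist < theta).sum(axis=1)  # diagonal contributes the self-count
    w = 1.0 / neighbors
    return w, float(w.sum())


def auto_theta(X: np.ndarray) -> float:
    """Mean normalized Hamming distance across row pairs (an approximation of
    the auto-tuned reweighting threshold of the original Gaussian-DCA code)."""
    if X.shape[0] < 2:
        return 0.5
    return float(pdist(X, metric="hamming").mean())


# ---------------------------------------------------------------------------
# 2. frequencies
# ---------------------------------------------------------------------------

def weighted_frequencies(
    X: np.ndarray, weights: np.ndarray, alpha: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudocounted weighted frequencies over the 20 amino-acid states.

    f_i(a)    = (1-alpha) fhat_i(a)    + alpha/q
    f_ij(a,b) = (1-alpha) fhat_ij(a,b) + alpha/q^2   (i != j)

    with q = 21 (the gap state absorbs the remaining mass and is not stored);
    the i = j diagonal keeps joint-equals-marginal consistency,
    f_ii(a,b) = delta_ab f_i(a).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    M, N = X.shape
    meff = float(weights.sum())
    q = N_STATES
    # one-hot over the 20 residue states; gap rows are all-zero
    A = np.zeros((M, N * 20))
    rows = np.repeat(np.arange(M), N)
    cols = (np.arange(N) * 20)[None, :] + X.astype(np.intp)
    keep = (X != GAP_STATE).ravel()
    A[rows[keep], cols.ravel()[keep]] = 1.0

    fi_hat = (weights[:, None] * A).sum(axis=0).reshape(N, 20) / meff
    f2_hat = (A * weights[:, None]).T @ A / meff  # (N*20, N*20)

    fi = (1.0 - alpha) * fi_hat + alpha / q
    fij = (1.0 - alpha) * f2_hat.reshape(N, 20, N, 20).transpose(0, 2, 1, 3) + alpha / q**2
    for i in range(N):
        fij[i, i] = np.diag(fi[i])
    return fi, fij


# ---------------------------------------------------------------------------
# 3. couplings
# ---------------------------------------------------------------------------

def couplings(fi: np.ndarray, fij: np.ndarray) -> np.ndarray:
    """J = -C^{-1} with C_{(i,a),(j,b)} = f_ij(a,b) - f_i(a) f_j(b)."""
    N = fi.shape[0]
    C = fij.transpose(0, 2, 1, 3).reshape(N * 20, N * 20) - np.outer(
        fi.ravel(), fi.ravel()
    )
    try:
        J = -scipy.linalg.inv(C, check_finite=False)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance matrix is singular; raise the pseudocount alpha"
        ) from exc
    return J


# ---------------------------------------------------------------------------
# 4. scoring
# ---------------------------------------------------------------------------

def frobenius_apc(J: np.ndarray, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Frobenius norms of the zero-sum-gauge coupling blocks, then APC.

    S_ij = F_ij - mean_i(F) * mean_j(F) / mean(F), with all means taken over
    off-diagonal entries; the diagonal of F and S is zero.
    """
    F = np.zeros((N, N))
    blocks = J.reshape(N, 20, N, 20)
    for i in range(N):
        for j in range(i + 1, N):
            K = blocks[i, :, j, :]
            K = K - K.mean(axis=0, keepdims=True) - K.mean(axis=1, keepdims=True) + K.mean()
            F[i, j] = F[j, i] = np.sqrt((K**2).sum())
    row_mean = F.sum(axis=1) / (N - 1)
    overall = F.sum() / (N * (N - 1))
    S = F - np.outer(row_mean, row_mean) / overall
    np.fill_diagonal(S, 0.0)
    return F, S


# ---------------------------------------------------------------------------
# 5. contact extraction
# ---------------------------------------------------------------------------

def extract_interprotein_contacts(
    S: np.ndarray,
    msa: PairedFamilyAlignment,
    top_n: int | None = None,
    score_cutoff: float | None = None,
    regions: Mapping[tuple[str, int], str] | None = None,
) -> list[ContactPrediction]:
    """Ranked inter-protein predictions in reference coordinates.

    Pairs with one column on each side of the boundary are sorted by score
    (descending; ties by ascending column pair), truncated by ``top_n`` and/or
    ``score_cutoff``, and mapped to the reference pair's residue numbering.
    Columns gapped in the reference are reported unmapped (``mapped`` False)
    and are skipped by structure validation.
    """
    B, N = msa.n_ecf, msa.n_columns
    if S.shape != (N, N):
        raise ValueError("score matrix does not match the alignment width")
    pairs = [(i, j) for i in range(B) for j in range(B, N)]
    pairs.sort(key=lambda ij: (-S[ij], ij))
    if score_cutoff is not None:
        pairs = [ij for ij in pairs if S[ij] >= score_cutoff]
    if top_n is not None:
        pairs = pairs[:top_n]
    refpos = msa.reference_positions()
    out: list[ContactPrediction] = []
    for rank, (i, j) in enumerate(pairs, start=1):
        ecf_res = refpos[i][0]
        asdi_res = refpos[j][1]
        out.append(
            ContactPrediction(
                col_i=i + 1,
                col_j=j + 1,
                score=float(S[i, j]),
                rank=rank,
                ecf_residue=ecf_res,
                asdi_residue=asdi_res,
                ecf_region=regions.get(("ecf", ecf_res)) if regions and ecf_res else None,
                asdi_region=regions.get(("asdi", asdi_res)) if regions and asdi_res else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def fit_dca(
    msa: PairedFamilyAlignment,
    theta: float | str = 0.46,
    alpha: float = 0.8,
    max_gap_fraction: float | None = None,
) -> DCAModel:
    """Run the full Gaussian-DCA pipeline on a paired alignment.

    ``theta="auto"`` sets the reweighting threshold to the mean normalized
    Hamming distance.  ``max_gap_fraction`` optionally masks gap-heavy columns
    from scoring (their S entries are set to -inf so they never rank).
    """
    X = msa.encoded()
    th = auto_theta(X) if theta == "auto" else float(theta)
    w, meff = sequence_weights(X, th)
    fi, fij = weighted_frequencies(X, w, alpha)
    J = couplings(fi, fij)
    F, S = frobenius_apc(J, msa.n_columns)
    if max_gap_fraction is not None:
        gappy = (X == GAP_STATE).mean(axis=0) > max_gap_fraction
        S = S.copy()
        S[gappy, :] = -np.inf
        S[:, gappy] = -np.inf
    return DCAModel(theta=th, alpha=alpha, weights=w, meff=meff, fi=fi, fij=fij, J=J, F=F, S=S)
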