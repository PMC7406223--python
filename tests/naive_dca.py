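"""Straight-line Gaussian-DCA reimplementation used as an independent oracle.

Deliberately naive: explicit loops, generic matrix inversion, no vectorized
shortcuts, no shared code with the package implementation.  Suitable only for
tiny alignments (M <= 10, N <= 6).
"""

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
Q = 21  # 20 residues + gap


def naive_score_matrix(rows: list[str], theta: float, alpha: float) -> np.ndarray:
    M = len(rows)
    N = len(rows[0])

    def state(c):
        return AA.index(c) if c in AA else 20

    X = [[state(c) for c in r] for r in rows]

    # reweighting
    w = []
    for m in range(M):
        cnt = 0
        for mm in range(M):
            ham = sum(1 for i in range(N) if X[m][i] != X[mm][i]) / N
            if ham < theta:
                cnt += 1
        w.append(1.0 / cnt)
    meff = sum(w)

    # single-site frequencies over the 20 residue states
    fi = np.zeros((N, 20))
    for i in range(N):
        for a in range(20):
            hat = sum(w[m] for m in range(M) if X[m][i] == a) / meff
            fi[i, a] = (1 - alpha) * hat + alpha / Q

    # pair frequencies
    fij = np.zeros((N, N, 20, 20))
    for i in range(N):
        for j in range(N):
            for a in range(20):
                for b in range(20):
                    if i == j:
                        fij[i, j, a, b] = fi[i, a] if a == b else 0.0
                    else:
                        hat = (
                            sum(
                                w[m]
                                for m in range(M)
                                if X[m][i] == a and X[m][j] == b
                            )
                            / meff
                        )
                        fij[i, j, a, b] = (1 - alpha) * hat + alpha / Q**2

    # covariance and couplings
    C = np.zeros((N * 20, N * 20))
    for i in range(N):
        for a in range(20):
            for j in range(N):
                for b in range(20):
                    C[i * 20 + a, j * 20 + b] = fij[i, j, a, b] - fi[i, a] * fi[j, b]
    J = -np.linalg.inv(C)

    # zero-sum gauge, Frobenius norm, APC
    F = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            K = np.array(
                [[J[i * 20 + a, j * 20 + b] for b in range(20)] for a in range(20)]
            )
            K = K - K.mean(axis=0, keepdims=True) - K.mean(axis=1, keepdims=True) + K.mean()
            F[i, j] = np.sqrt((K * K).sum())
    S = np.zeros((N, N))
    Fmean = F.sum() / (N * (N - 1))
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            mi = sum(F[i, k] for k in range(N) if k != i) / (N - 1)
            mj = sum(F[k, j] for k in range(N) if k != j) / (N - 1)
            S[i, j] = F[i, j] - mi * mj / Fmean
    return S
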