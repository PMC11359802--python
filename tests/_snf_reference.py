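"""Independent, loop-based reference implementation of the SNF equations.

Written deliberately without numpy linear algebra (explicit Python loops
for every matrix product and normalisation) so it shares no code path with
the package implementation it cross-checks.
"""

from __future__ import annotations


def ref_normalize(W):
    """Off-diag w_ij / (2 Σ_{j≠i} w_ij); diagonal 1/2; uniform fallback."""
    m = len(W)
    P = [[0.0] * m for _ in range(m)]
    for i in range(m):
        s = sum(W[i][j] for j in range(m) if j != i)
        for j in range(m):
            if i == j:
                P[i][j] = 0.5
            elif s == 0:
                P[i][j] = 0.5 / (m - 1)
            else:
                P[i][j] = W[i][j] / (2.0 * s)
    return P


def ref_kernel(W, K):
    """Top-K off-diagonal entries per row (ties to smallest index), row-renormalised."""
    m = len(W)
    S = [[0.0] * m for _ in range(m)]
    for i in range(m):
        candidates = sorted(
            (j for j in range(m) if j != i), key=lambda j: (-W[i][j], j)
        )
        keep = candidates[:K]
        total = sum(W[i][j] for j in keep)
        for j in keep:
            S[i][j] = (W[i][j] / total) if total > 0 else 1.0 / K
    return S


def _matmul(A, B):
    m = len(A)
    return [
        [sum(A[i][l] * B[l][j] for l in range(m)) for j in range(m)] for i in range(m)
    ]


def _transpose(A):
    m = len(A)
    return [[A[j][i] for j in range(m)] for i in range(m)]


def _symmetrize(A):
    m = len(A)
    return [[(A[i][j] + A[j][i]) / 2.0 for j in range(m)] for i in range(m)]


def ref_snf(views, K, t):
    """Full SNF fusion of a list of square similarity matrices (lists of lists)."""
    n = len(views)
    m = len(views[0])
    P = [_symmetrize(ref_normalize(W)) for W in views]
    S = [ref_kernel(Pv, K) for Pv in P]
    for _ in range(t):
        new = []
        for v in range(n):
            avg = [
                [
                    sum(P[w][i][j] for w in range(n) if w != v) / (n - 1)
                    for j in range(m)
                ]
                for i in range(m)
            ]
            new.append(_matmul(_matmul(S[v], avg), _transpose(S[v])))
        P = [_symmetrize(ref_normalize(Nv)) for Nv in new]
    W = [[sum(P[v][i][j] for v in range(n)) / n for j in range(m)] for i in range(m)]
    W = ref_normalize(W)
    return [
        [
            (W[i][j] + W[j][i]) / 2.0 + (0.5 if i == j else 0.0)
            for j in range(m)
        ]
        for i in range(m)
    ]
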