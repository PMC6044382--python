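"""Independent brute-force oracles used to cross-check the implementation.

Each function here recomputes a quantity by the most direct means available
(exhaustive enumeration, pairwise counting, dense eigendecomposition) and is
deliberately kept independent of the package's own code paths.
"""

import numpy as np


def ks_enrichment_bruteforce(positions, n):
    """Exhaustive max over all j of the two KS deviations."""
    v = sorted(positions)
    t = len(v)
    a = max(j / t - v[j - 1] / n for j in range(1, t + 1))
    b = max(v[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a >= b else -b


def rank_bruteforce(z, expr=None):
    """Stable selection of the best remaining gene, one rank at a time."""
    n = len(z)
    expr = [0.0] * n if expr is None else list(expr)
    remaining = list(range(n))
    ranks = [0] * n
    for r in range(1, n + 1):
        best = remaining[0]
        for i in remaining[1:]:
            if (z[i], expr[i], -i) > (z[best], expr[best], -best):
                best = i
        ranks[best] = r
        remaining.remove(best)
    return ranks


def c_index_pairwise(scores, labels):
    """O(n^2) concordant-pair count with ties at 0.5, floored at 0.5."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return max(total / (len(pos) * len(neg)), 0.5)


def youden_bruteforce(scores, labels):
    """Enumerate every observed score as a candidate cutoff; largest wins ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    best_cut, best_j = None, -np.inf
    for cut in sorted(set(scores)):
        sens = sum(s >= cut for s in pos) / len(pos)
        spec = sum(s < cut for s in neg) / len(neg)
        j = sens + spec - 1.0
        if j >= best_j - 1e-15:
            if j > best_j:
                best_j = j
            best_cut = cut
    return best_cut, best_j


def hits_eigen_oracle(w):
    """Principal eigenvectors of W W^T and W^T W, max-normalised, nonnegative."""

    def principal(m):
        _, vecs = np.linalg.eigh(m)
        v = np.abs(vecs[:, -1])
        return v / v.max() if v.max() > 0 else v

    return principal(w @ w.T), principal(w.T @ w)
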