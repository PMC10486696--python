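"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or dense
linear algebra, staying independent of the implementation path it
checks.
"""

from itertools import combinations

import numpy as np


def lmoments_exhaustive(x):
    """Sample L-moments by enumerating every size-n subset.

    lambda_n is the average over all n-subsets of the signed
    combination of the subset's order statistics:
    lambda_1 = mean, lambda_2 = E[(max - min)] / 2 over pairs,
    lambda_3 = E[x(3) - 2 x(2) + x(1)] / 3 over triples,
    lambda_4 = E[x(4) - 3 x(3) + 3 x(2) - x(1)] / 4 over quadruples.
    """
    x = np.asarray(x, dtype=float)
    out = [float(np.mean(x))]
    weights = {2: [-1, 1], 3: [1, -2, 1], 4: [-1, 3, -3, 1]}
    for r in (2, 3, 4):
        if len(x) < r:
            out.append(float("nan"))
            continue
        w = weights[r]
        acc = 0.0
        cnt = 0
        for sub in combinations(x, r):
            s = sorted(sub)
            acc += sum(wj * sj for wj, sj in zip(w, s)) / r
            cnt += 1
        out.append(acc / cnt)
    return out


def diagonal_average_bruteforce(tensor, window):
    """Mean over the pre-image of every sample index, by explicit loop."""
    K, w, i = tensor.shape
    L = K + w - 1
    sums = np.zeros(L * i)
    counts = np.zeros(L * i)
    for k in range(K):
        for a in range(w):
            for b in range(i):
                t = (k + a) * i + b
                sums[t] += tensor[k, a, b]
                counts[t] += 1
    return sums / counts


def sherman_morrison_mixing_update(S, y, f_y, lr):
    """Propagate the mixing estimate S through one demixing step.

    The demixing update is S_inv <- G S_inv with
    G = (1 + lr) I - lr f(y) y^T, hence S <- S G^{-1}; G^{-1} comes
    from the Sherman-Morrison identity for a rank-1 perturbation of a
    scaled identity.
    """
    r = len(y)
    c = lr / (1.0 + lr)
    denom = 1.0 - c * float(y @ f_y)
    G_inv = (np.eye(r) + np.outer(f_y, y) * (c / denom)) / (1.0 + lr)
    return S @ G_inv


def amari_index(P):
    """Permutation-invariant distance of P from a scaled permutation."""
    P = np.abs(np.asarray(P, dtype=float))
    n = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum() - n
    cols = (P / P.max(axis=0, keepdims=True)).sum() - n
    return float(rows + cols) / (2 * n * (n - 1))


def match_sources(estimated, truth):
    """Greedy absolute-correlation matching; one estimate per source."""
    r = truth.shape[0]
    C = np.abs(np.corrcoef(np.vstack([estimated, truth]))[: estimated.shape[0], estimated.shape[0]:])
    out = []
    used = set()
    for j in range(r):
        i = max(
            (i for i in range(estimated.shape[0]) if i not in used),
            key=lambda i: C[i, j],
        )
        used.add(i)
        out.append(C[i, j])
    return out


def band_power_fraction(x, fs, lo, hi):
    """Fraction of total spectral power inside [lo, hi], via periodogram."""
    x = np.asarray(x, dtype=float)
    spec = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(len(x), 1 / fs)
    total = spec.sum()
    if total == 0:
        return 0.0
    return float(spec[(f >= lo) & (f <= hi)].sum() / total)
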