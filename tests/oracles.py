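"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where feasible, the library
calls) of the implementation under test: plain-Python loops, log-gamma
arithmetic and exact combinatorics.
"""
import math
from typing import Dict, List, Sequence, Set


def nb_pmf(k: int, mean: float, size_r: float) -> float:
    """NB pmf via log-gamma; `size_r` is the size (r) parameter."""
    if mean <= 0:
        return 1.0 if k == 0 else 0.0
    log_p = (math.lgamma(k + size_r) - math.lgamma(size_r) - math.lgamma(k + 1)
             + size_r * math.log(size_r / (size_r + mean))
             + k * math.log(mean / (size_r + mean)))
    return math.exp(log_p)


def poisson_pmf(k: int, lam: float) -> float:
    return math.exp(-lam + k * math.log(lam) - math.lgamma(k + 1)) if lam > 0 else (k == 0)


def nb_exact_test_oracle(counts_a: Sequence[int], counts_b: Sequence[int],
                         sf_a: Sequence[float], sf_b: Sequence[float],
                         alpha: float) -> float:
    """Enumerate every allocation of the pooled total between the groups."""
    ya, yb = sum(counts_a), sum(counts_b)
    ma, mb = sum(sf_a), sum(sf_b)
    total = int(round(ya + yb))
    if total == 0:
        return 1.0
    mu = total / (ma + mb)

    def pmf(k, m):
        if alpha < 1e-10:
            return poisson_pmf(k, mu * m)
        return nb_pmf(k, mu * m, m / alpha)

    joint = [pmf(a, ma) * pmf(total - a, mb) for a in range(total + 1)]
    denom = sum(joint)
    observed = joint[int(round(ya))]
    p = sum(w for w in joint if w <= observed * (1 + 1e-12)) / denom
    return min(1.0, p)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by exact combinatorics."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        if n - j <= N - K:
            total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def hypergeom_lower_tail(k: int, N: int, K: int, n: int) -> float:
    denom = math.comb(N, n)
    total = 0
    for j in range(0, min(k, K, n) + 1):
        if n - j <= N - K:
            total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def poisson_upper_tail_oracle(k: int, lam: float, extra: int = 2000) -> float:
    """P(Poisson(lam) >= k) by direct pmf summation to negligible mass."""
    return sum(poisson_pmf(j, lam) for j in range(k, k + extra))


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def score_window(window: str, probs, background) -> float:
    s = 0.0
    for j, b in enumerate(window):
        i = "ACGT".index(b)
        s += math.log2(probs[i][j] / background[i])
    return s


def scan_oracle(sequence: str, probs, background, threshold: float) -> List[tuple]:
    """Per-position brute-force both-strand scan; reverse strand scored by
    reverse-complementing the window (not the matrix)."""
    L = len(probs[0])
    hits = []
    for j in range(len(sequence) - L + 1):
        window = sequence[j : j + L]
        if any(b not in "ACGT" for b in window):
            continue
        fwd = score_window(window, probs, background)
        if fwd >= threshold:
            hits.append((j, "+", fwd))
        rc = "".join(_COMP[b] for b in reversed(window))
        rev = score_window(rc, probs, background)
        if rev >= threshold:
            hits.append((j, "-", rev))
    return sorted(hits, key=lambda h: (h[0], h[1]))


def naive_direct_target_join(chip_targets: Set[str],
                             de_sets_by_age: Dict[str, Dict[str, Set[str]]],
                             base_tier: str = "2") -> Set[str]:
    """Direct targets = ChIP targets intersected with any-age, any-direction
    DE genes at the base fold tier."""
    de_any: Set[str] = set()
    for age, sets in de_sets_by_age.items():
        de_any |= set(sets.get(f"down_{base_tier}", set()))
        de_any |= set(sets.get(f"up_{base_tier}", set()))
    return set(chip_targets) & de_any
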