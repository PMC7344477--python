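"""Independent brute-force oracles used only by the test suite.

Everything here is written in deliberately naive pure Python (explicit
loops, ``statistics.stdev``, ``itertools.combinations``) and is kept
separate from the package's vectorized implementations so the two routes
stay independent.
"""
from __future__ import annotations

import itertools
import math
import statistics


def brute_pairwise_v(cq_rows: dict[str, list[float]], j: str, k: str) -> float:
    """s.d. of the per-sample log2 expression ratio between genes j and k,
    computed from first principles: a = 2^-Cq, A = log2(a_j / a_k)."""
    a = []
    for cj, ck in zip(cq_rows[j], cq_rows[k]):
        if cj is None or ck is None or math.isnan(cj) or math.isnan(ck):
            continue
        a.append(math.log2((2.0 ** -cj) / (2.0 ** -ck)))
    return statistics.stdev(a)


def brute_m(cq_rows: dict[str, list[float]], j: str,
            candidates: list[str]) -> float:
    vs = [brute_pairwise_v(cq_rows, j, k) for k in candidates if k != j]
    return sum(vs) / len(vs)


def brute_iterative_ranking(cq_rows: dict[str, list[float]],
                            candidates: list[str]
                            ) -> tuple[list[str], dict[str, float]]:
    """Stepwise exclusion of the highest-M gene (ties: drop the
    lexicographically last name) until two genes remain."""
    current = list(candidates)
    dropped: list[str] = []
    m_at_exclusion: dict[str, float] = {}
    while len(current) > 2:
        ms = {g: brute_m(cq_rows, g, current) for g in current}
        worst_val = max(ms.values())
        worst = max(g for g in current if ms[g] == worst_val)
        m_at_exclusion[worst] = ms[worst]
        dropped.append(worst)
        current.remove(worst)
    final_m = brute_pairwise_v(cq_rows, current[0], current[1])
    for g in current:
        m_at_exclusion[g] = final_m
    return sorted(current) + dropped[::-1], m_at_exclusion


def brute_nf(cq_rows: dict[str, list[float]], genes: list[str],
             sample_idx: int) -> float:
    """Geometric mean of the listed genes' cycles in one sample."""
    prod = 1.0
    for g in genes:
        prod *= cq_rows[g][sample_idx]
    return prod ** (1.0 / len(genes))


def brute_nf_variation(cq_rows: dict[str, list[float]], ranking: list[str],
                       n: int, n_samples: int) -> float:
    ratios = []
    for s in range(n_samples):
        nf_n = brute_nf(cq_rows, ranking[:n], s)
        nf_n1 = brute_nf(cq_rows, ranking[:n + 1], s)
        ratios.append(math.log2(nf_n / nf_n1))
    return statistics.stdev(ratios)


def brute_nf_stability(cq_rows: dict[str, list[float]], ranking: list[str],
                       n: int, candidates: list[str],
                       n_samples: int) -> float:
    rest = [g for g in candidates if g not in ranking[:n]]
    if not rest:
        return float("nan")
    vs = []
    for g in rest:
        a = []
        for s in range(n_samples):
            log_nf = math.log2(brute_nf(cq_rows, ranking[:n], s))
            log_expr = math.log2(2.0 ** -cq_rows[g][s])
            a.append(log_nf - log_expr)
        vs.append(statistics.stdev(a))
    return sum(vs) / len(vs)


def mw_u_brute(x: list[float], y: list[float]) -> float:
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mw_exact_p_enumeration(x: list[float], y: list[float]) -> float:
    """Two-sided exact p by enumerating every assignment of the pooled
    (tie-free) values to the two groups."""
    pooled = list(x) + list(y)
    n = len(x)
    nm = len(x) * len(y)
    u_obs = mw_u_brute(x, y)
    u_low = min(u_obs, nm - u_obs)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = mw_u_brute(xs, ys)
        if u <= u_low or u >= nm - u_low:
            hits += 1
        total += 1
    return min(1.0, hits / total)
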