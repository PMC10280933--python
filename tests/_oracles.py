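"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — enumeration, repeated deletion,
explicit running sums — and shares no code with the implementation paths it
checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def kcore_bruteforce(edges: list[tuple], nodes: list) -> dict:
    """Core number per node by repeated deletion, for every k from 0 up."""
    core = {n: 0 for n in nodes}
    k = 1
    while True:
        alive = set(nodes)
        current = [e for e in edges if e[0] in alive and e[1] in alive]
        changed = True
        while changed:
            deg = {n: 0 for n in alive}
            for a, b in current:
                deg[a] += 1
                deg[b] += 1
            drop = {n for n in alive if deg[n] < k}
            changed = bool(drop)
            alive -= drop
            current = [e for e in current if e[0] in alive and e[1] in alive]
        if not alive:
            return core
        for n in alive:
            core[n] = k
        k += 1


def hypergeom_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """P(overlap >= k) as an exact rational, by direct summation."""
    total = math.comb(N, n)
    hits = sum(math.comb(K, i) * math.comb(N - K, n - i)
               for i in range(k, min(K, n) + 1))
    return Fraction(hits, total)


def hypergeom_tail_enumeration(N: int, K: int, n: int, k: int) -> Fraction:
    """Same tail probability by enumerating every n-subset of the universe."""
    marked = set(range(K))
    hits = sum(1 for draw in itertools.combinations(range(N), n)
               if len(marked.intersection(draw)) >= k)
    return Fraction(hits, math.comb(N, n))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x: number of (xi, yj) pairs with xi > yj (+0.5 per tie)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mannwhitney_exact_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all labelings.

    Two-sidedness counts labelings at least as extreme in either direction:
    U' <= t or U' >= n1*n2 - t with t = min(u, n1*n2 - u).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = _u_statistic(x, y)
    t = min(u_obs, len(x) * len(y) - u_obs)
    hi = len(x) * len(y) - t
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xi = pooled[list(idx)]
        yi = np.delete(pooled, list(idx))
        u = _u_statistic(xi, yi)
        count += (u <= t + 1e-9) or (u >= hi - 1e-9)
        total += 1
    return u_obs, count / total


def welch_t_stat(x: np.ndarray, y: np.ndarray) -> float:
    vx = x.var(ddof=1) / len(x)
    vy = y.var(ddof=1) / len(y)
    return (x.mean() - y.mean()) / math.sqrt(vx + vy)


def welch_permutation_p_exhaustive(x, y) -> float:
    """Two-sided p by enumerating every relabeling of the pooled values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    t_obs = abs(welch_t_stat(x, y))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), len(x)):
        xi = pooled[list(idx)]
        yi = np.delete(pooled, list(idx))
        count += abs(welch_t_stat(xi, yi)) >= t_obs - 1e-12
        total += 1
    return count / total


def welch_permutation_p_mc(x, y, n_perm: int, seed: int) -> float:
    """Monte-Carlo label-permutation estimate of the two-sided Welch p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    t_obs = abs(welch_t_stat(x, y))
    rng = np.random.default_rng(seed)
    count = 0
    block = 2000
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        order = np.argsort(rng.random((b, n)), axis=1)
        perm = pooled[order]
        xs, ys = perm[:, :n1], perm[:, n1:]
        vx = xs.var(axis=1, ddof=1) / n1
        vy = ys.var(axis=1, ddof=1) / (n - n1)
        t = np.abs(xs.mean(axis=1) - ys.mean(axis=1)) / np.sqrt(vx + vy)
        count += int((t >= t_obs - 1e-12).sum())
        done += b
    return count / n_perm


def pearson_permutation_p_mc(x, y, n_perm: int, seed: int) -> float:
    """Monte-Carlo permutation estimate of the two-sided Pearson p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    n = len(x)
    r_obs = abs(float(xz @ yz) / n)
    rng = np.random.default_rng(seed)
    count = 0
    block = 2000
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        order = np.argsort(rng.random((b, n)), axis=1)
        r = np.abs(yz[order] @ xz) / n
        count += int((r >= r_obs - 1e-12).sum())
        done += b
    return count / n_perm


def pearson_bruteforce(x, y) -> float:
    """Pearson r from the raw covariance formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sxy = sum((a - x.mean()) * (b - y.mean()) for a, b in zip(x, y))
    sxx = sum((a - x.mean()) ** 2 for a in x)
    syy = sum((b - y.mean()) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def gsea_running_sum_trace(ranked, metric, members, exponent) -> list[float]:
    """Explicit step-by-step weighted-KS running sum."""
    members = set(members)
    n = len(ranked)
    n_hit = sum(1 for g in ranked if g in members)
    denom = sum(abs(m) ** exponent for g, m in zip(ranked, metric) if g in members)
    total = 0.0
    trace = []
    for g, m in zip(ranked, metric):
        if g in members:
            total += (abs(m) ** exponent) / denom if denom else 1.0 / n_hit
        else:
            total -= 1.0 / (n - n_hit)
        trace.append(total)
    return trace


def bh_stepup(pvalues) -> list[float]:
    """Hand-stepped Benjamini-Hochberg with monotonicity enforcement."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(prev, p[i] * m / rank_from_top)
        adj[i] = value
        prev = value
    return adj
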