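"""Independent brute-force oracles used only by the tests.

These deliberately avoid the implementation code paths they check:
direct neighbour enumeration for DBSCAN, exhaustive set-partition
search for the CPM optimum, and per-injection mass-action root finding
for the ITC isotherm.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


def brute_dbscan(dist: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Textbook DBSCAN by direct neighbour enumeration.

    Same semantics as the implementation contract: core = >= min_samples
    neighbours within eps including self; clusters = connected core
    points; border points attach to the lowest-indexed core neighbour.
    """
    n = dist.shape[0]
    neighbors = [set(np.flatnonzero(dist[i] <= eps)) for i in range(n)]
    core = [len(nb) >= min_samples for nb in neighbors]
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        frontier = {i}
        labels[i] = cluster
        while frontier:
            p = frontier.pop()
            for q in neighbors[p]:
                if core[q] and labels[q] == -1:
                    labels[q] = cluster
                    frontier.add(q)
        cluster += 1
    for i in range(n):
        if labels[i] == -1 and not core[i]:
            core_nbrs = sorted(q for q in neighbors[i] if core[q])
            if core_nbrs:
                labels[i] = labels[core_nbrs[0]]
    return labels


def set_partitions(items: list):
    """All set partitions of a list (Bell-number many)."""
    if len(items) == 1:
        yield [items]
        return
    first = items[0]
    for smaller in set_partitions(items[1:]):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
        yield [[first]] + smaller


def brute_cpm_optimum(s: np.ndarray, gamma: float) -> tuple[float, np.ndarray]:
    """Exhaustive CPM optimum over all partitions of <= ~10 nodes."""
    n = s.shape[0]
    best_q = -np.inf
    best_labels = None
    for part in set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, group in enumerate(part):
            labels[list(group)] = c
        q = 0.0
        for c in range(len(part)):
            members = np.flatnonzero(labels == c)
            sub = s[np.ix_(members, members)]
            e_c = (sub.sum() - np.trace(sub)) / 2.0
            q += e_c - gamma * len(members) * (len(members) - 1) / 2.0
        if q > best_q:
            best_q = q
            best_labels = labels
    return best_q, best_labels


def itc_heats_by_root_finding(
    n: float, kd: float, dh: float, titr
) -> np.ndarray:
    """Per-injection heats from mass-action equilibrium root finding.

    Solves [free ligand] numerically per injection instead of using the
    closed-form quadratic, with the same displacement-dilution scheme.
    """
    v0 = titr.cell_volume
    f = 1.0 - titr.injection_volumes / v0
    m_cur = titr.cell_conc
    x_cur = 0.0
    b_prev = 0.0
    heats = []
    for i in range(titr.n_injections):
        m_cur = m_cur * f[i]
        x_cur = x_cur * f[i] + titr.syringe_conc * titr.injection_volumes[i] / v0
        sites = n * m_cur

        def balance(free):
            # free-ligand mass balance: X_t = free + sites*free/(Kd+free)
            return free + sites * free / (kd + free) - x_cur

        free = brentq(balance, 0.0, x_cur, xtol=1e-18, rtol=1e-14)
        bound = sites * free / (kd + free)
        heats.append(dh * v0 * (bound - b_prev * f[i]) * 1.0e9)
        b_prev = bound
    return np.asarray(heats)


def rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Plain Rand index between two labelings (pairwise agreement)."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, k=1)
    return float(np.mean(same_a[iu] == same_b[iu]))
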