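"""Independent brute-force oracles used across the test suite.

These deliberately avoid the implementation's algorithms: clustering and
merging are checked with graph connectivity, interval statistics with
per-base enumeration, and distance estimation with grid-search maximum
likelihood.
"""

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def linkage_components(items, joined):
    """Partition ``items`` into transitively joined groups.

    ``joined(a, b)`` decides pairwise linkage; components come from graph
    connectivity (scipy csgraph), not from any sorted sweep.
    """
    n = len(items)
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if joined(items[i], items[j]):
                rows.append(i)
                cols.append(j)
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    groups = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        groups[lab].append(items[i])
    return groups


def _component_groups(adjacency):
    n_comp, labels = connected_components(csr_matrix(adjacency), directed=False)
    return n_comp, labels


def brute_cluster_tags(positions, counts, max_gap):
    """Single-linkage tag clusters via pairwise graph connectivity."""
    pos = np.asarray(positions)
    cnt = np.asarray(counts)
    adj = np.abs(pos[:, None] - pos[None, :]) <= max_gap
    n_comp, labels = _component_groups(adj)
    out = []
    for k in range(n_comp):
        m = labels == k
        out.append((int(pos[m].min()), int(pos[m].max()) + 1, int(cnt[m].sum())))
    return sorted(out)


def brute_merge_spans(spans, merge_dist):
    """Transitive merge of (start, end, n) spans by edge-to-edge gap."""
    starts = np.array([s for s, _, _ in spans])
    ends = np.array([e for _, e, _ in spans])
    ns = np.array([n for _, _, n in spans])
    gaps = np.maximum(starts[:, None], starts[None, :]) - np.minimum(
        ends[:, None], ends[None, :]
    )
    n_comp, labels = _component_groups(gaps <= merge_dist)
    out = []
    for k in range(n_comp):
        m = labels == k
        out.append((int(starts[m].min()), int(ends[m].max()), int(ns[m].sum())))
    return sorted(out)


def brute_overlap(a, b):
    """Per-base interval overlap (set intersection)."""
    if a.chrom != b.chrom:
        return 0
    return len(set(range(a.start, a.end)) & set(range(b.start, b.end)))


def brute_distance(a, b):
    """Edge-to-edge gap by enumeration: bases strictly between the intervals."""
    if brute_overlap(a, b) > 0:
        return 0
    closest = min(
        abs(x - y) for x in (a.start, a.end - 1) for y in (b.start, b.end - 1)
    )
    return closest - 1


def brute_covered_fraction(intervals, tes):
    """Per-base TE coverage fraction."""
    covered = 0
    total = 0
    for iv in intervals:
        for base in range(iv.start, iv.end):
            total += 1
            if any(t.chrom == iv.chrom and t.start <= base < t.end for t in tes):
                covered += 1
    return covered / total if total else 0.0


def brute_territory_owner(base, genes):
    """Index of the gene whose body is nearest to ``base`` (leftmost on tie)."""
    dists = []
    for i, (s, e) in enumerate(genes):
        d = 0 if s <= base < e else min(abs(base - s), abs(base - (e - 1)))
        dists.append((d, s, i))
    return min(dists)[2]


def brute_mannwhitney_p(a, b):
    """Exact two-sided rank-permutation p for tiny samples."""
    from itertools import combinations

    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(idx_a):
        xs = [pooled[i] for i in idx_a]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx_a]
        u = sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)
        return u

    observed = u_stat(tuple(range(n_a)))
    n_b = len(b)
    mu = n_a * n_b / 2.0
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_stat(idx) - mu) >= abs(observed - mu) - 1e-12:
            count += 1
    return count / total


def ml_grid_distance(counts, Q, pi, d_grid):
    """Grid-search ML branch length for a known rate matrix ``Q``.

    Likelihood: product over site patterns of pi_i * P(d)_ij with
    P(d) = expm(Q d) via eigendecomposition.
    """
    w, v = np.linalg.eig(Q)
    vinv = np.linalg.inv(v)
    best_d, best_ll = None, -np.inf
    for d in d_grid:
        P = (v * np.exp(w * d)) @ vinv
        P = np.clip(P.real, 1e-300, None)
        ll = float(np.sum(counts * np.log(pi[:, None] * P)))
        if ll > best_ll:
            best_d, best_ll = float(d), ll
    return best_d


def random_gtr(rng, min_pi=0.15):
    """Random reversible rate matrix (exchangeabilities x frequencies),
    normalized to one expected substitution per unit branch length."""
    pi = rng.dirichlet(np.full(4, 10.0))
    pi = np.clip(pi, min_pi, None)
    pi /= pi.sum()
    s = rng.uniform(0.5, 2.0, size=(4, 4))
    s = (s + s.T) / 2
    Q = s * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.sum(pi * np.diag(Q))
    return Q / rate, pi
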