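"""Independent brute-force oracles used by the test suite only.

Deliberately naive (loops, enumeration, closed forms) and independent of the
package's implementations, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import itertools

import numpy as np

# ---------------------------------------------------------------------------
# change factor / percent of mix: plain-python arithmetic
# ---------------------------------------------------------------------------


def brute_change_factors(inoc_rows, nodule_rows, pseudocount):
    """Per-experiment correction factors, ratios, truncated V and percents.

    ``inoc_rows``/``nodule_rows``: list (per experiment) of lists of counts.
    Returns dict with ratios, v, per-experiment percents, mean percents.
    """
    k = len(inoc_rows)
    S = len(inoc_rows[0])
    ratios, vs, percents = [], [], []
    for e in range(k):
        n_inoc = sum(inoc_rows[e]) + S * pseudocount
        p = [(c + pseudocount) / n_inoc for c in inoc_rows[e]]
        n_nod = sum(nodule_rows[e])
        q = [c / n_nod for c in nodule_rows[e]]
        r = []
        for s in range(S):
            if p[s] == 0:
                if q[s] > 0:
                    raise ZeroDivisionError("infinite ratio")
                r.append(0.0)
            else:
                r.append(q[s] / p[s])
        ratios.append(r)
        vs.append([x if x >= 1.0 else 0.0 for x in r])
        tot = sum(r)
        percents.append([100.0 * x / tot if tot > 0 else 0.0 for x in r])
    rbar = [sum(ratios[e][s] for e in range(k)) / k for s in range(S)]
    tot = sum(rbar)
    mean_percent = [100.0 * x / tot if tot > 0 else 0.0 for x in rbar]
    return {"ratios": ratios, "v": vs, "percents": percents, "mean_percent": mean_percent}


# ---------------------------------------------------------------------------
# trees: random additive matrices and exhaustive least-squares fitting
# ---------------------------------------------------------------------------


def enumerate_topologies(n: int):
    """All unrooted binary topologies on leaves 0..n-1 as edge lists.

    Edges are (u, v) pairs; leaves are 0..n-1, internal nodes n, n+1, ...
    Counts: 1, 3, 15, 105 for n = 3..6.
    """
    base = [(n, 0), (n, 1), (n, 2)]
    tops = [base]
    next_internal = n + 1
    for leaf in range(3, n):
        new_tops = []
        for edges in tops:
            for idx, (u, v) in enumerate(edges):
                w = next_internal
                rest = edges[:idx] + edges[idx + 1 :]
                new_tops.append(rest + [(u, w), (w, v), (w, leaf)])
        tops = new_tops
        next_internal += 1
    return tops


def _leaf_paths(edges, n):
    """For each leaf pair, the set of edge indices on the connecting path."""
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))

    def path(a, b):
        stack = [(a, None, [])]
        seen = {a}
        while stack:
            node, _, used = stack.pop()
            if node == b:
                return used
            for nxt, eidx in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, node, used + [eidx]))
        raise RuntimeError("disconnected topology")

    return {(a, b): path(a, b) for a, b in itertools.combinations(range(n), 2)}


def ls_fit(edges, n, D):
    """Least-squares branch lengths for one topology; returns (lengths, rss)."""
    paths = _leaf_paths(edges, n)
    pairs = list(paths)
    A = np.zeros((len(pairs), len(edges)))
    b = np.array([D[a, c] for a, c in pairs])
    for row, pair in enumerate(pairs):
        A[row, paths[pair]] = 1.0
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    rss = float(((A @ x - b) ** 2).sum())
    return x, rss


def edge_splits(edges, n):
    """Leaf set under each edge (the smaller/canonical side), by edge index."""
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    all_leaves = frozenset(range(n))
    splits = {}
    for idx, (u, v) in enumerate(edges):
        # leaves reachable from v without crossing this edge
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node < n:
                side.add(node)
            for nxt, eidx in adj[node]:
                if eidx != idx and nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        side = frozenset(side)
        comp = all_leaves - side
        splits[idx] = min(side, comp, key=lambda s: (len(s), tuple(sorted(s))))
    return splits


def random_additive_tree(n, rng, min_len=0.05, max_len=1.0):
    """Random unrooted binary topology with random branch lengths.

    Returns (edges, lengths, D) with D the exact additive leaf distance
    matrix.
    """
    tops = enumerate_topologies(n)
    edges = tops[rng.integers(0, len(tops))]
    lengths = rng.uniform(min_len, max_len, size=len(edges))
    paths = _leaf_paths(edges, n)
    D = np.zeros((n, n))
    for (a, b), eidxs in paths.items():
        D[a, b] = D[b, a] = lengths[eidxs].sum()
    return edges, lengths, D


def best_topology_by_ls(n, D):
    """Exhaustive enumeration: topology with minimal least-squares residual."""
    best = None
    for edges in enumerate_topologies(n):
        x, rss = ls_fit(edges, n, D)
        if best is None or rss < best[2]:
            best = (edges, x, rss)
    return best


# ---------------------------------------------------------------------------
# balanced RCBD factorial ANOVA: explicit deviation sums
# ---------------------------------------------------------------------------


def brute_rcbd_ss(values, varieties, treatments, blocks):
    """Sums of squares by explicit loops over factor-level deviations.

    All inputs are parallel sequences, one entry per observation.
    """
    y = list(map(float, values))
    N = len(y)
    grand = sum(y) / N

    def level_means(labels):
        levels = sorted(set(labels))
        out = {}
        for lv in levels:
            sel = [y[i] for i in range(N) if labels[i] == lv]
            out[lv] = (sum(sel) / len(sel), len(sel))
        return out

    def ss_of(labels):
        return sum(cnt * (m - grand) ** 2 for m, cnt in level_means(labels).values())

    cells = [f"{v}|{t}" for v, t in zip(varieties, treatments)]
    ss_total = sum((v - grand) ** 2 for v in y)
    ss_block = ss_of(blocks)
    ss_v = ss_of(varieties)
    ss_t = ss_of(treatments)
    ss_cells = ss_of(cells)
    ss_vt = ss_cells - ss_v - ss_t
    ss_err = ss_total - ss_block - ss_cells
    return {
        "block": ss_block,
        "variety": ss_v,
        "treatment": ss_t,
        "variety:treatment": ss_vt,
        "error": ss_err,
        "total": ss_total,
    }
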