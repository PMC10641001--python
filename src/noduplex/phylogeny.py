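"""ITS-based identification of nodule symbionts.

Pairwise evolutionary distances (p, Jukes-Cantor 69, Kimura 2-parameter) from
an aligned nucleotide matrix, classical Neighbor-Joining tree construction,
nonparametric bootstrap supports mapped onto the original-data tree with
low-support collapsing, outgroup rooting, and nearest-reference cluster calls
for unknown isolates. Trees are dendropy objects; bootstrap supports live on
internal nodes as ``node.support`` (percent) and are written as internal node
labels in Newick output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .strains import StrainLibrary

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "SaturationError",
    "ClusterAssignment",
    "pairwise_distance",
    "neighbor_joining",
    "bootstrap_support",
    "collapse_low_support",
    "root_with_outgroup",
    "assign_clusters",
    "bipartitions",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 255, "N": 255}
MODELS = ("p", "JC69", "K2P")


class SaturationError(ValueError):
    """A pairwise distance is undefined because divergence is saturated."""


@dataclass
class Alignment:
    """Aligned nucleotide matrix over {A, C, G, T, -, N}."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("one sequence per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")
        lens = {len(r) for r in self.rows}
        if len(lens) != 1:
            raise ValueError("all rows must have equal length")
        if not self.rows or len(self.rows[0]) == 0:
            raise ValueError("alignment must have at least one column")
        for label, row in zip(self.taxa, self.rows):
            bad = set(row) - set(_CODE)
            if bad:
                raise ValueError(f"record {label!r} contains invalid symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def encoded(self) -> np.ndarray:
        """uint8 matrix, ACGT -> 0..3, gap/N -> 255."""
        lut = np.full(256, 255, dtype=np.uint8)
        for ch, code in _CODE.items():
            lut[ord(ch)] = code
        raw = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
        return lut[raw].reshape(len(self.rows), self.length)

    @classmethod
    def from_library(cls, library: StrainLibrary, include_outgroup: bool = True) -> "Alignment":
        taxa = [s.id for s in library.strains]
        rows = [s.its_seq for s in library.strains]
        if include_outgroup:
            taxa.append(library.outgroup.id)
            rows.append(library.outgroup.its_seq)
        return cls(taxa=taxa, rows=rows)

    def subset_columns(self, columns: np.ndarray) -> "Alignment":
        rows = ["".join(row[c] for c in columns) for row in self.rows]
        return Alignment(taxa=list(self.taxa), rows=rows)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix in substitutions/site."""

    taxa: list[str]
    matrix: np.ndarray
    model: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape must match taxa")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (m < -1e-12).any():
            raise ValueError("distances must be non-negative")
        if not np.isfinite(m).all():
            raise ValueError("distances must be finite")
        self.matrix = m

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)


def _distances_from_encoded(
    X: np.ndarray, taxa: list[str], model: str, pairwise_deletion: bool
) -> DistanceMatrix:
    n = X.shape[0]
    valid = X < 4
    if not pairwise_deletion:  # complete deletion: drop columns with any gap/N
        keep = valid.all(axis=0)
        X = X[:, keep]
        valid = X < 4
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nv = int(both.sum())
            if nv == 0:
                raise ValueError(
                    f"pair ({taxa[i]!r}, {taxa[j]!r}) shares no comparable columns"
                )
            diff = (X[i] != X[j]) & both
            p = diff.sum() / nv
            if model == "p":
                dij = p
            elif model == "JC69":
                if p >= 0.75:
                    raise SaturationError(
                        f"pair ({taxa[i]!r}, {taxa[j]!r}) is saturated (p = {p:.3f} >= 0.75)"
                    )
                dij = -0.75 * np.log1p(-4.0 * p / 3.0)
            elif model == "K2P":
                ts = (diff & ((X[i] % 2) == (X[j] % 2))).sum() / nv
                tv = p - ts
                w1 = 1.0 - 2.0 * ts - tv
                w2 = 1.0 - 2.0 * tv
                if w1 <= 0 or w2 <= 0:
                    raise SaturationError(
                        f"pair ({taxa[i]!r}, {taxa[j]!r}) is saturated under K2P"
                    )
                dij = -0.5 * np.log(w1) - 0.25 * np.log(w2)
            else:
                raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(taxa=list(taxa), matrix=d, model=model)


def pairwise_distance(
    alignment: Alignment, model: str = "JC69", pairwise_deletion: bool = True
) -> DistanceMatrix:
    """Pairwise evolutionary distances for an alignment.

    ``model`` is one of ``"p"`` (proportion of differing sites), ``"JC69"``
    (d = -3/4 ln(1 - 4p/3)) or ``"K2P"`` (separate transition/transversion
    rates). With ``pairwise_deletion`` each pair skips only its own gap/N
    columns; otherwise any column containing a gap/N is removed globally.
    Saturated pairs raise :class:`SaturationError` naming the pair.
    """
    if len(alignment.taxa) < 2:
        raise ValueError("need at least two taxa")
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return _distances_from_encoded(
        alignment.encoded(), alignment.taxa, model, pairwise_deletion
    )


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Classical Neighbor-Joining tree from a distance matrix.

    Iteratively joins the pair minimizing Q(i,j) = (m-2) d(i,j) - R_i - R_j,
    with branch lengths from the standard rate formula. Ties in Q are broken
    by the lexicographically smallest pair of cluster keys (a cluster's key
    is its smallest leaf label). Negative branch lengths are truncated to
    zero with the deficit moved to the sister branch. The returned tree is
    unrooted (trifurcating seed node).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    tns = dendropy.TaxonNamespace(dm.taxa)
    nodes: list[dendropy.Node] = []
    for label in dm.taxa:
        nd = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(nd)
    keys = list(dm.taxa)
    D = dm.matrix.copy()
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> int:
        # negative-length truncation; the deficit moves to the sister branch
        # so the path length between the two joined clusters is preserved
        if li < 0:
            lj += li
            li = 0.0
        elif lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = max(li, 0.0)
        parent.add_child(nodes[j])
        nodes[j].edge.length = max(lj, 0.0)
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        return len(nodes) - 1

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - R[a] - R[b]
                key = tuple(sorted((keys[active[a]], keys[active[b]])))
                cand = (q, key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (R[a] - R[b]) / (2.0 * (m - 2))
        lj = dij - li
        u = join(i, j, li, lj)
        # distances from the new node to the remaining clusters
        newd = np.zeros(len(nodes))
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            newd[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[u, : u + 1] = np.append(newd[:u], 0.0)
        D[: u + 1, u] = D[u, : u + 1]
        active = [k for k in active if k not in (i, j)] + [u]

    # final three clusters: closed-form three-point attachment
    i, j, k = sorted(active, key=lambda x: keys[x])
    center = dendropy.Node()
    lengths = {
        i: 0.5 * (D[i, j] + D[i, k] - D[j, k]),
        j: 0.5 * (D[i, j] + D[j, k] - D[i, k]),
        k: 0.5 * (D[i, k] + D[j, k] - D[i, j]),
    }
    for x in (i, j, k):
        center.add_child(nodes[x])
        nodes[x].edge.length = max(lengths[x], 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of a tree, as canonical smaller-side leaf sets.

    Rooting-invariant: a rooted tree and its unrooted form give the same set.
    """
    all_taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    n = len(all_taxa)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = _leafset(node)
        if len(side) <= 1 or len(side) >= n - 1:
            continue
        comp = all_taxa - side
        canon = min(side, comp, key=lambda s: (len(s), tuple(sorted(s))))
        splits.add(canon)
    return splits


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    alignment: Alignment,
    model: str = "JC69",
    n_replicates: int = 1000,
    seed: int = 0,
    pairwise_deletion: bool = True,
) -> tuple[dendropy.Tree, dict]:
    """Bootstrap supports on the NJ tree of the original alignment.

    Columns are resampled with replacement to the original length; each
    replicate contributes its NJ tree, and the support of every internal edge
    of the reference tree is the percentage of replicate trees containing the
    same bipartition. Replicates whose distances saturate are skipped with a
    warning and removed from the denominator. Per-replicate RNG streams are
    derived from (seed, replicate-counter), so results are reproducible and
    independent of evaluation order.

    Returns the reference tree (supports attached as ``node.support``) and an
    info dict with ``n_valid`` and ``n_skipped``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    X = alignment.encoded()
    ref_tree = neighbor_joining(
        _distances_from_encoded(X, alignment.taxa, model, pairwise_deletion)
    )
    ref_splits = {}
    all_taxa = frozenset(alignment.taxa)
    n_tax = len(alignment.taxa)
    for node in ref_tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = _leafset(node)
        if len(side) <= 1 or len(side) >= n_tax - 1:
            continue
        canon = min(side, all_taxa - side, key=lambda s: (len(s), tuple(sorted(s))))
        ref_splits[canon] = node
    counts = {split: 0 for split in ref_splits}
    L = alignment.length
    n_skipped = 0
    for b in range(n_replicates):
        rng = np.random.default_rng([seed, b])
        cols = rng.integers(0, L, size=L)
        try:
            dmat = _distances_from_encoded(
                X[:, cols], alignment.taxa, model, pairwise_deletion
            )
        except (SaturationError, ValueError) as err:
            n_skipped += 1
            warnings.warn(f"bootstrap replicate {b} skipped: {err}", stacklevel=2)
            continue
        rep_splits = bipartitions(neighbor_joining(dmat))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    n_valid = n_replicates - n_skipped
    if n_valid == 0:
        raise SaturationError("every bootstrap replicate saturated")
    for split, node in ref_splits.items():
        node.support = 100.0 * counts[split] / n_valid
        node.label = f"{node.support:g}"
    return ref_tree, {"n_valid": n_valid, "n_skipped": n_skipped}


def collapse_low_support(tree: dendropy.Tree, threshold_percent: float = 50.0) -> dendropy.Tree:
    """Contract internal edges with support below the threshold into polytomies.

    Leaves and remaining supports are untouched. Operates on (and returns) a
    clone of the input tree.
    """
    out = tree.clone(depth=1)
    to_collapse = [
        nd
        for nd in out.preorder_node_iter()
        if nd.parent_node is not None
        and not nd.is_leaf()
        and getattr(nd, "support", None) is not None
        and nd.support < threshold_percent
    ]
    for nd in to_collapse:
        nd.edge.collapse()
    return out


def root_with_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Root a tree at the midpoint of the outgroup's pendant edge."""
    out = tree.clone(depth=1)
    leaf = None
    for lf in out.leaf_node_iter():
        if lf.taxon.label == outgroup_label:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"outgroup {outgroup_label!r} is not a leaf of the tree")
    elen = leaf.edge.length or 0.0
    out.reroot_at_edge(leaf.edge, length1=elen / 2.0, length2=elen / 2.0)
    out.is_rooted = True
    return out


# ---------------------------------------------------------------------------
# cluster assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterAssignment:
    """Nearest-reference call for one isolate sequence."""

    isolate: str
    nearest: str  # reference tag
    distance: float
    call: str  # reference tag, or "novel"
    tie: bool = False


def assign_clusters(
    isolate_seqs: dict[str, str],
    library: StrainLibrary,
    model: str = "JC69",
    novelty_cutoff: float = 0.05,
    pairwise_deletion: bool = True,
) -> list[ClusterAssignment]:
    """Assign isolates to the nearest reference strain, or call them novel.

    Isolate sequences must be aligned to the library's ITS coordinate system
    (same length). The call is ``"novel"`` when the minimum model distance to
    any reference exceeds ``novelty_cutoff`` (substitutions/site). Exact
    distance ties go to the alphabetically first tag and are flagged.
    """
    refs = library.references
    L = library.its_length
    out = []
    for label, seq in isolate_seqs.items():
        if len(seq) != L:
            raise ValueError(
                f"isolate {label!r} has length {len(seq)}, expected aligned length {L}"
            )
        aln = Alignment(
            taxa=[label] + [s.tag for s in refs],
            rows=[seq] + [s.its_seq for s in refs],
        )
        dmat = pairwise_distance(aln, model=model, pairwise_deletion=pairwise_deletion)
        dists = pd.Series(dmat.matrix[0, 1:], index=[s.tag for s in refs])
        dmin = dists.min()
        nearest_tags = sorted(dists.index[np.isclose(dists, dmin, rtol=0, atol=1e-15)])
        nearest = nearest_tags[0]
        call = "novel" if dmin > novelty_cutoff else nearest
        out.append(
            ClusterAssignment(
                isolate=label,
                nearest=nearest,
                distance=float(dmin),
                call=call,
                tie=len(nearest_tags) > 1,
            )
        )
    return out


def cluster_summary(assignments: list[ClusterAssignment]) -> pd.DataFrame:
    """Count isolates per cluster call."""
    return (
        pd.DataFrame([{"call": a.call} for a in assignments])
        .value_counts()
        .rename("n_isolates")
        .reset_index()
        .sort_values(["n_isolates", "call"], ascending=[False, True])
        .reset_index(drop=True)
    )
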