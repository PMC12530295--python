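"""Pairwise genetic distances, neighbour joining, bootstrap, monophyly.

Distances follow the conventions of whole-genome consensus comparisons:
pairwise deletion of any site that is ambiguous in either sequence, the
proportion of differing sites ("p-distance") as the raw statistic, and
the Tamura--Nei (1993) correction -- optionally with gamma-distributed
rate variation across sites -- when a substitution-model distance is
required.  Trees are built with the Saitou--Nei neighbour-joining
agglomeration and are returned as :class:`dendropy.Tree` objects so that
standard tree plumbing (Newick I/O, traversal) comes from dendropy.

Saturated pairs, where a logarithm argument of the TN93 transform is
non-positive, are flagged with the sentinel :data:`INESTIMABLE`
(``math.inf``) rather than NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .seqs import MISSING, StrainGenome, encode

#: sentinel for a distance that cannot be estimated (saturation / no sites)
INESTIMABLE = math.inf


@dataclass
class DistanceConfig:
    """Which distance to compute.

    model
        ``"p"`` (proportion of differing sites), ``"tn93"`` or
        ``"tn93g"`` (Tamura--Nei with gamma rate variation).
    gamma_shape
        Shape parameter alpha of the gamma distribution of rates across
        sites, used only by ``tn93g``.
    pairwise_deletion
        Kept for interface clarity; comparisons always drop sites that
        are ambiguous in either member of the pair.
    """

    model: str = "tn93"
    gamma_shape: float = 1.0
    pairwise_deletion: bool = True

    def __post_init__(self):
        if self.model not in ("p", "tn93", "tn93g"):
            raise ValueError(f"unknown distance model {self.model!r}")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")


@dataclass
class Alignment:
    """Equal-length sequences with an optional site -> (chrom, pos) map."""

    ids: list[str]
    data: np.ndarray  # (n_strains, n_sites) in 4-state encoding
    site_map: pd.DataFrame | None = None  # columns: chrom, pos (0-based)

    def __post_init__(self):
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("alignment ids must be unique")
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ids):
            raise ValueError("data must be (n_strains, n_sites)")

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def row(self, strain: str) -> np.ndarray:
        return self.data[self.ids.index(strain)]

    @classmethod
    def from_genomes(cls, genomes: list[StrainGenome]) -> "Alignment":
        """Concatenate per-chromosome sequences into one whole-genome row
        per strain; all genomes must share chromosome names and lengths."""
        ref = genomes[0]
        chroms = ref.chromosomes()
        for g in genomes[1:]:
            if g.chrom_lengths() != ref.chrom_lengths():
                raise ValueError(
                    f"genome {g.strain} does not share coordinates with {ref.strain}"
                )
        data = np.vstack([g.concatenated() for g in genomes])
        parts = []
        for c in chroms:
            n = len(ref.sequences[c])
            parts.append(pd.DataFrame({"chrom": c, "pos": np.arange(n)}))
        site_map = pd.concat(parts, ignore_index=True)
        return cls([g.strain for g in genomes], data, site_map)


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal; inf where inestimable
    n_sites: np.ndarray  # per-pair compared sites

    @property
    def inestimable(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# pairwise distances


def p_distance(a, b) -> tuple[float, int]:
    """Proportion of differing sites under pairwise deletion.

    Returns ``(distance, n_compared)``; with zero comparable sites the
    distance is :data:`INESTIMABLE`.
    """
    ea, eb = encode(a), encode(b)
    if ea.shape != eb.shape:
        raise ValueError("sequences must have equal length")
    valid = (ea != MISSING) & (eb != MISSING)
    n = int(valid.sum())
    if n == 0:
        return INESTIMABLE, 0
    diff = int((valid & (ea != eb)).sum())
    return diff / n, n


def _pair_counts(ea: np.ndarray, eb: np.ndarray):
    """Site counts needed by TN93: transitions split by purine/pyrimidine,
    transversions, and base frequencies averaged over the two sequences."""
    valid = (ea != MISSING) & (eb != MISSING)
    n = int(valid.sum())
    if n == 0:
        return 0, 0, 0, 0, np.zeros(4)
    a = ea[valid]
    b = eb[valid]
    diff = a != b
    x = a ^ b
    ts = diff & (x == 2)
    p1 = int((ts & (np.minimum(a, b) == 0)).sum())  # A<->G
    p2 = int((ts & (np.minimum(a, b) == 1)).sum())  # C<->T
    q = int(diff.sum()) - p1 - p2
    freqs = (np.bincount(a, minlength=4) + np.bincount(b, minlength=4)) / (2 * n)
    return n, p1, p2, q, freqs


def tn93_distance(a, b, cfg: DistanceConfig | None = None) -> float:
    """Tamura--Nei (1993) distance, closed form from transition/transversion
    proportions and empirical base frequencies.

    With ``cfg.model == "tn93g"`` the gamma-rates correction replaces each
    ``-log(w)`` term by ``alpha * (w**(-1/alpha) - 1)``.  Saturated pairs
    return :data:`INESTIMABLE`.
    """
    cfg = cfg or DistanceConfig()
    ea, eb = encode(a), encode(b)
    if ea.shape != eb.shape:
        raise ValueError("sequences must have equal length")
    n, p1c, p2c, qc, g = _pair_counts(ea, eb)
    if n == 0:
        raise ValueError("no comparable sites: cannot estimate base frequencies")
    if p1c + p2c + qc == 0:
        return 0.0
    gA, gC, gG, gT = g
    gR, gY = gA + gG, gC + gT
    if gR <= 0 or gY <= 0 or gA * gG <= 0 or gT * gC <= 0:
        return INESTIMABLE
    P1, P2, Q = p1c / n, p2c / n, qc / n
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1 - P1 / k1 - Q / (2 * gR)
    w2 = 1 - P2 / k2 - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return INESTIMABLE
    if cfg.model == "tn93g":
        alpha = cfg.gamma_shape
        d = alpha * (
            k1 * (w1 ** (-1 / alpha) - 1)
            + k2 * (w2 ** (-1 / alpha) - 1)
            + k3 * (w3 ** (-1 / alpha) - 1)
        )
    else:
        d = -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
    return max(d, 0.0)


def pair_distance(a, b, cfg: DistanceConfig) -> tuple[float, int]:
    """Distance under ``cfg.model`` plus the number of compared sites."""
    p, n = p_distance(a, b)
    if cfg.model == "p" or not math.isfinite(p):
        return p, n
    return tn93_distance(a, b, cfg), n


def distance_matrix(aln: Alignment, cfg: DistanceConfig | None = None) -> DistanceMatrix:
    cfg = cfg or DistanceConfig()
    n = len(aln.ids)
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        sites[i, i] = aln.n_sites
        for j in range(i + 1, n):
            d, m = pair_distance(aln.data[i], aln.data[j], cfg)
            values[i, j] = values[j, i] = d
            sites[i, j] = sites[j, i] = m
    return DistanceMatrix(list(aln.ids), values, sites)


# ---------------------------------------------------------------------------
# neighbour joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou--Nei neighbour joining.

    Ties on the Q criterion are broken by joining the pair whose cluster
    representatives (lexicographically smallest member ids) sort first,
    so the output is deterministic.  Negative branch lengths are clamped
    to zero.  The returned tree is unrooted (trifurcating seed node).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("distance matrix contains inestimable entries")

    tns = dendropy.TaxonNamespace(list(dm.ids))
    nodes = []
    for label in dm.ids:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(node)
    reps = list(dm.ids)
    D = dm.values.astype(float).copy()

    while len(reps) > 3:
        m = len(reps)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tol = 1e-12 * max(1.0, abs(qmin))
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if Q[i, j] <= qmin + tol:
                    key = tuple(sorted((reps[i], reps[j])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    # final three-way join solving the three-point equations
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = [
        max(0.5 * (d01 + d02 - d12), 0.0),
        max(0.5 * (d01 + d12 - d02), 0.0),
        max(0.5 * (d02 + d12 - d01), 0.0),
    ]
    center = dendropy.Node()
    for node, ln in zip(nodes, lens):
        center.add_child(node)
        node.edge.length = ln
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions, bootstrap, monophyly


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def _leafsets(tree: dendropy.Tree) -> dict[int, frozenset]:
    """Postorder leaf-label sets keyed by node id."""
    out: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[id(node)] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for ch in node.child_nodes():
                acc |= out[id(ch)]
            out[id(node)] = frozenset(acc)
    return out


def bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Non-trivial unrooted bipartitions, normalised to the side that does
    not contain the alphabetically first taxon.  Branch lengths are
    ignored; each bipartition maps to the child node of its edge."""
    leaves = _leaf_labels(tree)
    ref = min(leaves)
    sets = _leafsets(tree)
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = sets[id(node)]
        if len(below) < 2 or len(below) > len(leaves) - 2:
            continue
        if ref in below:
            below = frozenset(leaves - below)
        out[below] = node
    return out


def bootstrap_support(
    aln: Alignment,
    cfg: DistanceConfig | None = None,
    n_reps: int = 100,
    seed: int | None = None,
) -> dendropy.Tree:
    """NJ tree on the full alignment with internal edges annotated by the
    percentage of column-resampled replicates containing the same
    bipartition.  Supports are stored on ``node.support`` and mirrored
    into ``node.label`` for Newick output."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = cfg or DistanceConfig()
    tree = neighbor_joining(distance_matrix(aln, cfg))
    target = bipartitions(tree)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    L = aln.n_sites
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        rep_aln = Alignment(list(aln.ids), aln.data[:, idx])
        try:
            rep_tree = neighbor_joining(distance_matrix(rep_aln, cfg))
        except ValueError:  # saturated resample: counts unchanged
            continue
        for bp in bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    for bp, node in target.items():
        support = 100.0 * counts[bp] / n_reps
        node.support = support
        node.label = f"{support:g}"
    return tree


def root_with_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Return a copy of ``tree`` rooted on the edge leading to ``outgroup``."""
    rooted = tree.clone(depth=1)
    og = None
    for lf in rooted.leaf_node_iter():
        if lf.taxon.label == outgroup:
            og = lf
            break
    if og is None:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    rooted.reroot_at_edge(og.edge, update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def find_clade_node(tree: dendropy.Tree, tips: set[str]) -> dendropy.Node | None:
    """Node whose descendant leaf set equals ``tips`` on the rooted tree,
    or None if the tips are not a clade."""
    sets = _leafsets(tree)
    target = frozenset(tips)
    for node in tree.preorder_node_iter():
        if sets[id(node)] == target:
            return node
    return None


def mrca_node(tree: dendropy.Tree, tips: set[str]) -> dendropy.Node:
    """Smallest node (by descendant leaf count) containing all ``tips``."""
    sets = _leafsets(tree)
    target = frozenset(tips)
    best = None
    for node in tree.preorder_node_iter():
        s = sets[id(node)]
        if target <= s and (best is None or len(s) < len(best[1])):
            best = (node, s)
    if best is None:
        raise ValueError("tips not found in tree")
    return best[0]


def is_monophyletic(
    tree: dendropy.Tree,
    tips: set[str],
    min_support: float = 95.0,
    outgroup: str | None = None,
) -> tuple[bool, float]:
    """Do ``tips`` form a clade with bootstrap support >= ``min_support``?

    Unrooted trees require an ``outgroup`` to orient the test.  The whole
    leaf set and single tips are clades by convention (support 100).  A
    tree without bootstrap annotations is treated as fully supported, so
    the test reduces to topology.
    """
    tips = set(tips)
    leaves = _leaf_labels(tree)
    if not tips <= leaves:
        raise ValueError("tips must be a subset of the tree's leaves")
    if tips == leaves or len(tips) == 1:
        return True, 100.0
    if tree.is_rooted:
        rooted = tree
        node = find_clade_node(rooted, tips)
        if node is None:
            return False, 0.0
        support = _node_support(node)
    else:
        if outgroup is None:
            raise ValueError("an outgroup is required to root an unrooted tree")
        rooted = root_with_outgroup(tree, outgroup)
        if find_clade_node(rooted, tips) is None:
            return False, 0.0
        # support belongs to the unrooted bipartition, not to whichever
        # node carries the label after rerooting
        ref = min(leaves)
        bp = frozenset(tips) if ref not in tips else frozenset(leaves - tips)
        bp_node = bipartitions(tree).get(bp)
        support = _node_support(bp_node) if bp_node is not None else None
    if support is None:
        support = 100.0
    return support >= min_support, float(support)


def _node_support(node: dendropy.Node) -> float | None:
    support = getattr(node, "support", None)
    if support is None and node.label is not None:
        try:
            support = float(node.label)
        except ValueError:
            support = None
    return support


def tip_to_node_distance(tree: dendropy.Tree, tip: str, node: dendropy.Node) -> float:
    """Sum of branch lengths from a leaf up to an ancestral node."""
    cur = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == tip:
            cur = lf
            break
    if cur is None:
        raise ValueError(f"tip {tip!r} not in tree")
    total = 0.0
    while cur is not node:
        if cur.parent_node is None:
            raise ValueError(f"node is not an ancestor of tip {tip!r}")
        total += cur.edge.length or 0.0
        cur = cur.parent_node
    return total
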