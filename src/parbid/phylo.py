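"""Distance-based phylogeny core: p-distances under pairwise deletion,
neighbor-joining, nonparametric bootstrap, outgroup rooting and Newick I/O.

The p-distance between two aligned rows is the proportion of differing
sites among sites where both rows carry an unambiguous base (A/C/G/T);
gaps, N and IUPAC ambiguity codes are treated as missing and excluded per
pair ("pairwise deletion").  Trees are built by Saitou-Nei neighbor
joining on the Q-criterion; bootstrap supports are attached to the
full-data topology by bipartition matching.  Tree objects are
:class:`dendropy.Tree` instances sharing a taxon namespace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np

from .align import Alignment

__all__ = [
    "DistanceMatrix",
    "BootstrapResult",
    "p_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "root_with_outgroup",
    "write_newick",
    "read_newick",
    "tree_bipartitions",
    "UndefinedDistanceError",
    "OutgroupError",
]

logger = logging.getLogger(__name__)

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


class UndefinedDistanceError(ValueError):
    """A taxon pair shares zero comparable sites."""


class OutgroupError(ValueError):
    """Outgroup taxa absent or not monophyletic in the unrooted tree."""


def encode_alignment(alignment: Alignment) -> np.ndarray:
    """Rows as int8 codes: A/C/G/T -> 0..3, anything else -> -1 (missing)."""
    mat = np.vstack([
        _CODE[np.frombuffer(rec.residues.encode("ascii"), dtype=np.uint8)]
        for rec in alignment.records
    ])
    return mat


def _pair_counts(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(comparable_sites, differing_sites) for all row pairs, via matmuls."""
    valid = (X >= 0).astype(np.float64)
    comp = valid @ valid.T
    same = np.zeros_like(comp)
    for b in range(4):
        ind = (X == b).astype(np.float64)
        same += ind @ ind.T
    diff = comp - same
    return comp, diff


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair comparable-site counts."""

    taxa: List[str]
    d: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def __getitem__(self, pair: Tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.d[i, j])

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\t" + "\t".join(self.taxa) + "\n")
            for i, t in enumerate(self.taxa):
                fh.write(t + "\t" + "\t".join(f"{v:.6f}" for v in self.d[i]) + "\n")


def p_distance_matrix(alignment: Alignment, pairwise_deletion: bool = True) -> DistanceMatrix:
    """p-distances; sites with a gap/ambiguity in either row of a pair are
    excluded for that pair (pairwise deletion) or globally (complete)."""
    X = encode_alignment(alignment)
    if not pairwise_deletion:
        keep = (X >= 0).all(axis=0)
        X = X[:, keep]
    comp, diff = _pair_counts(X)
    n = X.shape[0]
    off = ~np.eye(n, dtype=bool)
    if (comp[off] < 1).any():
        i, j = np.argwhere((comp < 1) & off)[0]
        raise UndefinedDistanceError(
            f"no comparable sites between {alignment.ids[i]!r} and {alignment.ids[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        d = np.where(comp > 0, diff / np.maximum(comp, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(list(alignment.ids), d, comp.astype(int))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _nj_core(D0: np.ndarray) -> List[Tuple[int, List[Tuple[int, float]]]]:
    """Saitou-Nei agglomeration.

    Returns a list of (node_id, [(child_id, branch_length), ...]) in
    creation order; leaves are ids 0..n-1, the last entry is the basal
    degree-3 node of the unrooted tree.  Ties in the Q-criterion break to
    the lowest (i, j) pair in the current node ordering.
    """
    n0 = D0.shape[0]
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    size = 2 * n0
    D = np.zeros((size, size))
    D[:n0, :n0] = D0
    active: List[int] = list(range(n0))
    nodes: List[Tuple[int, List[Tuple[int, float]]]] = []
    next_id = n0

    while len(active) > 3:
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        m = len(active)
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major: lowest (i, j) wins ties
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, transferring the deficit to the sister edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i, k] + D[j, k] - dij)
            D[u, k] = D[k, u] = max(duk, 0.0)
        nodes.append((u, [(i, li), (j, lj)]))
        active = [k for k in active if k not in (i, j)] + [u]

    x, y, z = active
    lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    ly = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    lz = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    basal = next_id
    nodes.append((basal, [(x, max(lx, 0.0)), (y, max(ly, 0.0)), (z, max(lz, 0.0))]))
    return nodes


def _leafsets(nodes: List[Tuple[int, List[Tuple[int, float]]]], n_leaves: int
              ) -> Dict[int, int]:
    """Bitmask of descendant leaves per node id."""
    masks: Dict[int, int] = {i: 1 << i for i in range(n_leaves)}
    for node_id, children in nodes:
        m = 0
        for child, _ in children:
            m |= masks[child]
        masks[node_id] = m
    return masks


def _nontrivial_bipartitions(nodes, n_leaves: int, taxa: Sequence[str]
                             ) -> Dict[FrozenSet[str], int]:
    """Internal-edge bipartitions as normalized label sets (mask kept too)."""
    masks = _leafsets(nodes, n_leaves)
    all_labels = frozenset(taxa)
    anchor = sorted(all_labels)[0]
    out: Dict[FrozenSet[str], int] = {}
    for node_id, _ in nodes[:-1]:  # basal node's own "edge" does not exist
        mask = masks[node_id]
        labels = frozenset(taxa[i] for i in range(n_leaves) if (mask >> i) & 1)
        norm = labels if anchor not in labels else (all_labels - labels)
        if 1 < len(norm) < n_leaves - 1:
            out[norm] = mask
    return out


def _to_dendropy(nodes, taxa: Sequence[str],
                 taxon_namespace: Optional[dendropy.TaxonNamespace] = None
                 ) -> dendropy.Tree:
    tns = taxon_namespace or dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    n_leaves = len(taxa)
    dnode: Dict[int, dendropy.Node] = {}
    for i, label in enumerate(taxa):
        nd = dendropy.Node()
        nd.taxon = tns.require_taxon(label=label)
        dnode[i] = nd
    for node_id, children in nodes:
        nd = dendropy.Node()
        for child, bl in children:
            ch = dnode[child]
            ch.edge.length = float(bl)
            nd.add_child(ch)
        dnode[node_id] = nd
    tree.seed_node = dnode[nodes[-1][0]]
    tree.is_rooted = False
    return tree


def nj_tree(distance_matrix: DistanceMatrix,
            taxon_namespace: Optional[dendropy.TaxonNamespace] = None) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted; basal node of degree 3).

    Negative branch-length estimates are clamped to zero with the deficit
    transferred to the sister edge.
    """
    nodes = _nj_core(distance_matrix.d)
    return _to_dendropy(nodes, distance_matrix.taxa, taxon_namespace)


def tree_bipartitions(tree: dendropy.Tree) -> Dict[FrozenSet[str], dendropy.Node]:
    """Non-trivial bipartitions of a (rooted or unrooted) dendropy tree,
    keyed by the normalized label set (side not containing the first taxon
    in leaf-visit order)."""
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = sorted(all_labels)[0]
    out: Dict[FrozenSet[str], dendropy.Node] = {}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node or nd.is_leaf():
            continue
        labels = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        norm = labels if anchor not in labels else (all_labels - labels)
        if 1 < len(norm) < len(all_labels) - 1:
            out[norm] = nd
    return out


@dataclass
class BootstrapResult:
    replicates: int
    support: Dict[FrozenSet[str], float]
    tree: dendropy.Tree


def bootstrap_support(
    alignment: Alignment,
    replicates: int = 1000,
    seed: Optional[int] = None,
    max_redraws: int = 100,
) -> BootstrapResult:
    """Column-resampling bootstrap; supports attached to the full-data NJ
    topology by bipartition matching.

    Replicate ``r`` draws its columns from an independent, deterministic
    substream of ``seed``, so results are reproducible and invariant under
    taxon reordering of the input.  A replicate whose resampled columns
    leave some pair with no comparable sites is redrawn (logged), up to
    ``max_redraws`` times.
    """
    # canonicalize row order so tie-breaking (and hence supports) cannot
    # depend on how the caller happened to order the taxa
    alignment = Alignment(sorted(alignment.records, key=lambda r: r.id))
    X = encode_alignment(alignment)
    taxa = list(alignment.ids)
    n, L = X.shape
    ref_dm = p_distance_matrix(alignment)
    ref_nodes = _nj_core(ref_dm.d)
    ref_bips = _nontrivial_bipartitions(ref_nodes, n, taxa)
    counts = {labels: 0 for labels in ref_bips}
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))

    valid = (X >= 0)
    for r in range(replicates):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r,)))
        for attempt in range(max_redraws + 1):
            cols = rng.integers(0, L, size=L)
            Xr = X[:, cols]
            comp, diff = _pair_counts(Xr)
            off = ~np.eye(n, dtype=bool)
            if (comp[off] >= 1).all():
                break
            logger.warning("bootstrap replicate %d redrawn (undefined pair), attempt %d",
                           r, attempt + 1)
        else:
            raise UndefinedDistanceError(
                f"replicate {r}: undefined distance pair after {max_redraws} redraws"
            )
        with np.errstate(invalid="ignore"):
            d = diff / np.maximum(comp, 1)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
        rep_nodes = _nj_core(d)
        rep_bips = _nontrivial_bipartitions(rep_nodes, n, taxa)
        for labels in counts:
            if labels in rep_bips:
                counts[labels] += 1

    support = {labels: 100.0 * c / replicates for labels, c in counts.items()}
    tree = _to_dendropy(ref_nodes, taxa)
    for labels, node in tree_bipartitions(tree).items():
        if labels in support:
            node.label = f"{support[labels]:g}"
    return BootstrapResult(replicates=replicates, support=support, tree=tree)


def attach_supports(tree: dendropy.Tree, support: Dict[FrozenSet[str], float]) -> None:
    """(Re-)attach bootstrap percentages to internal-node labels by
    bipartition matching.  Needed after any rerooting, which reorients
    nodes and would otherwise leave labels on the wrong bipartitions."""
    for nd in tree.preorder_internal_node_iter():
        if nd is not tree.seed_node:
            nd.label = None
    for labels, node in tree_bipartitions(tree).items():
        if labels in support:
            node.label = f"{support[labels]:g}"


def root_with_outgroup(tree: dendropy.Tree, outgroup_taxa: Sequence[str]) -> dendropy.Tree:
    """Root on the edge separating the outgroup from the ingroup.

    The outgroup must be present and form a clade of the unrooted tree
    (one side of some branch); the root bisects that branch.
    """
    tree = tree.clone(depth=1)
    og = set(outgroup_taxa)
    if not og:
        raise OutgroupError("empty outgroup")
    all_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = og - all_labels
    if missing:
        raise OutgroupError(f"outgroup taxa absent from tree: {sorted(missing)}")
    target = None
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        labels = {lf.taxon.label for lf in nd.leaf_iter()}
        if labels == og or labels == (all_labels - og):
            target = nd
            break
    if target is None:
        raise OutgroupError(f"outgroup {sorted(og)} is not monophyletic in the tree")
    length = target.edge.length or 0.0
    tree.is_rooted = True
    tree.reroot_at_edge(target.edge, length1=length / 2.0, length2=length / 2.0,
                        update_bipartitions=False)
    return tree


def write_newick(tree: dendropy.Tree, path: Union[str, Path]) -> None:
    """Serialize with supports as internal-node labels, >=6 significant
    digits on branch lengths, quoted labels preserved."""
    text = tree.as_string(
        schema="newick",
        preserve_spaces=True,
        real_value_format_specifier=".10g",
        suppress_rooting=False,
    )
    Path(path).write_text(text)


def read_newick(path: Union[str, Path],
                taxon_namespace: Optional[dendropy.TaxonNamespace] = None) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            path=str(path),
            schema="newick",
            taxon_namespace=taxon_namespace,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
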