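"""Distance-based tree inference, bootstrap support, rooting, monophyly.

Trees are built by neighbor joining (Saitou–Nei Q-criterion) on p- or
Poisson-corrected distances derived from the trimmed alignment.  Support is
estimated by the standard nonparametric bootstrap: columns are resampled with
replacement, the tree is rebuilt, and each internal edge of the point tree is
annotated with the percentage of replicates containing its split.  The tree
is rooted on a designated outgroup (Class A monooxygenases in the survey this
package models), after which each family is assessed as monophyletic,
paraphyletic or polyphyletic.

Trees are :class:`dendropy.Tree` objects throughout; bootstrap supports are
stored as ``node.label`` (and a ``support`` attribute) on internal nodes, the
convention used by Newick internal-node labels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .msa import GAP, Msa, _identity_from_array

__all__ = [
    "DistanceMatrix",
    "MonophylyResult",
    "distances_from_msa",
    "nj_build",
    "tree_splits",
    "bootstrap_support",
    "root_at_outgroup",
    "assess_monophyly",
    "read_newick",
    "write_newick",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with the model that produced them."""

    taxa: tuple[str, ...]
    values: np.ndarray
    model: str = "p"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix entries must be finite")
        if np.any(v < 0):
            raise ValueError("distance matrix entries must be non-negative")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")


def _distances_from_identity(pct: np.ndarray, model: str, max_distance: float) -> np.ndarray:
    p = 1.0 - pct / 100.0
    np.fill_diagonal(p, 0.0)
    if model == "p":
        return p
    if model == "poisson":
        capped = p >= 1.0
        if np.any(capped[np.triu_indices(p.shape[0], k=1)]):
            warnings.warn(
                f"saturated pairs (p >= 1) capped at distance {max_distance}", stacklevel=3
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            d = -np.log(1.0 - p)
        d[capped] = max_distance
        return np.minimum(d, max_distance)
    raise ValueError(f"unknown distance model {model!r}")


def distances_from_msa(msa: Msa, model: str = "p", max_distance: float = 5.0) -> DistanceMatrix:
    """p-distance (1 − identity/100, pairwise deletion) or its Poisson correction.

    The Poisson model applies −ln(1 − p); saturated pairs (p ≥ 1) are capped
    at ``max_distance`` with a warning.
    """
    from .msa import pairwise_identity

    pct = pairwise_identity(msa).values
    return DistanceMatrix(msa.ids, _distances_from_identity(pct, model, max_distance), model)


def nj_build(D: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining (Saitou–Nei) on a distance matrix; returns an unrooted tree.

    Ties in the Q-criterion are broken by the lowest (row, column) index
    pair; negative estimated branch lengths are clamped to zero.
    """
    n = len(D.taxa)
    if n < 2:
        raise ValueError("neighbor joining needs at least two taxa")
    ns = dendropy.TaxonNamespace([str(t) for t in D.taxa])
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes: list[dendropy.Node] = []
    for taxon in ns:
        nd = dendropy.Node(taxon=taxon)
        nodes.append(nd)
    d = np.array(D.values, dtype=float)

    while len(nodes) > 2:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = divmod(int(np.argmin(q)), m)  # row-major argmin → lowest index pair
        if i > j:
            i, j = j, i
        dij = d[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = max(vi, 0.0)
        parent.add_child(nodes[j])
        nodes[j].edge.length = max(vj, 0.0)
        dk = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.empty((m - 1, m - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = dk[keep]
        new_d[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        d = new_d

    a, b = nodes
    if a.is_leaf() and b.is_leaf():  # two-taxon tree: single edge, held at a joint node
        root = dendropy.Node()
        root.add_child(a)
        a.edge.length = 0.0
        root.add_child(b)
        b.edge.length = max(d[0, 1], 0.0)
    else:
        root = a if not a.is_leaf() else b
        other = b if root is a else a
        root.add_child(other)
        other.edge.length = max(d[0, 1], 0.0)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def _leafset(node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def tree_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions as leaf-label sets, normalized to the side
    not containing the lexicographically smallest leaf label."""
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(labels)
    out: set[frozenset[str]] = set()
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node or nd.is_leaf():
            continue
        side = _leafset(nd)
        if 2 <= len(side) <= len(labels) - 2:
            out.add(labels - side if ref in side else side)
    return out


def bootstrap_support(
    msa: Msa,
    n_replicates: int = 100,
    seed: int | None = None,
    model: str = "p",
    max_distance: float = 5.0,
) -> dendropy.Tree:
    """NJ point tree with bootstrap supports on its internal edges.

    Columns are resampled with replacement (same column count) per
    replicate; each internal edge of the point tree is labelled with
    100 × (replicates containing its split) / n_replicates.  Alignments with
    fewer than four rows have no internal unrooted splits: the point tree is
    returned without supports, with a warning.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    arr = msa.to_array()
    point = nj_build(
        DistanceMatrix(msa.ids, _distances_from_identity(
            _identity_from_array(arr), model, max_distance), model)
    )
    if msa.n_rows < 4:
        warnings.warn("fewer than 4 taxa: no internal splits to support", stacklevel=2)
        return point
    rng = np.random.default_rng(seed)
    ncol = arr.shape[1]
    counts: dict[frozenset[str], int] = {s: 0 for s in tree_splits(point)}
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = arr[:, cols]
        dm = DistanceMatrix(
            msa.ids, _distances_from_identity(_identity_from_array(rep), model, max_distance),
            model,
        )
        rep_splits = tree_splits(nj_build(dm))
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    labels = frozenset(msa.ids)
    ref = min(labels)
    for nd in point.preorder_node_iter():
        if nd is point.seed_node or nd.is_leaf():
            continue
        side = _leafset(nd)
        if not (2 <= len(side) <= len(labels) - 2):
            continue
        key = labels - side if ref in side else side
        support = 100.0 * counts[key] / n_replicates
        nd.support = support
        nd.label = f"{support:g}"
    return point


def root_at_outgroup(tree: dendropy.Tree, outgroup) -> dendropy.Tree:
    """Root an unrooted tree on the edge separating the outgroup from the rest.

    The root is placed at the midpoint of that edge.  If no single edge
    separates the outgroup exactly (non-monophyletic outgroup), the edge
    maximising (outgroup leaves − non-outgroup leaves) on its far side is
    used instead and a warning is emitted.  The input tree is not modified.
    """
    outgroup = frozenset(outgroup)
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    if not outgroup or outgroup == labels:
        raise ValueError("outgroup must be a proper non-empty subset of leaves")
    missing = outgroup - labels
    if missing:
        raise ValueError(f"outgroup labels not in tree: {sorted(missing)}")

    work = tree.clone(depth=1)
    best_edge, best_score, exact = None, -math.inf, False
    for nd in work.preorder_node_iter():
        if nd is work.seed_node:
            continue
        side = _leafset(nd)
        for cand in (side, labels - side):
            score = len(cand & outgroup) - len(cand - outgroup)
            if cand == outgroup:
                best_edge, exact = nd.edge, True
                break
            if score > best_score:
                best_edge, best_score = nd.edge, score
        if exact:
            break
    if not exact:
        warnings.warn("outgroup is not separated by any single edge; rooting at the "
                      "best-scoring edge", stacklevel=2)
    length = best_edge.length or 0.0
    work.reroot_at_edge(best_edge, length1=length / 2.0, length2=length / 2.0,
                        update_bipartitions=False)
    work.is_rooted = True
    return work


@dataclass(frozen=True)
class MonophylyResult:
    """Monophyly status of one family on a rooted, fully labelled tree."""

    family: str
    status: str  # "monophyletic" | "paraphyletic" | "polyphyletic"
    mrca_clade_size: int
    intruders: tuple[str, ...]


def _family_is_mono(tree, labels, family) -> bool:
    members = {leaf for leaf, fam in labels.items() if fam == family}
    mrca = tree.mrca(taxon_labels=sorted(members))
    return _leafset(mrca) == members


def assess_monophyly(tree: dendropy.Tree, labels: dict[str, str], family: str) -> MonophylyResult:
    """Classify a family as monophyletic, paraphyletic or polyphyletic.

    Monophyletic: the MRCA of the family's leaves contains exactly the
    family.  Paraphyletic: every intruding leaf under the MRCA belongs to a
    family that is itself monophyletic on the tree (complete nested groups,
    e.g. BVMO and NMO clades nested inside an FMO grade).  Polyphyletic
    otherwise.
    """
    if not tree.is_rooted:
        raise ValueError("monophyly assessment requires a rooted tree")
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unlabeled = leaves - labels.keys()
    if unlabeled:
        raise ValueError(f"unlabeled leaves: {sorted(unlabeled)[:5]}")
    members = {leaf for leaf in leaves if labels[leaf] == family}
    if not members:
        raise ValueError(f"family {family!r} has no leaves on the tree")
    mrca = tree.mrca(taxon_labels=sorted(members))
    clade = _leafset(mrca)
    intruders = tuple(sorted(clade - members))
    if not intruders:
        status = "monophyletic"
    else:
        intruder_families = {labels[leaf] for leaf in intruders}
        if all(_family_is_mono(tree, labels, f) for f in intruder_families):
            status = "paraphyletic"
        else:
            status = "polyphyletic"
    return MonophylyResult(family, status, len(clade), intruders)


def read_newick(text_or_path: str, path: bool = False) -> dendropy.Tree:
    """Parse Newick; numeric internal-node labels are read as supports."""
    kwargs = dict(schema="newick", preserve_underscores=True,
                  suppress_internal_node_taxa=True)
    try:
        if path:
            tree = dendropy.Tree.get(path=str(text_or_path), **kwargs)
        else:
            tree = dendropy.Tree.get(data=text_or_path, **kwargs)
    except Exception as exc:
        raise ValueError(f"invalid Newick: {exc}") from exc
    seen = set()
    for lf in tree.leaf_node_iter():
        if lf.taxon.label in seen:
            raise ValueError(f"duplicate leaf label {lf.taxon.label!r}")
        seen.add(lf.taxon.label)
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf() and nd.label is not None:
            try:
                nd.support = float(nd.label)
            except ValueError:
                pass
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths and supports as internal-node labels."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
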