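"""Time-scaled breed phylogeny: construction, covariance, Pagel transforms.

The breed tree is assembled from a *lineage table* — a parent table with one
row per named node, ``child,parent,divergence_time_years`` — where the
divergence time is the age of the node named by ``child`` (years before
present; 0 for breed tips, which are all contemporaneous). Modern European
breeds, whose individual origins are undated but recent, are attached as a
star polytomy with 200-year terminal branches under a designated clade node;
the ancient Asian breeds (Tibetan mastiff, jindo, chow chow) form a polytomy
with 500-year terminal branches because their relative branching order is
unresolved.

Under Brownian-motion trait evolution the phylogenetic covariance between two
tips is the shared time from the root to their most recent common ancestor.
Pagel's branch-length transforms distort that covariance:

* kappa — exponent on individual branch lengths (kappa -> 0 concentrates
  change at divergence events, i.e. punctuational evolution);
* delta — exponent on node depths / covariance entries, rescaled to preserve
  tree height (delta > 1 means accelerating, recent trait evolution);
* lambda — multiplier on off-diagonal covariances (0 = star phylogeny, no
  signal; 1 = full Brownian expectation).

The composition order is fixed: kappa on branches, then the covariance is
built, then delta on its entries, then lambda on the off-diagonals;
(1, 1, 1) is the identity.

The bundled ``synthetic_ancient_lineages.csv`` is a synthetic reconstruction
of the ancient-breed lineage diagram with plausible (not literature-exact)
divergence dates; it exists so the full pipeline runs without external data.
"""

from __future__ import annotations

import importlib.resources
import warnings

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "build_tree",
    "tree_to_covariance",
    "apply_kappa",
    "apply_delta",
    "apply_lambda",
    "pagel_covariance",
    "is_ultrametric",
    "read_lineage_csv",
    "load_default_lineages",
    "read_newick",
    "write_newick",
    "tree_depth",
]

#: branch lengths of exactly zero (tied divergence times) are nudged to this
ZERO_BRANCH = 1e-6


def read_lineage_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"child", "parent", "divergence_time_years"}
    if not need <= set(df.columns):
        raise ValueError(f"lineage table must have columns {sorted(need)}")
    return df


def load_default_lineages() -> pd.DataFrame:
    """Bundled synthetic ancient-breed lineage table (see module docstring)."""
    ref = importlib.resources.files("canine_lag.data") / "synthetic_ancient_lineages.csv"
    with importlib.resources.as_file(ref) as p:
        return read_lineage_csv(p)


def _lineage_heights(lineages: pd.DataFrame) -> tuple[str, dict[str, str], dict[str, float]]:
    """Validate the parent table; return (root, parent-of, height-of)."""
    parent_of: dict[str, str] = {}
    height: dict[str, float] = {}
    roots = []
    for _, row in lineages.iterrows():
        child = str(row["child"]).strip()
        parent = row["parent"]
        t = float(row["divergence_time_years"])
        if child in height:
            raise ValueError(f"duplicate node in lineage table: {child!r}")
        height[child] = t
        if pd.isna(parent) or str(parent).strip() == "":
            roots.append(child)
        else:
            parent_of[child] = str(parent).strip()
    # names used as parents but never defined are implicit extra roots
    undefined = set(parent_of.values()) - set(height)
    if undefined:
        raise ValueError(f"parents without a defining row: {sorted(undefined)}")
    if len(roots) != 1:
        raise ValueError(f"lineage table must have exactly one root, found {roots}")
    root = roots[0]
    # cycle check + monotone times
    for node in height:
        seen = {node}
        cur = node
        while cur in parent_of:
            cur = parent_of[cur]
            if cur in seen:
                raise ValueError(f"cycle in lineage table involving {cur!r}")
            seen.add(cur)
        if cur != root:
            raise ValueError(f"node {node!r} does not descend from the root")
    for child, parent in parent_of.items():
        if height[parent] < height[child]:
            raise ValueError(
                f"divergence times must decrease towards the tips: "
                f"{child!r} ({height[child]}) under {parent!r} ({height[parent]})"
            )
    return root, parent_of, height


def build_tree(
    lineages: pd.DataFrame | None,
    modern_breeds: list[str],
    modern_branch: float = 200.0,
    asian_polytomy_branch: float = 500.0,
    modern_clade: str = "modern",
    asian_clade: str = "asian",
) -> dendropy.Tree:
    """Build the ultrametric time-scaled breed tree.

    Parameters
    ----------
    lineages : DataFrame or None
        Parent table ``child,parent,divergence_time_years``. ``None`` or an
        empty table yields a pure star phylogeny of the modern breeds with
        terminal branches of ``modern_branch`` years.
    modern_breeds : list of str
        Breeds attached as a star polytomy under the ``modern_clade`` node.
    modern_branch, asian_polytomy_branch : float
        Terminal branch lengths (years) for the modern polytomy and for the
        unresolved Asian ancient polytomy. These override the heights of the
        ``modern_clade`` / ``asian_clade`` nodes if present in the table.
    """
    modern_breeds = [str(b) for b in modern_breeds]
    if len(set(modern_breeds)) != len(modern_breeds):
        raise ValueError("duplicate modern breed names")

    if lineages is None or len(lineages) == 0:
        if not modern_breeds:
            raise ValueError("no lineages and no modern breeds: nothing to build")
        root, parent_of, height = modern_clade, {}, {modern_clade: float(modern_branch)}
    else:
        root, parent_of, height = _lineage_heights(lineages)
        if modern_breeds and modern_clade not in height:
            raise ValueError(
                f"modern clade node {modern_clade!r} not present in the lineage table"
            )
        if modern_clade in height:
            height[modern_clade] = float(modern_branch)
        if asian_clade in height:
            height[asian_clade] = float(asian_polytomy_branch)

    children: dict[str, list[str]] = {}
    for child, parent in parent_of.items():
        children.setdefault(parent, []).append(child)
    for b in modern_breeds:
        if b in height:
            raise ValueError(f"modern breed {b!r} already in the lineage table")
        height[b] = 0.0
        parent_of[b] = modern_clade
        children.setdefault(modern_clade, []).append(b)

    tips = [n for n in height if n not in children]
    for t in tips:
        if height[t] != 0.0:
            raise ValueError(
                f"tip {t!r} has non-zero divergence time {height[t]}; all tips "
                "must be breeds at the present"
            )
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate tip names")
    if len(tips) < 2:
        raise ValueError("tree needs at least two tips")

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[str, dendropy.Node] = {root: tree.seed_node}
    zero_branches = 0

    def attach(name: str) -> None:
        nonlocal zero_branches
        node = nodes[name]
        for child in sorted(children.get(name, [])):
            blen = height[name] - height[child]
            if blen == 0.0:
                blen = ZERO_BRANCH
                zero_branches += 1
            cnode = node.new_child(edge_length=blen)
            nodes[child] = cnode
            attach(child)

    attach(root)
    for name in tips:
        nodes[name].taxon = taxa.new_taxon(label=name)
    if zero_branches:
        warnings.warn(
            f"{zero_branches} zero-length branch(es) from tied divergence times "
            f"replaced by {ZERO_BRANCH} yr",
            UserWarning,
            stacklevel=2,
        )
    return tree


def _tip_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = float(node.edge.length or 0.0)
        else:
            depth[node] = depth[node.parent_node] + float(node.edge.length or 0.0)
    return depth


def tree_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length (tree height, in branch-length units)."""
    d = _tip_depths(tree)
    return max(d[leaf] for leaf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, rtol: float = 1e-6) -> bool:
    d = _tip_depths(tree)
    depths = np.array([d[leaf] for leaf in tree.leaf_node_iter()])
    return bool(depths.max() - depths.min() <= rtol * max(depths.max(), 1e-300))


def tree_to_covariance(tree: dendropy.Tree, check_ultrametric: bool = True) -> pd.DataFrame:
    """Brownian-motion covariance: V[i, j] = root-to-MRCA time of tips i, j.

    The diagonal holds each tip's root-to-tip depth (all equal for an
    ultrametric tree). A non-ultrametric tree triggers a warning and proceeds
    with per-tip depths (``check_ultrametric=False`` silences the warning,
    e.g. after a kappa transform, which deliberately unbalances depths).
    """
    if check_ultrametric and not is_ultrametric(tree):
        warnings.warn(
            "tree is not ultrametric; using per-tip root-to-tip depths on the "
            "diagonal",
            UserWarning,
            stacklevel=2,
        )
    depth = _tip_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    idx = {leaf: i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))
    # postorder sweep: cross-subtree pairs coalesce at the current node
    subtree: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node]
            V[i, i] = depth[node]
            subtree[node] = [i]
            continue
        groups = [subtree.pop(c) for c in node.child_nodes()]
        h = depth[node]  # time from root to this split
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    V[i, np.array(groups[b])] = h
                    V[np.array(groups[b]), i] = h
        merged: list[int] = []
        for g in groups:
            merged.extend(g)
        subtree[node] = merged
    return pd.DataFrame(V, index=labels, columns=labels)


def apply_kappa(tree: dendropy.Tree, kappa: float) -> dendropy.Tree:
    """Raise every branch length to the power kappa (kappa=0 -> unit branches)."""
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length) ** kappa
    return out


def _as_matrix(V):
    if isinstance(V, pd.DataFrame):
        return V.to_numpy(dtype=float, copy=True), V.index
    return np.array(V, dtype=float, copy=True), None


def apply_delta(V, delta: float):
    """Raise covariance entries to the power delta, preserving tree height.

    Entries are exponentiated and the whole matrix rescaled so the maximum
    diagonal entry keeps its pre-transform value, keeping residual-variance
    estimates comparable across delta.
    """
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    M, index = _as_matrix(V)
    top = float(M.diagonal().max())
    out = M**delta
    if top > 0 and delta != 1.0:
        out *= top / top**delta
    if index is not None:
        return pd.DataFrame(out, index=index, columns=index)
    return out


def apply_lambda(V, lam: float):
    """Scale off-diagonal covariances by lambda (0 = star phylogeny)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    M, index = _as_matrix(V)
    d = M.diagonal().copy()
    M *= lam
    np.fill_diagonal(M, d)
    if index is not None:
        return pd.DataFrame(M, index=index, columns=index)
    return M


def pagel_covariance(
    tree: dendropy.Tree,
    lam: float = 1.0,
    kappa: float = 1.0,
    delta: float = 1.0,
) -> pd.DataFrame:
    """Covariance under the fixed transform order kappa -> delta -> lambda."""
    t = apply_kappa(tree, kappa) if kappa != 1.0 else tree
    V = tree_to_covariance(t, check_ultrametric=(kappa == 1.0))
    V = apply_delta(V, delta)
    return apply_lambda(V, lam)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".8f",
    )
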