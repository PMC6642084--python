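"""Phylogeny handling and tree-level skew scans.

Trees are dendropy ``Tree`` objects (rooted; polytomies allowed; branch
lengths optional and ignored by all statistics — the tests here are purely
topological). On top of plain I/O, pruning and re-rooting, this module
implements the two tree procedures of the analysis:

* ``branch_scan`` — descend the tree cut by cut, from the root split down to
  single leaves, and at each newly exposed cluster test the segregation of
  HMM-positive and HMM-negative samples (cluster vs. the rest of the tree,
  exact 2x2 Fisher). The minimal-p cluster per HMM is the best candidate
  branch for a gain or loss event.
* ``simplify_tree`` — collapse nodes whose daughter branches fail to improve
  substantially the significance of any HMM, leaving a small set of terminal
  clusters that carries all the statistical signal.

Internal nodes are addressed by stable preorder ids ``N0`` (root), ``N1``,
...; leaves by their sample labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy

from .errors import FormatError, ParameterError
from .fisher import FisherResult, fisher_exact_2xk
from .hits import PresenceMatrix

DEFAULT_ALPHA = 1e-3
DEFAULT_IMPROVEMENT_FACTOR = 10.0


# ---------------------------------------------------------------------------
# tree I/O and surgery

def _index_nodes(tree: dendropy.Tree) -> None:
    """Assign stable ids: internal nodes N0.. in preorder, leaves their
    taxon label. Also caches per-node depth and preorder rank."""
    counter = 0
    for rank, node in enumerate(tree.preorder_node_iter()):
        if node.is_leaf():
            node.node_id = node.taxon.label
        else:
            node.node_id = f"N{counter}"
            counter += 1
        node.preorder_rank = rank
        node.depth = 0 if node.parent_node is None else node.parent_node.depth + 1


def _check_unique_leaves(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    seen, dups = set(), set()
    for lab in labels:
        if lab in seen:
            dups.add(lab)
        seen.add(lab)
    if dups:
        raise FormatError(f"duplicate leaf labels: {sorted(dups)}")


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree (quoted labels and
    polytomies supported; duplicate leaf labels rejected)."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise FormatError(f"duplicate leaf labels in Newick input: {exc}") from exc
    except Exception as exc:  # dendropy raises schema-specific parse errors
        raise FormatError(f"Newick parse error: {exc}") from exc
    tree.is_rooted = True
    _check_unique_leaves(tree)
    _index_nodes(tree)
    return tree


def read_newick(path) -> dendropy.Tree:
    """Read a rooted tree from a Newick file."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    except OSError as exc:
        raise FormatError(f"cannot read tree file {path}: {exc}") from exc
    return parse_newick(text)


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_newick(tree))


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True)


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_to(tree: dendropy.Tree, sample_ids: Sequence[str]) -> dendropy.Tree:
    """Restrict the tree to ``sample_ids``. Degree-2 internal nodes created
    by the pruning are suppressed, with branch lengths summed through them.
    Returns a new tree; the input is untouched."""
    wanted = list(dict.fromkeys(sample_ids))
    if not wanted:
        raise ParameterError("cannot prune to an empty sample set")
    have = set(leaf_labels(tree))
    unknown = [s for s in wanted if s not in have]
    if unknown:
        raise FormatError(f"samples not in tree: {unknown}")
    pruned = tree.extract_tree_with_taxa_labels(labels=wanted)
    pruned.is_rooted = True
    _index_nodes(pruned)
    return pruned


def reroot_on(tree: dendropy.Tree, outgroup: Sequence[str]) -> dendropy.Tree:
    """Re-root so the root separates ``outgroup`` from all other leaves.

    The outgroup must form a clade in the unrooted sense (i.e. either it or
    its complement is monophyletic on the current rooting) and must be a
    proper non-empty subset of the leaves. Returns a new tree.
    """
    out = set(outgroup)
    leaves = set(leaf_labels(tree))
    if not out or not out <= leaves:
        raise ParameterError(f"outgroup must be a non-empty subset of leaves; "
                             f"unknown: {sorted(out - leaves)}")
    if out == leaves:
        raise ParameterError("outgroup cannot be the entire leaf set")
    work = tree.clone(depth=1)
    work.is_rooted = True

    def _clade_node(labels: set[str]):
        mrca = work.mrca(taxon_labels=sorted(labels))
        if mrca is None:
            return None
        span = {l.taxon.label for l in mrca.leaf_iter()}
        return mrca if span == labels else None

    target = _clade_node(out) or _clade_node(leaves - out)
    if target is None:
        raise FormatError("outgroup is not monophyletic (unrooted sense)")
    if target.parent_node is not None:
        length = target.edge.length
        if length is not None:
            work.reroot_at_edge(target.edge, length1=length / 2.0,
                                length2=length / 2.0)
        else:
            work.reroot_at_edge(target.edge)
    work.is_rooted = True
    _index_nodes(work)
    return work


# ---------------------------------------------------------------------------
# tree cutting

@dataclass(frozen=True)
class Cluster:
    """One cluster of a tree cut: the subtree node it derives from and the
    samples beneath it."""

    node_id: str
    samples: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class ClusterPartition:
    """An ordered, disjoint, covering partition of the leaf set into
    tree-derived clusters (reported in tree preorder)."""

    clusters: tuple[Cluster, ...]

    def __post_init__(self):
        seen: set[str] = set()
        for cluster in self.clusters:
            if not cluster.samples:
                raise ParameterError("empty cluster in partition")
            if seen & cluster.samples:
                raise ParameterError("overlapping clusters in partition")
            seen |= cluster.samples
        object.__setattr__(self, "_all_samples", frozenset(seen))

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def samples(self) -> frozenset[str]:
        return self._all_samples

    def sizes(self) -> tuple[int, ...]:
        return tuple(c.size for c in self.clusters)


def _cut_schedule(tree: dendropy.Tree) -> list[list[dendropy.Node]]:
    """Successive cluster lists obtained by cutting the tree one node at a
    time, starting from the root split and expanding internal nodes in
    breadth-first (shallowest-first) order, ties broken by preorder rank.

    Element 0 is the root's children; each following element refines the
    previous by replacing exactly one internal node with its children, so the
    last element is the full leaf set as singletons.
    """
    root = tree.seed_node
    if len(root.child_nodes()) == 0:
        raise ParameterError("tree must have at least 2 leaves")
    active: list[dendropy.Node] = list(root.child_nodes())
    schedule = [list(active)]
    while True:
        internal = [n for n in active if not n.is_leaf()]
        if not internal:
            break
        nxt = min(internal, key=lambda n: (n.depth, n.preorder_rank))
        idx = active.index(nxt)
        active = active[:idx] + list(nxt.child_nodes()) + active[idx + 1:]
        schedule.append(list(active))
    return schedule


def _node_cluster(node: dendropy.Node) -> Cluster:
    return Cluster(node.node_id,
                   frozenset(l.taxon.label for l in node.leaf_iter()))


def cut_levels(tree: dendropy.Tree) -> list[ClusterPartition]:
    """The sequence of strictly refining partitions produced by successive
    node cuts (see ``_cut_schedule``), as ``ClusterPartition`` objects."""
    if not hasattr(tree.seed_node, "node_id"):
        _index_nodes(tree)
    return [ClusterPartition(tuple(_node_cluster(n) for n in nodes))
            for nodes in _cut_schedule(tree)]


# ---------------------------------------------------------------------------
# per-branch scanning

@dataclass(frozen=True)
class SplitResult:
    """Exact segregation test for one cluster exposed at one cut level:
    samples inside the cluster vs. all other samples, positives counted per
    side. ``is_best`` marks the minimal-p cluster for the HMM across the
    whole descent; ``significant`` flags p < alpha."""

    hmm_id: str
    level: int
    node_id: str
    n_in: int
    positives_in: int
    n_out: int
    positives_out: int
    p_value: float
    log10_p: float
    is_best: bool
    significant: bool


def _check_matrix_tree(matrix: PresenceMatrix, tree: dendropy.Tree) -> None:
    leaves = set(leaf_labels(tree))
    samples = set(matrix.samples)
    if leaves != samples:
        only_tree = sorted(leaves - samples)
        only_matrix = sorted(samples - leaves)
        raise FormatError(
            f"tree leaves and matrix samples differ; only in tree: "
            f"{only_tree}; only in matrix: {only_matrix}")


def _segregation_p(n_in: int, k_in: int, n_out: int, k_out: int) -> FisherResult:
    if n_out == 0:
        return FisherResult(1.0, 0.0)
    return fisher_exact_2xk((n_in, n_out), (k_in, k_out))


def branch_scan(tree: dendropy.Tree, matrix: PresenceMatrix,
                alpha: float = DEFAULT_ALPHA) -> list[SplitResult]:
    """Scan every cut level of the tree for every HMM.

    Cut level 1 exposes the root's child clusters; each subsequent level
    expands one internal node (breadth-first) and exposes its children. The
    cluster exposed is tested against the rest of the tree with the exact
    2x2 Fisher test. Results are ordered by HMM, then level, then preorder;
    exactly one row per HMM carries ``is_best`` (minimal p, ties resolved to
    the earliest level then lowest preorder rank).
    """
    if not 0 < alpha <= 1:
        raise ParameterError(f"alpha must be in (0, 1], got {alpha!r}")
    _check_matrix_tree(matrix, tree)
    if not hasattr(tree.seed_node, "node_id"):
        _index_nodes(tree)
    schedule = _cut_schedule(tree)
    n_total = len(matrix.samples)

    results: list[SplitResult] = []
    per_hmm_rows: dict[str, list[int]] = {h: [] for h in matrix.hmms}
    # nodes newly exposed at each level: level 1 = root children, then the
    # children of the node expanded at each step
    exposed: list[tuple[int, dendropy.Node]] = [(1, n) for n in schedule[0]]
    previous = set(id(n) for n in schedule[0])
    for level_idx in range(1, len(schedule)):
        new_nodes = [n for n in schedule[level_idx] if id(n) not in previous]
        exposed.extend((level_idx + 1, n) for n in new_nodes)
        previous |= {id(n) for n in new_nodes}

    cluster_cache = {n.node_id: _node_cluster(n) for _, n in exposed}
    for hmm in matrix.hmms:
        col = matrix.calls[hmm]
        k_total = int(col.sum())
        for level, node in exposed:
            cluster = cluster_cache[node.node_id]
            n_in = cluster.size
            k_in = int(col[list(cluster.samples)].sum())
            res = _segregation_p(n_in, k_in, n_total - n_in, k_total - k_in)
            per_hmm_rows[hmm].append(len(results))
            results.append(SplitResult(
                hmm, level, node.node_id, n_in, k_in,
                n_total - n_in, k_total - k_in,
                res.p_value, res.log10_p,
                is_best=False, significant=res.p_value < alpha))

    # mark the best (minimal-p) row per HMM
    rank = {n.node_id: n.preorder_rank for _, n in exposed}
    final: list[SplitResult] = list(results)
    for hmm, rows in per_hmm_rows.items():
        if not rows:
            continue
        best = min(rows, key=lambda i: (results[i].p_value, results[i].level,
                                        rank[results[i].node_id]))
        r = results[best]
        final[best] = SplitResult(r.hmm_id, r.level, r.node_id, r.n_in,
                                  r.positives_in, r.n_out, r.positives_out,
                                  r.p_value, r.log10_p, True, r.significant)
    return final


def best_splits(results: Sequence[SplitResult]) -> dict[str, SplitResult]:
    """The minimal-p row per HMM from a ``branch_scan`` result list."""
    return {r.hmm_id: r for r in results if r.is_best}


def simplify_tree(tree: dendropy.Tree, matrix: PresenceMatrix,
                  alpha: float = DEFAULT_ALPHA,
                  improvement_factor: float = DEFAULT_IMPROVEMENT_FACTOR,
                  ) -> ClusterPartition:
    """Collapse uninformative nodes into terminal clusters.

    A clade (any non-root node) is *qualified* when, for at least one HMM,
    its segregation p-value is below ``alpha`` AND below its parent clade's
    p-value divided by ``improvement_factor`` — i.e. splitting the parent
    substantially improves the significance of that HMM. Terminal clusters
    are formed by grouping every sample under its deepest qualified ancestor
    (the sample itself counts, so a single leaf can form a cluster); samples
    with no qualified ancestor are merged upward into one residual cluster
    attributed to the root. With a uniform matrix nothing qualifies and the
    result is a single cluster of all leaves.
    """
    if not 0 < alpha <= 1:
        raise ParameterError(f"alpha must be in (0, 1], got {alpha!r}")
    if improvement_factor < 1:
        raise ParameterError(
            f"improvement_factor must be >= 1, got {improvement_factor!r}")
    _check_matrix_tree(matrix, tree)
    if not hasattr(tree.seed_node, "node_id"):
        _index_nodes(tree)
    n_total = len(matrix.samples)
    columns = {h: matrix.calls[h] for h in matrix.hmms}
    totals = {h: int(col.sum()) for h, col in columns.items()}

    # per-node segregation p for every HMM; root has p = 1 by convention
    node_p: dict[int, dict[str, float]] = {}
    node_leaves: dict[int, list[str]] = {}
    for node in tree.preorder_node_iter():
        leaves = [l.taxon.label for l in node.leaf_iter()]
        node_leaves[id(node)] = leaves
        if node.parent_node is None:
            node_p[id(node)] = {h: 1.0 for h in matrix.hmms}
            continue
        n_in = len(leaves)
        ps = {}
        for hmm, col in columns.items():
            k_in = int(col[leaves].sum())
            ps[hmm] = _segregation_p(n_in, k_in, n_total - n_in,
                                     totals[hmm] - k_in).p_value
        node_p[id(node)] = ps

    def qualified(node: dendropy.Node) -> bool:
        if node.parent_node is None:
            return False
        parent_ps = node_p[id(node.parent_node)]
        own = node_p[id(node)]
        return any(own[h] < alpha and own[h] < parent_ps[h] / improvement_factor
                   for h in matrix.hmms)

    qualified_nodes = [n for n in tree.preorder_node_iter() if qualified(n)]

    assigned: dict[str, dendropy.Node] = {}
    for node in qualified_nodes:  # preorder: deeper nodes overwrite ancestors
        for leaf in node_leaves[id(node)]:
            assigned[leaf] = node

    clusters: dict[int, list[str]] = {}
    for node in qualified_nodes:
        members = [l for l in node_leaves[id(node)]
                   if assigned.get(l) is node]
        if members:
            clusters[id(node)] = members
    residual = [l for l in node_leaves[id(tree.seed_node)] if l not in assigned]

    ordered: list[Cluster] = []
    if residual:
        ordered.append(Cluster(tree.seed_node.node_id, frozenset(residual)))
    for node in qualified_nodes:
        if id(node) in clusters:
            ordered.append(Cluster(node.node_id, frozenset(clusters[id(node)])))
    # report in tree preorder of provenance nodes (residual carries the root)
    rank = {n.node_id: n.preorder_rank for n in tree.preorder_node_iter()}
    ordered.sort(key=lambda c: rank[c.node_id])
    return ClusterPartition(tuple(ordered))
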