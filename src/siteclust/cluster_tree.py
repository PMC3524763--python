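"""Hierarchical cluster tree over a k-sweep of attribute clusters.

As k decreases from N-1 to 2, clusters of interdependent sites merge into
larger ones.  Arranging the distinct clusters by *order* (site count) and
linking each to the next-larger cluster that absorbs most of its sites
yields a cluster tree.  A maximal chain followed downward from a
lowest-order cluster is a *branch*; branches are numbered left to right by
their smallest site label, mirroring sequence position.  A branch whose
clusters share no sites with other branches' clusters is *Type I*
(self-contained); one whose sites interlace with other branches is
*Type II*.  A *node* is a cluster where two or more branches converge, and
the set of branches converging there forms a *module* — strongly
interlacing branch groups with no common node may also be declared a
module.  Per branch, a *representative cluster* is chosen by maximal
SR(mode), preferring a higher-order cluster whose SR(mode) comes within a
relative tolerance of the best.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from siteclust.kmodes import ClusterConfiguration


@dataclass(frozen=True)
class TreeNode:
    """One distinct cluster (identified by its site set) in the tree."""

    sites: frozenset[int]
    order: int
    ks: tuple[int, ...]  #: every k at which this exact cluster appeared
    mode: int
    sr_mode: float

    @property
    def key(self) -> frozenset[int]:
        return self.sites

    def sorted_sites(self) -> tuple[int, ...]:
        return tuple(sorted(self.sites))


@dataclass(frozen=True)
class Branch:
    """A maximal nesting chain followed from one lowest-order cluster."""

    index: int  #: 1-based, numbered left to right by minimum site label
    chain: tuple[TreeNode, ...]  #: ordered by increasing order
    branch_type: str | None = None  #: "I" or "II" once classified

    def all_sites(self) -> frozenset[int]:
        out: set[int] = set()
        for node in self.chain:
            out |= node.sites
        return frozenset(out)


@dataclass(frozen=True)
class Module:
    """A group of branches converging at a node (or strongly interlacing)."""

    branches: tuple[int, ...]
    kind: str  #: "converging" or "interlaced"
    node_sites: frozenset[int] | None = None  #: converging cluster, if any


@dataclass
class ClusterTree:
    """Nodes, nesting edges, branches and modules of a k-sweep."""

    nodes: dict[frozenset[int], TreeNode] = field(default_factory=dict)
    parent: dict[frozenset[int], frozenset[int]] = field(default_factory=dict)
    branches: list[Branch] = field(default_factory=list)
    modules: list[Module] = field(default_factory=list)
    representatives: dict[int, TreeNode] = field(default_factory=dict)

    def node_branches(self, sites: frozenset[int]) -> set[int]:
        """Indices of the branches whose chain contains this cluster."""
        return {
            b.index
            for b in self.branches
            if any(nd.sites == sites for nd in b.chain)
        }

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "sites": sorted(nd.sites),
                    "order": nd.order,
                    "ks": list(nd.ks),
                    "mode": nd.mode,
                    "sr_mode": nd.sr_mode,
                }
                for nd in sorted(
                    self.nodes.values(), key=lambda n: (n.order, n.sorted_sites())
                )
            ],
            "edges": [
                {"child": sorted(c), "parent": sorted(p)}
                for c, p in sorted(
                    self.parent.items(), key=lambda cp: sorted(cp[0])
                )
            ],
            "branches": [
                {
                    "index": b.index,
                    "type": b.branch_type,
                    "chain": [sorted(nd.sites) for nd in b.chain],
                }
                for b in self.branches
            ],
            "modules": [
                {
                    "branches": list(m.branches),
                    "kind": m.kind,
                    "node_sites": sorted(m.node_sites) if m.node_sites else None,
                }
                for m in self.modules
            ],
            "representatives": {
                str(i): {
                    "sites": sorted(nd.sites),
                    "order": nd.order,
                    "mode": nd.mode,
                    "sr_mode": nd.sr_mode,
                }
                for i, nd in sorted(self.representatives.items())
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_dot(self) -> str:
        """Graphviz DOT rendering of the nesting graph."""
        def name(sites: frozenset[int]) -> str:
            return '"' + "-".join(str(s) for s in sorted(sites)) + '"'

        lines = ["digraph clustertree {", "  rankdir=TB;"]
        for nd in sorted(self.nodes.values(), key=lambda n: (n.order, n.sorted_sites())):
            label = ",".join(str(s) for s in nd.sorted_sites())
            lines.append(
                f'  {name(nd.sites)} [label="{label}\\nSR(mode)={nd.sr_mode:.3f}"];'
            )
        for child, par in sorted(self.parent.items(), key=lambda cp: sorted(cp[0])):
            lines.append(f"  {name(child)} -> {name(par)};")
        lines.append("}")
        return "\n".join(lines)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.branches:
            rep = self.representatives.get(b.index)
            module = next(
                (i for i, m in enumerate(self.modules, 1) if b.index in m.branches),
                None,
            )
            rows.append(
                {
                    "branch": b.index,
                    "type": b.branch_type,
                    "depth": len(b.chain),
                    "module": module,
                    "representative_sites": ",".join(
                        str(s) for s in rep.sorted_sites()
                    )
                    if rep
                    else "",
                    "representative_sr_mode": rep.sr_mode if rep else float("nan"),
                }
            )
        return pd.DataFrame(rows)


def _dedup_nodes(configs: Sequence[ClusterConfiguration]) -> dict[frozenset[int], TreeNode]:
    nodes: dict[frozenset[int], dict] = {}
    for cfg in configs:
        for c, members in enumerate(cfg.clusters):
            key = frozenset(members)
            if key not in nodes:
                nodes[key] = {
                    "ks": [],
                    "mode": cfg.modes[c],
                    "sr_mode": cfg.sr_mode[c],
                }
            nodes[key]["ks"].append(cfg.k)
    return {
        key: TreeNode(
            sites=key,
            order=len(key),
            ks=tuple(sorted(info["ks"], reverse=True)),
            mode=info["mode"],
            sr_mode=info["sr_mode"],
        )
        for key, info in nodes.items()
    }


def build_tree(
    configs: Sequence[ClusterConfiguration],
    *,
    min_interlace: int = 1,
    module_min_shared: int = 2,
    representative_tolerance: float = 0.05,
) -> ClusterTree:
    """Assemble a cluster tree from a k-sweep.

    Identical clusters recurring at several k values collapse to one tree
    node.  A cluster is linked to a parent found in the configuration at
    the next smaller k after its last appearance: the parent must have
    strictly larger order and contain a strict majority of the child's
    sites; among qualifying parents the one with maximal overlap wins
    (ties: smaller parent order, then lowest mode label).  Clusters with no
    qualifying parent stay unattached — they may still be structurally or
    functionally meaningful and are kept in the tree.  Branches, branch
    types, modules and per-branch representatives are derived afterwards.
    """
    if not configs:
        raise ValueError("no cluster configurations given")
    configs = sorted(configs, key=lambda c: -c.k)
    ks = [c.k for c in configs]
    by_k = {c.k: c for c in configs}
    nodes = _dedup_nodes(configs)

    tree = ClusterTree(nodes=nodes)

    # Nesting edges (only clusters of order >= 2 take part in nesting;
    # singletons remain isolated nodes).
    for key, node in nodes.items():
        if node.order < 2:
            continue
        k_last = min(node.ks)
        lower = [k for k in ks if k < k_last]
        if not lower:
            continue
        next_k = max(lower)
        candidates = []
        for c, members in enumerate(by_k[next_k].clusters):
            cand = frozenset(members)
            if len(cand) <= node.order:
                continue
            overlap = len(cand & key)
            if overlap * 2 > node.order:
                candidates.append(
                    (overlap, -len(cand), -by_k[next_k].modes[c], cand)
                )
        if candidates:
            candidates.sort(
                key=lambda t: (t[0], t[1], t[2]), reverse=True
            )
            tree.parent[key] = candidates[0][3]

    # Branches: chains followed from each lowest-order (no child) cluster
    # of order >= 2.  Singletons stay as isolated nodes.
    has_child = set(tree.parent.values())
    leaves = [
        nd
        for nd in nodes.values()
        if nd.order >= 2 and nd.sites not in has_child
    ]
    leaves.sort(key=lambda nd: (min(nd.sites), nd.order, nd.sorted_sites()))
    branches = []
    for idx, leaf in enumerate(leaves, start=1):
        chain = [leaf]
        cur = leaf.sites
        while cur in tree.parent:
            cur = tree.parent[cur]
            chain.append(nodes[cur])
        branches.append(Branch(index=idx, chain=tuple(chain)))
    tree.branches = branches

    tree.branches = [
        Branch(
            index=b.index,
            chain=b.chain,
            branch_type=classify_branch(b, tree, min_interlace=min_interlace),
        )
        for b in branches
    ]
    tree.modules = detect_modules(tree, min_shared=module_min_shared)
    tree.representatives = {
        b.index: select_representative(b, tolerance=representative_tolerance)
        for b in tree.branches
    }
    return tree


def classify_branch(
    branch: Branch, tree: ClusterTree, *, min_interlace: int = 1
) -> str:
    """Type II when >= ``min_interlace`` of the branch's own sites occur in
    a cluster belonging to a different branch; Type I otherwise.

    "Own sites" are the sites of the clusters exclusive to this branch.
    Clusters where branches converge belong to every converging branch, so
    neither they nor their sites count as interlacing: two branches that
    merge cleanly at a node stay Type I, while branches whose
    pre-convergence clusters straddle one another become Type II.
    """
    membership = {
        nd.sites: tree.node_branches(nd.sites) for nd in tree.nodes.values()
    }
    own_sites: set[int] = set()
    for nd in branch.chain:
        if membership[nd.sites] == {branch.index}:
            own_sites |= nd.sites
    interlaced_sites: set[int] = set()
    for site in own_sites:
        for sites, owners in membership.items():
            if not owners or branch.index in owners:
                continue
            if site in sites:
                interlaced_sites.add(site)
                break
    return "II" if len(interlaced_sites) >= min_interlace else "I"


def detect_modules(tree: ClusterTree, *, min_shared: int = 2) -> list[Module]:
    """Group branches into modules.

    Branches whose chains reach a common cluster (a node) form a converging
    module; a connected set of such nodes merges its branches into one
    module.  Among the remaining branches, groups in which branches pairwise
    share at least ``min_shared`` sites are declared interlaced modules.
    """
    g = nx.Graph()
    g.add_nodes_from(b.index for b in tree.branches)
    node_info: dict[frozenset[int], set[int]] = {}
    for nd in tree.nodes.values():
        owners = tree.node_branches(nd.sites)
        if len(owners) >= 2:
            node_info[nd.sites] = owners
            for a in owners:
                for b in owners:
                    if a < b:
                        g.add_edge(a, b, converging=True)
    modules: list[Module] = []
    converged: set[int] = set()
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if len(comp) < 2:
            continue
        # the largest shared cluster reached by branches of this component
        shared = [
            s
            for s, owners in node_info.items()
            if owners & set(comp)
        ]
        biggest = max(shared, key=len) if shared else None
        modules.append(
            Module(branches=tuple(comp), kind="converging", node_sites=biggest)
        )
        converged |= set(comp)

    rest = [b for b in tree.branches if b.index not in converged]
    h = nx.Graph()
    h.add_nodes_from(b.index for b in rest)
    sites_of = {b.index: b.all_sites() for b in rest}
    for i, a in enumerate(rest):
        for b in rest[i + 1:]:
            if len(sites_of[a.index] & sites_of[b.index]) >= min_shared:
                h.add_edge(a.index, b.index)
    for comp in nx.connected_components(h):
        comp = sorted(comp)
        if len(comp) >= 2:
            modules.append(Module(branches=tuple(comp), kind="interlaced"))
    modules.sort(key=lambda m: m.branches[0])
    return modules


def select_representative(
    branch: Branch, *, tolerance: float = 0.05
) -> TreeNode:
    """The branch's cluster with the highest SR(mode), preferring order.

    Any cluster whose SR(mode) is within a relative ``tolerance`` of the
    branch maximum competes; among those the highest order wins (then
    higher SR(mode), then lowest mode label).  A slightly weaker but larger
    cluster is therefore preferred, because it covers more sites.
    """
    if not branch.chain:
        raise ValueError("branch is empty")
    best = max(nd.sr_mode for nd in branch.chain)
    eligible = [
        nd for nd in branch.chain if nd.sr_mode >= best * (1.0 - tolerance)
    ]
    eligible.sort(key=lambda nd: (-nd.order, -nd.sr_mode, nd.mode))
    return eligible[0]
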