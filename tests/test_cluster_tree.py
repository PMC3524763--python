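"""Cluster-tree assembly: nesting, branches, types, modules, representatives."""

import numpy as np
import pytest

from siteclust.cluster_tree import (
    Branch,
    TreeNode,
    build_tree,
    classify_branch,
    detect_modules,
    select_representative,
)
from siteclust.kmodes import ClusterConfiguration

from conftest import rmat_from_R


def config(k, clusters, sr_modes=None, modes=None):
    """Hand-built ClusterConfiguration for tree tests."""
    clusters = tuple(frozenset(c) for c in clusters)
    if modes is None:
        modes = tuple(min(c) for c in clusters)
    if sr_modes is None:
        sr_modes = tuple(0.5 if len(c) > 1 else 0.0 for c in clusters)
    return ClusterConfiguration(
        k=k,
        clusters=clusters,
        modes=tuple(modes),
        sr_mode=tuple(sr_modes),
        iterations=1,
        seed=0,
        converged=True,
        objective=0.0,
    )


def node(sites, sr_mode=0.5, ks=(3,)):
    sites = frozenset(sites)
    return TreeNode(
        sites=sites, order=len(sites), ks=ks, mode=min(sites), sr_mode=sr_mode
    )


class TestBuildTree:
    def test_single_nested_chain(self):
        # {1,3} < {1,3,5} < {1,3,5,7} across k = 7, 6, 5 (padding singletons)
        all_sites = set(range(1, 9))
        cfgs = [
            config(7, [{1, 3}] + [{s} for s in sorted(all_sites - {1, 3})]),
            config(6, [{1, 3, 5}] + [{s} for s in sorted(all_sites - {1, 3, 5})]),
            config(5, [{1, 3, 5, 7}] + [{s} for s in sorted(all_sites - {1, 3, 5, 7})]),
        ]
        tree = build_tree(cfgs)
        assert len(tree.branches) == 1
        chain = [nd.sites for nd in tree.branches[0].chain]
        assert chain == [
            frozenset({1, 3}),
            frozenset({1, 3, 5}),
            frozenset({1, 3, 5, 7}),
        ]
        assert tree.parent[frozenset({1, 3})] == frozenset({1, 3, 5})

    def test_two_chains_merging_form_node_and_module(self):
        cfgs = [
            config(4, [{1, 2}, {3, 4}, {5}, {6}]),
            config(3, [{1, 2}, {3, 4}, {5, 6}]),
            config(2, [{1, 2, 3, 4}, {5, 6}]),
        ]
        tree = build_tree(cfgs)
        assert len(tree.branches) == 3  # {1,2}, {3,4}, {5,6}
        converging = [m for m in tree.modules if m.kind == "converging"]
        assert len(converging) == 1
        assert converging[0].node_sites == frozenset({1, 2, 3, 4})
        assert len(converging[0].branches) == 2

    def test_unattached_cluster_kept(self):
        cfgs = [
            config(3, [{1, 2}, {4, 5}, {7}]),
            config(2, [{1, 2, 7}, {4, 5}]),
        ]
        tree = build_tree(cfgs)
        # {4,5} persists identically at k=2, so it nests nowhere
        assert frozenset({4, 5}) not in tree.parent
        branches = {b.chain[0].sites for b in tree.branches}
        assert frozenset({4, 5}) in branches

    def test_majority_containment_verified_post_hoc(self):
        """Every edge of a randomized sweep satisfies the >50% rule."""
        rng = np.random.default_rng(4)
        N = 10
        labels = np.arange(1, N + 1)
        cfgs = []
        for k in range(6, 1, -1):
            order = rng.permutation(labels)
            cuts = np.sort(rng.choice(np.arange(1, N), size=k - 1, replace=False))
            parts = [set(chunk) for chunk in np.split(order, cuts)]
            cfgs.append(config(k, parts))
        tree = build_tree(cfgs)
        for child, parent in tree.parent.items():
            assert len(parent) > len(child)
            assert 2 * len(child & parent) > len(child)

    def test_every_cluster_appears_once(self):
        cfgs = [
            config(4, [{1, 2}, {3, 4}, {5}, {6}]),
            config(3, [{1, 2}, {3, 4}, {5, 6}]),
            config(2, [{1, 2, 3, 4}, {5, 6}]),
        ]
        tree = build_tree(cfgs)
        seen = set()
        for cfg in cfgs:
            for c in cfg.clusters:
                seen.add(frozenset(c))
        assert set(tree.nodes) == seen

    def test_edges_respect_strictly_increasing_order(self):
        cfgs = [
            config(4, [{1, 2}, {3, 4}, {5}, {6}]),
            config(3, [{1, 2}, {3, 4}, {5, 6}]),
            config(2, [{1, 2, 3, 4}, {5, 6}]),
        ]
        tree = build_tree(cfgs)
        for child, parent in tree.parent.items():
            assert len(parent) > len(child)

    def test_empty_configs_rejected(self):
        with pytest.raises(ValueError):
            build_tree([])


class TestClassifyBranch:
    def test_disjoint_branches_are_type_I(self):
        cfgs = [
            config(4, [{1, 2}, {3, 4}, {5}, {6}]),
            config(3, [{1, 2}, {3, 4}, {5, 6}]),
            config(2, [{1, 2, 3, 4}, {5, 6}]),
        ]
        tree = build_tree(cfgs)
        # branches merge cleanly at {1,2,3,4}; no straddling anywhere
        assert all(b.branch_type == "I" for b in tree.branches)

    def test_straddling_site_makes_both_type_II(self):
        # site 3 belongs to {1,2,3} at k=2 but to {3,4} at k=3: the two
        # chains interlace without converging
        cfgs = [
            config(3, [{1, 2}, {3, 4}, {5}]),
            config(2, [{1, 2, 3}, {4, 5}]),
        ]
        tree = build_tree(cfgs)
        types = {b.chain[0].sites: b.branch_type for b in tree.branches}
        assert types[frozenset({1, 2})] == "II"
        assert types[frozenset({3, 4})] == "II"

    def test_three_interlacing_chains_all_type_II(self):
        # three chains whose deeper clusters absorb a neighbouring leaf's
        # site (the straddling seen among mid-sequence branches)
        cfgs = [
            config(4, [{29, 30}, {34, 35}, {39, 40}, {31}]),
            config(3, [{29, 30, 34}, {35, 39, 40}, {31}]),
        ]
        tree = build_tree(cfgs)
        assert len(tree.branches) == 3
        assert all(b.branch_type == "II" for b in tree.branches)


class TestDetectModules:
    def test_independent_chains_no_modules(self):
        cfgs = [
            config(3, [{1, 2}, {4, 5}, {7}]),
            config(2, [{1, 2, 3}, {4, 5, 6}]),
        ]
        tree = build_tree(cfgs)
        assert tree.modules == []

    def test_interlaced_branches_declared_module(self):
        # three straddling chains that never reach a common cluster
        cfgs = [
            config(3, [{1, 2}, {3, 4}, {5, 6}]),
            config(2, [{1, 2, 3}, {4, 5, 6}]),
        ]
        tree = build_tree(cfgs, module_min_shared=1)
        assert len(tree.branches) == 3
        assert len(tree.modules) == 1
        assert tree.modules[0].kind == "interlaced"
        assert len(tree.modules[0].branches) == 3

    def test_min_shared_threshold(self):
        # chains sharing two sites group at the default threshold; a
        # single shared site needs min_shared=1
        cfgs = [
            config(3, [{1, 2, 3}, {4, 5}, {6}]),
            config(2, [{1, 2, 6}, {3, 4, 5}]),
        ]
        tree = build_tree(cfgs)
        assert len(tree.modules) == 1
        two_shared = tree.modules[0]
        assert two_shared.kind == "interlaced"
        assert len(two_shared.branches) == 2
        loose = build_tree(cfgs, module_min_shared=1)
        assert len(loose.modules) == 1
        assert len(loose.modules[0].branches) == 3


class TestSelectRepresentative:
    def test_clear_maximum_wins(self):
        branch = Branch(
            index=1,
            chain=(node({1, 2, 3, 4}, sr_mode=0.26),
                   node({1, 2, 3, 4, 5, 6}, sr_mode=0.20)),
        )
        rep = select_representative(branch, tolerance=0.05)
        assert rep.sites == frozenset({1, 2, 3, 4})

    def test_within_tolerance_prefers_higher_order(self):
        branch = Branch(
            index=1,
            chain=(node({1, 2, 3}, sr_mode=0.25),
                   node({1, 2, 3, 4, 5}, sr_mode=0.245)),
        )
        rep = select_representative(branch, tolerance=0.05)
        assert rep.sites == frozenset({1, 2, 3, 4, 5})

    def test_single_cluster_branch(self):
        branch = Branch(index=1, chain=(node({7, 9}, sr_mode=0.4),))
        assert select_representative(branch).sites == frozenset({7, 9})


class TestPlantedHierarchyRecovery:
    def test_pairwise_merge_schedule_recovered_exactly(self):
        """Blocks that merge pairwise as k decreases are re-linked exactly."""
        cfgs = [
            config(8, [{1, 2}, {3, 4}, {5, 6}, {7, 8}] + [{s} for s in (9, 10, 11, 12)]),
            config(6, [{1, 2, 3, 4}, {5, 6, 7, 8}, {9}, {10}, {11}, {12}]),
            config(5, [{1, 2, 3, 4, 5, 6, 7, 8}, {9}, {10}, {11}, {12}]),
        ]
        tree = build_tree(cfgs)
        expected = {
            frozenset({1, 2}): frozenset({1, 2, 3, 4}),
            frozenset({3, 4}): frozenset({1, 2, 3, 4}),
            frozenset({5, 6}): frozenset({5, 6, 7, 8}),
            frozenset({7, 8}): frozenset({5, 6, 7, 8}),
            frozenset({1, 2, 3, 4}): frozenset(range(1, 9)),
            frozenset({5, 6, 7, 8}): frozenset(range(1, 9)),
        }
        assert tree.parent == expected

    def test_json_and_dot_exports(self, tmp_path):
        cfgs = [
            config(3, [{1, 2}, {3, 4}, {5}]),
            config(2, [{1, 2, 3, 4}, {5}]),
        ]
        tree = build_tree(cfgs)
        payload = tree.to_json(tmp_path / "tree.json")
        assert (tmp_path / "tree.json").exists()
        assert '"branches"' in payload
        dot = tree.to_dot()
        assert dot.startswith("digraph") and "->" in dot
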