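"""Neighbor joining against exhaustive search, rooting, event placement,
and the deleteriousness ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from mptseq.cluster import CloneProfile
from mptseq.io import MISSING
from mptseq.lineage import (
    annotate_lineage_events,
    build_nj_tree,
    genotype_distance_matrix,
    neighbor_joining,
    rank_deleterious,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def random_additive_tree(n_leaves, rng):
    """Random binary topology with strictly positive branch lengths; returns
    (leaf names, pairwise distance matrix, set of non-trivial splits)."""
    names = [f"t{i}" for i in range(n_leaves)]
    nodes = [TreeNode(name=nm) for nm in names]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        for idx in (j, i):
            child = nodes.pop(idx)
            child.length = float(rng.uniform(0.5, 2.0))
            parent.append(child)
        nodes.append(parent)
    root = TreeNode()
    for child in nodes:
        child.length = float(rng.uniform(0.5, 2.0))
        root.append(child)
    dist = np.zeros((n_leaves, n_leaves))
    tips = {t.name: t for t in root.tips()}
    for a, b in itertools.combinations(names, 2):
        d = tips[a].distance(tips[b])
        dist[names.index(a), names.index(b)] = d
        dist[names.index(b), names.index(a)] = d
    return names, dist, tree_splits(root, set(names))


def tree_splits(tree, all_names):
    """Non-trivial unrooted splits as frozensets (smaller side, canonical)."""
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_names) - 1:
            other = frozenset(all_names - side)
            splits.add(min(side, other, key=sorted))
    return splits


def all_unrooted_trees(names):
    """Enumerate unrooted binary trees as nested tuples (recursive join)."""
    if len(names) == 3:
        return [tuple(names)]
    trees = []
    head, tail = names[-1], names[:-1]
    for tree in all_unrooted_trees(tail):
        for edge_tree in _insert_on_each_edge(tree, head):
            trees.append(edge_tree)
    return trees


def _edges(tree):
    """Indices of insertable positions: every subtree occurrence."""
    positions = []

    def walk(node, path):
        positions.append(path)
        if isinstance(node, tuple) and len(node) == 2:
            for i, child in enumerate(node):
                walk(child, path + (i,))

    if isinstance(tree, tuple):  # trifurcating root
        for i, child in enumerate(tree):
            walk(child, (i,))
    return positions


def _replace(tree, path, new):
    if not path:
        return new
    tree = list(tree)
    tree[path[0]] = _replace(tree[path[0]], path[1:], new)
    return tuple(tree)


def _insert_on_each_edge(tree, leaf):
    out = []
    for path in _edges(tree):
        def get(t, p):
            for i in p:
                t = t[i]
            return t

        target = get(tree, path)
        out.append(_replace(tree, path, (target, leaf)))
    return out


def _splits_of_nested(tree, all_names):
    splits = set()

    def leaves(node):
        if isinstance(node, tuple):
            out = []
            for child in node:
                out.extend(leaves(child))
            return out
        return [node]

    def walk(node):
        if isinstance(node, tuple):
            for child in node:
                side = frozenset(leaves(child))
                if 1 < len(side) < len(all_names) - 1:
                    other = frozenset(all_names - side)
                    splits.add(min(side, other, key=sorted))
                walk(child)

    walk(tree)
    return splits


def least_squares_best_topology(names, dist):
    """Exhaustive search: fit branch lengths to each topology by linear least
    squares on path indicators and return the splits of the best fit."""
    best = (np.inf, None)
    pairs = list(itertools.combinations(range(len(names)), 2))
    d = np.array([dist[i, j] for i, j in pairs])
    for tree in all_unrooted_trees(list(names)):
        splits = _splits_of_nested(tree, set(names))
        # branch parameters: one per leaf + one per internal split
        cols = [frozenset([nm]) for nm in names] + list(splits)
        a = np.zeros((len(pairs), len(cols)))
        for r, (i, j) in enumerate(pairs):
            for c, side in enumerate(cols):
                # branch separates the pair iff exactly one endpoint inside
                inside = (names[i] in side) + (names[j] in side)
                if inside == 1:
                    a[r, c] = 1.0
        fit, residual, *_ = np.linalg.lstsq(a, d, rcond=None)
        resid = ((a @ fit - d) ** 2).sum()
        if resid < best[0] - 1e-12:
            best = (resid, splits)
    return best[1]


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestNeighborJoining:
    @pytest.mark.parametrize("n_leaves", [4, 5])
    def test_additive_matrices_recover_generating_topology(self, n_leaves):
        rng = np.random.default_rng(7)
        for _ in range(50):
            names, dist, true_splits = random_additive_tree(n_leaves, rng)
            tree = neighbor_joining(pd.DataFrame(dist, index=names,
                                                 columns=names))
            assert tree_splits(tree, set(names)) == true_splits

    @pytest.mark.parametrize("n_leaves", [4, 5])
    def test_agrees_with_exhaustive_least_squares_oracle(self, n_leaves):
        rng = np.random.default_rng(11)
        for _ in range(10):
            names, dist, _ = random_additive_tree(n_leaves, rng)
            tree = neighbor_joining(pd.DataFrame(dist, index=names,
                                                 columns=names))
            oracle = least_squares_best_topology(names, dist)
            assert tree_splits(tree, set(names)) == oracle

    def test_agrees_with_reference_nj_implementation(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            names, dist, _ = random_additive_tree(6, rng)
            ours = neighbor_joining(pd.DataFrame(dist, index=names,
                                                 columns=names))
            reference = skbio_nj(DistanceMatrix(dist, names))
            assert tree_splits(ours, set(names)) == tree_splits(
                reference, set(names)
            )

    def test_branch_lengths_reproduce_additive_distances(self):
        rng = np.random.default_rng(3)
        names, dist, _ = random_additive_tree(5, rng)
        tree = neighbor_joining(pd.DataFrame(dist, index=names, columns=names))
        tips = {t.name: t for t in tree.tips()}
        for i, j in itertools.combinations(range(5), 2):
            assert tips[names[i]].distance(tips[names[j]]) == pytest.approx(
                dist[i, j], abs=1e-9
            )

    def test_asymmetric_matrix_rejected(self):
        bad = pd.DataFrame([[0, 1], [2, 0]], index=["a", "b"],
                           columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(bad)


def worked_profiles(n_truncal=15, p1=5, p2=8):
    """The four-taxon worked example: normal all-reference, an ancestor-like
    clone carrying only the truncal block, and two derived clones with
    disjoint private blocks."""
    n_var = n_truncal + p1 + p2
    normal = np.zeros(n_var, int)
    c3 = np.zeros(n_var, int)
    c3[:n_truncal] = 2
    c1 = c3.copy()
    c1[n_truncal:n_truncal + p1] = 2
    c2 = c3.copy()
    c2[n_truncal + p1:] = 2
    ids = [f"v{i}" for i in range(n_var)]

    def profile(label, codes, role):
        return CloneProfile(
            label=label, role=role, n_cells=100,
            consensus_ngt=pd.Series(codes, index=ids),
            frac_mutated=pd.Series((codes > 0).astype(float), index=ids),
        )

    return [
        profile("normal", normal, "normal"),
        profile("c3", c3, "tumor"),
        profile("c1", c1, "tumor"),
        profile("c2", c2, "tumor"),
    ]


class TestWorkedExample:
    def test_topology_places_ancestor_like_clone_basal(self):
        lineage = build_nj_tree(worked_profiles())
        root_children = {
            frozenset(t.name for t in child.tips()) or frozenset([child.name])
            for child in lineage.tree.children
        }
        assert frozenset(["normal"]) in root_children
        mrca = lineage.tree.find("MRCA")
        child_sets = sorted(
            (sorted(t.name for t in c.tips()) or [c.name])
            for c in mrca.children
        )
        assert child_sets == [["c1", "c2"], ["c3"]]

    def test_all_truncal_mutations_on_root_to_mrca_branch(self):
        lineage = build_nj_tree(worked_profiles())
        lineage = annotate_lineage_events(lineage, worked_profiles())
        truncal = [e for e in lineage.events if e.truncal]
        assert len(truncal) == 15
        assert all(e.branch == "MRCA" for e in truncal)

    def test_private_mutations_on_their_clone_branches(self):
        profiles = worked_profiles()
        lineage = annotate_lineage_events(build_nj_tree(profiles), profiles)
        by_branch = {}
        for e in lineage.events:
            by_branch.setdefault(e.branch, []).append(e.feature)
        assert len(by_branch["c1"]) == 5
        assert len(by_branch["c2"]) == 8
        assert not any(e.conflict for e in lineage.events)

    def test_two_identical_clusters_joined_by_zero_length_branch(self):
        profiles = worked_profiles(p1=0, p2=8)  # c1 identical to c3
        lineage = build_nj_tree(profiles)
        a = lineage.tree.find("c1")
        b = lineage.tree.find("c3")
        assert a.distance(b) == pytest.approx(0.0, abs=1e-12)


class TestEventAnnotation:
    def test_mutation_in_single_clone_goes_on_its_branch(self):
        profiles = worked_profiles()
        lineage = annotate_lineage_events(build_nj_tree(profiles), profiles)
        c1_only = [e for e in lineage.events if e.branch == "c1"]
        assert all(not e.truncal for e in c1_only)

    def test_cna_shared_by_sister_clones_goes_on_their_ancestor(self):
        profiles = worked_profiles()
        amps = [f"amp{j}" for j in range(6)]
        for p in profiles:
            call = pd.Series("neutral", index=amps)
            if p.label in ("c1", "c2"):
                call["amp0"] = "loss"
            p.cna_call = call
            p.median_copy_ratio = pd.Series(1.0, index=amps)
        lineage = annotate_lineage_events(build_nj_tree(profiles), profiles)
        cna = [e for e in lineage.events if e.kind == "cna"]
        assert len(cna) == 1
        # branch above the (c1, c2) ancestor, which is the internal node A1
        assert cna[0].branch == "A1"
        assert cna[0].detail == "loss" and not cna[0].truncal

    def test_non_nested_carrier_set_is_flagged_as_conflict(self):
        # tree built from the clean profiles; the annotated profiles carry an
        # extra mutation in c3 and c1, which is not a clade of that topology
        lineage = build_nj_tree(worked_profiles())
        profiles = worked_profiles()
        for p in profiles:
            p.consensus_ngt = pd.concat(
                [p.consensus_ngt, pd.Series({"vx": 0})]
            )
            p.frac_mutated = pd.concat(
                [p.frac_mutated, pd.Series({"vx": 0.0})]
            )
        for p in profiles:
            if p.label in ("c3", "c1"):
                p.consensus_ngt["vx"] = 2
        lineage = annotate_lineage_events(lineage, profiles)
        vx = [e for e in lineage.events if e.feature == "vx"]
        assert len(vx) == 1 and vx[0].conflict
        assert lineage.warnings

    def test_event_counts_conserved(self):
        profiles = worked_profiles()
        lineage = annotate_lineage_events(build_nj_tree(profiles), profiles)
        mutant_somewhere = sum(
            any(p.consensus_ngt[v] in (1, 2) for p in profiles
                if p.role == "tumor")
            for v in profiles[0].consensus_ngt.index
        )
        assert len([e for e in lineage.events if e.kind == "mutation"]) \
            == mutant_somewhere

    def test_newick_carries_branch_annotations(self):
        profiles = worked_profiles()
        lineage = annotate_lineage_events(build_nj_tree(profiles), profiles)
        text = lineage.newick()
        assert text.endswith(";")
        assert "[&muts=" in text
        # plain newick (no annotations) parses with standard tooling
        TreeNode.read([lineage.newick(annotate=False)])


class TestImpactRanking:
    def test_pass_rule_and_percentile_bands(self):
        table = pd.DataFrame({
            "gene": ["A", "B", "C"],
            "polyphen": [0.9, 0.5, np.nan],
            "sift": [0.5, 0.3, 0.05],
            "cadd": [24.0, 18.0, 33.0],
        })
        ranked = rank_deleterious(table)
        assert ranked.loc[0, "pass"]          # polyphen 0.9 > 0.8
        assert not ranked.loc[1, "pass"]      # (1-sift)=0.7 fails both
        assert ranked.loc[2, "pass"]          # (1-0.05) > 0.8
        assert ranked.loc[0, "cadd_band"] == "top 1%"
        assert ranked.loc[2, "cadd_band"] == "top 0.1%"
        assert ranked.loc[2, "rank"] == 1

    def test_missing_scores_fail_the_filter(self):
        table = pd.DataFrame({"polyphen": [np.nan], "sift": [np.nan],
                              "cadd": [np.nan]})
        ranked = rank_deleterious(table)
        assert not ranked.loc[0, "pass"]

    def test_exactly_top_30_retained_from_40_passers(self):
        table = pd.DataFrame({
            "polyphen": [0.95] * 40,
            "sift": [0.5] * 40,
            "cadd": np.linspace(10, 40, 40),
        })
        ranked = rank_deleterious(table)
        assert int(ranked["retained"].sum()) == 30
        assert ranked.loc[39, "rank"] == 1  # highest CADD first


class TestGenotypeDistances:
    def test_missing_entries_rescale_by_observed_fraction(self):
        frame = pd.DataFrame(
            [[2, 2, 0, 0], [0, MISSING, 0, 0]],
            index=["a", "b"],
        )
        dist = genotype_distance_matrix(frame)
        # observed sites: 3 of 4; raw L1 distance 2 -> rescaled 2 / (3/4)
        assert dist.loc["a", "b"] == pytest.approx(2 / 0.75)

    def test_no_co_observed_sites_errors(self):
        frame = pd.DataFrame([[2, MISSING], [MISSING, 0]], index=["a", "b"])
        with pytest.raises(ValueError, match="co-observed"):
            genotype_distance_matrix(frame)
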