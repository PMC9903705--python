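"""Neighbor-joining lineage trees, branch event annotation, impact ranking.

Trees are built over cluster consensus genotype profiles (3-5 taxa in
practice; per-cell trees are possible but noisy).  The pairwise genotype
distance is the L1 distance over numeric genotype codes with
pairwise-complete handling of missing entries (observed distance rescaled by
the fraction of co-observed sites).  L1 is the natural choice here: under a
perfect phylogeny the number of differing mutation calls is an additive tree
metric, which neighbor joining then recovers exactly; Euclidean distances on
the same profiles are not additive and can invert short internal branches.

Neighbor joining is the classical Saitou-Nei agglomeration, implemented
directly so that Q-matrix ties resolve deterministically toward the
lowest-index pair (zero-length internal branches are common with an
ancestor-like clone that carries no private mutations, and the tie-break
decides the printed topology).  Negative branch length estimates are clamped
to zero.

Mutations and copy-number events are annotated onto branches by
perfect-phylogeny placement: each event goes on the branch above the
smallest clade containing every tumor cluster that carries it, so events in
all tumor clusters land on the root-to-MRCA branch (truncal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .cluster import ROLE_NORMAL, CloneProfile
from .io import MISSING


@dataclass
class BranchEvent:
    branch: str        # name of the node below the branch
    kind: str          # "mutation" or "cna"
    feature: str       # variant or amplicon id
    detail: str        # genotype code or gain/loss
    truncal: bool
    conflict: bool = False


@dataclass
class LineageTree:
    tree: TreeNode                 # rooted; leaves named by cluster
    normal_leaf: str
    mrca: str                      # name of the MRCA internal node
    events: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.events])

    def newick(self, annotate: bool = True) -> str:
        """Newick string; branch events go into ``[&...]`` comment blocks."""
        by_branch = {}
        for ev in self.events:
            by_branch.setdefault(ev.branch, []).append(ev)

        def fmt(node):
            if node.children:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner}){node.name or ''}"
            else:
                label = node.name
            comment = ""
            if annotate and node.name in by_branch:
                evs = by_branch[node.name]
                muts = "|".join(e.feature for e in evs if e.kind == "mutation")
                cnas = "|".join(
                    f"{e.feature}:{e.detail}" for e in evs if e.kind == "cna"
                )
                parts = []
                if muts:
                    parts.append(f"muts={muts}")
                if cnas:
                    parts.append(f"cna={cnas}")
                comment = f"[&{','.join(parts)}]"
            length = node.length if node.length is not None else 0.0
            if node.parent is None:
                return f"{label}{comment}"
            return f"{label}{comment}:{length:g}"

        return fmt(self.tree) + ";"


# ---------------------------------------------------------------------------
# distances and NJ
# ---------------------------------------------------------------------------

def genotype_distance_matrix(
    profiles_or_matrix, metric: str = "cityblock"
) -> pd.DataFrame:
    """Pairwise distances over genotype codes with pairwise-complete missing
    handling: the distance over co-observed sites is rescaled by the inverse
    of the fraction observed."""
    if isinstance(profiles_or_matrix, list):
        frame = pd.DataFrame(
            {str(p.label): p.consensus_ngt for p in profiles_or_matrix}
        ).T
    else:
        frame = pd.DataFrame(profiles_or_matrix)
    x = frame.to_numpy(float)
    x[x == MISSING] = np.nan
    n = x.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(x[i]) & ~np.isnan(x[j])
            if not both.any():
                raise ValueError(
                    f"no co-observed sites between {frame.index[i]} and "
                    f"{frame.index[j]}"
                )
            diff = np.abs(x[i, both] - x[j, both])
            d = diff.sum() if metric == "cityblock" else np.sqrt((diff**2).sum())
            dist[i, j] = dist[j, i] = d / (both.mean())
    return pd.DataFrame(dist, index=frame.index, columns=frame.index)


def neighbor_joining(dist: pd.DataFrame) -> TreeNode:
    """Classical Saitou-Nei neighbor joining with lowest-index tie-breaking.

    Returns an unrooted tree represented with a trifurcating root.  Negative
    branch-length estimates are clamped to zero.
    """
    names = list(dist.index)
    d = dist.to_numpy(float).copy()
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.diag(d).any():
        raise ValueError("distance matrix must have a zero diagonal")
    nodes = [TreeNode(name=str(nm)) for nm in names]
    if len(nodes) < 2:
        raise ValueError("need at least 2 taxa")
    if len(nodes) == 2:
        root = TreeNode()
        for node, ln in zip(nodes, (d[0, 1] / 2, d[0, 1] / 2)):
            node.length = max(float(ln), 0.0)
            root.append(node)
        return root

    active = list(range(len(nodes)))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # first-occurrence argmin (row-major) = lowest-index pair tie-break
        fi, fj = np.unravel_index(np.argmin(q), q.shape)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = d[i, j]
        li = 0.5 * dij + (r[fi] - r[fj]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        nodes[i].length = max(float(li), 0.0)
        nodes[j].length = max(float(lj), 0.0)
        parent.append(nodes[i])
        parent.append(nodes[j])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    root = TreeNode()
    nodes[i].length = max(float(0.5 * (d[i, j] + d[i, k] - d[j, k])), 0.0)
    nodes[j].length = max(float(0.5 * (d[i, j] + d[j, k] - d[i, k])), 0.0)
    nodes[k].length = max(float(0.5 * (d[i, k] + d[j, k] - d[i, j])), 0.0)
    for idx in (i, j, k):
        root.append(nodes[idx])
    return root


def build_nj_tree(
    profiles_or_matrix,
    normal_label=None,
    metric: str = "cityblock",
) -> LineageTree:
    """NJ tree over clone profiles (or a labels x variants genotype frame),
    rooted on the branch to the normal cluster, with the MRCA of all tumor
    leaves named ``MRCA`` and deeper tumor-side ancestors ``A1``, ``A2``...

    ``normal_label`` defaults to the profile carrying the normal role (for a
    plain matrix, the first row).
    """
    warnings = []
    if isinstance(profiles_or_matrix, list):
        profiles = profiles_or_matrix
        if normal_label is None:
            normals = [p.label for p in profiles if p.role == ROLE_NORMAL]
            if not normals:
                raise ValueError("no normal-role profile; pass normal_label")
            normal_label = normals[0]
        dist = genotype_distance_matrix(profiles, metric=metric)
    else:
        dist = genotype_distance_matrix(profiles_or_matrix, metric=metric)
        if normal_label is None:
            normal_label = dist.index[0]
    normal_label = str(normal_label)
    if len(dist) < 3:
        warnings.append("fewer than 3 taxa; degenerate 2-leaf tree")
    unrooted = neighbor_joining(dist)
    normal = unrooted.find(normal_label)
    if len(dist) == 2:
        rooted = unrooted
        rooted.name = "root"
    else:
        rooted = unrooted.root_at(normal, above=True, root_name="root")

    tumor_leaves = [t for t in rooted.tips() if t.name != normal_label]
    mrca = rooted.lca(tumor_leaves) if len(tumor_leaves) > 1 else tumor_leaves[0]
    if mrca is rooted:
        # normal nested inside the tumor clade; fall back to the root's
        # non-normal child
        candidates = [c for c in rooted.children if normal_label not in
                      {t.name for t in c.tips()} | {c.name}]
        mrca = candidates[0] if candidates else rooted
        warnings.append("normal leaf is not an outgroup of all tumor leaves")
    if not mrca.name:
        mrca.name = "MRCA"
    counter = 1
    for node in mrca.preorder(include_self=False):
        if node.children and not node.name:
            node.name = f"A{counter}"
            counter += 1
    for node in rooted.preorder(include_self=False):
        if node.children and not node.name:
            node.name = f"A{counter}"
            counter += 1
    rooted.clear_caches()
    return LineageTree(
        tree=rooted, normal_leaf=normal_label, mrca=mrca.name, warnings=warnings
    )


# ---------------------------------------------------------------------------
# event annotation
# ---------------------------------------------------------------------------

def annotate_lineage_events(
    lineage: LineageTree, profiles: list
) -> LineageTree:
    """Place mutations and CNA calls on branches by smallest-clade placement.

    A mutation mutant (consensus 1 or 2) in a set S of tumor clusters goes on
    the branch above the LCA of S; if the LCA's clade strictly contains S the
    placement is flagged as a conflict (the event violates the clustered
    perfect phylogeny) but still recorded at the majority position.
    """
    tree = lineage.tree
    tumor = {
        str(p.label): p for p in profiles
        if str(p.label) != lineage.normal_leaf and p.role != ROLE_NORMAL
    }
    tumor_names = set(tumor)
    leaf_lookup = {t.name: t for t in tree.tips()}

    def place(carriers: set):
        nodes = [leaf_lookup[c] for c in carriers]
        lca = tree.lca(nodes) if len(nodes) > 1 else nodes[0]
        clade = {t.name for t in lca.tips()} if lca.children else {lca.name}
        clade &= tumor_names
        return lca, clade

    events = []
    variant_ids = profiles[0].consensus_ngt.index
    for vid in variant_ids:
        carriers = {
            name for name, p in tumor.items()
            if p.consensus_ngt[vid] in (1, 2)
        }
        if not carriers:
            continue
        lca, clade = place(carriers)
        conflict = clade != carriers
        codes = {tumor[name].consensus_ngt[vid] for name in carriers}
        events.append(
            BranchEvent(
                branch=lca.name,
                kind="mutation",
                feature=str(vid),
                detail="hom" if codes == {2} else "het" if codes == {1} else "mixed",
                truncal=carriers == tumor_names,
                conflict=conflict,
            )
        )
        if conflict:
            lineage.warnings.append(
                f"mutation {vid}: carriers {sorted(carriers)} are not a clade; "
                f"placed above {lca.name}"
            )

    first = next(iter(tumor.values()), None)
    if first is not None and first.cna_call is not None:
        for amp in first.cna_call.index:
            for call in ("gain", "loss"):
                carriers = {
                    name for name, p in tumor.items()
                    if p.cna_call is not None and p.cna_call[amp] == call
                }
                if not carriers:
                    continue
                lca, clade = place(carriers)
                conflict = clade != carriers
                events.append(
                    BranchEvent(
                        branch=lca.name,
                        kind="cna",
                        feature=str(amp),
                        detail=call,
                        truncal=carriers == tumor_names,
                        conflict=conflict,
                    )
                )
                if conflict:
                    lineage.warnings.append(
                        f"CNA {amp} ({call}): carriers {sorted(carriers)} are "
                        f"not a clade; placed above {lca.name}"
                    )
    lineage.events = events
    return lineage


# ---------------------------------------------------------------------------
# impact ranking
# ---------------------------------------------------------------------------

def cadd_band(cadd: float) -> str:
    """Scaled-CADD percentile band (scores are phred-scaled percentiles)."""
    if cadd > 30:
        return "top 0.1%"
    if cadd > 20:
        return "top 1%"
    if cadd > 10:
        return "top 10%"
    return "below top 10%"


def rank_deleterious(variants: pd.DataFrame, top_n: int = 30) -> pd.DataFrame:
    """Deleteriousness shortlist: pass if PolyPhen > 0.8 or (1 - SIFT) > 0.8
    (missing scores fail), then rank passers by CADD descending and keep the
    top ``top_n``.  Returns the full table with pass flag, rank (NaN for
    non-passers and beyond-top-n), and CADD percentile band."""
    table = variants.copy()
    polyphen = pd.to_numeric(table.get("polyphen"), errors="coerce")
    sift = pd.to_numeric(table.get("sift"), errors="coerce")
    cadd = pd.to_numeric(table.get("cadd"), errors="coerce")
    table["pass"] = (polyphen > 0.8).fillna(False) | (
        ((1.0 - sift) > 0.8).fillna(False)
    )
    table.loc[cadd.isna(), "pass"] = False
    table["cadd_band"] = cadd.map(
        lambda v: cadd_band(v) if pd.notna(v) else ""
    )
    table["rank"] = np.nan
    passers = table.index[table["pass"]]
    order = cadd.loc[passers].sort_values(ascending=False, kind="stable").index
    kept = order[:top_n]
    table.loc[kept, "rank"] = np.arange(1, len(kept) + 1)
    table["retained"] = table["rank"].notna()
    return table
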