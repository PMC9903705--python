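"""Cell embedding, agglomerative clustering, and per-cluster consensus.

Cluster detection runs in genotype space (complete-linkage agglomerative
clustering on Euclidean distances), with the cluster count chosen by mean
silhouette when not fixed by the caller.  The 2-D UMAP embedding is produced
for reporting only; it plays no part in cluster assignment, since the
low-dimensional projection adds dispersion that is technical rather than
biological in highly clonal samples.

Missing genotypes are imputed as reference (0) for distance computations but
excluded from consensus genotypes and mutated-fraction summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .io import MISSING, MatrixBundle

ROLE_TUMOR = "tumor"
ROLE_NORMAL = "normal"
ROLE_DOUBLET = "doublet"
ROLE_OUTLIER = "outlier"


@dataclass
class ClusterAssignment:
    labels: pd.Series              # cell_id -> integer cluster label
    roles: dict = field(default_factory=dict)  # label -> role

    @property
    def n_clusters(self) -> int:
        return self.labels.nunique()

    def cluster_labels(self, roles=None) -> list:
        """Cluster labels, optionally restricted to the given roles."""
        labels = sorted(self.labels.unique())
        if roles is None:
            return labels
        return [lab for lab in labels if self.roles.get(lab) in roles]

    def cells_in(self, label) -> list:
        return list(self.labels.index[self.labels == label])

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def non_doublet_clusters(self) -> list:
        return self.cluster_labels(roles={ROLE_TUMOR, ROLE_NORMAL})

    def drop_cells(self, cell_ids) -> "ClusterAssignment":
        keep = ~self.labels.index.isin(set(cell_ids))
        labels = self.labels[keep]
        roles = {lab: self.roles[lab] for lab in labels.unique()}
        return ClusterAssignment(labels, roles)


@dataclass
class CloneProfile:
    label: int
    role: str
    n_cells: int
    consensus_ngt: pd.Series             # variant -> genotype code
    frac_mutated: pd.Series              # variant -> fraction mutant among genotyped
    median_copy_ratio: pd.Series | None = None  # amplicon -> ratio
    cna_call: pd.Series | None = None    # amplicon -> loss/neutral/gain


def _imputed(bundle: MatrixBundle) -> np.ndarray:
    ngt = bundle.layers["NGT"].astype(float)
    ngt[bundle.layers["NGT"] == MISSING] = 0.0
    return ngt


def embed_cells(
    bundle: MatrixBundle,
    n_components: int | None = None,
    n_neighbors: int = 15,
    a: float = 1.0,
    b: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """PCA followed by UMAP to a 2-D reporting embedding.

    PCA keeps ``n_components`` components; by default the smallest number
    explaining >= 90% of variance, capped at 10.  The inter-patient preset of
    the downstream tooling (``a = b = 1.2``) is reached by passing those
    values explicitly.
    """
    from sklearn.decomposition import PCA
    import umap

    x = _imputed(bundle)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 variants to embed")
    max_comp = min(10, x.shape[1], x.shape[0] - 1)
    pca = PCA(n_components=max_comp, random_state=seed)
    scores = pca.fit_transform(x)
    if n_components is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_components = int(np.searchsorted(cum, 0.90) + 1)
    scores = scores[:, :n_components]
    reducer = umap.UMAP(
        n_components=2, n_neighbors=min(n_neighbors, x.shape[0] - 1),
        a=a, b=b, random_state=seed,
    )
    coords = reducer.fit_transform(scores)
    return pd.DataFrame(coords, index=bundle.cell_ids, columns=["umap1", "umap2"])


def min_cluster_size(n_cells: int) -> int:
    """Smallest cluster treated as real: 20 cells or 1% of cells."""
    return max(20, int(np.ceil(0.01 * n_cells)))


def cluster_cells(
    bundle_or_matrix,
    k: int | None = None,
    k_max: int = 8,
    linkage_method: str = "complete",
    metric: str = "euclidean",
    min_size: int | None = None,
    seed: int = 0,
) -> ClusterAssignment:
    """Agglomerative clustering with silhouette-based model selection.

    Accepts a genotype :class:`MatrixBundle` (missing imputed as reference)
    or any cells x features DataFrame (e.g. a copy-ratio matrix).  When ``k``
    is not given, the ``k`` in ``[2, k_max]`` maximising the mean silhouette
    is used.  Clusters smaller than ``min_size`` are labeled outliers; among
    the rest, the cluster whose consensus genotype carries the fewest mutant
    calls is labeled normal and the others tumor.  For non-genotype input the
    lowest-mean cluster plays the normal role.
    """
    if isinstance(bundle_or_matrix, MatrixBundle):
        x = _imputed(bundle_or_matrix)
        cell_ids = bundle_or_matrix.cell_ids
        genotype_input = True
    else:
        frame = pd.DataFrame(bundle_or_matrix)
        x = frame.to_numpy(float)
        cell_ids = list(frame.index)
        genotype_input = False
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")

    dist = pdist(x, metric=metric)
    if k is not None and k > 1 and dist.max() == 0:
        raise ValueError("all cells identical; cannot form k > 1 clusters")
    tree = linkage(dist, method=linkage_method)

    if k is None:
        square = squareform(dist)
        best_k, best_score = 1, -np.inf
        for cand in range(2, min(k_max, n - 1) + 1):
            labels = fcluster(tree, t=cand, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(square, labels, metric="precomputed")
            if score > best_score:
                best_k, best_score = cand, score
        k = best_k if best_k > 1 else 1
    if k == 1:
        labels = np.ones(n, dtype=int)
    else:
        labels = fcluster(tree, t=k, criterion="maxclust")

    # relabel clusters by decreasing size for stable, order-free naming
    counts = pd.Series(labels).value_counts()
    remap = {old: new + 1 for new, old in enumerate(counts.index)}
    labels = np.array([remap[l] for l in labels])
    series = pd.Series(labels, index=cell_ids, name="cluster")

    min_size = min_cluster_size(n) if min_size is None else min_size
    roles = {}
    real = []
    for lab, size in series.value_counts().items():
        if size < min_size:
            roles[lab] = ROLE_OUTLIER
        else:
            real.append(lab)
    if real:
        if genotype_input:
            burden = {}
            ngt = bundle_or_matrix.layers["NGT"]
            for lab in real:
                rows = np.asarray(series == lab)
                sub = ngt[rows]
                cons = _consensus_codes(sub)
                burden[lab] = int(np.isin(cons, (1, 2)).sum())
        else:
            burden = {
                lab: float(x[np.asarray(series == lab)].mean()) for lab in real
            }
        # normal = the mutation-poorest cluster, provided it is clearly
        # poorer than the richest (a lone all-tumor cluster stays tumor)
        low = min(sorted(real), key=lambda lab: burden[lab])
        b_min, b_max = burden[low], max(burden.values())
        has_normal = b_min == 0 or b_min < 0.5 * b_max
        for lab in real:
            roles[lab] = (
                ROLE_NORMAL if (lab == low and has_normal) else ROLE_TUMOR
            )
    return ClusterAssignment(series, roles)


def _consensus_codes(ngt_rows: np.ndarray) -> np.ndarray:
    """Columnwise modal non-missing genotype; ties break toward the lower
    code; all-missing columns give the missing sentinel."""
    n_var = ngt_rows.shape[1]
    out = np.full(n_var, MISSING, dtype=int)
    counts = np.stack([(ngt_rows == code).sum(axis=0) for code in (0, 1, 2)])
    genotyped = counts.sum(axis=0) > 0
    out[genotyped] = counts[:, genotyped].argmax(axis=0)  # argmax -> lowest on tie
    return out


def consensus_profiles(
    bundle: MatrixBundle, assignment: ClusterAssignment
) -> list:
    """Per-cluster consensus genotype and mutated fraction (genotype part of
    the clone profile; copy-number fields are filled by the CN module)."""
    ngt = bundle.layers["NGT"]
    index = pd.Index(bundle.cell_ids)
    profiles = []
    for lab in assignment.cluster_labels():
        cells = assignment.cells_in(lab)
        rows = index.get_indexer(cells)
        rows = rows[rows >= 0]
        sub = ngt[rows]
        cons = _consensus_codes(sub)
        genotyped = (sub != MISSING).sum(axis=0)
        mutated = np.isin(sub, (1, 2)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            frac = np.where(genotyped > 0, mutated / np.maximum(genotyped, 1),
                            np.nan)
        profiles.append(
            CloneProfile(
                label=lab,
                role=assignment.roles.get(lab, ROLE_TUMOR),
                n_cells=len(rows),
                consensus_ngt=pd.Series(cons, index=bundle.feature_ids),
                frac_mutated=pd.Series(frac, index=bundle.feature_ids),
            )
        )
    return profiles
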