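"""Coverage-uniformity metrics, ADO estimation, concordance, downsampling.

The Gini index measures how unevenly reads concentrate over cells or
amplicons (0 = perfectly even); the coefficient of variation is reported in
percent with the sample (n-1) standard deviation.  Allelic dropout is
estimated from known heterozygous sites (germline SNPs) as the fraction of
genotyped entries called homozygous.  Amplicon success follows the
0.2-x-grand-mean rule.  The downsampling harness thins reads binomially
(statistically equivalent to read-level subsampling for independent reads),
or subsamples mutations/cells uniformly, and reruns the QC-and-cluster
pipeline at each level to count detectable clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterAssignment, cluster_cells, min_cluster_size
from .io import MISSING, MatrixBundle
from .qc import ScFilterConfig, filter_single_cell_matrix


def gini(x) -> float:
    """Gini index in mean-absolute-difference form:
    ``sum_ij |x_i - x_j| / (2 n^2 mean)``.

    Computed via the sorted identity ``sum_i (2i - n - 1) x_(i)`` in
    O(n log n); the O(n^2) pairwise form is the test oracle.
    """
    x = np.asarray(x, float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("gini expects a non-empty 1-D vector")
    if (x < 0).any():
        raise ValueError("gini expects non-negative values")
    total = x.sum()
    if total == 0:
        raise ValueError("gini undefined for an all-zero vector")
    n = len(x)
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * xs).sum() / (n * total))


@dataclass
class QCMetrics:
    gini_amplicons: float
    gini_cells: float
    cv_amplicons: float        # percent
    cv_cells: float            # percent
    amplicon_success_pct: float
    per_amplicon_gini: pd.Series
    ado_pct: float | None = None
    doublet_pct: float | None = None

    def to_series(self) -> pd.Series:
        data = {
            "gini_amplicons": self.gini_amplicons,
            "gini_cells": self.gini_cells,
            "cv_amplicons": self.cv_amplicons,
            "cv_cells": self.cv_cells,
            "amplicon_success_pct": self.amplicon_success_pct,
            "ado_pct": self.ado_pct,
            "doublet_pct": self.doublet_pct,
        }
        return pd.Series(data, dtype=float)


def _cv_pct(x) -> float:
    x = np.asarray(x, float)
    m = x.mean()
    return float(100.0 * x.std(ddof=1) / m) if m > 0 and len(x) > 1 else 0.0


def estimate_ado(genotypes: MatrixBundle, known_het_sites) -> float:
    """Fraction of genotyped entries at known heterozygous sites that were
    called homozygous (either allele lost)."""
    sites = [s for s in known_het_sites if s in genotypes.feature_ids]
    if not sites:
        raise ValueError("no known heterozygous sites present in the bundle")
    idx = [genotypes.feature_ids.index(s) for s in sites]
    ngt = genotypes.layers["NGT"][:, idx]
    genotyped = ngt != MISSING
    if not genotyped.any():
        raise ValueError("known het sites have no genotyped entries")
    hom = (ngt == 0) | (ngt == 2)
    return float(hom[genotyped].sum() / genotyped.sum())


def coverage_metrics(
    counts: MatrixBundle,
    genotypes: MatrixBundle | None = None,
    known_het_sites=None,
    success_factor: float = 0.2,
    doublet_fraction: float | None = None,
) -> QCMetrics:
    """Summary coverage metrics for one sample.

    Per-amplicon Gini/CV are taken over cells and per-cell Gini/CV over
    amplicons, each then averaged over the sample; an amplicon succeeds when
    its mean reads exceed ``success_factor`` x the grand mean reads per cell
    per amplicon.
    """
    mat = counts.layers["COUNT"].astype(float)
    per_amp = pd.Series(
        [gini(mat[:, j]) if mat[:, j].sum() > 0 else np.nan
         for j in range(mat.shape[1])],
        index=counts.feature_ids,
    )
    cell_nonzero = mat.sum(axis=1) > 0
    per_cell = [gini(row) for row in mat[cell_nonzero]]
    per_amp_cv = [
        _cv_pct(mat[:, j]) for j in range(mat.shape[1]) if mat[:, j].sum() > 0
    ]
    per_cell_cv = [_cv_pct(row) for row in mat[cell_nonzero]]
    grand_mean = mat.mean()
    success = mat.mean(axis=0) > success_factor * grand_mean
    ado_pct = None
    if genotypes is not None and known_het_sites is not None:
        try:
            ado_pct = 100.0 * estimate_ado(genotypes, known_het_sites)
        except ValueError:
            ado_pct = None
    return QCMetrics(
        gini_amplicons=float(per_amp.mean()),
        gini_cells=float(np.mean(per_cell)),
        cv_amplicons=float(np.mean(per_amp_cv)),
        cv_cells=float(np.mean(per_cell_cv)),
        amplicon_success_pct=float(100.0 * success.mean()),
        per_amplicon_gini=per_amp,
        ado_pct=ado_pct,
        doublet_pct=(
            100.0 * doublet_fraction if doublet_fraction is not None else None
        ),
    )


def single_cell_vafs(genotypes: MatrixBundle, cells=None) -> pd.Series:
    """Aggregated single-cell VAF per variant: ``sum(NGT) / (2 x genotyped)``
    over the given cells (default all), missing entries excluded."""
    ngt = genotypes.layer_frame("NGT")
    if cells is not None:
        ngt = ngt.loc[[c for c in cells if c in ngt.index]]
    arr = ngt.to_numpy(float)
    arr[arr == MISSING] = np.nan
    genotyped = np.isfinite(arr)
    with np.errstate(invalid="ignore"):
        vaf = np.nansum(arr, axis=0) / (2.0 * genotyped.sum(axis=0))
    return pd.Series(vaf, index=genotypes.feature_ids, name="sc_vaf")


def concordance(
    sc_vaf: pd.Series,
    bulk_vaf: pd.Series,
    sc_cn: pd.Series | None = None,
    bulk_cn: pd.Series | None = None,
) -> dict:
    """Pearson correlations of single-cell aggregates against bulk references.

    Returns ``{"r_vaf": ..., "r_cn": ...}``; requires at least 3 shared keys
    and non-constant vectors (correlation is undefined otherwise).
    """

    def pearson(a: pd.Series, b: pd.Series) -> float:
        shared = a.index.intersection(b.index)
        a, b = a[shared].astype(float), b[shared].astype(float)
        ok = a.notna() & b.notna()
        a, b = a[ok], b[ok]
        if len(a) < 3:
            raise ValueError("fewer than 3 shared keys for correlation")
        if a.std() == 0 or b.std() == 0:
            raise ValueError("constant vector; correlation undefined")
        return float(stats.pearsonr(a, b).statistic)

    out = {"r_vaf": pearson(sc_vaf, bulk_vaf)}
    if sc_cn is not None and bulk_cn is not None:
        out["r_cn"] = pearson(sc_cn, bulk_cn)
    return out


# ---------------------------------------------------------------------------
# downsampling harness
# ---------------------------------------------------------------------------

def thin_counts(counts: MatrixBundle, p: float, rng) -> MatrixBundle:
    """Binomial thinning: keep each read independently with probability p."""
    if not 0 < p <= 1:
        raise ValueError("thinning probability must be in (0, 1]")
    mat = rng.binomial(counts.layers["COUNT"], p)
    return MatrixBundle(counts.cell_ids, counts.feature_ids, {"COUNT": mat})


def _detected_clusters(
    genotypes: MatrixBundle,
    qc_cfg: ScFilterConfig,
    counts: MatrixBundle | None = None,
    k_max: int = 8,
) -> int:
    """Rerun the QC -> cluster (-> doublet) pipeline; count real clusters.

    With a count matrix the full fit runs and doublet clusters are excluded
    from the count; without one, clusters at or above the minimum real size
    are counted directly.
    """
    if counts is not None:
        from .model import ClonalModel

        model = ClonalModel(
            counts=counts, genotypes=genotypes, qc=qc_cfg, k_max=k_max,
            doublet_probe_extra=0,
        )
        try:
            return model.fit(seed=0).n_clusters_detected
        except ValueError:
            return 0
    result = filter_single_cell_matrix(genotypes, qc_cfg)
    if result.all_filtered or result.bundle.n_cells < 2:
        return 0
    if result.bundle.shape[1] < 2:
        return 1
    assignment = cluster_cells(result.bundle, k_max=k_max)
    min_size = min_cluster_size(result.bundle.n_cells)
    sizes = assignment.sizes()
    return int((sizes >= min_size).sum())


def downsample_experiment(
    genotypes: MatrixBundle,
    counts: MatrixBundle | None,
    axis: str,
    levels,
    seeds,
    qc_cfg: ScFilterConfig | None = None,
    variant_pool=None,
    variant_amplicon=None,
) -> pd.DataFrame:
    """Sensitivity of cluster detection to depth, mutation count, or cells.

    ``axis`` is one of ``depth`` (target mean depth per cell per amplicon;
    counts binomially thinned and DP/GQ-derived masking reapplied),
    ``mutations`` (uniform random variant subsets of the given sizes), or
    ``cells`` (uniform random cell subsets).  ``levels`` must be sorted
    descending; each (level, seed) reruns QC + clustering and records the
    number of detected clusters.  ``variant_pool`` restricts the mutation
    axis to the given candidate variants (e.g. somatic sites only).

    Returns a tidy frame (axis, level, seed, k_detected) plus per-level
    medians merged in.
    """
    qc_cfg = qc_cfg or ScFilterConfig()
    levels = list(levels)
    if levels != sorted(levels, reverse=True):
        raise ValueError("levels must be sorted descending")
    rows = []
    for level in levels:
        for seed in seeds:
            rng = np.random.default_rng(int(seed))
            sub = genotypes
            sub_counts = counts
            if axis == "depth":
                if counts is None:
                    raise ValueError("depth axis requires the count matrix")
                current = counts.layers["COUNT"].mean()
                p = min(1.0, level / current)
                if level >= current:
                    p = 1.0
                thinned = thin_counts(counts, p, rng)
                # DP per variant is the thinned count at the variant's
                # amplicon; without an explicit map, variant i reads from
                # amplicon i mod n_amplicons (the simulator's layout)
                n_amp = len(counts.feature_ids)
                if variant_amplicon is not None:
                    amp_of = [counts.feature_ids.index(a)
                              for a in variant_amplicon]
                else:
                    amp_of = [i % n_amp
                              for i in range(len(genotypes.feature_ids))]
                new_dp = thinned.layers["COUNT"][:, amp_of]
                layers = dict(genotypes.layers)
                layers["DP"] = new_dp
                sub = MatrixBundle(
                    genotypes.cell_ids, genotypes.feature_ids, layers
                )
                sub_counts = thinned
            elif axis == "mutations":
                pool = [
                    v for v in (variant_pool or genotypes.feature_ids)
                    if v in genotypes.feature_ids
                ]
                if level > len(pool):
                    rows.append({"axis": axis, "level": level, "seed": seed,
                                 "k_detected": np.nan})
                    continue
                chosen = sorted(
                    rng.choice(len(pool), size=int(level), replace=False)
                )
                sub = genotypes.subset(features=[pool[i] for i in chosen])
            elif axis == "cells":
                if level > genotypes.n_cells:
                    rows.append({"axis": axis, "level": level, "seed": seed,
                                 "k_detected": np.nan})
                    continue
                chosen = sorted(
                    rng.choice(genotypes.n_cells, size=int(level), replace=False)
                )
                kept_cells = [genotypes.cell_ids[i] for i in chosen]
                sub = genotypes.subset(cells=kept_cells)
                if counts is not None:
                    sub_counts = counts.subset(cells=kept_cells)
            else:
                raise ValueError(f"unknown axis {axis!r}")
            rows.append({
                "axis": axis, "level": level, "seed": seed,
                "k_detected": _detected_clusters(sub, qc_cfg, sub_counts),
            })
    table = pd.DataFrame(rows)
    medians = (
        table.groupby("level")["k_detected"].median().rename("k_median")
    )
    return table.merge(medians, on="level")
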