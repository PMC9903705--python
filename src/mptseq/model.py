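"""Fitting interface: a clonal-substructure model over one sample's matrices.

:class:`ClonalModel` bundles the observed data (amplicon counts + genotype
layers) with the analysis configuration; :meth:`ClonalModel.fit` runs cell
calling, the genotype filter cascade, clustering, copy-ratio estimation,
doublet screening and lineage reconstruction, and returns a
:class:`ClonalResults` carrying the per-cell assignment, clone profiles,
copy-number calls, the annotated NJ tree, QC metrics and stage ledgers, with
a human-readable ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import benchmark as bm
from .cluster import (
    ROLE_DOUBLET,
    ROLE_NORMAL,
    ROLE_TUMOR,
    ClusterAssignment,
    cluster_cells,
    consensus_profiles,
)
from .copynumber import estimate_copy_ratios, summarize_cluster_cn
from .doublets import DoubletReport, detect_doublet_clusters
from .io import MatrixBundle
from .lineage import LineageTree, annotate_lineage_events, build_nj_tree
from .qc import ScFilterConfig, call_cells, filter_single_cell_matrix


@dataclass
class ClonalModel:
    """Unfitted model: data plus configuration.

    Parameters mirror the stage functions: ``qc`` is the filter cascade
    configuration; ``k`` fixes the cluster count (silhouette-selected when
    None); ``doublet_alpha`` is the family-wise level of the doublet screen,
    run iteratively by default so that several distinct doublet clusters can
    be peeled off; ``known_het_sites`` (germline SNP ids) enable allelic
    dropout estimation.
    """

    counts: MatrixBundle
    genotypes: MatrixBundle
    qc: ScFilterConfig = field(default_factory=ScFilterConfig)
    k: int | None = None
    k_max: int = 8
    doublet_alpha: float = 0.05
    doublet_iterative: bool = True
    doublet_probe_extra: int = 3
    gain_log2: float = 0.32
    loss_log2: float = -0.32
    known_het_sites: list | None = None

    @classmethod
    def from_simulation(cls, truth, counts, genotypes, **kwargs):
        kwargs.setdefault("known_het_sites", truth.germline_ids)
        return cls(counts=counts, genotypes=genotypes, **kwargs)

    def fit(self, seed: int = 0) -> "ClonalResults":
        # 1. cell calling on the count matrix
        called = call_cells(self.counts, self.qc)
        if not called:
            raise ValueError("no cells pass the calling thresholds")
        counts = self.counts.subset(cells=called)
        geno_ids = set(self.genotypes.cell_ids)
        genotypes = self.genotypes.subset(
            cells=[c for c in called if c in geno_ids]
        )

        # 2. genotype filter cascade
        qc_result = filter_single_cell_matrix(genotypes, self.qc)
        if qc_result.all_filtered:
            raise ValueError("filter cascade removed all cells or variants")
        filtered = qc_result.bundle

        # 3. clustering in genotype space
        assignment = cluster_cells(
            filtered, k=self.k, k_max=self.k_max, seed=seed
        )
        profiles = consensus_profiles(filtered, assignment)

        # 4. copy ratios against the normal cluster
        normal_labels = assignment.cluster_labels(roles={ROLE_NORMAL})
        if not normal_labels:
            raise ValueError(
                "no normal (reference) cluster identified; cannot normalize "
                "copy number"
            )
        count_ids = set(counts.cell_ids)
        normal_cells = [
            c for lab in normal_labels for c in assignment.cells_in(lab)
            if c in count_ids
        ]
        clustered = set(assignment.labels.index)
        ratio_cells = [c for c in counts.cell_ids if c in clustered]
        counts_clustered = counts.subset(cells=ratio_cells)
        ratios = estimate_copy_ratios(
            counts_clustered, normal_cells, scale="composition"
        )
        depth_ratios = estimate_copy_ratios(
            counts_clustered, normal_cells, scale="depth"
        )

        # 5. doublet screen on the depth-preserving ratios.  Silhouette
        # model selection can sit right at the edge of resolving a small
        # doublet cluster, so the screen also probes a few finer clusterings
        # (k+1 .. k+probe_extra) and keeps the resolution that isolates the
        # most doublet cells; under the null nothing flags at any resolution
        # and the probe is a no-op.
        def screen(candidate_assignment):
            updated, report = detect_doublet_clusters(
                depth_ratios, candidate_assignment,
                alpha=self.doublet_alpha, iterative=self.doublet_iterative,
            )
            cells_flagged = [
                c for lab in updated.cluster_labels(roles={ROLE_DOUBLET})
                for c in updated.cells_in(lab)
            ]
            return updated, report, cells_flagged

        assignment, doublet_report, doublet_cells = screen(assignment)
        k_selected = assignment.n_clusters
        for extra in range(1, max(self.doublet_probe_extra, 0) + 1):
            k_try = k_selected + extra
            if k_try > min(self.k_max + self.doublet_probe_extra,
                           filtered.n_cells - 1):
                break
            try:
                probe = cluster_cells(filtered, k=k_try, seed=seed)
            except ValueError:
                break
            probe_assignment, probe_report, probe_cells = screen(probe)
            if len(probe_cells) > len(doublet_cells):
                assignment, doublet_report, doublet_cells = (
                    probe_assignment, probe_report, probe_cells
                )
        retained = assignment.drop_cells(doublet_cells)
        doublet_set = set(doublet_cells)
        profiles = consensus_profiles(
            filtered.subset(cells=[c for c in filtered.cell_ids
                                   if c not in doublet_set]),
            retained,
        )

        # 6. cluster-level copy number on retained clusters
        cn_table = summarize_cluster_cn(
            ratios, retained, profiles=profiles,
            gain_log2=self.gain_log2, loss_log2=self.loss_log2,
        )

        # 7. lineage tree over real (non-outlier) clusters
        tree = None
        real = [p for p in profiles
                if p.role in (ROLE_TUMOR, ROLE_NORMAL)]
        if len(real) >= 2:
            tree = build_nj_tree(real)
            tree = annotate_lineage_events(tree, real)

        # 8. benchmark metrics
        doublet_fraction = (
            len(doublet_cells) / len(assignment.labels)
            if len(assignment.labels) else None
        )
        metrics = bm.coverage_metrics(
            counts, self.genotypes, self.known_het_sites,
            doublet_fraction=doublet_fraction,
        )

        return ClonalResults(
            model=self,
            called_cells=called,
            qc_ledger=qc_result.ledger,
            filtered=filtered,
            assignment=retained,
            full_assignment=assignment,
            profiles=profiles,
            copy_ratios=ratios,
            depth_ratios=depth_ratios,
            cn_table=cn_table,
            doublet_report=doublet_report,
            doublet_cells=doublet_cells,
            tree=tree,
            metrics=metrics,
            seed=seed,
        )


@dataclass
class ClonalResults:
    model: ClonalModel
    called_cells: list
    qc_ledger: pd.DataFrame
    filtered: MatrixBundle
    assignment: ClusterAssignment       # doublet cells removed
    full_assignment: ClusterAssignment  # doublet clusters kept, role-marked
    profiles: list
    copy_ratios: object
    depth_ratios: object
    cn_table: pd.DataFrame
    doublet_report: DoubletReport
    doublet_cells: list
    tree: LineageTree | None
    metrics: object
    seed: int

    @property
    def n_clusters_detected(self) -> int:
        """Non-doublet, non-outlier clusters."""
        return len(self.assignment.non_doublet_clusters())

    def cluster_table(self) -> pd.DataFrame:
        rows = []
        for p in self.profiles:
            n_mut = int(p.consensus_ngt.isin([1, 2]).sum())
            rows.append({
                "cluster": p.label, "role": p.role, "n_cells": p.n_cells,
                "n_mutations": n_mut,
                "n_gain": int((p.cna_call == "gain").sum())
                if p.cna_call is not None else 0,
                "n_loss": int((p.cna_call == "loss").sum())
                if p.cna_call is not None else 0,
            })
        return pd.DataFrame(rows)

    def sc_vafs(self) -> pd.Series:
        cells = list(self.assignment.labels.index)
        return bm.single_cell_vafs(self.model.genotypes, cells=cells)

    def tumor_mean_copy_ratio(self) -> pd.Series:
        """Cell-weighted mean of tumor-cluster median copy ratios."""
        tumor = [p for p in self.profiles
                 if p.role == ROLE_TUMOR and p.median_copy_ratio is not None]
        if not tumor:
            raise ValueError("no tumor clusters with copy ratios")
        weights = np.array([p.n_cells for p in tumor], float)
        stacked = pd.concat([p.median_copy_ratio for p in tumor], axis=1)
        return stacked @ (weights / weights.sum())

    def summary(self) -> str:
        lines = []
        lines.append("Clonal substructure fit")
        lines.append("=" * 60)
        lines.append(
            f"cells called: {len(self.called_cells)}   "
            f"after QC: {self.filtered.n_cells}   "
            f"variants kept: {self.filtered.shape[1]}"
        )
        lines.append(
            f"clusters detected (non-doublet): {self.n_clusters_detected}   "
            f"doublet cells removed: {len(self.doublet_cells)}"
        )
        lines.append("")
        table = self.cluster_table()
        if len(table):
            lines.append(table.to_string(index=False))
        for test in self.doublet_report.tests:
            lines.append(
                f"doublet test: cluster {test.candidate} "
                f"t={test.t:.3f} df={test.df} p={test.p_value:.3g} "
                f"mean-diff={test.mean_difference:.3f} "
                f"[{test.ci_low:.3f}, {test.ci_high:.3f}] "
                f"{'FLAGGED' if test.flagged else 'not flagged'}"
            )
        m = self.metrics
        lines.append("")
        lines.append(
            f"coverage: amplicon GI={m.gini_amplicons:.3f} "
            f"cell GI={m.gini_cells:.3f} "
            f"CV amplicons={m.cv_amplicons:.1f}% cells={m.cv_cells:.1f}%"
        )
        extras = [f"amplicon success={m.amplicon_success_pct:.1f}%"]
        if m.ado_pct is not None:
            extras.append(f"ADO={m.ado_pct:.1f}%")
        if m.doublet_pct is not None:
            extras.append(f"doublets={m.doublet_pct:.1f}%")
        lines.append("metrics: " + "  ".join(extras))
        if self.tree is not None:
            truncal = sum(
                1 for e in self.tree.events
                if e.truncal and e.kind == "mutation"
            )
            lines.append(
                f"lineage: MRCA={self.tree.mrca}; "
                f"{truncal} truncal mutations; newick below"
            )
            lines.append(self.tree.newick(annotate=False))
        return "\n".join(lines)
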