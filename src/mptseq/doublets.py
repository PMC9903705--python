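"""Doublet screening from normalized read-depth ratios.

Doublets carry roughly twice the DNA content of a singlet, so on a
depth-preserving ratio scale their cluster sits near 2x while genuine cell
clusters sit near 1x.  The screen takes an existing cluster assignment,
summarises each non-outlier cluster by the log2 of the grand mean of its
ratio values, and tests the highest cluster against the per-variant mean of
the remaining tumor clusters with a one-sided paired t-test (paired across
variants/amplicons).  A significantly higher candidate is re-labeled as a
doublet cluster and its cells excluded downstream.

Because the candidate is chosen as the maximum of ``k`` cluster summaries,
the test is Bonferroni-corrected by the number of clusters in the comparison
by default; without the correction the max-selection inflates the false-flag
rate above the nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import (
    ROLE_DOUBLET,
    ROLE_NORMAL,
    ROLE_OUTLIER,
    ROLE_TUMOR,
    ClusterAssignment,
)
from .copynumber import CopyRatioMatrix


@dataclass
class DoubletTest:
    candidate: int
    flagged: bool
    t: float
    df: int
    p_value: float
    alpha_effective: float
    mean_difference: float
    ci_low: float
    ci_high: float
    candidate_log2_mean: float
    comparison_log2_mean: float


@dataclass
class DoubletReport:
    tests: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def flagged_clusters(self) -> list:
        return [t.candidate for t in self.tests if t.flagged]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.tests])


def cluster_ratio_summaries(
    ratios: pd.DataFrame, assignment: ClusterAssignment, labels=None
) -> pd.DataFrame:
    """Per-cluster per-variant mean ratio plus log2 grand mean."""
    rows = {}
    for lab in labels if labels is not None else assignment.cluster_labels():
        cells = [c for c in assignment.cells_in(lab) if c in ratios.index]
        if cells:
            rows[lab] = ratios.loc[cells].mean(axis=0)
    frame = pd.DataFrame(rows).T
    frame["log2_mean_ratio"] = np.log2(frame.mean(axis=1))
    return frame


def detect_doublet_clusters(
    ratios: CopyRatioMatrix | pd.DataFrame,
    assignment: ClusterAssignment,
    alpha: float = 0.05,
    iterative: bool = False,
    correct_for_selection: bool = True,
    min_log2_effect: float = 0.5,
) -> tuple[ClusterAssignment, DoubletReport]:
    """Flag the highest-ratio cluster as doublets when significantly elevated.

    Returns an updated assignment (roles modified; flagged clusters get the
    doublet role) and a report with the t statistic, degrees of freedom,
    mean of differences and its 95% CI for every test performed.  With
    ``iterative`` the screen repeats on the remaining clusters until the top
    cluster is no longer significant, which matters when doublets of
    different clone pairs split into several clusters.
    """
    frame = ratios.defined if isinstance(ratios, CopyRatioMatrix) else ratios
    frame = frame.dropna(axis=1, how="any")
    report = DoubletReport()
    roles = dict(assignment.roles)

    if frame.shape[1] < 5:
        report.warnings.append("fewer than 5 amplicons; t-test not attempted")
        return ClusterAssignment(assignment.labels, roles), report

    while True:
        active = [lab for lab in assignment.cluster_labels()
                  if roles.get(lab) in (ROLE_TUMOR, ROLE_NORMAL)]
        if len(active) < 2:
            report.warnings.append("fewer than 2 non-outlier clusters; no-op")
            break
        summaries = cluster_ratio_summaries(frame, assignment, labels=active)
        candidate = summaries["log2_mean_ratio"].idxmax()
        rest = [lab for lab in active if lab != candidate
                and roles.get(lab) != ROLE_NORMAL]
        if not rest:  # only the normal cluster remains for comparison
            rest = [lab for lab in active if lab != candidate]
        cand_vec = summaries.loc[candidate].drop("log2_mean_ratio")
        # cell-count weighting keeps a second small elevated (doublet)
        # cluster from dragging the comparison level upward
        weights = np.array(
            [len(assignment.cells_in(lab)) for lab in rest], float
        )
        comp_vec = (
            summaries.loc[rest].drop(columns="log2_mean_ratio")
            .mul(weights / weights.sum(), axis=0)
            .sum(axis=0)
        )

        n_compared = len(active)
        alpha_eff = alpha / n_compared if correct_for_selection else alpha
        res = stats.ttest_rel(cand_vec, comp_vec, alternative="greater")
        diff = cand_vec - comp_vec
        df = len(diff) - 1
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        t_crit = stats.t.ppf(0.975, df)
        log2_shift = (
            float(summaries.loc[candidate, "log2_mean_ratio"])
            - float(np.log2(comp_vec.mean()))
        )
        # doublets are a discrete ~2x (log2 = 1) phenomenon; the effect floor
        # keeps the very powerful paired test from flagging percent-level
        # depth drifts between genuine cell clusters
        flagged = bool(
            res.pvalue < alpha_eff
            and diff.mean() > 0
            and log2_shift >= min_log2_effect
        )
        report.tests.append(
            DoubletTest(
                candidate=candidate,
                flagged=flagged,
                t=float(res.statistic),
                df=df,
                p_value=float(res.pvalue),
                alpha_effective=alpha_eff,
                mean_difference=float(diff.mean()),
                ci_low=float(diff.mean() - t_crit * se),
                ci_high=float(diff.mean() + t_crit * se),
                candidate_log2_mean=float(summaries.loc[candidate, "log2_mean_ratio"]),
                comparison_log2_mean=float(np.log2(comp_vec.mean())),
            )
        )
        if not flagged:
            break
        roles[candidate] = ROLE_DOUBLET
        if not iterative:
            break
    return ClusterAssignment(assignment.labels, roles), report
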