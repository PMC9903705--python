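"""Amplicon read-depth copy-number estimation.

Two normalization flavours are produced from the same count matrix:

* ``composition`` (default) -- the two-step scheme used for per-cluster copy
  ratios: each cell's counts are divided by the cell's total reads, then each
  amplicon by the median of that normalized value over the diploid reference
  cells.  This removes per-cell capture/depth variation entirely, so 1.0
  means "represented like two copies in a diploid cell".  Because it is
  compositional, values are relative: a clone whose mean copy number differs
  from 2 carries a clone-constant scale bias, and total-content effects
  (e.g. doublets) are invisible by construction.

* ``depth`` -- each amplicon is divided by the median raw count of the
  reference cells at that amplicon, with no per-cell rescaling.  Per-cell
  capture noise survives, but so does total DNA content, which is exactly
  the signal doublet screening needs; cluster-level averaging then washes
  the capture noise out.

Cluster medians of the composition ratios, thresholded on the log2 scale,
give the gain/loss calls; integer copy number for pseudo-bulk references is
obtained by scaling segment ratios with a FACS-derived ploidy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment, CloneProfile
from .io import MatrixBundle

GAIN_LOG2 = 0.32   # ~1.25x
LOSS_LOG2 = -0.32  # ~0.80x


@dataclass
class CopyRatioMatrix:
    """Cells x amplicons ratios plus provenance of the reference cells."""

    ratios: pd.DataFrame
    reference_cells: list
    undefined_amplicons: list  # normal median was 0; excluded downstream
    scale: str = "composition"

    @property
    def defined(self) -> pd.DataFrame:
        return self.ratios.drop(columns=self.undefined_amplicons)


@dataclass
class PloidyModel:
    """FACS DNA-content peaks: ploidy = 2 x aneuploid peak / diploid peak."""

    diploid_peak_position: float
    aneuploid_peak_position: float

    @property
    def ploidy(self) -> float:
        if self.diploid_peak_position <= 0 or self.aneuploid_peak_position <= 0:
            raise ValueError("FACS peak positions must be positive")
        return 2.0 * self.aneuploid_peak_position / self.diploid_peak_position


def estimate_copy_ratios(
    counts: MatrixBundle, normal_cells, scale: str = "composition"
) -> CopyRatioMatrix:
    """Normalize counts against the diploid reference population.

    ``normal_cells`` are the cells whose per-amplicon medians define the
    reference representation.  Cells with zero total reads are excluded and
    reported implicitly by their absence.  Amplicons whose reference median
    is 0 are flagged undefined.
    """
    normal_cells = list(normal_cells)
    if not normal_cells:
        raise ValueError("reference (normal) cell set is empty")
    frame = counts.layer_frame("COUNT").astype(float)
    missing = set(normal_cells) - set(frame.index)
    if missing:
        raise ValueError(f"unknown reference cells: {sorted(missing)[:3]}...")

    if scale == "composition":
        totals = frame.sum(axis=1)
        usable = totals > 0
        norm = frame[usable].div(totals[usable], axis=0)
    elif scale == "depth":
        norm = frame
        usable = pd.Series(True, index=frame.index)
    else:
        raise ValueError(f"unknown scale {scale!r}")

    ref = norm.loc[[c for c in normal_cells if usable.get(c, False)]]
    if not len(ref):
        raise ValueError("no usable reference cells (all zero-total)")
    ref_median = ref.median(axis=0)
    undefined = list(ref_median.index[ref_median == 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = norm.div(ref_median, axis=1)
    ratios[undefined] = np.nan
    return CopyRatioMatrix(ratios, normal_cells, undefined, scale=scale)


def summarize_cluster_cn(
    ratios: CopyRatioMatrix,
    assignment: ClusterAssignment,
    profiles: list | None = None,
    gain_log2: float = GAIN_LOG2,
    loss_log2: float = LOSS_LOG2,
) -> pd.DataFrame:
    """Per-cluster median copy ratio and gain/loss calls.

    Returns a tidy frame (cluster, amplicon, median_ratio, log2_ratio, call)
    and, when clone ``profiles`` are supplied, attaches the ratio and call
    vectors to each profile in place.
    """
    frame = ratios.defined
    rows = []
    by_label = {}
    for lab in assignment.cluster_labels():
        cells = [c for c in assignment.cells_in(lab) if c in frame.index]
        if not cells:
            raise ValueError(f"cluster {lab} has no cells in the ratio matrix")
        med = frame.loc[cells].median(axis=0)
        with np.errstate(divide="ignore"):
            log2 = np.log2(med.where(med > 0))
        call = pd.Series("neutral", index=med.index)
        call[log2 >= gain_log2] = "gain"
        call[log2 <= loss_log2] = "loss"
        by_label[lab] = (med, call)
        for amp in med.index:
            rows.append({
                "cluster": lab, "amplicon": amp,
                "median_ratio": med[amp], "log2_ratio": log2[amp],
                "call": call[amp],
            })
    if profiles is not None:
        for profile in profiles:
            if profile.label in by_label:
                med, call = by_label[profile.label]
                profile.median_copy_ratio = med
                profile.cna_call = call
    return pd.DataFrame(rows)


def integer_cn_profile(
    segment_ratios, ploidy: float | PloidyModel
) -> np.ndarray:
    """Integer copy number per segment: ``round(ratio x ploidy)``.

    ``segment_ratios`` may be a vector (one cell) or a cells x segments
    array.  Rounding is half-away-from-zero, so a ratio exactly at ``x.5``
    copies rounds up rather than to the nearest even integer.
    """
    if isinstance(ploidy, PloidyModel):
        ploidy = ploidy.ploidy
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    ratios = np.asarray(segment_ratios, float)
    if (ratios < 0).any():
        raise ValueError("segment ratios must be non-negative")
    scaled = ratios * ploidy
    return np.floor(scaled + 0.5).astype(int)


def consensus_integer_cn(
    cell_segment_ratios, ploidy: float | PloidyModel
) -> np.ndarray:
    """Pseudo-bulk consensus: per-segment median of the cells' integer
    copy-number profiles."""
    per_cell = integer_cn_profile(np.atleast_2d(cell_segment_ratios), ploidy)
    return np.median(per_cell, axis=0)
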