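"""Synthetic targeted single-cell DNA-seq datasets with matched ground truth.

The generator emulates the structure of a targeted-panel tumor experiment:
a diploid normal population plus 1-3 tumor subclones related by a perfect
phylogeny (no back mutation), clone-specific integer copy-number states,
per-amplicon amplification-efficiency variation, per-cell capture noise,
overdispersed (negative-binomial) amplicon counts, allelic dropout on
heterozygous sites, sporadic genotype errors, and doublets formed by
co-encapsulation of two independently drawn cells.

Default rates follow the experimental regime the pipeline is designed for:
~164x mean depth per cell per amplicon, ~9% allelic dropout, ~8% doublets,
negative-binomial dispersion ``size = 10`` and lognormal per-cell capture
noise (sigma = 0.3), which together give amplicon-level coverage Gini around
0.3 and cell-level Gini noticeably higher, matching targeted amplicon
chemistry where cell-to-cell capture varies more than amplicon-to-amplicon
efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, MatrixBundle


@dataclass
class CnaEvent:
    """Assign integer copy number ``cn`` to ``amplicons`` on the branch above
    ``clone`` (the clone and every descendant clone inherit the state)."""

    clone: int  # 1-based tumor clone index
    amplicons: list
    cn: int


@dataclass
class SimTruth:
    """Ground truth for one simulated sample.

    Clone 0 is always the diploid normal population (genotype all reference,
    copy number 2 everywhere).  Tumor clones are numbered 1..k.  Somatic
    variants come first in ``variant_ids``; germline heterozygous SNPs (het in
    every cell, used downstream as known-het sites for allelic-dropout
    estimation) are appended after them.
    """

    clone_parents: list          # parent index per clone; root (clone 0) -> -1
    clone_genotypes: np.ndarray  # clones x somatic variants, NGT codes
    clone_cn: np.ndarray         # clones x amplicons, integer copies
    clone_proportions: np.ndarray
    amplicon_efficiency: np.ndarray
    variant_amplicon: np.ndarray  # amplicon index per variant (somatic+germline)
    variant_ids: list
    amplicon_ids: list
    n_germline_snps: int
    doublet_rate: float = 0.08
    ado_rate: float = 0.09
    error_rate: float = 0.005
    mean_depth: float = 164.0
    dispersion: float = 10.0      # negative-binomial size; larger = less noise
    capture_sigma: float = 0.3    # lognormal sigma of per-cell capture factor

    @property
    def n_clones(self) -> int:
        return self.clone_cn.shape[0]

    @property
    def n_somatic(self) -> int:
        return self.clone_genotypes.shape[1]

    @property
    def somatic_ids(self) -> list:
        return self.variant_ids[: self.n_somatic]

    @property
    def germline_ids(self) -> list:
        return self.variant_ids[self.n_somatic:]

    def clone_mutation_counts(self) -> np.ndarray:
        """Number of somatic mutations carried by each clone."""
        return (self.clone_genotypes > 0).sum(axis=1)

    def cell_genotype(self, clone: int) -> np.ndarray:
        """Full NGT vector (somatic then germline-het) for a singlet cell."""
        germ = np.ones(self.n_germline_snps, dtype=int)
        return np.concatenate([self.clone_genotypes[clone], germ])

    def validate(self):
        prop = np.asarray(self.clone_proportions, float)
        if not np.isclose(prop.sum(), 1.0):
            raise ValueError("clone proportions must sum to 1")
        if (self.clone_genotypes[0] != 0).any():
            raise ValueError("diploid clone must be all-reference")
        if (self.clone_cn[0] != 2).any():
            raise ValueError("diploid clone must be CN 2 everywhere")
        for child in range(1, self.n_clones):
            parent = self.clone_parents[child]
            if parent < 0:
                continue
            pmut = self.clone_genotypes[parent] > 0
            cmut = self.clone_genotypes[child] > 0
            if (pmut & ~cmut).any():
                raise ValueError(
                    f"clone {child} lost a mutation of its parent (back mutation)"
                )


@dataclass
class CellTruth:
    cell_id: str
    clone: int
    clone2: int | None = None  # second parent clone for doublets

    @property
    def is_doublet(self) -> bool:
        return self.clone2 is not None


def simulate_truth(
    n_clones: int = 3,
    n_variants: int = 69,
    n_amplicons: int = 330,
    n_truncal: int = 15,
    private_counts: tuple | None = None,
    cna_events: list | None = None,
    tumor_fraction: float = 0.8,
    clone_proportions=None,
    n_germline_snps: int = 20,
    mutation_ngt: int = 2,
    seed: int = 0,
    **rates,
) -> SimTruth:
    """Build the ground-truth clonal structure of one sample.

    ``n_clones`` counts tumor subclones; a diploid population (clone 0) is
    always added.  The first tumor clone carries the truncal mutations plus
    its own private block; every later clone descends from the first tumor
    clone and adds its private block, so clone mutation sets are nested along
    each root-to-leaf path (perfect phylogeny).  With the defaults
    (``n_truncal=15``, ``private_counts=(0, 8, 28)``) the three tumor clones
    carry 15/23/43 mutations.

    ``cna_events`` is a list of :class:`CnaEvent`; each applies to a tumor
    clone and all of its descendants.  ``mutation_ngt`` is the genotype code
    given to somatic mutations (homozygous alternate by default, the dominant
    pattern at high-VAF truncal sites).
    """
    rng = np.random.default_rng(seed)
    if n_clones < 1:
        raise ValueError("need at least one tumor clone")
    if private_counts is None:
        # first three clones follow the benchmark pattern; further clones
        # get modest random private blocks
        base = (0, 8, 28)
        private_counts = tuple(
            base[i] if i < len(base) else int(rng.integers(3, 11))
            for i in range(n_clones)
        )
    if len(private_counts) != n_clones:
        raise ValueError("private_counts must have one entry per tumor clone")
    total_mut = n_truncal + sum(private_counts)
    if total_mut > n_variants - 0:
        raise ValueError(
            f"mutation budget {total_mut} exceeds n_variants={n_variants}"
        )
    if n_variants > n_amplicons:
        raise ValueError("need at least one amplicon per variant")

    # clone 0 = diploid; clone 1 = first tumor clone; clones 2..k children of 1
    parents = [-1, 0] + [1] * (n_clones - 1)
    genotypes = np.zeros((n_clones + 1, n_variants), dtype=int)
    cursor = 0
    truncal_idx = np.arange(cursor, cursor + n_truncal)
    cursor += n_truncal
    genotypes[1:, truncal_idx] = mutation_ngt
    for i, k in enumerate(private_counts):
        idx = np.arange(cursor, cursor + k)
        cursor += k
        clone = i + 1
        genotypes[clone, idx] = mutation_ngt
        # descendants inherit (children of clone 1 inherit its privates)
        for child in range(1, n_clones + 1):
            if parents[child] == clone:
                genotypes[child, idx] = mutation_ngt

    cn = np.full((n_clones + 1, n_amplicons), 2, dtype=int)
    for event in cna_events or []:
        if not 1 <= event.clone <= n_clones:
            raise ValueError(f"CNA event names unknown clone {event.clone}")
        members = [event.clone] + [
            c for c in range(1, n_clones + 1) if parents[c] == event.clone
        ]
        for clone in members:
            cn[clone, list(event.amplicons)] = event.cn

    if clone_proportions is None:
        tumor = np.full(n_clones, tumor_fraction / n_clones)
        # mildly uneven subclone sizes, fixed split pattern
        if n_clones == 3:
            tumor = tumor_fraction * np.array([0.45, 0.30, 0.25])
        elif n_clones == 2:
            tumor = tumor_fraction * np.array([0.6, 0.4])
        proportions = np.concatenate([[1.0 - tumor_fraction], tumor])
    else:
        proportions = np.asarray(clone_proportions, float)
        if len(proportions) != n_clones + 1:
            raise ValueError("clone_proportions must include the diploid clone")

    # lognormal sigma ~0.95 reproduces the cell-level coverage inequality of
    # targeted amplicon panels (per-cell across-amplicon Gini ~0.5, CV ~125%)
    # and leaves ~85-90% of amplicons above the 0.2x-mean success threshold
    efficiency = rng.lognormal(mean=0.0, sigma=0.95, size=n_amplicons)
    efficiency /= efficiency.mean()

    variant_amplicon = np.arange(n_variants + n_germline_snps) % n_amplicons
    variant_ids = [f"v{i:03d}" for i in range(n_variants)] + [
        f"snp{i:03d}" for i in range(n_germline_snps)
    ]
    amplicon_ids = [f"amp{i:03d}" for i in range(n_amplicons)]
    truth = SimTruth(
        clone_parents=parents,
        clone_genotypes=genotypes,
        clone_cn=cn,
        clone_proportions=proportions,
        amplicon_efficiency=efficiency,
        variant_amplicon=variant_amplicon,
        variant_ids=variant_ids,
        amplicon_ids=amplicon_ids,
        n_germline_snps=n_germline_snps,
        **rates,
    )
    truth.validate()
    return truth


def simulate_cells(truth: SimTruth, n_cells: int, seed: int = 0) -> list:
    """Draw cell clone labels and doublet status.

    Each barcode is a doublet with probability ``truth.doublet_rate``; a
    doublet's two parent cells are drawn independently from the clone
    proportions (so a fraction are same-clone doublets, which are genuinely
    indistinguishable in genotype space).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    clones = rng.choice(truth.n_clones, size=n_cells, p=truth.clone_proportions)
    is_doublet = rng.random(n_cells) < truth.doublet_rate
    second = rng.choice(truth.n_clones, size=n_cells, p=truth.clone_proportions)
    cells = []
    for i in range(n_cells):
        cells.append(
            CellTruth(
                cell_id=f"cell{i:05d}",
                clone=int(clones[i]),
                clone2=int(second[i]) if is_doublet[i] else None,
            )
        )
    return cells


def _nb_counts(rng, lam, size):
    """Negative binomial draws with mean ``lam`` and dispersion ``size``
    (Gamma-Poisson mixture); ``size -> inf`` degenerates to Poisson."""
    lam = np.asarray(lam, float)
    if not np.isfinite(size):
        return rng.poisson(lam)
    gamma = rng.gamma(shape=size, scale=1.0 / size, size=lam.shape)
    return rng.poisson(lam * gamma)


def simulate_observations(
    truth: SimTruth, cells: list, seed: int = 0
) -> tuple[MatrixBundle, MatrixBundle]:
    """Generate the observed count and genotype bundles for a set of cells.

    Count model: ``COUNT[c, a] ~ NegBin`` with mean
    ``mean_depth * efficiency[a] * (CN[c, a] / 2) * capture[c]`` where
    ``capture[c]`` is lognormal cell-to-cell noise.  A doublet's expected
    counts are the sum of its two parents' expectations, i.e. roughly twice
    the total content of a singlet before capture noise.

    Genotypes: the cell's true NGT, with heterozygous sites dropped to a
    homozygous call with probability ``ado_rate`` (ref/alt symmetric), then
    flipped to a random other code with probability ``error_rate``.  DP is
    the count at the variant's amplicon, AF is binomial given DP and the
    called genotype, and GQ is high for faithful calls and low for errors.
    """
    rng = np.random.default_rng(seed)
    n_cells = len(cells)
    n_amp = len(truth.amplicon_ids)
    n_var = len(truth.variant_ids)

    capture = rng.lognormal(mean=-0.5 * truth.capture_sigma**2,
                            sigma=truth.capture_sigma, size=n_cells)
    base = truth.mean_depth * truth.amplicon_efficiency  # per-amplicon scale

    lam = np.empty((n_cells, n_amp))
    true_ngt = np.empty((n_cells, n_var), dtype=int)
    for i, cell in enumerate(cells):
        expected = base * (truth.clone_cn[cell.clone] / 2.0)
        g1 = truth.cell_genotype(cell.clone)
        if cell.is_doublet:
            expected = expected + base * (truth.clone_cn[cell.clone2] / 2.0)
            g2 = truth.cell_genotype(cell.clone2)
            # combined allele content of the two cells, called as one barcode
            alt_frac = (g1 + g2) / 4.0
            true_ngt[i] = np.select(
                [alt_frac == 0, alt_frac == 1], [0, 2], default=1
            )
        else:
            true_ngt[i] = g1
        lam[i] = expected * capture[i]

    counts = _nb_counts(rng, lam, truth.dispersion)

    ngt = true_ngt.copy()
    het = ngt == 1
    drop = het & (rng.random(ngt.shape) < truth.ado_rate)
    ngt[drop] = np.where(rng.random(ngt.shape)[drop] < 0.5, 0, 2)
    err = rng.random(ngt.shape) < truth.error_rate
    shift = rng.integers(1, 3, size=ngt.shape)
    ngt[err] = (ngt[err] + shift[err]) % 3
    errored = err & (ngt != true_ngt)

    dp = counts[:, truth.variant_amplicon]
    p_alt = np.array([0.002, 0.5, 0.998, 0.0])[ngt]
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_reads = rng.binomial(dp, p_alt)
        af = np.where(dp > 0, alt_reads / np.maximum(dp, 1), 0.0)
    gq = rng.integers(60, 100, size=ngt.shape)
    gq[errored] = rng.integers(10, 51, size=int(errored.sum()))

    cell_ids = [c.cell_id for c in cells]
    count_bundle = MatrixBundle(
        cell_ids, truth.amplicon_ids, {"COUNT": counts.astype(int)}
    )
    genotype_bundle = MatrixBundle(
        cell_ids, truth.variant_ids,
        {"NGT": ngt, "DP": dp.astype(int), "GQ": gq.astype(int), "AF": af},
    )
    return count_bundle, genotype_bundle


def simulate_dataset(
    truth: SimTruth, n_cells: int, seed: int = 0
) -> tuple[MatrixBundle, MatrixBundle, list]:
    """Convenience wrapper: draw cells then observations (two derived seeds)."""
    rng = np.random.default_rng(seed)
    s1, s2 = rng.integers(0, 2**31 - 1, size=2)
    cells = simulate_cells(truth, n_cells, seed=int(s1))
    counts, genotypes = simulate_observations(truth, cells, seed=int(s2))
    return counts, genotypes, cells


def derive_pseudobulk(truth: SimTruth) -> tuple[pd.Series, pd.Series]:
    """Exact (sampling-free) bulk references implied by the clone mixture.

    Bulk VAF at a locus pools alleles over clones:
    ``sum_z p_z * alt_copies(z) / sum_z p_z * total_copies(z)`` where a
    heterozygous clone contributes half its copies as alternate.  Bulk copy
    number is the proportion-weighted mean of clone copy number.
    """
    prop = truth.clone_proportions
    n_var = len(truth.variant_ids)
    vaf = np.zeros(n_var)
    for v in range(n_var):
        amp = truth.variant_amplicon[v]
        total = alt = 0.0
        for z in range(truth.n_clones):
            cn = truth.clone_cn[z, amp]
            g = truth.cell_genotype(z)[v]
            alt += prop[z] * cn * (g / 2.0)
            total += prop[z] * cn
        vaf[v] = alt / total if total > 0 else np.nan
    bulk_cn = truth.clone_cn.T @ prop
    return (
        pd.Series(vaf, index=truth.variant_ids, name="bulk_vaf"),
        pd.Series(bulk_cn, index=truth.amplicon_ids, name="bulk_cn"),
    )


def truth_tables(truth: SimTruth, cells: list) -> dict:
    """Ground truth as plain DataFrames (for writing next to simulated data)."""
    clones = pd.DataFrame(
        truth.clone_genotypes,
        index=[f"clone{z}" for z in range(truth.n_clones)],
        columns=truth.somatic_ids,
    )
    cn = pd.DataFrame(
        truth.clone_cn,
        index=[f"clone{z}" for z in range(truth.n_clones)],
        columns=truth.amplicon_ids,
    )
    cell_table = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "clone": [c.clone for c in cells],
            "clone2": [c.clone2 if c.is_doublet else -1 for c in cells],
            "is_doublet": [c.is_doublet for c in cells],
        }
    )
    return {"clone_genotypes": clones, "clone_cn": cn, "cells": cell_table}
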