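"""Cell calling, the single-cell genotype filter cascade, and bulk filters.

The single-cell cascade mirrors the standard targeted scDNA-seq defaults:
entries are first masked to missing where genotype quality < 30, depth < 10,
or an alternate call has allele fraction < 20%; then variants genotyped in
fewer than 50% of cells, cells genotyped at fewer than 50% of variants,
variants mutated in fewer than 1% of cells, and variants heterozygous in
more than 95% of cells (germline SNPs) are dropped; finally any remaining
row/column with more than 50% missing entries is dropped.  Because the
row/column stages interact (dropping variants changes per-cell completeness),
the cascade loops to a fixed point, which also makes it idempotent.

Every removal is recorded in a tab-friendly ledger DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, MatrixBundle


@dataclass
class ScFilterConfig:
    min_gq: float = 30.0
    min_dp: int = 10
    min_af_for_alt: float = 0.20
    min_frac_cells_genotyped_per_variant: float = 0.50
    min_frac_variants_genotyped_per_cell: float = 0.50
    min_frac_cells_mutated: float = 0.01
    germline_het_frac: float = 0.95
    max_na_frac: float = 0.50
    cell_completeness: float = 0.80
    total_reads_factor: float = 0.20  # cutoff = factor x median per-cell total


@dataclass
class BulkFilterConfig:
    min_supporting_reads: int = 3
    cluster_window_bp: int = 10
    min_site_coverage: int = 10
    min_mapq: int = 40  # applies only to read-level ingest; no-op on VCF input


def call_cells(counts: MatrixBundle, cfg: ScFilterConfig | None = None) -> list:
    """Barcodes kept as cells: >= ``cell_completeness`` of amplicons covered
    and a total-read count above ``total_reads_factor`` x the median cell."""
    cfg = cfg or ScFilterConfig()
    mat = counts.layers["COUNT"]
    if mat.shape[1] == 0:
        raise ValueError("count matrix has zero amplicons")
    completeness = (mat > 0).mean(axis=1)
    totals = mat.sum(axis=1)
    cutoff = cfg.total_reads_factor * np.median(totals)
    keep = (completeness >= cfg.cell_completeness) & (totals >= cutoff)
    return [c for c, k in zip(counts.cell_ids, keep) if k]


@dataclass
class FilterResult:
    bundle: MatrixBundle | None  # None when everything was filtered
    ledger: pd.DataFrame

    @property
    def all_filtered(self) -> bool:
        return self.bundle is None


def _ledger_row(stage, rule, axis, item, detail=""):
    return {"stage": stage, "rule": rule, "axis": axis, "item": item,
            "detail": detail}


def filter_single_cell_matrix(
    bundle: MatrixBundle, cfg: ScFilterConfig | None = None
) -> FilterResult:
    """Run the six-stage genotype filter cascade; see module docstring."""
    cfg = cfg or ScFilterConfig()
    ngt = bundle.layers["NGT"].copy()
    dp = bundle.layers["DP"]
    gq = bundle.layers["GQ"]
    af = bundle.layers["AF"]
    rows = []

    # stage 1: entry-level masking
    low_gq = gq < cfg.min_gq
    low_dp = dp < cfg.min_dp
    low_af = np.isin(ngt, (1, 2)) & (af < cfg.min_af_for_alt)
    mask = (low_gq | low_dp | low_af) & (ngt != MISSING)
    for rule, m in (("min_gq", low_gq), ("min_dp", low_dp),
                    ("min_af_for_alt", low_af)):
        n = int((m & (ngt != MISSING)).sum())
        if n:
            rows.append(_ledger_row("1_mask", rule, "entry", "", f"n={n}"))
    ngt[mask] = MISSING

    cells = np.array(bundle.cell_ids, dtype=object)
    variants = np.array(bundle.feature_ids, dtype=object)
    keep_c = np.ones(len(cells), bool)
    keep_v = np.ones(len(variants), bool)

    def frac(mask_ok, axis):
        with np.errstate(invalid="ignore"):
            return mask_ok.mean(axis=axis)

    changed = True
    iteration = 0
    while changed:
        changed = False
        iteration += 1
        sub = ngt[np.ix_(keep_c, keep_v)]
        genotyped = sub != MISSING

        # stage 2: variants genotyped in too few cells
        if sub.shape[0] and sub.shape[1]:
            v_frac = genotyped.mean(axis=0)
            drop = v_frac < cfg.min_frac_cells_genotyped_per_variant
            if drop.any():
                for vid, f in zip(variants[keep_v][drop], v_frac[drop]):
                    rows.append(_ledger_row(
                        "2_variant_genotyped", "min_frac_cells_genotyped",
                        "variant", vid, f"frac={f:.3f}"))
                idx = np.where(keep_v)[0][drop]
                keep_v[idx] = False
                changed = True
                sub = ngt[np.ix_(keep_c, keep_v)]
                genotyped = sub != MISSING

        # stage 3: cells genotyped at too few variants
        if sub.shape[0] and sub.shape[1]:
            c_frac = genotyped.mean(axis=1)
            drop = c_frac < cfg.min_frac_variants_genotyped_per_cell
            if drop.any():
                for cid, f in zip(cells[keep_c][drop], c_frac[drop]):
                    rows.append(_ledger_row(
                        "3_cell_genotyped", "min_frac_variants_genotyped",
                        "cell", cid, f"frac={f:.3f}"))
                idx = np.where(keep_c)[0][drop]
                keep_c[idx] = False
                changed = True
                sub = ngt[np.ix_(keep_c, keep_v)]
                genotyped = sub != MISSING

        if not (sub.shape[0] and sub.shape[1]):
            break

        # stage 4: variants mutated in too few genotyped cells
        mutated = np.isin(sub, (1, 2))
        with np.errstate(invalid="ignore"):
            mut_frac = np.where(
                genotyped.sum(axis=0) > 0,
                mutated.sum(axis=0) / np.maximum(genotyped.sum(axis=0), 1),
                0.0,
            )
        drop = mut_frac < cfg.min_frac_cells_mutated
        if drop.any():
            for vid, f in zip(variants[keep_v][drop], mut_frac[drop]):
                rows.append(_ledger_row(
                    "4_rarely_mutated", "min_frac_cells_mutated",
                    "variant", vid, f"frac={f:.4f}"))
            idx = np.where(keep_v)[0][drop]
            keep_v[idx] = False
            changed = True
            sub = ngt[np.ix_(keep_c, keep_v)]
            genotyped = sub != MISSING

        # stage 5: germline heterozygous variants.  Allelic dropout converts
        # a slice of true hets to homozygous calls, so a pure het-fraction
        # test would miss germline SNPs whenever ADO exceeds the 5% margin;
        # the rule therefore asks for the alt allele present in >95% of
        # genotyped cells with heterozygous as the dominant mutant state.
        if sub.shape[1]:
            mutated5 = np.isin(sub, (1, 2))
            het = sub == 1
            with np.errstate(invalid="ignore"):
                n_geno = np.maximum(genotyped.sum(axis=0), 1)
                present_frac = np.where(
                    genotyped.sum(axis=0) > 0, mutated5.sum(axis=0) / n_geno, 0.0
                )
                het_share = np.where(
                    mutated5.sum(axis=0) > 0,
                    het.sum(axis=0) / np.maximum(mutated5.sum(axis=0), 1),
                    0.0,
                )
            drop = (present_frac > cfg.germline_het_frac) & (het_share > 0.5)
            if drop.any():
                for vid, f in zip(variants[keep_v][drop], present_frac[drop]):
                    rows.append(_ledger_row(
                        "5_germline_het", "germline_het_frac",
                        "variant", vid, f"frac={f:.3f}"))
                idx = np.where(keep_v)[0][drop]
                keep_v[idx] = False
                changed = True
                sub = ngt[np.ix_(keep_c, keep_v)]
                genotyped = sub != MISSING

        # stage 6: rows/columns with too much missing
        if sub.shape[0] and sub.shape[1]:
            na_v = (sub == MISSING).mean(axis=0)
            drop = na_v > cfg.max_na_frac
            if drop.any():
                for vid, f in zip(variants[keep_v][drop], na_v[drop]):
                    rows.append(_ledger_row(
                        "6_na_fraction", "max_na_frac", "variant", vid,
                        f"frac={f:.3f}"))
                idx = np.where(keep_v)[0][drop]
                keep_v[idx] = False
                changed = True
                sub = ngt[np.ix_(keep_c, keep_v)]
            if sub.shape[0] and sub.shape[1]:
                na_c = (sub == MISSING).mean(axis=1)
                drop = na_c > cfg.max_na_frac
                if drop.any():
                    for cid, f in zip(cells[keep_c][drop], na_c[drop]):
                        rows.append(_ledger_row(
                            "6_na_fraction", "max_na_frac", "cell", cid,
                            f"frac={f:.3f}"))
                    idx = np.where(keep_c)[0][drop]
                    keep_c[idx] = False
                    changed = True

    ledger = pd.DataFrame(rows, columns=["stage", "rule", "axis", "item",
                                         "detail"])
    if not keep_c.any() or not keep_v.any():
        return FilterResult(None, ledger)

    kept_cells = list(cells[keep_c])
    kept_variants = list(variants[keep_v])
    ci = np.where(keep_c)[0]
    vi = np.where(keep_v)[0]
    layers = {
        "NGT": ngt[np.ix_(ci, vi)],
        "DP": dp[np.ix_(ci, vi)],
        "GQ": gq[np.ix_(ci, vi)],
        "AF": af[np.ix_(ci, vi)],
    }
    return FilterResult(MatrixBundle(kept_cells, kept_variants, layers), ledger)


def filter_bulk_variants(
    table: pd.DataFrame, cfg: BulkFilterConfig | None = None
) -> pd.DataFrame:
    """Bulk variant filters: consensus support, clustered-region removal, and
    low-coverage NA flagging.

    Variants with fewer than ``min_supporting_reads`` supporting reads are
    removed.  Any group of two or more variants on the same chromosome whose
    positions fall within a ``cluster_window_bp`` sliding window are all
    removed (the window rule removes every member, not just the extras).
    Sites with coverage below ``min_site_coverage`` are retained but flagged
    ``is_na`` so downstream consumers can skip them.
    """
    cfg = cfg or BulkFilterConfig()
    table = table.copy().reset_index(drop=True)
    if "supporting_reads" in table:
        support = table["supporting_reads"].fillna(0)
        table = table[support >= cfg.min_supporting_reads].reset_index(drop=True)

    drop = np.zeros(len(table), bool)
    for chrom, group in table.groupby("chrom"):
        pos = group["pos"].to_numpy()
        order = np.argsort(pos)
        pos_sorted = pos[order]
        idx = group.index.to_numpy()[order]
        for i in range(len(pos_sorted) - 1):
            j = i + 1
            while j < len(pos_sorted) and pos_sorted[j] - pos_sorted[i] < cfg.cluster_window_bp:
                drop[idx[i]] = drop[idx[j]] = True
                j += 1
    table = table[~drop].reset_index(drop=True)

    if "depth" in table:
        table["is_na"] = table["depth"] < cfg.min_site_coverage
    else:
        table["is_na"] = False
    return table
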