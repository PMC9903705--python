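"""Filter cascade exactness on a hand-enumerated fixture, idempotence,
ledger accounting, per-rule monotonicity, and the bulk filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mptseq.io import MISSING, MatrixBundle
from mptseq.qc import (
    BulkFilterConfig,
    ScFilterConfig,
    call_cells,
    filter_bulk_variants,
    filter_single_cell_matrix,
)

M = MISSING


def cascade_fixture() -> MatrixBundle:
    """10 cells x 8 variants with exactly one violation of each cascade rule.

    Hand-enumerated expectations (defaults: GQ>=30, DP>=10, AF>=0.2 for alt
    calls, >=50% genotyped both ways, >=1% mutated, <=95% germline-present,
    <=50% NA):

    * entries (c0,v1), (c1,v1), (c2,v1) masked by the GQ, DP and AF rules;
    * v2 dropped (genotyped in 4/10 cells);
    * c9 dropped (genotyped at 3/7 remaining variants);
    * v3 dropped (mutated in 0 cells);
    * v4 dropped (germline: heterozygous in every genotyped cell);
    * v5 dropped (NA fraction 5/9 after c9 is removed);
    * v0, v1, v6, v7 and cells c0..c8 survive.
    """
    cells = [f"c{i}" for i in range(10)]
    variants = [f"v{j}" for j in range(8)]
    ngt = np.zeros((10, 8), int)
    gq = np.full((10, 8), 99)
    dp = np.full((10, 8), 50)
    af = np.zeros((10, 8), float)

    def set_ngt(ci, vj, code, a=None):
        ngt[ci, vj] = code
        af[ci, vj] = (code / 2.0 if code in (1, 2) else 0.0) if a is None else a

    # v0: clean somatic variant, hom-alt in c0..c4
    for c in range(5):
        set_ngt(c, 0, 2)
    # v1: intended het in c0..c4; c0 fails GQ, c1 fails DP, c2 fails AF
    for c in range(5):
        set_ngt(c, 1, 1)
    gq[0, 1] = 25
    dp[1, 1] = 5
    af[2, 1] = 0.10
    # v2: genotyped only in c0..c3
    for c in range(4, 10):
        ngt[c, 2] = M
    # v3: all reference (never mutated)
    # v4: germline heterozygous SNP in every cell
    for c in range(10):
        set_ngt(c, 4, 1)
    # v5: missing in c0..c4, hom-alt in c5..c8, ref in c9; only the NA rule
    # (after c9's removal) can take it out
    for c in range(5):
        ngt[c, 5] = M
    for c in range(5, 9):
        set_ngt(c, 5, 2)
    # v6: hom-alt in c0..c2
    for c in range(3):
        set_ngt(c, 6, 2)
    # v7: het in c5..c8
    for c in range(5, 9):
        set_ngt(c, 7, 1)
    # c9: genotyped only at v0, v5, v7 among the variants that survive
    # stage 2 (missing at v1, v3, v4, v6; v2 already missing above)
    for vj in (1, 3, 4, 6):
        ngt[9, vj] = M
    return MatrixBundle(cells, variants,
                        {"NGT": ngt, "DP": dp, "GQ": gq, "AF": af})


class TestCascadeFixture:
    def test_exact_masks_and_removals(self):
        result = filter_single_cell_matrix(cascade_fixture())
        bundle = result.bundle
        assert bundle.cell_ids == [f"c{i}" for i in range(9)]
        assert bundle.feature_ids == ["v0", "v1", "v6", "v7"]
        # the three rule-1 masked entries are missing in the output
        v1 = bundle.feature_ids.index("v1")
        assert bundle.layers["NGT"][0, v1] == M
        assert bundle.layers["NGT"][1, v1] == M
        assert bundle.layers["NGT"][2, v1] == M
        assert bundle.layers["NGT"][3, v1] == 1  # untouched het survives

    def test_each_stage_recorded_with_expected_rule(self):
        ledger = filter_single_cell_matrix(cascade_fixture()).ledger
        by_stage = ledger.groupby("stage")["item"].apply(list).to_dict()
        assert by_stage["2_variant_genotyped"] == ["v2"]
        assert by_stage["3_cell_genotyped"] == ["c9"]
        assert by_stage["4_rarely_mutated"] == ["v3"]
        assert by_stage["5_germline_het"] == ["v4"]
        assert by_stage["6_na_fraction"] == ["v5"]
        masked = ledger[ledger["stage"] == "1_mask"]
        assert sorted(masked["rule"]) == ["min_af_for_alt", "min_dp", "min_gq"]
        assert all(d == "n=1" for d in masked["detail"])

    def test_ledger_accounting_is_exact(self):
        result = filter_single_cell_matrix(cascade_fixture())
        ledger = result.ledger
        n_var_removed = (ledger["axis"] == "variant").sum()
        n_cell_removed = (ledger["axis"] == "cell").sum()
        assert 8 == result.bundle.shape[1] + n_var_removed
        assert 10 == result.bundle.n_cells + n_cell_removed

    def test_cascade_is_idempotent(self):
        once = filter_single_cell_matrix(cascade_fixture())
        twice = filter_single_cell_matrix(once.bundle)
        assert twice.bundle.equals(once.bundle)
        assert len(twice.ledger) == 0

    def test_all_filtered_outcome_is_explicit_not_a_crash(self):
        bundle = MatrixBundle(
            ["c0", "c1"], ["v0", "v1"],
            {"NGT": np.full((2, 2), M), "DP": np.full((2, 2), 50),
             "GQ": np.full((2, 2), 99), "AF": np.zeros((2, 2))},
        )
        result = filter_single_cell_matrix(bundle)
        assert result.all_filtered
        assert result.bundle is None


class TestCascadeRuleEdges:
    def test_low_gq_entry_masked_to_missing(self):
        bundle = cascade_fixture()
        result = filter_single_cell_matrix(bundle)
        v1 = result.bundle.feature_ids.index("v1")
        assert result.bundle.layers["NGT"][0, v1] == M

    def test_variant_present_in_96pct_of_cells_removed_as_germline(self):
        rng = np.random.default_rng(0)
        n = 100
        ngt = np.ones((n, 2), int)
        ngt[:50, 1] = 2  # somatic-like control column kept
        ngt[50:, 1] = 0
        ngt[:4, 0] = 0   # germline candidate het in 96/100
        bundle = MatrixBundle(
            [f"c{i}" for i in range(n)], ["germ", "soma"],
            {"NGT": ngt, "DP": np.full((n, 2), 50),
             "GQ": np.full((n, 2), 99), "AF": ngt / 2.0},
        )
        result = filter_single_cell_matrix(bundle)
        assert result.bundle.feature_ids == ["soma"]
        row = result.ledger.set_index("item").loc["germ"]
        assert row["stage"] == "5_germline_het"

    def test_variant_mutated_in_half_percent_of_cells_removed(self):
        n = 1000
        ngt = np.zeros((n, 2), int)
        ngt[:5, 0] = 2    # 0.5% mutated -> removed
        ngt[:500, 1] = 2  # control kept
        bundle = MatrixBundle(
            [f"c{i}" for i in range(n)], ["rare", "common"],
            {"NGT": ngt, "DP": np.full((n, 2), 50),
             "GQ": np.full((n, 2), 99), "AF": ngt / 2.0},
        )
        result = filter_single_cell_matrix(bundle)
        assert result.bundle.feature_ids == ["common"]

    @given(st.integers(0, 40))
    @settings(max_examples=20, deadline=None)
    def test_relaxing_gq_threshold_never_masks_more_entries(self, gq_cut):
        bundle = cascade_fixture()
        strict = filter_single_cell_matrix(bundle, ScFilterConfig(min_gq=gq_cut))
        relaxed = filter_single_cell_matrix(
            bundle, ScFilterConfig(min_gq=max(gq_cut - 10, 0))
        )

        def masked_count(res):
            sub = res.ledger[res.ledger["stage"] == "1_mask"]
            return sum(int(d.split("=")[1]) for d in sub["detail"])

        assert masked_count(relaxed) <= masked_count(strict)


class TestCallCells:
    def make_counts(self, rows):
        return MatrixBundle(
            [f"c{i}" for i in range(len(rows))],
            [f"a{j}" for j in range(len(rows[0]))],
            {"COUNT": np.array(rows)},
        )

    def test_cell_covering_70pct_of_amplicons_excluded(self):
        rows = [[50] * 10 for _ in range(9)]
        rows.append([50] * 7 + [0, 0, 0])  # 70% completeness
        counts = self.make_counts(rows)
        kept = call_cells(counts)
        assert "c9" not in kept and len(kept) == 9

    def test_identical_nonzero_cells_all_retained(self):
        counts = self.make_counts([[10] * 5] * 8)
        assert len(call_cells(counts)) == 8

    def test_hand_fixture_retains_exactly_eight_of_ten(self):
        rows = [[100] * 10 for _ in range(8)]
        rows.append([100] * 6 + [0] * 4)   # 60% completeness
        rows.append([5] * 10)              # low total (50 << 0.2 x 1000)
        counts = self.make_counts(rows)
        kept = call_cells(counts)
        assert kept == [f"c{i}" for i in range(8)]

    def test_zero_amplicons_errors(self):
        counts = MatrixBundle(["c0"], [], {"COUNT": np.zeros((1, 0), int)})
        with pytest.raises(ValueError, match="zero amplicons"):
            call_cells(counts)


class TestBulkFilters:
    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "supporting_reads",
                                           "depth"])

    def test_low_support_variant_removed(self):
        table = self.make_table([("chr1", 100, 2, 50), ("chr1", 500, 5, 50)])
        out = filter_bulk_variants(table)
        assert out["pos"].tolist() == [500]

    def test_clustered_variants_within_window_all_removed(self):
        table = self.make_table([("chr1", 100, 5, 50), ("chr1", 105, 5, 50),
                                 ("chr1", 400, 5, 50)])
        out = filter_bulk_variants(table)
        assert out["pos"].tolist() == [400]

    def test_variants_outside_window_both_retained(self):
        table = self.make_table([("chr1", 100, 5, 50), ("chr1", 150, 5, 50)])
        out = filter_bulk_variants(table)
        assert out["pos"].tolist() == [100, 150]

    def test_low_coverage_sites_flagged_na_but_retained(self):
        table = self.make_table([("chr1", 100, 5, 8), ("chr1", 500, 5, 50)])
        out = filter_bulk_variants(table)
        assert out["is_na"].tolist() == [True, False]

    def test_window_rule_is_per_chromosome(self):
        table = self.make_table([("chr1", 100, 5, 50), ("chr2", 105, 5, 50)])
        out = filter_bulk_variants(table)
        assert len(out) == 2
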