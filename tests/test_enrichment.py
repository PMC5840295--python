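"""Enrichment statistics: control pooling, G-test, fold change, Welch t,
bait-level correction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import baitcall as bc
from baitcall.enrichment import g_test_arrays


def _brute_force_g(k1, n1, k2, n2):
    """Independent oracle: direct 2*sum O*ln(O/E) over the 2x2 table."""
    n = n1 + n2
    row = [k1 + k2, (n1 - k1) + (n2 - k2)]
    col = [n1, n2]
    g = 0.0
    for col_i, (k, tot) in enumerate([(k1, n1), (k2, n2)]):
        for row_j, o in enumerate([k, tot - k]):
            e = (row[row_j] * col[col_i]) / n
            if o > 0:
                g += o * math.log(o / e)
    return 2.0 * g


def _matrix(counts: dict, meta: list) -> bc.SpectralCountMatrix:
    runs = [m[0] for m in meta]
    cdf = pd.DataFrame(counts, index=runs).T
    mdf = pd.DataFrame(
        [{"run_id": r, "construct": c, "batch": b, "replicate": i}
         for i, (r, c, b) in enumerate(meta)]
    ).set_index("run_id")
    return bc.SpectralCountMatrix(cdf, mdf)


class TestPoolControls:
    def test_single_control_run_is_identity(self):
        m = _matrix({"A": [3, 7], "B": [1, 0]},
                    [("c1", "control", "A"), ("w1", "WT", "A")])
        pooled, total = bc.pool_controls(m)
        assert pooled.tolist() == [3, 1]
        assert total == 4

    def test_pooling_sums_published_bait_row(self):
        # five mock-capture runs with bait background counts 6,9,2,5,5
        meta = [(f"c{i}", "control", "A") for i in range(5)]
        m = _matrix({"MATR3": [6, 9, 2, 5, 5]}, meta)
        pooled, total = bc.pool_controls(m)
        assert pooled["MATR3"] == 27

    def test_no_controls_rejected(self):
        m = _matrix({"A": [3]}, [("w1", "WT", "A")])
        with pytest.raises(ValueError, match="control"):
            bc.pool_controls(m)

    def test_zero_total_rejected(self):
        m = _matrix({"A": [0, 5], "B": [0, 2]},
                    [("c1", "control", "A"), ("w1", "WT", "A")])
        with pytest.raises(ValueError, match="zero"):
            bc.pool_controls(m)


class TestGTest:
    def test_equal_proportions_give_zero(self):
        g, p = bc.g_test(8, 100, 8, 100)
        assert g == 0.0
        assert p == 1.0

    def test_frozen_example_against_oracle(self):
        g, p = bc.g_test(8, 100, 2, 100)
        assert g == pytest.approx(_brute_force_g(8, 100, 2, 100), abs=1e-12)
        assert g == pytest.approx(4.0444, abs=1e-3)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        k1=st.integers(0, 400), k2=st.integers(0, 400),
        extra1=st.integers(1, 5000), extra2=st.integers(1, 5000),
    )
    def test_oracle_equivalence_on_random_tables(self, k1, k2, extra1, extra2):
        n1, n2 = k1 + extra1, k2 + extra2
        g, _ = bc.g_test(k1, n1, k2, n2)
        assert g == pytest.approx(_brute_force_g(k1, n1, k2, n2), abs=1e-9)

    def test_large_count_limit_matches_pearson_chi2(self):
        # both statistics are asymptotically equivalent; draw homogeneous
        # tables (one shared proportion) with all expected cells >= 50
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 50:
            p = rng.uniform(0.1, 0.4)
            n1, n2 = rng.integers(600, 3000, size=2)
            k1, k2 = rng.binomial(n1, p), rng.binomial(n2, p)
            table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
            if stats.contingency.expected_freq(table).min() < 50:
                continue
            g, _ = bc.g_test(k1, n1, k2, n2)
            chi2 = stats.chi2_contingency(table, correction=False).statistic
            if chi2 > 0.1:
                assert abs(g - chi2) / chi2 < 0.05
            checked += 1

    def test_monotone_in_bait_count(self):
        gs = [bc.g_test(k, 500, 5, 500)[0] for k in range(6, 60, 5)]
        assert all(b > a for a, b in zip(gs, gs[1:]))

    def test_count_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            bc.g_test(11, 10, 2, 100)


class TestFoldChange:
    @pytest.mark.parametrize(
        "bait,ctrl,pc,expected",
        [([10, 10], [2, 2], 0.0, 5.0), ([7, 7], [7, 7], 1.3, 1.0),
         ([4, 4], [0, 0], 0.5, 9.0)],
    )
    def test_arithmetic(self, bait, ctrl, pc, expected):
        assert bc.fold_change(bait, ctrl, pc) == pytest.approx(expected)

    def test_zero_denominator_guidance(self):
        with pytest.raises(ValueError, match="pseudocount"):
            bc.fold_change([4], [0], 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bc.fold_change([], [1])


class TestWelchT:
    def test_identical_groups_give_half(self):
        assert bc.welch_t([5, 5, 5], [5, 5, 5]) == 0.5

    def test_strong_enrichment_significant(self):
        bait, ctrl = [40, 38, 43, 31], [2, 0, 0, 0, 0]
        p = bc.welch_t(bait, ctrl)
        # closed-form Welch oracle
        ma, mb = np.mean(bait), np.mean(ctrl)
        va, vb = np.var(bait, ddof=1) / 4, np.var(ctrl, ddof=1) / 5
        t = (ma - mb) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 4)
        assert p == pytest.approx(stats.t.sf(t, df), rel=1e-9)
        assert p < 0.01

    def test_label_swap_antisymmetry(self):
        a, b = [9, 12, 7, 11], [3, 5, 2, 4]
        assert bc.welch_t(a, b) + bc.welch_t(b, a) == pytest.approx(1.0)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            bc.welch_t([5], [1, 2, 3])


class TestBaitCorrection:
    def _m(self, bait_by_construct):
        meta, counts = [], []
        for construct, vals in bait_by_construct.items():
            for i, v in enumerate(vals):
                meta.append((f"{construct}_{i}", construct, "A"))
                counts.append(v)
        return _matrix({"BAIT": counts, "PREY": [4] * len(counts)}, meta)

    def test_equal_means_give_unit_factors(self):
        m = self._m({"control": [5, 5], "WT": [30, 30], "dZnF1": [30, 30]})
        f = bc.bait_correction(m, "BAIT", "WT")
        assert f.rounded == {"control": 1.0, "WT": 1.0, "dZnF1": 1.0}

    def test_published_factor_scenarios(self):
        # reference bait mean twice the deletion's -> factor 2;
        # 60 vs 50 -> factor 1.2
        m = self._m({"control": [5, 5], "WT": [60, 60],
                     "dZnF1": [50, 50], "dZnF2": [30, 30]})
        f = bc.bait_correction(m, "BAIT", "WT")
        assert f.rounded["dZnF2"] == 2.0
        assert f.rounded["dZnF1"] == 1.2

    def test_zero_bait_rejected(self):
        m = self._m({"control": [5, 5], "WT": [30, 30], "dZnF1": [0, 0]})
        with pytest.raises(ValueError, match="zero mean"):
            bc.bait_correction(m, "BAIT", "WT")


class TestApplyCorrection:
    def test_unit_factors_leave_matrix_unchanged(self, apms_sim):
        _, _, matrix, _ = apms_sim
        f = bc.CorrectionFactors(
            {c: 1.0 for c in matrix.constructs}, reference="WT"
        )
        out = bc.apply_correction(matrix, f)
        assert np.allclose(out.counts.to_numpy(),
                           matrix.counts.to_numpy(dtype=float))

    def test_factor_scales_only_its_construct(self, apms_sim):
        _, _, matrix, _ = apms_sim
        factors = {c: 1.0 for c in matrix.constructs}
        factors["dZnF2"] = 2.0
        out = bc.apply_correction(matrix, bc.CorrectionFactors(factors, "WT"))
        znf2 = matrix.runs_for("dZnF2")
        rest = [r for r in matrix.counts.columns if r not in znf2]
        assert np.allclose(out.counts[znf2].to_numpy(),
                           2.0 * matrix.counts[znf2].to_numpy())
        assert np.allclose(out.counts[rest].to_numpy(),
                           matrix.counts[rest].to_numpy(dtype=float))

    def test_scale_invariance(self, apms_sim):
        # multiplying a construct's raw counts by c and applying factor 1/c
        # restores the original values
        _, _, matrix, _ = apms_sim
        c = 2.0
        scaled = matrix.counts.copy().astype(float)
        runs = matrix.runs_for("dRRM1")
        scaled[runs] *= c
        scaled_m = bc.SpectralCountMatrix(scaled, matrix.run_meta)
        factors = {cc: 1.0 for cc in matrix.constructs}
        factors["dRRM1"] = 1.0 / c
        out = bc.apply_correction(scaled_m, bc.CorrectionFactors(factors, "WT"))
        assert np.allclose(out.counts.to_numpy(),
                           matrix.counts.to_numpy(dtype=float))

    def test_missing_factor_rejected(self, apms_sim):
        _, _, matrix, _ = apms_sim
        with pytest.raises(ValueError, match="factor"):
            bc.apply_correction(
                matrix, bc.CorrectionFactors({"WT": 1.0}, "WT")
            )


def test_enrichment_table_shape_and_ranges(apms_sim, wt_calls):
    _, _, matrix, _ = apms_sim
    table, _, _, _ = wt_calls
    assert (table["fold_change"] > 0).all()
    assert table["t_p"].between(0, 1).all()
    n_bait_runs = len(matrix.runs_for("WT"))
    assert (table["n_runs_significant"] <= n_bait_runs).all()
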