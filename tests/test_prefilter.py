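from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from o2weave import (
    FormatError,
    OmicsBlock,
    differential_ions,
    generate_peak_table,
    intersect_signatures,
    subset_significant,
)
from o2weave.prefilter import PeakTable, anova_pvalues, peak_table_to_block


def make_peaks(intensities, groups=None):
    intensities = np.asarray(intensities, dtype=float)
    n_ions, n_samples = intensities.shape
    if groups is None:
        half = n_samples // 2
        groups = ["control"] * half + ["treated"] * (n_samples - half)
    return PeakTable(
        ion_ids=[f"ion{j}" for j in range(n_ions)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        intensities=intensities,
        groups=groups,
    )


class TestDifferentialIons:
    def test_identical_groups_not_selected(self):
        peaks = make_peaks([[10.0, 12.0, 11.0, 10.0, 12.0, 11.0]])
        res = differential_ions(peaks, "control", "treated")
        assert res.loc[0, "log2fc"] == 0.0
        assert not res.loc[0, "selected"]

    def test_conjunctive_rule_needs_both_arms(self):
        # tiny but consistent shift: p is small, |log2fc| ~ 0.5 -> rejected
        ctrl = [100.0, 100.5, 99.5]
        trt = [141.0, 141.5, 140.5]
        peaks = make_peaks([ctrl + trt])
        res = differential_ions(peaks, "control", "treated")
        assert res.loc[0, "p_value"] < 0.01
        assert abs(res.loc[0, "log2fc"]) < 1.0
        assert not res.loc[0, "selected"]

    def test_strong_fold_change_selected(self):
        peaks, _ = generate_peak_table(1, 3, effect_log2fc=2.0, noise_cv=0.05, seed=1)
        res = differential_ions(peaks, "control", "treated")
        assert abs(res.loc[0, "log2fc"] - 2.0) < 0.3
        assert res.loc[0, "selected"]

    def test_anova_equals_pooled_t_test(self):
        """Two-group one-way ANOVA p equals the two-sided pooled-variance t
        test p: algebraic identity F = t^2, checked to 1e-12."""
        rng = np.random.default_rng(0)
        intensities = rng.lognormal(3, 0.4, size=(50, 6))
        peaks = make_peaks(intensities)
        res = differential_ions(peaks, "control", "treated")
        t_p = sps.ttest_ind(intensities[:, 3:], intensities[:, :3], axis=1).pvalue
        np.testing.assert_allclose(res["p_value"].to_numpy(), t_p, atol=1e-12)

    def test_exhaustive_permutation_oracle_rank_order(self):
        """Parametric ANOVA p-values order ions the same way as the exact
        permutation p over all C(6,3) group relabelings."""
        rng = np.random.default_rng(3)
        effects = np.array([0.0, 0.4, 0.8, 1.6, 3.0])
        base = 100.0
        ctrl = base * rng.lognormal(0, 0.08, size=(5, 3))
        trt = base * 2.0 ** effects[:, None] * rng.lognormal(0, 0.08, size=(5, 3))
        values = np.hstack([ctrl, trt])
        peaks = make_peaks(values)
        res = differential_ions(peaks, "control", "treated")

        def perm_p(row):
            obs_f = f_stat(row[:3], row[3:])
            count = 0
            total = 0
            for idx in combinations(range(6), 3):
                a = row[list(idx)]
                b = row[[j for j in range(6) if j not in idx]]
                if f_stat(a, b) >= obs_f - 1e-12:
                    count += 1
                total += 1
            return count / total

        def f_stat(a, b):
            res_ = sps.f_oneway(a, b)
            return res_.statistic

        perm = np.array([perm_p(values[i]) for i in range(5)])
        par = res["p_value"].to_numpy()
        for i in range(5):
            for j in range(5):
                if perm[i] < perm[j] - 1e-12:
                    assert par[i] < par[j]

    def test_all_zero_ion_never_selected(self, caplog):
        peaks = make_peaks([[0.0] * 6, [1.0, 2.0, 1.5, 9.0, 8.0, 10.0]])
        with caplog.at_level("WARNING"):
            res = differential_ions(peaks, "control", "treated")
        assert res.loc[0, "p_value"] == 1.0
        assert res.loc[0, "log2fc"] == 0.0
        assert not res.loc[0, "selected"]
        assert "all-zero" in caplog.text

    def test_small_group_rejected(self):
        peaks = make_peaks([[1.0, 2.0, 3.0]], groups=["control", "treated", "treated"])
        with pytest.raises(FormatError, match="at least 2"):
            differential_ions(peaks, "control", "treated")

    def test_invariance_to_sample_order_and_global_scaling(self):
        rng = np.random.default_rng(5)
        intensities = rng.lognormal(4, 0.5, size=(30, 6))
        peaks = make_peaks(intensities)
        res = differential_ions(peaks, "control", "treated")
        # shuffle samples within groups
        order = [2, 0, 1, 5, 3, 4]
        shuffled = make_peaks(intensities[:, order])
        res_shuf = differential_ions(shuffled, "control", "treated")
        np.testing.assert_allclose(res_shuf["p_value"], res["p_value"], atol=1e-12)
        np.testing.assert_allclose(res_shuf["log2fc"], res["log2fc"], atol=1e-12)
        # common positive rescaling
        res_scaled = differential_ions(make_peaks(37.5 * intensities), "control", "treated")
        np.testing.assert_allclose(res_scaled["p_value"], res["p_value"], atol=1e-12)
        np.testing.assert_allclose(res_scaled["log2fc"], res["log2fc"], atol=1e-12)
        assert (res_scaled["selected"] == res["selected"]).all()

    def test_selection_monotone_in_thresholds(self):
        peaks, _ = generate_peak_table(
            200, 3, np.linspace(-2, 2, 200), noise_cv=0.2, seed=6
        )
        n_sel = lambda p_thr, lfc_thr: int(
            differential_ions(peaks, "control", "treated", p_thr, lfc_thr)["selected"].sum()
        )
        assert n_sel(0.05, 1.5) <= n_sel(0.05, 1.0)
        assert n_sel(0.01, 1.0) <= n_sel(0.05, 1.0)

    def test_multigroup_anova_option(self):
        rng = np.random.default_rng(7)
        intensities = rng.lognormal(3, 0.3, size=(10, 12))
        groups = ["control"] * 3 + ["infested"] * 3 + ["wound"] * 3 + ["wound_regurgitate"] * 3
        peaks = make_peaks(intensities, groups=groups)
        p = anova_pvalues(peaks, ["control", "infested", "wound", "wound_regurgitate"])
        assert p.shape == (10,)
        assert np.all((p >= 0) & (p <= 1))


class TestSubsetSignificant:
    @pytest.fixture
    def block(self):
        rng = np.random.default_rng(1)
        return OmicsBlock(
            "transcriptome",
            [f"s{i}" for i in range(6)],
            [f"GRMZM2G{j:06d}" for j in range(126)],
            rng.standard_normal((6, 126)),
        )

    def test_keep_all_is_identity(self, block):
        out = subset_significant(block, list(block.feature_ids))
        assert out.feature_ids == block.feature_ids
        np.testing.assert_array_equal(out.values, block.values)

    def test_empty_keep_errors(self, block):
        with pytest.raises(FormatError, match="empty"):
            subset_significant(block, [])

    def test_original_order_and_count(self, block):
        keep = [block.feature_ids[j] for j in np.random.default_rng(2).permutation(126)[:85]]
        out = subset_significant(block, keep)
        assert out.n_features == 85
        # block's original column order is preserved regardless of keep order
        positions = [block.feature_ids.index(f) for f in out.feature_ids]
        assert positions == sorted(positions)
        assert out.sample_ids == block.sample_ids

    def test_unknown_identifiers_listed(self, block):
        with pytest.raises(FormatError, match="ghost"):
            subset_significant(block, ["ghost1", block.feature_ids[0]])

    def test_allow_missing_logs_count(self, block, caplog):
        with caplog.at_level("WARNING"):
            out = subset_significant(block, ["ghost1", block.feature_ids[0]], allow_missing=True)
        assert out.n_features == 1
        assert "absent" in caplog.text


class TestIntersectSignatures:
    def test_disjoint(self):
        shared, only_a, only_b = intersect_signatures(["a", "b"], ["c", "d"])
        assert shared == [] and only_a == ["a", "b"] and only_b == ["c", "d"]

    def test_identical(self):
        shared, only_a, only_b = intersect_signatures(["a", "b"], ["b", "a"])
        assert shared == ["a", "b"] and only_a == [] and only_b == []

    def test_partition_property(self):
        rng = np.random.default_rng(9)
        universe = [f"f{j}" for j in range(40)]
        a = [universe[j] for j in rng.permutation(40)[:25]]
        b = [universe[j] for j in rng.permutation(40)[:18]]
        shared, only_a, only_b = intersect_signatures(a, b)
        assert sorted(shared + only_a) == sorted(a)
        assert sorted(shared + only_b) == sorted(b)
        assert not set(only_a) & set(b)

    def test_seven_gene_overlap_fixture(self):
        """Synthetic stand-in for the two treatment signatures: the seven
        maize gene models shared between the insect-feeding and regurgitate
        responses must be recovered as the intersection."""
        seven = [
            "GRMZM2G030583",
            "GRMZM2G025441",
            "GRMZM5G843555",
            "GRMZM2G013448",
            "GRMZM2G045155",
            "GRMZM2G099420",
            "GRMZM2G412598",
        ]
        rng = np.random.default_rng(4)
        feeding_only = [f"GRMZM2G{j:06d}" for j in range(100000, 100119)]
        regurg_only = [f"GRMZM2G{j:06d}" for j in range(200000, 200263)]
        feeding = feeding_only + seven
        regurg = regurg_only + seven
        feeding = [feeding[j] for j in rng.permutation(len(feeding))]
        regurg = [regurg[j] for j in rng.permutation(len(regurg))]
        shared, only_a, only_b = intersect_signatures(feeding, regurg)
        assert sorted(shared) == sorted(seven)
        assert len(shared) == 7
        assert "GRMZM2G030583" in shared


def test_peak_table_to_block_round_trip():
    peaks, _ = generate_peak_table(10, 3, 1.0, seed=8)
    block = peak_table_to_block(peaks)
    assert block.n_samples == 6 and block.n_features == 10
    np.testing.assert_array_equal(block.values.T, peaks.intensities)
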