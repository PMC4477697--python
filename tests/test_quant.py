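"""Spectral counting, the quasi-Poisson rate test, and signature AUC."""

import numpy as np
import pandas as pd
import pytest

from protasm import synthetic
from protasm.assembly import AssemblyConfig, assemble
from protasm.psm_io import BipartiteMap
from protasm.quant import (
    SpectralCountMatrix,
    count_matrix,
    differential_counts,
    filter_min_average,
    pairwise_signature_auc,
    resolve_duplicates,
    select_signature,
)


def _matrix(counts: dict, groups: dict) -> SpectralCountMatrix:
    return SpectralCountMatrix(
        counts=pd.DataFrame(counts),  # dict of sample -> feature -> count
        samples=pd.DataFrame({"group": pd.Series(groups)}),
    )


@pytest.fixture
def small_assembly(tiny_bmap):
    rows = []
    for i in range(3):  # 3 PSMs for the A/B group in sample s1
        rows.append(("s1", f"a{i}", "PEPTIDEONEK", ("A", "B"), False))
    rows.append(("s2", "c1", "PEPTIDETHREEK", ("C",), False))
    rows.append(("s1", "a3", "PEPTIDETWOK", ("A", "B"), False))
    rows.append(("s2", "c2", "PEPTIDEFOURK", ("C",), False))
    psms = pd.DataFrame(
        {
            "sample": [r[0] for r in rows],
            "fraction": 1,
            "scan": [r[1] for r in rows],
            "engine": "e1",
            "peptide": [r[2] for r in rows],
            "charge": 2,
            "score": 5.0,
            "proteins": [r[3] for r in rows],
            "decoy": [r[4] for r in rows],
        }
    )
    return assemble(psms, tiny_bmap, AssemblyConfig(psm_fdr_max=1.0))


class TestCountMatrix:
    def test_cells_count_psms_per_group_and_sample(self, small_assembly):
        samples = pd.DataFrame({"group": ["A", "B"]}, index=["s1", "s2"])
        mat = count_matrix(small_assembly, samples)
        assert mat.counts.loc["A", "s1"] == 4  # 3 + 1 PSMs on the A/B group
        assert mat.counts.loc["A", "s2"] == 0
        assert mat.counts.loc["C", "s2"] == 2

    def test_single_sample_group_is_nonzero_in_one_column(self, small_assembly):
        samples = pd.DataFrame({"group": ["A", "B"]}, index=["s1", "s2"])
        mat = count_matrix(small_assembly, samples)
        assert (mat.counts.loc["C"] > 0).sum() == 1

    def test_total_equals_number_of_assigned_psms(self, small_assembly):
        samples = pd.DataFrame({"group": ["A", "B"]}, index=["s1", "s2"])
        mat = count_matrix(small_assembly, samples)
        # no shared peptides across groups here, so counting is conservative
        assert mat.counts.to_numpy().sum() == len(small_assembly.retained_psms)

    def test_unknown_sample_is_an_error(self, small_assembly):
        samples = pd.DataFrame({"group": ["A"]}, index=["s1"])
        with pytest.raises(ValueError, match="missing from metadata"):
            count_matrix(small_assembly, samples)


class TestResolveDuplicates:
    def test_larger_total_wins(self):
        m = _matrix(
            {"s1": {"f1": 1000}, "s2": {"f1": 900}},
            {"s1": "A", "s2": "A"},
        )
        out = resolve_duplicates(m, [("s1", "s2")])
        assert list(out.counts.columns) == ["s1"]

    def test_tie_keeps_lexicographically_first(self):
        m = _matrix({"s2": {"f1": 5}, "s1": {"f1": 5}}, {"s1": "A", "s2": "A"})
        out = resolve_duplicates(m, [("s2", "s1")])
        assert list(out.counts.columns) == ["s1"]

    def test_no_duplicates_is_identity(self):
        m = _matrix({"s1": {"f1": 3}, "s2": {"f1": 4}}, {"s1": "A", "s2": "B"})
        out = resolve_duplicates(m, [])
        pd.testing.assert_frame_equal(out.counts, m.counts)

    def test_five_pairs_on_95_columns_leave_90(self):
        rng = np.random.default_rng(0)
        cols = [f"s{i:02d}" for i in range(95)]
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(10, 95)), index=[f"f{i}" for i in range(10)],
            columns=cols,
        )
        m = SpectralCountMatrix(
            counts=counts, samples=pd.DataFrame({"group": "A"}, index=cols)
        )
        pairs = [(f"s{2 * i:02d}", f"s{2 * i + 1:02d}") for i in range(5)]
        out = resolve_duplicates(m, pairs)
        assert out.counts.shape[1] == 90

    def test_unknown_sample_in_pair_rejected(self):
        m = _matrix({"s1": {"f1": 3}}, {"s1": "A"})
        with pytest.raises(ValueError, match="unknown sample"):
            resolve_duplicates(m, [("s1", "nope")])


class TestFilterMinAverage:
    def test_criterion_of_1p4_counts_over_32_samples_is_45_total(self):
        cols = [f"s{i}" for i in range(32)]
        counts = pd.DataFrame(0, index=["keep", "drop"], columns=cols)
        counts.loc["keep", cols[:13]] = 2  # 26
        counts.loc["keep", cols[13:32]] = 1  # +19 = exactly 45 total
        counts.loc["drop", cols[:12]] = 2  # 24
        counts.loc["drop", cols[12:32]] = 1  # +20 = 44 total
        m = SpectralCountMatrix(
            counts=counts,
            samples=pd.DataFrame({"group": "A"}, index=counts.columns),
        )
        out = filter_min_average(m, 1.4)
        assert list(out.counts.index) == ["keep"]

    def test_zero_threshold_is_identity(self):
        m = _matrix({"s1": {"f1": 0}, "s2": {"f1": 0}}, {"s1": "A", "s2": "B"})
        out = filter_min_average(m, 0)
        pd.testing.assert_frame_equal(out.counts, m.counts)

    def test_all_zero_feature_always_dropped(self):
        m = _matrix(
            {"s1": {"f1": 0, "f2": 9}, "s2": {"f1": 0, "f2": 9}},
            {"s1": "A", "s2": "B"},
        )
        out = filter_min_average(m, 0.1)
        assert "f1" not in out.counts.index


class TestDifferentialCounts:
    def test_equal_rates_give_unit_fold_change_and_large_p(self):
        counts = {f"{g}{i}": {"f0": 50, "f1": 10} for g in "AB" for i in range(4)}
        m = _matrix(counts, {f"{g}{i}": g for g in "AB" for i in range(4)})
        res = differential_counts(m)
        assert res.loc["f0", "fold_change"] == pytest.approx(1.0, abs=0.05)
        assert res.loc["f0", "pvalue"] > 0.5

    def test_matches_quasipoisson_glm(self):
        import statsmodels.api as sm

        m, _ = synthetic.simulate_counts(
            synthetic.CountSimConfig(
                n_features=20, n_signature_features=4, signature_fold_change=8,
                baseline_mean=15, seed=7,
            )
        )
        mine = differential_counts(m)
        totals = m.counts.sum(axis=0).to_numpy(dtype=float)
        grp = (m.samples.loc[m.counts.columns, "group"] == "A").astype(float)
        design = sm.add_constant(grp.to_numpy())
        for feat in list(m.counts.index)[:8]:
            y = m.counts.loc[feat].to_numpy(dtype=float)
            if y[grp == 1].sum() == 0 or y[grp == 0].sum() == 0:
                continue
            glm = sm.GLM(
                y, design, family=sm.families.Poisson(), offset=np.log(totals)
            ).fit(scale="X2")
            assert mine.loc[feat, "statistic"] == pytest.approx(
                glm.params[1] / glm.bse[1], rel=1e-6
            )

    def test_degenerate_all_zero_group_rejected(self):
        counts = {"a0": {"f": 3}, "a1": {"f": 4}, "b0": {"f": 0}, "b1": {"f": 0}}
        m = _matrix(counts, {"a0": "A", "a1": "A", "b0": "B", "b1": "B"})
        with pytest.raises(ValueError, match="all-zero total"):
            differential_counts(m)

    def test_groups_need_two_samples(self):
        m = _matrix({"a0": {"f": 3}, "b0": {"f": 1}}, {"a0": "A", "b0": "B"})
        with pytest.raises(ValueError, match="at least two samples"):
            differential_counts(m)


class TestSelectSignature:
    def test_trivial_thresholds_select_everything(self):
        res = pd.DataFrame(
            {"fold_change": [2.0, 0.1], "fdr": [0.9, 0.5]}, index=["f1", "f2"]
        )
        assert set(select_signature(res, min_fold=1.0, max_fdr=1.0)) == {"f1", "f2"}

    def test_direction_is_signed(self):
        res = pd.DataFrame(
            {"fold_change": [64.0, 1 / 64.0, 3.0], "fdr": [1e-5, 1e-5, 1e-5]},
            index=["up", "down", "weak"],
        )
        sig = select_signature(res, min_fold=32, max_fdr=0.001)
        assert sig == {"up": 1, "down": -1}

    def test_empty_results_give_empty_signature(self):
        assert select_signature(pd.DataFrame(), 32, 0.001) == {}


class TestPairwiseAuc:
    def test_sixteen_by_sixteen_gives_256_aucs(self):
        m, sig = synthetic.simulate_counts(
            synthetic.CountSimConfig(
                n_features=100, n_signature_features=10, signature_fold_change=64,
                baseline_mean=30, seed=1,
            )
        )
        res = pairwise_signature_auc(m, sig)
        assert res.auc_matrix.shape == (16, 16)
        assert res.auc_matrix.notna().sum().sum() == 256

    def test_strong_separation_drives_auc_to_one(self):
        m, sig = synthetic.simulate_counts(
            synthetic.CountSimConfig(
                n_features=100, n_signature_features=10, signature_fold_change=1024,
                baseline_mean=50, dispersion=0.0, seed=2,
            )
        )
        res = pairwise_signature_auc(m, sig)
        assert res.median_auc >= 0.99

    def test_no_signal_sits_at_one_half(self):
        medians = []
        for seed in range(5):
            m, _ = synthetic.simulate_counts(
                synthetic.CountSimConfig(
                    n_features=200, n_signature_features=0, signature_fold_change=1.0,
                    baseline_mean=20, seed=seed,
                )
            )
            null_sig = {f: 1 if i % 2 == 0 else -1
                        for i, f in enumerate(list(m.counts.index)[:20])}
            medians.append(pairwise_signature_auc(m, null_sig).median_auc)
        assert np.mean(medians) == pytest.approx(0.5, abs=0.05)

    def test_empty_signature_rejected(self):
        m = _matrix(
            {"a0": {"f": 3}, "a1": {"f": 1}, "b0": {"f": 2}, "b1": {"f": 2}},
            {"a0": "A", "a1": "A", "b0": "B", "b1": "B"},
        )
        with pytest.raises(ValueError, match="signature is empty"):
            pairwise_signature_auc(m, {})
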