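"""Metric exclusion, robust PCA, distances, T-squared calls and ANOVA shares."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from protasm import synthetic
from protasm.qc import (
    QCMetricsTable,
    compref_acceptance,
    exclude_low_variance,
    fraction_distances,
    qc_pipeline,
    read_quameter,
    robust_pca,
    t2_outliers,
    variance_components,
    write_quameter,
)


def _table(x: np.ndarray, n_fractions: int = 5) -> QCMetricsTable:
    n = len(x)
    assert n % n_fractions == 0
    return QCMetricsTable(
        metrics=pd.DataFrame(x, columns=[f"M{i}" for i in range(x.shape[1])]),
        labels=pd.DataFrame(
            {
                "sample": np.repeat([f"S{i}" for i in range(n // n_fractions)], n_fractions),
                "fraction": np.tile(np.arange(1, n_fractions + 1), n // n_fractions),
            }
        ),
    )


class TestExcludeLowVariance:
    def test_generator_constants_are_excluded_at_any_positive_floor(self):
        table, truth = synthetic.simulate_qc_metrics(
            synthetic.QcSimConfig(n_samples=6, n_fractions=5, seed=0)
        )
        _, excluded = exclude_low_variance(table, rel_floor=1e-6)
        assert set(excluded) == set(truth["constant_metrics"])

    def test_zero_floor_and_no_patterns_is_identity(self):
        table, _ = synthetic.simulate_qc_metrics(
            synthetic.QcSimConfig(n_samples=4, n_fractions=5, seed=1)
        )
        reduced, excluded = exclude_low_variance(table, rel_floor=0.0)
        assert excluded == []
        assert reduced.metrics.shape == table.metrics.shape

    def test_name_patterns_are_honored(self):
        table, _ = synthetic.simulate_qc_metrics(
            synthetic.QcSimConfig(n_samples=4, n_fractions=5, seed=2)
        )
        _, excluded = exclude_low_variance(
            table, rel_floor=1e-6, name_patterns=("Metric.0*",)
        )
        assert "Metric.01" in excluded and "Metric.10" not in excluded


class TestRobustPca:
    def test_rank_one_data_explained_by_first_component(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=6)
        x = rng.normal(size=(40, 1)) @ direction[None, :]
        pca = robust_pca(_table(x), center="mean", scale="none")
        assert pca.explained[0] == pytest.approx(1.0)

    def test_rotation_leaves_spectrum_unchanged_in_plain_mode(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(60, 5)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.1])
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        a = robust_pca(_table(x), center="mean", scale="none")
        b = robust_pca(_table(x @ q), center="mean", scale="none")
        np.testing.assert_allclose(a.explained, b.explained, atol=1e-10)

    def test_explained_fractions_are_non_increasing_and_sum_to_one(self):
        table, _ = synthetic.simulate_qc_metrics(
            synthetic.QcSimConfig(n_samples=8, n_fractions=5, seed=3)
        )
        reduced, _ = exclude_low_variance(table)
        pca = robust_pca(reduced)
        assert np.all(np.diff(pca.explained) <= 1e-12)
        assert pca.explained.sum() == pytest.approx(1.0)

    def test_constant_column_must_be_excluded_first(self):
        x = np.ones((20, 3))
        x[:, :2] = np.random.default_rng(4).normal(size=(20, 2))
        with pytest.raises(ValueError, match="zero-MAD"):
            robust_pca(_table(x))


class TestFractionDistances:
    def test_identical_runs_have_zero_distance(self):
        x = np.zeros((4, 2))
        x[2:] = 5.0  # two samples, two identical runs each
        scores = pd.DataFrame(x, columns=["PC1", "PC2"])
        labels = pd.Series(["a", "a", "b", "b"])
        d = fraction_distances(scores, labels)
        assert d.to_numpy() == pytest.approx([0, 0, 0, 0])

    def test_displaced_run_has_largest_median_distance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(scale=0.1, size=(4, 3))
        x[3] += 4.0
        d = fraction_distances(
            pd.DataFrame(x, columns=["PC1", "PC2", "PC3"]),
            pd.Series(["a"] * 4),
        )
        assert d.idxmax() == 3
        assert d.iloc[3] > 2 * d.iloc[:3].max()

    def test_distances_are_symmetric_and_triangular(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(3, 2))
        sd = x.std(axis=0, ddof=1)
        z = x / sd
        d01 = np.linalg.norm(z[0] - z[1])
        d02 = np.linalg.norm(z[0] - z[2])
        d12 = np.linalg.norm(z[1] - z[2])
        assert d01 <= d02 + d12 and d02 <= d01 + d12
        # with 3 runs each median equals the smaller of the two distances;
        # check consistency against the direct computation
        d = fraction_distances(pd.DataFrame(x, columns=["PC1", "PC2"]), pd.Series(["a"] * 3))
        assert d.iloc[0] == pytest.approx(np.median([d01, d02]))

    def test_single_run_sample_is_an_error(self):
        scores = pd.DataFrame(np.zeros((3, 2)), columns=["PC1", "PC2"])
        with pytest.raises(ValueError, match="at least two runs"):
            fraction_distances(scores, pd.Series(["a", "a", "b"]))


class TestT2Outliers:
    def test_central_run_is_not_flagged(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(60, 2))
        x[0] = x[1:].mean(axis=0)  # plant a run near the center
        labels = pd.DataFrame(
            {"sample": np.repeat([f"s{i}" for i in range(12)], 5),
             "fraction": np.tile(np.arange(1, 6), 12)}
        )
        rep = t2_outliers(pd.DataFrame(x, columns=["PC1", "PC2"]), labels, robust=False)
        assert rep.runs["pvalue"].iloc[0] > 0.9
        assert not rep.runs["outlier"].iloc[0]

    def test_flags_are_exactly_the_chi2_exceedances(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(50, 2))
        labels = pd.DataFrame(
            {"sample": np.repeat([f"s{i}" for i in range(10)], 5),
             "fraction": np.tile(np.arange(1, 6), 10)}
        )
        rep = t2_outliers(pd.DataFrame(x, columns=["PC1", "PC2"]), labels, alpha=0.01)
        cutoff = stats.chi2.isf(0.01, df=2)  # 9.21 for two components
        assert cutoff == pytest.approx(9.2103, abs=1e-3)
        np.testing.assert_array_equal(
            rep.runs["outlier"].to_numpy(), rep.runs["t2"].to_numpy() > cutoff
        )

    def test_singular_covariance_is_reported(self):
        x = np.random.default_rng(9).normal(size=(20, 1))
        scores = pd.DataFrame(np.column_stack([x, x]), columns=["PC1", "PC2"])
        labels = pd.DataFrame(
            {"sample": np.repeat(["a", "b", "c", "d"], 5),
             "fraction": np.tile(np.arange(1, 6), 4)}
        )
        with pytest.raises(ValueError, match="singular|fewer components"):
            t2_outliers(scores, labels, robust=False)


class TestPipeline:
    def test_injected_outliers_recovered(self):
        sens, ffr = [], []
        for seed in range(10):
            table, truth = synthetic.simulate_qc_metrics(
                synthetic.QcSimConfig(
                    n_samples=40, n_fractions=15, outlier_fraction=0.05,
                    outlier_shift=5.0, seed=seed,
                )
            )
            rep = qc_pipeline(table, alpha=0.01)
            flagged = rep.runs["outlier"].to_numpy()
            truth_v = truth["outliers"]
            sens.append((flagged & truth_v).sum() / truth_v.sum())
            ffr.append((flagged & ~truth_v).sum() / (~truth_v).sum())
        assert np.mean(sens) >= 0.8
        assert np.mean(ffr) <= 0.02  # 2 x alpha

    def test_quameter_roundtrip(self, tmp_path):
        table, _ = synthetic.simulate_qc_metrics(
            synthetic.QcSimConfig(n_samples=4, n_fractions=5, seed=10)
        )
        path = tmp_path / "metrics.tsv"
        write_quameter(table, path)
        back = read_quameter(path)
        pd.testing.assert_frame_equal(back.metrics, table.metrics)
        assert list(back.labels["sample"]) == list(table.labels["sample"])


class TestVarianceComponents:
    def test_pure_sample_effects_take_all_variance(self):
        df = pd.DataFrame(
            {
                "sample": np.repeat(["a", "b", "c"], 4),
                "fraction": np.tile(np.arange(4), 3),
                "value": np.repeat([10.0, 20.0, 30.0], 4),
            }
        )
        vc = variance_components(df)
        assert vc["sample"] == pytest.approx(1.0)
        assert vc["fraction"] == pytest.approx(0.0, abs=1e-12)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {
                "sample": np.repeat([f"s{i}" for i in range(6)], 5),
                "fraction": np.tile(np.arange(5), 6),
                "value": rng.normal(size=30),
            }
        )
        vc = variance_components(df)
        assert sum(vc.values()) == pytest.approx(1.0)

    def test_pure_noise_shares_match_degrees_of_freedom(self):
        rng = np.random.default_rng(12)
        I, J = 12, 8
        shares = []
        for _ in range(20):
            df = pd.DataFrame(
                {
                    "sample": np.repeat(range(I), J),
                    "fraction": np.tile(range(J), I),
                    "value": rng.normal(size=I * J),
                }
            )
            vc = variance_components(df)
            shares.append([vc["sample"], vc["fraction"]])
        mean_shares = np.mean(shares, axis=0)
        n = I * J - 1
        assert mean_shares[0] == pytest.approx((I - 1) / n, abs=0.02)
        assert mean_shares[1] == pytest.approx((J - 1) / n, abs=0.02)

    def test_incomplete_layout_rejected(self):
        df = pd.DataFrame(
            {"sample": ["a", "a", "b"], "fraction": [1, 2, 1], "value": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="complete"):
            variance_components(df)


class TestComprefAcceptance:
    @pytest.mark.parametrize(
        "spectra,density,charge2,passed,n_reasons",
        [
            (5001, 201, 0.41, True, 0),
            (5000, 201, 0.41, False, 1),  # boundary is strict
            (6000, 100, 0.50, False, 1),
            (100, 100, 0.10, False, 3),
        ],
    )
    def test_rule_evaluation(self, spectra, density, charge2, passed, n_reasons):
        ok, reasons = compref_acceptance(spectra, density, charge2)
        assert ok is passed
        assert len(reasons) == n_reasons
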