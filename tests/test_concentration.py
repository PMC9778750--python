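"""Tests for dataset I/O, descriptive statistics, fitting, selection and sampling."""

import math
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from ricerisk.concentration import (
    ConcentrationDataset,
    ConcentrationSample,
    EmptyDatasetError,
    FittedDistribution,
    InsufficientDataError,
    descriptive_stats,
    distribution_mean,
    fit_candidates,
    fit_family,
    pearson_correlation,
    read_dataset,
    sample_concentrations,
    select_best,
    welch_t_test,
)
from ricerisk.synthetic_data import default_white_spec, generate_dataset


def write_csv(path, rows):
    header = "sample_id,rice_type,origin,city,state,variety,ias_ng_g,cd_ng_g\n"
    path.write_text(header + "\n".join(rows) + "\n")


class TestReadDataset:
    def test_well_formed_rows(self, tmp_path):
        p = tmp_path / "d.csv"
        write_csv(p, [
            "s1,white,market,,,," + "100.0,",
            "s2,brown,farm,Pelotas,RS,Puita,55.5,20.1",
            "s3,white,,,,,80.0,",
        ])
        ds = read_dataset(p)
        assert len(ds) == 3
        assert ds.samples[1].variety == "Puita"
        assert ds.samples[1].cd_ng_g == pytest.approx(20.1)
        assert ds.samples[2].origin == "unknown"

    def test_negative_concentration_row_skipped(self, tmp_path, caplog):
        p = tmp_path / "d.csv"
        write_csv(p, ["s1,white,market,,,,100.0,", "s2,white,market,,,,-5.0,"])
        ds = read_dataset(p)
        assert len(ds) == 1

    def test_all_rows_invalid_raises(self, tmp_path):
        p = tmp_path / "d.csv"
        write_csv(p, ["s1,white,market,,,,-1.0,"])
        with pytest.raises(EmptyDatasetError):
            read_dataset(p)

    def test_synthetic_white_file_mean_in_sampling_band(self, tmp_path):
        ds = generate_dataset(default_white_spec(seed=7))
        p = tmp_path / "white.csv"
        ds.to_csv(p)
        loaded = read_dataset(p)
        assert len(loaded) == 64
        # sampling-distribution bound: |mean - 100.17| < 3 * 44.62 / sqrt(64)
        assert abs(loaded.values().mean() - 100.17) < 3 * 44.62 / 8.0


class TestDescriptiveStats:
    def test_basic_stats(self):
        ds = ConcentrationDataset(
            [ConcentrationSample(f"s{i}", "white", v) for i, v in enumerate([1.0, 2.0, 3.0])]
        )
        out = descriptive_stats(ds)
        row = out.iloc[0]
        assert row["n"] == 3
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)  # sample sd, n-1 divisor
        assert row["min"] == 1.0 and row["max"] == 3.0

    def test_single_value_group_has_undefined_sd(self):
        ds = ConcentrationDataset([ConcentrationSample("s", "white", 7.0)])
        out = descriptive_stats(ds)
        assert out.iloc[0]["mean"] == 7.0
        assert math.isnan(out.iloc[0]["sd"])

    def test_unknown_group_field_rejected(self):
        ds = ConcentrationDataset([ConcentrationSample("s", "white", 7.0)])
        with pytest.raises(ValueError):
            descriptive_stats(ds, group_by="ias_ng_g")

    def test_origin_grouping_matches_generator_strata(self):
        from ricerisk.synthetic_data import default_brown_spec

        ds = generate_dataset(default_brown_spec(seed=11))
        out = descriptive_stats(ds, group_by="origin")
        # generator targets: farm (57.36, 34.6), market (154.91, 44.8)
        assert abs(out.loc["farm", "mean"] - 57.36) < 3 * 34.6 / math.sqrt(69)
        assert abs(out.loc["market", "mean"] - 154.91) < 3 * 44.8 / math.sqrt(21)


class TestFitting:
    def test_exponential_closed_form_rate(self):
        values = [25.0, 50.0, 75.0]  # mean 50
        fit = fit_family(values, "exponential")
        assert fit.params["rate"] == pytest.approx(0.02, rel=1e-12)

    def test_normal_mle_uses_n_divisor(self):
        fit = fit_family([1.0, 2.0, 3.0], "normal")
        assert fit.params["mean"] == pytest.approx(2.0)
        assert fit.params["sd"] == pytest.approx(math.sqrt(2.0 / 3.0), rel=1e-12)

    def test_lognormal_parameter_recovery(self):
        rng = np.random.default_rng(42)
        draws = rng.lognormal(4.1, 0.9, size=5000)
        fit = fit_family(draws, "lognormal")
        assert fit.params["mu"] == pytest.approx(4.1, rel=0.05)
        assert fit.params["sigma"] == pytest.approx(0.9, rel=0.05)

    def test_lognormal_excludes_nonpositive_values_only(self):
        values = [0.0, 10.0, 20.0, 40.0]
        logfit = fit_family(values, "lognormal")
        assert logfit.n == 3
        assert fit_family(values, "normal").n == 4

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_family([1.0], "normal")

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(0.1, 1e3), min_size=2, max_size=50, unique=True),
    )
    def test_aic_definition_holds_for_every_fit(self, values):
        for fit in fit_candidates(values):
            assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.log_likelihood, rel=1e-12)

    def test_matches_r_fitdistrplus_oracle(self):
        """Cross-check log-likelihood/AIC of all three families against fitdistrplus."""
        rng = np.random.default_rng(3)
        values = np.round(rng.lognormal(4.0, 0.6, size=30), 4)
        vec = ",".join(str(v) for v in values)
        script = textwrap.dedent(f"""
            suppressMessages(library(fitdistrplus))
            x <- c({vec})
            for (d in c("norm", "lnorm", "exp")) {{
              f <- fitdist(x, d)
              cat(sprintf("%s %.10f\\n", d, f$aic))
            }}
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        ).stdout
        r_aic = {line.split()[0]: float(line.split()[1]) for line in out.strip().splitlines()}
        ours = {f.family: f.aic for f in fit_candidates(values)}
        # fitdistrplus optimizes numerically; closed-form MLEs should agree closely
        assert ours["normal"] == pytest.approx(r_aic["norm"], rel=1e-4)
        assert ours["lognormal"] == pytest.approx(r_aic["lnorm"], rel=1e-4)
        assert ours["exponential"] == pytest.approx(r_aic["exp"], rel=1e-4)


class TestSelection:
    def test_minimum_aic_wins(self):
        fits = [
            FittedDistribution("normal", {"mean": 0, "sd": 1}, aic=12.0),
            FittedDistribution("lognormal", {"mu": 0, "sigma": 1}, aic=10.0),
            FittedDistribution("exponential", {"rate": 1}, aic=14.0),
        ]
        assert select_best(fits).family == "lognormal"

    def test_tie_broken_by_family_order(self):
        fits = [
            FittedDistribution("exponential", {"rate": 1}, aic=10.0),
            FittedDistribution("normal", {"mean": 0, "sd": 1}, aic=10.0),
        ]
        assert select_best(fits).family == "normal"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestSampling:
    def test_degenerate_distribution_returns_constant(self):
        dist = FittedDistribution("normal", {"mean": 80.0, "sd": 0.0})
        draws = sample_concentrations(dist, 100, seed=0)
        assert np.all(draws == 80.0)

    def test_truncated_normal_draws_nonnegative_with_correct_mean(self):
        dist = FittedDistribution("normal", {"mean": 100.17, "sd": 44.62})
        draws = sample_concentrations(dist, 100_000, seed=1)
        assert draws.min() >= 0.0
        assert abs(draws.mean() - distribution_mean(dist)) < 3 * 44.62 / math.sqrt(100_000)

    def test_lognormal_log_scale_mean(self):
        dist = FittedDistribution("lognormal", {"mu": 4.1, "sigma": 0.9})
        draws = sample_concentrations(dist, 100_000, seed=2)
        expected = math.exp(4.1 + 0.9**2 / 2)  # ~90.5
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se

    def test_arithmetic_convention_reinterprets_parameters(self):
        dist = FittedDistribution("lognormal", {"mu": 4.1, "sigma": 0.9})
        draws = sample_concentrations(dist, 100_000, seed=3, param_convention="arithmetic")
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - 4.1) < 3 * se

    def test_invalid_convention_rejected(self):
        dist = FittedDistribution("lognormal", {"mu": 4.1, "sigma": 0.9})
        with pytest.raises(ValueError):
            sample_concentrations(dist, 10, seed=0, param_convention="moments")


class TestDistributionMean:
    def test_exponential_mean(self):
        assert distribution_mean(FittedDistribution("exponential", {"rate": 0.02})) == 50.0

    def test_lognormal_closed_form(self):
        d = FittedDistribution("lognormal", {"mu": 4.1, "sigma": 0.9})
        assert distribution_mean(d) == pytest.approx(math.exp(4.1 + 0.405), rel=1e-12)
        assert distribution_mean(d) == pytest.approx(90.5, abs=0.1)

    @pytest.mark.parametrize("mean,sd", [(100.17, 44.62), (30.55, 16.85)])
    def test_truncated_normal_mean_against_numerical_integration(self, mean, sd):
        d = FittedDistribution("normal", {"mean": mean, "sd": sd})
        norm_const = stats.norm.cdf(mean / sd)
        oracle, _ = quad(
            lambda x: x * stats.norm.pdf(x, mean, sd) / norm_const, 0, mean + 12 * sd
        )
        assert distribution_mean(d) == pytest.approx(oracle, rel=1e-9)

    def test_truncation_flag_off_returns_raw_mean(self):
        d = FittedDistribution("normal", {"mean": 30.55, "sd": 16.85}, truncate_at_zero=False)
        assert distribution_mean(d) == 30.55


class TestCorrelationAndTTest:
    def test_perfect_linear_relationship(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_correlation(x, [2 * v + 1 for v in x]).r == pytest.approx(1.0)
        assert pearson_correlation([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_symmetry_and_scale_shift_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        r_xy = pearson_correlation(x, y).r
        assert pearson_correlation(y, x).r == pytest.approx(r_xy, rel=1e-12)
        assert pearson_correlation(3.0 * x + 7.0, y).r == pytest.approx(r_xy, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_identical_groups_t_zero_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        t, p = welch_t_test(a, list(a))
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_reject(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(10.0, 1.0, 30)  # shifted by 10 pooled sd
        _, p = welch_t_test(a, b)
        assert p < 1e-6

    def test_white_vs_brown_generator_gap_detected(self):
        """White (n=64, mean ~101.6) vs brown (n=90, mean ~80): t-test rejects."""
        from ricerisk.synthetic_data import default_brown_spec

        white = generate_dataset(default_white_spec(seed=21)).values()
        brown = generate_dataset(default_brown_spec(seed=22)).values()
        t, p = welch_t_test(white, brown)
        assert t > 0  # white mean above brown mean
        assert p < 0.05
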