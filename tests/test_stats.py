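"""Poisson-null GOF, homogeneity, spacing summaries and Games-Howell."""

import numpy as np
import pytest
from scipy import stats as sps

from meioscope import (
    Stage,
    ValidationError,
    chisq_homogeneity,
    distribution_from_counts,
    estimate_nu,
    foci_distribution,
    games_howell,
    genotype_presets,
    poisson_gof,
    sample_stationary_gamma_process,
    simulate_experiment,
    spacing_cv,
)

WT_COUNTS = [54, 238, 220, 39]  # 551 wild-type bivalents by foci 0..3


def brute_force_chi2(observed, expected):
    return float(sum((o - e) ** 2 / e for o, e in zip(observed, expected)))


class TestPoissonGof:
    def test_lambda_is_the_sample_mean(self):
        dist = distribution_from_counts(WT_COUNTS)
        fit = poisson_gof(dist)
        assert fit.lambda_hat == pytest.approx(795 / 551)

    def test_excel_policy_layout(self):
        """Spreadsheet layout: one extra empty category, pmf expectations,
        df = categories - 1."""
        dist = distribution_from_counts(WT_COUNTS)
        fit = poisson_gof(dist, "excel_k_minus_1")
        assert fit.categories == (0, 1, 2, 3, 4)
        assert fit.observed[-1] == 0.0
        n, lam = 551, 795 / 551
        np.testing.assert_allclose(
            fit.expected, n * sps.poisson.pmf(np.arange(5), lam), rtol=1e-12
        )
        assert fit.df == 4

    def test_folded_policy_tail_mass_and_df(self):
        dist = distribution_from_counts(WT_COUNTS)
        fit = poisson_gof(dist, "folded_k_minus_2")
        assert all(e >= 5 for e in fit.expected)
        assert fit.df == len(fit.categories) - 2
        # last expected is the Poisson tail mass, so expectations sum to n
        assert sum(fit.expected) == pytest.approx(551.0, rel=1e-12)

    @pytest.mark.parametrize("policy", ["excel_k_minus_1", "folded_k_minus_2"])
    def test_chi2_matches_brute_force(self, policy, presets):
        cells = simulate_experiment(presets["AACC_wt"], 29)
        for dist in (
            distribution_from_counts(WT_COUNTS),
            foci_distribution(cells, Stage.DIAKINESIS),
        ):
            fit = poisson_gof(dist, policy)
            assert fit.chi2 == pytest.approx(
                brute_force_chi2(fit.observed, fit.expected), abs=1e-10
            )
            assert fit.p_value == pytest.approx(
                float(sps.chi2.sf(fit.chi2, fit.df)), abs=1e-15
            )

    def test_wild_type_counts_reject_under_both_policies(self):
        """The printed wild-type distribution deviates enormously from
        Poisson; both binning conventions agree on extreme rejection."""
        dist = distribution_from_counts(WT_COUNTS)
        for policy in ("excel_k_minus_1", "folded_k_minus_2"):
            assert poisson_gof(dist, policy).p_value < 1e-20

    def test_pvalues_roughly_uniform_under_the_null(self):
        """Folded-policy p-values on true Poisson data are ~Uniform(0,1)."""
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(1000):
            counts = np.bincount(rng.poisson(1.44, 551))
            ps.append(poisson_gof(distribution_from_counts(counts),
                                  "folded_k_minus_2").p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_bivalents_rejected(self):
        with pytest.raises(ValidationError, match=">= 20"):
            poisson_gof(distribution_from_counts([5, 5]))

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValidationError, match="policy"):
            poisson_gof(distribution_from_counts(WT_COUNTS), "bonferroni")


class TestChisqHomogeneity:
    def test_identical_distributions_do_not_differ(self):
        a = distribution_from_counts([54, 238, 220, 39])
        chi2, df, p = chisq_homogeneity(a, a)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_type_one_error_calibrated(self):
        """Two samples from one multinomial differ ~5% of the time at 5%."""
        rng = np.random.default_rng(7)
        probs = np.array([0.10, 0.43, 0.40, 0.07])
        rejections = 0
        for _ in range(1000):
            a = rng.multinomial(500, probs)
            b = rng.multinomial(500, probs)
            _, _, p = chisq_homogeneity(
                distribution_from_counts(a), distribution_from_counts(b)
            )
            rejections += p < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_interference_loss_is_detected(self, presets):
        """Wild-type-like and single-allele-like distributions differ."""
        wt = foci_distribution(
            simulate_experiment(presets["AACC_wt"], 500), Stage.DIAKINESIS
        )
        mut = foci_distribution(
            simulate_experiment(presets["aaCc"], 500), Stage.DIAKINESIS
        )
        _, _, p = chisq_homogeneity(wt, mut)
        assert p < 0.001

    def test_degenerate_table_rejected(self):
        a = distribution_from_counts([50])
        with pytest.raises(ValidationError):
            chisq_homogeneity(a, a)


class TestSpacingCV:
    def test_constant_spacings_have_zero_cv(self):
        assert spacing_cv([0.25] * 10) == 0.0

    def test_exponential_spacings_have_unit_cv(self):
        rng = np.random.default_rng(1)
        assert spacing_cv(rng.exponential(0.5, 10_000)) == pytest.approx(1.0, abs=0.1)

    def test_gamma_nine_spacings_have_cv_one_third(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(9.0, 1.0, 10_000)
        assert spacing_cv(x) == pytest.approx(1 / 3, abs=0.1)

    def test_fewer_than_two_spacings_rejected(self):
        with pytest.raises(ValidationError):
            spacing_cv([0.5])

    def test_mean_spacing_falls_and_cv_rises_as_interference_weakens(self):
        """Losing interference pulls adjacent foci closer (smaller mean
        relative distance) and makes their spacing more irregular (CV
        approaches the exponential value)."""
        means, cvs = [], []
        for i, nu in enumerate([8.0, 4.0, 2.0, 1.0]):
            rng = np.random.default_rng([900, i])
            spacings = []
            for _ in range(4000):
                pos = sample_stationary_gamma_process(1.0, 1.995, nu, rng)
                spacings.extend(np.diff(pos))
            means.append(np.mean(spacings))
            cvs.append(spacing_cv(spacings))
        assert all(a > b for a, b in zip(means, means[1:]))
        assert all(a < b for a, b in zip(cvs, cvs[1:]))


class TestEstimateNu:
    def test_recovers_gamma_shape_five(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(5.0, 0.1, 10_000)
        est = estimate_nu(x, n_boot=0)
        assert 4.5 <= est.nu_hat <= 5.5

    def test_exponential_spacings_give_shape_one(self):
        rng = np.random.default_rng(4)
        est = estimate_nu(rng.exponential(0.3, 10_000), n_boot=0)
        assert est.nu_hat == pytest.approx(1.0, abs=0.15)

    def test_bootstrap_interval_brackets_truth_and_is_seeded(self):
        rng = np.random.default_rng(5)
        x = rng.gamma(3.0, 0.2, 2000)
        a = estimate_nu(x, n_boot=200, seed=11)
        b = estimate_nu(x, n_boot=200, seed=11)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low < 3.0 < a.ci_high

    def test_simulator_output_recovery_with_mild_censoring_bias(self):
        """Pinned regression: on 1000 finite bivalents the estimate stays
        within 25% of truth despite edge censoring of long gaps."""
        rng = np.random.default_rng(6)
        spacings = []
        for _ in range(1000):
            pos = sample_stationary_gamma_process(1.0, 5.0, 5.0, rng)
            spacings.extend(np.diff(pos))
        est = estimate_nu(spacings, n_boot=0)
        assert abs(est.nu_hat - 5.0) / 5.0 < 0.25

    def test_too_few_spacings_rejected(self):
        with pytest.raises(ValidationError, match=">= 30"):
            estimate_nu([0.1] * 10)


class TestGamesHowell:
    def test_identical_groups_are_not_distinguished(self):
        x = np.linspace(0.0, 1.0, 20)
        comps = games_howell({"a": x, "b": x})
        assert comps[0].mean_diff == 0.0
        assert comps[0].p_adjusted == pytest.approx(1.0)

    def test_matches_independent_reference_implementation(self):
        """Cross-check every output column against pingouin on one dataset."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        data = {
            "g0": rng.normal(0.0, 1.0, 40),
            "g1": rng.normal(0.5, 2.0, 25),
            "g2": rng.normal(1.0, 0.5, 60),
        }
        mine = games_howell(data)
        df = pd.DataFrame(
            {
                "y": np.concatenate(list(data.values())),
                "g": np.repeat(list(data), [len(v) for v in data.values()]),
            }
        )
        ref = pg.pairwise_gameshowell(dv="y", between="g", data=df)
        for c in mine:
            row = ref[(ref.A == c.group_a) & (ref.B == c.group_b)].iloc[0]
            assert c.p_adjusted == pytest.approx(row.pval, abs=1e-6)
            assert c.df == pytest.approx(row.df, rel=1e-9)
            assert c.standard_error == pytest.approx(row.se, rel=1e-9)

    def test_agrees_with_tukey_under_equal_variance_equal_n(self):
        """With equal sample variances and sizes the Welch machinery reduces
        to the classical Tukey HSD up to the df convention."""
        rng = np.random.default_rng(17)
        data = []
        for mu in (0.0, 0.25, 0.45):
            x = rng.normal(0, 1, 50)
            x = (x - x.mean()) / x.std(ddof=1)
            data.append(x + mu)
        mine = games_howell({f"g{i}": d for i, d in enumerate(data)})
        ref = sps.tukey_hsd(*data)
        for c in mine:
            i, j = int(c.group_a[1]), int(c.group_b[1])
            assert abs(c.p_adjusted - ref.pvalue[i, j]) / ref.pvalue[i, j] < 0.05

    def test_family_wise_error_is_calibrated(self):
        """Under the global null across 4 groups the probability of any
        false positive stays near the nominal 5%."""
        rng = np.random.default_rng(3)
        hits = 0
        reps = 300  # smoke-level; the full 1000-replicate calibration runs
        for _ in range(reps):  # in the acceptance suite
            groups = {f"g{i}": rng.normal(0, 1, 30) for i in range(4)}
            hits += any(c.p_adjusted < 0.05 for c in games_howell(groups))
        assert 0.01 <= hits / reps <= 0.10

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValidationError, match="zero variance"):
            games_howell({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
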