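import numpy as np
import pytest
from scipy import stats as sps

from scsim import (
    EmpiricalHistogram,
    MortalityScenario,
    PopulationSpec,
    chisq_exceedance,
    diagnose_pair,
    expected_null_exceedance,
    project_adult_histogram,
    sample_descriptives,
)
from scsim.diagnostics import (
    VERDICT_INDETERMINATE,
    VERDICT_KNIFE_EDGE,
    VERDICT_SECOND_POPULATION,
    NullExceedance,
)


def make_stats(**kw):
    base = dict(n=100, mean=30.0, median=30.0, min=20.0, max=40.0, range=20.0,
                sd=5.0, skewness=0.0, excess_kurtosis=0.0, pct_exceeding=None)
    base.update(kw)
    from scsim import SampleStats

    return SampleStats(**base)


class TestDiagnosePair:
    def test_identical_batteries_are_indeterminate(self):
        j = make_stats()
        a = make_stats()
        assert diagnose_pair(j, a).verdict == VERDICT_INDETERMINATE

    def test_knife_edge_signature_with_exceedance_inside_null(self):
        j = make_stats()
        a = make_stats(mean=33.0, sd=3.0, min=28.0, range=12.0,
                       skewness=0.8, excess_kurtosis=0.5, pct_exceeding=0.5)
        report = diagnose_pair(j, a, null_exceedance=(1.0, 0.0, 3.0))
        assert report.verdict == VERDICT_KNIFE_EDGE

    def test_exceedance_above_null_band_blocks_knife_edge(self):
        j = make_stats()
        a = make_stats(mean=33.0, sd=3.0, min=28.0, range=12.0,
                       skewness=0.8, excess_kurtosis=0.5, pct_exceeding=12.0)
        report = diagnose_pair(j, a, null_exceedance=(1.0, 0.0, 3.0))
        assert report.verdict == VERDICT_SECOND_POPULATION

    def test_variance_expansion_means_second_population(self):
        """Mean up but SD/range up: the signature of an unsampled larger population."""
        j = make_stats()
        a = make_stats(mean=33.0, sd=6.5, max=48.0, range=28.0)
        assert diagnose_pair(j, a).verdict == VERDICT_SECOND_POPULATION

    def test_missing_shape_statistics_fall_back_to_indeterminate(self):
        j = make_stats(skewness=float("nan"), excess_kurtosis=float("nan"))
        a = make_stats(mean=33.0, sd=3.0, range=12.0,
                       skewness=float("nan"), excess_kurtosis=float("nan"),
                       pct_exceeding=0.0)
        report = diagnose_pair(j, a, null_exceedance=(1.0, 0.0, 3.0))
        assert report.verdict == VERDICT_INDETERMINATE
        assert any("unavailable" in n for n in report.notes)

    def test_report_serialises_every_checklist_item(self, tmp_path):
        j = make_stats()
        a = make_stats(mean=33.0, sd=6.5, range=28.0)
        report = diagnose_pair(j, a)
        d = report.as_dict()
        for stat in ("mean", "sd", "range", "skewness", "kurtosis"):
            assert f"direction_{stat}" in d
        report.to_json(tmp_path / "report.json")
        assert "verdict" in (tmp_path / "report.json").read_text()
        assert "verdict" in report.to_text()


class TestCohoCaseStudy:
    """Observed juvenile (age-0, 2000) vs immature (age-1, 2001) coho
    intercirculus-distance summaries from a published Strait of Georgia study."""

    JUVENILE = make_stats(n=87, mean=0.038, range=0.018, min=0.031, max=0.049,
                          sd=0.004, excess_kurtosis=-0.43, skewness=0.40)
    ADULT = make_stats(n=248, mean=0.043, range=0.027, min=0.031, max=0.058,
                       sd=0.004, excess_kurtosis=0.15, skewness=0.04)

    def test_verdict_is_second_population(self):
        report = diagnose_pair(self.JUVENILE, self.ADULT)
        assert report.verdict == VERDICT_SECOND_POPULATION
        assert report.directions["mean"] == "increased"
        assert report.directions["range"] == "increased"
        assert report.directions["sd"] == "unchanged"
        assert report.directions["skewness"] == "decreased"


class TestExpectedNullExceedance:
    def test_null_mean_matches_exchangeability(self, study_spec):
        """With no mortality, P(adult > juvenile max) = 1/(juvenile_n + 1)."""
        scenario = MortalityScenario(rate=0.0, critical_limit=-np.inf)
        null = expected_null_exceedance(99, 100, study_spec, scenario,
                                        replicates=4000, seed=2)
        # 3 Monte-Carlo SEs of the mean percentage
        se = 3.5 / np.sqrt(4000) * 3  # empirical sd of per-replicate pct is ~3.5
        assert null.mean == pytest.approx(1.0, abs=max(se, 0.2))

    def test_band_is_ordered_and_median_small_at_80pct(self, study_spec):
        scenario = MortalityScenario.from_rate(0.8, spec=study_spec)
        null = expected_null_exceedance(1000, 1000, study_spec, scenario,
                                        replicates=500, seed=3)
        assert null.lower <= null.median <= null.upper
        assert null.median <= 1.0

    def test_order_statistic_plug_in_cross_check(self, study_spec):
        """Median exceedance at 80% mortality, 50/50 design, vs the closed-form
        plug-in: juvenile max at quantile 0.5**(1/n), tail beyond it rescaled."""
        scenario = MortalityScenario.from_rate(0.8, spec=study_spec)
        null = expected_null_exceedance(50, 50, study_spec, scenario,
                                        replicates=4000, seed=4)
        jmax_med = sps.norm.ppf(0.5 ** (1 / 50), loc=30, scale=5)
        plug_in = 100 * sps.norm.sf(jmax_med, loc=30, scale=5) / 0.2
        assert null.median == pytest.approx(plug_in, abs=1.1)  # granularity 2%/count

    def test_few_replicates_warn(self, study_spec):
        scenario = MortalityScenario.from_rate(0.2, spec=study_spec)
        with pytest.warns(UserWarning, match="replicates"):
            null = expected_null_exceedance(10, 10, study_spec, scenario,
                                            replicates=50, seed=5)
        assert null.warning is not None


class TestChisqExceedance:
    def test_exact_agreement_gives_zero(self):
        res = chisq_exceedance(5, 100, 0.05)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_hand_arithmetic_example(self):
        res = chisq_exceedance(15, 100, 0.05)
        assert res.statistic == pytest.approx(21.0526, abs=1e-3)
        assert res.df == 1

    def test_critical_value_at_p05(self):
        assert sps.chi2.sf(3.84, 1) == pytest.approx(0.05, abs=2e-4)
        res = chisq_exceedance(15, 100, 0.05)
        assert res.pvalue == pytest.approx(sps.chi2.sf(res.statistic, 1))

    @pytest.mark.parametrize("obs,n,p", [(3, 40, 0.1), (0, 25, 0.5), (17, 17, 0.9)])
    def test_matches_scipy_chisquare_oracle(self, obs, n, p):
        ours = chisq_exceedance(obs, n, p)
        ref = sps.chisquare([obs, n - obs], [n * p, n * (1 - p)])
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.pvalue == pytest.approx(ref.pvalue)

    def test_small_expected_cell_flags(self):
        with pytest.warns(UserWarning, match="below 1"):
            res = chisq_exceedance(1, 50, 0.01)
        assert res.tiny_expected_cell and res.small_expected_cell
        ok = chisq_exceedance(10, 100, 0.5)
        assert not ok.small_expected_cell

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            chisq_exceedance(5, 100, 0.0)
        with pytest.raises(ValueError):
            chisq_exceedance(101, 100, 0.5)


class TestProjectAdultHistogram:
    def test_rate_zero_rescales_only(self):
        h = EmpiricalHistogram([0, 1, 2, 3], [2, 4, 6])
        out = project_adult_histogram(h, 0.0, 24)
        np.testing.assert_allclose(out.counts, [4, 8, 12])
        np.testing.assert_array_equal(out.bin_edges, h.bin_edges)

    def test_uniform_half_cut(self):
        h = EmpiricalHistogram(np.arange(11), np.full(10, 7.0))
        out = project_adult_histogram(h, 0.5, 70.0)
        np.testing.assert_allclose(out.counts, [0] * 5 + [14.0] * 5)

    def test_three_bin_worked_example(self):
        h = EmpiricalHistogram([0, 1, 2, 3], [10, 20, 10])
        out = project_adult_histogram(h, 0.375, 100)
        np.testing.assert_allclose(out.counts, [0.0, 60.0, 40.0])

    def test_mass_conservation_on_random_histograms(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            b = rng.integers(1, 12)
            edges = np.sort(rng.uniform(0, 100, b + 1))
            edges += np.arange(b + 1) * 1e-6  # enforce strict ascent
            counts = rng.integers(0, 50, b)
            if counts.sum() == 0:
                counts[rng.integers(b)] = 1
            rate = rng.uniform(0, 0.95)
            total = rng.uniform(1, 500)
            out = project_adult_histogram(EmpiricalHistogram(edges, counts), rate, total)
            assert out.counts.sum() == pytest.approx(total, rel=1e-9)
            assert (out.counts >= 0).all()

    def test_higher_rate_is_stochastically_larger(self):
        h = EmpiricalHistogram(np.arange(11), np.random.default_rng(7).integers(1, 30, 10))
        low = project_adult_histogram(h, 0.3, 1.0)
        high = project_adult_histogram(h, 0.7, 1.0)
        assert np.all(np.cumsum(high.counts) <= np.cumsum(low.counts) + 1e-12)

    def test_rate_one_rejected(self):
        h = EmpiricalHistogram([0, 1], [5])
        with pytest.raises(ValueError):
            project_adult_histogram(h, 1.0, 10)
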