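"""Reduced-variable perturbation analysis: reduction, response fits,
robustness summaries, and the wing-loading check."""

import numpy as np
import pandas as pd
import pytest

from samaraflight.errors import (DomainError, MissingBaselineError,
                                 SingularFitError)
from samaraflight.perturbation import (fit_responses, reduce,
                                       robustness_summary,
                                       wing_loading_check)
from samaraflight.synthetic_data import (GeneratorConfig,
                                         generate_perturbation_study,
                                         generate_population)

MASS_LEVELS = np.geomspace(0.5, 2.0, 6)
ABLATION_LEVELS = np.geomspace(0.65, 1.0, 5)[:-1]


def _zero_noise_study(kind, levels, seed=3, **kwargs):
    cfg = GeneratorConfig(seed=seed, noise_sd_v=0.0, noise_sd_dynamics=0.0)
    population, _ = generate_population(cfg)
    return generate_perturbation_study(
        population, cfg, kind, levels,
        rng=np.random.default_rng(seed + 100), **kwargs)


@pytest.fixture(scope="module")
def mass_study():
    return _zero_noise_study("mass", MASS_LEVELS)


@pytest.fixture(scope="module")
def ablation_study():
    return _zero_noise_study("ablation", ABLATION_LEVELS)


class TestReduce:
    def test_baseline_only_gives_unit_ratios(self, mass_study):
        base = mass_study[mass_study["level_index"] == 0]
        red = reduce(base)
        assert (red[["v_ratio", "omega_ratio", "theta_ratio"]] == 1.0).all().all()

    def test_simple_ratio(self, mass_study):
        red = reduce(mass_study)
        row = red[(red["level_index"] == 1)].iloc[0]
        base = red[(red["specimen_id"] == row["specimen_id"])
                   & (red["level_index"] == 0)].iloc[0]
        assert row["v_ratio"] == pytest.approx(
            row["v_d_m_s"] / base["v_d_m_s"], rel=1e-12)

    def test_closed_form_at_double_mass(self):
        """Zero noise at m/m0 = 2 gives V ratio 2^0.12 = 1.0868 exactly."""
        study = _zero_noise_study("mass", [2.0])
        red = reduce(study)
        doubled = red[red["level_index"] == 1]
        assert np.allclose(doubled["v_ratio"], 2.0**0.12, rtol=1e-12)
        assert np.allclose(doubled["omega_ratio"], 2.0**0.70, rtol=1e-12)
        assert np.allclose(doubled["theta_ratio"], 2.0**-0.48, rtol=1e-12)

    def test_idempotent(self, mass_study):
        once = reduce(mass_study)
        twice = reduce(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_baseline_names_specimen(self, mass_study):
        broken = mass_study[mass_study["level_index"] > 0]
        sid = broken["specimen_id"].iloc[0]
        with pytest.raises(MissingBaselineError, match=sid):
            reduce(broken)


class TestFitResponses:
    def test_noise_free_mass_exponents_exact(self, mass_study):
        fits = {f.response: f.fit for f in
                fit_responses(reduce(mass_study), driver="m_ratio")}
        assert fits["v_ratio"].exponent == pytest.approx(0.12, abs=1e-8)
        assert fits["omega_ratio"].exponent == pytest.approx(0.70, abs=1e-8)
        assert fits["theta_ratio"].exponent == pytest.approx(-0.48, abs=1e-8)

    def test_noise_free_ablation_exponents_exact(self, ablation_study):
        fits = {f.response: f.fit for f in
                fit_responses(reduce(ablation_study), driver="a_ratio")}
        assert fits["v_ratio"].exponent == pytest.approx(-0.79, abs=1e-8)
        assert fits["omega_ratio"].exponent == pytest.approx(0.03, abs=1e-8)
        assert fits["theta_ratio"].exponent == pytest.approx(-0.38, abs=1e-8)

    @pytest.mark.parametrize("true_exponent", [-1.0, -0.31, 0.0, 0.55, 1.0])
    def test_exact_recovery_across_exponent_range(self, true_exponent):
        """Any configured V-vs-mass exponent in [-1, 1] is recovered."""
        from samaraflight.synthetic_data import ResponseExponents
        cfg = GeneratorConfig(seed=6, noise_sd_v=0.0, noise_sd_dynamics=0.0,
                              response_exponents=ResponseExponents(
                                  v_vs_m=true_exponent))
        population, _ = generate_population(cfg)
        study = generate_perturbation_study(
            population, cfg, "mass", MASS_LEVELS,
            rng=np.random.default_rng(1))
        fits = {f.response: f.fit for f in
                fit_responses(reduce(study), driver="m_ratio")}
        assert fits["v_ratio"].exponent == pytest.approx(true_exponent,
                                                         abs=1e-8)

    def test_degenerate_driver(self, mass_study):
        base = reduce(mass_study[mass_study["level_index"] == 0])
        with pytest.raises(SingularFitError):
            fit_responses(base, driver="m_ratio")

    def test_failed_records_are_excluded(self, mass_study):
        red = reduce(mass_study)
        fits = fit_responses(red, driver="m_ratio")
        # A. macrophyllum fails above m/m0 = 1.3; those points must not
        # participate, so n is below the full row count.
        assert fits[0].fit.n < len(red)
        assert red["failed"].any()

    def test_species_scope(self, mass_study):
        red = reduce(mass_study)
        fits = fit_responses(red, driver="m_ratio", scope="A. negundo")
        assert all(f.species_scope == "A. negundo" for f in fits)
        assert fits[0].fit.n < fit_responses(red, "m_ratio")[0].fit.n


class TestRobustness:
    def test_predicted_change_from_printed_exponent(self, mass_study):
        fits = fit_responses(reduce(mass_study), driver="m_ratio")
        summaries = robustness_summary(mass_study, fits)
        for s in summaries:
            # 2^0.12 - 1 = 8.68 %, comfortably below the 15 % bound
            assert s.predicted_v_change_at_double_mass == pytest.approx(
                0.0867, abs=1e-3)
            assert s.predicted_v_change_at_double_mass < 0.15
            assert s.max_m_ratio_sustained >= 1.0
            assert s.min_a_ratio_sustained <= 1.0

    def test_square_root_law_would_violate_the_bound(self):
        # the wing-loading prediction V ~ m^0.5 gives a 41 % change
        assert 2.0**0.5 - 1.0 > 0.15

    def test_negundo_sustains_to_its_preset_bound(self):
        study = _zero_noise_study("mass", [0.5, 1.5, 2.25, 2.5])
        fits = fit_responses(reduce(study), driver="m_ratio")
        by_species = {s.species: s for s in robustness_summary(study, fits)}
        assert by_species["A. negundo"].max_m_ratio_sustained == pytest.approx(2.25)
        # the most mass-sensitive species fails well before that
        assert by_species["A. macrophyllum"].max_m_ratio_sustained < 1.5


class TestWingLoadingCheck:
    def test_within_specimen_beats_across(self):
        """Altered series obey V² ~ m g/A better than the population does."""
        cfg = GeneratorConfig(seed=12)
        population, _ = generate_population(cfg)
        study = generate_perturbation_study(
            population, cfg, "mass", MASS_LEVELS,
            rng=np.random.default_rng(99))
        cmp = wing_loading_check(study)
        assert cmp.r2_within_mean > cmp.r2_across
        assert cmp.n_specimens == 12

    def test_degenerate_series_is_singular(self, mass_study):
        base = mass_study[mass_study["level_index"] == 0]
        with pytest.raises(SingularFitError):
            wing_loading_check(base)

    def test_shuffled_driver_kills_correlation(self, rng):
        cfg = GeneratorConfig(seed=21)
        population, _ = generate_population(cfg)
        study = generate_perturbation_study(
            population, cfg, "mass", MASS_LEVELS,
            rng=np.random.default_rng(7))
        shuffled = study.copy()
        shuffled["v_d_m_s"] = rng.permutation(shuffled["v_d_m_s"].to_numpy())
        cmp = wing_loading_check(shuffled)
        assert cmp.r2_within_mean < 0.5  # mean of per-specimen small-n fits
        assert cmp.r2_across < 0.3


class TestSeriesGeneration:
    def test_level_one_is_exactly_baseline(self, mass_study):
        base = mass_study[mass_study["level_index"] == 0]
        assert (base["m_ratio"] == 1.0).all()
        assert (base["a_ratio"] == 1.0).all()
        assert not base["failed"].any()

    def test_mass_addition_area_band(self, mass_study):
        added = mass_study[mass_study["kind"] == "mass_add"]
        added = added[added["level_index"] > 0]
        assert ((added["a_ratio"] >= 1.0) & (added["a_ratio"] <= 1.05)).all()
        subbed = mass_study[(mass_study["kind"] == "mass_sub")
                            & (mass_study["level_index"] > 0)]
        assert (subbed["a_ratio"] == 1.0).all()

    def test_ablation_mass_band(self, ablation_study):
        abl = ablation_study[ablation_study["level_index"] > 0]
        assert ((abl["m_ratio"] >= 0.96) & (abl["m_ratio"] <= 1.0)).all()
        assert (abl["a_ratio"] < 1.0).all()

    def test_ablation_below_failure_bound_is_flagged(self):
        study = _zero_noise_study("ablation", [0.5])
        abl = study[study["level_index"] == 1]
        assert abl["failed"].all()  # every preset bound is above 0.5

    def test_kind_level_mismatch_rejected(self):
        with pytest.raises(DomainError):
            _zero_noise_study("ablation", [1.2])
        with pytest.raises(DomainError):
            _zero_noise_study("mass_add", [0.8])
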