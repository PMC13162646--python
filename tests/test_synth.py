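"""The survey generator: determinism, covariate structure, occupancy truth,
and the record stream's consistency with the event pipeline."""

import dataclasses
import filecmp
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from trapcomm.covariates import DegenerateColumnError, standardize
from trapcomm.events import EventTable, build_detection_history, filter_independent_events
from trapcomm.synth import (
    ConfigurationError,
    SpeciesTruth,
    SurveyScenario,
    TruthSet,
    generate_covariates,
    generate_records,
    generate_survey,
    generate_truth,
    sample_occupancy,
    write_survey,
)


class TestScenario:
    def test_invalid_configurations_rejected(self):
        with pytest.raises(ConfigurationError):
            SurveyScenario(n_sites=1)
        with pytest.raises(ConfigurationError):
            SurveyScenario(occasion_length_days=0)
        with pytest.raises(ConfigurationError):
            SpeciesTruth("x", 0.0, (0.0,) * 13, (0.0,) * 4, event_rate=0.5, guild="g")
        with pytest.raises(ConfigurationError):
            SpeciesTruth("x", 0.0, (0.0,) * 3, (0.0,) * 4, event_rate=1.0, guild="g")

    def test_non_positive_definite_correlations_rejected(self):
        bad = np.full((6, 6), 0.99)
        np.fill_diagonal(bad, 1.0)
        bad[0, 1] = bad[1, 0] = -0.99  # inconsistent with the 0.99 block
        with pytest.raises(ConfigurationError):
            generate_covariates(SurveyScenario(covariate_correlations=bad))


class TestCovariates:
    def test_standardized_elevation_centered(self):
        sc = SurveyScenario(n_sites=1000, covariate_correlations=np.eye(6), seed=3)
        cov = generate_covariates(sc)
        assert abs(cov.standardized["ele"].mean()) < 0.1
        assert abs(cov.standardized["ele"].std(ddof=1) - 1) < 0.1
        assert cov.raw["ele"].between(1330, 4551).all()
        assert (cov.raw[[c for c in cov.raw if c.startswith("dist")]] >= 0).all().all()
        np.testing.assert_allclose(
            cov.standardized["ele2"], cov.standardized["ele"] ** 2, atol=1e-12
        )

    def test_constant_column_flagged_degenerate(self):
        tab = pd.DataFrame({"ele": [5.0, 5.0, 5.0], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(DegenerateColumnError, match="ele"):
            standardize(tab)

    def test_same_seed_byte_identical_files(self, tmp_path):
        sc = SurveyScenario(n_sites=25, n_species=6, survey_days=84, seed=5)
        for d in ("a", "b"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                write_survey(tmp_path / d, sc, *generate_survey(sc))
        for f in ("records.csv", "deployments.csv", "covariates.csv", "truth.json"):
            assert filecmp.cmp(tmp_path / "a" / f, tmp_path / "b" / f, shallow=False), f


def _flat_scenario(**beta):
    arch = [{"name": "g", "alpha": 0.0, "beta": beta}]
    return SurveyScenario(
        n_sites=60, n_species=4, guild_archetypes=arch,
        coef_spread=0.0, alpha_spread=0.0, seed=9,
    )


class TestTruth:
    def test_null_coefficients_give_half_occupancy(self):
        sc = _flat_scenario()
        cov = generate_covariates(sc)
        truth = generate_truth(sc, cov)
        np.testing.assert_allclose(truth.psi, 0.5)

    def test_positive_elevation_effect_is_monotone(self):
        sc = _flat_scenario(ele=2.0)
        cov = generate_covariates(sc)
        truth = generate_truth(sc, cov)
        order = np.argsort(cov.standardized["ele"].to_numpy())
        assert (np.diff(truth.psi[0][order]) > 0).all()

    def test_negative_quadratic_is_hump_shaped(self):
        sc = _flat_scenario(ele2=-1.0)
        cov = generate_covariates(sc)
        truth = generate_truth(sc, cov)
        ele = cov.standardized["ele"].to_numpy()
        # psi on this grid peaks where standardized elevation is nearest 0
        assert np.argmax(truth.psi[0]) == np.argmin(np.abs(ele))
        np.testing.assert_allclose(truth.psi[0], expit(-(ele**2)))

    def test_occupancy_frequency_converges_to_psi(self, rng):
        sc = SurveyScenario(n_sites=30, n_species=3, seed=2)
        cov = generate_covariates(sc)
        truth = generate_truth(sc, cov)
        n_rep = 4000
        freq = sum(sample_occupancy(truth.psi, rng) for _ in range(n_rep)) / n_rep
        tol = 4 * np.sqrt(truth.psi * (1 - truth.psi) / n_rep)
        assert (np.abs(freq - truth.psi) <= tol + 1e-9).all()


class TestRecords:
    def test_unoccupied_species_yields_no_records(self, small_scenario):
        sc = dataclasses.replace(small_scenario, disturbance_rate=0.0)
        cov = generate_covariates(sc)
        truth = generate_truth(sc, cov)
        z = truth.z.copy()
        z[0] = 0
        truth0 = TruthSet(species=truth.species, psi=truth.psi, z=z, site_ids=truth.site_ids)
        records, _ = generate_records(sc, truth0, cov)
        assert not (records["species"] == truth.species[0].species_id).any()

    def test_zero_disturbance_rate_means_no_pseudo_species(self):
        sc = SurveyScenario(n_sites=25, n_species=4, survey_days=84,
                            disturbance_rate=0.0, seed=4)
        cov = generate_covariates(sc)
        assert (cov.raw["disturb"] == 0).all()
        records, _ = generate_records(sc, generate_truth(sc, cov), cov)
        assert not records["species"].isin(["human", "livestock"]).any()

    def test_perfect_detection_roundtrip_matches_truth(self):
        """With p = 1 and one burst per detected occasion, the events module
        reconstructs the latent occupancy-by-effort matrix exactly."""
        sc = SurveyScenario(n_sites=30, n_species=5, survey_days=112,
                            disturbance_rate=0.0, seed=21)
        cov = generate_covariates(sc)
        truth = generate_truth(sc, cov)
        truth = TruthSet(
            species=[
                dataclasses.replace(t, gamma=(20.0, 0.0, 0.0, 0.0), event_rate=1.0)
                for t in truth.species
            ],
            psi=truth.psi, z=truth.z, site_ids=truth.site_ids,
        )
        records, deployments = generate_records(sc, truth, cov)
        ev = filter_independent_events(records, deployments)
        hist = build_detection_history(
            ev, deployments, survey_start="2017-10-01",
            survey_end=pd.Timestamp("2017-10-01") + pd.Timedelta(days=sc.survey_days - 1),
            species=[t.species_id for t in truth.species],
        )
        wd = hist.workday.to_numpy()
        for s, t in enumerate(truth.species):
            h = hist.histories[t.species_id].to_numpy()
            expected = np.where(wd > 0, (truth.z[s][:, None] == 1).astype(float), np.nan)
            np.testing.assert_array_equal(np.nan_to_num(h, nan=-1.0),
                                          np.nan_to_num(expected, nan=-1.0))
        # one burst per detected occasion: events = occupied surveyed occasions
        n_occupied_occ = int(((wd > 0) * truth.z[:, :, None]).sum())
        assert ev.n_events == n_occupied_occ
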