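"""Marginal occupancy likelihood, the sampler, and response classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy import optimize

from trapcomm.occupancy import (
    OccupancyModelSpec,
    classify_elevation_response,
    detection_design,
    fit_occupancy,
    occupancy_loglik,
    split_rhat,
)


def brute_force_lik(psi, p, y):
    """Enumerate every latent occupancy vector (oracle)."""
    S = len(psi)
    total = 0.0
    for z in itertools.product([0, 1], repeat=S):
        prob = 1.0
        for i in range(S):
            yi = y[i][~np.isnan(y[i])]
            if z[i]:
                prob *= psi[i] * np.prod(
                    np.where(yi == 1, p[i][~np.isnan(y[i])], 1 - p[i][~np.isnan(y[i])])
                )
            else:
                prob *= (1 - psi[i]) * float((yi == 0).all())
        total += prob
    return total


class TestLoglik:
    @pytest.mark.parametrize(
        "y, expected",
        [
            ([[0.0, 0.0]], 0.625),  # 0.5 * 0.25 + 0.5
            ([[1.0, 0.0]], 0.125),  # occupied branch only
            ([[1.0, np.nan]], 0.25),  # missing occasion contributes no factor
        ],
    )
    def test_toy_likelihoods(self, y, expected):
        # psi = 0.5 and p = 0.5 via zero intercepts, no covariates
        ll = occupancy_loglik(0.0, np.zeros(1), np.zeros(1), np.array(y), np.zeros((1, 1)))
        assert np.exp(ll) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration(self, rng):
        for _ in range(25):
            S, J = int(rng.integers(2, 7)), int(rng.integers(1, 5))
            alpha = rng.normal()
            beta = rng.normal(size=2)
            g = rng.normal(size=1)
            Z = rng.normal(size=(S, 2))
            y = (rng.random((S, J)) < 0.4).astype(float)
            y[rng.random((S, J)) < 0.2] = np.nan
            psi = expit(alpha + Z @ beta)
            p = np.full((S, J), expit(g[0]))
            ll = occupancy_loglik(alpha, beta, g, y, Z)
            assert ll == pytest.approx(np.log(brute_force_lik(psi, p, y)), abs=1e-10)

    def test_occasion_permutation_invariance(self, rng):
        S, J = 5, 6
        y = (rng.random((S, J)) < 0.4).astype(float)
        Z = rng.normal(size=(S, 2))
        D = rng.normal(size=(S, J, 1))
        perm = rng.permutation(J)
        a = occupancy_loglik(0.3, np.r_[1.0, -0.5], np.r_[0.1, 0.4], y, Z, D)
        b = occupancy_loglik(0.3, np.r_[1.0, -0.5], np.r_[0.1, 0.4], y[:, perm], Z, D[:, perm])
        assert a == pytest.approx(b, rel=1e-12)

    def test_perfect_detection_recovers_naive_occupancy(self):
        # p -> 1 with full effort: psi's MLE is the naive occupancy proportion
        y = np.array([[1.0, 1], [1, 1], [0, 0], [0, 0], [0, 0]])
        Z = np.zeros((5, 1))

        def nll(a):
            return -occupancy_loglik(a, np.zeros(1), np.array([20.0]), y, Z)

        grid = np.linspace(-5, 5, 2001)
        best = grid[np.argmin([nll(a) for a in grid])]
        assert expit(best) == pytest.approx(0.4, abs=1e-3)

    def test_non_finite_predictor_rejected(self):
        with pytest.raises(FloatingPointError):
            occupancy_loglik(np.inf, np.zeros(1), np.zeros(1),
                             np.zeros((1, 2)), np.zeros((1, 1)))


class TestFit:
    def _simulate(self, rng, n_sites=120, n_occ=6, alpha=0.2, beta=(1.0,), p=0.5):
        Z = rng.normal(size=(n_sites, len(beta)))
        psi = expit(alpha + Z @ np.asarray(beta))
        z = (rng.random(n_sites) < psi).astype(float)
        y = (rng.random((n_sites, n_occ)) < p) * z[:, None]
        return y.astype(float), Z

    def test_map_matches_grid_search(self, rng):
        # near-flat prior: the posterior mode equals the likelihood's maximum
        y, Z = self._simulate(rng, n_sites=40, n_occ=3, beta=())
        y = y[:, :3]
        spec = OccupancyModelSpec(
            occ_predictors=(), det_covariates=(), prior_scale=1000.0,
            iterations=50, warmup=50, thin=1, seed=0,
        )
        if np.nansum(y) == 0:
            pytest.skip("degenerate draw")
        fit = fit_occupancy(spec, y, np.zeros((len(y), 0)), None)
        grid = np.linspace(-4, 4, 161)
        vals = np.array(
            [[occupancy_loglik(a, np.zeros(0), np.array([g]), y, np.zeros((len(y), 0)))
              for g in grid] for a in grid]
        )
        ia, ig = np.unravel_index(np.argmax(vals), vals.shape)
        assert fit.map_estimate[0] == pytest.approx(grid[ia], abs=0.06)
        assert fit.map_estimate[1] == pytest.approx(grid[ig], abs=0.06)

    def test_recovers_strong_effect(self, rng):
        y, Z = self._simulate(rng, n_sites=300, n_occ=8, beta=(1.2,))
        spec = OccupancyModelSpec(
            occ_predictors=("x0",), det_covariates=(), seed=1,
            iterations=400, warmup=300, thin=2,
        )
        fit = fit_occupancy(spec, y, Z, None)
        s = fit.summary.loc["beta_x0"]
        assert s["q05"] < 1.2 < s["q95"]
        assert s["p_dir"] > 0.95

    def test_null_predictor_direction_probability_near_half(self, rng):
        # a predictor that is identically zero carries no information: its
        # posterior is the (symmetric) prior, so P(beta > 0) ~ 0.5
        y, Z = self._simulate(rng, n_sites=100, n_occ=5, beta=(0.8,))
        Z2 = np.column_stack([Z, np.zeros(len(Z))])
        spec = OccupancyModelSpec(
            occ_predictors=("x0", "null"), det_covariates=(), seed=2,
            iterations=800, warmup=400, thin=2,
        )
        fit = fit_occupancy(spec, y, Z2, None)
        assert fit.summary.loc["beta_null", "p_dir"] == pytest.approx(0.5, abs=0.06)

    def test_all_zero_history_rejected(self):
        spec = OccupancyModelSpec(occ_predictors=(), det_covariates=())
        with pytest.raises(ValueError, match="all-zero"):
            fit_occupancy(spec, np.zeros((4, 3)), np.zeros((4, 0)), None)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            OccupancyModelSpec(chains=1)

    def test_split_rhat_agrees_with_arviz(self, rng):
        az = pytest.importorskip("arviz")
        draws = rng.normal(size=(4, 250, 3))
        draws[1] += 0.3  # one shifted chain inflates rhat
        mine = split_rhat(draws)
        ref = az.rhat(az.convert_to_dataset(draws), method="split").x.to_numpy()
        np.testing.assert_allclose(mine, ref, rtol=1e-6)

    def test_seeded_reproducibility(self, rng):
        y, Z = self._simulate(rng, n_sites=60, n_occ=4)
        spec = OccupancyModelSpec(
            occ_predictors=("x0",), det_covariates=(), seed=9,
            iterations=100, warmup=100, thin=1,
        )
        a = fit_occupancy(spec, y, Z, None)
        b = fit_occupancy(spec, y, Z, None)
        np.testing.assert_array_equal(a.draws, b.draws)


class TestClassification:
    @pytest.mark.parametrize(
        "dirs, label",
        [
            (("-", "0"), "monotone decreasing"),
            (("+", "0"), "monotone increasing"),
            (("0", "-"), "hump-shaped"),
            (("+", "-"), "hump-shaped (high-skewed)"),
            (("-", "-"), "hump-shaped (low-skewed)"),
            (("0", "+"), "U-shaped"),
            (("0", "0"), "flat"),
        ],
    )
    def test_response_labels(self, dirs, label):
        assert classify_elevation_response(dirs) == label


def test_detection_design_alignment(small_survey):
    from trapcomm.events import build_detection_history, filter_independent_events

    cov, truth, records, deployments = small_survey
    ev = filter_independent_events(records, deployments)
    hist = build_detection_history(ev, deployments)
    ct = deployments.drop_duplicates("camera_id").set_index("camera_id")["camera_type"]
    D = detection_design(hist, cov, ct)
    assert D.shape == (len(hist.workday), hist.n_occasions, 3)
    surveyed = hist.workday.to_numpy() > 0
    w = D[:, :, 0][surveyed]
    assert abs(w.mean()) < 1e-9 and abs(w.std(ddof=1) - 1) < 1e-9
    assert set(np.unique(D[:, :, 2])) <= {0.0, 1.0}
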