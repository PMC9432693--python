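"""Royle-Nichols primitives, the marginal likelihood against enumeration,
and the community MCMC on small problems with independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from scipy.stats import poisson

from retdiv.capture_data import DetectionArray
from retdiv.occupancy import (
    MCMCConfig,
    RNModelSpec,
    cumulative_detection,
    fit_community_rn,
    occupancy_from_lambda,
    posterior_predictive_check,
    rn_detection_prob,
    rn_marginal_loglik,
)


def enumerate_loglik(history, lam, r, n_terms=400):
    """Independent brute-force enumeration over latent abundance."""
    y = np.asarray(history, dtype=float)
    obs = ~np.isnan(y)
    r = np.broadcast_to(np.asarray(r, dtype=float), y.shape)
    total = 0.0
    for n in range(n_terms):
        w = poisson.pmf(n, lam)
        for yk, rk in zip(y[obs], r[obs]):
            p = 1.0 - (1.0 - rk) ** n
            w *= p if yk > 0 else (1.0 - p)
        total += w
    return np.log(total) if total > 0 else -np.inf


class TestClosedForms:
    @pytest.mark.parametrize(
        "r,n,expected",
        [(0.5, 0, 0.0), (0.35, 1, 0.35), (0.35, 2, 0.5775), (1.0, 3, 1.0)],
    )
    def test_rn_detection_prob(self, r, n, expected):
        assert rn_detection_prob(r, n) == pytest.approx(expected)

    def test_rn_detection_prob_invalid(self):
        with pytest.raises(ValueError):
            rn_detection_prob(1.5, 1)
        with pytest.raises(ValueError):
            rn_detection_prob(0.5, -1)

    @pytest.mark.parametrize("lam,expected", [(0.0, 0.0), (1.0, 0.6321205588)])
    def test_occupancy_from_lambda(self, lam, expected):
        assert occupancy_from_lambda(lam) == pytest.approx(expected)

    def test_occupancy_limit_saturates(self):
        assert occupancy_from_lambda(50.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            occupancy_from_lambda(-0.1)

    @pytest.mark.parametrize(
        "p,k,expected", [(0.35, 4, 0.82149375), (1.0, 3, 1.0), (0.7, 0, 0.0)]
    )
    def test_cumulative_detection(self, p, k, expected):
        # note 1-(1-0.35)^4 = 0.8215: the closed form for the 4-night session
        assert cumulative_detection(p, k) == pytest.approx(expected)


class TestMarginalLoglik:
    def test_zero_lambda_cases(self):
        assert rn_marginal_loglik([0, 0, 0, 0], 0.0, 0.3) == 0.0
        assert rn_marginal_loglik([0, 1, 0, 0], 0.0, 0.3) == -np.inf

    def test_worked_example_matches_enumeration(self):
        ll = rn_marginal_loglik([1, 0, 0, 1], 0.8, 0.3, n_max=50)
        assert ll == pytest.approx(enumerate_loglik([1, 0, 0, 1], 0.8, 0.3), abs=1e-12)

    def test_missing_occasions_are_skipped(self):
        full = rn_marginal_loglik([1, 0, np.nan, np.nan], 1.2, 0.4)
        short = rn_marginal_loglik([1, 0], 1.2, 0.4)
        assert full == pytest.approx(short)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            rn_marginal_loglik([np.nan, np.nan], 1.0, 0.3)

    def test_per_occasion_detection_vector(self):
        r = [0.2, 0.5, 0.3, 0.4]
        ll = rn_marginal_loglik([1, 1, 0, 0], 0.9, r, n_max=80)
        assert ll == pytest.approx(enumerate_loglik([1, 1, 0, 0], 0.9, r), abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        lam=st.floats(min_value=0.01, max_value=5.0),
        r=st.floats(min_value=0.01, max_value=0.95),
        hist=st.lists(st.integers(0, 1), min_size=1, max_size=4),
    )
    def test_agrees_with_enumeration_everywhere(self, lam, r, hist):
        ll = rn_marginal_loglik(hist, lam, r, n_max=100)
        assert ll == pytest.approx(enumerate_loglik(hist, lam, r), abs=1e-10)

    def test_monotone_in_lambda_and_r_for_detection(self):
        # probability of a detection-bearing history rises with lambda and r
        lams = [0.2, 0.5, 1.0, 2.0]
        lls = [rn_marginal_loglik([1], lam, 0.3) for lam in lams]
        assert all(np.diff(lls) > 0)
        rs = [0.1, 0.3, 0.5, 0.7]
        lls = [rn_marginal_loglik([1], 1.0, r) for r in rs]
        assert all(np.diff(lls) > 0)


def build_detection_data(
    n_units: int,
    lam: float,
    r: float,
    seed: int,
    classes=("clearcut",),
    n_occasions: int = 4,
) -> DetectionArray:
    """Single-species RN data on a simple design, one unit per stand."""
    rng = np.random.default_rng(seed)
    rows = []
    y = np.zeros((1, n_units, n_occasions))
    for j in range(n_units):
        cls = classes[j % len(classes)]
        rows.append(
            {"unit": f"u{j}", "block": "B1", "stand": f"s{j}", "treatment": "RA",
             "subplot": f"u{j}", "cover_type": "clearcut", "patch_context": "none",
             "subplot_class": cls, "year": 1, "week": 1,
             "occasions_sampled": n_occasions}
        )
        n = rng.poisson(lam)
        p = 1.0 - (1.0 - r) ** n
        y[0, j] = (rng.random(n_occasions) < p).astype(float)
    return DetectionArray(y=y, species=("SP01",), units=pd.DataFrame(rows))


class TestCommunityFit:
    def test_single_species_matches_grid_search_ml(self):
        # profile ML over (lambda, r) by grid search as the independent oracle
        data = build_detection_data(n_units=150, lam=1.5, r=0.4, seed=5)
        spec = RNModelSpec(
            subplot_classes=("clearcut",),
            stand_random_intercept=False,
            mcmc=MCMCConfig(chains=2, iterations=800, warmup=800, seed=9),
        )
        fit = fit_community_rn(data, spec)
        sp = fit.stacked("species_params")
        lam_draws = np.exp(sp[:, 0, 0])

        # histories reduce to (detections d, occasions 4): profile over the
        # 5 distinct history types weighted by their unit counts
        d = np.nansum(data.y[0], axis=1).astype(int)
        counts = np.bincount(d, minlength=5)
        lam_grid = np.linspace(0.2, 4.0, 60)
        r_grid = np.linspace(0.05, 0.9, 60)
        best = (-np.inf, None)
        for lg in lam_grid:
            for rg in r_grid:
                ll = sum(
                    counts[k] * rn_marginal_loglik([1] * k + [0] * (4 - k), lg, rg, n_max=50)
                    for k in range(5)
                    if counts[k]
                )
                if ll > best[0]:
                    best = (ll, lg)
        assert abs(lam_draws.mean() - best[1]) <= 3 * lam_draws.std()

    def test_same_seed_reproduces_draws(self):
        data = build_detection_data(n_units=40, lam=1.0, r=0.35, seed=2)
        spec = RNModelSpec(
            subplot_classes=("clearcut",),
            mcmc=MCMCConfig(chains=2, iterations=100, warmup=100, seed=4),
        )
        f1 = fit_community_rn(data, spec)
        f2 = fit_community_rn(data, spec)
        for k in f1.draws:
            np.testing.assert_array_equal(f1.draws[k], f2.draws[k])

    def test_effects_for_unobserved_class_shrink_to_community_prior(self):
        # no rotation units in the data: the rotation effect must still be
        # estimable by hierarchical shrinkage, with posterior SD no wider
        # than the community-mean prior SD, and derived psi inside (0, 1)
        rng = np.random.default_rng(0)
        n_units, n_sp = 60, 6
        rows = []
        y = np.zeros((n_sp, n_units, 4))
        for j in range(n_units):
            cls = "clearcut" if j % 2 == 0 else "riparian_patch"
            rows.append(
                {"unit": f"u{j}", "stand": f"s{j // 4}", "subplot": f"u{j}",
                 "subplot_class": cls, "year": 1, "week": 1 + (j % 4),
                 "occasions_sampled": 4}
            )
            for i in range(n_sp):
                n = rng.poisson(0.8)
                p = 1.0 - 0.6**n
                y[i, j] = (rng.random(4) < p).astype(float)
        data = DetectionArray(
            y=y, species=tuple(f"S{i}" for i in range(n_sp)), units=pd.DataFrame(rows)
        )
        spec = RNModelSpec(
            subplot_classes=("clearcut", "riparian_patch", "rotation"),
            mcmc=MCMCConfig(chains=2, iterations=300, warmup=300, seed=1),
        )
        fit = fit_community_rn(data, spec)
        rot = fit.effects[fit.effects["class"] == "rotation"]
        assert (rot["sd"] <= spec.prior_mean_sd).all()
        psi = fit.psi
        assert ((psi["psi_mean"] > 0) & (psi["psi_mean"] < 1)).all()
        # credible intervals are ordered
        assert (fit.effects["ci_low"] <= fit.effects["mean"]).all()
        assert (fit.effects["mean"] <= fit.effects["ci_high"]).all()

    def test_empty_species_rejected(self, tiny_design, registry):
        from retdiv.capture_data import build_detection_histories
        from tests.conftest import make_table

        det = build_detection_histories(make_table([], registry), tiny_design)
        with pytest.raises(ValueError, match="no species"):
            fit_community_rn(det, RNModelSpec())


def test_hyperparameter_calibration_over_replicate_datasets():
    """Simulation-based calibration at reduced scale: across 20 synthetic
    experiments, the 95% credible interval of each community-mean
    hyperparameter covers its generating value in at least 16 of 20."""
    from retdiv.synthetic import SimulationConfig, simulate_experiment

    # generating community means (single species group, no arboreal split,
    # so species-level parameters are exactly iid Normal as the model assumes)
    targets = {
        "effect_upland_patch": 0.0,
        "effect_riparian_patch": 0.3,
        "detection_intercept": -0.7,
        "detection_week": 0.0,
    }
    hits = {k: 0 for k in targets}
    for rep in range(20):
        cfg = SimulationConfig(
            n_blocks=2, n_rotation_stands=0, include_rotation=False,
            n_species=8, n_arboreal=0, n_years=1, missingness=False,
            seed=600 + rep,
        )
        _, det, _ = simulate_experiment(cfg)
        spec = RNModelSpec(
            subplot_classes=("clearcut", "upland_patch", "riparian_patch"),
            mcmc=MCMCConfig(chains=2, iterations=300, warmup=300, seed=700 + rep),
        )
        fit = fit_community_rn(det, spec)
        for pname, truth in targets.items():
            p = fit.param_names.index(pname)
            mu_draws = fit.stacked("mu")[:, p]
            lo, hi = np.percentile(mu_draws, [2.5, 97.5])
            hits[pname] += lo <= truth <= hi
    for pname, n_cov in hits.items():
        assert n_cov >= 16, f"{pname}: community mean covered in {n_cov}/20"


class TestPosteriorPredictiveCheck:
    def test_zero_draw_posterior_rejected(self):
        data = build_detection_data(n_units=20, lam=1.0, r=0.3, seed=1)
        spec = RNModelSpec(
            subplot_classes=("clearcut",),
            mcmc=MCMCConfig(chains=2, iterations=50, warmup=50, seed=3),
        )
        fit = fit_community_rn(data, spec)
        for k in fit.draws:
            fit.draws[k] = fit.draws[k][:, :0]
        with pytest.raises(ValueError, match="draws"):
            posterior_predictive_check(fit)

    def test_misspecified_data_flagged(self):
        # data no (lambda, r) pair can produce: every unit detected on
        # exactly 2 of 4 nights, with none of the binomial dispersion the
        # model implies -> observed discrepancy far below replicated
        n_units = 120
        rows = []
        y = np.zeros((1, n_units, 4))
        for j in range(n_units):
            rows.append(
                {"unit": f"u{j}", "stand": f"s{j // 4}", "subplot": f"u{j}",
                 "subplot_class": "clearcut", "year": 1, "week": 1,
                 "occasions_sampled": 4}
            )
            y[0, j] = [1.0, 1.0, 0.0, 0.0]
        data = DetectionArray(y=y, species=("S0",), units=pd.DataFrame(rows))
        spec = RNModelSpec(
            subplot_classes=("clearcut",),
            stand_random_intercept=False,
            mcmc=MCMCConfig(chains=2, iterations=400, warmup=400, seed=5),
        )
        fit = fit_community_rn(data, spec)
        p_val = posterior_predictive_check(fit, seed=7)
        assert p_val < 0.05 or p_val > 0.95

    def test_sets_bayes_p_on_fit(self):
        data = build_detection_data(n_units=40, lam=1.2, r=0.4, seed=8)
        spec = RNModelSpec(
            subplot_classes=("clearcut",),
            mcmc=MCMCConfig(chains=2, iterations=200, warmup=200, seed=2),
        )
        fit = fit_community_rn(data, spec)
        p_val = posterior_predictive_check(fit, seed=2)
        assert fit.bayes_p == p_val
        assert 0.0 <= p_val <= 1.0
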