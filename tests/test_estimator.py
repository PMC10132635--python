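"""Model fitting, derived abundance, and information criteria."""

import numpy as np
import pytest
from sklearn.base import clone

from reefcmr import (
    RDModelSpec, RobustDesignModel, StudyDesign, fit_model,
    information_criterion, rd_log_likelihood,
)
from reefcmr.reference import closed_population_grid_mle
from reefcmr.specs import ParameterLayout


def _sig3(a, b):
    """Agreement to three significant figures."""
    if b == 0:
        return abs(a) < 1e-12
    scale = 10.0 ** (np.floor(np.log10(abs(b))) - 2)
    return abs(a - b) <= 0.5 * scale


def test_closed_model_matches_grid_search_oracle():
    """Single-primary, no-emigration fit == full-likelihood grid MLE.

    The conditional and full-likelihood estimators differ by O(1) animals,
    so the comparison runs at a sample size where that gap is far below
    three-significant-figure resolution.
    """
    rng = np.random.default_rng(42)
    d1 = StudyDesign.regular("2016-05", 1, 6)
    for _ in range(5):
        N = int(rng.integers(1500, 3000))
        p = rng.uniform(0.15, 0.4)
        data = (rng.random((N, 6)) < p).astype(np.int8)
        data = data[data.sum(axis=1) > 0]
        est = RobustDesignModel("constant", "none", "constant",
                                design=d1).fit(data)
        N_hat = est.abundance()["N_hat"][0]
        N_grid, p_grid = closed_population_grid_mle(data)
        assert _sig3(N_hat, N_grid)
        assert _sig3(est.params_.p[0, 0], p_grid)


def test_everyone_always_detected_hits_boundary_without_failure():
    d1 = StudyDesign.regular("2016-05", 1, 4)
    data = np.ones((25, 4), dtype=np.int8)
    est = RobustDesignModel("constant", "none", "constant", design=d1)
    est.fit(data)                      # must not raise
    assert est.params_.p[0, 0] > 0.999
    assert est.boundary_
    ab = est.abundance()
    assert ab["N_hat"][0] == pytest.approx(25, abs=1e-6)


def test_fit_recovers_interior_truth_roughly():
    """One large replicate: estimates land near the generating values."""
    from reefcmr import build_capture_matrix, make_scenario, simulate_population
    cfg = make_scenario("stable_homogeneous", seed=11)
    recs, truth = simulate_population(cfg)
    m = build_capture_matrix(recs, cfg.design(), cfg.site, cfg.species)
    est = RobustDesignModel("constant", "random", "constant").fit(m)
    assert est.converged_ and not est.boundary_
    assert est.params_.S[0] == pytest.approx(0.8, abs=0.08)
    assert est.params_.p[0, 0] == pytest.approx(0.25, abs=0.05)
    assert est.params_.gamma_prime[0] == pytest.approx(0.3, abs=0.12)
    ab = est.abundance()
    assert (ab["N_hat"] >= ab["n"]).all()
    assert (ab["se"] >= 0).all()


def _inject(est, design, spec, theta, n_t):
    """Set fitted state directly (for closed-form abundance checks)."""
    lay = ParameterLayout(spec, design)
    est.layout_ = lay
    est.design_ = design
    est.theta_ = np.asarray(theta, dtype=float)
    est.params_ = lay.expand(est.theta_)
    est.covariance_ = np.zeros((lay.n_par, lay.n_par))
    est.n_t_ = np.asarray(n_t)
    return est


def test_abundance_closed_form_single_class():
    """n=30 with two secondaries at p=0.5: p* = 0.75, N = 40."""
    d = StudyDesign.regular("2016-05", 1, 2)
    est = _inject(RobustDesignModel(), d, RDModelSpec("constant", "none",
                                                      "constant"),
                  [0.0], [30])
    ab = est.abundance()
    assert ab["p_star"][0] == pytest.approx(0.75, abs=1e-12)
    assert ab["N_hat"][0] == pytest.approx(40.0, abs=1e-9)


def test_abundance_perfect_detection():
    from scipy.special import logit
    d = StudyDesign.regular("2016-05", 1, 3)
    est = _inject(RobustDesignModel(), d,
                  RDModelSpec("constant", "none", "constant"),
                  [logit(1 - 1e-9)], [17])
    ab = est.abundance()
    assert ab["N_hat"][0] == pytest.approx(17.0, abs=1e-6)


def test_abundance_mixture_pools_pstar():
    """pi=0.5 with class p* of 0.75 and 0.19: pooled p* 0.47, N = 100."""
    from scipy.special import logit
    d = StudyDesign.regular("2016-05", 1, 2)
    # class monthly p of 0.5 and 0.1 give per-primary p* of 0.75 and 0.19
    est = _inject(RobustDesignModel(detection="mixture2"), d,
                  RDModelSpec("constant", "none", "mixture2"),
                  [logit(0.5), logit(0.1), logit(0.5)], [47])
    ab = est.abundance()
    assert ab["p_star"][0] == pytest.approx(0.47, abs=1e-12)
    assert ab["N_hat"][0] == pytest.approx(100.0, abs=1e-9)


def test_undefined_abundance_below_pstar_floor():
    from scipy.special import logit
    d = StudyDesign.regular("2016-05", 1, 1)
    est = _inject(RobustDesignModel(), d,
                  RDModelSpec("constant", "none", "constant"),
                  [logit(1e-9)], [3])
    ab = est.abundance()
    assert np.isnan(ab["N_hat"][0])


def test_information_criterion_formulas():
    class Fit:
        log_likelihood = -100.0
        n_par = 5
    aic, qaic = information_criterion(Fit())
    assert aic == 210.0 and qaic == 210.0          # c_hat = 1: QAIC == AIC
    aic, qaic = information_criterion(Fit(), c_hat=2.0)
    assert aic == 210.0 and qaic == 110.0
    with pytest.warns(UserWarning, match="clamped"):
        _, qaic = information_criterion(Fit(), c_hat=0.5)
    assert qaic == 210.0


def test_nested_models_never_fit_worse(rng):
    """Richer structures reach at least the nested maximum likelihood."""
    from reefcmr import build_capture_matrix, make_scenario, simulate_population
    cfg = make_scenario("stable_homogeneous", seed=2,
                        n_initial=60, recruitment=10, n_primary=4)
    recs, _ = simulate_population(cfg)
    m = build_capture_matrix(recs, cfg.design(), cfg.site, cfg.species)
    chains = [
        [("constant", "none", "constant"),
         ("constant", "random", "constant"),
         ("constant", "markovian", "constant"),
         ("seasonal", "markovian", "seasonal")],
        [("constant", "none", "constant"),
         ("constant", "none", "seasonal"),
         ("constant", "none", "seasonal_by_month")],
    ]
    for chain in chains:
        lls = []
        for s, g, p in chain:
            est = RobustDesignModel(s, g, p).fit(m)
            lls.append(est.loglik_)
        for a, b in zip(lls[:-1], lls[1:]):
            assert b >= a - 1e-4


def test_fit_model_wrapper_and_score():
    from reefcmr import build_capture_matrix, make_scenario, simulate_population
    cfg = make_scenario("stable_homogeneous", seed=3, n_initial=50,
                        recruitment=0, n_primary=3)
    recs, _ = simulate_population(cfg)
    m = build_capture_matrix(recs, cfg.design(), cfg.site, cfg.species)
    fit = fit_model(m, RDModelSpec("constant", "none", "constant"))
    assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * fit.n_par)
    assert fit.log_likelihood <= 0.0        # binary data
    assert fit.log_likelihood == pytest.approx(
        rd_log_likelihood(m, fit.estimates), rel=1e-9)


def test_sklearn_estimator_contract():
    est = RobustDesignModel(survival="seasonal", emigration="random",
                            detection="mixture2")
    params = est.get_params()
    assert params["survival"] == "seasonal"
    twin = clone(est)
    assert twin.get_params() == params
    est.set_params(detection="constant")
    assert est.spec.detection == "constant"
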