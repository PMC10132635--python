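"""Derived demographic statistics and the per-site analysis pipeline."""

import json
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from reefcmr import (
    average_annual_growth, build_capture_matrix, classify_stability,
    growth_cv, make_scenario, relative_change, run_site_analysis,
    simulate_population, write_report,
)
from reefcmr.demographics import report_to_dict, validate_report_dict


def test_relative_change_examples():
    assert relative_change([10.0, 20.0]).tolist() == [2.0]
    assert np.allclose(relative_change([50.0] * 5), 1.0)
    assert len(relative_change(np.arange(1, 9, dtype=float))) == 7


def test_relative_change_flags_undefined_pairs():
    r = relative_change([10.0, np.nan, 20.0])
    assert np.isnan(r[0]) and np.isnan(r[1])
    with pytest.raises(ValueError):
        relative_change([10.0])


def test_average_annual_growth_printed_formula():
    assert average_annual_growth(10, 20, 3.5) == pytest.approx(21.9, abs=0.05)
    assert average_annual_growth(123.4, 123.4, 2.0) == 0.0
    assert average_annual_growth(10, 5, 1.0) == pytest.approx(-50.0)
    with pytest.raises(ValueError):
        average_annual_growth(0.0, 5, 1.0)


def test_growth_cv_examples():
    assert growth_cv([0.1, 0.2, 0.3]) == pytest.approx(0.5, abs=1e-12)
    assert growth_cv([1.3, 1.3, 1.3, 1.3]) == 0.0
    with pytest.raises(ValueError):
        growth_cv([1.1])
    with pytest.raises(ValueError):
        growth_cv([1.0, -1.0])


@given(st.lists(st.floats(10.0, 1e4), min_size=3, max_size=10),
       st.floats(0.5, 8.0))
def test_growth_consistent_with_compounded_ratios(n_hat, t_years):
    """Compounding the interval ratios reproduces final/initial, and
    annualizing that product reproduces the growth figure."""
    n = np.asarray(n_hat)
    ratios = relative_change(n)
    assert np.prod(ratios) == pytest.approx(n[-1] / n[0], rel=1e-9)
    g = average_annual_growth(n[0], n[-1], t_years)
    implied = (np.prod(ratios) ** (1 / t_years) - 1) * 100
    assert g == pytest.approx(implied, rel=1e-9, abs=1e-9)


@given(st.lists(st.floats(5.0, 500.0), min_size=3, max_size=9),
       st.floats(0.1, 50.0))
def test_growth_cv_is_scale_invariant(n_hat, scale):
    n = np.asarray(n_hat)
    try:
        base = growth_cv(relative_change(n))
    except ValueError:
        return
    assert growth_cv(relative_change(n * scale)) == pytest.approx(
        base, rel=1e-9, abs=1e-12)


def test_growing_recruitment_yields_positive_growth():
    """Recruitment far above mortality gives positive estimated growth."""
    from reefcmr import RobustDesignModel
    positive = 0
    n_rep = 12
    for seed in range(n_rep):
        cfg = make_scenario("growing_recruitment", seed=seed)
        recs, _ = simulate_population(cfg)
        m = build_capture_matrix(recs, cfg.design(), cfg.site, cfg.species)
        est = RobustDesignModel("constant", "none", "constant").fit(m)
        n_hat = est.abundance()["N_hat"].to_numpy()
        t = cfg.n_primary * 0.5 - 0.5
        positive += average_annual_growth(n_hat[0], n_hat[-1], t) > 0
    assert positive == n_rep


def test_classification_quadrants():
    assert classify_stability(5.0, 0.1, 0.3) == "increasing-stable"
    assert classify_stability(5.0, 0.5, 0.3) == "increasing-unstable"
    assert classify_stability(-2.0, 0.1, 0.3) == "decreasing-stable"
    assert classify_stability(-2.0, 0.5, 0.3) == "decreasing-unstable"


@pytest.fixture(scope="module")
def site_report():
    cfg = make_scenario("stable_homogeneous", seed=9, n_initial=120,
                        recruitment=20, n_primary=5)
    recs, _ = simulate_population(cfg)
    m = build_capture_matrix(recs, cfg.design(), cfg.site, cfg.species)
    specs = None  # full 30-model suite
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_site_analysis(m)


def test_site_analysis_structure(site_report):
    r = site_report
    assert len(r.table) == 30
    assert r.criterion in ("AIC", "QAIC")
    key = "qaic" if r.criterion == "QAIC" else "aic"
    converged = r.table[r.table.converged]
    assert r.best_spec is not None
    best_row = converged.loc[converged[key].idxmin()]
    # ties broken toward fewer parameters: the chosen model matches the
    # minimal criterion value and no model with that value has fewer params
    at_min = converged[np.isclose(converged[key], best_row[key])]
    chosen = converged[converged.model == r.best_spec.name].iloc[0]
    assert chosen[key] == pytest.approx(best_row[key])
    assert chosen.n_par == at_min.n_par.min()


def test_site_analysis_ranking_switches_with_gof(site_report):
    assert site_report.criterion == \
        ("QAIC" if site_report.gof.failed else "AIC")


def test_annual_survival_compounds_six_month_estimate(site_report):
    est6 = site_report.best_fit.conf_int.loc["S", "estimate"] \
        if "S" in site_report.best_fit.conf_int.index else None
    if est6 is not None:
        assert site_report.annual_survival[0] == pytest.approx(est6 ** 2)
    # worked numeric example: a constant six-month survival of 0.9
    # compounds to 0.81 annually
    assert 0.9 ** 2 == pytest.approx(0.81)


def test_summary_counts(site_report):
    s = site_report.summary
    T = site_report.abundance.shape[0]
    assert len(s.relative_change) == T - 1
    assert s.average_annual_growth > -100.0
    assert s.cv >= 0.0


def test_report_bundle_and_schema(tmp_path, site_report):
    summary = write_report([site_report], tmp_path / "out", figures=False)
    assert len(summary) == 1
    d = report_to_dict(site_report)
    validate_report_dict(d)             # shipped schema accepts real output
    bad = dict(d)
    bad.pop("site")
    with pytest.raises(ValueError, match="missing required key"):
        validate_report_dict(bad)
    # determinism: identical inputs give byte-identical tables
    write_report([site_report], tmp_path / "a", figures=False)
    write_report([site_report], tmp_path / "b", figures=False)
    for name in ("summary.csv", "SIM.Reef_hawksbill.json"):
        assert (tmp_path / "a" / name).read_bytes() == \
            (tmp_path / "b" / name).read_bytes()
    parsed = json.loads((tmp_path / "a" / "SIM.Reef_hawksbill.json").read_text())
    assert parsed["best_model"] == site_report.best_spec.name


def test_growth_vs_cv_table_one_row_per_site(tmp_path, site_report):
    summary = write_report([site_report], tmp_path / "o", figures=True)
    assert set(summary.columns) >= {"site", "species", "best_model", "cv",
                                    "average_annual_growth_pct",
                                    "classification"}
    assert (tmp_path / "o" / "growth_vs_cv.png").exists()
    assert (tmp_path / "o" / "abundance_series.png").exists()
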