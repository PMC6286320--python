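"""Joint model fitting and the likelihood-ratio cascade."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import erf

import bdchrono as bc
from bdchrono.modeltest import ExperimentConfig, lrt_cascade, model_test


def chi2_1_quantile(p):
    """Independent oracle: chi2(1) CDF is erf(sqrt(x/2))."""
    return brentq(lambda x: erf(np.sqrt(x / 2)) - p, 1e-12, 100.0)


def test_equal_vs_compatible_threshold_is_mixture_rule():
    """Reject equal rates iff LR > chi2_1 quantile at 1 - 2 alpha:
    2.71 at alpha = 0.05 (the boundary-mixture construction)."""
    out = lrt_cascade(0.0, 2.70 / 2, 0.0, alpha=0.05)
    assert not out["rejected"]["equal_vs_compatible"]
    out = lrt_cascade(0.0, 2.72 / 2, 0.0, alpha=0.05)
    assert out["rejected"]["equal_vs_compatible"]
    assert chi2_1_quantile(0.90) == pytest.approx(2.71, abs=0.005)


def test_thresholds_at_stricter_level_match_quantile_oracle():
    thr = chi2_1_quantile(0.98)  # alpha = 0.01 -> tail below 2 alpha = 0.02
    out = lrt_cascade(0.0, (thr - 0.01) / 2, 0.0, alpha=0.01)
    assert not out["rejected"]["equal_vs_compatible"]
    out = lrt_cascade(0.0, (thr + 0.01) / 2, 0.0, alpha=0.01)
    assert out["rejected"]["equal_vs_compatible"]
    assert thr == pytest.approx(5.412, abs=0.005)


def test_equal_vs_incompatible_uses_two_degrees():
    # chi2(2) CDF is 1 - exp(-x/2): threshold -2 ln(alpha)
    thr = -2 * np.log(0.05)
    out = lrt_cascade(0.0, 0.0, (thr - 0.01) / 2, alpha=0.05)
    assert not out["rejected"]["equal_vs_incompatible"]
    out = lrt_cascade(0.0, 0.0, (thr + 0.01) / 2, alpha=0.05)
    assert out["rejected"]["equal_vs_incompatible"]


def test_cascade_selects_simplest_surviving_model():
    assert lrt_cascade(0.0, 0.0, 0.0, 0.05)["selected"] == "equal"
    # equal rejected, compatible survives
    out = lrt_cascade(0.0, 10.0, 10.5, 0.05)
    assert out["selected"] == "compatible"
    # everything rejected in turn
    out = lrt_cascade(0.0, 10.0, 30.0, 0.05)
    assert out["selected"] == "incompatible"
    # equal rejected by the boundary test, compatible survives vs incompatible
    out = lrt_cascade(0.0, 2.2, 2.9, 0.05)
    assert out["selected"] == "compatible"
    # equal survives the mixture test but fails the 2-df test -> compatible
    out = lrt_cascade(0.0, 1.0, 4.0, 0.05)
    assert out["rejected"]["equal_vs_incompatible"]
    assert not out["rejected"]["equal_vs_compatible"]
    assert out["selected"] != "equal"


def test_incompatible_fit_range_component_is_closed_form(compatible_dataset):
    phylo, stats, _ = compatible_dataset
    fit = bc.joint_ml_fit(phylo, stats, "incompatible", seed=1)
    B, D, S = stats
    assert fit.rates.lambda_star == pytest.approx(B / S, rel=1e-9)
    assert fit.rates.mu_star == pytest.approx(D / S, rel=1e-9)


def test_nesting_inequality(compatible_dataset, budding_dataset):
    for phylo, stats in [compatible_dataset[:2], budding_dataset]:
        report = model_test(phylo, stats, seed=3)
        ll_eq = report.fits["equal"].loglik
        ll_co = report.fits["compatible"].loglik
        ll_in = report.fits["incompatible"].loglik
        assert ll_in >= ll_co - 1e-4
        assert ll_co >= ll_eq - 1e-4


def test_budding_truth_hits_compatible_boundary(budding_dataset):
    """Data generated under pure budding: the compatible fit collapses
    to the equal fit (c -> 0)."""
    phylo, stats = budding_dataset
    report = model_test(phylo, stats, seed=4)
    assert report.fits["compatible"].loglik == pytest.approx(
        max(report.fits["equal"].loglik, report.fits["compatible"].loglik),
        abs=0.5,
    )
    assert report.selected(0.95) in ("equal", "compatible")


def test_compatible_truth_detected(strong_compatible_dataset):
    """Data generated at the worked quadruple (0.2, 0.16, 0.5, 0.46):
    the cascade picks the compatible model and recovers the rates."""
    phylo, stats = strong_compatible_dataset
    truth = bc.fossil_rates_from_bdc(0.2, 0.16, 0.7, 0.16)
    report = model_test(phylo, stats, seed=5)
    assert report.selected(0.95) == "compatible"
    assert report.selected(0.99) == "compatible"
    r = report.fits["compatible"].rates
    assert r.lambda_star == pytest.approx(truth.lambda_star, abs=0.05)
    assert r.mu_star == pytest.approx(truth.mu_star, abs=0.05)
    # report carries the BDC summaries
    d = report.to_dict()
    assert "lambda_a_interval" in d and "mode_prevalence" in d
    lo, hi = d["lambda_a_interval"]
    assert lo <= 0.16 <= hi  # the generating anagenesis rate is bracketed


def test_selection_invariant_to_time_rescaling(compatible_dataset):
    """Rescaling all ages (rates rescale reciprocally) leaves LRs and
    the selected model unchanged."""
    phylo, stats, _ = compatible_dataset
    s = 3.0
    phylo2 = bc.PhyloData(
        n=phylo.n,
        branching_ages=phylo.branching_ages * s,
        origin_age=phylo.origin_age * s,
        rho=phylo.rho,
    )
    B, D, S = stats
    r1 = model_test(phylo, stats, seed=6)
    r2 = model_test(phylo2, (B, D, S * s), seed=6)
    assert r2.selected(0.95) == r1.selected(0.95)
    lr1 = r1.cascades[0.95]["LR"]["equal_vs_compatible"]
    lr2 = r2.cascades[0.95]["LR"]["equal_vs_compatible"]
    assert lr2 == pytest.approx(lr1, abs=0.05)
    assert r2.fits["compatible"].rates.lambda_ == pytest.approx(
        r1.fits["compatible"].rates.lambda_ / s, rel=0.02
    )


def test_selection_experiment_reproducible_and_consistent():
    cfg = ExperimentConfig(schedule=bc.RateSchedule.constant(0.3, 0.1),
                           n_extant=50)
    t1 = bc.selection_experiment(cfg, n_reps=6, seed=9)
    t2 = bc.selection_experiment(cfg, n_reps=6, seed=9)
    assert t1.equals(t2)
    for _, row in t1.iterrows():
        assert row[["equal", "compatible", "incompatible"]].sum() == pytest.approx(100.0)
        assert row["n_ok"] == 6


def test_independent_generators_yield_incompatible():
    """Trees and ranges from unrelated clades with random rates are
    mostly flagged incompatible."""
    cfg = ExperimentConfig(schedule=bc.RateSchedule.constant(0.3, 0.1),
                           n_extant=60, independent=True)
    tab = bc.selection_experiment(cfg, n_reps=12, seed=10)
    assert tab.loc[0.95, "incompatible"] > 50.0
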