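"""Unit tests for the platform-trial engine: bins, priors, model, decisions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit, logit

from ispy_engine import (DriftPath, PatientRecord, PosteriorDraws,
                         SamplerConfig, SignatureDef, TimeMachinePrior,
                         TrialConfig, TrialScenario, assign_time_bin,
                         build_model, drift_log_prior, evaluate_arm_status,
                         impute_endpoint, linear_ramp, phase3_success_prob,
                         predictive_prob_phase3, prepare_analysis_set,
                         prob_superior, randomization_probabilities,
                         sample_posterior, subtype_rate)
from ispy_engine.trial_engine import HER2_NEG, HER2_POS

from conftest import trial_records


# ---------------------------------------------------------------------------
# time bins


@pytest.mark.parametrize("days_back,expected", [
    (750, 9),   # randomized 750 days before the analysis
    (91, 2),    # first day of the second bin
    (0, 1),     # randomized on the analysis day
    (90, 1),    # last day of the most recent bin
    (180, 2),
    (181, 3),
])
def test_assign_time_bin(days_back, expected):
    assert assign_time_bin(1000 - days_back, 1000) == expected


def test_assign_time_bin_rejects_future_records():
    with pytest.raises(ValueError, match="future-dated"):
        assign_time_bin(1001, 1000)


@given(day=st.integers(0, 5000), analysis=st.integers(0, 5000),
       width=st.integers(1, 365))
def test_assign_time_bin_monotone_and_positive(day, analysis, width):
    if day > analysis:
        return
    t = assign_time_bin(day, analysis, width)
    assert t >= 1
    # randomizing later (closer to analysis) never lands in an older bin
    t_later = assign_time_bin(min(day + 30, analysis), analysis, width)
    assert t_later <= t


# ---------------------------------------------------------------------------
# drift prior


def test_drift_prior_zero_path_is_modal():
    prior = TimeMachinePrior()
    tau = 0.01
    base = drift_log_prior(DriftPath(HER2_NEG, np.zeros(8), tau), prior)
    for k in range(4, 8):
        bumped = np.zeros(8)
        bumped[k] = 0.05
        assert drift_log_prior(DriftPath(HER2_NEG, bumped, tau), prior) < base


def test_drift_prior_frozen_bin_violation_is_minus_inf():
    prior = TimeMachinePrior()
    delta = np.array([0.2, 0.0, 0.0, 0.0, 0.0, 0.0])
    assert drift_log_prior(DriftPath(HER2_NEG, delta, 0.01), prior) == -np.inf


def test_drift_prior_matches_scalar_density_oracle():
    # independently sum the normal / inverse-gamma terms for a concrete path
    prior = TimeMachinePrior()
    delta = np.array([0.0, 0.0, 0.0, 0.0, 0.1, 0.1, 0.3])
    tau_sq = 0.01
    expected = (
        stats.norm.logpdf(0.1, 0.0, math.sqrt(0.001))        # delta(5)
        + stats.norm.logpdf(0.1 - 0.1, 0.0, math.sqrt(0.001))  # slope
        + stats.norm.logpdf(0.3 - 0.2 + 0.1, 0.0, math.sqrt(tau_sq))
        + stats.invgamma.logpdf(tau_sq, a=1.0, scale=0.001)
    )
    got = drift_log_prior(DriftPath(HER2_NEG, delta, tau_sq), prior)
    assert got == pytest.approx(expected, abs=1e-12)


def test_drift_prior_rejects_nonpositive_tau():
    with pytest.raises(ValueError):
        DriftPath(HER2_NEG, np.zeros(6), -1.0)


# ---------------------------------------------------------------------------
# endpoint imputation


@pytest.mark.parametrize("pcr,deviation,expected", [
    (1, "none", 1),
    (0, "none", 0),
    (None, "withdrew", 0),
    (None, "no_surgery", 0),
    (None, "nonprotocol_therapy", 0),
    (1, "withdrew", 1),  # observed outcome wins
])
def test_impute_endpoint(pcr, deviation, expected):
    rec = PatientRecord("p", "pgm", True, False, 0.0, 10, pcr, deviation)
    assert impute_endpoint(rec) == expected


def test_unevaluable_patient_excluded_with_warning():
    good = PatientRecord("a", "pgm", True, False, 0.0, 10, 1)
    bad = PatientRecord("b", "pgm", True, False, 0.0, 10, None, "none")
    with pytest.warns(UserWarning, match="unevaluable"):
        kept = prepare_analysis_set([good, bad])
    assert [p.patient_id for p in kept] == ["a"]


# ---------------------------------------------------------------------------
# model construction


def _mk_patient(pid, arm, hr, her2, day, pcr=0, mp=0.0):
    return PatientRecord(pid, arm, hr, her2, mp, day, pcr)


def test_model_collapses_when_all_patients_in_frozen_bins():
    pats = [_mk_patient(f"p{i}", "pgm" if i % 2 else "control",
                        i % 3 == 0, False, 1800 - (i * 10) % 350, pcr=i % 2)
            for i in range(40)]
    model = build_model(pats, ["control", "pgm"], TimeMachinePrior(), 1800)
    assert not model.has_drift
    assert model.drift_bins[HER2_NEG] == []


def test_drift_offsets_assigned_per_her2_stratum():
    pats = [_mk_patient(f"c{i}", "control", False, False, 1750, pcr=i % 2)
            for i in range(6)]
    pats.append(_mk_patient("neg9", "pgm", False, False, 1800 - 750, 1))
    pats.append(_mk_patient("pos9", "pgm", False, True, 1800 - 750, 1))
    model = build_model(pats, ["control", "pgm"], TimeMachinePrior(), 1800)
    assert model.drift_bins[HER2_NEG] == list(range(5, 10))
    assert model.drift_bins[HER2_POS] == list(range(5, 10))
    row_neg = next(i for i, p in enumerate(pats) if p.patient_id == "neg9")
    row_pos = next(i for i, p in enumerate(pats) if p.patient_id == "pos9")
    assert row_neg in model.drift_rows[HER2_NEG][-1]   # delta-(9)
    assert row_pos in model.drift_rows[HER2_POS][-1]   # delta+(9)


def test_empty_arm_excluded_and_missing_control_fatal():
    pats = [_mk_patient(f"p{i}", "control", True, False, 1790, pcr=i % 2)
            for i in range(10)]
    with pytest.warns(UserWarning, match="no patients"):
        model = build_model(pats, ["control", "ghost"], TimeMachinePrior(),
                            1800)
    assert model.arm_cols == {}
    with pytest.raises(ValueError, match="control"):
        build_model([_mk_patient("q", "pgm", True, False, 1790, 1)],
                    ["control", "pgm"], TimeMachinePrior(), 1800)


# ---------------------------------------------------------------------------
# sampling


def test_sampler_is_deterministic_given_seed():
    pats = trial_records(TrialScenario(
        seed=5, arms=(("control", 60, 1400, 1800, 0.0),
                      ("pgm", 60, 1400, 1800, 0.5))))
    model = build_model(pats, ["control", "pgm"], TimeMachinePrior(), 1800)
    cfg = SamplerConfig(seed=3, chains=2, warmup=100, draws=150)
    a = sample_posterior(model, cfg)
    b = sample_posterior(model, cfg)
    assert np.array_equal(a.coefficients, b.coefficients)
    assert all(np.array_equal(a.tau_sq[s], b.tau_sq[s]) for s in a.tau_sq)


def test_degenerate_all_nonpcr_outcome_is_stable():
    pats = [_mk_patient(f"p{i}", "pgm" if i % 2 else "control",
                        i % 3 == 0, False, 1800 - (i * 37) % 1500, pcr=0)
            for i in range(80)]
    model = build_model(pats, ["control", "pgm"], TimeMachinePrior(), 1800)
    post = sample_posterior(model, SamplerConfig(seed=1, chains=2,
                                                 warmup=200, draws=300))
    sig = SignatureDef("all HER2-", her2=False)
    rates = subtype_rate(post, "control", sig)
    assert np.all(np.isfinite(rates))
    assert rates.mean() < 0.10


def test_arm_effect_recovery_without_drift(recovery_effect=1.0):
    sc = TrialScenario(
        seed=11,
        arms=(("control", 200, 1500, 1800, 0.0),
              ("pgm", 200, 1500, 1800, recovery_effect)),
        deviation_frac=0.0)
    # tuple arms -> ArmSpec coercion happens in trial_records helper
    pats = trial_records(sc)
    model = build_model(pats, ["control", "pgm"], TimeMachinePrior(), 1800)
    post = sample_posterior(model, SamplerConfig(seed=2, chains=2,
                                                 warmup=300, draws=600))
    j = post.coef_names.index("arm[pgm]")
    arm_draws = post.coefficients[:, j]
    z = abs(arm_draws.mean() - recovery_effect) / arm_draws.std()
    assert z < 3.0


def test_drift_posterior_shrinks_under_concentrated_tau_prior():
    # a step drift in old bins; concentrating tau^2 near 0 must shrink the
    # posterior spread of the second differences of delta
    drift = {HER2_NEG: linear_ramp(16, 0.25, start_bin=6)}
    sc = TrialScenario(seed=9,
                       arms=(("control", 300, 0, 1800, 0.0),
                             ("pgm", 100, 1400, 1800, 0.0)),
                       drift=drift, deviation_frac=0.0)
    pats = trial_records(sc)

    def second_diff_var(alpha):
        prior = TimeMachinePrior(alpha=alpha)
        model = build_model(pats, ["control", "pgm"], prior, 1800)
        post = sample_posterior(model, SamplerConfig(seed=4, chains=2,
                                                     warmup=300, draws=500))
        d = post.drift[HER2_NEG]
        d2 = d[:, 2:] - 2 * d[:, 1:-1] + d[:, :-2]
        return d2.var(axis=0).mean()

    assert second_diff_var(alpha=200.0) < second_diff_var(alpha=1.0)


# ---------------------------------------------------------------------------
# derived rates and decisions (toy posteriors)


def _toy_posterior(coeffs, pats, arms=("control", "pgm")):
    model = build_model(pats, list(arms), TimeMachinePrior(), 1800)
    return PosteriorDraws(
        coefficients=np.asarray(coeffs, dtype=float),
        coef_names=model.coef_names, drift={}, drift_bins={}, tau_sq={},
        model=model), model


def test_subtype_rate_matches_hand_computed_mixture():
    # two covariate profiles (HR+ and HR-), equal weights
    pats = [_mk_patient("a", "control", True, False, 1790, 0),
            _mk_patient("b", "control", False, False, 1790, 1),
            _mk_patient("c", "pgm", True, False, 1790, 0),
            _mk_patient("d", "pgm", False, False, 1790, 1)]
    # columns: intercept, hr, arm[pgm]
    coeffs = [[-1.0, 0.5, 0.3], [-2.0, 1.0, 0.0], [0.0, -0.5, 1.0]]
    post, model = _toy_posterior(coeffs, pats)
    assert model.coef_names == ["intercept", "hr", "arm[pgm]"]
    sig = SignatureDef("all HER2-", her2=False)
    got = subtype_rate(post, "pgm", sig)
    expected = [0.5 * (expit(b0 + b1 + ba) + expit(b0 + ba))
                for b0, b1, ba in coeffs]
    np.testing.assert_allclose(got, expected, atol=1e-12)
    got_ctrl = subtype_rate(post, "control", sig)
    expected_ctrl = [0.5 * (expit(b0 + b1) + expit(b0))
                     for b0, b1, _ in coeffs]
    np.testing.assert_allclose(got_ctrl, expected_ctrl, atol=1e-12)


def test_subtype_rate_mixture_mean_of_two_profiles():
    # a single draw in which the per-profile control rates are 0.1 and 0.3,
    # profiles equally frequent among the observed patients
    pats = [_mk_patient("a", "control", True, False, 1790, 0),
            _mk_patient("b", "control", False, False, 1790, 1),
            _mk_patient("c", "pgm", True, False, 1790, 1),
            _mk_patient("d", "pgm", False, False, 1790, 1)]
    b0 = logit(0.1)
    b1 = logit(0.3) - logit(0.1)
    post, _ = _toy_posterior([[b0, b1, 0.0]], pats)
    sig = SignatureDef("all HER2-", her2=False)
    assert subtype_rate(post, "control", sig)[0] == pytest.approx(0.2)


def test_subtype_rate_errors_on_empty_stratum():
    pats = [_mk_patient("a", "control", True, False, 1790, 0),
            _mk_patient("c", "pgm", False, False, 1790, 1)]
    post, _ = _toy_posterior([[0.0, 0.0, 0.0]], pats)
    with pytest.raises(ValueError, match="no patients match"):
        subtype_rate(post, "pgm", SignatureDef("HER2+", her2=True))


def test_prob_superior_counts_paired_draws():
    pats = [_mk_patient("a", "control", False, False, 1790, 0),
            _mk_patient("c", "pgm", False, False, 1790, 1)]
    # single profile; control rate fixed at 0.25, arm rates .3, .2, .4
    b0 = logit(0.25)
    arms = [logit(0.3) - b0, logit(0.2) - b0, logit(0.4) - b0]
    post, _ = _toy_posterior([[b0, a] for a in arms], pats)
    sig = SignatureDef("all HER2-", her2=False)
    assert prob_superior(post, "pgm", sig) == pytest.approx(2 / 3)


def test_prob_superior_extremes(default_posterior):
    sig = SignatureDef("all HER2-", her2=False)
    p = prob_superior(default_posterior, "pgm", sig)
    assert 0.0 <= p <= 1.0


# ---------------------------------------------------------------------------
# phase-3 predictive probability


def _brute_force_phase3(p_a, p_c, n, alpha):
    z_crit = stats.norm.ppf(1 - alpha)
    total = 0.0
    for xa in range(n + 1):
        for xc in range(n + 1):
            pbar = (xa + xc) / (2 * n)
            var = pbar * (1 - pbar) * 2 / n
            if var <= 0:
                continue
            z = (xa / n - xc / n) / math.sqrt(var)
            if z > z_crit:
                total += (stats.binom.pmf(xa, n, p_a)
                          * stats.binom.pmf(xc, n, p_c))
    return total


@pytest.mark.parametrize("pa,pc", [(0.2, 0.2), (0.3, 0.15), (0.9, 0.1)])
def test_phase3_success_prob_matches_enumeration_oracle(pa, pc):
    got = phase3_success_prob(pa, pc, n_per_arm=150, alpha=0.025)[0]
    assert got == pytest.approx(_brute_force_phase3(pa, pc, 150, 0.025),
                                abs=1e-10)


def test_phase3_point_mass_null_is_test_size():
    # at p_arm = p_ctrl the predictive probability is the test's actual size
    got = phase3_success_prob(0.2, 0.2, n_per_arm=150, alpha=0.025)[0]
    assert got == pytest.approx(0.025, abs=0.01)


def test_phase3_overwhelming_effect():
    assert phase3_success_prob(0.9, 0.1, 150, 0.025)[0] > 0.9999


def test_predictive_prob_phase3_from_point_mass_posterior():
    pats = [_mk_patient("a", "control", False, False, 1790, 0),
            _mk_patient("c", "pgm", False, False, 1790, 1)]
    b0 = logit(0.2)
    post, _ = _toy_posterior([[b0, 0.0]], pats)
    cfg = TrialConfig()
    sig = SignatureDef("all HER2-", her2=False)
    got = predictive_prob_phase3(post, "pgm", sig, cfg)
    assert got == pytest.approx(_brute_force_phase3(0.2, 0.2, 150, 0.025),
                                abs=1e-9)


# ---------------------------------------------------------------------------
# graduation / futility / randomization


@pytest.mark.parametrize("pps,expected", [
    ({"a": 0.33, "b": 0.21, "c": 0.51}, "continue"),
    ({"a": 0.05, "b": 0.08, "c": 0.02}, "futility_stop"),
    ({"a": 0.86, "b": 0.10, "c": 0.10}, "graduate"),
    ({"a": 0.85}, "graduate"),
    ({"a": 0.0999}, "futility_stop"),
])
def test_evaluate_arm_status(pps, expected):
    assert evaluate_arm_status(pps, TrialConfig()).status == expected


def test_evaluate_arm_status_max_accrual():
    d = evaluate_arm_status({"a": 0.5}, TrialConfig(), accrual_reached=True)
    assert d.status == "max_accrual_stop"
    with pytest.raises(ValueError):
        evaluate_arm_status({}, TrialConfig())


def test_randomization_single_arm_forced_split(default_posterior):
    probs = randomization_probabilities(
        default_posterior, SignatureDef("all HER2-", her2=False),
        ["control", "pgm"], TrialConfig())
    assert probs == {"control": 0.20, "pgm": pytest.approx(0.80)}


def test_randomization_best_arm_counting():
    pats = [_mk_patient("a", "control", False, False, 1790, 0),
            _mk_patient("b", "armA", False, False, 1790, 1),
            _mk_patient("c", "armB", False, False, 1790, 1)]
    # columns: intercept, arm[armA], arm[armB]; A best in 3 of 4 draws
    coeffs = [[0.0, 1.0, 0.5], [0.0, 0.8, 0.2], [0.0, 0.3, 0.9],
              [0.0, 0.6, 0.1]]
    post, model = _toy_posterior(coeffs, pats, arms=["control", "armA",
                                                     "armB"])
    probs = randomization_probabilities(
        post, SignatureDef("all HER2-", her2=False),
        ["control", "armA", "armB"], TrialConfig())
    assert probs["control"] == 0.20
    assert probs["armA"] == pytest.approx(0.8 * 0.75)
    assert probs["armB"] == pytest.approx(0.8 * 0.25)
    assert sum(probs.values()) == pytest.approx(1.0)


def test_randomization_requires_open_arm(default_posterior):
    with pytest.raises(ValueError, match="no open experimental arms"):
        randomization_probabilities(
            default_posterior, SignatureDef("all HER2-", her2=False),
            ["control"], TrialConfig())
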