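"""GP model selection: BIC arithmetic, fits, LR test and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chromdyn.dynamics import (
    GPFit,
    bic,
    classify_dynamics,
    classify_profiles,
    fit_gp_models,
)
from chromdyn._normalize import transform_times


def test_bic_worked_values():
    assert bic(3, 12, -10.0) == pytest.approx(3 * np.log(12) + 20, abs=1e-10)
    assert bic(1, 12, -15.0) == pytest.approx(np.log(12) + 30, abs=1e-10)
    assert bic(0, 5, 0.0) == 0.0
    with pytest.raises(ValueError):
        bic(3, 0, -10.0)
    with pytest.raises(ValueError):
        bic(-1, 5, 0.0)


def test_constant_profile_prefers_static(times):
    fd, fs = fit_gp_models((times, np.full((2, 6), 50.0)))
    assert fs.bic < fd.bic
    # static is a boundary case of dynamic: likelihood can only improve
    assert fd.log_marginal_likelihood >= fs.log_marginal_likelihood - 1e-6


def test_strong_monotone_profile_prefers_dynamic(times):
    rng = np.random.default_rng(3)
    z = np.tile(np.arange(6.0), (2, 1)) + rng.normal(0, 0.1, (2, 6))
    fd, fs = fit_gp_models((times, z - z.mean()), normalizer=None)
    assert fd.bic < fs.bic
    call = classify_dynamics(fd, fs)
    assert call.dynamic_by_bic and call.dynamic_by_lr


def _grid_oracle_lml(y, t, n_grid=20):
    """Independent brute-force grid search over the hyperparameter box."""
    d2 = (t[:, None] - t[None, :]) ** 2
    span = t.max() - t.min()
    best = -np.inf
    for ell in np.geomspace(0.1 * span, 10 * span, n_grid):
        lam, Q = np.linalg.eigh(np.exp(-0.5 * d2 / ell**2))
        w = (Q.T @ y) ** 2
        for sf2 in np.geomspace(1e-4, 1e4, n_grid):
            for sn2 in np.geomspace(1e-4, 1e4, n_grid):
                e = sf2 * lam + sn2
                lml = (
                    -0.5 * np.sum(w / e)
                    - 0.5 * np.sum(np.log(e))
                    - len(y) / 2 * np.log(2 * np.pi)
                )
                best = max(best, lml)
    return best


def test_optimizer_matches_grid_oracle_on_example(times):
    rng = np.random.default_rng(3)
    z = np.tile(np.arange(6.0), (2, 1)) + rng.normal(0, 0.1, (2, 6))
    z = z - z.mean()
    fd, _ = fit_gp_models((times, z), normalizer=None)
    t = np.tile(transform_times(times), 2)
    assert fd.log_marginal_likelihood >= _grid_oracle_lml(z.ravel(), t) - 1e-3


def test_nesting_holds_on_random_profiles(times):
    rng = np.random.default_rng(12)
    for _ in range(10):
        z = rng.normal(0, rng.uniform(0.05, 2.0), (2, 6))
        fd, fs = fit_gp_models((times, z - z.mean()), normalizer=None)
        assert fd.log_marginal_likelihood >= fs.log_marginal_likelihood - 1e-6


def _fit(ll, model="dynamic", n=12):
    k = 3 if model == "dynamic" else 1
    return GPFit(model, ll, {}, k=k, n=n)


def test_classify_equal_likelihoods_gives_null_call():
    call = classify_dynamics(_fit(-20.0), _fit(-20.0, "static"))
    assert call.lr == 0.0
    assert call.p_value == 1.0
    assert not call.dynamic_by_lr


def test_classify_lr_five_matches_chi2_table():
    call = classify_dynamics(_fit(-17.5), _fit(-20.0, "static"))
    assert call.lr == pytest.approx(5.0)
    assert call.p_value == pytest.approx(0.02535, abs=1e-4)
    assert call.dynamic_by_lr


def test_bic_and_lr_flags_are_independent_rules():
    # 3.84 < LR < 2 ln 12: significant by chi2(1) but BIC still favours static
    call = classify_dynamics(_fit(-17.9), _fit(-20.0, "static"))
    assert call.dynamic_by_lr and not call.dynamic_by_bic


def test_mismatched_observation_counts_raise():
    with pytest.raises(ValueError):
        classify_dynamics(_fit(-17.5, n=12), _fit(-20.0, "static", n=18))


def test_bic_field_consistent_with_formula():
    f = _fit(-10.0)
    assert f.bic == pytest.approx(bic(3, 12, -10.0))


def test_profile_validation(times):
    with pytest.raises(ValueError):
        fit_gp_models((times[:2], np.ones((1, 2))))  # too few time points
    with pytest.raises(ValueError):
        fit_gp_models((times[::-1], np.ones((1, 6))))  # not increasing
    with pytest.raises(ValueError):
        fit_gp_models((times, -np.ones((1, 6))))  # negative raw counts


def test_calls_invariant_to_count_rescaling(scaffold_small, sim_small):
    """CPM + log2 makes dynamic/static calls scale equivariant."""
    counts = sim_small["peak_counts"].iloc[:15]
    a = classify_profiles(counts)
    b = classify_profiles(counts * 13)
    assert (a["dynamic_by_lr"] == b["dynamic_by_lr"]).all()
    assert (a["dynamic_by_bic"] == b["dynamic_by_bic"]).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**32 - 1), st.floats(0.05, 3.0))
def test_lr_nonnegative_and_p_in_unit_interval(seed, sd):
    rng = np.random.default_rng(seed)
    t = np.array([0, 20, 60, 120, 240, 1440], dtype=float)
    z = rng.normal(0, sd, (2, 6))
    fd, fs = fit_gp_models((t, z - z.mean()), normalizer=None)
    call = classify_dynamics(fd, fs)
    assert call.lr >= 0.0
    assert 0.0 <= call.p_value <= 1.0
    assert call.p_value == pytest.approx(stats.chi2.sf(call.lr, 1))
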