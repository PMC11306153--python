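"""Estimator algebra, closed forms, bootstrap determinism and calibration."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from pqtlmr.estimators import (
    EstimatorConfig,
    NoInstrumentsError,
    cochran_q,
    ivw,
    mr_egger,
    mr_presso,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from pqtlmr.harmonize import InstrumentPair, InstrumentSet
from pqtlmr.simulate import quick_instrument_set

from conftest import random_instrument_set

CFG = EstimatorConfig(seed=1234)


def _set(bx, by, sy, sx=None):
    bx = np.asarray(bx, dtype=float)
    return InstrumentSet.from_arrays(
        bx, sx if sx is not None else np.full(bx.size, 0.01), by, sy
    )


# ---------------------------------------------------------------------------
# Wald ratio


def test_wald_ratio_arithmetic():
    res = wald_ratio(InstrumentPair("v", beta_x=0.5, se_x=0.01, beta_y=0.25, se_y=0.05))
    assert res.beta == pytest.approx(0.5)
    assert res.se == pytest.approx(0.1)


def test_wald_null_effect():
    res = wald_ratio(InstrumentPair("v", beta_x=0.5, se_x=0.01, beta_y=0.0, se_y=0.05))
    assert res.beta == 0.0 and res.pvalue == pytest.approx(1.0)


def test_wald_zero_exposure_rejected():
    with pytest.raises(ValueError):
        wald_ratio(InstrumentPair("v", beta_x=0.0, se_x=0.01, beta_y=0.1, se_y=0.05))


def test_wald_random_pairs_match_oracle(rng):
    for _ in range(100):
        bx, by = rng.normal(0.3, 0.1), rng.normal(0, 0.05)
        sx, sy = rng.uniform(0.005, 0.02), rng.uniform(0.005, 0.05)
        res = wald_ratio(InstrumentPair("v", beta_x=bx, se_x=sx, beta_y=by, se_y=sy))
        assert res.beta == pytest.approx(by / bx, rel=1e-12)
        assert res.se == pytest.approx(sy / abs(bx), rel=1e-12)
        assert res.pvalue == pytest.approx(2 * sps.norm.sf(abs(res.beta / res.se)), rel=1e-10)


# ---------------------------------------------------------------------------
# IVW


def test_ivw_equal_weights_symmetry():
    s = _set([0.5, 0.5], [0.1, 0.2], [0.05, 0.05])
    assert ivw(s, "fe").beta == pytest.approx(0.3)


def test_ivw_single_pair_reduces_to_wald():
    s = _set([0.5], [0.25], [0.05])
    for model in ("fe", "mre"):
        res = ivw(s, model)
        assert res.beta == pytest.approx(0.5) and res.se == pytest.approx(0.1)


def test_ivw_empty_set_raises():
    with pytest.raises(NoInstrumentsError):
        ivw(_set([], [], []))


def test_ivw_mre_floor_never_below_fe(rng):
    for _ in range(50):
        s = random_instrument_set(rng, int(rng.integers(2, 12)))
        assert ivw(s, "mre").se >= ivw(s, "fe").se - 1e-15


def test_ivw_mre_floor_can_be_disabled(rng):
    cfg = EstimatorConfig(seed=0, mre_variance_floor=False)
    found_smaller = False
    for _ in range(50):
        s = random_instrument_set(rng, 6)
        if ivw(s, "mre", cfg).se < ivw(s, "fe").se:
            found_smaller = True
            break
    assert found_smaller


def test_ivw_equals_meta_analysis_and_wls(rng):
    """Three-way identity: IVW-fe == IV meta-analysis of ratios == zero-intercept WLS."""
    for _ in range(50):
        s = random_instrument_set(rng, int(rng.integers(2, 15)))
        res = ivw(s, "fe")
        theta = s.beta_y / s.beta_x
        w = s.beta_x**2 / s.se_y**2
        meta = np.sum(w * theta) / np.sum(w)
        assert res.beta == pytest.approx(meta, rel=1e-10)
        assert res.se == pytest.approx(np.sum(w) ** -0.5, rel=1e-10)
        wls = sm.WLS(s.beta_y, s.beta_x, weights=1 / s.se_y**2).fit()
        assert res.beta == pytest.approx(wls.params[0], rel=1e-10)


# ---------------------------------------------------------------------------
# Cochran's Q


def test_q_zero_for_identical_ratios():
    s = _set([0.2, 0.4, 0.5], [0.06, 0.12, 0.15], [0.05, 0.05, 0.05])
    res = cochran_q(s)
    assert res.q == pytest.approx(0.0, abs=1e-20)
    assert res.q_pvalue == pytest.approx(1.0)


def test_q_two_instrument_closed_form():
    # unit ratio-SEs: se_y/|bx| = 1, ratios 0 and 2 -> Q = 2, df 1
    s = _set([1.0, 1.0], [0.0, 2.0], [1.0, 1.0])
    res = cochran_q(s)
    assert res.q == pytest.approx(2.0, rel=1e-12)
    assert res.q_df == 1
    assert res.q_pvalue == pytest.approx(sps.chi2.sf(2.0, 1), rel=1e-12)
    assert res.q_pvalue == pytest.approx(0.1573, abs=2e-4)


def test_q_undefined_below_two_instruments():
    res = cochran_q(_set([0.5], [0.25], [0.05]))
    assert res.q is None and res.q_df is None


def test_q_null_distribution_matches_chisquare():
    """Homogeneous strong-instrument sets: Q ~ chi-square(L-1) by KS test."""
    rng = np.random.default_rng(7)
    L, reps = 5, 2000
    qs = np.empty(reps)
    for i in range(reps):
        s = quick_instrument_set(rng, L=L, theta=0.3, effect_size_range=(5, 20))
        qs[i] = cochran_q(s).q
    d, p = sps.kstest(qs, "chi2", args=(L - 1,))
    assert p > 0.01


# ---------------------------------------------------------------------------
# MR-Egger


def test_egger_recovers_exact_proportionality():
    bx = np.array([0.2, 0.3, 0.5, 0.7])
    s = _set(bx, 0.3 * bx, [0.05] * 4)
    res, sens = mr_egger(s)
    assert res.beta == pytest.approx(0.3, abs=1e-10)
    assert sens.egger_intercept == pytest.approx(0.0, abs=1e-10)


def test_egger_recovers_affine_relation():
    bx = np.array([0.2, 0.3, 0.5, 0.7])
    s = _set(bx, 0.1 + 0.3 * bx, [0.05] * 4)
    res, sens = mr_egger(s)
    assert res.beta == pytest.approx(0.3, abs=1e-10)
    assert sens.egger_intercept == pytest.approx(0.1, abs=1e-10)


def test_egger_requires_three_instruments():
    with pytest.raises(ValueError):
        mr_egger(_set([0.2, 0.3], [0.1, 0.1], [0.05, 0.05]))


def test_egger_matches_wls_oracle(rng):
    """Slope/intercept equal statsmodels WLS on oriented data to 1e-10."""
    for _ in range(50):
        s = random_instrument_set(rng, int(rng.integers(3, 15)))
        res, sens = mr_egger(s)
        sign = np.where(s.beta_x < 0, -1.0, 1.0)
        bx, by = s.beta_x * sign, s.beta_y * sign
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1 / s.se_y**2).fit()
        assert sens.egger_intercept == pytest.approx(fit.params[0], rel=1e-10, abs=1e-12)
        assert res.beta == pytest.approx(fit.params[1], rel=1e-10, abs=1e-12)


# ---------------------------------------------------------------------------
# weighted median / mode


def test_weighted_median_equal_weight_fixture():
    s = _set([1.0, 1.0, 1.0], [0.1, 0.3, 0.9], [1.0, 1.0, 1.0])
    res = weighted_median(s, CFG)
    assert res.beta == pytest.approx(0.3)


def test_weighted_median_within_ratio_range(rng):
    for _ in range(20):
        s = random_instrument_set(rng, 7)
        theta = s.beta_y / s.beta_x
        res = weighted_median(s, CFG)
        assert theta.min() - 1e-12 <= res.beta <= theta.max() + 1e-12


def test_weighted_median_seeded_reproducible():
    rng = np.random.default_rng(5)
    s = random_instrument_set(rng, 6)
    a = weighted_median(s, EstimatorConfig(seed=42))
    b = weighted_median(s, EstimatorConfig(seed=42))
    assert a == b
    c = weighted_median(s, EstimatorConfig(seed=43))
    assert c.se != a.se  # different seed, different bootstrap


def test_weighted_mode_degenerate_all_equal():
    bx = np.array([0.2, 0.4, 0.5])
    s = _set(bx, 0.25 * bx, [0.05] * 3)
    res = weighted_mode(s, CFG)
    assert res.beta == pytest.approx(0.25)


def test_weighted_mode_resists_single_outlier():
    # majority cluster near 0.3, one gross outlier at 3.0
    bx = np.array([0.5, 0.5, 0.5, 0.5, 0.5])
    ratios = np.array([0.28, 0.30, 0.32, 0.31, 3.0])
    s = _set(bx, ratios * bx, [0.05] * 5)
    res = weighted_mode(s, CFG)
    assert 0.2 < res.beta < 0.4


def test_weighted_mode_seeded_reproducible(rng):
    s = random_instrument_set(rng, 6)
    assert weighted_mode(s, EstimatorConfig(seed=9)) == weighted_mode(s, EstimatorConfig(seed=9))


# ---------------------------------------------------------------------------
# MR-PRESSO


def test_presso_clean_fixture_over_seed_batch():
    """No pleiotropy: the global test should not reject in ~95% of seed draws."""
    clean = 0
    n_seeds = 30
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        s = quick_instrument_set(rng, L=6, theta=0.3, effect_size_range=(5, 20))
        sens, corrected = mr_presso(s, EstimatorConfig(seed=seed, presso_simulations=400))
        if sens.presso_global_p >= 0.05 and not sens.presso_outliers:
            clean += 1
    assert clean >= 27  # >= 90% of seeds


def test_presso_flags_gross_outlier():
    # one gross pleiotropic variant (ratio 10x the rest) among 30 clean ones;
    # the outlier must be flagged and the corrected IVW must recover the
    # clean effect (clean variants near the outlier's leave-one-out pull may
    # be co-flagged; that does not bias the corrected estimate)
    rng = np.random.default_rng(0)
    L = 30
    bx = rng.uniform(0.3, 0.7, L + 1)
    ratios = np.concatenate([rng.normal(0.3, 0.005, L), [3.0]])
    s = InstrumentSet.from_arrays(
        bx, [0.01] * (L + 1), ratios * bx, [0.02] * (L + 1),
        variant_ids=[f"v{i}" for i in range(L)] + ["outlier"],
    )
    sens, corrected = mr_presso(s, EstimatorConfig(seed=3))
    assert "outlier" in sens.presso_outliers
    assert sens.presso_global_p <= 0.05
    assert corrected is not None and corrected.method == "presso_corrected"
    assert corrected.beta == pytest.approx(0.3, abs=0.05)


def test_presso_requires_four_and_is_deterministic(rng):
    with pytest.raises(ValueError):
        mr_presso(_set([0.2, 0.3, 0.4], [0.1] * 3, [0.05] * 3), CFG)
    s = random_instrument_set(rng, 6)
    a = mr_presso(s, EstimatorConfig(seed=11))
    b = mr_presso(s, EstimatorConfig(seed=11))
    assert a == b


# ---------------------------------------------------------------------------
# odds-ratio conversion and invariances


def test_odds_ratio_null_and_roundtrip(rng):
    orp, lcl, ucl = to_odds_ratio(0.0, 0.1)
    assert orp == pytest.approx(1.0)
    assert lcl == pytest.approx(np.exp(-sps.norm.ppf(0.975) * 0.1))
    for _ in range(20):
        beta, se = rng.normal(0, 0.5), rng.uniform(0.01, 0.5)
        _, lcl, ucl = to_odds_ratio(beta, se)
        z = sps.norm.ppf(0.975)
        assert np.log(ucl / lcl) / (2 * z) == pytest.approx(se, rel=1e-10)


def test_odds_ratio_tiny_se_collapses_ci():
    orp, lcl, ucl = to_odds_ratio(np.log(2), 1e-14)
    assert orp == pytest.approx(2.0)
    assert lcl == pytest.approx(2.0, rel=1e-9) and ucl == pytest.approx(2.0, rel=1e-9)


def test_estimators_invariant_under_per_variant_sign_flips(rng):
    """Allele reorientation (joint sign flip of one variant) changes nothing."""
    s = random_instrument_set(rng, 6)
    flip = rng.random(6) < 0.5
    sign = np.where(flip, -1.0, 1.0)
    s2 = InstrumentSet.from_arrays(
        s.beta_x * sign, s.se_x, s.beta_y * sign, s.se_y
    )
    for model in ("fe", "mre"):
        assert ivw(s, model).beta == pytest.approx(ivw(s2, model).beta, rel=1e-12)
    assert cochran_q(s).q == pytest.approx(cochran_q(s2).q, rel=1e-12)
    r1, i1 = mr_egger(s)
    r2, i2 = mr_egger(s2)
    assert r1.beta == pytest.approx(r2.beta, rel=1e-12)
    assert i1.egger_intercept == pytest.approx(i2.egger_intercept, rel=1e-12)
    m1 = weighted_median(s, EstimatorConfig(seed=5))
    m2 = weighted_median(s2, EstimatorConfig(seed=5))
    assert m1.beta == pytest.approx(m2.beta, rel=1e-12)


def test_config_validation():
    with pytest.raises(ValueError):
        EstimatorConfig(bootstrap_iterations=10)
    with pytest.raises(ValueError):
        EstimatorConfig(seed=None).rng()
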