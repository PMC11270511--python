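"""JZS Bayes factor: oracle equivalence, monotonicity, categories, masks."""

import numpy as np
import pytest
from scipy import stats

from perisacc.bayes import (
    BFSettings,
    DEFAULT_PRIOR_SCALE,
    _categorize,
    bf_mask,
    bf_timecourse,
    evidence_clusters,
    jzs_bf,
    jzs_bf_from_t,
)


def delta_grid_oracle(t: float, n: int, r: float = DEFAULT_PRIOR_SCALE) -> float:
    """Independent oracle: dense trapezoid integration of the noncentral-t
    likelihood over the Cauchy effect-size prior."""
    df = n - 1
    # the noncentral-t factor kills the integrand far from delta = t/sqrt(n),
    # so a +-15-wide window around it captures the mass to well below 1e-6
    half = abs(t) / np.sqrt(n) + 15.0
    d = np.linspace(-half, half, 40001)
    y = stats.nct.pdf(t, df, d * np.sqrt(n)) * stats.cauchy.pdf(d, scale=r)
    return float(np.trapezoid(y, d) / stats.t.pdf(t, df))


@pytest.mark.parametrize("n", [5, 18, 50])
@pytest.mark.parametrize("t", [-10.0, -3.0, 0.0, 1.0, 2.5, 5.0, 10.0])
def test_oracle_equivalence(n, t):
    """Adaptive integration matches the dense-grid oracle to 1e-4."""
    oracle = delta_grid_oracle(t, n)
    mine = jzs_bf_from_t(t, n)
    assert abs(mine - oracle) / oracle < 1e-4


def test_cross_check_against_pingouin():
    pg = pytest.importorskip("pingouin")
    for n in (5, 18, 50):
        for t in (-3.0, 0.0, 2.5, 5.0):
            ref = float(pg.bayesfactor_ttest(t, n))
            assert abs(jzs_bf_from_t(t, n) - ref) / ref < 1e-3


def test_null_consistent_data_favor_h0():
    assert jzs_bf_from_t(0.0, 18) < 1.0


def test_strong_effect_favors_h1():
    assert jzs_bf_from_t(5.0, 18) > 3.0


def test_bf_at_null_decreases_with_n():
    """With t = 0 the evidence for the null accumulates with sample size."""
    bfs = [jzs_bf_from_t(0.0, n) for n in (5, 18, 50, 100)]
    assert all(a > b for a, b in zip(bfs, bfs[1:]))
    assert bfs[-1] < 1 / 3


def test_wider_prior_hurts_h1_at_null():
    a = jzs_bf_from_t(0.0, 18, BFSettings(prior_scale=DEFAULT_PRIOR_SCALE))
    b = jzs_bf_from_t(0.0, 18, BFSettings(prior_scale=2 * DEFAULT_PRIOR_SCALE))
    assert b < a


def test_one_sided_priors_average_to_two_sided():
    for t in (-2.0, 0.0, 3.0):
        g = jzs_bf_from_t(t, 18, BFSettings(sidedness="greater"))
        le = jzs_bf_from_t(t, 18, BFSettings(sidedness="less"))
        two = jzs_bf_from_t(t, 18)
        assert (g + le) / 2 == pytest.approx(two, rel=1e-6)
    assert jzs_bf_from_t(3.0, 18, BFSettings(sidedness="greater")) > jzs_bf_from_t(
        3.0, 18, BFSettings(sidedness="less")
    )


def test_jzs_bf_from_values():
    rng = np.random.default_rng(0)
    v = 0.5 + rng.normal(0, 0.05, 18)
    t = (v.mean() - 0.5) / (v.std(ddof=1) / np.sqrt(18))
    assert jzs_bf(v, BFSettings(null_value=0.5)) == pytest.approx(
        jzs_bf_from_t(t, 18), rel=1e-10
    )


def test_zero_variance_degenerate():
    assert jzs_bf(np.full(10, 0.7), BFSettings(null_value=0.5)) == np.inf
    assert jzs_bf(np.full(10, 0.5), BFSettings(null_value=0.5)) == 0.0


def test_too_few_values_rejected():
    with pytest.raises(ValueError):
        jzs_bf(np.array([0.6]))


def test_invalid_settings_rejected():
    with pytest.raises(ValueError):
        BFSettings(prior_scale=0.0)
    with pytest.raises(ValueError):
        BFSettings(sidedness="sideways")


def test_evidence_categories_strict_thresholds():
    cats = _categorize(np.array([3.0, 3.01, 1 / 3, 0.332, 1.0]))
    assert cats.tolist() == [
        "inconclusive",
        "substantial_alt",
        "inconclusive",
        "substantial_null",
        "inconclusive",
    ]


def test_timecourse_null_simulation_mostly_substantial_null():
    """Subjects at chance with small jitter: most timepoints show
    substantial evidence for the null with n = 24."""
    rng = np.random.default_rng(5)
    values = 0.5 + rng.normal(0, 0.02, (24, 60))
    tc = bf_timecourse(values, np.arange(60) / 256.0, BFSettings(null_value=0.5))
    # BF10 < 1/3 needs roughly |t| < 1 at this n, so "most" here means the
    # majority of timepoints, with essentially no false alternatives
    assert (tc.category == "substantial_null").mean() > 0.6
    assert (tc.category == "substantial_alt").mean() < 0.1


def test_timecourse_localized_effect():
    rng = np.random.default_rng(6)
    values = 0.5 + rng.normal(0, 0.02, (18, 60))
    values[:, 30] += 0.1  # strong effect at one timepoint
    tc = bf_timecourse(values, np.arange(60) / 256.0, BFSettings(null_value=0.5))
    assert tc.category[30] == "substantial_alt"
    others = np.delete(tc.category, 30)
    assert (others == "substantial_alt").mean() < 0.1


def test_bf_mask_null_simulation_sparse():
    rng = np.random.default_rng(7)
    diffs = rng.normal(0, 0.05, (10, 8, 40))
    mask = bf_mask(diffs, BFSettings(null_value=0.0), threshold=10.0)
    assert mask.mean() < 0.05


def test_bf_mask_infinite_threshold_empty():
    rng = np.random.default_rng(8)
    diffs = rng.normal(0.3, 0.05, (10, 4, 10))
    mask = bf_mask(diffs, BFSettings(null_value=0.0), threshold=np.inf)
    assert not mask.any()


def test_bf_mask_flags_real_effect():
    rng = np.random.default_rng(9)
    diffs = rng.normal(0, 0.05, (10, 4, 10))
    diffs[:, 1, 4:7] += 0.3
    mask = bf_mask(diffs, BFSettings(null_value=0.0), threshold=10.0)
    assert mask[1, 4:7].all()


def test_evidence_clusters_runs():
    m = np.array([0, 1, 1, 0, 1, 0, 1, 1, 1], dtype=bool)
    assert evidence_clusters(m, min_len=2) == [(1, 3), (6, 9)]
    assert evidence_clusters(m, min_len=4) == []
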