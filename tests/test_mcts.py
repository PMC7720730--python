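"""The nine pairwise MCTs: hand-derived examples, library cross-checks,
step-down logic, and the structural invariants shared by all tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mctbench import (
    AlphaPolicy,
    Dataset,
    DegenerateVarianceError,
    InvalidInputError,
    TEST_NAMES,
    adjust_bonferroni,
    adjust_sidak,
    duncan,
    fisher_lsd,
    fit_oneway,
    pairwise_t,
    run_all_tests,
    scheffe,
    snk,
    tukey_hsd,
)
from .conftest import random_dataset


def by_pair(results):
    return {r.pair: r for r in results}


# ---------------------------------------------------------------------------
# adjusters


@pytest.mark.parametrize(
    "p,m,expected",
    [(0.02, 1, 0.02), (0.01, 3, 0.03), (0.5, 3, 1.0)],
)
def test_bonferroni_closed_form(p, m, expected):
    assert adjust_bonferroni(p, m) == pytest.approx(expected)


@pytest.mark.parametrize("p,m,expected", [(0.05, 1, 0.05), (0.01, 3, 0.029701)])
def test_sidak_closed_form(p, m, expected):
    assert adjust_sidak(p, m) == pytest.approx(expected, abs=1e-9)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(p=st.floats(0.0, 1.0), m=st.integers(1, 50))
def test_sidak_never_exceeds_bonferroni(p, m):
    sid = adjust_sidak(p, m)
    assert 0.0 <= sid <= 1.0
    assert sid <= adjust_bonferroni(p, m) + 1e-12


@pytest.mark.parametrize("adjuster", [adjust_bonferroni, adjust_sidak])
def test_adjuster_rejects_bad_m(adjuster):
    with pytest.raises(InvalidInputError):
        adjuster(0.05, 0)


# ---------------------------------------------------------------------------
# hand-derived example values on the toy dataset (means 2, 3, 7, mse 1)


def test_pairwise_t_hand_oracle(toy_dataset):
    res = by_pair(pairwise_t(toy_dataset, correction="none"))
    r = res[("g1", "g2")]
    assert r.statistic == pytest.approx(-1.2247, abs=1e-4)
    assert r.p_value == pytest.approx(2 * stats.t.sf(1.22474, 4), abs=1e-4)


def test_pairwise_t_matches_scipy(rng):
    for _ in range(10):
        data = random_dataset(rng, balanced=False)
        res = pairwise_t(data, correction="none")
        for r in res:
            i = data.groups.index(r.pair[0])
            j = data.groups.index(r.pair[1])
            t_ref, p_ref = stats.ttest_ind(data.values[i], data.values[j])
            assert r.statistic == pytest.approx(float(t_ref), rel=1e-10)
            assert r.p_value == pytest.approx(float(p_ref), rel=1e-8)


def test_fisher_lsd_hand_oracle(toy_fit):
    r = by_pair(fisher_lsd(toy_fit))[("g1", "g3")]
    assert r.statistic == pytest.approx(-5.0 / np.sqrt(2.0 / 3.0), abs=1e-4)
    assert r.p_value == pytest.approx(2 * stats.t.sf(6.1237, 6), abs=1e-4)


def test_tukey_hand_oracle(toy_fit):
    r = by_pair(tukey_hsd(toy_fit))[("g1", "g2")]
    assert r.statistic == pytest.approx(np.sqrt(3.0), abs=1e-4)
    ref = stats.studentized_range.sf(np.sqrt(3.0), 3, 6)
    assert r.p_value == pytest.approx(float(ref), abs=1e-6)


def test_tukey_matches_scipy_tukey_hsd(rng):
    for balanced in (True, False):
        data = random_dataset(rng, k=4, balanced=balanced)
        fit = fit_oneway(data)
        ours = by_pair(tukey_hsd(fit))
        ref = stats.tukey_hsd(*data.values)
        for (i, j), r in [((data.groups.index(a), data.groups.index(b)), v) for (a, b), v in ours.items()]:
            assert r.p_value == pytest.approx(float(ref.pvalue[i, j]), abs=1e-6)


def test_scheffe_hand_oracle(toy_fit):
    r = by_pair(scheffe(toy_fit))[("g1", "g3")]
    # SS_c = 25 / (2/3) = 37.5; F = 37.5 / 2 on (2, 6) df
    assert r.statistic == pytest.approx(18.75)
    assert r.p_value == pytest.approx(float(stats.f.sf(18.75, 2, 6)), rel=1e-10)


def test_scheffe_contrast_interface(toy_fit):
    (r,) = scheffe(toy_fit, contrast=[1.0, 0.0, -1.0])
    assert r.statistic == pytest.approx(18.75)
    with pytest.raises(InvalidInputError):
        scheffe(toy_fit, contrast=[1.0, 1.0, -1.0])
    with pytest.raises(InvalidInputError):
        scheffe(toy_fit, contrast=[1.0, -1.0])


def test_snk_stepdown_decisions(toy_fit):
    res = by_pair(snk(toy_fit, AlphaPolicy(0.05)))
    assert res[("g1", "g3")].reject and res[("g2", "g3")].reject
    assert not res[("g1", "g2")].reject
    # adjacent pair's reported p is its span-2 stepwise p (enclosing ranges
    # are more significant here)
    assert res[("g1", "g2")].p_value == pytest.approx(2 * stats.t.sf(np.sqrt(3.0) / np.sqrt(2), 6), abs=1e-6)


def test_snk_blocking_forces_nonrejection(rng):
    """Every reported step-down p is at least the full-range stepwise p (the
    widest range encloses every pair), so a nonsignificant full range blocks
    all rejections."""
    from mctbench import studentized_range_sf

    for _ in range(20):
        data = random_dataset(rng, spread=float(rng.uniform(0, 1)))
        fit = fit_oneway(data)
        res = snk(fit, AlphaPolicy(0.05))
        pos = np.argsort(fit.means, kind="stable")
        extreme = {fit.groups[pos[0]], fit.groups[pos[-1]]}
        (top,) = [r for r in res if set(r.pair) == extreme]
        p_full = studentized_range_sf(abs(top.statistic), fit.k, fit.df_within)
        for r in res:
            assert r.p_value >= p_full - 1e-12
        if p_full >= 0.05:
            assert not any(r.reject for r in res)


def test_duncan_span_level_mapping(toy_fit):
    """Duncan's reported p for a span-r pair maps the stepwise p through
    1 - (1-p)^(1/(r-1)); at alpha=0.05, span 3 runs at 1 - 0.95^2 = 0.0975."""
    snk_res = by_pair(snk(toy_fit))
    dun_res = by_pair(duncan(toy_fit))
    p3 = snk_res[("g1", "g3")].p_value  # span-3 pair, unblocked
    assert dun_res[("g1", "g3")].p_value == pytest.approx(1 - (1 - p3) ** 0.5, rel=1e-9)
    assert 1 - 0.95**2 == pytest.approx(0.0975)
    # span-2 pairs share SNK's stepwise p when unblocked
    assert dun_res[("g2", "g3")].p_value == pytest.approx(snk_res[("g2", "g3")].p_value, rel=1e-9)


def test_degenerate_pair_variance_raises():
    data = Dataset.from_groups([(1.0, 1.0), (2.0, 2.0), (0.0, 3.0)])
    with pytest.raises(DegenerateVarianceError):
        pairwise_t(data)


# ---------------------------------------------------------------------------
# structural invariants


def test_run_all_tests_row_counts(toy_dataset, rng):
    rows = run_all_tests(toy_dataset)
    assert len(rows) == 9 * 3
    assert [r.test_name for r in rows[:3]] == ["scheffe"] * 3
    data7 = random_dataset(rng, k=7, n=5)
    assert len(run_all_tests(data7)) == 9 * 21
    data6 = random_dataset(rng, k=6, n=5)
    rows6 = run_all_tests(data6)
    per_test = {t: sum(r.test_name == t for r in rows6) for t in TEST_NAMES}
    assert all(c == 15 for c in per_test.values())  # C(6,2) = 15 pairs


def test_pair_ordering_identical_across_tests(rng):
    data = random_dataset(rng, k=5)
    rows = run_all_tests(data)
    orders = {}
    for t in TEST_NAMES:
        orders[t] = [r.pair for r in rows if r.test_name == t]
    ref = orders[TEST_NAMES[0]]
    assert all(o == ref for o in orders.values())


def test_reject_iff_p_below_alpha(rng):
    for alpha in (0.01, 0.05, 0.2):
        data = random_dataset(rng, spread=1.5)
        for r in run_all_tests(data, AlphaPolicy(alpha)):
            assert 0.0 <= r.p_value <= 1.0
            assert r.reject == (r.p_value < alpha)


def test_rejection_nesting(rng):
    """Scheffe <= Tukey <= SNK <= Duncan <= LSD; Bonferroni <= Sidak <= raw."""
    chains = [
        ("scheffe", "tukey_hsd", "snk", "duncan_mrt", "fisher_lsd"),
        ("t_bonferroni", "t_sidak"),
        ("lsd_bonferroni", "lsd_sidak", "fisher_lsd"),
    ]
    for _ in range(60):
        data = random_dataset(rng, spread=float(rng.uniform(0.2, 2.0)))
        rows = run_all_tests(data, AlphaPolicy(0.05))
        rej = {t: {r.pair for r in rows if r.test_name == t and r.reject} for t in TEST_NAMES}
        for chain in chains:
            for narrow, wide in zip(chain, chain[1:]):
                assert rej[narrow] <= rej[wide], (narrow, wide)


def test_k2_collapse(rng):
    """With two groups all range/step-down/corrected tests equal the pooled
    t-test and Scheffe equals the omnibus ANOVA p."""
    for _ in range(10):
        data = random_dataset(rng, k=2, balanced=bool(rng.integers(2)))
        fit = fit_oneway(data)
        rows = run_all_tests(data)
        p_t = 2 * stats.t.sf(
            abs(by_pair(pairwise_t(data))[("g1", "g2")].statistic), data.values[0].size + data.values[1].size - 2
        )
        for r in rows:
            if r.test_name == "scheffe":
                assert r.p_value == pytest.approx(fit.p_omnibus, rel=1e-9)
            else:
                assert r.p_value == pytest.approx(p_t, rel=1e-7), r.test_name


def test_scheffe_protected_quick(rng):
    for _ in range(200):
        data = random_dataset(rng, spread=0.0)
        fit = fit_oneway(data)
        if fit.p_omnibus >= 0.05:
            assert not any(r.reject for r in scheffe(fit, AlphaPolicy(0.05)))


def test_identical_groups_no_rejections():
    data = Dataset.from_groups([(1, 2, 3)] * 4)
    for r in run_all_tests(data):
        assert not r.reject
        assert r.p_value > 0.5
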