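"""Association statistics against exact-enumeration and closed-form oracles."""

from itertools import combinations, product
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from tcrtme import stats as ts
from tcrtme.exceptions import InsufficientDataError, UndefinedStatisticError


# ---------------------------------------------------------------- oracles
def exact_signed_rank_p(diff) -> float:
    """Two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diff, float)
    d = d[d != 0]
    r = sps.rankdata(np.abs(d))
    w_obs = r[d > 0].sum()
    ws = np.array(
        [sum(rr for rr, s in zip(r, signs) if s) for signs in product((0, 1), repeat=len(d))]
    )
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(p, 1.0)


def exact_rank_sum_p(a, b) -> float:
    """Two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    r = sps.rankdata(pooled)
    obs = r[: len(a)].sum()
    sums = np.array([r[list(c)].sum() for c in combinations(range(len(pooled)), len(a))])
    p = 2 * min((sums <= obs).mean(), (sums >= obs).mean())
    return min(p, 1.0)


# ---------------------------------------------------------------- paired test
def test_identical_pairs_give_p_one():
    x = np.arange(10.0)
    res = ts.paired_test(x, x)
    assert res.p_value == 1.0
    assert res.direction == 0


def test_constant_shift_is_detected():
    pre = np.random.default_rng(1).normal(10, 2, size=20)
    res = ts.paired_test(pre, pre + 5)
    assert res.p_value < 0.01
    assert res.direction == 1


def test_all_positive_differences_hit_the_exact_null_extreme():
    # untied positive shifts: the signed-rank statistic sits at the top of the
    # exact null, so the two-sided p is exactly 2 / 2^20
    rng = np.random.default_rng(1)
    pre = rng.normal(10, 2, size=20)
    res = ts.paired_test(pre, pre + rng.uniform(1, 5, size=20))
    assert res.p_value == pytest.approx(2 / 2**20, rel=1e-9)


def test_too_few_pairs_is_an_error():
    with pytest.raises(InsufficientDataError):
        ts.paired_test([1.0, 2.0], [2.0, 3.0])


def test_incomplete_pairs_are_dropped():
    pre = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
    post = np.array([2.0, 1.0, 3.0, np.nan, 6.0])
    res = ts.paired_test(pre, post)
    assert res.n == 3


@pytest.mark.parametrize("seed", range(8))
def test_paired_test_matches_exact_enumeration(seed):
    rng = np.random.default_rng(seed)
    pre = rng.normal(size=9)
    post = pre + rng.normal(size=9)
    res = ts.paired_test(pre, post)
    assert res.p_value == pytest.approx(exact_signed_rank_p(post - pre), abs=1e-10)


def test_paired_type_one_error_is_nominal():
    rng = np.random.default_rng(42)
    rejections = sum(
        ts.paired_test(rng.normal(size=15), rng.normal(size=15)).p_value < 0.05
        for _ in range(400)
    )
    assert 0.02 <= rejections / 400 <= 0.08


# ---------------------------------------------------------------- group test
def test_identical_groups_are_not_separated():
    x = np.arange(12.0)
    assert ts.group_test(x, x).p_value >= 0.9


def test_fully_separated_groups_hit_the_exact_tail():
    a = np.arange(10.0)
    b = np.arange(100.0, 110.0)
    res = ts.group_test(a, b)
    assert res.p_value == pytest.approx(2 / comb(20, 10), rel=1e-9)
    assert res.p_value < 1e-4
    assert res.direction == -1


@pytest.mark.parametrize("seed", range(8))
def test_group_test_matches_exact_enumeration(seed):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=6), rng.normal(size=5)
    res = ts.group_test(a, b)
    assert res.p_value == pytest.approx(exact_rank_sum_p(a, b), abs=1e-10)


def test_group_type_one_error_is_nominal():
    rng = np.random.default_rng(7)
    rejections = sum(
        ts.group_test(rng.normal(size=15), rng.normal(size=15)).p_value < 0.05
        for _ in range(400)
    )
    assert 0.02 <= rejections / 400 <= 0.08


def test_small_group_is_an_error():
    with pytest.raises(InsufficientDataError):
        ts.group_test([1.0, 2.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------- correlation
def test_spearman_monotone_extremes():
    x = np.arange(10.0)
    assert ts.spearman(x, np.exp(x))[0] == pytest.approx(1.0)
    assert ts.spearman(x, -(x**3))[0] == pytest.approx(-1.0)


def test_spearman_constant_vector_is_undefined():
    with pytest.raises(UndefinedStatisticError):
        ts.spearman(np.ones(10), np.arange(10.0))


def test_spearman_null_is_centered():
    rng = np.random.default_rng(3)
    rhos = [ts.spearman(rng.normal(size=30), rng.normal(size=30))[0] for _ in range(300)]
    assert abs(np.mean(rhos)) < 0.05


# ---------------------------------------------------------------- BH adjust
def test_single_p_unchanged():
    assert ts.bh_adjust([0.03]) == pytest.approx([0.03])


def test_bh_hand_computed_step_up():
    # ranked: 0.01*4/1=0.04, 0.02*4/2=0.04, 0.03*4/3=0.04, 0.04*4/4=0.04
    adj = ts.bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_is_group_wise():
    p = [0.01, 0.02, 0.03, 0.04]
    joint = ts.bh_adjust(p, groups=["a", "a", "b", "b"])
    a = ts.bh_adjust(p[:2])
    b = ts.bh_adjust(p[2:])
    assert joint == pytest.approx(np.concatenate([a, b]))


def test_bh_dominates_raw_and_is_order_invariant():
    rng = np.random.default_rng(5)
    p = rng.random(20)
    groups = rng.integers(0, 3, size=20)
    adj = ts.bh_adjust(p, groups)
    assert (adj >= p - 1e-15).all()
    perm = rng.permutation(20)
    adj_perm = ts.bh_adjust(p[perm], groups[perm])
    assert adj_perm == pytest.approx(adj[perm])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        ts.bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------- ROC
def test_perfect_separation_gives_auc_one():
    scores = np.concatenate([np.zeros(8), np.ones(8)])
    labels = scores > 0.5
    auc, lo, hi = ts.roc_auc(scores, labels, n_boot=100, seed=0)
    assert auc == 1.0
    assert lo <= auc <= hi


def test_auc_matches_sklearn_trapezoid():
    sk = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(9)
    for _ in range(10):
        scores = rng.integers(0, 6, size=40).astype(float)  # heavy ties
        labels = rng.random(40) < 0.4
        if labels.all() or not labels.any():
            continue
        auc, _, _ = ts.roc_auc(scores, labels, n_boot=0)
        assert auc == pytest.approx(float(sk.roc_auc_score(labels, scores)), abs=1e-12)


def test_shuffled_labels_give_null_auc():
    rng = np.random.default_rng(11)
    aucs = []
    for _ in range(200):
        scores = rng.normal(size=30)
        labels = np.concatenate([np.ones(15, bool), np.zeros(15, bool)])
        rng.shuffle(labels)
        aucs.append(ts.roc_auc(scores, labels, n_boot=0)[0])
    assert abs(np.mean(aucs) - 0.5) < 0.03


def test_single_class_auc_is_undefined():
    with pytest.raises(UndefinedStatisticError):
        ts.roc_auc([1.0, 2.0, 3.0], [True, True, True])


def test_bootstrap_ci_is_deterministic_under_seed():
    rng = np.random.default_rng(13)
    scores = rng.normal(size=30)
    labels = rng.random(30) < 0.5
    a = ts.roc_auc(scores, labels, n_boot=200, seed=5)
    b = ts.roc_auc(scores, labels, n_boot=200, seed=5)
    assert a == b


# ---------------------------------------------------------------- survival
def survival_frame(n, hr, seed, censor=None):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=n).astype(float)
    t = rng.exponential(1.0 / (0.1 * np.exp(np.log(hr) * x)))
    if censor is None:
        return pd.DataFrame({"time": t, "event": np.ones(n), "x": x})
    return pd.DataFrame(
        {"time": np.minimum(t, censor), "event": (t <= censor).astype(float), "x": x}
    )


def test_logrank_identical_groups_is_null():
    df = survival_frame(60, 1.0, 0)
    dup = pd.concat([df.assign(g="a"), df.assign(g="b")])
    chi2, p, medians = ts.km_logrank(dup["time"], dup["event"], dup["g"])
    assert chi2 == pytest.approx(0.0, abs=1e-9)
    assert p > 0.99
    assert medians["a"] == medians["b"]


def test_logrank_detects_a_strong_hazard_ratio():
    hits = 0
    for seed in range(20):
        df = survival_frame(200, 3.0, seed)
        _, p, _ = ts.km_logrank(df["time"], df["event"], df["x"])
        hits += p < 0.001
    assert hits >= 19


def test_logrank_single_group_is_an_error():
    df = survival_frame(20, 1.0, 1)
    with pytest.raises(ValueError):
        ts.km_logrank(df["time"], df["event"], np.zeros(20))


def test_logrank_warns_on_event_free_group():
    df = survival_frame(40, 1.0, 2)
    df.loc[df["x"] == 1, "event"] = 0.0
    with pytest.warns(UserWarning, match="no events"):
        ts.km_logrank(df["time"], df["event"], df["x"])


def test_cox_recovers_known_hazard_ratio():
    hrs = []
    for seed in range(25):
        df = survival_frame(300, 2.0, seed, censor=6.6)
        fits = ts.cox_stage(df, "time", "event", ["x"])
        hrs.append(fits[0].hazard_ratio)
    assert np.mean(hrs) == pytest.approx(2.0, abs=0.2)


def test_cox_entry_gate_blocks_weak_covariates():
    """A covariate with univariable p > entry_p never reaches stage 2."""
    rng = np.random.default_rng(21)
    df = survival_frame(300, 2.0, 3, censor=6.6)
    df["noise"] = rng.normal(size=len(df))
    fits = ts.cox_stage(df, "time", "event", ["x", "noise"])
    uni = {f.variable: f for f in fits if f.stage == "univariate"}
    multi = {f.variable for f in fits if f.stage == "multivariate"}
    for var in multi:
        assert uni[var].p_value <= 0.05
    if uni["noise"].p_value > 0.05:
        assert "noise" not in multi


def test_cox_constant_covariate_rejected():
    df = survival_frame(50, 1.0, 4)
    df["flat"] = 1.0
    with pytest.raises(ValueError):
        ts.cox_stage(df, "time", "event", ["flat"])


def test_cox_warns_on_few_events():
    df = survival_frame(30, 1.5, 5)
    df.loc[df.index[8:], "event"] = 0.0
    with pytest.warns(UserWarning, match="events"):
        ts.cox_stage(df, "time", "event", ["x"])


def test_backward_elimination_drops_redundant_terms():
    """Two copies of the same signal: at most one survives elimination."""
    df = survival_frame(400, 2.5, 6, censor=6.6)
    rng = np.random.default_rng(8)
    df["x2"] = df["x"] + rng.normal(0, 0.05, size=len(df))
    fits = ts.cox_stage(df, "time", "event", ["x", "x2"])
    multi = [f for f in fits if f.stage == "multivariate"]
    assert len(multi) <= 1 or all(f.p_value <= 0.05 for f in multi)


# ---------------------------------------------------------------- contingency
def test_fisher_matches_hypergeometric_tail():
    table = [[8, 2], [1, 9]]
    _, p, method = ts.contingency_test(table)
    assert method == "fisher"
    # two-sided Fisher p: sum of hypergeometric probabilities <= P(observed),
    # with margins N=20 total, 9 first-column "successes", 10 drawn in row 1
    probs = [sps.hypergeom.pmf(k, 20, 9, 10) for k in range(10)]
    p_obs = sps.hypergeom.pmf(8, 20, 9, 10)
    expected = sum(q for q in probs if q <= p_obs + 1e-12)
    assert p == pytest.approx(expected, rel=1e-9)


def test_stratified_cmh_runs_on_homogeneous_tables():
    strata = [[[20, 10], [10, 20]], [[18, 12], [12, 18]]]
    stat, p, method = ts.contingency_test(None, strata=np.array(strata).transpose(1, 2, 0))
    assert method == "cmh"
    assert 0 <= p <= 1
    assert stat >= 0
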