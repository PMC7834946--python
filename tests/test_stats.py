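import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pupilload.features import ALL_FEATURES
from pupilload.stats import (
    bonferroni_pairwise,
    rm_anova_gg,
    select_features,
    shapiro_gate,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon_p(diffs):
    """Exact two-sided p by enumerating every sign assignment."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    signs = np.array(list(itertools.product([0, 1], repeat=n)))
    w_all = signs @ ranks
    center = ranks.sum() / 2.0
    lower = np.mean(w_all <= w_obs + 1e-9)
    upper = np.mean(w_all >= w_obs - 1e-9)
    return min(1.0, 2 * min(lower, upper))


def test_shapiro_gate_routes_heavy_tails(rng):
    x = np.where(rng.uniform(size=500) < 0.85, rng.normal(0, 1, 500),
                 rng.normal(0, 12, 500))
    assert shapiro_gate(x) == "non_normal"
    assert shapiro_gate(rng.normal(0, 1, 500)) == "normal"


def test_shapiro_gate_degenerate_inputs():
    with pytest.raises(ValueError):
        shapiro_gate([1.0, 2.0])
    with pytest.warns(UserWarning, match="constant"):
        assert shapiro_gate([3.0, 3.0, 3.0, 3.0]) == "non_normal"


def test_wilcoxon_all_positive_differences():
    res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
    assert res.w_minus == 0.0
    assert res.p_value == pytest.approx(2 / 32)
    assert res.method == "exact"


def test_wilcoxon_symmetric_pair():
    res = wilcoxon_signed_rank([1.0, -1.0])
    assert res.w_plus == res.w_minus
    assert res.p_value == 1.0


def test_wilcoxon_degenerate():
    with pytest.raises(ValueError, match="degenerate"):
        wilcoxon_signed_rank([0.0, 0.0])


@pytest.mark.parametrize("seed", range(20))
def test_wilcoxon_exact_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 13))
    d = np.round(rng.normal(0.4, 1.0, n), 1)  # rounding creates ties/zeros
    if np.all(d == 0):
        d[0] = 0.5
    res = wilcoxon_signed_rank(d)
    assert res.p_value == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_wilcoxon_approx_matches_scipy(seed):
    rng = np.random.default_rng(seed)
    d = rng.normal(0.3, 1.0, 40)
    res = wilcoxon_signed_rank(d)
    ref = sps.wilcoxon(d, correction=True, method="approx")
    assert res.method == "approx"
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)
    assert abs(res.z) == pytest.approx(abs(ref.zstatistic), rel=1e-10)


def test_wilcoxon_sign_convention():
    # x systematically below y -> negative z (the usual reporting direction)
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 30)
    res = wilcoxon_signed_rank(x, x + 1.0)
    assert res.z < 0 and res.p_value < 0.01


def _toy_dataset(rng, n_participants=16, effect=("MPDC", "PD")):
    rows = []
    for i in range(n_participants):
        for level, world in [("L1a", "A"), ("L2a", "A"), ("L3b", "B"),
                             ("L4b", "B")]:
            base = {f: rng.normal(10, 1) for f in ALL_FEATURES}
            if world == "B":
                for f in effect:
                    base[f] += 5.0
            rows.append({"participant_id": f"p{i:02d}", "level_id": level,
                         "world": world, **base})
    return pd.DataFrame(rows)


def test_select_features_finds_injected_effect(rng):
    # strict alpha keeps the six null features out with high probability
    sets = select_features(_toy_dataset(rng), alpha=0.005)
    assert sets.p_selected == ("MPDC", "PD")
    assert set(sets.g_selected) == set()


def test_select_features_alpha_one_selects_all(rng):
    sets = select_features(_toy_dataset(rng), alpha=1.0)
    assert set(sets.g_selected + sets.p_selected) == set(ALL_FEATURES)


def test_select_features_invariant_to_participant_relabeling(rng):
    df = _toy_dataset(rng)
    relabeled = df.copy()
    relabeled["participant_id"] = "z_" + relabeled["participant_id"]
    a = select_features(df)
    b = select_features(relabeled)
    assert a.g_selected == b.g_selected and a.p_selected == b.p_selected
    for f in ALL_FEATURES:
        assert a.results[f].p_value == b.results[f].p_value


def test_select_features_drops_incomplete_participants(rng):
    df = _toy_dataset(rng)
    df = df[~((df.participant_id == "p00") & (df.world == "B"))]
    with pytest.warns(UserWarning, match="missing a world"):
        sets = select_features(df)
    assert sets.p_selected == ("MPDC", "PD")


def test_rm_anova_two_conditions_epsilon_is_one(rng):
    res = rm_anova_gg(rng.normal(0, 1, size=(10, 2)))
    assert res.epsilon_gg == 1.0
    assert res.p_gg == pytest.approx(res.p_uncorrected, rel=1e-12)


def test_rm_anova_epsilon_bounds(rng):
    res = rm_anova_gg(rng.normal(0, 1, size=(14, 6)))
    assert 0.2 <= res.epsilon_gg <= 1.0
    assert res.mauchly_df == 14  # k = 6 conditions


def test_rm_anova_rejects_missing_cells(rng):
    y = rng.normal(0, 1, size=(10, 3))
    y[2, 1] = np.nan
    with pytest.raises(ValueError, match="missing"):
        rm_anova_gg(y)


@pytest.mark.parametrize("seed,shape", [(0, (14, 6)), (1, (12, 4)), (2, (9, 3))])
def test_rm_anova_matches_pingouin_oracle(seed, shape):
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(seed)
    subj_eff = rng.normal(0, 1.0, size=(shape[0], 1))
    y = subj_eff + rng.normal(0, 1, size=shape) @ rng.uniform(
        0.4, 1.2, size=(shape[1], shape[1]))
    res = rm_anova_gg(y)
    df = pd.DataFrame(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sph = pg.sphericity(df)
        eps = pg.epsilon(df, correction="gg")
        aov = pg.rm_anova(df, correction=True)
    row = aov.iloc[0]
    assert res.f == pytest.approx(row["F"], rel=1e-8)
    assert res.p_uncorrected == pytest.approx(row["p_unc"], rel=1e-8)
    assert res.epsilon_gg == pytest.approx(eps, rel=1e-8)
    assert res.mauchly_w == pytest.approx(sph.W, rel=1e-8)
    assert res.mauchly_chi2 == pytest.approx(sph.chi2, rel=1e-8)
    assert res.mauchly_p == pytest.approx(sph.pval, rel=1e-8)
    assert res.p_gg == pytest.approx(row["p_GG_corr"], rel=1e-6)


def test_bonferroni_combinatorics(rng):
    res = bonferroni_pairwise(rng.normal(0, 1, size=(12, 6)))
    assert len(res.p_raw) == 15
    assert res.alpha_adjusted == pytest.approx(0.05 / 15)


def test_bonferroni_null_data_single_group(rng):
    y = rng.normal(0, 1, size=(12, 4))
    res = bonferroni_pairwise(y)
    assert len(res.groups) == 1  # no pair separates at alpha/6


def test_bonferroni_grouping_pattern(rng):
    # three separated singleton conditions plus a tight cluster of three
    s = 14
    base = rng.normal(0, 0.3, size=(s, 6))
    shifts = np.array([8.0, -8.0, 4.0, 0.0, 0.05, -0.05])
    y = base + shifts
    names = ("white", "black", "scramble", "g1", "g2", "g3")
    res = bonferroni_pairwise(y, condition_names=names)
    labels = res.group_labels()
    assert labels["g1"] == labels["g2"] == labels["g3"]
    assert len({labels["white"], labels["black"], labels["scramble"],
                labels["g1"]}) == 4
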