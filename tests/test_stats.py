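"""Split-plot decomposition, sphericity correction, effect sizes, post hoc."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from padvoice.core import round_half_away
from padvoice.pad import list_emotions
from padvoice.stats import (
    _rm_anova_one_gender,
    fit_mixed_anova,
    greenhouse_geisser_epsilon,
    marginal_means,
    omega_squared,
    posthoc_pairwise,
    simple_main_effects,
    split_plot_ss,
    validate_feature_table,
)

EMOTIONS = [e.label for e in list_emotions()]

# published velocity grid (s/word): female, male columns per state
VELOCITY_CELLS = pd.DataFrame(
    {
        "neutral": [0.29, 0.26],
        "exuberant": [0.28, 0.24],
        "bored": [0.52, 0.48],
        "dependent": [0.38, 0.36],
        "disdainful": [0.29, 0.25],
        "relaxed": [0.34, 0.30],
        "anxious": [0.26, 0.21],
        "docile": [0.33, 0.28],
        "hostile": [0.28, 0.24],
    },
    index=["female", "male"],
)


class TestMarginalMeans:
    def test_velocity_grid_marginals(self):
        m = marginal_means(VELOCITY_CELLS)
        assert round_half_away(m["state"]["bored"]) == 0.50
        assert round_half_away(m["state"]["neutral"]) == 0.28
        assert round_half_away(m["gender"]["female"]) == 0.33
        assert round_half_away(m["gender"]["male"]) == 0.29

    def test_single_cell_identity(self):
        one = pd.DataFrame({"neutral": [0.4]}, index=["female"])
        m = marginal_means(one)
        assert m["grand"] == pytest.approx(0.4)

    def test_missing_cells_error(self):
        bad = VELOCITY_CELLS.copy()
        bad.loc["male", "bored"] = np.nan
        with pytest.raises(ValueError):
            marginal_means(bad)


def brute_force_ss(female, male):
    """Independent loop-based split-plot decomposition (balanced designs)."""
    k = female.shape[1]
    all_obs = np.vstack([female, male])
    gm = all_obs.mean()
    ss_total = sum((y - gm) ** 2 for y in all_obs.ravel())
    mats = {"f": female, "m": male}
    # between-subject stratum
    subj_means = {(g, i): mats[g][i].mean() for g in mats for i in range(mats[g].shape[0])}
    grp_means = {g: mats[g].mean() for g in mats}
    ss_between = k * sum((v - gm) ** 2 for v in subj_means.values())
    ss_gender = k * sum(
        mats[g].shape[0] * (grp_means[g] - gm) ** 2 for g in mats
    )
    ss_block = ss_between - ss_gender
    # within stratum
    state_means = all_obs.mean(axis=0)
    ss_state = all_obs.shape[0] * sum((m - gm) ** 2 for m in state_means)
    cell = {g: mats[g].mean(axis=0) for g in mats}
    ss_inter = sum(
        mats[g].shape[0] * (cell[g][j] - grp_means[g] - state_means[j] + gm) ** 2
        for g in mats
        for j in range(k)
    )
    ss_error = ss_total - ss_between - ss_state - ss_inter
    return dict(
        ss_gender=ss_gender, ss_block=ss_block, ss_state=ss_state,
        ss_inter=ss_inter, ss_error=ss_error, ss_total=ss_total,
    )


class TestSplitPlotDecomposition:
    def test_tiny_fixture_matches_brute_force(self):
        # 2 genders x 3 subjects x 9 states, hand-seeded integers
        rng = np.random.default_rng(12)
        female = rng.integers(0, 10, (3, 9)).astype(float)
        male = rng.integers(0, 10, (3, 9)).astype(float)
        ours = split_plot_ss(female, male)
        ref = brute_force_ss(female, male)
        for key in ("ss_gender", "ss_block", "ss_state", "ss_inter", "ss_error"):
            assert ours[key] == pytest.approx(ref[key], rel=1e-10, abs=1e-10)

    def test_total_ss_decomposes(self):
        rng = np.random.default_rng(3)
        female = rng.normal(0, 1, (8, 9))
        male = rng.normal(0.3, 1.2, (8, 9))
        d = split_plot_ss(female, male)
        total = ((np.vstack([female, male]) - np.vstack([female, male]).mean()) ** 2).sum()
        parts = d["ss_gender"] + d["ss_block"] + d["ss_state"] + d["ss_inter"] + d["ss_error"]
        assert parts == pytest.approx(total, rel=1e-8)

    def test_uncorrected_dfs(self, make_long_table, rng):
        tab = make_long_table(rng.normal(0, 1, (31, 9)), rng.normal(0, 1, (31, 9)))
        res = fit_mixed_anova(tab, "x")
        t = res.table
        assert t.loc["gender", "df_uncorrected"] == 1
        assert t.loc["state", "df_uncorrected"] == 8
        assert t.loc["gender_x_state", "df_uncorrected"] == 8
        assert t.loc["block", "df_uncorrected"] == 60
        assert t.loc["error", "df_uncorrected"] == 480

    def test_two_level_within_factor_equals_paired_t_squared(self, rng):
        mat = rng.normal(0, 1, (12, 2)) + np.array([0.0, 0.4])
        _, df1, df2, f, p, _ = _rm_anova_one_gender(mat, epsilon_correction=False)
        t = sps.ttest_rel(mat[:, 0], mat[:, 1])
        assert f == pytest.approx(t.statistic**2, rel=1e-10)
        assert p == pytest.approx(t.pvalue, rel=1e-10)


class TestGreenhouseGeisser:
    def test_compound_symmetry_gives_one(self):
        k = 9
        cov = 0.4 * np.ones((k, k)) + 0.6 * np.eye(k)
        assert greenhouse_geisser_epsilon(cov) == pytest.approx(1.0)

    def test_rank_one_gives_lower_bound(self):
        v = np.arange(1.0, 10.0)
        cov = np.outer(v, v)
        assert greenhouse_geisser_epsilon(cov) == pytest.approx(1 / 8)

    def test_matches_naive_eigenvalue_formula(self, rng):
        k = 9
        a = rng.normal(0, 1, (30, k))
        cov = np.cov(a, rowvar=False)
        h = np.eye(k) - np.ones((k, k)) / k
        lam = np.linalg.eigvalsh(h @ cov @ h)
        naive = lam.sum() ** 2 / ((k - 1) * (lam**2).sum())
        assert greenhouse_geisser_epsilon(cov) == pytest.approx(naive, abs=1e-10)

    def test_epsilon_bounds_in_fit(self, make_long_table, rng):
        tab = make_long_table(rng.normal(0, 1, (10, 9)), rng.normal(0, 1, (10, 9)))
        res = fit_mixed_anova(tab, "x")
        assert 1 / 8 <= res.epsilon_gg <= 1.0


class TestAgainstIndependentReference:
    def test_f_statistics_match_pingouin(self, make_long_table, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(10):
            female = rng.normal(0, 1, (9, 9)) + rng.normal(0, 0.5, 9)
            male = rng.normal(0.2, 1.1, (9, 9))
            tab = make_long_table(female, male)
            res = fit_mixed_anova(tab, "x", epsilon_correction=False)
            aov = pg.mixed_anova(
                data=tab.rename(columns={"subject_id": "subj"}),
                dv="value", within="emotion", between="gender", subject="subj",
            ).set_index("Source")
            assert res.table.loc["gender", "F"] == pytest.approx(
                float(aov.loc["gender", "F"]), rel=1e-6
            )
            assert res.table.loc["state", "F"] == pytest.approx(
                float(aov.loc["emotion", "F"]), rel=1e-6
            )
            assert res.table.loc["gender_x_state", "F"] == pytest.approx(
                float(aov.loc["Interaction", "F"]), rel=1e-6
            )


class TestOmegaSquared:
    def test_zero_effect_floors_at_zero(self, make_long_table, rng):
        base = rng.normal(0, 1, (15, 1)) * np.ones((1, 9))
        noise = rng.normal(0, 0.5, (30, 9))
        female, male = base + noise[:15], base + noise[15:]
        # force identical cell means so SS_state is ~0
        female -= female.mean(axis=0)
        male -= male.mean(axis=0)
        tab = make_long_table(female, male)
        res = fit_mixed_anova(tab, "x")
        assert omega_squared(res, "state") == 0.0

    def test_increases_with_interaction_strength(self, make_long_table, rng):
        omegas = []
        pattern = np.linspace(-1, 1, 9)
        for scale in (0.0, 0.5, 1.5):
            female = rng.normal(0, 1, (20, 9)) + scale * pattern
            male = rng.normal(0, 1, (20, 9)) - scale * pattern
            res = fit_mixed_anova(make_long_table(female, male), "x")
            omegas.append(omega_squared(res, "gender_x_state"))
        assert omegas[0] < omegas[1] < omegas[2]


class TestSimpleEffectsAndPosthoc:
    def test_gender_direction_flips_with_labels(self, make_long_table, rng):
        female = rng.normal(1.0, 0.3, (12, 9))
        male = rng.normal(0.0, 0.3, (12, 9))
        eff = simple_main_effects(make_long_table(female, male), "x")
        swapped = simple_main_effects(make_long_table(male, female), "x")
        for emo in EMOTIONS:
            d1 = eff.gender_within_state.loc[emo, "direction"]
            d2 = swapped.gender_within_state.loc[emo, "direction"]
            assert d1 == "female > male"
            assert d2 == "male > female"

    def test_all_equal_means_yield_empty_posthoc(self, make_long_table, rng):
        noise = rng.normal(0, 1, (10, 1)) * np.ones((1, 9))
        female = noise + rng.normal(0, 0.01, (10, 9))
        male = rng.normal(0, 0.01, (10, 9))
        # no state structure at all: differences are pure noise
        res = posthoc_pairwise(make_long_table(female, male), "x", alpha=1e-6)
        assert res.pairs == []

    def test_adjusted_p_not_below_raw(self, make_long_table, rng):
        female = rng.normal(0, 1, (10, 9)) + np.linspace(0, 2, 9)
        male = rng.normal(0, 1, (10, 9)) + np.linspace(0, 2, 9)
        tab = make_long_table(female, male)
        mat = np.vstack([female, male])
        res = posthoc_pairwise(tab, "x", alpha=0.05)
        for i, j, p_adj in res.pairs:
            a, b = i - 1, j - 1
            raw = sps.ttest_rel(mat[:, a], mat[:, b]).pvalue
            assert p_adj >= raw - 1e-15

    def test_posthoc_no_pair_in_both_directions(self, make_long_table, rng):
        female = rng.normal(0, 1, (15, 9)) + np.linspace(0, 3, 9)
        male = rng.normal(0, 1, (15, 9)) + np.linspace(0, 3, 9)
        res = posthoc_pairwise(make_long_table(female, male), "x")
        seen = {(i, j) for i, j, _ in res.pairs}
        assert not any((j, i) in seen for i, j in seen)

    def test_notation_format(self, make_long_table):
        rng = np.random.default_rng(99)
        female = rng.normal(0, 0.1, (15, 9))
        female[:, 2] += 5.0  # state 3 (bored) far above the rest
        male = female + rng.normal(0, 0.1, (15, 9))
        res = posthoc_pairwise(make_long_table(female, male), "x")
        assert res.notation().startswith("(3) > (1), (2), (4)")


class TestValidation:
    def test_incomplete_subject_dropped(self, make_long_table, rng):
        tab = make_long_table(rng.normal(0, 1, (5, 9)), rng.normal(0, 1, (5, 9)))
        tab = tab[~((tab.subject_id == "f000") & (tab.emotion == "bored"))]
        cleaned = validate_feature_table(tab)
        assert "f000" not in set(cleaned["subject_id"])

    def test_subject_in_two_genders_rejected(self, make_long_table, rng):
        tab = make_long_table(rng.normal(0, 1, (3, 9)), rng.normal(0, 1, (3, 9)))
        tab.loc[tab.index[-1], "subject_id"] = "f000"
        with pytest.raises(ValueError):
            validate_feature_table(tab)

    def test_minimum_group_size(self, make_long_table, rng):
        with pytest.raises(ValueError):
            split_plot_ss(rng.normal(0, 1, (1, 9)), rng.normal(0, 1, (5, 9)))
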