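"""Two-way mixed-design (split-plot) ANOVA for the study layout.

One between-subjects factor (gender, 2 levels) crossed with one
within-subjects factor (emotional state, 9 levels), subject as random
block.  The within-stratum tests carry a Greenhouse-Geisser sphericity
correction; effect sizes are partial omega squared; simple main effects and
pairwise post hoc orderings mirror the study's reporting layout.

The sums-of-squares decomposition is:

    between stratum:  SS_gender   vs  SS_block (subjects within gender)
    within  stratum:  SS_state, SS_interaction  vs  SS_error
                      (state x subjects within gender)

computed from unweighted cell means with harmonic-mean group size, which
reduces to the classical balanced decomposition when group sizes are equal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .pad import list_emotions

logger = logging.getLogger(__name__)

GENDERS = ("female", "male")
FEATURE_COLUMNS = ("subject_id", "gender", "emotion", "feature", "value")


# ---------------------------------------------------------------------------
# FeatureTable handling


def validate_feature_table(df: pd.DataFrame) -> pd.DataFrame:
    """Schema check plus listwise deletion of incomplete subjects.

    A subject must contribute all nine emotions for each feature analysed;
    subjects failing this are dropped with a logged warning.  Subject IDs
    must be nested in exactly one gender.
    """
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    df = df.copy()
    genders_per_subject = df.groupby("subject_id")["gender"].nunique()
    bad = genders_per_subject[genders_per_subject > 1]
    if len(bad):
        raise ValueError(f"subjects in more than one gender: {list(bad.index)}")
    k = len(list_emotions())
    counts = (
        df.dropna(subset=["value"])
        .groupby(["feature", "subject_id"])["emotion"]
        .nunique()
    )
    incomplete = counts[counts < k]
    if len(incomplete):
        drop = set(incomplete.index)
        logger.warning(
            "dropping %d incomplete (feature, subject) combinations", len(drop)
        )
        mask = df.set_index(["feature", "subject_id"]).index.isin(drop)
        df = df[~np.asarray(mask)]
    return df


def feature_matrices(
    df: pd.DataFrame, feature: str
) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per gender: ordered subject IDs and the (subjects x 9 states) matrix."""
    emotions = [e.label for e in list_emotions()]
    sub = df[(df["feature"] == feature) & df["value"].notna()]
    if sub.empty:
        raise ValueError(f"no rows for feature {feature!r}")
    out = {}
    for gender in GENDERS:
        g = sub[sub["gender"] == gender]
        wide = g.pivot_table(
            index="subject_id", columns="emotion", values="value", aggfunc="mean"
        )
        wide = wide.dropna().reindex(columns=emotions)
        if wide.isna().any().any():
            wide = wide.dropna()
        out[gender] = (list(wide.index), wide.to_numpy(float))
    return out


# ---------------------------------------------------------------------------
# Core decomposition


def split_plot_ss(female: np.ndarray, male: np.ndarray) -> dict[str, float]:
    """Sums of squares and dfs of the two-group split-plot design.

    ``female`` and ``male`` are (subjects x states) matrices with the same
    number of states.
    """
    mats = (np.asarray(female, float), np.asarray(male, float))
    k = mats[0].shape[1]
    if mats[1].shape[1] != k:
        raise ValueError("state dimension mismatch")
    n = [m.shape[0] for m in mats]
    if min(n) < 2:
        raise ValueError("need at least two subjects per gender")
    n_subj = sum(n)
    nh = 2.0 / (1.0 / n[0] + 1.0 / n[1])

    cell = np.vstack([m.mean(axis=0) for m in mats])  # (2, k)
    m_g = cell.mean(axis=1)
    m_s = cell.mean(axis=0)
    gm = cell.mean()

    ss_gender = k * (m_g[0] - m_g[1]) ** 2 / (1.0 / n[0] + 1.0 / n[1])
    ss_state = 2.0 * nh * float(((m_s - gm) ** 2).sum())
    ss_inter = nh * float(
        ((cell - m_g[:, None] - m_s[None, :] + gm) ** 2).sum()
    )

    ss_block = 0.0
    ss_error = 0.0
    for gi, m in enumerate(mats):
        subj_means = m.mean(axis=1)
        group_mean = subj_means.mean()
        ss_block += k * float(((subj_means - group_mean) ** 2).sum())
        resid = m - cell[gi][None, :] - subj_means[:, None] + group_mean
        ss_error += float((resid**2).sum())

    return {
        "ss_gender": ss_gender,
        "ss_state": ss_state,
        "ss_inter": ss_inter,
        "ss_block": ss_block,
        "ss_error": ss_error,
        "df_gender": 1.0,
        "df_block": float(n_subj - 2),
        "df_state": float(k - 1),
        "df_inter": float(k - 1),
        "df_error": float((k - 1) * (n_subj - 2)),
        "n_subjects": n_subj,
        "n_states": k,
    }


def greenhouse_geisser_epsilon(within_covariance: np.ndarray) -> float:
    """GG sphericity estimate from the subject-by-state covariance.

    epsilon = (sum lambda)^2 / ((k-1) sum lambda^2) on the eigenvalues of
    the double-centered covariance, clamped to [1/(k-1), 1].
    """
    s = np.asarray(within_covariance, float)
    k = s.shape[0]
    if s.shape != (k, k):
        raise ValueError("covariance must be square")
    h = np.eye(k) - np.ones((k, k)) / k
    c = h @ s @ h
    tr = float(np.trace(c))
    tr2 = float(np.trace(c @ c))
    lower = 1.0 / (k - 1)
    if tr2 <= 0 or tr <= 0:
        logger.warning("degenerate within-covariance; epsilon at lower bound")
        return lower
    eps = tr**2 / ((k - 1) * tr2)
    return float(np.clip(eps, lower, 1.0))


def _pooled_covariance(mats: list[np.ndarray]) -> np.ndarray:
    num = sum((m.shape[0] - 1) * np.cov(m, rowvar=False) for m in mats)
    den = sum(m.shape[0] - 1 for m in mats)
    return np.asarray(num) / den


# ---------------------------------------------------------------------------
# Results


@dataclass
class MixedAnovaResult:
    """ANOVA table plus the descriptive grids it was computed from."""

    table: pd.DataFrame  # index: gender, state, gender_x_state, block, error
    epsilon_gg: float
    cell_means: pd.DataFrame  # genders x emotions
    marginal_means: dict
    feature: str
    alpha: float
    n_subjects: int
    n_obs: int


@dataclass
class PosthocResult:
    """Directional significant pairs in ordinal-ID notation."""

    pairs: list[tuple[int, int, float]]  # (winner_id, loser_id, p_adjusted)
    method: str
    alpha: float

    def notation(self) -> str:
        """Paper-style grouped ordering, e.g. '(3) > (1), (2); (4) > (7)'."""
        by_winner: dict[int, list[int]] = {}
        for i, j, _ in self.pairs:
            by_winner.setdefault(i, []).append(j)
        parts = []
        for i in sorted(by_winner):
            losers = ", ".join(f"({j})" for j in sorted(by_winner[i]))
            parts.append(f"({i}) > {losers}")
        return "; ".join(parts)


@dataclass
class SimpleEffectsResult:
    """State-within-gender and gender-within-state simple main effects."""

    state_within_gender: pd.DataFrame  # per gender: F, df1, df2, p, epsilon
    state_posthoc: dict[str, PosthocResult]
    gender_within_state: pd.DataFrame  # per emotion: F, df, p, means, direction
    alpha: float


# ---------------------------------------------------------------------------
# Operations


def marginal_means(cell_means: pd.DataFrame) -> dict:
    """Unweighted marginals of a genders-by-states cell-mean grid."""
    if cell_means.isna().any().any():
        raise ValueError("cell-mean grid has missing cells")
    return {
        "state": cell_means.mean(axis=0),
        "gender": cell_means.mean(axis=1),
        "grand": float(cell_means.to_numpy().mean()),
    }


def fit_mixed_anova(
    df: pd.DataFrame,
    feature: str,
    alpha: float = 0.05,
    epsilon_correction: bool = True,
) -> MixedAnovaResult:
    """Fit the gender x state split-plot ANOVA for one feature.

    With the correction enabled, within-stratum dfs (state, interaction,
    error) are multiplied by the GG epsilon; MS is reported at the corrected
    df as in standard software output, leaving F unchanged.
    """
    df = validate_feature_table(df)
    mats = feature_matrices(df, feature)
    female, male = mats["female"][1], mats["male"][1]
    d = split_plot_ss(female, male)
    k = d["n_states"]
    n_subj = d["n_subjects"]

    eps = greenhouse_geisser_epsilon(_pooled_covariance([female, male]))
    scale = eps if epsilon_correction else 1.0

    rows = {}
    df_state = d["df_state"] * scale
    df_error = d["df_error"] * scale
    ms_state = d["ss_state"] / df_state
    ms_inter = d["ss_inter"] / df_state
    ms_error = d["ss_error"] / df_error
    ms_block = d["ss_block"] / d["df_block"]
    ms_gender = d["ss_gender"] / d["df_gender"]

    f_gender = ms_gender / ms_block
    f_state = ms_state / ms_error
    f_inter = ms_inter / ms_error

    rows["gender"] = (
        d["ss_gender"], d["df_gender"], ms_gender, f_gender,
        float(sps.f.sf(f_gender, d["df_gender"], d["df_block"])),
    )
    rows["state"] = (
        d["ss_state"], df_state, ms_state, f_state,
        float(sps.f.sf(f_state, df_state, df_error)),
    )
    rows["gender_x_state"] = (
        d["ss_inter"], df_state, ms_inter, f_inter,
        float(sps.f.sf(f_inter, df_state, df_error)),
    )
    rows["block"] = (d["ss_block"], d["df_block"], ms_block, np.nan, np.nan)
    rows["error"] = (d["ss_error"], df_error, ms_error, np.nan, np.nan)

    table = pd.DataFrame(
        rows, index=["SS", "df", "MS", "F", "p"]
    ).T
    table["df_uncorrected"] = [
        d["df_gender"], d["df_state"], d["df_inter"], d["df_block"], d["df_error"],
    ]

    emotions = [e.label for e in list_emotions()]
    cell = pd.DataFrame(
        np.vstack([female.mean(axis=0), male.mean(axis=0)]),
        index=list(GENDERS),
        columns=emotions,
    )
    n_obs = n_subj * k
    result = MixedAnovaResult(
        table=table,
        epsilon_gg=eps,
        cell_means=cell,
        marginal_means=marginal_means(cell),
        feature=feature,
        alpha=alpha,
        n_subjects=n_subj,
        n_obs=n_obs,
    )
    table["omega_sq"] = [
        omega_squared(result, e) for e in table.index
    ]
    return result


def omega_squared(result: MixedAnovaResult, effect: str) -> float:
    """Partial omega squared against the effect's own error stratum.

    (SS_eff - df_eff * MS_err) / (SS_eff + (n_obs - df_eff) * MS_err),
    floored at zero; uncorrected dfs are used.
    """
    t = result.table
    if effect not in ("gender", "state", "gender_x_state"):
        return float("nan")
    err = "block" if effect == "gender" else "error"
    ss_eff = float(t.loc[effect, "SS"])
    df_eff = float(t.loc[effect, "df_uncorrected"])
    ms_err = float(t.loc[err, "SS"]) / float(t.loc[err, "df_uncorrected"])
    num = ss_eff - df_eff * ms_err
    den = ss_eff + (result.n_obs - df_eff) * ms_err
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def _rm_anova_one_gender(mat: np.ndarray, epsilon_correction: bool = True):
    """One-way repeated-measures ANOVA within a single gender."""
    n, k = mat.shape
    cell = mat.mean(axis=0)
    subj = mat.mean(axis=1)
    grand = mat.mean()
    ss_state = n * float(((cell - grand) ** 2).sum())
    resid = mat - cell[None, :] - subj[:, None] + grand
    ss_err = float((resid**2).sum())
    eps = greenhouse_geisser_epsilon(np.cov(mat, rowvar=False))
    scale = eps if epsilon_correction else 1.0
    df1 = (k - 1) * scale
    df2 = (k - 1) * (n - 1) * scale
    f = (ss_state / df1) / (ss_err / df2)
    p = float(sps.f.sf(f, df1, df2))
    return ss_state, df1, df2, f, p, eps


def posthoc_pairwise(
    df: pd.DataFrame,
    feature: str,
    scope: str = "pooled",
    alpha: float = 0.05,
    method: str = "bonferroni",
) -> PosthocResult:
    """Paired comparisons of all 36 state pairs within the given scope.

    ``scope`` is 'pooled', 'female' or 'male'.  Adjusted p-values use the
    configured method; significant pairs are emitted as directional
    orderings (winner ordinal ID) > (loser ordinal ID).
    """
    df = validate_feature_table(df)
    mats = feature_matrices(df, feature)
    if scope == "pooled":
        mat = np.vstack([mats["female"][1], mats["male"][1]])
    elif scope in GENDERS:
        mat = mats[scope][1]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    emotions = list_emotions()
    k = len(emotions)
    raw, pairs_meta = [], []
    for a in range(k):
        for b in range(a + 1, k):
            diff = mat[:, a] - mat[:, b]
            if np.allclose(diff.std(ddof=1), 0.0):
                p = 1.0 if np.allclose(diff.mean(), 0.0) else 0.0
            else:
                p = float(sps.ttest_rel(mat[:, a], mat[:, b]).pvalue)
            raw.append(p)
            pairs_meta.append((a, b, float(diff.mean())))
    reject, p_adj, _, _ = multipletests(raw, alpha=alpha, method=method)
    pairs = []
    for (a, b, delta), rej, p in zip(pairs_meta, reject, p_adj):
        if rej and delta != 0.0:
            winner, loser = (a, b) if delta > 0 else (b, a)
            pairs.append(
                (emotions[winner].ordinal_id, emotions[loser].ordinal_id, float(p))
            )
    pairs.sort()
    return PosthocResult(pairs=pairs, method=method, alpha=alpha)


def simple_main_effects(
    df: pd.DataFrame,
    feature: str,
    alpha: float = 0.05,
    gender_test: str = "welch",
    posthoc_method: str = "bonferroni",
) -> SimpleEffectsResult:
    """Simple main effects in the study's reporting layout.

    State within gender: one-way repeated-measures ANOVA per gender with its
    own GG correction plus a pairwise post hoc ordering.  Gender within
    state: an independent two-sample comparison per emotion (Welch by
    default, 'pooled' mirrors equal-variance software defaults); the
    direction and both means are reported only when significant.
    """
    df = validate_feature_table(df)
    mats = feature_matrices(df, feature)
    emotions = list_emotions()

    sw_rows = {}
    posthocs = {}
    for gender in GENDERS:
        mat = mats[gender][1]
        ss, df1, df2, f, p, eps = _rm_anova_one_gender(mat)
        sw_rows[gender] = {
            "SS": ss, "df1": df1, "df2": df2, "F": f, "p": p, "epsilon": eps,
        }
        posthocs[gender] = posthoc_pairwise(
            df, feature, scope=gender, alpha=alpha, method=posthoc_method
        )
    state_within = pd.DataFrame(sw_rows).T

    gw_rows = []
    female, male = mats["female"][1], mats["male"][1]
    for si, emotion in enumerate(emotions):
        a, b = female[:, si], male[:, si]
        equal_var = gender_test == "pooled"
        t = sps.ttest_ind(a, b, equal_var=equal_var)
        mf, mm = float(a.mean()), float(b.mean())
        signif = t.pvalue < alpha
        if signif:
            direction = "female > male" if mf > mm else "male > female"
        else:
            direction = ""
        gw_rows.append(
            {
                "emotion": emotion.label,
                "F": float(t.statistic**2),
                "df": float(t.df),
                "p": float(t.pvalue),
                "mean_female": mf,
                "mean_male": mm,
                "significant": bool(signif),
                "direction": direction,
            }
        )
    gender_within = pd.DataFrame(gw_rows).set_index("emotion")
    return SimpleEffectsResult(
        state_within_gender=state_within,
        state_posthoc=posthocs,
        gender_within_state=gender_within,
        alpha=alpha,
    )
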