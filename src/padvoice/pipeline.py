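"""End-to-end study runs: synthesize -> extract -> analyze -> report.

A run is fully reproducible from a StudyConfig: the cohort seed drives
synthesis, and every downstream number is a deterministic function of the
generated audio and the statistics options.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pvio
from .core import AcousticFeatureVector, round_half_away
from .features import ExtractionConfig, extract_features
from .pad import list_emotions
from .presets import build_emotion_presets, generate_cohort
from .stats import (
    GENDERS,
    MixedAnovaResult,
    PosthocResult,
    SimpleEffectsResult,
    fit_mixed_anova,
    posthoc_pairwise,
    simple_main_effects,
)

logger = logging.getLogger(__name__)

FEATURES = list(AcousticFeatureVector.FEATURE_NAMES)


@dataclass
class StudyConfig:
    """Everything needed to reproduce a run."""

    n_female: int = 31
    n_male: int = 31
    seed: int = 0
    between_subject_sd: float | dict | None = None
    n_words: int = 9
    pause_fraction: float = 0.2
    alpha: float = 0.05
    posthoc_method: str = "bonferroni"
    gender_test: str = "welch"
    epsilon_correction: bool = True
    min_voiced_fraction: float = 0.3
    features: list = field(default_factory=lambda: list(FEATURES))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class FeatureAnalysis:
    anova: MixedAnovaResult
    simple_effects: SimpleEffectsResult
    posthoc_pooled: PosthocResult


@dataclass
class StudyReport:
    config: StudyConfig
    feature_table: pd.DataFrame
    truth_table: pd.DataFrame
    analyses: dict[str, FeatureAnalysis]
    qc: dict

    @property
    def provenance(self) -> dict:
        return {"config_digest": self.config.digest(), "seed": self.config.seed}


def cohort_feature_table(
    cfg: StudyConfig, extraction: ExtractionConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate the cohort and extract features from every utterance.

    Returns (feature table, ground-truth table, QC summary).  Utterances
    with voiced_fraction below the QC gate are flagged and excluded.
    """
    extraction = extraction or ExtractionConfig()
    presets = build_emotion_presets(
        n_words=cfg.n_words,
        pause_fraction=cfg.pause_fraction,
        between_subject_sd=cfg.between_subject_sd,
    )
    utterances, truth = generate_cohort(
        cfg.n_female, cfg.n_male, presets, seed=cfg.seed
    )
    rows = []
    voiced_fractions = []
    flagged = []
    for cu in utterances:
        vec = extract_features(cu.utterance, cfg=extraction)
        voiced_fractions.append(vec.voiced_fraction)
        if vec.voiced_fraction < cfg.min_voiced_fraction:
            flagged.append((cu.subject_id, cu.emotion.label))
            logger.warning(
                "QC: excluding %s/%s (voiced_fraction=%.2f)",
                cu.subject_id, cu.emotion.label, vec.voiced_fraction,
            )
            continue
        for name, value in vec.as_dict().items():
            if name in ("n_periods", "voiced_fraction"):
                continue
            rows.append(
                {
                    "subject_id": cu.subject_id,
                    "gender": cu.gender,
                    "emotion": cu.emotion.label,
                    "feature": name,
                    "value": value,
                }
            )
    table = pd.DataFrame(rows)
    qc = {
        "n_utterances": len(utterances),
        "n_excluded": len(flagged),
        "excluded": flagged,
        "voiced_fraction_mean": float(np.mean(voiced_fractions)),
        "voiced_fraction_min": float(np.min(voiced_fractions)),
    }
    return table, truth, qc


def analyze_feature_table(cfg: StudyConfig, table: pd.DataFrame) -> dict:
    analyses = {}
    for feature in cfg.features:
        anova = fit_mixed_anova(
            table, feature, alpha=cfg.alpha,
            epsilon_correction=cfg.epsilon_correction,
        )
        effects = simple_main_effects(
            table, feature, alpha=cfg.alpha,
            gender_test=cfg.gender_test, posthoc_method=cfg.posthoc_method,
        )
        pooled = posthoc_pairwise(
            table, feature, scope="pooled", alpha=cfg.alpha,
            method=cfg.posthoc_method,
        )
        analyses[feature] = FeatureAnalysis(anova, effects, pooled)
    return analyses


def run_study(
    cfg: StudyConfig, extraction: ExtractionConfig | None = None
) -> StudyReport:
    """Full pipeline: cohort synthesis, feature extraction, statistics."""
    table, truth, qc = cohort_feature_table(cfg, extraction)
    analyses = analyze_feature_table(cfg, table)
    return StudyReport(
        config=cfg, feature_table=table, truth_table=truth,
        analyses=analyses, qc=qc,
    )


# ---------------------------------------------------------------------------
# Rendering


def _fmt(x: float, nd: int = 2) -> str:
    if isinstance(x, float) and not np.isfinite(x):
        return ""
    return f"{round_half_away(float(x), nd):.{nd}f}"


def _stars(p: float, alpha: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return ""


def render_cell_grid(anova: MixedAnovaResult) -> str:
    """Fine grid of cell and marginal means (descriptives layout)."""
    cell = anova.cell_means
    marg = anova.marginal_means
    lines = [f"Feature: {anova.feature}", "state\tfemale\tmale\tmarginal"]
    for emotion in list_emotions():
        e = emotion.label
        lines.append(
            f"{e}\t{_fmt(cell.loc['female', e])}\t{_fmt(cell.loc['male', e])}"
            f"\t{_fmt(marg['state'][e])}"
        )
    lines.append(
        f"marginal\t{_fmt(marg['gender']['female'])}"
        f"\t{_fmt(marg['gender']['male'])}\t{_fmt(marg['grand'])}"
    )
    return "\n".join(lines)


def render_anova_abstract(analysis: FeatureAnalysis) -> str:
    """Two-way ANOVA abstract with the pooled post hoc ordering."""
    a = analysis.anova
    t = a.table
    lines = [
        f"Two-way mixed ANOVA: {a.feature} "
        f"(GG epsilon = {a.epsilon_gg:.3f})",
        "effect\tSS\tDf\tMS\tF\tp\tomega_sq\tpost hoc",
    ]
    posthoc = {
        "state": analysis.posthoc_pooled.notation(),
        "gender": _gender_direction(a),
    }
    for effect in ("gender", "state", "gender_x_state", "block", "error"):
        r = t.loc[effect]
        fcell = (
            f"{_fmt(r['F'])}{_stars(r['p'], a.alpha)}" if np.isfinite(r["F"]) else ""
        )
        lines.append(
            f"{effect}\t{_fmt(r['SS'])}\t{_fmt(r['df'])}\t{_fmt(r['MS'])}"
            f"\t{fcell}\t{_fmt(r['p'], 4)}\t{_fmt(r.get('omega_sq', np.nan))}"
            f"\t{posthoc.get(effect, '')}"
        )
    return "\n".join(lines)


def _gender_direction(a: MixedAnovaResult) -> str:
    if a.table.loc["gender", "p"] >= a.alpha:
        return ""
    g = a.marginal_means["gender"]
    if g["female"] > g["male"]:
        return f"Female (M = {_fmt(g['female'])}) > Male (M = {_fmt(g['male'])})"
    return f"Male (M = {_fmt(g['male'])}) > Female (M = {_fmt(g['female'])})"


def render_simple_effects(analysis: FeatureAnalysis) -> str:
    """Simple-main-effects table in the per-feature reporting layout."""
    eff = analysis.simple_effects
    a = analysis.anova
    lines = [f"Simple main effects: {a.feature}", "STATE (within gender)"]
    for gender in GENDERS:
        r = eff.state_within_gender.loc[gender]
        lines.append(
            f"{gender}\tSS={_fmt(r['SS'])}\tDf={_fmt(r['df1'])}"
            f"\tF={_fmt(r['F'])}{_stars(r['p'], eff.alpha)}"
            f"\t{eff.state_posthoc[gender].notation()}"
        )
    lines.append("GENDER (within state)")
    for emotion in list_emotions():
        r = eff.gender_within_state.loc[emotion.label]
        if r["significant"]:
            hi, lo = (
                ("Female", "Male") if r["mean_female"] > r["mean_male"]
                else ("Male", "Female")
            )
            hi_m = max(r["mean_female"], r["mean_male"])
            lo_m = min(r["mean_female"], r["mean_male"])
            direction = f"{hi} (M = {_fmt(hi_m)}) > {lo} (M = {_fmt(lo_m)})"
        else:
            direction = ""
        lines.append(
            f"{emotion.label}\tF={_fmt(r['F'])}{_stars(r['p'], eff.alpha)}"
            f"\t{direction}"
        )
    return "\n".join(lines)


def render_report(report: StudyReport) -> dict[str, str]:
    """Pure rendering of a report to named text documents."""
    docs = {}
    summary = [
        "Study report",
        f"config digest: {report.provenance['config_digest']}",
        f"seed: {report.provenance['seed']}",
        f"utterances: {report.qc['n_utterances']} "
        f"(excluded by QC: {report.qc['n_excluded']})",
        f"voiced fraction: mean {_fmt(report.qc['voiced_fraction_mean'])}, "
        f"min {_fmt(report.qc['voiced_fraction_min'])}",
    ]
    docs["summary.txt"] = "\n".join(summary)
    for feature, analysis in report.analyses.items():
        docs[f"{feature}_grid.txt"] = render_cell_grid(analysis.anova)
        docs[f"{feature}_anova.txt"] = render_anova_abstract(analysis)
        docs[f"{feature}_simple_effects.txt"] = render_simple_effects(analysis)
    return docs


def write_report(report: StudyReport, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    pvio.write_feature_table(report.feature_table, out / "features.csv")
    paths.append(out / "features.csv")
    pvio.write_feature_table(report.truth_table, out / "ground_truth.csv")
    paths.append(out / "ground_truth.csv")
    for name, text in render_report(report).items():
        p = out / name
        p.write_text(text + "\n", encoding="utf-8")
        paths.append(p)
    return paths
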