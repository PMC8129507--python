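"""Parameter-recovery stimuli: one dial under test, the others benign.

The generator's perturbation dials interact physically in the rendered
waveform exactly as they do in real voices -- cycle-to-cycle jitter is
itself aperiodicity, so it depresses measured harmonicity; additive noise
perturbs period marks and amplitude estimates.  Recovery of each estimator
is therefore assessed on stimuli that carry the tested dial at its target
value and hold the remaining dials at benign levels.
"""
from __future__ import annotations

import numpy as np

from .features import ExtractionConfig, extract_features
from .pad import Emotion
from .presets import build_emotion_presets
from .synth import VoiceSynthesisSpec, synthesize_utterance

#: Benign companion levels used while one dial is under test.
BENIGN = {
    "f0_sd": 5.0,
    "jitter_target": 0.5,
    "shimmer_target": 2.0,
    "hnr_target": 30.0,
}

#: Feature name measured for each dial.
DIAL_FEATURE = {
    "mean_f0": "mean_f0",
    "f0_sd": "f0_sd",
    "jitter_target": "jitter_pct",
    "shimmer_target": "shimmer_pct",
    "hnr_target": "hnr",
}


def recovery_spec(
    dial: str, gender: str, emotion: Emotion, seed: int = 0, **overrides
) -> VoiceSynthesisSpec:
    """Isolation stimulus for one dial of one preset cell.

    The tested dial takes the preset-cell value; mean F0 comes from the same
    cell (the detector must work at that pitch); the remaining perturbation
    dials take benign levels.  HNR recovery additionally needs a nearly
    deterministic harmonic part, so its companions are extra quiet.
    """
    presets = build_emotion_presets()
    cell = presets.spec_for(gender, emotion)
    base = dict(
        mean_f0=cell.mean_f0,
        f0_sd=BENIGN["f0_sd"],
        jitter_target=BENIGN["jitter_target"],
        shimmer_target=BENIGN["shimmer_target"],
        hnr_target=BENIGN["hnr_target"],
        n_words=9,
        seconds_per_word=0.3,
        pause_fraction=0.2,
        seed=seed,
    )
    if dial != "mean_f0":
        base[dial] = getattr(cell, dial)
    if dial == "mean_f0":
        # the pitch-recovery stimulus carries ordinary voice quality:
        # 1% jitter over a 25 dB noise floor
        base.update(jitter_target=1.0, hnr_target=25.0)
    elif dial == "hnr_target":
        base.update(f0_sd=1.0, jitter_target=0.1, shimmer_target=0.5)
    base.update(overrides)
    return VoiceSynthesisSpec(**base)


def recover_dial(
    dial: str,
    gender: str,
    emotion: Emotion,
    n_seeds: int = 20,
    seed: int = 0,
    cfg: ExtractionConfig | None = None,
    **overrides,
) -> tuple[float, float]:
    """Across-seed mean of the re-extracted value and the injected truth."""
    cfg = cfg or ExtractionConfig()
    feature = DIAL_FEATURE[dial]
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_seeds)]
    values = []
    truth = None
    for s in child_seeds:
        spec = recovery_spec(dial, gender, emotion, seed=s, **overrides)
        truth = getattr(spec, dial)
        vec = extract_features(synthesize_utterance(spec), cfg=cfg)
        values.append(getattr(vec, feature))
    return float(np.mean(values)), float(truth)
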