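"""The PAD (pleasure-arousal-dominance) emotion octants.

Mehrabian's three bipolar dimensions split emotion space into 2^3 sign
octants, each naming one basic emotional state; neutral is the reference
state outside the octant set and carries no coordinates.
"""
from __future__ import annotations

import enum
from typing import NamedTuple


class PADOctant(NamedTuple):
    """A sign triple (+1/-1) on the pleasure, arousal and dominance axes."""

    pleasure_sign: int
    arousal_sign: int
    dominance_sign: int

    def __str__(self) -> str:
        return "".join(
            ("+" if s > 0 else "-") + axis
            for s, axis in zip(self, "PAD")
        )


def _validate(octant: PADOctant) -> PADOctant:
    octant = PADOctant(*octant)
    if any(s not in (1, -1) for s in octant):
        raise ValueError(f"octant signs must be +1 or -1, got {tuple(octant)}")
    return octant


class Emotion(enum.Enum):
    """The nine emotional states, ordinal IDs 1-9 in protocol listing order."""

    NEUTRAL = 1
    EXUBERANT = 2
    BORED = 3
    DEPENDENT = 4
    DISDAINFUL = 5
    RELAXED = 6
    ANXIOUS = 7
    DOCILE = 8
    HOSTILE = 9

    @property
    def ordinal_id(self) -> int:
        return self.value

    @property
    def label(self) -> str:
        """Lowercase ASCII serialization used in CSV headers and the CLI."""
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Emotion":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown emotion label: {label!r}") from None


_OCTANT_TO_EMOTION: dict[PADOctant, Emotion] = {
    PADOctant(+1, +1, +1): Emotion.EXUBERANT,
    PADOctant(-1, -1, -1): Emotion.BORED,
    PADOctant(+1, +1, -1): Emotion.DEPENDENT,
    PADOctant(-1, -1, +1): Emotion.DISDAINFUL,
    PADOctant(+1, -1, +1): Emotion.RELAXED,
    PADOctant(-1, +1, -1): Emotion.ANXIOUS,
    PADOctant(+1, -1, -1): Emotion.DOCILE,
    PADOctant(-1, +1, +1): Emotion.HOSTILE,
}

_EMOTION_TO_OCTANT = {e: o for o, e in _OCTANT_TO_EMOTION.items()}


def octant_to_emotion(octant: PADOctant) -> Emotion:
    """Map a PAD sign octant to its named emotional state."""
    return _OCTANT_TO_EMOTION[_validate(octant)]


def emotion_to_octant(emotion: Emotion) -> PADOctant | None:
    """Inverse mapping; returns None for neutral (the reference state)."""
    if emotion is Emotion.NEUTRAL:
        return None
    return _EMOTION_TO_OCTANT[emotion]


def list_emotions() -> tuple[Emotion, ...]:
    """All nine states in ordinal order, neutral first."""
    return tuple(sorted(Emotion, key=lambda e: e.ordinal_id))
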