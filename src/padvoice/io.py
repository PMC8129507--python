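"""File formats: WAV audio, word-annotation sidecars, feature tables, config.

WAV is RIFF PCM16 (or float) mono; stereo and exotic codecs are rejected
with distinct errors.  Word annotations are tab-separated (start_s, end_s,
word_index).  Feature tables are long-format CSV with undefined values as
empty cells, never zero.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .core import AudioFormatError, VoiceRecording
from .stats import FEATURE_COLUMNS

PCM16_SCALE = 32768.0


def read_wav(path: str | Path) -> VoiceRecording:
    """Read a mono RIFF WAV into a normalized [-1, 1] recording."""
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except ValueError as exc:
        raise AudioFormatError(f"unsupported WAV codec in {path.name}: {exc}") from exc
    except Exception as exc:  # struct errors etc. from truncated files
        raise AudioFormatError(f"truncated or unreadable WAV {path.name}: {exc}") from exc
    if data.ndim != 1:
        raise AudioFormatError(
            f"{path.name} has {data.shape[1]} channels; only mono is supported"
        )
    if data.dtype == np.int16:
        samples = data / PCM16_SCALE
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(float)
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 128.0
    else:
        raise AudioFormatError(f"unsupported WAV sample format {data.dtype}")
    return VoiceRecording(np.clip(samples, -1.0, 1.0), float(rate), source_id=path.stem)


def write_wav(rec: VoiceRecording, path: str | Path) -> None:
    """Write as PCM16; full scale maps 1.0 -> 32767."""
    pcm = np.clip(np.round(rec.samples * PCM16_SCALE), -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), int(rec.sample_rate), pcm)


def write_annotation(boundaries, path: str | Path) -> None:
    """Word boundaries as TSV (start_s, end_s, word_index)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("start_s\tend_s\tword_index\n")
        for i, (start, end) in enumerate(boundaries):
            fh.write(f"{start:.6f}\t{end:.6f}\t{i}\n")


def read_annotation(path: str | Path) -> tuple[tuple[float, float], ...]:
    df = pd.read_csv(path, sep="\t")
    needed = {"start_s", "end_s"}
    if not needed <= set(df.columns):
        raise ValueError(f"annotation file needs columns {sorted(needed)}")
    df = df.sort_values("start_s")
    return tuple(zip(df["start_s"].astype(float), df["end_s"].astype(float)))


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """Long-format CSV; NaN serializes as an empty cell."""
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    df.loc[:, list(FEATURE_COLUMNS)].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{Path(path).name} is not a feature table; missing columns "
            f"{sorted(missing)}"
        )
    return df
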