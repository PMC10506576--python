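"""The 13-tone "Lightly Row" passage and its eight band-limited versions.

Experiment 2 replaces the isolated tone pairs with a familiar melody:
thirteen tones spelling the opening of "Lightly Row" (G E E | F D D |
C D E F | G G G), each note a harmonic complex tone subjected to the same
eight elimination conditions (X1..X4, Y1..Y4) as experiment 1.  A listener
attending to the (possibly missing) fundamental hears the correct melody;
a listener attending to the surviving partials can hear it off-key.

Note frequencies use a just-intonation C-major scale anchored at
C = 230 Hz (D 9/8, E 5/4, F 4/3, G 3/2).  The anchor keeps the scale's
E–G minor third at the exact 6:5 ratio (316 cents) used by the
experiment-1 tone pair, and places the third harmonic of G (3 × 345 =
1035 Hz) alone inside both Y-series passbands, so versions Y3 and Y4
contain pure tones — a structural feature of the stimulus set.  Phrase-final
notes (positions 3, 6 and 13) last 1000 ms; all others 500 ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptySpectrumError, InvalidParameterError
from .stimulus import (
    CONDITION_NAMES,
    DEFAULT_RAMP,
    DEFAULT_SAMPLE_RATE,
    HIGH_CUT_X,
    HIGH_CUT_Y,
    LOW_CUTS,
    ComplexTone,
    synthesize_tone,
)

__all__ = [
    "MelodyNote",
    "MelodyVersion",
    "DEFAULT_SCALE",
    "PASSAGE_DEGREES",
    "LONG_NOTE_POSITIONS",
    "lightly_row_passage",
    "build_experiment2_versions",
    "render_melody",
    "melody_manifest",
]

#: Just-intonation C major anchored at C = 230 Hz (ratios 1, 9/8, 5/4, 4/3, 3/2).
DEFAULT_SCALE: dict[str, float] = {
    "C": 230.0,
    "D": 230.0 * 9 / 8,    # 258.75
    "E": 230.0 * 5 / 4,    # 287.5
    "F": 230.0 * 4 / 3,    # 306.666…
    "G": 230.0 * 3 / 2,    # 345
}

#: The passage, by scale degree: G E E | F D D | C D E F | G G G.
PASSAGE_DEGREES: tuple[str, ...] = (
    "G", "E", "E", "F", "D", "D", "C", "D", "E", "F", "G", "G", "G",
)

#: 1-based positions of the phrase-final 1000-ms notes.
LONG_NOTE_POSITIONS: tuple[int, ...] = (3, 6, 13)

_SHORT = 0.5
_LONG = 1.0


@dataclass(frozen=True)
class MelodyNote:
    """One note of the passage before band-limiting."""

    degree: str
    f0: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration not in (_SHORT, _LONG):
            raise InvalidParameterError(
                f"note duration must be {_SHORT} or {_LONG} s, got {self.duration}"
            )
        if self.f0 <= 0:
            raise InvalidParameterError("note f0 must be positive")


@dataclass(frozen=True)
class MelodyVersion:
    """One band-limited rendition of the passage (13 ComplexTone notes)."""

    name: str
    low_cut: float
    high_cut: float
    notes: tuple[ComplexTone, ...]
    degrees: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.name not in CONDITION_NAMES:
            raise InvalidParameterError(f"unknown version name {self.name!r}")
        if len(self.notes) != 13:
            raise InvalidParameterError(
                f"a melody version needs exactly 13 notes, got {len(self.notes)}"
            )

    @property
    def has_pure_tone(self) -> bool:
        return any(t.is_pure for t in self.notes)

    @property
    def total_duration(self) -> float:
        return sum(t.duration for t in self.notes)


def lightly_row_passage(
    scale_table: Mapping[str, float] | None = None,
    long_positions: tuple[int, ...] = LONG_NOTE_POSITIONS,
) -> list[MelodyNote]:
    """The 13-note passage with the configured scale and rhythm."""
    scale = dict(DEFAULT_SCALE if scale_table is None else scale_table)
    missing = sorted(set(PASSAGE_DEGREES) - set(scale))
    if missing:
        raise ConfigurationError(f"scale table is missing degrees: {missing}")
    notes = []
    for pos, degree in enumerate(PASSAGE_DEGREES, start=1):
        dur = _LONG if pos in long_positions else _SHORT
        notes.append(MelodyNote(degree=degree, f0=scale[degree], duration=dur))
    return notes


def build_experiment2_versions(
    passage: list[MelodyNote] | None = None,
    ramp: float = DEFAULT_RAMP,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> list[MelodyVersion]:
    """Apply the eight elimination conditions to every note of the passage.

    Raises
    ------
    EmptySpectrumError
        Naming the note and version, if band-limiting would silence a note.
    """
    if passage is None:
        passage = lightly_row_passage()
    versions = []
    for series, high_cut in (("X", HIGH_CUT_X), ("Y", HIGH_CUT_Y)):
        for i, low_cut in enumerate(LOW_CUTS, start=1):
            name = f"{series}{i}"
            tones = []
            for pos, note in enumerate(passage, start=1):
                try:
                    tones.append(
                        ComplexTone.from_band(
                            note.f0,
                            low_cut,
                            high_cut,
                            duration=note.duration,
                            ramp=ramp,
                            sample_rate=sample_rate,
                        )
                    )
                except EmptySpectrumError as exc:
                    raise EmptySpectrumError(
                        f"version {name}, note {pos} ({note.degree}, "
                        f"{note.f0:g} Hz): no partial survives "
                        f"[{low_cut}, {high_cut}] Hz"
                    ) from exc
            versions.append(
                MelodyVersion(
                    name=name,
                    low_cut=low_cut,
                    high_cut=high_cut,
                    notes=tuple(tones),
                    degrees=tuple(n.degree for n in passage),
                )
            )
    return versions


def render_melody(version: MelodyVersion) -> np.ndarray:
    """Concatenate the per-note waveforms (each with its own 10-ms ramps), gapless."""
    return np.concatenate([synthesize_tone(t) for t in version.notes])


def melody_manifest(versions: list[MelodyVersion] | None = None) -> pd.DataFrame:
    """Tabular manifest: one row per (version, note index)."""
    if versions is None:
        versions = build_experiment2_versions()
    rows = []
    for v in versions:
        for idx, (deg, tone) in enumerate(zip(v.degrees, v.notes), start=1):
            rows.append(
                {
                    "version": v.name,
                    "note_index": idx,
                    "degree": deg,
                    "f0_hz": tone.f0,
                    "low_cut_hz": v.low_cut,
                    "high_cut_hz": v.high_cut,
                    "harmonic_ranks": " ".join(str(k) for k in tone.harmonic_ranks),
                    "partials_hz": " ".join(f"{f:g}" for f in tone.partials),
                    "duration_s": tone.duration,
                }
            )
    return pd.DataFrame(rows)
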