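"""Band-limited harmonic complex-tone stimuli for the pitch-shift experiment.

A harmonic complex tone is a sum of sinusoidal partials at integer multiples
of a fundamental frequency (F0).  Simulated low-tone hearing loss removes
partials *below* a low cutoff (250/500/750/1000 Hz); simulated high-tone
hearing loss removes partials *above* a high cutoff (1600 Hz for the X
series, 1300 Hz for the Y series).  Eight such tone pairs (X1..X4, Y1..Y4)
are built from two F0s, 230 Hz (tone A) and 276 Hz (tone B), a 316-cent
interval.  Every pair is designed so the tone with the *lower* F0 has the
*higher* lowest partial — the crossover that elicits pitch shifts in
spectral listeners.

The cutoffs are elimination thresholds read strictly ("less than" /
"greater than"), so a partial exactly at a cutoff is retained.  No partial
of this stimulus set lies on a boundary, so the reading is inert in
practice but is honoured with a small numeric tolerance.
"""

from __future__ import annotations

import math
import wave
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptySpectrumError, InvalidParameterError

__all__ = [
    "ComplexTone",
    "ConditionPair",
    "harmonic_partials",
    "band_limited_partials",
    "cents_interval",
    "build_experiment1_pairs",
    "synthesize_tone",
    "write_wav",
    "read_wav",
    "pairs_manifest",
    "LOW_CUTS",
    "HIGH_CUT_X",
    "HIGH_CUT_Y",
    "F0_TONE_A",
    "F0_TONE_B",
    "CONDITION_NAMES",
]

#: Low-frequency elimination cutoffs, indexed 1..4 within each series.
LOW_CUTS: tuple[float, ...] = (250.0, 500.0, 750.0, 1000.0)
HIGH_CUT_X: float = 1600.0
HIGH_CUT_Y: float = 1300.0
F0_TONE_A: float = 230.0
F0_TONE_B: float = 276.0

CONDITION_NAMES: tuple[str, ...] = ("X1", "X2", "X3", "X4", "Y1", "Y2", "Y3", "Y4")

DEFAULT_SAMPLE_RATE = 44100
DEFAULT_BIT_DEPTH = 16
DEFAULT_DURATION = 0.5
DEFAULT_RAMP = 0.01

#: relative tolerance for "is this harmonic inside the passband" at the boundary
_CUT_RTOL = 1e-9


def harmonic_partials(f0: float, max_freq: float) -> list[tuple[int, float]]:
    """All harmonics of ``f0`` up to ``max_freq``, as (rank, frequency) pairs.

    Raises
    ------
    InvalidParameterError
        If ``f0`` is not positive or no harmonic fits below ``max_freq``.
    """
    if f0 <= 0:
        raise InvalidParameterError(f"f0 must be positive, got {f0}")
    n = int(math.floor(max_freq / f0 * (1.0 + _CUT_RTOL)))
    if n < 1:
        raise InvalidParameterError(
            f"no harmonic of f0={f0} Hz fits below max_freq={max_freq} Hz"
        )
    return [(k, k * f0) for k in range(1, n + 1)]


def band_limited_partials(
    f0: float, low_cut: float, high_cut: float
) -> list[tuple[int, float]]:
    """Harmonics of ``f0`` surviving strict elimination outside [low_cut, high_cut].

    Partials strictly below ``low_cut`` or strictly above ``high_cut`` are
    eliminated; a partial exactly at a cutoff is retained.

    Raises
    ------
    EmptySpectrumError
        If no harmonic survives (the caller decides whether that is a
        designed pure-elimination condition or a bug).
    """
    if f0 <= 0:
        raise InvalidParameterError(f"f0 must be positive, got {f0}")
    if not low_cut < high_cut:
        raise InvalidParameterError(
            f"low_cut must be below high_cut, got {low_cut} >= {high_cut}"
        )
    k_lo = max(1, int(math.ceil(low_cut / f0 * (1.0 - _CUT_RTOL))))
    k_hi = int(math.floor(high_cut / f0 * (1.0 + _CUT_RTOL)))
    if k_hi < k_lo:
        raise EmptySpectrumError(
            f"no harmonic of f0={f0} Hz lies in [{low_cut}, {high_cut}] Hz"
        )
    return [(k, k * f0) for k in range(k_lo, k_hi + 1)]


def cents_interval(f_low: float, f_high: float) -> float:
    """Musical interval from ``f_low`` to ``f_high`` in cents.

    1200 × log2(f_high / f_low); negative when ``f_high`` < ``f_low``.
    """
    if f_low <= 0 or f_high <= 0:
        raise InvalidParameterError("frequencies must be positive")
    return 1200.0 * math.log2(f_high / f_low)


@dataclass(frozen=True)
class ComplexTone:
    """A harmonic complex tone: F0 plus the retained partial set.

    ``partials`` and ``harmonic_ranks`` are parallel, strictly increasing,
    with every partial equal to rank × f0.
    """

    f0: float
    partials: tuple[float, ...]
    harmonic_ranks: tuple[int, ...]
    duration: float = DEFAULT_DURATION
    ramp: float = DEFAULT_RAMP
    sample_rate: int = DEFAULT_SAMPLE_RATE
    bit_depth: int = DEFAULT_BIT_DEPTH

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise InvalidParameterError(f"f0 must be positive, got {self.f0}")
        if len(self.partials) == 0:
            raise EmptySpectrumError("a tone with zero retained partials is invalid")
        if len(self.partials) != len(self.harmonic_ranks):
            raise InvalidParameterError("partials and harmonic_ranks lengths differ")
        for k, f in zip(self.harmonic_ranks, self.partials):
            if k < 1 or abs(f - k * self.f0) > 1e-9 * max(f, k * self.f0):
                raise InvalidParameterError(
                    f"partial {f} Hz is not harmonic rank {k} of f0={self.f0} Hz"
                )
        if any(b <= a for a, b in zip(self.partials, self.partials[1:])):
            raise InvalidParameterError("partials must be strictly increasing")
        if not self.duration > 2 * self.ramp:
            raise InvalidParameterError(
                f"duration {self.duration}s must exceed twice the ramp {self.ramp}s"
            )

    @classmethod
    def from_band(
        cls,
        f0: float,
        low_cut: float,
        high_cut: float,
        **kwargs,
    ) -> "ComplexTone":
        """Build the band-limited tone for one elimination condition."""
        pairs = band_limited_partials(f0, low_cut, high_cut)
        ranks = tuple(k for k, _ in pairs)
        freqs = tuple(f for _, f in pairs)
        return cls(f0=f0, partials=freqs, harmonic_ranks=ranks, **kwargs)

    @property
    def lowest_partial(self) -> float:
        return self.partials[0]

    @property
    def top_frequency(self) -> float:
        """Frequency of the highest retained partial."""
        return self.partials[-1]

    @property
    def is_pure(self) -> bool:
        """True if only a single partial survives (a pure tone)."""
        return len(self.partials) == 1

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.sample_rate)


@dataclass(frozen=True)
class ConditionPair:
    """One of the eight experiment-1 conditions: tone A (F0 230) vs tone B (F0 276)."""

    name: str
    low_cut: float
    high_cut: float
    tone_a: ComplexTone
    tone_b: ComplexTone

    def __post_init__(self) -> None:
        if self.name not in CONDITION_NAMES:
            raise InvalidParameterError(f"unknown condition name {self.name!r}")
        if self.low_cut not in LOW_CUTS:
            raise InvalidParameterError(f"low_cut {self.low_cut} not in {LOW_CUTS}")
        expected_high = HIGH_CUT_X if self.name.startswith("X") else HIGH_CUT_Y
        if self.high_cut != expected_high:
            raise InvalidParameterError(
                f"{self.name} requires high_cut {expected_high}, got {self.high_cut}"
            )
        if not self.tone_a.lowest_partial > self.tone_b.lowest_partial:
            raise InvalidParameterError(
                f"{self.name}: designed crossover violated "
                f"(lowest A={self.tone_a.lowest_partial}, B={self.tone_b.lowest_partial})"
            )


def build_experiment1_pairs(
    duration: float = DEFAULT_DURATION,
    ramp: float = DEFAULT_RAMP,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> list[ConditionPair]:
    """The eight experiment-1 tone pairs X1..X4 (high cut 1600 Hz), Y1..Y4 (1300 Hz)."""
    kwargs = dict(duration=duration, ramp=ramp, sample_rate=sample_rate)
    pairs = []
    for series, high_cut in (("X", HIGH_CUT_X), ("Y", HIGH_CUT_Y)):
        for i, low_cut in enumerate(LOW_CUTS, start=1):
            pairs.append(
                ConditionPair(
                    name=f"{series}{i}",
                    low_cut=low_cut,
                    high_cut=high_cut,
                    tone_a=ComplexTone.from_band(F0_TONE_A, low_cut, high_cut, **kwargs),
                    tone_b=ComplexTone.from_band(F0_TONE_B, low_cut, high_cut, **kwargs),
                )
            )
    return pairs


def synthesize_tone(tone: ComplexTone) -> np.ndarray:
    """Render a tone to a float waveform in [-1, 1].

    Equal-amplitude zero-phase sine partials are summed, shaped with
    raised-cosine (Hann half-window) rise/fall ramps, and peak-normalized to
    1 − 2^−(bit_depth−1) so the subsequent integer quantization cannot clip.
    The first and last samples are exactly zero (the ramps start and end at
    zero amplitude).
    """
    n = tone.n_samples
    t = np.arange(n) / tone.sample_rate
    x = np.zeros(n)
    for f in tone.partials:
        x += np.sin(2.0 * np.pi * f * t)

    r = round(tone.ramp * tone.sample_rate)
    if r > 0:
        rise = 0.5 * (1.0 - np.cos(np.pi * np.arange(r) / r))
        env = np.ones(n)
        env[:r] = rise
        env[n - r :] = rise[::-1]
        x *= env

    target = 1.0 - 2.0 ** -(tone.bit_depth - 1)
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= target / peak
    if np.max(np.abs(x)) > target + 1e-12:  # pragma: no cover - guarded above
        raise RuntimeError("internal error: waveform clipped after scaling")
    return x


def write_wav(
    waveform: Sequence[float] | np.ndarray,
    sample_rate: int,
    path: str | Path,
    bit_depth: int = DEFAULT_BIT_DEPTH,
    stereo: bool = False,
) -> Path:
    """Write a [-1, 1] waveform as a PCM WAV file (16-bit little-endian).

    ``stereo=True`` duplicates the mono signal into two identical channels
    (diotic presentation); the default is mono.
    """
    x = np.asarray(waveform, dtype=np.float64)
    if x.size == 0:
        raise InvalidParameterError("cannot write an empty waveform")
    if np.max(np.abs(x)) > 1.0 + 1e-12:
        raise InvalidParameterError("waveform samples must lie in [-1, 1]")
    if bit_depth != 16:
        raise InvalidParameterError("only 16-bit PCM output is supported")
    scale = 2 ** (bit_depth - 1) - 1
    q = np.round(x * scale).astype("<i2")
    if stereo:
        q = np.repeat(q, 2)
    path = Path(path)
    with wave.open(str(path), "wb") as fh:
        fh.setnchannels(2 if stereo else 1)
        fh.setsampwidth(bit_depth // 8)
        fh.setframerate(sample_rate)
        fh.writeframes(q.tobytes())
    return path


def read_wav(path: str | Path) -> tuple[int, np.ndarray]:
    """Read a 16-bit PCM WAV file back to (sample_rate, float waveform).

    Stereo files are averaged to mono.  Samples are rescaled by the same
    factor used on write, so a write→read round trip is exact to within the
    quantization step.
    """
    with wave.open(str(path), "rb") as fh:
        if fh.getsampwidth() != 2:
            raise InvalidParameterError("only 16-bit PCM WAV files are supported")
        rate = fh.getframerate()
        nch = fh.getnchannels()
        raw = fh.readframes(fh.getnframes())
    q = np.frombuffer(raw, dtype="<i2").astype(np.float64)
    if nch > 1:
        q = q.reshape(-1, nch).mean(axis=1)
    return rate, q / (2**15 - 1)


def pairs_manifest(pairs: list[ConditionPair] | None = None) -> pd.DataFrame:
    """Tabular stimulus manifest: one row per (condition, tone)."""
    if pairs is None:
        pairs = build_experiment1_pairs()
    rows = []
    for p in pairs:
        for label, tone in (("toneA", p.tone_a), ("toneB", p.tone_b)):
            rows.append(
                {
                    "condition": p.name,
                    "tone": label,
                    "f0_hz": tone.f0,
                    "low_cut_hz": p.low_cut,
                    "high_cut_hz": p.high_cut,
                    "harmonic_ranks": " ".join(str(k) for k in tone.harmonic_ranks),
                    "partials_hz": " ".join(f"{f:g}" for f in tone.partials),
                    "duration_s": tone.duration,
                }
            )
    return pd.DataFrame(rows)
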