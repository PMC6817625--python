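"""Deterministic transforms from raw acoustic measurements to derived vocal parameters.

All pitch quantities are expressed on a semitone scale relative to A4
(440 Hz by default); formant spacing and apparent vocal-tract length follow
the uniform-tube (closed at one end) model, where the i-th resonance sits at
(2i - 1)/2 times the spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SPEED_OF_SOUND_CM_S",
    "AcousticRecord",
    "VocalProfile",
    "ModulationIndex",
    "hz_to_semitone",
    "semitone_to_note_label",
    "f0_range_semitones",
    "estimate_delta_f",
    "vtl_from_delta_f",
    "build_vocal_profile",
    "modulation_indices",
    "profiles_from_recordings",
]

#: Speed of sound (cm/s) in a uniform tube with one end closed.
SPEED_OF_SOUND_CM_S = 33_500.0

_NOTE_NAMES = ("C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B")
#: chromatic index of A4 counting from C0 = 0
_A4_INDEX = 57

_DISPLAYS = frozenset({"speech", "singing"})


def _check_positive_finite(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")
    return value


@dataclass(frozen=True)
class AcousticRecord:
    """Raw measurements of a single recording.

    ``formants_hz`` holds the medians of the first four formants (F1..F4),
    strictly increasing.
    """

    recording_id: str
    person_id: str
    display: str
    item: str
    mean_f0_hz: float
    min_f0_hz: float
    max_f0_hz: float
    formants_hz: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.display not in _DISPLAYS:
            raise ValueError(f"display must be one of {sorted(_DISPLAYS)}, got {self.display!r}")
        for name in ("mean_f0_hz", "min_f0_hz", "max_f0_hz"):
            _check_positive_finite(getattr(self, name), name)
        if not (self.min_f0_hz <= self.mean_f0_hz <= self.max_f0_hz):
            raise ValueError(
                f"require min_f0_hz <= mean_f0_hz <= max_f0_hz, got "
                f"({self.min_f0_hz}, {self.mean_f0_hz}, {self.max_f0_hz})"
            )
        fmts = tuple(float(f) for f in self.formants_hz)
        if len(fmts) != 4:
            raise ValueError(f"exactly 4 formants required, got {len(fmts)}")
        for f in fmts:
            _check_positive_finite(f, "formant")
        if any(b <= a for a, b in zip(fmts, fmts[1:])):
            raise ValueError(f"formants must be strictly increasing, got {fmts}")
        object.__setattr__(self, "formants_hz", fmts)


@dataclass(frozen=True)
class VocalProfile:
    """Per-person, per-display derived vocal parameters."""

    person_id: str
    display: str
    mean_f0_st: float
    f0_range_st: float
    delta_f_hz: float
    vtl_cm: float
    n_recordings: int

    def __post_init__(self) -> None:
        if self.display not in _DISPLAYS:
            raise ValueError(f"display must be one of {sorted(_DISPLAYS)}, got {self.display!r}")
        if self.f0_range_st < 0:
            raise ValueError("f0_range_st must be >= 0")
        _check_positive_finite(self.delta_f_hz, "delta_f_hz")
        _check_positive_finite(self.vtl_cm, "vtl_cm")
        if self.n_recordings < 1:
            raise ValueError("n_recordings must be >= 1")


@dataclass(frozen=True)
class ModulationIndex:
    """Absolute singing-minus-speech differences; symmetric in display order."""

    person_id: str
    abs_df0_st: float
    abs_drange_st: float
    abs_dvtl_cm: float

    def __post_init__(self) -> None:
        for name in ("abs_df0_st", "abs_drange_st", "abs_dvtl_cm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def hz_to_semitone(f0_hz: float, reference_hz: float = 440.0) -> float:
    """Convert a frequency to a semitone offset from the reference.

    Returns ``12 * log2(f0_hz / reference_hz)``: 0 at the reference and
    +12 per octave (doubling).
    """
    f0_hz = _check_positive_finite(f0_hz, "f0_hz")
    reference_hz = _check_positive_finite(reference_hz, "reference_hz")
    return 12.0 * math.log2(f0_hz / reference_hz)


def semitone_to_note_label(st: float) -> str:
    """Nearest note name (sharps only, scientific pitch notation) for a
    semitone offset from A4.

    Ties (exact .5 fractions) round away from zero.
    """
    st = float(st)
    if not math.isfinite(st):
        raise ValueError(f"semitone offset must be finite, got {st!r}")
    # round half away from zero
    nearest = math.floor(st + 0.5) if st >= 0 else math.ceil(st - 0.5)
    index = _A4_INDEX + nearest
    octave, degree = divmod(index, 12)
    return f"{_NOTE_NAMES[degree]}{octave}"


def f0_range_semitones(min_f0_hz: float, max_f0_hz: float) -> float:
    """Perceptual F0 range in semitones, ``12 * log2(max / min)``."""
    min_f0_hz = _check_positive_finite(min_f0_hz, "min_f0_hz")
    max_f0_hz = _check_positive_finite(max_f0_hz, "max_f0_hz")
    if min_f0_hz > max_f0_hz:
        raise ValueError(f"min_f0_hz ({min_f0_hz}) exceeds max_f0_hz ({max_f0_hz})")
    return 12.0 * math.log2(max_f0_hz / min_f0_hz)


def estimate_delta_f(formants_hz: Sequence[float]) -> float:
    """Formant spacing: through-origin least-squares slope of Fi on (2i-1)/2.

    Closed form sum(x_i F_i) / sum(x_i^2) with x_i = (2i - 1)/2, i = 1..4.
    """
    fmts = [float(f) for f in formants_hz]
    if len(fmts) != 4:
        raise ValueError(f"exactly 4 formants required, got {len(fmts)}")
    for f in fmts:
        _check_positive_finite(f, "formant")
    if any(b <= a for a, b in zip(fmts, fmts[1:])):
        raise ValueError(f"formants must be strictly increasing, got {tuple(fmts)}")
    x = np.arange(1, 5) - 0.5
    return float(np.dot(x, fmts) / np.dot(x, x))


def vtl_from_delta_f(delta_f_hz: float, speed_of_sound_cm_s: float = SPEED_OF_SOUND_CM_S) -> float:
    """Apparent vocal-tract length in cm: ``c / (2 * delta_f)``."""
    delta_f_hz = _check_positive_finite(delta_f_hz, "delta_f_hz")
    speed_of_sound_cm_s = _check_positive_finite(speed_of_sound_cm_s, "speed_of_sound_cm_s")
    return speed_of_sound_cm_s / (2.0 * delta_f_hz)


def build_vocal_profile(
    records: Iterable[AcousticRecord],
    speed_of_sound_cm_s: float = SPEED_OF_SOUND_CM_S,
    vtl_averaging: str = "delta_f",
) -> VocalProfile:
    """Average per-recording transforms into a per-person, per-display profile.

    Per-recording mean F0 is converted to semitones first and the semitone
    values are averaged; likewise ranges and formant spacings. With
    ``vtl_averaging="delta_f"`` (default) VTL is computed once from the
    averaged spacing; ``"per_recording"`` instead averages per-recording VTLs
    (not identical, by convexity of 1/x).
    """
    records = list(records)
    if not records:
        raise ValueError("at least one record is required")
    persons = {r.person_id for r in records}
    displays = {r.display for r in records}
    if len(persons) != 1 or len(displays) != 1:
        raise ValueError(f"records mix persons {sorted(persons)} / displays {sorted(displays)}")
    if vtl_averaging not in ("delta_f", "per_recording"):
        raise ValueError(f"unknown vtl_averaging {vtl_averaging!r}")

    mean_sts = [hz_to_semitone(r.mean_f0_hz) for r in records]
    ranges = [f0_range_semitones(r.min_f0_hz, r.max_f0_hz) for r in records]
    spacings = [estimate_delta_f(r.formants_hz) for r in records]
    delta_f = float(np.mean(spacings))
    if vtl_averaging == "delta_f":
        vtl = vtl_from_delta_f(delta_f, speed_of_sound_cm_s)
    else:
        vtl = float(np.mean([vtl_from_delta_f(d, speed_of_sound_cm_s) for d in spacings]))
    return VocalProfile(
        person_id=records[0].person_id,
        display=records[0].display,
        mean_f0_st=float(np.mean(mean_sts)),
        f0_range_st=float(np.mean(ranges)),
        delta_f_hz=delta_f,
        vtl_cm=vtl,
        n_recordings=len(records),
    )


def modulation_indices(speech: VocalProfile, singing: VocalProfile) -> ModulationIndex:
    """Component-wise absolute speech/singing differences (display order irrelevant)."""
    if speech.person_id != singing.person_id:
        raise ValueError(
            f"profiles belong to different persons: {speech.person_id!r} vs {singing.person_id!r}"
        )
    if {speech.display, singing.display} != _DISPLAYS:
        raise ValueError("need exactly one speech and one singing profile")
    return ModulationIndex(
        person_id=speech.person_id,
        abs_df0_st=abs(singing.mean_f0_st - speech.mean_f0_st),
        abs_drange_st=abs(singing.f0_range_st - speech.f0_range_st),
        abs_dvtl_cm=abs(singing.vtl_cm - speech.vtl_cm),
    )


def profiles_from_recordings(
    recordings: pd.DataFrame,
    speed_of_sound_cm_s: float = SPEED_OF_SOUND_CM_S,
    vtl_averaging: str = "delta_f",
) -> pd.DataFrame:
    """Build one :class:`VocalProfile` row per person x display from a
    validated recordings table (schema of ``recordings.csv``)."""
    rows = []
    for (person, display), grp in recordings.groupby(["person_id", "display"], sort=True):
        recs = [
            AcousticRecord(
                recording_id=str(r.recording_id),
                person_id=str(person),
                display=str(display),
                item=str(r.item),
                mean_f0_hz=r.mean_f0_hz,
                min_f0_hz=r.min_f0_hz,
                max_f0_hz=r.max_f0_hz,
                formants_hz=(r.f1_hz, r.f2_hz, r.f3_hz, r.f4_hz),
            )
            for r in grp.itertuples()
        ]
        prof = build_vocal_profile(recs, speed_of_sound_cm_s, vtl_averaging)
        rows.append(
            {
                "person_id": prof.person_id,
                "display": prof.display,
                "mean_f0_st": prof.mean_f0_st,
                "f0_range_st": prof.f0_range_st,
                "delta_f_hz": prof.delta_f_hz,
                "vtl_cm": prof.vtl_cm,
                "n_recordings": prof.n_recordings,
            }
        )
    return pd.DataFrame(rows)
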