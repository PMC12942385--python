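"""Simulated patients and synthetic paired-measurement cohorts.

Live participants are replaced by a psychometric response model: each eye
has a true logMAR threshold L and answers an optotype of size x correctly
with probability g + (1-g) * logistic((x - L)/s), where g is the guessing
floor (1/vocabulary size for forced-choice naming) and s the psychometric
slope in logMAR units; s = 0 degenerates to a deterministic threshold
reader (certain at or above threshold, guessing below). Pinhole viewing is
modelled as a second, never-worse threshold per eye, emulating correctable
refractive error. Speech-recognition confusions and occluder-pose errors
are injected at stated rates so the full pipeline can be exercised.

The cohort generator produces paired manual/automated logMAR tables for
the agreement-statistics suite: manual acuities from a truncated Normal,
automated = manual + bias + noise, both snapped to the 0.02 letter grid,
with an optional fraction of planted outlier eyes shifted by >= 0.4 logMAR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .chart import LETTER_STEP, ChartSpec, snellen_to_logmar
from .engine import ExamPhase, Stimulus
from .interpreter import ParsedResponse


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PatientProfile:
    """True per-eye acuities plus response/speech/pose error parameters."""

    true_logmar_right: float
    true_logmar_left: float
    pinhole_logmar_right: Optional[float] = None
    pinhole_logmar_left: Optional[float] = None
    guess_rate: float = 1.0 / 9.0
    slope: float = 0.0
    speech_sub_rate: float = 0.0
    pose_error_rate: float = 0.0
    blurred_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.guess_rate < 1.0:
            raise SimulationError("guess_rate must be in [0, 1)")
        if self.slope < 0:
            raise SimulationError("slope must be non-negative")
        for r in (self.speech_sub_rate, self.pose_error_rate, self.blurred_prob):
            if not 0.0 <= r <= 1.0:
                raise SimulationError("rates must lie in [0, 1]")
        ph_r = self.pinhole_logmar_right
        ph_l = self.pinhole_logmar_left
        if ph_r is not None and ph_r > self.true_logmar_right + 1e-12:
            raise SimulationError("pinhole acuity cannot be worse than unaided (right)")
        if ph_l is not None and ph_l > self.true_logmar_left + 1e-12:
            raise SimulationError("pinhole acuity cannot be worse than unaided (left)")

    def threshold(self, eye: str, pinhole: bool) -> float:
        if eye not in ("right", "left"):
            raise SimulationError(f"unknown eye {eye!r}")
        unaided = self.true_logmar_right if eye == "right" else self.true_logmar_left
        if not pinhole:
            return unaided
        ph = self.pinhole_logmar_right if eye == "right" else self.pinhole_logmar_left
        return unaided if ph is None else ph

    @classmethod
    def from_yaml(cls, path) -> "PatientProfile":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data.get("patient", data))


def phase_eye(phase: ExamPhase) -> tuple[str, bool]:
    """(eye, pinhole?) for a test phase."""
    return {
        ExamPhase.RIGHT_UNAIDED: ("right", False),
        ExamPhase.LEFT_UNAIDED: ("left", False),
        ExamPhase.RIGHT_PINHOLE: ("right", True),
        ExamPhase.LEFT_PINHOLE: ("left", True),
    }[phase]


def p_correct(optotype_logmar: float, profile: PatientProfile, eye: str = "right", pinhole: bool = False) -> float:
    """Probability of naming one optotype correctly (larger optotypes have
    larger logMAR, hence are easier)."""
    L = profile.threshold(eye, pinhole)
    g = profile.guess_rate
    if profile.slope == 0.0:
        return 1.0 if optotype_logmar >= L else g
    z = (optotype_logmar - L) / profile.slope
    return g + (1.0 - g) * (1.0 / (1.0 + math.exp(-z)))


def spoken_symbols(
    stimulus: Stimulus,
    profile: PatientProfile,
    phase: ExamPhase,
    rng: np.random.Generator,
    vocab: tuple[str, ...],
) -> Optional[list[str]]:
    """Draw the symbols the patient utters, or ``None`` for "blurred".

    Per-symbol Bernoulli(p_correct); a wrong answer is uniform over the
    rest of the vocabulary; when every symbol fails the patient may say
    "blurred" instead of guessing aloud; speech-recognition substitutions
    corrupt the uttered symbols at ``speech_sub_rate``.
    """
    eye, pinhole = phase_eye(phase)
    p = p_correct(stimulus.line.logmar, profile, eye, pinhole)
    correct = rng.random(len(stimulus.symbols)) < p
    if not correct.any() and rng.random() < profile.blurred_prob:
        return None
    others = list(vocab)
    out: list[str] = []
    for sym, ok in zip(stimulus.symbols, correct):
        if ok:
            out.append(sym)
        else:
            pool = [s for s in others if s != sym]
            out.append(str(rng.choice(pool)))
    if profile.speech_sub_rate:
        for i, sym in enumerate(out):
            if rng.random() < profile.speech_sub_rate:
                pool = [s for s in others if s != sym]
                out[i] = str(rng.choice(pool))
    return out


def respond(
    stimulus: Stimulus,
    profile: PatientProfile,
    phase: ExamPhase,
    rng: np.random.Generator,
    vocab: tuple[str, ...],
) -> ParsedResponse:
    """One simulated response as the engine would receive it."""
    syms = spoken_symbols(stimulus, profile, phase, rng, vocab)
    if syms is None:
        return ParsedResponse.of_command("BLURRED")
    return ParsedResponse.of_symbols(syms)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic paired manual/automated cohort."""

    n_participants: int = 72
    logmar_mean: float = 0.2
    logmar_sd: float = 0.25
    logmar_range: tuple[float, float] = (0.0, 1.1)
    bias: float = 0.0
    noise_sd: float = 0.0
    outlier_fraction: float = 0.0
    outlier_shift_range: tuple[float, float] = (0.4, 0.7)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise SimulationError("n_participants must be >= 1")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise SimulationError("outlier_fraction must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        blk = dict(data.get("cohort", data))
        for key in ("logmar_range", "outlier_shift_range"):
            if key in blk:
                blk[key] = tuple(blk[key])
        return cls(**blk)


def snap_to_letter_grid(x):
    """Snap logMAR values to the 0.02 per-letter grid."""
    return np.round(np.asarray(x, dtype=float) / LETTER_STEP) * LETTER_STEP


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Two eye-rows per participant with paired manual/automated logMAR.

    Columns: participant_id, eye (OD/OS), manual_logmar, automated_logmar,
    manual_pinhole_logmar / automated_pinhole_logmar (present only for eyes
    worse than 6/9, NaN otherwise) and planted_outlier. Deterministic per
    seed; every emitted acuity sits on the 0.02 letter grid.
    """
    rng = np.random.default_rng(spec.seed)
    n_eyes = 2 * spec.n_participants
    lo, hi = spec.logmar_range
    a = (lo - spec.logmar_mean) / spec.logmar_sd
    b = (hi - spec.logmar_mean) / spec.logmar_sd
    manual = sps.truncnorm.rvs(a, b, loc=spec.logmar_mean, scale=spec.logmar_sd, size=n_eyes, random_state=rng)
    manual = snap_to_letter_grid(manual)

    noise = rng.normal(0.0, spec.noise_sd, size=n_eyes) if spec.noise_sd > 0 else np.zeros(n_eyes)
    shift = np.zeros(n_eyes)
    planted = rng.random(n_eyes) < spec.outlier_fraction
    if planted.any():
        mag = rng.uniform(*spec.outlier_shift_range, size=int(planted.sum()))
        sign = rng.choice([-1.0, 1.0], size=int(planted.sum()))
        shift[planted] = snap_to_letter_grid(mag) * sign
    automated = snap_to_letter_grid(manual + spec.bias + noise) + shift

    pinhole_cut = snellen_to_logmar(9, 0)
    has_ph = manual > pinhole_cut
    improvement = snap_to_letter_grid(rng.uniform(0.0, 0.3, size=n_eyes))
    manual_ph = np.where(has_ph, np.clip(manual - improvement, 0.0, None), np.nan)
    auto_ph_noise = rng.normal(0.0, spec.noise_sd, size=n_eyes) if spec.noise_sd > 0 else np.zeros(n_eyes)
    automated_ph = np.where(has_ph, snap_to_letter_grid(manual_ph + spec.bias + auto_ph_noise), np.nan)

    return pd.DataFrame(
        {
            "participant_id": [f"P{i // 2 + 1:03d}" for i in range(n_eyes)],
            "eye": ["OD", "OS"] * spec.n_participants,
            "manual_logmar": manual,
            "automated_logmar": automated,
            "manual_pinhole_logmar": manual_ph,
            "automated_pinhole_logmar": automated_ph,
            "planted_outlier": planted,
        }
    )
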