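"""Optotype chart model: Snellen lines, letter-by-letter logMAR scoring.

A Snellen fraction 6/x denotes the line a standard eye resolves at x metres
when viewed from 6 m; its logMAR value is log10(x/6), so 6/6 = 0.0 and
6/60 = 1.0. Charts here carry five-optotype rows and score partial lines
with the conventional 0.02 logMAR per-letter increment: "6/12 -1" means the
6/12 row was read with one miss (logMAR 0.301 + 0.02).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import yaml

#: logMAR change per single optotype on a 5-letter row (0.1 per line / 5).
LETTER_STEP = 0.02

#: Default Snellen denominators, largest optotype first.
DEFAULT_DENOMINATORS = (120, 60, 36, 24, 18, 12, 9, 6)

#: Nine-letter default vocabulary: the Sloan set minus "O", which is
#: indistinguishable from "zero" in spoken responses.
DEFAULT_LETTER_VOCAB = ("C", "D", "H", "K", "N", "R", "S", "V", "Z")
DEFAULT_NUMBER_VOCAB = tuple(str(d) for d in range(10))

LETTERS = "LETTERS"
NUMBERS = "NUMBERS"


class ChartDomainError(ValueError):
    """Raised for arguments outside the chart model's domain."""


class _WorseThanChart:
    """Sentinel acuity for an eye that cannot read the largest optotype.

    Its logMAR is +inf so ordering comparisons (e.g. the pinhole trigger)
    remain well defined; report writers render it as a flag, not a number.
    """

    logmar = math.inf

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "WORSE_THAN_CHART"


WORSE_THAN_CHART = _WorseThanChart()


@dataclass(frozen=True, order=False)
class OptotypeLine:
    """One chart line identified by its Snellen 6/x denominator."""

    denominator: float
    row_length: int = 5

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ChartDomainError(f"denominator must be positive, got {self.denominator}")
        if self.row_length < 1:
            raise ChartDomainError("row_length must be >= 1")

    @property
    def logmar(self) -> float:
        return math.log10(self.denominator / 6.0)

    @property
    def snellen(self) -> str:
        d = self.denominator
        return f"6/{int(d) if float(d).is_integer() else d}"

    def __repr__(self) -> str:
        return f"OptotypeLine({self.snellen})"


@dataclass(frozen=True)
class ChartSpec:
    """An ordered chart: lines from largest to smallest optotype plus the
    symbol vocabulary responses are drawn from."""

    lines: tuple[OptotypeLine, ...]
    vocab_mode: str = LETTERS
    vocab: tuple[str, ...] = DEFAULT_LETTER_VOCAB
    distance_m: float = 6.0

    def __post_init__(self) -> None:
        if not self.lines:
            raise ChartDomainError("chart needs at least one line")
        denoms = [ln.denominator for ln in self.lines]
        if any(nxt >= prev for nxt, prev in zip(denoms[1:], denoms)):
            raise ChartDomainError("lines must be strictly ordered largest to smallest")
        if self.vocab_mode not in (LETTERS, NUMBERS):
            raise ChartDomainError(f"unknown vocab_mode {self.vocab_mode!r}")
        allowed = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ") if self.vocab_mode == LETTERS else set("0123456789")
        bad = [s for s in self.vocab if s not in allowed]
        if bad:
            raise ChartDomainError(f"vocab symbols {bad} not allowed in mode {self.vocab_mode}")
        if len(set(self.vocab)) != len(self.vocab):
            raise ChartDomainError("vocab symbols must be unique")
        if not (4.0 <= self.distance_m <= 6.0):
            raise ChartDomainError("test distance must be within 4-6 m")

    @classmethod
    def default(cls, vocab_mode: str = LETTERS) -> "ChartSpec":
        vocab = DEFAULT_LETTER_VOCAB if vocab_mode == LETTERS else DEFAULT_NUMBER_VOCAB
        return cls(
            lines=tuple(OptotypeLine(d) for d in DEFAULT_DENOMINATORS),
            vocab_mode=vocab_mode,
            vocab=vocab,
        )

    @property
    def largest(self) -> OptotypeLine:
        return self.lines[0]

    @property
    def smallest(self) -> OptotypeLine:
        return self.lines[-1]

    def index_of(self, line: OptotypeLine) -> int:
        return self.lines.index(line)

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "chart": {
                "lines": [ln.denominator for ln in self.lines],
                "row_length": self.lines[0].row_length,
                "vocab_mode": self.vocab_mode,
                "vocab": list(self.vocab),
                "distance_m": self.distance_m,
            }
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ChartSpec":
        blk = data.get("chart", data)
        row_length = int(blk.get("row_length", 5))
        lines = tuple(OptotypeLine(float(d), row_length) for d in blk.get("lines", DEFAULT_DENOMINATORS))
        mode = blk.get("vocab_mode", LETTERS)
        default_vocab = DEFAULT_LETTER_VOCAB if mode == LETTERS else DEFAULT_NUMBER_VOCAB
        vocab = tuple(str(s).upper() for s in blk.get("vocab", default_vocab))
        return cls(lines=lines, vocab_mode=mode, vocab=vocab, distance_m=float(blk.get("distance_m", 6.0)))

    @classmethod
    def from_yaml(cls, path) -> "ChartSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class VAScore:
    """A measured acuity: base line plus a letter adjustment.

    ``adjustment`` follows clinical convention: "-m" = m optotypes missed on
    the recorded line (worse by 0.02*m logMAR), "+k" = k optotypes read on
    the next smaller line beyond a fully read row (better by 0.02*k).
    """

    line: Union[OptotypeLine, _WorseThanChart]
    adjustment: int = 0

    def __post_init__(self) -> None:
        if abs(self.adjustment) > 2:
            raise ChartDomainError(f"|adjustment| must be <= 2, got {self.adjustment}")

    @property
    def is_offchart(self) -> bool:
        return self.line is WORSE_THAN_CHART

    @property
    def logmar(self) -> float:
        if self.is_offchart:
            return math.inf
        return self.line.logmar - LETTER_STEP * self.adjustment

    def __str__(self) -> str:
        if self.is_offchart:
            return "worse than chart"
        if self.adjustment == 0:
            return self.line.snellen
        return f"{self.line.snellen} {self.adjustment:+d}"


@dataclass(frozen=True)
class OptotypeRow:
    """A concrete presentation row: symbols drawn from the chart vocabulary,
    no within-row repeats (repeats would make spoken responses ambiguous)."""

    line: OptotypeLine
    symbols: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.symbols) != self.line.row_length:
            raise ChartDomainError("row length mismatch")
        if len(set(self.symbols)) != len(self.symbols):
            raise ChartDomainError("row symbols must not repeat")


def snellen_to_logmar(denominator: float, adjustment: int = 0) -> float:
    """Convert a Snellen 6/denominator score with letter adjustment to logMAR.

    logMAR = log10(denominator/6) - 0.02 * adjustment. Full precision; any
    rounding is a display concern.
    """
    if denominator <= 0:
        raise ChartDomainError(f"denominator must be positive, got {denominator}")
    if abs(adjustment) > 2:
        raise ChartDomainError(f"|adjustment| must be <= 2, got {adjustment}")
    return math.log10(denominator / 6.0) - LETTER_STEP * adjustment


def logmar_to_snellen(logmar: float, chart: ChartSpec):
    """Inverse mapping for reports: nearest chart line plus clamped adjustment.

    Returns ``(OptotypeLine, adjustment)`` or ``(WORSE_THAN_CHART, 0)`` when
    the value lies more than two letters beyond the largest line. Exact
    round trip for values produced by :func:`snellen_to_logmar` on chart
    lines with |adjustment| <= 2.
    """
    if not chart.lines:
        raise ChartDomainError("chart is empty")
    worst = chart.largest.logmar
    if logmar > worst + 2 * LETTER_STEP + 1e-12:
        return WORSE_THAN_CHART, 0
    line = min(chart.lines, key=lambda ln: abs(logmar - ln.logmar))
    adj = round((line.logmar - logmar) / LETTER_STEP)
    adj = max(-2, min(2, adj))
    return line, adj


def generate_row(line: OptotypeLine, chart: ChartSpec, seed: int) -> OptotypeRow:
    """Draw a presentation row: ``row_length`` distinct vocabulary symbols,
    deterministic for a given seed."""
    import numpy as np

    if len(chart.vocab) < line.row_length:
        raise ChartDomainError(
            f"vocabulary of {len(chart.vocab)} symbols cannot fill a row of {line.row_length}"
        )
    rng = np.random.default_rng(seed)
    symbols = tuple(rng.choice(list(chart.vocab), size=line.row_length, replace=False))
    return OptotypeRow(line=line, symbols=symbols, seed=seed)
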