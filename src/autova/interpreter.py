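"""Transcript interpretation under the constrained exam vocabulary.

The recogniser is a pluggable backend producing :class:`Transcript` objects;
the exam only ever needs optotype symbols (nine letters or the digits 0-9)
plus the control commands OK / BLURRED / SKIP / REPEAT. A deterministic
:class:`MockRecognizer` stands in for a real ASR+VAD pipeline and injects
seeded confusions, so recognition error handling is testable without audio.

Word error rate, the standard ASR evaluation metric, is computed from a
minimum edit-distance alignment: WER = 100 * (S + I + D) / N with S
substitutions, I insertions, D deletions against a reference of N tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import yaml

from .chart import LETTERS, NUMBERS

COMMANDS = ("OK", "BLURRED", "SKIP", "REPEAT")


class InterpreterError(ValueError):
    pass


@dataclass(frozen=True)
class Transcript:
    """One recognised utterance with its speech-segment times."""

    text: str
    segment_start_s: float = 0.0
    segment_end_s: float = 0.0
    backend_id: str = "mock"

    def __post_init__(self) -> None:
        if self.segment_end_s < self.segment_start_s:
            raise InterpreterError("segment end before start")


@dataclass(frozen=True)
class ParsedResponse:
    """Either a sequence of optotype symbols or a single control command."""

    kind: str  # "SYMBOLS" | "COMMAND"
    symbols: tuple[str, ...] = ()
    command: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == "SYMBOLS" and (self.command is not None or not self.symbols):
            raise InterpreterError("SYMBOLS response must carry symbols only")
        if self.kind == "COMMAND" and (self.command not in COMMANDS or self.symbols):
            raise InterpreterError("COMMAND response must carry one known command")

    @classmethod
    def of_symbols(cls, symbols: Sequence[str]) -> "ParsedResponse":
        return cls(kind="SYMBOLS", symbols=tuple(symbols))

    @classmethod
    def of_command(cls, command: str) -> "ParsedResponse":
        return cls(kind="COMMAND", command=command)


@dataclass(frozen=True)
class WERResult:
    S: int
    I: int
    D: int
    N: int

    @property
    def wer_percent(self) -> float:
        return 100.0 * (self.S + self.I + self.D) / self.N


def _load_homophones() -> dict:
    with resources.files("autova.data").joinpath("homophones.yml").open() as fh:
        return yaml.safe_load(fh)


_HOMOPHONES = _load_homophones()


def normalize(transcript, vocab_mode: str = LETTERS, homophones: Optional[dict] = None) -> list[str]:
    """Canonicalise a transcript into candidate tokens.

    Upper-cases, strips punctuation, splits on whitespace, and maps spoken
    forms ("bee" -> B, "zero" -> 0) through the homophone table for the
    active mode. Unknown tokens are retained (the parser decides what to do
    with them). Idempotent: normalising its own output is a no-op.
    """
    text = transcript.text if isinstance(transcript, Transcript) else str(transcript)
    table = homophones if homophones is not None else _HOMOPHONES
    mode_map = dict(table.get("numbers" if vocab_mode == NUMBERS else "letters", {}))
    cmd_map = dict(table.get("commands", {}))
    tokens: list[str] = []
    for raw in re.sub(r"[^\w\s]", " ", text.upper()).split():
        tok = mode_map.get(raw, cmd_map.get(raw, raw))
        tokens.append(tok)
    return tokens


def parse(tokens: Sequence[str], vocab: Iterable[str]) -> ParsedResponse:
    """Interpret normalised tokens against the active vocabulary.

    Command words alone yield a COMMAND; vocabulary symbols (with unknown
    tokens dropped) yield SYMBOLS; a mixture of commands and symbols is
    ambiguous and, like an empty usable transcript, resolves to REPEAT so
    the stimulus is re-presented.
    """
    vocab_set = set(vocab)
    commands = [t for t in tokens if t in COMMANDS]
    symbols = [t for t in tokens if t in vocab_set]
    if commands and symbols:
        return ParsedResponse.of_command("REPEAT")
    if commands:
        return ParsedResponse.of_command(commands[0])
    if symbols:
        return ParsedResponse.of_symbols(symbols)
    return ParsedResponse.of_command("REPEAT")


def wer(reference: Sequence[str], hypothesis: Sequence[str]) -> WERResult:
    """Word error rate from a unit-cost minimum edit-distance alignment.

    Ties between a substitution and an insertion+deletion pair are broken
    in favour of the substitution, which makes the (S, I, D) split
    deterministic; the total S+I+D is the Levenshtein distance either way.
    WER may exceed 100% when the hypothesis is much longer than the
    reference.
    """
    n, m = len(reference), len(hypothesis)
    if n == 0:
        raise InterpreterError("reference must be non-empty")
    # dist[i][j] = edit distance between reference[:i] and hypothesis[:j]
    dist = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        dist[i][0] = i
    for j in range(m + 1):
        dist[0][j] = j
    for i in range(1, n + 1):
        ri = reference[i - 1]
        for j in range(1, m + 1):
            sub = dist[i - 1][j - 1] + (ri != hypothesis[j - 1])
            dist[i][j] = min(sub, dist[i - 1][j] + 1, dist[i][j - 1] + 1)
    # Backtrace, diagonal first so substitutions win ties.
    S = I = D = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dist[i][j] == dist[i - 1][j - 1] + (reference[i - 1] != hypothesis[j - 1]):
            S += reference[i - 1] != hypothesis[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and dist[i][j] == dist[i - 1][j] + 1:
            D += 1
            i -= 1
        else:
            I += 1
            j -= 1
    return WERResult(S=S, I=I, D=D, N=n)


@dataclass
class ConfusionSpec:
    """Per-token corruption model for the mock recogniser.

    sub_rate: probability a token is replaced by a member of its confusion
    set (or dropped if the set is empty). drop_rate / dup_rate: independent
    deletion and duplication probabilities.
    """

    sub_rate: float = 0.0
    drop_rate: float = 0.0
    dup_rate: float = 0.0
    confusions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.drop_rate, self.dup_rate):
            if not 0.0 <= r <= 1.0:
                raise InterpreterError("rates must lie in [0, 1]")


class MockRecognizer:
    """Deterministic test double for the VAD+ASR backend contract.

    Consumes true utterances and emits :class:`Transcript` objects with
    seeded per-token confusions. With all rates zero the transcript equals
    the utterance exactly, which is what lets end-to-end tests compare the
    speech path against direct symbol injection.
    """

    backend_id = "mock"

    def __init__(self, spec: Optional[ConfusionSpec] = None, seed: int = 0) -> None:
        self.spec = spec or ConfusionSpec()
        self.rng = np.random.default_rng(seed)
        self._clock = 0.0

    def _corrupt(self, token: str) -> list[str]:
        out = [token]
        spec = self.spec
        if spec.sub_rate and self.rng.random() < spec.sub_rate:
            choices = spec.confusions.get(token, [])
            out = [str(self.rng.choice(choices))] if choices else []
        if out and spec.drop_rate and self.rng.random() < spec.drop_rate:
            out = []
        if out and spec.dup_rate and self.rng.random() < spec.dup_rate:
            out = out + out
        return out

    def transcribe(self, utterance: str) -> Transcript:
        tokens: list[str] = []
        for tok in utterance.split():
            tokens.extend(self._corrupt(tok))
        start = self._clock
        self._clock += 1.0
        return Transcript(
            text=" ".join(tokens),
            segment_start_s=start,
            segment_end_s=self._clock,
            backend_id=self.backend_id,
        )

    def run(self, script: Iterable[str]) -> Iterator[Transcript]:
        for utterance in script:
            yield self.transcribe(utterance)


def mock_recognizer(script: Sequence[str], spec: Optional[ConfusionSpec] = None, seed: int = 0) -> list[Transcript]:
    """Convenience wrapper: transcribe a whole script deterministically."""
    return list(MockRecognizer(spec, seed).run(script))
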