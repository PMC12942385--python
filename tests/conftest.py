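import math

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from autova import engine as eng
from autova.chart import ChartSpec
from autova.interpreter import ParsedResponse


@pytest.fixture
def chart() -> ChartSpec:
    return ChartSpec.default()


def confirmed_exam(chart: ChartSpec, seed: int = 0) -> eng.ExamState:
    """A session past the instruction phase, at the largest line."""
    state = eng.start_exam(chart, seed)
    eng.apply_response(state, ParsedResponse.of_command("OK"))
    return state


def wrong_symbol(vocab, avoid: str) -> str:
    return next(s for s in vocab if s != avoid)


def threshold_response(stim, threshold_logmar: float, vocab) -> ParsedResponse:
    """Deterministic threshold reader: any optotype at or above the
    threshold is read correctly, anything smaller is missed."""
    readable = stim.line.logmar >= threshold_logmar - 1e-12
    if readable:
        return ParsedResponse.of_symbols(stim.symbols)
    return ParsedResponse.of_symbols(tuple(wrong_symbol(vocab, s) for s in stim.symbols))


def run_threshold_exam(chart: ChartSpec, right: float, left: float, seed: int = 0,
                       pinhole_right: float | None = None, pinhole_left: float | None = None):
    """Drive a full exam with per-eye deterministic thresholds; pinhole
    thresholds default to the unaided ones."""
    thresholds = {
        eng.ExamPhase.RIGHT_UNAIDED: right,
        eng.ExamPhase.LEFT_UNAIDED: left,
        eng.ExamPhase.RIGHT_PINHOLE: pinhole_right if pinhole_right is not None else right,
        eng.ExamPhase.LEFT_PINHOLE: pinhole_left if pinhole_left is not None else left,
    }
    state = confirmed_exam(chart, seed)
    for _ in range(10_000):
        if state.complete:
            return state
        stim = eng.next_stimulus(state)
        eng.apply_response(state, threshold_response(stim, thresholds[state.phase], chart.vocab))
        if state.phase_finalized:
            eng.advance_phase(state)
    raise AssertionError("exam did not terminate")


def run_scripted_phase(chart: ChartSpec, row_correct: dict[int, int], single_fail_at: int, seed: int = 0):
    """Drive one phase with scripted outcomes: singles pass until line
    index ``single_fail_at`` (exclusive), then each ROW presentation at
    line index i scores ``row_correct[i]`` correct positions."""
    state = confirmed_exam(chart, seed)
    for _ in range(1000):
        if state.phase_finalized or state.phase != eng.ExamPhase.RIGHT_UNAIDED:
            return state
        stim = eng.next_stimulus(state)
        idx = state.current_line_index
        if stim.kind == "SINGLE_OPTOTYPE":
            ok = idx < single_fail_at
            syms = stim.symbols if ok else (wrong_symbol(chart.vocab, stim.symbols[0]),)
        else:
            n_ok = row_correct.get(idx, 0)
            syms = tuple(
                s if i < n_ok else wrong_symbol(chart.vocab, s)
                for i, s in enumerate(stim.symbols)
            )
        eng.apply_response(state, ParsedResponse.of_symbols(syms))
    raise AssertionError("phase did not terminate")
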