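"""State-driven adaptive visual-acuity examination.

Protocol, per eye: descend the chart showing only the FIRST optotype of
each line until the patient misses one; then present full five-optotype
rows starting at the last line whose single optotype was read. A row passes
when more than half its optotypes are identified; passing advances to the
next smaller line, failing ends the phase. The recorded acuity is the
smallest line whose row passed, with letter adjustments: "-m" for m misses
on that row, "+k" for k extra optotypes read on the next smaller row after
a fully read line. Testing order is right eye then left eye, unaided; an
eye that does not achieve 6/9 or better repeats the protocol through a
pinhole occluder. Every transition is logged with an injectable clock so
whole sessions replay deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional

from .chart import (
    LETTER_STEP,
    WORSE_THAN_CHART,
    ChartSpec,
    OptotypeLine,
    OptotypeRow,
    VAScore,
    generate_row,
    snellen_to_logmar,
)
from .interpreter import ParsedResponse
from .pose import PoseClassification, PoseLabel


class ExamError(RuntimeError):
    pass


class ExamPhase(Enum):
    IDLE = "IDLE"
    INSTRUCT = "INSTRUCT"
    RIGHT_UNAIDED = "RIGHT_UNAIDED"
    LEFT_UNAIDED = "LEFT_UNAIDED"
    RIGHT_PINHOLE = "RIGHT_PINHOLE"
    LEFT_PINHOLE = "LEFT_PINHOLE"
    COMPLETE = "COMPLETE"
    ASSIST = "ASSIST"


#: Phases in which stimuli are presented, in protocol order.
TEST_PHASES = (
    ExamPhase.RIGHT_UNAIDED,
    ExamPhase.LEFT_UNAIDED,
    ExamPhase.RIGHT_PINHOLE,
    ExamPhase.LEFT_PINHOLE,
)

#: Occluder pose required for each test phase (labels name the TESTED eye).
REQUIRED_POSE = {
    ExamPhase.RIGHT_UNAIDED: PoseLabel.RIGHT,
    ExamPhase.LEFT_UNAIDED: PoseLabel.LEFT,
    ExamPhase.RIGHT_PINHOLE: PoseLabel.RIGHT_PH,
    ExamPhase.LEFT_PINHOLE: PoseLabel.LEFT_PH,
}

SINGLE = "SINGLE"
ROW = "ROW"


@dataclass(frozen=True)
class Stimulus:
    kind: str  # "SINGLE_OPTOTYPE" | "FULL_ROW"
    line: OptotypeLine
    symbols: tuple[str, ...]


@dataclass
class Event:
    t: float
    phase: str
    kind: str
    payload: dict

    def to_json(self) -> str:
        return json.dumps(
            {"t": self.t, "phase": self.phase, "kind": self.kind, "payload": self.payload},
            sort_keys=True,
        )


class StepClock:
    """Deterministic clock: advances a fixed step on every reading."""

    def __init__(self, step_s: float = 1.0) -> None:
        self.step_s = step_s
        self._t = 0.0

    def __call__(self) -> float:
        t = self._t
        self._t += self.step_s
        return t


@dataclass
class ExamState:
    """Snapshot of one examination (mutable; transition functions below)."""

    chart: ChartSpec
    seed: int
    session_id: str = "session"
    phase: ExamPhase = ExamPhase.INSTRUCT
    mode: str = SINGLE
    current_line_index: int = 0
    last_single_pass_index: Optional[int] = None
    row_results: dict = field(default_factory=dict)  # line index -> (correct, presented)
    passed_rows: set = field(default_factory=set)
    per_phase_results: dict = field(default_factory=dict)  # ExamPhase -> VAScore
    phase_finalized: bool = False
    event_log: list = field(default_factory=list)
    clock: Callable[[], float] = field(default_factory=StepClock)
    aborted: bool = False
    _resume_phase: Optional[ExamPhase] = None
    _pending: Optional[Stimulus] = None
    _row_cache: dict = field(default_factory=dict)      # (phase, idx) -> OptotypeRow
    _attempt_counter: dict = field(default_factory=dict)  # (phase, idx) -> presentations

    @property
    def required_pose(self) -> Optional[PoseLabel]:
        return REQUIRED_POSE.get(self.phase)

    @property
    def complete(self) -> bool:
        return self.phase == ExamPhase.COMPLETE

    def log(self, kind: str, payload: dict) -> None:
        self.event_log.append(Event(t=self.clock(), phase=self.phase.value, kind=kind, payload=payload))

    # -- internal helpers --------------------------------------------------

    def _row_for(self, idx: int) -> OptotypeRow:
        key = (self.phase, idx)
        if key not in self._row_cache:
            attempt = self._attempt_counter.get(key, 0)
            phase_ord = TEST_PHASES.index(self.phase)
            row_seed = (self.seed * 1_000_003 + phase_ord * 10_007 + idx * 101 + attempt * 7) % (2**31)
            self._row_cache[key] = generate_row(self.chart.lines[idx], self.chart, row_seed)
        return self._row_cache[key]

    def _consume_row(self, idx: int) -> None:
        key = (self.phase, idx)
        self._attempt_counter[key] = self._attempt_counter.get(key, 0) + 1
        self._row_cache.pop(key, None)


def start_exam(chart: ChartSpec, seed: int, session_id: str = "session", clock: Optional[Callable[[], float]] = None) -> ExamState:
    """Begin a session in the instruction phase; the exam proper starts
    only after a verbal "OK" confirmation."""
    state = ExamState(chart=chart, seed=seed, session_id=session_id)
    if clock is not None:
        state.clock = clock
    state.log("COMMAND", {"event": "session_start", "session_id": session_id, "seed": seed})
    return state


def _begin_phase(state: ExamState, phase: ExamPhase, start_index: int = 0) -> None:
    state.phase = phase
    state.mode = SINGLE
    state.current_line_index = start_index
    state.last_single_pass_index = None
    state.row_results = {}
    state.passed_rows = set()
    state.phase_finalized = False
    state._pending = None
    state.log("COMMAND", {"event": "phase_start", "start_line": state.chart.lines[start_index].snellen})


def next_stimulus(state: ExamState) -> Stimulus:
    """The stimulus to present now: the current line's first optotype in
    SINGLE mode, or its full row in ROW mode. Stable across REPEATs."""
    if state.phase not in TEST_PHASES:
        raise ExamError(f"no stimulus in phase {state.phase.value}")
    if state.phase_finalized:
        raise ExamError("phase already finalized; advance_phase first")
    if state._pending is None:
        row = state._row_for(state.current_line_index)
        if state.mode == SINGLE:
            state._pending = Stimulus("SINGLE_OPTOTYPE", row.line, (row.symbols[0],))
        else:
            state._pending = Stimulus("FULL_ROW", row.line, row.symbols)
        state.log(
            "STIMULUS",
            {"kind": state._pending.kind, "line": row.line.snellen, "symbols": list(state._pending.symbols)},
        )
    return state._pending


def _finalize(state: ExamState) -> VAScore:
    """Score the phase: smallest passed row, with letter adjustments."""
    if not state.passed_rows:
        score = VAScore(WORSE_THAN_CHART, 0)
    else:
        best = max(state.passed_rows)  # largest index = smallest optotype
        correct, presented = state.row_results[best]
        misses = presented - correct
        if misses > 0:
            adj = -misses
        else:
            adj = 0
            nxt = state.row_results.get(best + 1)
            if nxt is not None and best + 1 not in state.passed_rows and 1 <= nxt[0] <= 2:
                adj = nxt[0]
        score = VAScore(state.chart.lines[best], adj)
    state.per_phase_results[state.phase] = score
    state.phase_finalized = True
    state._pending = None
    state.log("SCORE", {"score": str(score), "logmar": None if score.is_offchart else round(score.logmar, 4)})
    return score


def finalize_phase(state: ExamState) -> VAScore:
    """The finalized score of the current phase (computed when a row
    outcome terminated it)."""
    if not state.phase_finalized:
        raise ExamError("phase is not finished")
    return state.per_phase_results[state.phase]


def apply_response(state: ExamState, response: ParsedResponse) -> ExamState:
    """Apply one parsed response and update the progression.

    SINGLE mode: a correct symbol descends one line (or switches to ROW
    mode at the smallest line); a miss/BLURRED/SKIP anchors ROW mode at the
    last single-optotype pass, or ends the phase worse-than-chart if there
    was none. ROW mode: symbols are marked positionally; >half correct
    passes and advances, otherwise the phase is scored (backing up a line
    when nothing has passed yet). REPEAT re-presents the same stimulus.
    """
    if state.phase == ExamPhase.INSTRUCT:
        if response.kind == "COMMAND" and response.command == "OK":
            state.log("COMMAND", {"command": "OK"})
            _begin_phase(state, ExamPhase.RIGHT_UNAIDED, 0)
        else:
            state.log("COMMAND", {"command": "ignored_during_instruct"})
        return state
    if state.phase not in TEST_PHASES or state.phase_finalized:
        raise ExamError(f"cannot apply a response in phase {state.phase.value}")

    stim = next_stimulus(state)

    if response.kind == "COMMAND":
        if response.command == "REPEAT":
            state.log("RESPONSE", {"command": "REPEAT"})
            return state
        if response.command == "OK":
            state.log("RESPONSE", {"command": "ignored_ok"})
            return state
        # BLURRED / SKIP: cannot read the stimulus
        state.log("RESPONSE", {"command": response.command})
        return _mark(state, stim, correct_positions=0)

    # Symbols outside the chart vocabulary are a recognizer artefact:
    # reject and re-prompt without counting.
    offvocab = [s for s in response.symbols if s not in state.chart.vocab]
    if offvocab:
        state.log("RESPONSE", {"rejected": offvocab, "reason": "out_of_vocabulary"})
        return state

    if stim.kind == "SINGLE_OPTOTYPE":
        ok = bool(response.symbols) and response.symbols[0] == stim.symbols[0]
        state.log("RESPONSE", {"symbols": list(response.symbols), "correct": int(ok)})
        return _mark(state, stim, correct_positions=1 if ok else 0)

    # FULL_ROW: positional marking; short responses leave positions wrong.
    marks = [
        i < len(response.symbols) and response.symbols[i] == sym
        for i, sym in enumerate(stim.symbols)
    ]
    state.log("RESPONSE", {"symbols": list(response.symbols), "marks": [int(m) for m in marks]})
    return _mark(state, stim, correct_positions=sum(marks))


def _mark(state: ExamState, stim: Stimulus, correct_positions: int) -> ExamState:
    idx = state.current_line_index
    last = len(state.chart.lines) - 1
    state._pending = None

    if stim.kind == "SINGLE_OPTOTYPE":
        if correct_positions:
            state.last_single_pass_index = idx
            if idx == last:
                state.mode = ROW  # smallest line read as a single: confirm with its row
            else:
                state.current_line_index = idx + 1
        else:
            if state.last_single_pass_index is None:
                _finalize(state)
            else:
                state.mode = ROW
                state.current_line_index = state.last_single_pass_index
        return state

    # FULL_ROW outcome
    state._consume_row(idx)
    state.row_results[idx] = (correct_positions, len(stim.symbols))
    passed = 2 * correct_positions > len(stim.symbols)
    if passed:
        state.passed_rows.add(idx)
        if idx == last:
            _finalize(state)
        else:
            state.current_line_index = idx + 1
    else:
        if state.passed_rows:
            _finalize(state)
        elif idx > 0:
            state.current_line_index = idx - 1  # back up until some row passes
        else:
            _finalize(state)
    return state


def pinhole_needed(unaided: VAScore, chart: ChartSpec) -> bool:
    """Pinhole testing is indicated when the unaided acuity, letter
    adjustments included, is worse than 6/9 (strictly greater logMAR)."""
    return unaided.logmar > snellen_to_logmar(9, 0)


def _pinhole_start_index(state: ExamState, unaided: VAScore) -> int:
    if unaided.is_offchart:
        return 0
    return max(0, state.chart.index_of(unaided.line) - 2)


def advance_phase(state: ExamState) -> ExamState:
    """Move to the next phase: right then left unaided, then a pinhole
    phase for each eye whose unaided score triggers it, then COMPLETE.
    Pinhole phases restart the single-then-row protocol two lines above
    the eye's unaided score."""
    if state.phase not in TEST_PHASES or not state.phase_finalized:
        raise ExamError("current phase is not finalized")
    res = state.per_phase_results
    if state.phase == ExamPhase.RIGHT_UNAIDED:
        _begin_phase(state, ExamPhase.LEFT_UNAIDED, 0)
        return state
    order = []
    if pinhole_needed(res[ExamPhase.RIGHT_UNAIDED], state.chart):
        order.append((ExamPhase.RIGHT_PINHOLE, res[ExamPhase.RIGHT_UNAIDED]))
    if pinhole_needed(res[ExamPhase.LEFT_UNAIDED], state.chart):
        order.append((ExamPhase.LEFT_PINHOLE, res[ExamPhase.LEFT_UNAIDED]))
    remaining = [(ph, sc) for ph, sc in order if ph not in res]
    if remaining:
        ph, unaided = remaining[0]
        _begin_phase(state, ph, _pinhole_start_index(state, unaided))
    else:
        state.phase = ExamPhase.COMPLETE
        state.log("COMMAND", {"event": "exam_complete"})
    return state


def gate_on_pose(state: ExamState, pose: PoseClassification) -> bool:
    """True when stimulus presentation is allowed: the (already debounced)
    pose matches the phase's required occluder state. A mismatch logs a
    guidance event and pauses the exam."""
    if state.phase not in TEST_PHASES:
        raise ExamError("pose gating applies only to active test phases")
    label = pose.label if isinstance(pose, PoseClassification) else pose
    ok = label == state.required_pose
    state.log("POSE", {"label": str(label), "required": str(state.required_pose), "allowed": int(ok)})
    if not ok:
        state.log("COMMAND", {"event": "pose_guidance", "required": str(state.required_pose)})
    return ok


def request_assist(state: ExamState) -> ExamState:
    """Staff intervention: pause without terminating the session."""
    if state.phase in (ExamPhase.ASSIST, ExamPhase.COMPLETE):
        raise ExamError("assist unavailable in this phase")
    state._resume_phase = state.phase
    state.phase = ExamPhase.ASSIST
    state.log("ASSIST", {"event": "assist_start"})
    return state


def resume_from_assist(state: ExamState) -> ExamState:
    if state.phase != ExamPhase.ASSIST or state._resume_phase is None:
        raise ExamError("not in assist")
    state.phase = state._resume_phase
    state._resume_phase = None
    state.log("ASSIST", {"event": "assist_end"})
    return state


@dataclass
class SessionReport:
    """Final summary: per-eye scores, per-phase durations, event counts."""

    session_id: str
    seed: int
    scores: dict            # phase name -> {"score": str, "logmar": float|None}
    durations_s: dict       # phase name -> float
    event_counts: dict      # event kind -> int
    aborted: bool = False
    feedback: Optional[int] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "session_id": self.session_id,
                "seed": self.seed,
                "scores": self.scores,
                "durations_s": self.durations_s,
                "event_counts": self.event_counts,
                "aborted": self.aborted,
                "feedback": self.feedback,
            },
            sort_keys=True,
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"Session {self.session_id} (seed {self.seed})"]
        if self.aborted:
            lines.append("  ** ABORTED — partial results **")
        for phase, entry in self.scores.items():
            lm = entry["logmar"]
            lm_txt = "n/a" if lm is None else f"{lm:+.2f}"
            lines.append(f"  {phase:14s} {entry['score']:>16s}  logMAR {lm_txt}  ({self.durations_s.get(phase, 0.0):.1f} s)")
        return "\n".join(lines)

    def csv_rows(self) -> list[dict]:
        """One row per eye for the agreement-statistics input schema."""

        def lm(phase: str):
            e = self.scores.get(phase)
            return None if e is None else e["logmar"]

        return [
            {
                "session_id": self.session_id,
                "eye": "OD",
                "unaided_logmar": lm("RIGHT_UNAIDED"),
                "pinhole_logmar": lm("RIGHT_PINHOLE"),
                "duration_s": self.durations_s.get("RIGHT_UNAIDED", 0.0) + self.durations_s.get("RIGHT_PINHOLE", 0.0),
            },
            {
                "session_id": self.session_id,
                "eye": "OS",
                "unaided_logmar": lm("LEFT_UNAIDED"),
                "pinhole_logmar": lm("LEFT_PINHOLE"),
                "duration_s": self.durations_s.get("LEFT_UNAIDED", 0.0) + self.durations_s.get("LEFT_PINHOLE", 0.0),
            },
        ]


def generate_report(state: ExamState, feedback: Optional[int] = None) -> SessionReport:
    """Summarise a session; an incomplete exam yields a partial report
    flagged as aborted."""
    aborted = not state.complete
    scores = {}
    for phase, score in state.per_phase_results.items():
        scores[phase.value] = {
            "score": str(score),
            "logmar": None if score.is_offchart else round(score.logmar, 4),
        }
    durations: dict[str, float] = {}
    starts: dict[str, float] = {}
    for ev in state.event_log:
        starts.setdefault(ev.phase, ev.t)
        durations[ev.phase] = ev.t - starts[ev.phase]
    durations = {p: durations.get(p, 0.0) for p in scores}
    counts: dict[str, int] = {}
    for ev in state.event_log:
        counts[ev.kind] = counts.get(ev.kind, 0) + 1
    return SessionReport(
        session_id=state.session_id,
        seed=state.seed,
        scores=scores,
        durations_s=durations,
        event_counts=counts,
        aborted=aborted,
        feedback=feedback,
    )
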