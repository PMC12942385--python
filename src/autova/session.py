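"""End-to-end session workflows: simulated and interactive examinations,
and the pose-table validation harness.

A simulated session wires the whole pipeline together: the simulated
patient produces spoken responses, a (mock) recogniser transcribes them,
the interpreter parses the transcript under the chart vocabulary, the pose
stream is debounced and gated, and the exam engine drives progression.
Everything downstream of the seed is deterministic, so identical configs
replay byte-for-byte.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, TextIO

import numpy as np

from . import engine as eng
from .chart import ChartSpec
from .engine import ExamPhase, ExamState, SessionReport, StepClock
from .interpreter import ConfusionSpec, MockRecognizer, normalize, parse
from .pose import (
    EXPECTED_FINAL_POSE,
    POSE_DESCRIPTIONS,
    PoseClassification,
    PoseLabel,
    classify_pose,
    synth_pose_fixture,
)
from .simulate import PatientProfile, respond, spoken_symbols


class SessionError(RuntimeError):
    pass


@dataclass
class SessionConfig:
    chart: ChartSpec
    patient: PatientProfile
    seed: int = 0
    session_id: str = "session"
    use_speech_path: bool = True
    recognizer_spec: ConfusionSpec = field(default_factory=ConfusionSpec)
    debounce_k: int = 5
    clock_step_s: float = 1.0
    log_path: Optional[Path] = None
    report_path: Optional[Path] = None
    max_events: int = 5000


def _gate_until_valid(state: ExamState, required: PoseLabel, error_rate: float, k: int, rng: np.random.Generator) -> None:
    """Feed simulated (debounced) pose frames until the required occluder
    state holds for k consecutive frames."""
    run = 0
    for _ in range(10_000):
        bad = rng.random() < error_rate
        label = PoseLabel.INVALID if bad else required
        if label == PoseLabel.INVALID:
            run = 0
            eng.gate_on_pose(state, PoseClassification(label, False, frozenset()))
            continue
        run += 1
        if run >= k:
            allowed = eng.gate_on_pose(state, PoseClassification(label, True, frozenset()))
            if allowed:
                return
            run = 0
    raise SessionError("pose never stabilised on the required occluder state")


def run_simulated_session(config: SessionConfig) -> SessionReport:
    """Run a full examination against the simulated patient.

    Returns the session report; when ``log_path`` / ``report_path`` are set
    the JSONL event log and JSON report are written as well.
    """
    clock = StepClock(config.clock_step_s)
    state = eng.start_exam(config.chart, config.seed, config.session_id, clock=clock)
    ss = np.random.SeedSequence(config.seed)
    patient_rng, pose_rng, reco_seed = ss.spawn(3)
    patient_rng = np.random.default_rng(patient_rng)
    pose_rng = np.random.default_rng(pose_rng)
    recognizer = MockRecognizer(config.recognizer_spec, seed=int(reco_seed.generate_state(1)[0] % (2**31)))

    eng.apply_response(state, parse(normalize("OK", config.chart.vocab_mode), config.chart.vocab))

    events = 0
    while not state.complete:
        events += 1
        if events > config.max_events:
            state.aborted = True
            break
        _gate_until_valid(state, state.required_pose, config.patient.pose_error_rate, config.debounce_k, pose_rng)
        stim = eng.next_stimulus(state)
        if config.use_speech_path:
            syms = spoken_symbols(stim, config.patient, state.phase, patient_rng, config.chart.vocab)
            utterance = "blurred" if syms is None else " ".join(syms)
            transcript = recognizer.transcribe(utterance)
            response = parse(normalize(transcript, config.chart.vocab_mode), config.chart.vocab)
        else:
            response = respond(stim, config.patient, state.phase, patient_rng, config.chart.vocab)
        eng.apply_response(state, response)
        if state.phase_finalized:
            eng.advance_phase(state)

    report = eng.generate_report(state)
    _write_outputs(state, report, config.log_path, config.report_path)
    return report


def run_interactive_session(config: SessionConfig, stdin: Optional[TextIO] = None, stdout: Optional[TextIO] = None) -> SessionReport:
    """Terminal-driven session: stimuli are printed, responses typed.

    Commands (ok / blurred / skip / repeat) and symbol rows are parsed
    exactly as spoken responses would be. EOF aborts with a partial report.
    """
    fin = stdin or sys.stdin
    fout = stdout or sys.stdout
    clock = StepClock(config.clock_step_s)
    state = eng.start_exam(config.chart, config.seed, config.session_id, clock=clock)
    print("Say/type OK to begin the examination.", file=fout)
    try:
        while not state.complete:
            if state.phase == ExamPhase.INSTRUCT:
                line = _read(fin, fout, "> ")
                eng.apply_response(state, parse(normalize(line, config.chart.vocab_mode), config.chart.vocab))
                continue
            stim = eng.next_stimulus(state)
            shown = " ".join(stim.symbols)
            print(f"[{state.phase.value} | {stim.line.snellen}] read: {shown}", file=fout)
            line = _read(fin, fout, "> ")
            eng.apply_response(state, parse(normalize(line, config.chart.vocab_mode), config.chart.vocab))
            if state.phase_finalized:
                print(f"  phase score: {eng.finalize_phase(state)}", file=fout)
                eng.advance_phase(state)
    except EOFError:
        state.aborted = True
    report = eng.generate_report(state)
    print(report.to_text(), file=fout)
    _write_outputs(state, report, config.log_path, config.report_path)
    return report


def _read(fin: TextIO, fout: TextIO, prompt: str) -> str:
    if fin is sys.stdin:  # pragma: no cover - interactive only
        return input(prompt)
    line = fin.readline()
    if line == "":
        raise EOFError
    return line.strip()


def _write_outputs(state: ExamState, report: SessionReport, log_path, report_path) -> None:
    if log_path is not None:
        with open(log_path, "w") as fh:
            for ev in state.event_log:
                fh.write(ev.to_json() + "\n")
    if report_path is not None:
        with open(report_path, "w") as fh:
            fh.write(report.to_json() + "\n")


def session_log_lines(state: ExamState) -> list[str]:
    return [ev.to_json() for ev in state.event_log]


def validate_pose_table(n_seeds: int = 1, base_seed: int = 0) -> tuple[list[dict], bool]:
    """Classify synthetic fixtures for the nine validation poses and
    compare against the expected final-pose column.

    Returns (rows, all_match); each row reports the pose id, description,
    detected marker ids, the classified label, the expectation and the
    number of seeds checked.
    """
    rows = []
    all_match = True
    for pose_id in range(1, 10):
        labels = set()
        ids_seen = set()
        for s in range(n_seeds):
            obs = synth_pose_fixture(pose_id, seed=base_seed + 1000 * pose_id + s)
            cls = classify_pose(obs)
            labels.add(cls.label)
            ids_seen.add(tuple(sorted(obs.marker_ids)))
        expected = EXPECTED_FINAL_POSE[pose_id]
        match = labels == {expected}
        all_match = all_match and match
        rows.append(
            {
                "pose_id": pose_id,
                "description": POSE_DESCRIPTIONS[pose_id],
                "marker_ids": sorted(ids_seen.pop()) if len(ids_seen) == 1 else sorted(ids_seen),
                "final_pose": str(next(iter(labels))) if len(labels) == 1 else sorted(str(l) for l in labels),
                "expected": str(expected),
                "seeds": n_seeds,
                "match": match,
            }
        )
    return rows, all_match
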