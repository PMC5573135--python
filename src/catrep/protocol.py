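"""Trial schedules and session logs for the two-phase categorization task.

A session is 6 blocks of 100 trials. Blocks 1-5 train two category contrasts
(A vs B and C vs D) with feedback; block 6 is a transfer test on the novel
B vs C contrast with no feedback. Two questioning conditions exist:

* ``AB`` (classification): each trial shows a pair question ("A or B?",
  "C or D?", at test "B or C?") and the response is a category button.
* ``YN`` (concept): each trial names a single target category ("Is this a
  'B'?") and the response is yes/no; "no" implies the target's contrast
  partner (A<->B, C<->D in training, B<->C at test).

Every stimulus in the 600-stimulus set appears exactly once, and the
training and test stimulus sets are disjoint. Categories, questioned pairs
and (for YN) target labels are balanced within each block up to rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structures import (
    DEFAULT_COUNTS,
    LABELS,
    CategoryStructure,
    make_structure,
    sample_stimuli,
)

__all__ = [
    "Trial",
    "Session",
    "Cohort",
    "SessionParseError",
    "SessionValidationError",
    "TRAIN_PAIRS",
    "TEST_PAIR",
    "contrast_partner",
    "build_schedule",
    "record_response",
    "write_session_csv",
    "read_session_csv",
    "write_cohort",
    "read_cohort",
]

TRAIN_PAIRS: tuple[tuple[str, str], ...] = (("A", "B"), ("C", "D"))
TEST_PAIR: tuple[str, str] = ("B", "C")

CATEGORY_RESPONSES = {"A", "B", "C", "D"}
YESNO_RESPONSES = {"yes", "no"}
NONRESPONSES = {"timeout", "wrong_key", "none"}

CSV_HEADER = (
    "participant_id,condition,structure,block,trial,phase,question,"
    "dim1,dim2,true_category,response,implied_category,correct,feedback_given"
)


class SessionParseError(ValueError):
    """Malformed session CSV (bad header or row); carries the line number."""


class SessionValidationError(ValueError):
    """A structurally valid file that violates a session invariant."""


def contrast_partner(label: str, phase: str) -> str:
    """The category a 'no' response implies for a given target and phase."""
    if phase == "test":
        mapping = {"B": "C", "C": "B"}
    else:
        mapping = {"A": "B", "B": "A", "C": "D", "D": "C"}
    return mapping[label]


@dataclass
class Trial:
    """One row of a session log.

    ``question`` is encoded ``"A|B"`` (pair question, AB condition) or
    ``"is:A"`` (target question, YN condition). ``response`` is a raw token
    (category label, ``yes``/``no``, or ``timeout``/``wrong_key``/``none``);
    ``implied_category`` is the category the response commits to given the
    question.
    """

    index: int
    block: int
    phase: str  # "train" | "test"
    question: str
    dim1: float
    dim2: float
    true_category: str
    response: str | None = None
    implied_category: str | None = None
    correct: int | None = None
    feedback_given: int = 0

    @property
    def stimulus(self) -> np.ndarray:
        return np.array([self.dim1, self.dim2])

    @property
    def is_pair_question(self) -> bool:
        return "|" in self.question

    @property
    def target(self) -> str:
        """Target label of a YN question."""
        if not self.question.startswith("is:"):
            raise ValueError(f"not a target question: {self.question!r}")
        return self.question[3:]

    def question_pair(self) -> tuple[str, str]:
        """The ordered category pair a question discriminates."""
        if self.is_pair_question:
            a, b = self.question.split("|")
            return (a, b)
        t = self.target
        u = contrast_partner(t, self.phase)
        return (t, u) if LABELS.index(t) < LABELS.index(u) else (u, t)

    @property
    def has_category_response(self) -> bool:
        return self.response in CATEGORY_RESPONSES or self.response in YESNO_RESPONSES


def record_response(trial: Trial, token: str) -> None:
    """Fill a trial's response fields from a raw response token.

    Derives ``implied_category`` (pressed label, or the target / its contrast
    partner for yes/no), ``correct``, and ``feedback_given`` (training trials
    with a category response only).
    """
    trial.response = token
    if token in NONRESPONSES:
        trial.implied_category = None
        trial.correct = None
        trial.feedback_given = 0
        return
    if trial.is_pair_question:
        if token not in trial.question_pair():
            raise ValueError(f"response {token!r} not in questioned pair {trial.question!r}")
        trial.implied_category = token
    else:
        if token not in YESNO_RESPONSES:
            raise ValueError(f"expected yes/no for question {trial.question!r}, got {token!r}")
        t = trial.target
        trial.implied_category = t if token == "yes" else contrast_partner(t, trial.phase)
    trial.correct = int(trial.implied_category == trial.true_category)
    trial.feedback_given = int(trial.phase == "train")


@dataclass
class Session:
    """One participant's ordered 600-trial log plus condition metadata."""

    participant_id: str
    condition: str  # "AB" | "YN"
    structure_kind: str  # "RB" | "II"
    seed: int
    trials: list[Trial] = field(default_factory=list)

    @property
    def has_responses(self) -> bool:
        return any(t.response is not None for t in self.trials)

    def block(self, b: int) -> list[Trial]:
        return [t for t in self.trials if t.block == b]

    def training_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.phase == "train"]

    def test_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.phase == "test"]

    def trial_window(self, lo: int, hi: int) -> list[Trial]:
        """Trials with index in [lo, hi] (1-based, inclusive)."""
        return [t for t in self.trials if lo <= t.index <= hi]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "participant_id": self.participant_id,
                    "condition": self.condition,
                    "structure": self.structure_kind,
                    "block": t.block,
                    "trial": t.index,
                    "phase": t.phase,
                    "question": t.question,
                    "dim1": t.dim1,
                    "dim2": t.dim2,
                    "true_category": t.true_category,
                    "response": t.response,
                    "implied_category": t.implied_category,
                    "correct": t.correct,
                    "feedback_given": t.feedback_given,
                }
            )
        return pd.DataFrame(rows)

    def validate(self) -> None:
        """Raise SessionValidationError on the first violated invariant."""
        _validate_session(self)


def _validate_session(s: Session) -> None:
    if len(s.trials) != 600:
        raise SessionValidationError(f"600 trials expected, got {len(s.trials)}")
    if [t.index for t in s.trials] != list(range(1, 601)):
        raise SessionValidationError("trial indices must be 1..600 in order")
    for b in range(1, 7):
        n = len(s.block(b))
        if n != 100:
            raise SessionValidationError(f"block {b} has {n} trials, expected 100")
    pair_counts = {p: 0 for p in TRAIN_PAIRS}
    stimuli = set()
    for t in s.trials:
        expected_phase = "train" if t.block <= 5 else "test"
        if t.phase != expected_phase:
            raise SessionValidationError(
                f"trial {t.index}: phase {t.phase!r} inconsistent with block {t.block}"
            )
        expected_fb = int(t.phase == "train" and t.has_category_response)
        if int(t.feedback_given) != expected_fb:
            raise SessionValidationError(
                f"trial {t.index}: feedback_given={t.feedback_given} but phase={t.phase!r}"
            )
        pair = t.question_pair()
        if t.phase == "train":
            if pair not in TRAIN_PAIRS:
                raise SessionValidationError(f"trial {t.index}: training question pair {pair}")
            pair_counts[pair] += 1
        else:
            if pair != TEST_PAIR:
                raise SessionValidationError(f"trial {t.index}: test question pair {pair}")
        if t.true_category not in pair:
            raise SessionValidationError(
                f"trial {t.index}: true category {t.true_category!r} outside pair {pair}"
            )
        if s.condition == "AB" and not t.is_pair_question:
            raise SessionValidationError(f"trial {t.index}: AB condition requires pair questions")
        if s.condition == "YN" and t.is_pair_question:
            raise SessionValidationError(f"trial {t.index}: YN condition requires target questions")
        stimuli.add((t.dim1, t.dim2))
    if len(stimuli) != 600:
        raise SessionValidationError("each stimulus must occur exactly once")
    if pair_counts[("A", "B")] != 250 or pair_counts[("C", "D")] != 250:
        raise SessionValidationError(
            f"training pairs must number 250 each, got {pair_counts}"
        )


@dataclass
class Cohort:
    """A list of sessions plus free-form metadata (e.g. ground-truth tags)."""

    sessions: list[Session]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.participant_id for s in self.sessions]
        if len(ids) != len(set(ids)):
            raise ValueError("participant_ids must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.sessions)

    def session(self, participant_id: str) -> Session:
        for s in self.sessions:
            if s.participant_id == participant_id:
                return s
        raise KeyError(participant_id)


def build_schedule(
    structure: CategoryStructure | str,
    condition: str,
    seed: int,
    participant_id: str = "",
    counts: Sequence[int] | None = None,
) -> Session:
    """Build a response-empty 600-trial schedule.

    Stimuli come from :func:`catrep.structures.sample_stimuli` with the
    default (125, 175, 175, 125) per-category counts. Each training block
    gets 25 stimuli per category (so AB and CD questions are equally
    likely), the test block 50 B and 50 C stimuli; YN target labels are
    crossed with the true category 50/50 up to rounding within each
    (block, category) cell. Trial order is shuffled within blocks.
    """
    if isinstance(structure, str):
        structure = make_structure(structure)
    if condition not in ("AB", "YN"):
        raise ValueError(f"unknown condition: {condition!r} (expected 'AB' or 'YN')")
    ss = np.random.SeedSequence(seed)
    stim_ss, order_ss = ss.spawn(2)
    sample = sample_stimuli(structure, counts=counts or DEFAULT_COUNTS, seed=stim_ss)
    rng = np.random.default_rng(order_ss)

    # Partition each category's stimuli into training and test pools.
    train_pool: dict[str, list[np.ndarray]] = {}
    test_pool: dict[str, list[np.ndarray]] = {}
    for lab in LABELS:
        pts = list(sample.subset(lab))
        n_test = 50 if lab in TEST_PAIR else 0
        n_train = len(pts) - n_test
        if n_train < 125 or n_train % 5:
            raise ValueError(f"category {lab}: cannot split {len(pts)} stimuli into 5 blocks")
        train_pool[lab] = pts[:n_train]
        test_pool[lab] = pts[n_train:]

    trials: list[Trial] = []
    idx = 1
    per_block = {lab: len(train_pool[lab]) // 5 for lab in LABELS}
    for b in range(1, 6):
        block_trials: list[Trial] = []
        for lab in LABELS:
            k = per_block[lab]
            pts = train_pool[lab][(b - 1) * k : b * k]
            questions = _training_questions(condition, lab, len(pts), rng)
            for pt, q in zip(pts, questions):
                block_trials.append(
                    Trial(
                        index=0,
                        block=b,
                        phase="train",
                        question=q,
                        dim1=float(pt[0]),
                        dim2=float(pt[1]),
                        true_category=lab,
                    )
                )
        rng.shuffle(block_trials)
        for t in block_trials:
            t.index = idx
            idx += 1
        trials.extend(block_trials)

    block_trials = []
    for lab in TEST_PAIR:
        pts = test_pool[lab]
        questions = _test_questions(condition, lab, len(pts), rng)
        for pt, q in zip(pts, questions):
            block_trials.append(
                Trial(
                    index=0,
                    block=6,
                    phase="test",
                    question=q,
                    dim1=float(pt[0]),
                    dim2=float(pt[1]),
                    true_category=lab,
                )
            )
    rng.shuffle(block_trials)
    for t in block_trials:
        t.index = idx
        idx += 1
    trials.extend(block_trials)

    session = Session(
        participant_id=participant_id or f"{structure.kind}-{condition}-s{seed}",
        condition=condition,
        structure_kind=structure.kind,
        seed=int(seed),
        trials=trials,
    )
    session.validate()
    return session


def _training_questions(condition, label, n, rng) -> list[str]:
    pair = next(p for p in TRAIN_PAIRS if label in p)
    if condition == "AB":
        return [f"{pair[0]}|{pair[1]}"] * n
    partner = contrast_partner(label, "train")
    # Cross target (own label vs partner) with truth 50/50 up to rounding;
    # the odd trial's target is picked at random.
    n_own = n // 2 + (int(rng.integers(2)) if n % 2 else 0)
    qs = [f"is:{label}"] * n_own + [f"is:{partner}"] * (n - n_own)
    rng.shuffle(qs)
    return qs


def _test_questions(condition, label, n, rng) -> list[str]:
    if condition == "AB":
        return [f"{TEST_PAIR[0]}|{TEST_PAIR[1]}"] * n
    partner = contrast_partner(label, "test")
    n_own = n // 2 + (int(rng.integers(2)) if n % 2 else 0)
    qs = [f"is:{label}"] * n_own + [f"is:{partner}"] * (n - n_own)
    rng.shuffle(qs)
    return qs


# ---------------------------------------------------------------------------
# Session CSV I/O
# ---------------------------------------------------------------------------

def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_session_csv(session: Session, path) -> None:
    """Write a session in the fixed CSV dialect (UTF-8, LF, full precision)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(CSV_HEADER + "\n")
        for t in session.trials:
            fields = [
                session.participant_id,
                session.condition,
                session.structure_kind,
                t.block,
                t.index,
                t.phase,
                t.question,
                t.dim1,
                t.dim2,
                t.true_category,
                t.response,
                t.implied_category,
                t.correct,
                t.feedback_given,
            ]
            fh.write(",".join(_fmt(f) for f in fields) + "\n")


def read_session_csv(path) -> Session:
    """Read and validate a session CSV written by :func:`write_session_csv`.

    Raises :class:`SessionParseError` (with a line number) on malformed
    input and :class:`SessionValidationError` if the parsed session violates
    a schedule invariant.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != CSV_HEADER:
            raise SessionParseError(f"{path.name}:1: unexpected header {header!r}")
        meta: dict | None = None
        trials: list[Trial] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 14:
                raise SessionParseError(
                    f"{path.name}:{lineno}: expected 14 fields, got {len(parts)}"
                )
            (pid, cond, struct, block, trial, phase, question, dim1, dim2,
             true_cat, response, implied, correct, feedback) = parts
            try:
                t = Trial(
                    index=int(trial),
                    block=int(block),
                    phase=phase,
                    question=question,
                    dim1=float(dim1),
                    dim2=float(dim2),
                    true_category=true_cat,
                    response=response or None,
                    implied_category=implied or None,
                    correct=int(correct) if correct else None,
                    feedback_given=int(feedback),
                )
            except ValueError as exc:
                raise SessionParseError(f"{path.name}:{lineno}: {exc}") from exc
            if meta is None:
                meta = {"pid": pid, "cond": cond, "struct": struct}
            elif (pid, cond, struct) != (meta["pid"], meta["cond"], meta["struct"]):
                raise SessionParseError(
                    f"{path.name}:{lineno}: inconsistent session metadata"
                )
            trials.append(t)
    if meta is None:
        raise SessionParseError(f"{path.name}:2: file contains no trials")
    session = Session(
        participant_id=meta["pid"],
        condition=meta["cond"],
        structure_kind=meta["struct"],
        seed=-1,
        trials=trials,
    )
    session.validate()
    return session


def write_cohort(cohort: Cohort, directory) -> None:
    """Write a cohort as one session CSV per participant plus manifest.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for s in cohort.sessions:
        fname = f"{s.participant_id}.csv"
        write_session_csv(s, directory / fname)
        files[s.participant_id] = fname
    manifest = {
        "participants": [s.participant_id for s in cohort.sessions],
        "files": files,
        "seeds": {s.participant_id: s.seed for s in cohort.sessions},
        "metadata": cohort.metadata,
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_cohort(directory) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    sessions = []
    for pid in manifest["participants"]:
        s = read_session_csv(directory / manifest["files"][pid])
        s.seed = manifest.get("seeds", {}).get(pid, -1)
        sessions.append(s)
    return Cohort(sessions=sessions, metadata=manifest.get("metadata", {}))
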