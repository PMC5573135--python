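"""Synthetic observers with known representational type.

The human data these analyses were designed for is not bundled here, so the
pipeline is exercised end to end with simulated participants whose
representation is known by construction:

* a *within* agent maintains running per-category Gaussian estimates
  (mean and (co)variance, updated online from feedback) and responds from
  the density ratio of the two candidate categories;
* a *between* agent maintains only one criterion per trained pair on the
  structure's projection axis (the midpoint of the running per-side
  projected means — bookkeeping, never used directly in the response
  policy) plus a perceptual-noise SD, and responds from cumulative-Gaussian
  bound probabilities. At test, where no B/C bound was trained, it combines
  the two trained bounds and is accordingly stuck near chance.

Both agents share the softmax decision rule with their own noise scalar
``alpha_agent``, guess uniformly during a burn-in period, and identify the
true category of every training stimulus from the question plus feedback
(which is always possible in this task).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np

from .models import boundary_region_prob_test, decision_prob
from .protocol import Cohort, Session, Trial, build_schedule, record_response
from .structures import CategoryStructure, LABELS, make_structure

__all__ = ["AgentConfig", "simulate_session", "simulate_cohort"]


@dataclass(frozen=True)
class AgentConfig:
    """Configuration of one synthetic observer.

    ``alpha_agent`` plays the role of the softmax noise parameter (0 means
    pure guessing); ``learn_burnin`` is the number of initial trials of
    uniform guessing; ``noise_sd`` is the between-agent's perceptual noise
    on the projection axis, in stimulus units (unused by within agents).
    """

    representation: str  # "within" | "between"
    alpha_agent: float = 20.0
    learn_burnin: int = 50
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.representation not in ("within", "between"):
            raise ValueError(f"unknown representation: {self.representation!r}")
        if self.alpha_agent < 0:
            raise ValueError("alpha_agent must be >= 0")
        if not 0 <= self.learn_burnin <= 500:
            raise ValueError("learn_burnin must be in [0, 500]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


class _WithinKnowledge:
    """Running per-category mean/covariance estimates (Welford updates)."""

    def __init__(self, structure: CategoryStructure):
        self.mode = structure.density_mode
        self.n = {lab: 0 for lab in LABELS}
        self.mean = {lab: np.zeros(2) for lab in LABELS}
        self.m2 = {lab: np.zeros((2, 2)) for lab in LABELS}

    def update(self, label: str, stimulus: np.ndarray) -> None:
        n = self.n[label] + 1
        delta = stimulus - self.mean[label]
        self.mean[label] = self.mean[label] + delta / n
        delta2 = stimulus - self.mean[label]
        self.m2[label] = self.m2[label] + np.outer(delta, delta2)
        self.n[label] = n

    def log_density(self, label: str, stimulus: np.ndarray) -> float | None:
        n = self.n[label]
        if n < 2:
            return None
        cov = self.m2[label] / n
        if self.mode == "univariate":
            var = max(cov[1, 1], 1e-6)
            d = stimulus[1] - self.mean[label][1]
            return -0.5 * (np.log(2 * np.pi * var) + d * d / var)
        cov = cov + 1e-6 * np.eye(2)
        diff = stimulus - self.mean[label]
        sign, logdet = np.linalg.slogdet(cov)
        maha = diff @ np.linalg.solve(cov, diff)
        return -0.5 * (2 * np.log(2 * np.pi) + logdet + maha)

    def region_prob(self, x_label: str, y_label: str, stimulus: np.ndarray) -> float | None:
        lx = self.log_density(x_label, stimulus)
        ly = self.log_density(y_label, stimulus)
        if lx is None or ly is None:
            return None
        with np.errstate(over="ignore"):
            return float(1.0 / (1.0 + np.exp(ly - lx)))


class _BetweenKnowledge:
    """Running per-pair criteria on the projection axis, plus noise SD.

    The per-side projected means are bookkeeping used only to place the
    criterion; the response policy sees nothing but (criterion, noise SD).
    """

    def __init__(self, structure: CategoryStructure, noise_sd: float):
        self.axis = structure.projection_axis
        self.noise_sd = noise_sd
        self.n = {lab: 0 for lab in LABELS}
        self.mean_z = {lab: 0.0 for lab in LABELS}

    def update(self, label: str, stimulus: np.ndarray) -> None:
        z = float(stimulus @ self.axis)
        n = self.n[label] + 1
        self.mean_z[label] += (z - self.mean_z[label]) / n
        self.n[label] = n

    def criterion(self, pair: tuple[str, str]) -> float | None:
        lo, hi = pair
        if self.n[lo] == 0 or self.n[hi] == 0:
            return None
        return 0.5 * (self.mean_z[lo] + self.mean_z[hi])

    def cdf(self, pair: tuple[str, str], stimulus: np.ndarray) -> float | None:
        from scipy.special import ndtr

        c = self.criterion(pair)
        if c is None:
            return None
        z = float(stimulus @ self.axis)
        return float(ndtr((z - c) / self.noise_sd))

    def region_prob_train(self, pair: tuple[str, str], x_label: str, stimulus) -> float | None:
        f = self.cdf(pair, stimulus)
        if f is None:
            return None
        p_first = 1.0 - f
        return p_first if x_label == pair[0] else 1.0 - p_first

    def region_prob_test(self, x_label: str, stimulus) -> float | None:
        f_ab = self.cdf(("A", "B"), stimulus)
        f_cd = self.cdf(("C", "D"), stimulus)
        if f_ab is None or f_cd is None:
            return None
        denom = f_ab + (1.0 - f_cd)
        p_b = f_ab / denom if denom > 0 else 0.5
        return p_b if x_label == "B" else 1.0 - p_b


def simulate_session(schedule: Session, agent: AgentConfig) -> Session:
    """Fill a response-empty schedule with one synthetic observer's responses.

    Returns a new :class:`Session`; the input schedule is not modified.
    Deterministic for a fixed (schedule, agent) pair.
    """
    if schedule.has_responses:
        raise ValueError("schedule already has responses; expected an empty schedule")
    structure = make_structure(schedule.structure_kind)
    rng = np.random.default_rng(agent.seed)
    knowledge = (
        _WithinKnowledge(structure)
        if agent.representation == "within"
        else _BetweenKnowledge(structure, agent.noise_sd)
    )
    session = copy.deepcopy(schedule)
    for t in session.trials:
        if t.is_pair_question:
            x_label, y_label = t.question_pair()
        else:
            x_label = t.target
            from .protocol import contrast_partner

            y_label = contrast_partner(x_label, t.phase)
        p_region = None
        if t.index > agent.learn_burnin:
            if agent.representation == "within":
                p_region = knowledge.region_prob(x_label, y_label, t.stimulus)
            elif t.phase == "train":
                p_region = knowledge.region_prob_train(t.question_pair(), x_label, t.stimulus)
            else:
                p_region = knowledge.region_prob_test(x_label, t.stimulus)
        if p_region is None:
            p_region = 0.5
        p_resp = decision_prob(p_region, 1.0 - p_region, agent.alpha_agent)
        choose_x = rng.random() < p_resp
        chosen = x_label if choose_x else y_label
        if t.is_pair_question:
            token = chosen
        else:
            token = "yes" if chosen == x_label else "no"
        record_response(t, token)
        # Feedback plus the question identify the true label on every
        # training trial, so the agent can update the correct category.
        if t.phase == "train":
            knowledge.update(t.true_category, t.stimulus)
    return session


def simulate_cohort(
    structure_kind: str,
    condition: str,
    n_within: int,
    n_between: int,
    agent_defaults: AgentConfig | dict | None = None,
    seed: int = 0,
    id_prefix: str = "",
) -> Cohort:
    """Simulate a cohort of within and between agents on fresh schedules.

    Each participant gets an independent schedule seed and agent seed
    expanded deterministically from the master ``seed``. Ground-truth
    representation tags are recorded in the cohort metadata for model
    recovery scoring.
    """
    if n_within + n_between < 1:
        raise ValueError("cohort must contain at least one agent")
    if isinstance(agent_defaults, AgentConfig):
        defaults = {
            "alpha_agent": agent_defaults.alpha_agent,
            "learn_burnin": agent_defaults.learn_burnin,
            "noise_sd": agent_defaults.noise_sd,
        }
    else:
        defaults = dict(agent_defaults or {})
    structure = make_structure(structure_kind)
    rng = np.random.default_rng(seed)
    prefix = id_prefix or f"{structure_kind}-{condition}"
    sessions: list[Session] = []
    truth: dict[str, str] = {}
    roster = [("within", i) for i in range(n_within)] + [
        ("between", i) for i in range(n_between)
    ]
    for rep, i in roster:
        schedule_seed = int(rng.integers(2**31))
        agent_seed = int(rng.integers(2**31))
        pid = f"{prefix}-{rep}-{i + 1:02d}"
        schedule = build_schedule(structure, condition, seed=schedule_seed, participant_id=pid)
        agent = AgentConfig(representation=rep, seed=agent_seed, **defaults)
        sessions.append(simulate_session(schedule, agent))
        truth[pid] = rep
    metadata = {
        "structure": structure_kind,
        "condition": condition,
        "seed": int(seed),
        "agent_defaults": defaults,
        "ground_truth": truth,
    }
    return Cohort(sessions=sessions, metadata=metadata)
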