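"""Synthetic recovery studies: can the pipeline identify what it assumes?

Three standard checks run on synthetic cohorts whose representational
ground truth is known by construction:

* **model recovery** — simulate within- and between-representation agents
  under every structure x condition cell and score how often the
  cross-validated verdict matches the generating representation;
* **parameter recovery** — compare density-model means fitted from
  within-agent sessions against the generative category means;
* **transfer pattern** — verify the signature behavioral dissociation:
  within-agents carry their training accuracy into the novel B-vs-C test
  block while between-agents fall to chance there.

Every function takes a single integer seed and is deterministic given it.
"""

from __future__ import annotations

import numpy as np

from .agents import AgentConfig, simulate_cohort, simulate_session
from .models import fit_density_params
from .protocol import build_schedule
from .selection import classify_cohort
from .structures import make_structure

__all__ = ["model_recovery", "density_mean_recovery", "transfer_pattern"]


def model_recovery(
    seed: int,
    n_within: int = 30,
    n_between: int = 30,
    structures: tuple[str, ...] = ("RB", "II"),
    conditions: tuple[str, ...] = ("AB", "YN"),
    agent_defaults: dict | None = None,
) -> dict:
    """Classify synthetic cohorts and score agreement with the ground truth.

    Returns per-cell recovery rates plus the pooled rate over all cells,
    with excluded participants counted in ``n_excluded`` and left out of
    the rate denominators.
    """
    rng = np.random.default_rng(seed)
    cells = {}
    recovered = total = excluded = 0
    for kind in structures:
        for cond in conditions:
            cohort = simulate_cohort(
                kind,
                cond,
                n_within,
                n_between,
                agent_defaults=agent_defaults,
                seed=int(rng.integers(2**31)),
            )
            cc = classify_cohort(cohort)
            truth = cohort.metadata["ground_truth"]
            hits = n = 0
            for c in cc.classifications:
                if c.verdict is None:
                    excluded += 1
                    continue
                n += 1
                hits += int(c.verdict == truth[c.participant_id])
            cells[f"{kind}-{cond}"] = {"recovered": hits, "n": n, "rate": hits / n}
            recovered += hits
            total += n
    return {
        "cells": cells,
        "recovered": recovered,
        "n": total,
        "n_excluded": excluded,
        "rate": recovered / total,
    }


def density_mean_recovery(
    seed: int,
    n_sessions: int = 5,
    structure_kind: str = "RB",
    conditions: tuple[str, ...] = ("AB", "YN"),
    min_trials: int = 20,
) -> dict:
    """Fit density means from within-agent sessions vs the generative means.

    For the RB structure the comparison is on the dim2 category means; only
    categories with at least ``min_trials`` usable fitted trials enter.
    Returns the per-cell absolute errors plus their max and mean.
    """
    structure = make_structure(structure_kind)
    rng = np.random.default_rng(seed)
    errors: list[float] = []
    for cond in conditions:
        for _ in range(n_sessions):
            schedule = build_schedule(
                structure, cond, seed=int(rng.integers(2**31))
            )
            session = simulate_session(
                schedule,
                AgentConfig("within", seed=int(rng.integers(2**31))),
            )
            params = fit_density_params(session)
            for lab in "ABCD":
                if params.counts[lab] < min_trials:
                    continue
                gen = structure.means[lab]
                fitted = params.means[lab]
                target = gen[1] if params.mode == "univariate" else gen
                errors.append(float(np.max(np.abs(fitted - target))))
    return {
        "n_cells": len(errors),
        "max_abs_error": max(errors),
        "mean_abs_error": float(np.mean(errors)),
    }


def transfer_pattern(
    seed: int,
    n_seeds: int = 20,
    structure_kind: str = "RB",
    condition: str = "AB",
) -> dict:
    """Block-5 and block-6 accuracy of within- and between-agents.

    Averages over ``n_seeds`` independent (schedule, agent) pairs per agent
    type. The expected pattern: within-agents keep their end-of-training
    accuracy at test, between-agents drop to chance because no B/C bound
    was ever trained.
    """
    rng = np.random.default_rng(seed)
    acc = {"within": {5: [], 6: []}, "between": {5: [], 6: []}}
    for _ in range(n_seeds):
        schedule_seed = int(rng.integers(2**31))
        schedule = build_schedule(structure_kind, condition, seed=schedule_seed)
        for rep in ("within", "between"):
            session = simulate_session(
                schedule, AgentConfig(rep, seed=int(rng.integers(2**31)))
            )
            for b in (5, 6):
                acc[rep][b].append(
                    float(np.mean([t.correct for t in session.block(b)]))
                )
    out = {
        rep: {f"block{b}_accuracy": float(np.mean(v)) for b, v in blocks.items()}
        for rep, blocks in acc.items()
    }
    out["n_seeds"] = n_seeds
    out["trials_per_block"] = 100
    return out
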