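"""Cross-validated classification of participants by representation type.

For each participant, both observer models are fit to the last 200 training
trials (blocks 4-5) — representational parameters by maximum likelihood,
then the softmax noise alpha by SSE — and evaluated on the block-6 transfer
trials with all parameters frozen. The model with the smaller test RMSD
(generalization error) names the verdict: density -> within-category
representation, boundary -> between-category representation. Evaluating on
transfer rather than training data removes the density model's built-in
advantage (the boundary model is nested in it with half the parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models
from .models import (
    BoundaryModelParams,
    DensityModelParams,
    NonIdentifiableBoundError,
    UnderdeterminedCategoryError,
)
from .protocol import Cohort, Session

__all__ = [
    "ModelFit",
    "FitClassification",
    "CohortClassification",
    "EmptyCohortError",
    "crossvalidate_participant",
    "classify_cohort",
]

#: Categories whose densities are needed to predict the B-vs-C test phase.
TEST_REQUIRED_CATEGORIES = ("B", "C")


class EmptyCohortError(ValueError):
    """No classifiable participant in the cohort."""


@dataclass
class ModelFit:
    """One fitted model: parameters, training SSE, and test RMSD."""

    params: DensityModelParams | BoundaryModelParams
    alpha: float
    train_sse: float
    test_rmsd: float

    def to_json(self) -> dict:
        return {
            "params": self.params.to_json(),
            "alpha": self.alpha,
            "train_sse": self.train_sse,
            "test_rmsd": self.test_rmsd,
        }


@dataclass
class FitClassification:
    """Per-participant cross-validation outcome."""

    participant_id: str
    condition: str
    structure_kind: str
    density: ModelFit | None = None
    boundary: ModelFit | None = None
    verdict: str | None = None  # "within" | "between" | None when excluded
    excluded: bool = False
    flags: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "condition": self.condition,
            "structure": self.structure_kind,
            "density": self.density.to_json() if self.density else None,
            "boundary": self.boundary.to_json() if self.boundary else None,
            "verdict": self.verdict,
            "excluded": self.excluded,
            "flags": list(self.flags),
        }


def _fit_one_model(session: Session, params, fit_window) -> ModelFit:
    train_series = models.training_region_probs(session, params, fit_window)
    alpha, sse = models.fit_alpha(train_series)
    params.alpha = alpha
    test_series = models.test_region_probs(session, params).with_alpha(alpha)
    return ModelFit(
        params=params, alpha=alpha, train_sse=sse, test_rmsd=models.rmsd(test_series)
    )


def crossvalidate_participant(
    session: Session,
    fit_window: tuple[int, int] = models.DEFAULT_FIT_WINDOW,
) -> FitClassification:
    """Fit both models on the training window and compare test RMSDs.

    Test predictions never refit any parameter. Participants for whom the
    density model lacks at least 3 usable trials for a test-relevant
    category (B or C), or for whom a bound is non-identifiable, are marked
    excluded with the reason flagged; there is no silent fallback.

    The verdict is ``"within"`` iff the density model's test RMSD is
    strictly smaller than the boundary model's; ties go to the more
    parsimonious boundary model (``"between"``).
    """
    out = FitClassification(
        participant_id=session.participant_id,
        condition=session.condition,
        structure_kind=session.structure_kind,
    )
    try:
        dparams = models.fit_density_params(
            session, fit_window, required=TEST_REQUIRED_CATEGORIES
        )
        out.flags.extend(dparams.flags)
        out.density = _fit_one_model(session, dparams, fit_window)
    except UnderdeterminedCategoryError as exc:
        out.excluded = True
        out.flags.append(f"excluded:underdetermined_density:{','.join(exc.labels)}")
    try:
        bparams = models.fit_boundary_params(session, fit_window)
        out.boundary = _fit_one_model(session, bparams, fit_window)
    except NonIdentifiableBoundError as exc:
        out.excluded = True
        out.flags.append(f"excluded:non_identifiable_bound:{'-'.join(exc.pair)}")
    if out.excluded:
        out.verdict = None
        return out
    out.verdict = (
        "within" if out.density.test_rmsd < out.boundary.test_rmsd else "between"
    )
    return out


@dataclass
class CohortClassification:
    """Cohort-level classification results and RMSD summary."""

    classifications: list[FitClassification]
    counts: pd.DataFrame  # per condition: n, within, between, excluded
    rmsd_summary: pd.DataFrame  # condition x verdict x model mean test RMSD

    def verdict_of(self, participant_id: str) -> str | None:
        for c in self.classifications:
            if c.participant_id == participant_id:
                return c.verdict
        raise KeyError(participant_id)


def classify_cohort(
    cohort: Cohort,
    fit_window: tuple[int, int] = models.DEFAULT_FIT_WINDOW,
) -> CohortClassification:
    """Cross-validate every session and summarize verdicts per condition.

    The RMSD summary mirrors the usual reporting layout: within each
    (condition, verdict) group, the mean test RMSD of both models over the
    participants in the group.
    """
    classifications = [crossvalidate_participant(s, fit_window) for s in cohort.sessions]
    usable = [c for c in classifications if not c.excluded]
    if not usable:
        raise EmptyCohortError("all participants excluded; nothing to classify")
    rows = []
    for c in usable:
        rows.append(
            {
                "participant_id": c.participant_id,
                "condition": c.condition,
                "verdict": c.verdict,
                "density_rmsd": c.density.test_rmsd,
                "boundary_rmsd": c.boundary.test_rmsd,
            }
        )
    df = pd.DataFrame(rows)
    counts = []
    for cond, grp in df.groupby("condition"):
        n_excl = sum(1 for c in classifications if c.condition == cond and c.excluded)
        counts.append(
            {
                "condition": cond,
                "n": len(grp) + n_excl,
                "within": int((grp["verdict"] == "within").sum()),
                "between": int((grp["verdict"] == "between").sum()),
                "excluded": n_excl,
                "proportion_within": float((grp["verdict"] == "within").mean()),
            }
        )
    summary_rows = []
    for (cond, verdict), grp in df.groupby(["condition", "verdict"]):
        for model_name, col in (("boundary", "boundary_rmsd"), ("density", "density_rmsd")):
            summary_rows.append(
                {
                    "condition": cond,
                    "verdict": verdict,
                    "model": model_name,
                    "mean_test_rmsd": float(grp[col].mean()),
                    "n": len(grp),
                }
            )
    return CohortClassification(
        classifications=classifications,
        counts=pd.DataFrame(counts),
        rmsd_summary=pd.DataFrame(summary_rows),
    )
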