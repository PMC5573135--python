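"""Within-category (density) and between-category (boundary) observer models.

Both models turn a stimulus into the probability of locating it in the
perceptual region of one of two candidate categories, and share a softmax
decision rule that maps region probabilities to response probabilities:

* density model: ``p(C_X | d) = f_X(d) / (f_X(d) + f_Y(d))`` where ``f_X``
  is a Gaussian density estimated per response category from the
  participant's own responses (sample mean and variance, i.e. the MLEs).
  The same rule applies in training and at test. Under the RB structure the
  densities are univariate on dim2 (8 representational parameters); under
  the II structure they are bivariate with a full covariance.
* boundary model: each trained bound (AB, CD) is a 1-D cumulative Gaussian
  on a fixed projection axis, with a location and a perceptual-noise SD
  (4 representational parameters). During training
  ``p(C_A | d) = 1 - F_AB(d)``; at test, where no BC bound exists,
  ``p(C_B | d) = F_AB(d) / (F_AB(d) + (1 - F_CD(d)))``.
* decision rule: ``p(R_X | d) = exp(a p(C_X|d)) / (exp(a p(C_X|d)) +
  exp(a p(C_Y|d)))`` with the noise parameter ``a`` (alpha) estimated by
  minimizing the sum of squared errors against the 0/1 response indicators,
  after and conditional on the representational parameters.

Model fits deliberately see only what an experimenter could see: responses,
questions and stimuli.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import log_ndtr, ndtr

from .protocol import TEST_PAIR, TRAIN_PAIRS, Session, Trial
from .structures import make_structure

__all__ = [
    "VARIANCE_FLOOR",
    "SIGMA_FLOOR",
    "ALPHA_BOUNDS",
    "DensityModelParams",
    "BoundaryModelParams",
    "PredictionSeries",
    "UnderdeterminedCategoryError",
    "NonIdentifiableBoundError",
    "select_fitting_trials",
    "fit_density_params",
    "density_region_prob",
    "fit_boundary_params",
    "boundary_region_prob_train",
    "boundary_region_prob_test",
    "decision_prob",
    "fit_alpha",
    "rmsd",
    "training_region_probs",
    "test_region_probs",
    "DEFAULT_FIT_WINDOW",
]

#: Floor on fitted variances / covariance diagonals (squared stimulus units).
VARIANCE_FLOOR = 1e-4
#: Floor on fitted bound noise SDs (stimulus units).
SIGMA_FLOOR = 1e-3
#: Search interval for the softmax noise parameter alpha.
ALPHA_BOUNDS = (0.0, 50.0)
#: Last 200 training trials (blocks 4-5), the cross-validation fit window.
DEFAULT_FIT_WINDOW = (301, 500)


class UnderdeterminedCategoryError(ValueError):
    """Too few usable trials to estimate a category density."""

    def __init__(self, labels: Sequence[str], min_trials: int):
        self.labels = tuple(labels)
        self.min_trials = min_trials
        super().__init__(
            f"categories {self.labels} have fewer than {min_trials} usable trials"
        )


class NonIdentifiableBoundError(ValueError):
    """All responses on one side of a pair: the bound location is unbounded."""

    def __init__(self, pair: tuple[str, str]):
        self.pair = pair
        super().__init__(f"all responses identical within pair {pair}; bound not identifiable")


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class DensityModelParams:
    """Per-category Gaussian estimates plus the decision-noise alpha.

    ``mode`` is ``"univariate"`` (dim2 only; RB structures) or
    ``"bivariate"`` (both dims, full covariance; II structures). ``means``
    maps fitted labels to (k,) vectors and ``covs`` to (k, k) matrices with
    k = 1 or 2.
    """

    mode: Literal["univariate", "bivariate"]
    means: dict[str, np.ndarray]
    covs: dict[str, np.ndarray]
    counts: dict[str, int] = field(default_factory=dict)
    alpha: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def fitted_categories(self) -> frozenset[str]:
        return frozenset(self.means)

    def coords(self, stimuli: np.ndarray) -> np.ndarray:
        """Extract the modeled coordinates from (n, 2) stimuli."""
        x = np.atleast_2d(np.asarray(stimuli, dtype=float))
        return x[:, 1:2] if self.mode == "univariate" else x

    def log_density(self, label: str, stimuli: np.ndarray) -> np.ndarray:
        x = self.coords(stimuli)
        mean = self.means[label]
        cov = self.covs[label]
        diff = x - mean
        sign, logdet = np.linalg.slogdet(cov)
        maha = np.einsum("ni,ij,nj->n", diff, np.linalg.inv(cov), diff)
        k = x.shape[1]
        return -0.5 * (k * np.log(2 * np.pi) + logdet + maha)

    def to_json(self) -> dict:
        return {
            "model": "density",
            "mode": self.mode,
            "parameters": {
                lab: {"mean": self.means[lab].tolist(), "cov": self.covs[lab].tolist()}
                for lab in sorted(self.means)
            },
            "counts": dict(sorted(self.counts.items())),
            "alpha": self.alpha,
            "flags": list(self.flags),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "DensityModelParams":
        return cls(
            mode=obj["mode"],
            means={k: np.asarray(v["mean"], float) for k, v in obj["parameters"].items()},
            covs={k: np.asarray(v["cov"], float) for k, v in obj["parameters"].items()},
            counts={k: int(v) for k, v in obj.get("counts", {}).items()},
            alpha=obj.get("alpha"),
            flags=list(obj.get("flags", [])),
        )


@dataclass
class BoundaryModelParams:
    """AB and CD bound locations and noise SDs on a fixed projection axis."""

    projection_axis: np.ndarray
    c_ab: float
    sigma_ab: float
    c_cd: float
    sigma_cd: float
    alpha: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        axis = np.asarray(self.projection_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if not np.isclose(norm, 1.0):
            raise ValueError(f"projection axis must have unit norm, got {norm}")
        self.projection_axis = axis

    def project(self, stimuli: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(stimuli, dtype=float)) @ self.projection_axis

    def cdf(self, pair: tuple[str, str], stimuli: np.ndarray) -> np.ndarray:
        """F_pair(d): probability mass on the upper-label side of the bound."""
        z = self.project(stimuli)
        if pair == ("A", "B"):
            c, s = self.c_ab, self.sigma_ab
        elif pair == ("C", "D"):
            c, s = self.c_cd, self.sigma_cd
        else:
            raise ValueError(f"no bound for pair {pair}")
        return ndtr((z - c) / s)

    def to_json(self) -> dict:
        return {
            "model": "boundary",
            "projection_axis": self.projection_axis.tolist(),
            "parameters": {
                "c_ab": self.c_ab,
                "sigma_ab": self.sigma_ab,
                "c_cd": self.c_cd,
                "sigma_cd": self.sigma_cd,
            },
            "alpha": self.alpha,
            "flags": list(self.flags),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "BoundaryModelParams":
        p = obj["parameters"]
        return cls(
            projection_axis=np.asarray(obj["projection_axis"], float),
            c_ab=p["c_ab"],
            sigma_ab=p["sigma_ab"],
            c_cd=p["c_cd"],
            sigma_cd=p["sigma_cd"],
            alpha=obj.get("alpha"),
            flags=list(obj.get("flags", [])),
        )


@dataclass
class PredictionSeries:
    """Per-trial model predictions aligned with observed 0/1 indicators.

    For each trial, ``label`` is the reference category X (the first label
    of a pair question, or the named target of a yes/no question),
    ``p_region`` is p(C_X|d), ``p_response`` is p(R_X|d) after the softmax,
    and ``observed`` is 1 iff the participant's implied category was X.
    """

    trial_index: np.ndarray
    label: np.ndarray
    p_region: np.ndarray
    p_response: np.ndarray | None
    observed: np.ndarray

    def __len__(self) -> int:
        return len(self.trial_index)

    def with_alpha(self, alpha: float) -> "PredictionSeries":
        return PredictionSeries(
            trial_index=self.trial_index,
            label=self.label,
            p_region=self.p_region,
            p_response=decision_prob(self.p_region, 1.0 - self.p_region, alpha),
            observed=self.observed,
        )


# ---------------------------------------------------------------------------
# Trial selection
# ---------------------------------------------------------------------------

def _window_trials(session: Session, trial_window) -> list[Trial]:
    if trial_window is None:
        lo, hi = DEFAULT_FIT_WINDOW
        return session.trial_window(lo, hi)
    if isinstance(trial_window, tuple) and len(trial_window) == 2:
        return session.trial_window(*trial_window)
    return list(trial_window)


def select_fitting_trials(
    session: Session,
    model: Literal["density", "boundary"],
    key,
    trial_window=None,
) -> list[Trial]:
    """Select the trials that inform one model component.

    density + YN: for category X, trials whose question target is X and the
    response was "yes" (a "no" does not reveal which category the
    participant had in mind). density + AB: trials whose implied category is
    X, i.e. the X button was pressed, regardless of the question.
    boundary + YN: all trials whose target belongs to the pair.
    boundary + AB: all trials in which either pair button was pressed.
    Non-category responses (timeouts etc.) are always excluded.
    """
    trials = [t for t in _window_trials(session, trial_window) if t.has_category_response]
    if model == "density":
        label = key
        if session.condition == "YN":
            return [t for t in trials if t.target == label and t.response == "yes"]
        return [t for t in trials if t.implied_category == label]
    if model == "boundary":
        pair = tuple(key)
        if session.condition == "YN":
            return [t for t in trials if t.target in pair]
        return [t for t in trials if t.implied_category in pair]
    raise ValueError(f"unknown model: {model!r}")


# ---------------------------------------------------------------------------
# Density model
# ---------------------------------------------------------------------------

def fit_density_params(
    session: Session,
    trial_window=None,
    required: Sequence[str] = ("A", "B", "C", "D"),
    min_trials: int = 3,
) -> DensityModelParams:
    """Fit per-category Gaussian densities by maximum likelihood.

    Each category's mean and (co)variance are the sample moments of the
    stimuli on its selected trials (see :func:`select_fitting_trials`); the
    RB structure is fit on dim2 only, the II structure on both dimensions.
    Variances are floored at ``VARIANCE_FLOOR``. Alpha is left unset.

    Categories in ``required`` with fewer than ``min_trials`` usable trials
    raise :class:`UnderdeterminedCategoryError`; other underdetermined
    categories are skipped and flagged.
    """
    mode = make_structure(session.structure_kind).density_mode
    means: dict[str, np.ndarray] = {}
    covs: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    flags: list[str] = []
    missing: list[str] = []
    for label in ("A", "B", "C", "D"):
        trials = select_fitting_trials(session, "density", label, trial_window)
        counts[label] = len(trials)
        if len(trials) < min_trials:
            if label in required:
                missing.append(label)
            else:
                flags.append(f"underdetermined:{label}")
            continue
        x = np.array([[t.dim1, t.dim2] for t in trials])
        if mode == "univariate":
            x = x[:, 1:2]
        mean = x.mean(axis=0)
        cov = np.atleast_2d(np.cov(x, rowvar=False, ddof=0))
        d = np.arange(cov.shape[0])
        floored = cov[d, d] < VARIANCE_FLOOR
        if floored.any():
            cov[d, d] = np.maximum(cov[d, d], VARIANCE_FLOOR)
            # A floored diagonal can leave the matrix non-PSD; drop the
            # off-diagonal in that case (only arises in degenerate samples).
            if np.any(np.linalg.eigvalsh(cov) <= 0):
                cov = np.diag(cov[d, d])
            flags.append(f"variance_floor:{label}")
        means[label] = mean
        covs[label] = cov
    if missing:
        raise UnderdeterminedCategoryError(missing, min_trials)
    return DensityModelParams(mode=mode, means=means, covs=covs, counts=counts, flags=flags)


def density_region_prob(
    params: DensityModelParams,
    stimuli: np.ndarray,
    pair: tuple[str, str],
) -> np.ndarray:
    """p(C_X|d) = f_X(d) / (f_X(d) + f_Y(d)) for pair = (X, Y).

    Used identically during training and at test. If both densities
    underflow to zero the convention is maximum ignorance, 0.5.
    """
    x_label, y_label = pair
    if x_label not in params.means or y_label not in params.means:
        raise UnderdeterminedCategoryError(
            [l for l in pair if l not in params.means], min_trials=0
        )
    scalar = np.asarray(stimuli).ndim == 1
    log_fx = params.log_density(x_label, stimuli)
    log_fy = params.log_density(y_label, stimuli)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(log_fy - log_fx))
    both_zero = np.isneginf(log_fx) & np.isneginf(log_fy)
    p = np.where(both_zero, 0.5, p)
    return float(p[0]) if scalar else p


# ---------------------------------------------------------------------------
# Boundary model
# ---------------------------------------------------------------------------

def _fit_one_bound(z: np.ndarray, y: np.ndarray, pair: tuple[str, str]) -> tuple[float, float]:
    """Probit MLE of (c, sigma) for p(upper|z) = Phi((z - c) / sigma)."""
    if y.min() == y.max():
        raise NonIdentifiableBoundError(pair)
    m1 = z[y == 1].mean()
    m0 = z[y == 0].mean()
    c0 = 0.5 * (m0 + m1)
    s0 = max(float(z.std(ddof=0)), SIGMA_FLOOR)
    span = float(z.max() - z.min()) or 1.0

    def nll(theta):
        c, s = theta
        # log Phi / log(1 - Phi) via log_ndtr for numerical stability.
        u = (z - c) / s
        return -(np.where(y == 1, log_ndtr(u), log_ndtr(-u))).sum()

    res = minimize(
        nll,
        x0=np.array([c0, s0]),
        method="L-BFGS-B",
        bounds=[(z.min() - 2 * span, z.max() + 2 * span), (SIGMA_FLOOR, 10 * span)],
        options={"ftol": 1e-8, "gtol": 1e-8, "maxiter": 500},
    )
    c, s = res.x
    return float(c), float(s)


def fit_boundary_params(session: Session, trial_window=None) -> BoundaryModelParams:
    """Fit the AB and CD bounds by maximum likelihood.

    For each trained pair, responses are reduced to "upper label pressed /
    implied" indicators and a cumulative Gaussian in the stimulus projection
    is fit by probit MLE with a deterministic initialization (location at
    the midpoint of the per-response projected means, SD at the pooled
    projected SD). Alpha is left unset.
    """
    structure = make_structure(session.structure_kind)
    axis = structure.projection_axis
    fitted: dict[tuple[str, str], tuple[float, float]] = {}
    for pair in TRAIN_PAIRS:
        trials = select_fitting_trials(session, "boundary", pair, trial_window)
        if not trials:
            raise NonIdentifiableBoundError(pair)
        z = np.array([[t.dim1, t.dim2] for t in trials]) @ axis
        y = np.array([int(t.implied_category == pair[1]) for t in trials])
        fitted[pair] = _fit_one_bound(z, y, pair)
    (c_ab, s_ab), (c_cd, s_cd) = fitted[("A", "B")], fitted[("C", "D")]
    return BoundaryModelParams(
        projection_axis=axis, c_ab=c_ab, sigma_ab=s_ab, c_cd=c_cd, sigma_cd=s_cd
    )


def boundary_region_prob_train(
    params: BoundaryModelParams,
    stimuli: np.ndarray,
    pair: tuple[str, str],
) -> np.ndarray:
    """p(C_first|d) = 1 - F_pair(d) for a trained pair (A,B) or (C,D)."""
    scalar = np.asarray(stimuli).ndim == 1
    p = 1.0 - params.cdf(tuple(pair), stimuli)
    return float(p[0]) if scalar else p


def boundary_region_prob_test(params: BoundaryModelParams, stimuli: np.ndarray) -> np.ndarray:
    """p(C_B|d) at test, where no BC bound was ever learned.

    Both trained bounds are consulted: the numerator is the probability of
    a B response according to the AB bound, and the denominator adds the
    probability of a C response according to the CD bound,
    ``p(C_B|d) = F_AB(d) / (F_AB(d) + (1 - F_CD(d)))``. When both terms
    vanish the convention is 0.5.
    """
    scalar = np.asarray(stimuli).ndim == 1
    f_ab = params.cdf(("A", "B"), stimuli)
    not_d = 1.0 - params.cdf(("C", "D"), stimuli)
    denom = f_ab + not_d
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(denom > 0, f_ab / np.where(denom > 0, denom, 1.0), 0.5)
    return float(p[0]) if scalar else p


# ---------------------------------------------------------------------------
# Decision rule, alpha fitting, RMSD
# ---------------------------------------------------------------------------

def decision_prob(p_cx, p_cy, alpha: float):
    """Softmax of the two region probabilities with noise parameter alpha.

    ``p(R_X|d) = exp(a p_cx) / (exp(a p_cx) + exp(a p_cy))``; alpha = 0 is
    pure guessing, large alpha makes the response deterministic in the sign
    of ``p_cx - p_cy``.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    p_cx = np.asarray(p_cx, dtype=float)
    p_cy = np.asarray(p_cy, dtype=float)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-alpha * (p_cx - p_cy)))
    return float(out) if out.ndim == 0 else out


def fit_alpha(series: PredictionSeries) -> tuple[float, float]:
    """Estimate alpha by minimizing the SSE against the 0/1 indicators.

    ``SSE(a) = sum_i (y_i - p(R_X|d_i; a))^2`` is minimized by bounded
    scalar search on ``ALPHA_BOUNDS`` (tolerance 1e-6); the interval
    endpoints are also evaluated so a monotone SSE returns the bound.
    Returns ``(alpha, sse)``.
    """
    if len(series) == 0:
        raise ValueError("cannot fit alpha on an empty series")
    p = series.p_region
    y = series.observed.astype(float)

    def sse(a: float) -> float:
        pr = decision_prob(p, 1.0 - p, a)
        return float(((y - pr) ** 2).sum())

    res = minimize_scalar(
        sse, bounds=ALPHA_BOUNDS, method="bounded", options={"xatol": 1e-6}
    )
    candidates = [(float(res.x), float(res.fun))]
    candidates += [(a, sse(a)) for a in ALPHA_BOUNDS]
    # Exact SSE ties only occur on saturated plateaus; prefer the bound there.
    alpha, best = min(candidates, key=lambda t: (t[1], -t[0]))
    return alpha, best


def rmsd(series: PredictionSeries) -> float:
    """Root mean squared deviation between p(R_X|d) and the 0/1 indicators."""
    if len(series) == 0:
        raise ValueError("cannot compute RMSD of an empty series")
    if series.p_response is None:
        raise ValueError("series has no response probabilities; apply with_alpha first")
    err = series.observed.astype(float) - series.p_response
    return float(np.sqrt(np.mean(err**2)))


# ---------------------------------------------------------------------------
# Series construction over sessions
# ---------------------------------------------------------------------------

def _trial_reference_label(trial: Trial) -> tuple[str, str]:
    """(X, Y): the reference category and its alternative for one trial."""
    if trial.is_pair_question:
        return trial.question_pair()
    t = trial.target
    from .protocol import contrast_partner

    return t, contrast_partner(t, trial.phase)


def training_region_probs(
    session: Session,
    params: DensityModelParams | BoundaryModelParams,
    trial_window=None,
) -> PredictionSeries:
    """Region probabilities p(C_X|d) over training trials in the window.

    Trials referencing a category the density model could not fit are
    skipped (the boundary model always covers both trained pairs).
    """
    idx, labels, probs, obs = [], [], [], []
    for t in _window_trials(session, trial_window):
        if t.phase != "train" or not t.has_category_response:
            continue
        x_label, y_label = _trial_reference_label(t)
        if isinstance(params, DensityModelParams):
            if x_label not in params.means or y_label not in params.means:
                continue
            p = density_region_prob(params, t.stimulus, (x_label, y_label))
        else:
            pair = t.question_pair()
            p_first = boundary_region_prob_train(params, t.stimulus, pair)
            p = p_first if x_label == pair[0] else 1.0 - p_first
        idx.append(t.index)
        labels.append(x_label)
        probs.append(p)
        obs.append(int(t.implied_category == x_label))
    return PredictionSeries(
        trial_index=np.array(idx, dtype=int),
        label=np.array(labels, dtype=object),
        p_region=np.array(probs, dtype=float),
        p_response=None,
        observed=np.array(obs, dtype=int),
    )


def test_region_probs(
    session: Session,
    params: DensityModelParams | BoundaryModelParams,
) -> PredictionSeries:
    """Region probabilities over the block-6 (B vs C) test trials."""
    idx, labels, probs, obs = [], [], [], []
    for t in session.test_trials():
        if not t.has_category_response:
            continue
        x_label, y_label = _trial_reference_label(t)
        if isinstance(params, DensityModelParams):
            p = density_region_prob(params, t.stimulus, (x_label, y_label))
        else:
            p_b = boundary_region_prob_test(params, t.stimulus)
            p = p_b if x_label == "B" else 1.0 - p_b
        idx.append(t.index)
        labels.append(x_label)
        probs.append(p)
        obs.append(int(t.implied_category == x_label))
    return PredictionSeries(
        trial_index=np.array(idx, dtype=int),
        label=np.array(labels, dtype=object),
        p_region=np.array(probs, dtype=float),
        p_response=None,
        observed=np.array(obs, dtype=int),
    )
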