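"""Category structures and moment-matched stimulus sampling.

Two four-category structures on a 2-D stimulus space (dim1 = bar width,
dim2 = orientation, abstract units):

* ``RB`` (rule-based): the four category means differ only on dim2, so a
  verbalizable criterion on a single dimension separates them.
* ``II`` (information-integration): the means fall along a diagonal and the
  shared covariance is correlated, so no single-dimension rule is optimal.

Stimulus sets are drawn from the category Gaussians and then linearly
transformed ("moment matched") so the per-category sample mean and covariance
equal the generative parameters exactly — the classic randomization technique
used to remove sampling noise from category-learning stimulus sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LABELS",
    "CategoryDistribution",
    "CategoryStructure",
    "StimulusSample",
    "DegenerateSampleError",
    "make_structure",
    "moment_match",
    "sample_stimuli",
    "DEFAULT_COUNTS",
]

LABELS: tuple[str, ...] = ("A", "B", "C", "D")

#: Per-category counts for the canonical 600-stimulus set: 500 training trials
#: over four equally likely categories (125 each) plus 100 B/C test trials
#: (50 each), so every stimulus is shown exactly once.
DEFAULT_COUNTS: tuple[int, ...] = (125, 175, 175, 125)


class DegenerateSampleError(ValueError):
    """Raised when a point sample has a singular covariance (e.g. collinear)."""


@dataclass(frozen=True)
class CategoryDistribution:
    """A labeled bivariate-normal category distribution."""

    label: str
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if mean.shape != (2,):
            raise ValueError(f"mean must be a 2-vector, got shape {mean.shape}")
        if cov.shape != (2, 2):
            raise ValueError(f"cov must be 2x2, got shape {cov.shape}")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("covariance must be positive definite")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)


@dataclass(frozen=True)
class CategoryStructure:
    """Four labeled category distributions plus structure-level conventions.

    ``density_mode`` is the dimensionality convention for within-category
    (density) observers and fits: the RB structure is represented on dim2
    only (one mean and one variance per category), the II structure on both
    dimensions with a full covariance.

    ``projection_axis`` is the unit axis on which between-category bounds
    live: dim2 for RB (the single relevant dimension); the direction
    orthogonal to the II category-mean axis, (1, -1)/sqrt(2), for II.
    """

    kind: str
    categories: tuple[CategoryDistribution, ...]

    def __post_init__(self) -> None:
        labels = tuple(c.label for c in self.categories)
        if labels != LABELS:
            raise ValueError(f"categories must be labeled {LABELS} in order, got {labels}")

    def distribution(self, label: str) -> CategoryDistribution:
        for cat in self.categories:
            if cat.label == label:
                return cat
        raise KeyError(label)

    @property
    def means(self) -> dict[str, np.ndarray]:
        return {c.label: c.mean for c in self.categories}

    @property
    def covs(self) -> dict[str, np.ndarray]:
        return {c.label: c.cov for c in self.categories}

    @property
    def density_mode(self) -> str:
        return "univariate" if self.kind == "RB" else "bivariate"

    @property
    def projection_axis(self) -> np.ndarray:
        if self.kind == "RB":
            return np.array([0.0, 1.0])
        return np.array([1.0, -1.0]) / np.sqrt(2.0)

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project (n, 2) points (or a single point) onto the bound axis."""
        return np.asarray(points, dtype=float) @ self.projection_axis


_RB_MEANS = {"A": (1.9, 0.30), "B": (1.9, 0.67), "C": (1.9, 1.03), "D": (1.9, 1.40)}
_RB_COV = ((0.44, 0.0), (0.0, 0.01))
_II_MEANS = {"A": (0.92, 2.49), "B": (1.50, 1.93), "C": (2.02, 1.41), "D": (2.59, 0.82)}
_II_COV = ((0.06, 0.04), (0.04, 0.06))


def make_structure(kind: str) -> CategoryStructure:
    """Return the canonical RB or II four-category structure.

    Parameters
    ----------
    kind
        ``"RB"`` for the rule-based structure (means spaced along dim2,
        diagonal covariance) or ``"II"`` for the information-integration
        structure (diagonal mean axis, correlated covariance).
    """
    if kind == "RB":
        means, cov = _RB_MEANS, _RB_COV
    elif kind == "II":
        means, cov = _II_MEANS, _II_COV
    else:
        raise ValueError(f"unknown structure kind: {kind!r} (expected 'RB' or 'II')")
    cats = tuple(
        CategoryDistribution(label, np.array(means[label]), np.array(cov)) for label in LABELS
    )
    return CategoryStructure(kind=kind, categories=cats)


def moment_match(
    points: np.ndarray | Sequence[Sequence[float]],
    target_mean: np.ndarray | Sequence[float],
    target_cov: np.ndarray | Sequence[Sequence[float]],
) -> np.ndarray:
    """Linearly transform points so their sample moments equal the targets.

    Applies ``y_i = m + T (x_i - xbar)`` with ``T = L_t L_s^{-1}``, where
    ``L_s`` and ``L_t`` are the lower-triangular Cholesky factors of the
    sample covariance (ddof=1) and the target covariance. The returned
    sample then has mean ``target_mean`` and covariance ``target_cov``
    exactly (to floating-point precision), and the map is idempotent.

    Raises
    ------
    DegenerateSampleError
        If the sample covariance is singular (fewer than 3 points, or all
        points collinear).
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    m = np.asarray(target_mean, dtype=float)
    s = np.asarray(target_cov, dtype=float)
    if x.shape[0] < 2:
        raise DegenerateSampleError("need at least 2 points to estimate a covariance")
    xbar = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    try:
        ls = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise DegenerateSampleError("sample covariance is singular") from exc
    lt = np.linalg.cholesky(s)
    t = lt @ np.linalg.inv(ls)
    return m + (x - xbar) @ t.T


@dataclass
class StimulusSample:
    """A labeled 2-D stimulus set tied to a generating structure."""

    points: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,) of category labels
    structure_kind: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.points.shape[0] != self.labels.shape[0]:
            raise ValueError("points and labels must have equal length")

    def __len__(self) -> int:
        return self.points.shape[0]

    def subset(self, label: str) -> np.ndarray:
        return self.points[self.labels == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dim1": self.points[:, 0], "dim2": self.points[:, 1], "category": self.labels}
        )

    def to_csv(self, path) -> None:
        """Write as ``dim1,dim2,category`` CSV (UTF-8, LF, full precision)."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("dim1,dim2,category\n")
            for (d1, d2), lab in zip(self.points, self.labels):
                fh.write(f"{float(d1)!r},{float(d2)!r},{lab}\n")

    @classmethod
    def from_csv(cls, path, structure_kind: str = "") -> "StimulusSample":
        df = pd.read_csv(path, dtype={"category": str}, float_precision="round_trip")
        expected = ["dim1", "dim2", "category"]
        if list(df.columns) != expected:
            raise ValueError(f"expected header {expected}, got {list(df.columns)}")
        return cls(
            points=df[["dim1", "dim2"]].to_numpy(float),
            labels=df["category"].to_numpy(object),
            structure_kind=structure_kind,
        )


def _normalize_counts(counts) -> dict[str, int]:
    if counts is None:
        counts = DEFAULT_COUNTS
    if isinstance(counts, Mapping):
        out = {lab: int(counts[lab]) for lab in LABELS}
    else:
        seq = list(counts)
        if len(seq) != 4:
            raise ValueError("counts must give one value per category A-D")
        out = dict(zip(LABELS, (int(c) for c in seq)))
    for lab, n in out.items():
        if n < 4:
            raise ValueError(f"count for category {lab} must be >= 4, got {n}")
    return out


def sample_stimuli(
    structure: CategoryStructure,
    counts: Mapping[str, int] | Iterable[int] | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> StimulusSample:
    """Draw a moment-matched stimulus set from a category structure.

    Per category, ``counts[label]`` points are drawn from the generative
    bivariate normal and moment matched to it; the pooled set is then
    shuffled deterministically by ``seed``.
    """
    per_cat = _normalize_counts(counts)
    rng = np.random.default_rng(seed)
    pts, labs = [], []
    for cat in structure.categories:
        n = per_cat[cat.label]
        raw = rng.multivariate_normal(cat.mean, cat.cov, size=n)
        pts.append(moment_match(raw, cat.mean, cat.cov))
        labs.extend([cat.label] * n)
    points = np.vstack(pts)
    labels = np.asarray(labs, dtype=object)
    order = rng.permutation(points.shape[0])
    return StimulusSample(points=points[order], labels=labels[order], structure_kind=structure.kind)
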