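"""Group-level descriptive statistics and the report bundle.

Blockwise accuracy curves (group mean with between-subject SEM), the
pooled-variance two-proportion z test used to compare the share of
within-representation participants across training conditions, and a
serializable report combining verdict counts, RMSD summaries and accuracy
tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .protocol import Cohort
from .selection import CohortClassification

__all__ = [
    "UndefinedVarianceError",
    "block_accuracy",
    "two_proportion_z",
    "reproduce_report",
    "validate_report",
    "REPORT_SCHEMA",
]


class UndefinedVarianceError(ValueError):
    """Pooled proportion is 0 or 1: the z statistic's variance vanishes."""


def block_accuracy(
    cohort: Cohort,
    classification: CohortClassification | None = None,
    by: str = "condition",
) -> pd.DataFrame:
    """Per-block accuracy, averaged over participants within groups.

    Per-participant block accuracy is correct responses over valid
    (category-response) trials; the table reports the group mean, the
    between-subject SEM (sample SD over participants / sqrt(n); 0 for
    singleton groups) and n per (group, block).

    ``by`` is ``"condition"``, ``"verdict"`` or ``"condition,verdict"``;
    verdict grouping requires ``classification``. Participants without a
    verdict (excluded) are dropped from verdict groupings with a warning
    flag in the table attrs.
    """
    group_cols = [c.strip() for c in by.split(",") if c.strip()]
    for col in group_cols:
        if col not in ("condition", "verdict"):
            raise ValueError(f"cannot group by {col!r}")
    if "verdict" in group_cols and classification is None:
        raise ValueError("verdict grouping requires a CohortClassification")
    rows = []
    dropped = []
    for s in cohort.sessions:
        verdict = None
        if classification is not None:
            try:
                verdict = classification.verdict_of(s.participant_id)
            except KeyError:
                verdict = None
        if "verdict" in group_cols and verdict is None:
            dropped.append(s.participant_id)
            continue
        for b in range(1, 7):
            trials = [t for t in s.block(b) if t.has_category_response]
            if not trials:
                continue
            acc = float(np.mean([t.correct for t in trials]))
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "condition": s.condition,
                    "verdict": verdict,
                    "block": b,
                    "accuracy": acc,
                }
            )
    if not rows:
        raise ValueError("no valid trials in cohort")
    per_part = pd.DataFrame(rows)
    out = (
        per_part.groupby(group_cols + ["block"])["accuracy"]
        .agg(
            mean_accuracy="mean",
            sem=lambda a: float(a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0,
            n="count",
        )
        .reset_index()
    )
    out.attrs["dropped_participants"] = dropped
    return out


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> float:
    """Pooled-variance two-proportion z statistic (no continuity correction).

    ``z = (k1/n1 - k2/n2) / sqrt(p(1-p)(1/n1 + 1/n2))`` with
    ``p = (k1+k2)/(n1+n2)``. Raises :class:`UndefinedVarianceError` when the
    pooled proportion is 0 or 1.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise UndefinedVarianceError("pooled proportion is 0 or 1")
    z, _ = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(z)


#: Structural schema of the report bundle: required keys and value types.
REPORT_SCHEMA: dict = {
    "structure": str,
    "conditions": list,
    "verdict_counts": list,  # records of selection counts per condition
    "proportion_tests": list,  # records with k/n pairs and the z statistic
    "rmsd_summary": list,  # records: condition, verdict, model, mean RMSD, n
    "block_accuracy": list,  # records: condition, block, mean, sem, n
    "recovery": (dict, type(None)),  # present when ground-truth tags exist
}


def validate_report(report: dict) -> None:
    """Check a report against :data:`REPORT_SCHEMA`; raise ValueError if bad."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has type {type(report[key]).__name__}")
    for rec in report["verdict_counts"]:
        for k in ("condition", "n", "within", "between"):
            if k not in rec:
                raise ValueError(f"verdict_counts record missing {k!r}")


def reproduce_report(
    cohort: Cohort,
    classification: CohortClassification,
    out_dir: str | Path | None = None,
    make_plots: bool = False,
) -> dict:
    """Assemble the cohort's full results bundle.

    Emits verdict counts and proportions per condition, the two-condition
    proportion z test (when both conditions are present and the variance is
    defined), the Tables-style RMSD summary, blockwise accuracy overall and
    split by verdict, and — when the cohort metadata carries ground-truth
    representation tags — the model recovery rate.

    If ``out_dir`` is given, writes ``report.json``, ``block_accuracy.csv``
    and ``rmsd_summary.csv`` (plus PNG figures when ``make_plots``).
    """
    counts = classification.counts
    acc_by_cond = block_accuracy(cohort, by="condition")
    acc_by_verdict = block_accuracy(cohort, classification, by="condition,verdict")

    proportion_tests = []
    conds = list(counts["condition"])
    if len(conds) == 2:
        rec1 = counts[counts["condition"] == conds[0]].iloc[0]
        rec2 = counts[counts["condition"] == conds[1]].iloc[0]
        n1 = int(rec1["within"] + rec1["between"])
        n2 = int(rec2["within"] + rec2["between"])
        try:
            z = two_proportion_z(int(rec1["within"]), n1, int(rec2["within"]), n2)
            proportion_tests.append(
                {
                    "contrast": f"{conds[0]} vs {conds[1]}",
                    "k1": int(rec1["within"]),
                    "n1": n1,
                    "k2": int(rec2["within"]),
                    "n2": n2,
                    "z": z,
                }
            )
        except UndefinedVarianceError:
            proportion_tests.append(
                {"contrast": f"{conds[0]} vs {conds[1]}", "z": None, "note": "undefined variance"}
            )

    recovery = None
    truth = cohort.metadata.get("ground_truth")
    if truth:
        matched = 0
        total = 0
        for c in classification.classifications:
            if c.verdict is None or c.participant_id not in truth:
                continue
            total += 1
            matched += int(c.verdict == truth[c.participant_id])
        if total:
            recovery = {"n": total, "recovered": matched, "rate": matched / total}

    report = {
        "structure": str(cohort.metadata.get("structure", "")),
        "conditions": conds,
        "verdict_counts": counts.to_dict(orient="records"),
        "proportion_tests": proportion_tests,
        "rmsd_summary": classification.rmsd_summary.to_dict(orient="records"),
        "block_accuracy": acc_by_cond.to_dict(orient="records"),
        "block_accuracy_by_verdict": acc_by_verdict.to_dict(orient="records"),
        "recovery": recovery,
    }
    validate_report(report)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        acc_by_cond.to_csv(out_dir / "block_accuracy.csv", index=False)
        classification.rmsd_summary.to_csv(out_dir / "rmsd_summary.csv", index=False)
        if make_plots:
            _plot_block_accuracy(acc_by_cond, out_dir / "block_accuracy.png")
    return report


def _plot_block_accuracy(table: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for cond, grp in table.groupby("condition"):
        ax.errorbar(grp["block"], grp["mean_accuracy"], yerr=grp["sem"], label=cond, marker="o")
    ax.axhline(0.5, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("Block")
    ax.set_ylabel("Mean accuracy")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
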