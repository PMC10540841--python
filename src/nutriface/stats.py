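"""Cohort 2x2 contingency statistics and subgroup accuracy reports.

All 2x2 tests use the Pearson chi-square with Yates continuity correction
(1 degree of freedom): each observed count is moved 0.5 toward its expected
value (never past it) before the chi-square sum, so a table whose deviations
are at most 0.5 scores a statistic of exactly 0 (p = 1).  A validity warning
is attached whenever any expected cell count falls below 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency

__all__ = ["ContingencyTable2x2", "yates_chi2", "subgroup_report"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts; rows are groups, columns outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def yates_chi2(table) -> tuple[float, float]:
    """Yates-corrected chi-square test on a 2x2 table.

    Accepts a :class:`ContingencyTable2x2` or any 2x2 array-like.  Returns
    ``(statistic, p_value)`` with the p-value from the upper tail of
    chi-square with 1 df.  Raises on a zero row or column marginal.
    """
    if isinstance(table, ContingencyTable2x2):
        obs = table.as_array()
    else:
        obs = np.asarray(table, dtype=float)
        if obs.shape != (2, 2):
            raise ValueError("expected a 2x2 table")
        if (obs < 0).any():
            raise ValueError("cell counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row or column marginal")

    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if (expected < 5).any():
        warnings.warn(
            "chi-square approximation may be unreliable: expected cell < 5",
            stacklevel=2,
        )
    stat, p, _, _ = chi2_contingency(obs, correction=True)
    return float(stat), float(p)


def subgroup_report(records, predictions, attribute: str) -> dict:
    """Per-level prediction accuracy plus a chi-square homogeneity test.

    ``records`` is a list of sample records carrying ``nrs_score`` and the
    grouping attribute (``age_group``, ``gender`` or ``site``);
    ``predictions`` are labels (1 = NRS < 3) aligned with the records.  The
    p-value comes from the Yates chi-square on the level x (correct,
    incorrect) table and is reported as None unless exactly two levels are
    present.
    """
    from .classifier import label_from_score

    if len(records) != len(predictions):
        raise ValueError("records and predictions are not aligned")
    if len(records) == 0:
        raise ValueError("empty input")
    truth = label_from_score([r.nrs_score for r in records])
    pred = np.asarray(predictions, dtype=int)
    correct = truth == pred
    levels_present = sorted({getattr(r, attribute) for r in records})

    rows = []
    for level in levels_present:
        sel = np.array([getattr(r, attribute) == level for r in records])
        n_corr = int(correct[sel].sum())
        n_inc = int(sel.sum()) - n_corr
        rows.append(
            {
                "name": level,
                "correct": n_corr,
                "incorrect": n_inc,
                "total": int(sel.sum()),
                "accuracy": n_corr / int(sel.sum()),
            }
        )

    report = {
        "attribute": attribute,
        "levels": rows,
        "correction": "yates",
        "chi2": None,
        "p": None,
    }
    if len(rows) == 2:
        table = np.array(
            [[rows[0]["correct"], rows[0]["incorrect"]],
             [rows[1]["correct"], rows[1]["incorrect"]]]
        )
        if (table.sum(axis=0) == 0).any():
            # all-correct (or all-incorrect) in both levels: outcomes are
            # perfectly homogeneous, so no evidence of heterogeneity
            report["chi2"], report["p"] = 0.0, 1.0
        else:
            stat, p = yates_chi2(table)
            report["chi2"], report["p"] = stat, p
    else:
        warnings.warn(
            f"attribute {attribute!r} has {len(rows)} observed levels; "
            "p-value unavailable",
            stacklevel=2,
        )
    return report


def format_subgroup_table(report: dict) -> str:
    """Plain-text rendering with accuracies to one decimal place."""
    lines = [f"{report['attribute']}: correct incorrect total accuracy"]
    for row in report["levels"]:
        lines.append(
            f"  {row['name']}: {row['correct']} {row['incorrect']} "
            f"{row['total']} {100 * row['accuracy']:.1f}%"
        )
    if report["p"] is not None:
        lines.append(f"  P = {report['p']:.3f} (Yates chi-square)")
    return "\n".join(lines)
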