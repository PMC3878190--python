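"""Likelihood-ratio ordering, optimal ROC construction and AUC computation.

The central objects are *risk groups*: disjoint events G_j carrying a
probability mass under cases, ``P(G_j | D)``, and under controls,
``P(G_j | D̄)``.  Ordering groups by their likelihood ratio
``P(G_j | D) / P(G_j | D̄)`` and accumulating masses yields the optimal
(concave) ROC curve of any classifier built on those groups; its area equals
the probability that a random case outranks a random control, ties counted
half.  Both the design stage (theoretical genotype distributions) and the
build stage (empirical group counts) reduce to these primitives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

#: absolute tolerance for probability-mass comparisons
MASS_ATOL = 1e-9
#: relative tolerance under which two likelihood ratios are considered tied
LR_RTOL = 1e-12

__all__ = [
    "MASS_ATOL",
    "LR_RTOL",
    "RiskGroup",
    "GroupMassTable",
    "ROCPoints",
    "lr_order",
    "roc_from_groups",
    "auc_from_groups",
    "empirical_auc",
]


@dataclass(frozen=True)
class RiskGroup:
    """One risk group with its case/control probability masses."""

    label: str
    mass_case: float
    mass_control: float

    def __post_init__(self) -> None:
        if self.mass_case < -MASS_ATOL or self.mass_control < -MASS_ATOL:
            raise ValueError(f"group {self.label!r}: negative mass")
        if self.mass_case <= 0 and self.mass_control <= 0:
            raise ValueError(f"group {self.label!r}: both masses zero")

    @property
    def lr(self) -> float:
        """Likelihood ratio ``mass_case / mass_control`` (+inf if control mass is 0)."""
        if self.mass_control > 0:
            return self.mass_case / self.mass_control
        return math.inf


@dataclass(frozen=True)
class GroupMassTable:
    """A complete set of risk groups; both margins must sum to one."""

    groups: tuple[RiskGroup, ...]

    def __init__(self, groups: Iterable[RiskGroup]):
        object.__setattr__(self, "groups", tuple(groups))
        if not self.groups:
            raise ValueError("no risk groups")
        for total, side in (
            (sum(g.mass_case for g in self.groups), "case"),
            (sum(g.mass_control for g in self.groups), "control"),
        ):
            if abs(total - 1.0) > MASS_ATOL:
                raise ValueError(f"{side} masses sum to {total!r}, expected 1")

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)

    @property
    def mass_case(self) -> np.ndarray:
        return np.array([g.mass_case for g in self.groups])

    @property
    def mass_control(self) -> np.ndarray:
        return np.array([g.mass_control for g in self.groups])

    @property
    def lrs(self) -> np.ndarray:
        return np.array([g.lr for g in self.groups])


@dataclass(frozen=True)
class ROCPoints:
    """An ROC polyline as (fpr, tpr) vertices from (0,0) to (1,1)."""

    points: tuple[tuple[float, float], ...]

    @property
    def fpr(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def tpr(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def to_tsv(self, path) -> None:
        """Write the curve as a two-column ``fpr\\ttpr`` table."""
        with open(path, "w") as fh:
            fh.write("fpr\ttpr\n")
            for x, y in self.points:
                fh.write(f"{x:.10g}\t{y:.10g}\n")

    def plot(self, ax=None, label: str | None = None):
        """Draw the curve on a matplotlib axis (created if not given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr, marker=".", label=label)
        ax.plot([0, 1], [0, 1], linestyle=":", color="grey", linewidth=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_xlim(-0.02, 1.02)
        ax.set_ylim(-0.02, 1.02)
        if label:
            ax.legend(loc="lower right")
        return ax


def _lr_tied(a: float, b: float) -> bool:
    if math.isinf(a) or math.isinf(b):
        return math.isinf(a) and math.isinf(b)
    return math.isclose(a, b, rel_tol=LR_RTOL, abs_tol=0.0)


def lr_order(table: GroupMassTable) -> GroupMassTable:
    """Sort groups by likelihood ratio, descending, merging exact LR ties.

    Groups whose LRs agree to within :data:`LR_RTOL` relative tolerance are
    collapsed into a single group with summed masses (the optimal ROC is
    defined on LR level sets); groups with infinite LR sort first and are
    merged together.
    """
    if not table.groups:  # pragma: no cover - GroupMassTable forbids this
        raise ValueError("no risk groups")
    ordered = sorted(table.groups, key=lambda g: g.lr, reverse=True)
    merged: list[RiskGroup] = []
    for grp in ordered:
        if merged and _lr_tied(merged[-1].lr, grp.lr):
            prev = merged[-1]
            merged[-1] = RiskGroup(
                label=f"{prev.label}+{grp.label}",
                mass_case=prev.mass_case + grp.mass_case,
                mass_control=prev.mass_control + grp.mass_control,
            )
        else:
            merged.append(grp)
    return GroupMassTable(merged)


def roc_from_groups(ordered: GroupMassTable) -> ROCPoints:
    """Cumulate LR-ordered masses into ROC vertices.

    Point ``k`` is the (cumulative control mass, cumulative case mass) over
    the first ``k`` groups, prepended with (0, 0).  Raises if the input is
    not in non-increasing LR order.
    """
    lrs = ordered.lrs
    for i in range(1, len(lrs)):
        if lrs[i] > lrs[i - 1] and not _lr_tied(lrs[i], lrs[i - 1]):
            raise ValueError(
                f"groups not in LR order: lr[{i}]={lrs[i]!r} > lr[{i - 1}]={lrs[i - 1]!r}"
            )
    fpr = np.concatenate([[0.0], np.cumsum(ordered.mass_control)])
    tpr = np.concatenate([[0.0], np.cumsum(ordered.mass_case)])
    if abs(fpr[-1] - 1.0) > MASS_ATOL or abs(tpr[-1] - 1.0) > MASS_ATOL:
        raise ValueError("cumulative masses do not reach 1")
    fpr[-1] = 1.0
    tpr[-1] = 1.0
    return ROCPoints(tuple(zip(fpr.tolist(), tpr.tolist())))


def auc_from_groups(table: GroupMassTable) -> float:
    """AUC of the optimal (LR-ordered) ROC of ``table``.

    Equals ``P(LR_case > LR_control) + 0.5 * P(LR_case = LR_control)`` for
    independent draws from the case and control margins.
    """
    ordered = lr_order(table)
    case = ordered.mass_case
    control = ordered.mass_control
    cum_before = np.concatenate([[0.0], np.cumsum(case)[:-1]])
    return float(np.sum(control * (cum_before + case / 2.0)))


def empirical_auc(
    case_scores: Sequence[float], control_scores: Sequence[float]
) -> float:
    """Mann-Whitney AUC estimate with half-credit for ties."""
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both score sequences must be non-empty")
    ranks = rankdata(np.concatenate([cases, controls]))
    u = ranks[: cases.size].sum() - cases.size * (cases.size + 1) / 2.0
    return float(u / (cases.size * controls.size))
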