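"""Design stage: theoretical AUC of a multilocus model and sample-size planning.

Per-marker inputs are either genotype frequencies conditional on disease
status, or population genotype frequencies (optionally a single risk-allele
frequency expanded under Hardy-Weinberg equilibrium) together with genotype
relative risks.  Markers are combined under linkage equilibrium and
multiplicative joint effects; the resulting multilocus genotype groups are
LR-ordered to give the optimal-ROC AUC.  Power and sample size for testing
the AUC against a null value use an asymptotic normal test with the
Hanley-McNeil variance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm

from .core import (
    MASS_ATOL,
    GroupMassTable,
    RiskGroup,
    ROCPoints,
    auc_from_groups,
    lr_order,
    roc_from_groups,
)

#: maximum number of loci combined exhaustively (3**15 = 14,348,907 groups)
MAX_DESIGN_LOCI = 15

__all__ = [
    "MAX_DESIGN_LOCI",
    "SnpDesignInfo",
    "DesignConfig",
    "DesignResult",
    "hwe_genotype_freqs",
    "conditional_freqs_from_rr",
    "to_conditional",
    "combine_independent",
    "design_auc",
    "auc_variance",
    "power_at_n",
    "required_sample_size",
    "run_design",
]


def hwe_genotype_freqs(allele_freq: float) -> tuple[float, float, float]:
    """Expand a risk-allele frequency q to genotype frequencies under HWE."""
    if not 0.0 < allele_freq < 1.0:
        raise ValueError(f"allele frequency {allele_freq} outside (0,1)")
    q = allele_freq
    return ((1.0 - q) ** 2, 2.0 * q * (1.0 - q), q * q)


def _check_triple(name: str, triple: Sequence[float]) -> tuple[float, float, float]:
    arr = tuple(float(x) for x in triple)
    if len(arr) != 3:
        raise ValueError(f"{name} must have exactly 3 entries, got {len(arr)}")
    if any(x < 0 for x in arr):
        raise ValueError(f"{name} has negative entries: {arr}")
    if abs(sum(arr) - 1.0) > MASS_ATOL:
        raise ValueError(f"{name} sums to {sum(arr)!r}, expected 1")
    return arr


@dataclass(frozen=True)
class SnpDesignInfo:
    """Design-stage information for one SNP (genotypes coded 0/1/2).

    Exactly one of two modes:

    ``conditional``
        genotype frequencies in cases (``freq_case``) and controls
        (``freq_control``).
    ``population_rr``
        population genotype frequencies (``freq_pop``) and genotype relative
        risks (``rr``, baseline genotype fixed at 1).
    """

    snp_id: str
    mode: Literal["conditional", "population_rr"]
    freq_case: tuple[float, float, float] | None = None
    freq_control: tuple[float, float, float] | None = None
    freq_pop: tuple[float, float, float] | None = None
    rr: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode == "conditional":
            if self.freq_case is None or self.freq_control is None:
                raise ValueError(f"{self.snp_id}: conditional mode needs freq_case and freq_control")
            if self.freq_pop is not None or self.rr is not None:
                raise ValueError(f"{self.snp_id}: conditional mode forbids freq_pop/rr")
            object.__setattr__(self, "freq_case", _check_triple(f"{self.snp_id} freq_case", self.freq_case))
            object.__setattr__(self, "freq_control", _check_triple(f"{self.snp_id} freq_control", self.freq_control))
        elif self.mode == "population_rr":
            if self.freq_pop is None or self.rr is None:
                raise ValueError(f"{self.snp_id}: population_rr mode needs freq_pop and rr")
            if self.freq_case is not None or self.freq_control is not None:
                raise ValueError(f"{self.snp_id}: population_rr mode forbids freq_case/freq_control")
            object.__setattr__(self, "freq_pop", _check_triple(f"{self.snp_id} freq_pop", self.freq_pop))
            rr = tuple(float(x) for x in self.rr)
            if len(rr) != 3 or any(x <= 0 for x in rr):
                raise ValueError(f"{self.snp_id}: rr must be 3 positive numbers, got {self.rr}")
            object.__setattr__(self, "rr", rr)
        else:
            raise ValueError(f"{self.snp_id}: unknown mode {self.mode!r}")


@dataclass(frozen=True)
class DesignConfig:
    """Study-design parameters for the AUC hypothesis test."""

    prevalence: float
    alpha: float = 0.05
    power: float = 0.95
    auc0: float = 0.5
    case_control_ratio: float = 1.0
    two_sided: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence {self.prevalence} outside (0,1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha {self.alpha} outside (0,1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError(f"power {self.power} outside (0,1)")
        if not 0.5 <= self.auc0 < 1.0:
            raise ValueError(f"auc0 {self.auc0} outside [0.5,1)")
        if self.case_control_ratio <= 0:
            raise ValueError("case_control_ratio must be positive")


@dataclass(frozen=True)
class DesignResult:
    auc: float
    roc: ROCPoints
    n_groups: int
    n_cases_required: int | None = None
    n_controls_required: int | None = None


def conditional_freqs_from_rr(
    freq_pop: Sequence[float],
    rr: Sequence[float],
    prevalence: float,
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Convert population genotype frequencies + relative risks to case/control frequencies.

    With penetrance f_g = k * rr_g scaled so the population prevalence equals
    ``prevalence``, Bayes' rule gives

        P(g | case)    = freq_pop_g * rr_g / sum_h freq_pop_h * rr_h
        P(g | control) = freq_pop_g * (1 - k * rr_g) / (1 - prevalence)

    Raises if any implied penetrance exceeds one.
    """
    fp = np.asarray(_check_triple("freq_pop", freq_pop))
    r = np.asarray([float(x) for x in rr])
    if r.shape != (3,) or np.any(r <= 0):
        raise ValueError(f"rr must be 3 positive numbers, got {rr}")
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence {prevalence} outside (0,1)")
    denom = float(fp @ r)
    k = prevalence / denom
    if k * r.max() > 1.0 + 1e-12:
        raise ValueError(
            f"impossible penetrance: prevalence {prevalence} with rr {tuple(r)} "
            f"implies max penetrance {k * r.max():.4g} > 1"
        )
    case = fp * r / denom
    control = fp * (1.0 - k * r) / (1.0 - prevalence)
    control = control / control.sum()  # guard fp rounding
    return tuple(case.tolist()), tuple(control.tolist())


def to_conditional(snp: SnpDesignInfo, prevalence: float) -> SnpDesignInfo:
    """Return ``snp`` in conditional mode, converting population_rr via Bayes."""
    if snp.mode == "conditional":
        return snp
    case, control = conditional_freqs_from_rr(snp.freq_pop, snp.rr, prevalence)
    return SnpDesignInfo(
        snp_id=snp.snp_id, mode="conditional", freq_case=case, freq_control=control
    )


def combine_independent(
    snps: Sequence[SnpDesignInfo], prevalence: float, max_loci: int = MAX_DESIGN_LOCI
) -> GroupMassTable:
    """Joint multilocus genotype distribution under between-marker independence.

    One group per multilocus genotype combination; masses are products of the
    per-marker conditional frequencies within each disease class.
    """
    if len(snps) == 0:
        raise ValueError("no SNPs to combine")
    if len(snps) > max_loci:
        raise ValueError(
            f"{len(snps)} loci exceed the exhaustive-combination limit of {max_loci}; "
            "aggregate markers before the design stage"
        )
    cond = [to_conditional(s, prevalence) for s in snps]
    groups = []
    for combo in itertools.product(range(3), repeat=len(cond)):
        mc = 1.0
        mk = 1.0
        for snp, g in zip(cond, combo):
            mc *= snp.freq_case[g]
            mk *= snp.freq_control[g]
        if mc <= 0.0 and mk <= 0.0:
            continue
        label = "/".join(f"{s.snp_id}={g}" for s, g in zip(cond, combo))
        groups.append(RiskGroup(label=label, mass_case=mc, mass_control=mk))
    return GroupMassTable(groups)


def design_auc(snps: Sequence[SnpDesignInfo], config: DesignConfig) -> DesignResult:
    """Optimal-ROC AUC of the proposed multilocus model (no sample size)."""
    joint = combine_independent(snps, config.prevalence)
    ordered = lr_order(joint)
    return DesignResult(
        auc=auc_from_groups(ordered),
        roc=roc_from_groups(ordered),
        n_groups=len(ordered),
    )


def auc_variance(auc: float, n_case: int, n_control: int) -> float:
    """Hanley-McNeil asymptotic variance of the empirical AUC.

    ``[A(1-A) + (n_case-1)(Q1-A^2) + (n_control-1)(Q2-A^2)] / (n_case*n_control)``
    with ``Q1 = A/(2-A)`` and ``Q2 = 2A^2/(1+A)``.
    """
    if not 0.0 < auc < 1.0:
        raise ValueError(f"auc {auc} outside (0,1)")
    if n_case < 1 or n_control < 1:
        raise ValueError("counts must be >= 1")
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    return (
        a * (1.0 - a)
        + (n_case - 1) * (q1 - a * a)
        + (n_control - 1) * (q2 - a * a)
    ) / (n_case * n_control)


def power_at_n(
    auc1: float,
    auc0: float,
    alpha: float,
    n_cases: int,
    n_controls: int,
    two_sided: bool = False,
) -> float:
    """Power of the asymptotic normal AUC test at the given group sizes."""
    a = alpha / 2.0 if two_sided else alpha
    z = norm.ppf(1.0 - a)
    sd0 = math.sqrt(auc_variance(auc0, n_cases, n_controls))
    sd1 = math.sqrt(auc_variance(auc1, n_cases, n_controls))
    return float(norm.cdf((auc1 - auc0 - z * sd0) / sd1))


def required_sample_size(
    auc1: float,
    auc0: float,
    alpha: float,
    power: float,
    ratio: float = 1.0,
    two_sided: bool = False,
) -> tuple[int, int]:
    """Smallest case count (controls = ceil(ratio * cases)) reaching ``power``.

    Doubling search for an upper bracket followed by bisection; the power
    function is monotone increasing in n.
    """
    if auc1 <= auc0:
        raise ValueError(f"alternative AUC {auc1} must exceed null AUC {auc0}")
    if ratio <= 0:
        raise ValueError("ratio must be positive")

    def _controls(n: int) -> int:
        return max(1, math.ceil(ratio * n - 1e-9))

    def _power(n: int) -> float:
        return power_at_n(auc1, auc0, alpha, n, _controls(n), two_sided=two_sided)

    hi = 2
    while _power(hi) < power:
        hi *= 2
        if hi > 1 << 40:  # pragma: no cover
            raise RuntimeError("sample-size search did not converge")
    lo = hi // 2 if hi > 2 else 1
    while lo < hi:
        mid = (lo + hi) // 2
        if _power(mid) >= power:
            hi = mid
        else:
            lo = mid + 1
    return hi, _controls(hi)


def run_design(snps: Sequence[SnpDesignInfo], config: DesignConfig) -> DesignResult:
    """Full design pipeline: AUC estimate plus required sample size."""
    base = design_auc(snps, config)
    if base.auc > config.auc0:
        n_case, n_control = required_sample_size(
            base.auc,
            config.auc0,
            config.alpha,
            config.power,
            ratio=config.case_control_ratio,
            two_sided=config.two_sided,
        )
        return replace(base, n_cases_required=n_case, n_controls_required=n_control)
    return base
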