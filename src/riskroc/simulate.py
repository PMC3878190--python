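"""Retrospective case-control genotype simulation with known ground truth.

Unlinked biallelic SNPs are generated under a multiplicative penetrance
model: each genotype's relative risk is the product of per-SNP genotype
relative risks (times optional pairwise epistatic multipliers), scaled so
the population prevalence matches the requested value.  Cases and controls
are then drawn i.i.d. from the implied conditional joint genotype
distributions, matching a retrospective sampling design, and missing calls
are masked completely at random.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .build import MISSING, GenotypeDataset
from .core import GroupMassTable, RiskGroup, auc_from_groups
from .design import SnpDesignInfo, hwe_genotype_freqs

#: joint enumeration guard (3**12 = 531,441 multilocus genotypes)
MAX_SIM_LOCI = 12

__all__ = ["MAX_SIM_LOCI", "EpistasisTerm", "SimConfig", "truth_spec", "simulate_case_control"]


@dataclass(frozen=True)
class EpistasisTerm:
    """Penetrance multiplier applied to genotype pairs of two SNPs.

    ``multipliers[g_i][g_j]`` scales the joint relative risk of samples
    carrying genotype ``g_i`` at ``snp_i`` and ``g_j`` at ``snp_j``.
    """

    snp_i: int
    snp_j: int
    multipliers: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        m = tuple(tuple(float(x) for x in row) for row in self.multipliers)
        if len(m) != 3 or any(len(row) != 3 for row in m):
            raise ValueError("multipliers must be a 3x3 table")
        if any(x <= 0 for row in m for x in row):
            raise ValueError("all multipliers must be > 0")
        object.__setattr__(self, "multipliers", m)


@dataclass(frozen=True)
class SimConfig:
    n_case: int
    n_control: int
    mafs: tuple[float, ...]
    rr: tuple[tuple[float, float, float], ...]
    prevalence: float
    epistasis: tuple[EpistasisTerm, ...] = ()
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mafs", tuple(float(m) for m in self.mafs))
        object.__setattr__(
            self, "rr", tuple(tuple(float(x) for x in t) for t in self.rr)
        )
        object.__setattr__(self, "epistasis", tuple(self.epistasis))
        if len(self.mafs) != len(self.rr):
            raise ValueError("mafs and rr must have the same length")
        if len(self.mafs) > MAX_SIM_LOCI:
            raise ValueError(f"at most {MAX_SIM_LOCI} loci supported")
        if any(not 0.0 < m <= 0.5 for m in self.mafs):
            raise ValueError("risk-allele frequencies must lie in (0, 0.5]")
        if any(len(t) != 3 or any(x <= 0 for x in t) for t in self.rr):
            raise ValueError("each rr entry must be 3 positive numbers")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0,1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0,1)")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one case and one control")
        for term in self.epistasis:
            if not (0 <= term.snp_i < len(self.mafs) and 0 <= term.snp_j < len(self.mafs)):
                raise ValueError("epistasis term references an unknown SNP index")
            if term.snp_i == term.snp_j:
                raise ValueError("epistasis term must reference two distinct SNPs")

    @property
    def n_snps(self) -> int:
        return len(self.mafs)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(f"snp{i + 1}" for i in range(self.n_snps))


def _joint_distribution(config: SimConfig):
    """Enumerate multilocus genotypes with population frequency and relative risk."""
    pop_triples = [np.array(hwe_genotype_freqs(m)) for m in config.mafs]
    combos = np.array(
        list(itertools.product(range(3), repeat=config.n_snps)), dtype=np.int8
    )
    freq = np.ones(len(combos))
    rel = np.ones(len(combos))
    for i in range(config.n_snps):
        g = combos[:, i]
        freq *= pop_triples[i][g]
        rel *= np.array(config.rr[i])[g]
    for term in config.epistasis:
        mult = np.array(term.multipliers)
        rel *= mult[combos[:, term.snp_i], combos[:, term.snp_j]]
    k = config.prevalence / float(freq @ rel)
    if k * rel.max() > 1.0 + 1e-12:
        raise ValueError(
            f"penetrance model infeasible: max penetrance {k * rel.max():.4g} > 1"
        )
    mass_case = freq * rel * k / config.prevalence
    mass_control = freq * (1.0 - k * rel) / (1.0 - config.prevalence)
    return combos, mass_case, mass_control


def _joint_table(combos, mass_case, mass_control, snp_ids) -> GroupMassTable:
    groups = []
    for combo, mc, mk in zip(combos, mass_case, mass_control):
        if mc <= 0.0 and mk <= 0.0:
            continue
        label = "/".join(f"{s}={int(g)}" for s, g in zip(snp_ids, combo))
        groups.append(RiskGroup(label=label, mass_case=float(mc), mass_control=float(mk)))
    return GroupMassTable(groups)


def truth_spec(
    config: SimConfig,
) -> tuple[list[SnpDesignInfo] | None, GroupMassTable, float]:
    """Exact generating distributions and their theoretical optimal-ROC AUC.

    Returns ``(per_snp_conditional, joint_table, theoretical_auc)``; the
    per-SNP conditional design spec is only available without epistasis
    (independence of the per-marker effects), otherwise ``None`` is returned
    in its place and the joint table is authoritative.
    """
    combos, mass_case, mass_control = _joint_distribution(config)
    joint = _joint_table(combos, mass_case, mass_control, config.snp_ids)
    theoretical_auc = auc_from_groups(joint)
    if config.epistasis:
        return None, joint, theoretical_auc
    snps = []
    for i, snp_id in enumerate(config.snp_ids):
        case = tuple(float(mass_case[combos[:, i] == g].sum()) for g in range(3))
        control = tuple(float(mass_control[combos[:, i] == g].sum()) for g in range(3))
        case = tuple(x / sum(case) for x in case)
        control = tuple(x / sum(control) for x in control)
        snps.append(
            SnpDesignInfo(
                snp_id=snp_id, mode="conditional", freq_case=case, freq_control=control
            )
        )
    return snps, joint, theoretical_auc


def simulate_case_control(config: SimConfig) -> GenotypeDataset:
    """Draw a retrospective case-control genotype dataset from the truth model."""
    rng = np.random.default_rng(config.seed)
    combos, mass_case, mass_control = _joint_distribution(config)
    case_rows = combos[
        rng.choice(len(combos), size=config.n_case, p=mass_case / mass_case.sum())
    ]
    control_rows = combos[
        rng.choice(
            len(combos), size=config.n_control, p=mass_control / mass_control.sum()
        )
    ]
    geno = np.vstack([case_rows, control_rows]).astype(np.int8)
    if config.missing_rate > 0.0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = MISSING
    phenotype = np.concatenate(
        [np.ones(config.n_case, dtype=np.int8), np.zeros(config.n_control, dtype=np.int8)]
    )
    sample_ids = tuple(
        [f"case_{i + 1}" for i in range(config.n_case)]
        + [f"control_{i + 1}" for i in range(config.n_control)]
    )
    return GenotypeDataset(sample_ids, phenotype, config.snp_ids, geno)
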