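import math

import numpy as np
import pytest

from riskroc.core import GroupMassTable, RiskGroup


def pairwise_auc_oracle(mass_case, mass_control, lrs) -> float:
    """Brute-force P(LR_case > LR_control) + 0.5 P(=) over all group pairs."""
    total = 0.0
    for ci, li in zip(mass_case, lrs):
        for kj, lj in zip(mass_control, lrs):
            if math.isinf(li) and math.isinf(lj):
                total += 0.5 * ci * kj
            elif li > lj:
                total += ci * kj
            elif li == lj:
                total += 0.5 * ci * kj
    return total


def auc_of_order(mass_case, mass_control) -> float:
    """AUC of the ROC built by accumulating groups in the given order."""
    cum = 0.0
    auc = 0.0
    for c, k in zip(mass_case, mass_control):
        auc += k * (cum + c / 2.0)
        cum += c
    return auc


def random_mass_table(rng: np.random.Generator, n_groups: int) -> GroupMassTable:
    case = rng.dirichlet(np.ones(n_groups))
    control = rng.dirichlet(np.ones(n_groups))
    return GroupMassTable(
        RiskGroup(f"g{i}", float(case[i]), float(control[i])) for i in range(n_groups)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
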