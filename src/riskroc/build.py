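"""Build stage: F-ROC forward selection of a risk-group partition tree.

Starting from a single root group holding every sample, each step splits all
current groups by the candidate SNP that maximizes the training AUC of the
resulting partition, optionally re-merging statistically indistinguishable
adjacent groups (by empirical likelihood ratio).  Stratified k-fold
cross-validation provides internal validation and, under ``stop_rule='cv'``,
chooses the model size; an independent dataset can be scored for external
validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.stats import chi2_contingency, fisher_exact

from .core import GroupMassTable, RiskGroup, empirical_auc, auc_from_groups

#: internal genotype code for a missing call
MISSING = -1
#: minimum training-AUC improvement for a forward step to count
AUC_IMPROVEMENT_EPS = 1e-9

MissingMode = Literal["own_category", "impute_mode"]
StopRule = Literal["fixed", "cv"]

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "RiskNode",
    "FitResult",
    "handle_missing",
    "empirical_lr",
    "split_group",
    "merge_groups",
    "partition_auc",
    "forward_step",
    "fit_froc",
    "cross_validated_auc",
    "apply_model",
]


@dataclass(frozen=True)
class GenotypeDataset:
    """Case-control genotype table.

    ``genotypes`` holds minor-allele counts 0/1/2 (treated as nominal
    categories) with :data:`MISSING` for missing calls; additional
    non-negative codes are tolerated for categorical environmental predictors
    with up to 8 levels.
    """

    sample_ids: tuple[str, ...]
    phenotype: np.ndarray  # int8, 0 = control, 1 = case
    snp_ids: tuple[str, ...]
    genotypes: np.ndarray  # int8 (n_samples, n_snps)

    def __post_init__(self) -> None:
        pheno = np.asarray(self.phenotype, dtype=np.int8)
        geno = np.asarray(self.genotypes, dtype=np.int8)
        object.__setattr__(self, "phenotype", pheno)
        object.__setattr__(self, "genotypes", geno)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        if geno.ndim != 2 or geno.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"genotype matrix shape {geno.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if pheno.shape != (len(self.sample_ids),):
            raise ValueError("phenotype length must equal sample count")
        if not set(np.unique(pheno)) <= {0, 1}:
            raise ValueError("phenotype must be coded 0 (control) / 1 (case)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int(self.n_samples - self.n_cases)

    def require_classes(self) -> None:
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError("dataset must contain at least one case and one control")

    def column(self, snp_id: str) -> np.ndarray:
        try:
            j = self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in dataset") from None
        return self.genotypes[:, j]


@dataclass
class RiskNode:
    """A risk group: samples sharing a genotype path, with empirical LR.

    ``path`` maps SNP id to the set of genotype categories defining the
    group (a singleton for plain split children, larger after merges).
    ``indices`` are the training-sample row numbers the node covers.
    """

    path: dict[str, frozenset[int]]
    n_case: int
    n_control: int
    lr: float
    indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    children: list["RiskNode"] = field(default_factory=list)

    def path_label(self) -> str:
        if not self.path:
            return "root"
        parts = []
        for snp, cats in self.path.items():
            cat_txt = ",".join("NA" if c == MISSING else str(c) for c in sorted(cats))
            parts.append(f"{snp}={cat_txt}")
        return " & ".join(parts)


@dataclass(frozen=True)
class FitResult:
    """A fitted F-ROC model."""

    selected_snps: tuple[str, ...]
    tree: RiskNode
    leaves: GroupMassTable
    train_auc_per_step: tuple[float, ...]
    cv_auc_per_step: tuple[float, ...]
    k_folds: int
    seed: int
    train_auc: float
    n_cases: int
    n_controls: int
    missing_mode: MissingMode
    # routing: observed genotype tuple over selected_snps -> leaf LR
    routing: Mapping[tuple[int, ...], float]
    impute_values: Mapping[str, int]
    leaf_nodes: tuple[RiskNode, ...]


def handle_missing(data: GenotypeDataset, mode: MissingMode) -> GenotypeDataset:
    """Resolve missing genotype calls.

    ``own_category`` keeps missing codes, to be treated as an extra genotype
    category downstream; ``impute_mode`` replaces each missing call by the
    SNP's most frequent non-missing code (ties broken toward the lower code).
    A SNP with no observed calls at all is an error either way.
    """
    geno = data.genotypes
    for j, snp in enumerate(data.snp_ids):
        if np.all(geno[:, j] == MISSING):
            raise ValueError(f"SNP {snp!r} is entirely missing")
    if mode == "own_category":
        return data
    if mode != "impute_mode":
        raise ValueError(f"unknown missing-data mode {mode!r}")
    imputed = geno.copy()
    for j in range(geno.shape[1]):
        col = geno[:, j]
        mask = col == MISSING
        if not mask.any():
            continue
        codes, counts = np.unique(col[~mask], return_counts=True)
        fill = int(codes[np.argmax(counts)])  # np.unique sorts: ties -> lower code
        imputed[mask, j] = fill
    return GenotypeDataset(data.sample_ids, data.phenotype, data.snp_ids, imputed)


def column_modes(data: GenotypeDataset) -> dict[str, int]:
    """Most frequent non-missing code per SNP (ties toward the lower code)."""
    modes: dict[str, int] = {}
    for j, snp in enumerate(data.snp_ids):
        col = data.genotypes[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            raise ValueError(f"SNP {snp!r} is entirely missing")
        codes, counts = np.unique(obs, return_counts=True)
        modes[snp] = int(codes[np.argmax(counts)])
    return modes


def empirical_lr(
    n_case: int,
    n_control: int,
    n_cases_total: int,
    n_controls_total: int,
    smoothing: float = 0.0,
    n_groups: int = 1,
) -> float:
    """Empirical likelihood ratio of a group, optionally pseudo-count smoothed.

    ``((n_case + c) / (N_D + c*G)) / ((n_control + c) / (N_D̄ + c*G))`` with
    ``c`` the pseudo-count and ``G`` the number of groups at evaluation time;
    with ``c = 0`` a case-only group has LR +inf.
    """
    if n_cases_total <= 0 or n_controls_total <= 0:
        raise ValueError("totals must be positive")
    if n_case > n_cases_total or n_control > n_controls_total:
        raise ValueError("group counts exceed totals")
    if n_case == 0 and n_control == 0 and smoothing == 0.0:
        raise ValueError("group empty on both margins")
    c = float(smoothing)
    num = (n_case + c) / (n_cases_total + c * n_groups)
    den = (n_control + c) / (n_controls_total + c * n_groups)
    if den == 0.0:
        return math.inf
    return num / den


def _make_node(
    path: dict[str, frozenset[int]],
    indices: np.ndarray,
    data: GenotypeDataset,
    smoothing: float,
    n_groups: int,
) -> RiskNode:
    pheno = data.phenotype[indices]
    n_case = int(pheno.sum())
    n_control = int(indices.size - n_case)
    lr = empirical_lr(
        n_case, n_control, data.n_cases, data.n_controls, smoothing, n_groups
    )
    return RiskNode(path=path, n_case=n_case, n_control=n_control, lr=lr, indices=indices)


def split_group(
    node: RiskNode,
    snp: str,
    data: GenotypeDataset,
    smoothing: float = 0.0,
    n_groups: int = 1,
    attach: bool = False,
) -> list[RiskNode]:
    """Split a group by one SNP, one child per genotype category observed in it.

    Missing codes (under ``own_category`` handling) form their own category.
    Children's counts sum to the parent's; empty categories are omitted.
    With ``attach=True`` the children are recorded on ``node.children``.
    """
    if snp in node.path:
        raise ValueError(f"SNP {snp!r} already on the group's path")
    col = data.column(snp)[node.indices]
    children: list[RiskNode] = []
    for cat in np.unique(col):
        sub = node.indices[col == cat]
        child_path = dict(node.path)
        child_path[snp] = frozenset([int(cat)])
        children.append(_make_node(child_path, sub, data, smoothing, n_groups))
    if attach:
        node.children = children
    return children


def _merge_pair_pvalue(a: RiskNode, b: RiskNode) -> float:
    """p-value of the 2x2 case/control homogeneity test between two groups."""
    table = np.array([[a.n_case, a.n_control], [b.n_case, b.n_control]], dtype=float)
    if table.sum() == 0:  # pragma: no cover
        return 1.0
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        # a zero margin means the two groups are indistinguishable on that axis
        return 1.0
    expected = row @ col / table.sum()
    if expected.min() < 5.0:
        return float(fisher_exact(table)[1])
    return float(chi2_contingency(table, correction=True)[1])


def merge_groups(
    leaves: Sequence[RiskNode],
    alpha_merge: float,
    data: GenotypeDataset | None = None,
    smoothing: float = 0.0,
) -> list[RiskNode]:
    """Agglomerate LR-adjacent groups that a 2x2 association test cannot separate.

    Groups are sorted by LR; while the largest adjacent-pair p-value (chi-square
    with continuity correction, Fisher exact when any expected count < 5) is at
    least ``alpha_merge``, that pair is merged.  ``alpha_merge = 0`` disables
    merging entirely.
    """
    result = list(leaves)
    if alpha_merge <= 0.0 or len(result) < 2:
        return sorted(result, key=lambda n: n.lr, reverse=True)
    n_cases_total = sum(n.n_case for n in result)
    n_controls_total = sum(n.n_control for n in result)
    while len(result) > 1:
        result.sort(key=lambda n: n.lr, reverse=True)
        pvals = [
            _merge_pair_pvalue(result[i], result[i + 1]) for i in range(len(result) - 1)
        ]
        best = int(np.argmax(pvals))
        if pvals[best] < alpha_merge:
            break
        a, b = result[best], result[best + 1]
        path: dict[str, frozenset[int]] = {}
        for snp in {*a.path, *b.path}:
            path[snp] = a.path.get(snp, frozenset()) | b.path.get(snp, frozenset())
        merged = RiskNode(
            path=path,
            n_case=a.n_case + b.n_case,
            n_control=a.n_control + b.n_control,
            lr=empirical_lr(
                a.n_case + b.n_case,
                a.n_control + b.n_control,
                n_cases_total,
                n_controls_total,
                smoothing,
                len(result) - 1,
            ),
            indices=np.concatenate([a.indices, b.indices]),
        )
        result[best : best + 2] = [merged]
    result.sort(key=lambda n: n.lr, reverse=True)
    return result


def _leaf_mass_table(leaves: Sequence[RiskNode], n_cases: int, n_controls: int) -> GroupMassTable:
    return GroupMassTable(
        RiskGroup(
            label=leaf.path_label(),
            mass_case=leaf.n_case / n_cases,
            mass_control=leaf.n_control / n_controls,
        )
        for leaf in leaves
    )


def partition_auc(leaves: Sequence[RiskNode], n_cases: int, n_controls: int) -> float:
    """AUC of the partition: LR-ordered optimal ROC of the empirical group masses.

    Identical to the Mann-Whitney AUC with every sample scored by its leaf's LR.
    """
    if not leaves:
        raise ValueError("no leaves")
    return auc_from_groups(_leaf_mass_table(leaves, n_cases, n_controls))


def forward_step(
    current_leaves: Sequence[RiskNode],
    candidate_snps: Sequence[str],
    data: GenotypeDataset,
    alpha_merge: float = 0.05,
    smoothing: float = 0.0,
) -> tuple[str, list[RiskNode], float]:
    """Evaluate every candidate SNP and keep the partition with the best AUC.

    Each candidate splits every current leaf, the result is merged, and the
    candidate with maximal training AUC wins; ties break toward the earlier
    dataset column.
    """
    if not candidate_snps:
        raise ValueError("no candidate SNPs")
    order = {snp: j for j, snp in enumerate(data.snp_ids)}
    best: tuple[float, int, str, list[RiskNode]] | None = None
    for snp in candidate_snps:
        trial: list[RiskNode] = []
        for leaf in current_leaves:
            trial.extend(split_group(leaf, snp, data, smoothing))
        n_groups = len(trial)
        if smoothing > 0.0:
            trial = [
                _make_node(n.path, n.indices, data, smoothing, n_groups) for n in trial
            ]
        merged = merge_groups(trial, alpha_merge, data, smoothing)
        auc = partition_auc(merged, data.n_cases, data.n_controls)
        key = (auc, -order[snp])
        if best is None or key > (best[0], best[1]):
            best = (auc, -order[snp], snp, merged)
    assert best is not None
    return best[2], best[3], best[0]


def _commit_step(
    leaves: list[RiskNode],
    snp: str,
    data: GenotypeDataset,
    alpha_merge: float,
    smoothing: float,
) -> list[RiskNode]:
    """Split every partition group by ``snp``, merge, and wire up child links.

    A merged group combining children of different parents is shared between
    those parents' ``children`` lists (the display structure is then a DAG
    rather than a strict tree).
    """
    children_of: dict[int, list[RiskNode]] = {}
    all_children: list[RiskNode] = []
    for leaf in leaves:
        ch = split_group(leaf, snp, data, smoothing)
        children_of[id(leaf)] = ch
        all_children.extend(ch)
    if smoothing > 0.0:
        n_groups = len(all_children)
        resmoothed = [
            _make_node(n.path, n.indices, data, smoothing, n_groups)
            for n in all_children
        ]
        for leaf in leaves:
            k = len(children_of[id(leaf)])
            children_of[id(leaf)], resmoothed = resmoothed[:k], resmoothed[k:]
        all_children = [c for leaf in leaves for c in children_of[id(leaf)]]
    merged = merge_groups(all_children, alpha_merge, smoothing=smoothing)
    owner: dict[int, RiskNode] = {}
    for node in merged:
        for i in node.indices:
            owner[int(i)] = node
    for leaf in leaves:
        linked: list[RiskNode] = []
        seen: set[int] = set()
        for child in children_of[id(leaf)]:
            node = owner[int(child.indices[0])]
            if id(node) not in seen:
                seen.add(id(node))
                linked.append(node)
        leaf.children = linked
    return merged


def _greedy_path(
    data: GenotypeDataset,
    max_predictors: int,
    alpha_merge: float,
    smoothing: float,
) -> tuple[list[str], list[list[RiskNode]], list[float], RiskNode]:
    """Grow the forward-selection sequence on ``data``; returns per-step snapshots."""
    all_idx = np.arange(data.n_samples, dtype=np.int64)
    root = _make_node({}, all_idx, data, smoothing, 1)
    leaves: list[RiskNode] = [root]
    selected: list[str] = []
    snapshots: list[list[RiskNode]] = []
    train_aucs: list[float] = []
    current_auc = 0.5
    while len(selected) < max_predictors:
        candidates = [s for s in data.snp_ids if s not in selected]
        if not candidates:
            break
        snp, _, auc = forward_step(leaves, candidates, data, alpha_merge, smoothing)
        if auc <= current_auc + AUC_IMPROVEMENT_EPS:
            break
        leaves = _commit_step(leaves, snp, data, alpha_merge, smoothing)
        selected.append(snp)
        snapshots.append(list(leaves))
        train_aucs.append(auc)
        current_auc = auc
    return selected, snapshots, train_aucs, root


def _routing_table(
    leaves: Sequence[RiskNode], selected: Sequence[str], data: GenotypeDataset
) -> dict[tuple[int, ...], float]:
    """Map each observed genotype tuple over the selected SNPs to its leaf LR."""
    cols = np.column_stack([data.column(s) for s in selected]) if selected else None
    routing: dict[tuple[int, ...], float] = {}
    for leaf in leaves:
        if cols is None:
            routing[()] = leaf.lr
            continue
        for row in cols[leaf.indices]:
            routing[tuple(int(v) for v in row)] = leaf.lr
    return routing


def _stratified_folds(
    phenotype: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Seeded stratified fold assignment; returns held-out index arrays."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (0, 1):
        idx = np.flatnonzero(phenotype == cls)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.sort(np.array(f, dtype=np.int64)) for f in folds]


def _subset(data: GenotypeDataset, idx: np.ndarray) -> GenotypeDataset:
    return GenotypeDataset(
        tuple(data.sample_ids[i] for i in idx),
        data.phenotype[idx],
        data.snp_ids,
        data.genotypes[idx],
    )


def _cv_scores_per_step(
    data: GenotypeDataset,
    max_steps: int,
    k_folds: int,
    seed: int,
    alpha_merge: float,
    smoothing: float,
) -> list[float]:
    """Pooled held-out AUC after each forward step, via stratified k-fold CV.

    Each fold refits the whole forward-selection procedure on the remaining
    folds; held-out samples are scored by their matched leaf's training LR
    (unmatched genotype paths score 1).  A fold whose own selection stops
    early keeps contributing its last available model to later steps.
    """
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(data.phenotype, k_folds, rng)
    scores = np.ones((max_steps, data.n_samples))
    for held in folds:
        train_idx = np.setdiff1d(np.arange(data.n_samples), held)
        train = _subset(data, train_idx)
        if train.n_cases == 0 or train.n_controls == 0:  # pragma: no cover
            raise ValueError("a CV training fold lost one of the classes")
        selected, snapshots, _, _ = _greedy_path(
            train, max_steps, alpha_merge, smoothing
        )
        for step in range(max_steps):
            s = min(step, len(snapshots) - 1)
            if s < 0:
                continue  # fold selected nothing: held-out scores stay at 1
            routing = _routing_table(snapshots[s], selected[: s + 1], train)
            cols = np.column_stack(
                [data.column(snp)[held] for snp in selected[: s + 1]]
            )
            for r, i in enumerate(held):
                scores[step, i] = routing.get(tuple(int(v) for v in cols[r]), 1.0)
    case_mask = data.phenotype == 1
    out = []
    for step in range(max_steps):
        step_scores = scores[step]
        if np.all(step_scores == step_scores[0]):
            out.append(0.5)
        else:
            out.append(empirical_auc(step_scores[case_mask], step_scores[~case_mask]))
    return out


def fit_froc(
    data: GenotypeDataset,
    max_predictors: int,
    k_folds: int = 10,
    seed: int = 0,
    alpha_merge: float = 0.05,
    stop_rule: StopRule = "fixed",
    missing: MissingMode = "own_category",
    smoothing: float = 0.0,
) -> FitResult:
    """Fit an F-ROC risk-partition model by forward selection.

    Selection stops at ``max_predictors`` or when no candidate improves the
    training AUC; with ``stop_rule='cv'`` the returned model is the one at
    the CV-AUC-maximizing step.
    """
    data.require_classes()
    if max_predictors < 1:
        raise ValueError("max_predictors must be >= 1")
    if k_folds < 2 or k_folds > min(data.n_cases, data.n_controls):
        raise ValueError(
            f"k_folds must be between 2 and min(class counts) = "
            f"{min(data.n_cases, data.n_controls)}, got {k_folds}"
        )
    impute_values = column_modes(data) if missing == "impute_mode" else {}
    data = handle_missing(data, missing)

    selected, snapshots, train_aucs, root = _greedy_path(
        data, max_predictors, alpha_merge, smoothing
    )
    if not selected:
        # no SNP improves on the root group: degenerate single-leaf model
        cv_aucs: list[float] = []
        n_steps = 0
        selected_used: list[str] = []
        leaves = [root]
    else:
        cv_aucs = _cv_scores_per_step(
            data, len(selected), k_folds, seed, alpha_merge, smoothing
        )
        if stop_rule == "cv":
            n_steps = int(np.argmax(cv_aucs)) + 1
        else:
            n_steps = len(selected)
        selected_used = selected[:n_steps]
        if n_steps < len(selected):
            # rebuild a clean tree at the chosen size
            selected_used, snapshots, train_aucs, root = _greedy_path(
                data, n_steps, alpha_merge, smoothing
            )
            cv_aucs = cv_aucs[: len(selected_used)]
            n_steps = len(selected_used)
        leaves = snapshots[n_steps - 1]
    routing = _routing_table(leaves, selected_used, data)
    return FitResult(
        selected_snps=tuple(selected_used),
        tree=root,
        leaves=_leaf_mass_table(leaves, data.n_cases, data.n_controls),
        train_auc_per_step=tuple(train_aucs[:n_steps]),
        cv_auc_per_step=tuple(cv_aucs[:n_steps]),
        k_folds=k_folds,
        seed=seed,
        train_auc=train_aucs[n_steps - 1] if n_steps else 0.5,
        n_cases=data.n_cases,
        n_controls=data.n_controls,
        missing_mode=missing,
        routing=routing,
        impute_values=impute_values,
        leaf_nodes=tuple(leaves),
    )


def cross_validated_auc(
    data: GenotypeDataset,
    max_predictors: int,
    k: int = 10,
    seed: int = 0,
    alpha_merge: float = 0.05,
    missing: MissingMode = "own_category",
    smoothing: float = 0.0,
) -> float:
    """Pooled held-out AUC of the full fitting procedure at ``max_predictors`` steps."""
    data.require_classes()
    if k < 2 or k > min(data.n_cases, data.n_controls):
        raise ValueError("k out of range for stratified CV")
    data = handle_missing(data, missing)
    return _cv_scores_per_step(data, max_predictors, k, seed, alpha_merge, smoothing)[-1]


def apply_model(
    fit: FitResult, newdata: GenotypeDataset
) -> tuple[np.ndarray, float | None]:
    """Score an independent dataset with a fitted model.

    Each sample is routed to the risk group matching its genotypes at the
    selected SNPs; genotype combinations unseen in training score LR = 1.
    Returns the per-sample scores and, when both classes are present, the
    Mann-Whitney AUC.
    """
    for snp in fit.selected_snps:
        if snp not in newdata.snp_ids:
            raise KeyError(f"validation data lacks selected SNP {snp!r}")
    geno = newdata.genotypes.copy()
    if fit.missing_mode == "impute_mode":
        for j, snp in enumerate(newdata.snp_ids):
            if snp in fit.impute_values:
                col = geno[:, j]
                col[col == MISSING] = fit.impute_values[snp]
    if fit.selected_snps:
        cols = np.column_stack(
            [geno[:, newdata.snp_ids.index(s)] for s in fit.selected_snps]
        )
        scores = np.array(
            [
                fit.routing.get(tuple(int(v) for v in row), 1.0)
                for row in cols
            ]
        )
    else:
        scores = np.ones(newdata.n_samples)
    auc: float | None = None
    if newdata.n_cases > 0 and newdata.n_controls > 0:
        mask = newdata.phenotype == 1
        auc = empirical_auc(scores[mask], scores[~mask])
    return scores, auc
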