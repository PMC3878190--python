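"""Readers, writers and reporting for the command-line surface.

Supported formats: structured-text design/simulation specs (YAML, of which
JSON is a subset), delimited genotype tables (TSV/CSV with a mandatory
header and a case-insensitive ``phenotype`` column), the PLINK ``.raw``
dialect, TSV ROC-point tables, PNG/SVG plots, Graphviz DOT trees and JSON
run reports.  Readers reject malformed input with file coordinates; the
only silent coercions are the documented near-1 probability renormalization
and the PLINK phenotype remap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .build import MISSING, GenotypeDataset, RiskNode
from .core import ROCPoints
from .design import DesignConfig, SnpDesignInfo
from .simulate import EpistasisTerm, SimConfig

logger = logging.getLogger("riskroc")

#: probability triples off unity by no more than this are renormalized
RENORM_TOL = 1e-6

_MISSING_TOKENS = {"NA", "na", "NaN", "nan", "-9", ""}

__all__ = [
    "RENORM_TOL",
    "RunReport",
    "read_design_spec",
    "read_sim_config",
    "read_genotypes",
    "tree_to_dot",
    "write_outputs",
]


@dataclass
class RunReport:
    """Serializable record of one CLI run."""

    command: str
    parameters: dict
    results: dict
    warnings: list[str] = field(default_factory=list)
    package_version: str = __version__

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))


def _renormalized(name: str, triple: Sequence[float], warnings: list[str]) -> tuple[float, ...]:
    vals = [float(x) for x in triple]
    if len(vals) != 3:
        raise ValueError(f"{name}: expected 3 probabilities, got {len(vals)}")
    total = sum(vals)
    if abs(total - 1.0) > RENORM_TOL:
        raise ValueError(f"{name}: probabilities sum to {total!r}, off unity by more than {RENORM_TOL}")
    if total != 1.0:
        msg = f"{name}: probabilities summed to {total!r}; renormalized"
        warnings.append(msg)
        logger.warning(msg)
        vals = [v / total for v in vals]
    return tuple(vals)


def _load_structured(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return doc


def read_design_spec(path) -> tuple[list[SnpDesignInfo], DesignConfig, list[str]]:
    """Parse a design specification file (YAML/JSON)."""
    doc = _load_structured(path)
    warnings: list[str] = []
    try:
        config = DesignConfig(
            prevalence=float(doc["prevalence"]),
            alpha=float(doc.get("alpha", 0.05)),
            power=float(doc.get("power", 0.95)),
            auc0=float(doc.get("auc0", 0.5)),
            case_control_ratio=float(doc.get("ratio", 1.0)),
            two_sided=bool(doc.get("two_sided", False)),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing required key {exc.args[0]!r}") from None
    entries = doc.get("snps")
    if not entries:
        raise ValueError(f"{path}: 'snps' list is missing or empty")
    snps: list[SnpDesignInfo] = []
    for i, entry in enumerate(entries):
        where = f"{path}: snps[{i}]"
        if "id" not in entry or "mode" not in entry:
            raise ValueError(f"{where}: each SNP needs 'id' and 'mode'")
        snp_id, mode = str(entry["id"]), str(entry["mode"])
        if mode == "conditional":
            for key in ("freq_case", "freq_control"):
                if key not in entry:
                    raise ValueError(f"{where} ({snp_id}): missing {key!r}")
            snps.append(
                SnpDesignInfo(
                    snp_id=snp_id,
                    mode="conditional",
                    freq_case=_renormalized(f"{where} freq_case", entry["freq_case"], warnings),
                    freq_control=_renormalized(f"{where} freq_control", entry["freq_control"], warnings),
                )
            )
        elif mode == "population_rr":
            if "rr" not in entry:
                raise ValueError(f"{where} ({snp_id}): missing 'rr'")
            rr = [float(x) for x in entry["rr"]]
            if any(x <= 0 for x in rr):
                raise ValueError(f"{where} ({snp_id}): rr entries must be > 0")
            if "freq_pop" in entry:
                freq_pop = _renormalized(f"{where} freq_pop", entry["freq_pop"], warnings)
            elif "allele_freq" in entry:
                from .design import hwe_genotype_freqs

                freq_pop = hwe_genotype_freqs(float(entry["allele_freq"]))
            else:
                raise ValueError(f"{where} ({snp_id}): needs 'freq_pop' or 'allele_freq'")
            snps.append(
                SnpDesignInfo(snp_id=snp_id, mode="population_rr", freq_pop=freq_pop, rr=tuple(rr))
            )
        else:
            raise ValueError(f"{where} ({snp_id}): unknown mode {mode!r}")
    return snps, config, warnings


def read_sim_config(path, seed: int | None = None) -> SimConfig:
    """Parse a simulation configuration file (YAML/JSON)."""
    doc = _load_structured(path)
    for key in ("n_case", "n_control", "mafs", "rr", "prevalence"):
        if key not in doc:
            raise ValueError(f"{path}: missing required key {key!r}")
    epistasis = tuple(
        EpistasisTerm(
            snp_i=int(t["snp_i"]), snp_j=int(t["snp_j"]), multipliers=tuple(map(tuple, t["multipliers"]))
        )
        for t in doc.get("epistasis", [])
    )
    return SimConfig(
        n_case=int(doc["n_case"]),
        n_control=int(doc["n_control"]),
        mafs=tuple(float(m) for m in doc["mafs"]),
        rr=tuple(tuple(float(x) for x in t) for t in doc["rr"]),
        prevalence=float(doc["prevalence"]),
        epistasis=epistasis,
        missing_rate=float(doc.get("missing_rate", 0.0)),
        seed=int(doc["seed"]) if seed is None and "seed" in doc else (seed or 0),
    )


def _detect_dialect(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    fields = header.split()
    if len(fields) >= 6 and fields[0] == "FID" and fields[1] == "IID":
        return "plink_raw"
    return "delimited"


def _parse_genotype(token: str, row: int, col_name: str, path) -> int:
    t = token.strip()
    if t in _MISSING_TOKENS:
        return MISSING
    try:
        value = float(t)
    except ValueError:
        raise ValueError(
            f"{path}: invalid genotype code {token!r} at data row {row}, column {col_name!r}"
        ) from None
    if value != int(value) or int(value) not in (0, 1, 2):
        raise ValueError(
            f"{path}: invalid genotype code {token!r} at data row {row}, column {col_name!r}"
        )
    return int(value)


def _read_delimited(path) -> GenotypeDataset:
    with open(path) as fh:
        header_line = fh.readline()
    sep = "\t" if "\t" in header_line else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    if "phenotype" not in cols:
        raise ValueError(f"{path}: no 'phenotype' column in header")
    pheno_col = cols["phenotype"]
    id_col = cols.get("id")
    snp_cols = [c for c in df.columns if c not in (pheno_col, id_col)]
    if not snp_cols:
        raise ValueError(f"{path}: no genotype columns")
    phenotype = []
    for row, token in enumerate(df[pheno_col]):
        t = str(token).strip()
        if t not in ("0", "1"):
            raise ValueError(f"{path}: phenotype {token!r} at data row {row} not 0/1")
        phenotype.append(int(t))
    geno = np.empty((len(df), len(snp_cols)), dtype=np.int8)
    for j, col in enumerate(snp_cols):
        for row, token in enumerate(df[col]):
            geno[row, j] = _parse_genotype(str(token), row, col, path)
    sample_ids = (
        tuple(str(x) for x in df[id_col]) if id_col else tuple(f"s{i + 1}" for i in range(len(df)))
    )
    data = GenotypeDataset(sample_ids, np.array(phenotype, dtype=np.int8), tuple(snp_cols), geno)
    data.require_classes()
    return data


def _read_plink_raw(path) -> GenotypeDataset:
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    required = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[:6]) != required:
        raise ValueError(f"{path}: not a PLINK .raw header (expected columns {required})")
    snp_cols = list(df.columns[6:])
    if not snp_cols:
        raise ValueError(f"{path}: no genotype columns")
    keep_rows, phenotype = [], []
    for row, token in enumerate(df["PHENOTYPE"]):
        t = str(token).strip()
        if t in ("-9", "NA", "0", ""):
            logger.warning("%s: dropping sample at data row %d with missing phenotype %r", path, row, token)
            continue
        if t not in ("1", "2"):
            raise ValueError(f"{path}: PHENOTYPE {token!r} at data row {row} not 1/2")
        keep_rows.append(row)
        phenotype.append(int(t) - 1)
    geno = np.empty((len(keep_rows), len(snp_cols)), dtype=np.int8)
    for j, col in enumerate(snp_cols):
        series = df[col]
        for i, row in enumerate(keep_rows):
            geno[i, j] = _parse_genotype(str(series.iloc[row]), row, col, path)
    sample_ids = tuple(str(df["IID"].iloc[r]) for r in keep_rows)
    data = GenotypeDataset(sample_ids, np.array(phenotype, dtype=np.int8), tuple(snp_cols), geno)
    data.require_classes()
    return data


def read_genotypes(path, dialect: str | None = None) -> GenotypeDataset:
    """Read a case-control genotype table (delimited text or PLINK ``.raw``)."""
    if dialect is None:
        dialect = _detect_dialect(path)
    if dialect == "delimited":
        return _read_delimited(path)
    if dialect == "plink_raw":
        return _read_plink_raw(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotypes(data: GenotypeDataset, path) -> None:
    """Write a genotype table as TSV (missing calls as ``NA``)."""
    with open(path, "w") as fh:
        fh.write("id\tphenotype\t" + "\t".join(data.snp_ids) + "\n")
        for i, sid in enumerate(data.sample_ids):
            row = [
                "NA" if g == MISSING else str(int(g)) for g in data.genotypes[i]
            ]
            fh.write(f"{sid}\t{int(data.phenotype[i])}\t" + "\t".join(row) + "\n")


def _fmt_lr(lr: float) -> str:
    return "inf" if lr == float("inf") else f"{lr:.4g}"


def tree_to_dot(root: RiskNode) -> str:
    """Render the risk-group structure as Graphviz DOT.

    Node labels read ``path | cases/controls | LR``.  Merged groups shared
    by several parents appear once with multiple in-edges.
    """
    lines = ["digraph risk_groups {", "  node [shape=box];"]
    ids: dict[int, str] = {}
    order: list[RiskNode] = []

    def visit(node: RiskNode) -> None:
        if id(node) in ids:
            return
        ids[id(node)] = f"n{len(ids)}"
        order.append(node)
        for child in node.children:
            visit(child)

    visit(root)
    for node in order:
        label = f"{node.path_label()} | {node.n_case}/{node.n_control} | LR={_fmt_lr(node.lr)}"
        lines.append(f'  {ids[id(node)]} [label="{label}"];')
    emitted: set[tuple[str, str]] = set()
    for node in order:
        for child in node.children:
            edge = (ids[id(node)], ids[id(child)])
            if edge not in emitted:
                emitted.add(edge)
                lines.append(f"  {edge[0]} -> {edge[1]};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_outputs(
    report: RunReport,
    roc_sets: Mapping[str, ROCPoints],
    tree: RiskNode | None,
    outdir,
    plot_format: str = "png",
) -> list[Path]:
    """Write the run report, ROC tables, an overlay ROC plot and the DOT tree.

    File contents are deterministic functions of the inputs (no timestamps).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report_path = outdir / "report.json"
    report_path.write_text(report.to_json() + "\n")
    written.append(report_path)
    for name, roc in roc_sets.items():
        tsv = outdir / f"roc_{name}.tsv"
        roc.to_tsv(tsv)
        written.append(tsv)
    if roc_sets:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        for name, roc in roc_sets.items():
            roc.plot(ax=ax, label=name)
        plot_path = outdir / f"roc.{plot_format}"
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
        written.append(plot_path)
    if tree is not None:
        dot_path = outdir / "tree.dot"
        dot_path.write_text(tree_to_dot(tree))
        written.append(dot_path)
    return written
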