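"""Delimited-text readers/writers and run configuration.

File conventions follow the common bioinformatics layout: expression tables
are genes-as-rows by default (header row = sample ids, first column = gene
ids) but held samples x genes in memory; annotations are TSV with columns
``sample_id``, ``group`` and optionally ``outcome``.  Control gene lists
are plain text, one id per line.  Categorical levels are taken in order of
first appearance so outputs are deterministic across platforms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adjust import ExpressionMatrix, FactorDesign
from .scoring import GeneRanking, ScoringFit

__all__ = [
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_annotation",
    "read_gene_list",
    "write_ranking",
    "write_fit",
    "load_run_config",
]

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(
    path: str | Path,
    genes_as_rows: bool = True,
    sep: str | None = None,
    impute: str = "reject",
) -> ExpressionMatrix:
    """Read a delimited expression table into samples x genes orientation.

    ``impute`` is ``"reject"`` (default: any missing value is an error) or
    ``"mean"`` (per-gene mean fill, recorded nowhere but the log — prefer
    cleaning the file upstream).  Non-numeric cells are reported with their
    row id and column id.
    """
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0,
                     float_precision="round_trip")
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r} "
            f"in {path}"
        )
    if body.isna().to_numpy().any():
        if impute == "reject":
            r, c = np.argwhere(body.isna().to_numpy())[0]
            raise ValueError(
                f"missing value at row {df.index[r]!r}, column {df.columns[c]!r}; "
                "pass impute='mean' to mean-fill"
            )
        if impute != "mean":
            raise ValueError(f"unknown imputation policy {impute!r}")
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"duplicate row or column ids in {path}")
    if genes_as_rows:
        body = body.T
    if impute == "mean" and body.isna().to_numpy().any():
        body = body.fillna(body.mean(axis=0))
    return ExpressionMatrix(
        values=body.to_numpy(dtype=float),
        sample_ids=[str(s) for s in body.index],
        gene_ids=[str(g) for g in body.columns],
    )


def write_expression(
    X: ExpressionMatrix,
    path: str | Path,
    genes_as_rows: bool = True,
    sep: str | None = None,
) -> None:
    df = pd.DataFrame(X.values, index=X.sample_ids, columns=X.gene_ids)
    if genes_as_rows:
        df = df.T
    df.to_csv(path, sep=_sep_for(path, sep), float_format=_FLOAT_FMT)


def read_annotation(
    path: str | Path,
    sample_ids: list[str],
    mode: str | None = None,
    sep: str | None = None,
) -> FactorDesign:
    """Build a FactorDesign from a sample annotation table.

    Rows are realigned to the expression matrix's sample order; a sample-id
    mismatch in either direction is an error naming the offenders.  The
    ``group`` column becomes the indicator G (levels in first-appearance
    order); an ``outcome`` column, if present, becomes Y — an indicator for
    categorical outcomes, a single centered column for numeric ones.
    """
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype={"sample_id": str})
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError("annotation needs 'sample_id' and 'group' columns")
    ann_ids = list(df["sample_id"])
    missing = sorted(set(sample_ids) - set(ann_ids))
    extra = sorted(set(ann_ids) - set(sample_ids))
    if missing or extra:
        raise ValueError(
            f"sample mismatch between annotation and expression: "
            f"missing={missing[:5]} extra={extra[:5]}"
        )
    df = df.set_index("sample_id").loc[sample_ids]
    group = df["group"].astype(str)
    # level order follows first appearance in the expression sample order, so
    # a shuffled annotation file yields an identical design
    levels = list(dict.fromkeys(group))
    G = np.zeros((len(sample_ids), len(levels)))
    for i, g in enumerate(group):
        G[i, levels.index(g)] = 1.0
    Y = None
    if "outcome" in df.columns:
        col = df["outcome"]
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.notna().all():
            y = numeric.to_numpy(dtype=float)
            Y = (y - y.mean())[:, None]
        else:
            ylevels = list(dict.fromkeys(col.astype(str)))
            Y = np.zeros((len(sample_ids), len(ylevels)))
            for i, v in enumerate(col.astype(str)):
                Y[i, ylevels.index(v)] = 1.0
    if mode is None:
        mode = "supervised" if Y is not None else "unsupervised"
    return FactorDesign(G=G, group_labels=levels, Y=Y, mode=mode)


def read_gene_list(path: str | Path) -> set[str]:
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


def write_ranking(
    ranking: GeneRanking, path: str | Path, sep: str = "\t"
) -> None:
    ids = ranking.gene_ids or [str(j) for j in range(len(ranking.order))]
    rows = [
        (r + 1, ids[j], ranking.scores[j])
        for r, j in enumerate(ranking.order)
    ]
    df = pd.DataFrame(rows, columns=["rank", "gene_id", "score"])
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


def write_fit(fit: ScoringFit, outdir: str | Path, gene_ids: list[str],
              seed: int | None = None) -> None:
    """Serialise a scoring fit: B, Theta, objective trace, run metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(fit.B, index=gene_ids).to_csv(
        outdir / "B.tsv", sep="\t", float_format=_FLOAT_FMT
    )
    pd.DataFrame(fit.Theta).to_csv(
        outdir / "theta.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame({"iteration": range(len(fit.objective_trace)),
                  "objective": fit.objective_trace}).to_csv(
        outdir / "objective_trace.tsv", sep="\t", index=False,
        float_format=_FLOAT_FMT,
    )
    meta = {
        "lambda": fit.lam,
        "l": fit.l,
        "penalty": fit.penalty.kind,
        "epsilon": fit.penalty.epsilon,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "seed": seed,
    }
    (outdir / "fit_meta.json").write_text(json.dumps(meta, indent=2) + "\n")


_RUNCONFIG_KEYS = {
    "mode", "K", "m", "lam", "lambda_min", "lambda_max", "lambda_count",
    "penalty", "l", "tol", "max_outer", "seed", "genes_as_rows",
    "expression", "annotation", "out",
}


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    mode: str = "unsupervised"
    K: int = 0
    m: int | None = None
    lam: float | None = None
    lambda_min: float = 1e-4
    lambda_max: float = 3.0
    lambda_count: int = 20
    penalty: str = "l21"
    l: int | None = None
    tol: float = 1e-6
    max_outer: int = 100
    seed: int = 0
    genes_as_rows: bool = True
    expression: str | None = None
    annotation: str | None = None
    out: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("unsupervised", "supervised"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.penalty not in ("l21", "log-sum"):
            raise ValueError(f"unknown penalty {self.penalty!r}")

    def to_json(self) -> str:
        d = asdict(self)
        d.pop("extras")
        return json.dumps(d, indent=2) + "\n"


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration, rejecting unknown keys."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - _RUNCONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
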