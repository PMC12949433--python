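"""Tabular readers/writers and the pipeline orchestrator.

Input tables are CSV or TSV with a header row.  If the first column is named
like a sample identifier (or is non-numeric) it is used as the sample index
and rows are aligned across files by id; otherwise rows align positionally
(with a logged warning).  Missing or non-numeric payload entries are
reported, not silently dropped.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import ExpressionMatrix
from .pipeline import NetworkGuidedResult, fit_network_guided
from .hubs import hub_table

logger = logging.getLogger("hublasso")

ID_COLUMN_NAMES = {"sample", "sample_id", "id", "sampleid", ""}


@dataclass
class RunConfig:
    """Configuration of one `fit` pipeline run."""

    expression_path: str
    confounders_path: str | None
    outcome_path: str
    outcome_col: str | None = None
    delta: float = 0.02
    tau: int | None = None
    gamma: float = 0.5
    centrality: str = "degree"
    folds: int = 5
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self):
        if not 0 < self.delta < 1:
            raise ValueError(f"delta must lie in (0, 1), got {self.delta}")

    def metadata(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def write_tabular(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a table so that a later :func:`read_tabular` is bit-exact.

    ``%.17g`` preserves every float64 exactly through the decimal round trip.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, float_format="%.17g", index=index)


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    first = df.columns[0]
    if str(first).strip().lower() in ID_COLUMN_NAMES or df[first].dtype == object:
        df = df.set_index(first)
        df.index = df.index.astype(str)
    else:
        df.index = [str(i) for i in range(len(df))]
        logger.warning(
            "%s: no sample-id column detected; aligning rows positionally", path
        )
    return df


def _require_numeric(df: pd.DataFrame, path: str) -> pd.DataFrame:
    bad_cols = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad_cols:
        raise ValueError(f"{path}: non-numeric columns {bad_cols}")
    if df.isna().any().any():
        na_rows = df.index[df.isna().any(axis=1)].tolist()[:10]
        na_cols = df.columns[df.isna().any(axis=0)].tolist()[:10]
        raise ValueError(
            f"{path}: missing values (rows {na_rows}, columns {na_cols})"
        )
    return df


def read_tabular(path: str | Path, role: str):
    """Read one input table as the typed object its role demands.

    Roles: ``expression`` → :class:`ExpressionMatrix`; ``confounders`` →
    DataFrame; ``outcome`` → Series (single numeric column).
    """
    if role not in ("expression", "confounders", "outcome"):
        raise ValueError(f"unknown role {role!r}")
    df = _require_numeric(_read_frame(path), str(path))
    if role == "expression":
        return ExpressionMatrix.from_dataframe(df)
    if role == "confounders":
        return df
    if df.shape[1] != 1:
        raise ValueError(f"{path}: outcome table must have exactly one column")
    return df.iloc[:, 0]


def align_samples(expr: ExpressionMatrix, *frames: pd.DataFrame):
    """Check that all inputs cover the same samples, reordering by id."""
    ids = list(expr.sample_ids)
    out = []
    for fr in frames:
        if fr is None:
            out.append(None)
            continue
        missing = [i for i in ids if i not in fr.index]
        extra = [i for i in fr.index if i not in ids]
        if missing or extra:
            raise ValueError(
                f"sample ids disagree (missing {missing[:5]}, extra {extra[:5]})"
            )
        out.append(fr.loc[ids])
    return out


def write_network(res: NetworkGuidedResult, out_dir: Path) -> list[Path]:
    edges = res.network.edge_list()
    edge_path = out_dir / "network_edges.tsv"
    edges.to_csv(edge_path, sep="\t", index=False)
    rho_path = out_dir / "partial_correlations.csv"
    pd.DataFrame(
        res.network.rho,
        index=res.network.feature_names,
        columns=res.network.feature_names,
    ).to_csv(rho_path)
    return [edge_path, rho_path]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute read → network → hubs → fit → write; returns artifact paths.

    Each stage is logged with its timing.  On a stage failure, already-written
    artifacts are kept, a ``FAILED`` marker naming the stage is dropped in the
    output directory, and the error is re-raised.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "read-inputs"
    try:
        t0 = time.perf_counter()
        expr = read_tabular(cfg.expression_path, "expression")
        z_df = (
            read_tabular(cfg.confounders_path, "confounders")
            if cfg.confounders_path
            else None
        )
        y_ser = read_tabular(cfg.outcome_path, "outcome")
        if cfg.outcome_col and y_ser.name != cfg.outcome_col:
            raise ValueError(
                f"outcome column {cfg.outcome_col!r} not found (saw {y_ser.name!r})"
            )
        z_df, y_ser = align_samples(expr, z_df, y_ser)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "network-and-hubs-and-fit"
        t0 = time.perf_counter()
        res = fit_network_guided(
            expr,
            z_df.to_numpy() if z_df is not None else None,
            y_ser.to_numpy(),
            delta=cfg.delta,
            tau=cfg.tau,
            centrality_measure=cfg.centrality,
            gamma=cfg.gamma,
            k_folds=cfg.folds,
            seed=cfg.seed,
            confounder_names=list(z_df.columns) if z_df is not None else None,
        )
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "write-artifacts"
        t0 = time.perf_counter()
        for pth in write_network(res, out_dir):
            artifacts[pth.name] = str(pth)
        hubs_path = out_dir / "hub_table.tsv"
        hub_table(res.centrality, res.hubs).to_csv(hubs_path, sep="\t", index=False)
        artifacts[hubs_path.name] = str(hubs_path)
        coef_path = out_dir / "coefficients.csv"
        res.coefficient_table().to_csv(coef_path, index=False)
        artifacts[coef_path.name] = str(coef_path)
        meta_path = out_dir / "run_metadata.json"
        nu, lam = res.cv.chosen
        meta = {
            "config": cfg.metadata(),
            "chosen_nu": nu,
            "chosen_lambda": lam,
            "h": res.hubs.h,
            "hub_features": [
                res.feature_names[i] for i in res.hubs.hub_indices
            ],
            "ebic_lambda": res.precision.lambda_used,
            "ebic_gamma": res.precision.gamma,
            "n_edges": res.precision.n_edges,
            "seeds": {"top_level": cfg.seed},
        }
        meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
        artifacts[meta_path.name] = str(meta_path)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
    except Exception as exc:
        marker = out_dir / "FAILED"
        marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise
    return artifacts
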