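"""Readers and writers for the plain-text table formats the pipeline uses."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml

from .trending import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = ["load_study", "read_group_config", "write_study", "write_truth"]


def _read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=index_col)


def read_group_config(path: str | Path) -> tuple[str, str, str]:
    """Read a YAML config with keys resistant, intermediate, vulnerable."""
    cfg = yaml.safe_load(Path(path).read_text())
    try:
        return (str(cfg["resistant"]), str(cfg["intermediate"]),
                str(cfg["vulnerable"]))
    except (TypeError, KeyError) as exc:
        raise ValueError(f"{path}: config needs keys resistant, "
                         "intermediate, vulnerable") from exc


def load_study(matrix_path: str | Path, samples_path: str | Path,
               group_order: tuple[str, str, str], *,
               missing: Literal["error", "drop"] = "error",
               ) -> ExpressionStudy:
    """Load an expression study from a matrix table and a sample sheet.

    Matrix: TSV/CSV, first column transcript_id, remaining columns sample
    ids, log2 values. Sample sheet: CSV with columns sample_id, group.
    Rows with missing values are rejected by default; ``missing="drop"``
    removes them with a logged count.
    """
    matrix = _read_table(matrix_path, index_col=0)
    samples = pd.read_csv(samples_path)
    for col in ("sample_id", "group"):
        if col not in samples.columns:
            raise ValueError(f"{samples_path}: missing column {col!r}")
    groups = samples.set_index("sample_id")["group"]
    if matrix.isna().to_numpy().any():
        if missing == "drop":
            before = len(matrix)
            matrix = matrix.dropna(axis=0)
            logger.warning("dropped %d transcript row(s) with missing values",
                           before - len(matrix))
        else:
            bad = matrix.index[matrix.isna().any(axis=1)]
            raise ValueError(f"missing values in transcripts "
                             f"{list(bad[:5])}; pass missing='drop' to "
                             "remove them")
    return ExpressionStudy(matrix=matrix, groups=groups,
                           group_order=group_order)


def write_study(study: ExpressionStudy, outdir: str | Path,
                prefix: str = "study") -> dict[str, Path]:
    """Write a study back out in the dialect :func:`load_study` consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix_path = outdir / f"{prefix}_matrix.tsv"
    samples_path = outdir / f"{prefix}_samples.csv"
    config_path = outdir / f"{prefix}_groups.yaml"
    study.matrix.to_csv(matrix_path, sep="\t", index_label="transcript_id")
    (study.groups.rename_axis("sample_id").rename("group").reset_index()
     .to_csv(samples_path, index=False))
    config_path.write_text(yaml.safe_dump({
        "resistant": study.group_order[0],
        "intermediate": study.group_order[1],
        "vulnerable": study.group_order[2],
    }))
    return {"matrix": matrix_path, "samples": samples_path,
            "config": config_path}


def write_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    """Write a planted-truth table as TSV (transcript_id, truth_label)."""
    path = Path(path)
    truth.to_csv(path, sep="\t", index=False)
    return path
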