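"""Relative quantification: ddCt for qPCR and ratio normalization for blots.

ddCt: for sample s, dCt_s = Ct(target, s) - Ct(reference, s); ddCt_s =
dCt_s - mean(dCt over control samples); relative quantity RQ_s =
efficiency^-ddCt (efficiency 2 = perfect doubling per cycle). The control
group's geometric-mean RQ is 1 by construction. The reference gene in the
study this emulates is beta-actin.

Densitometry: per-lane ratio = target band intensity / loading-control
intensity, compared between groups by Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._stats import sem, two_sample_test

__all__ = ["CtTable", "ddct", "normalize_density", "read_ct_csv",
           "read_density_csv"]


@dataclass(frozen=True)
class CtTable:
    """Long-format qPCR Ct values: sample_id, condition, gene_id, ct."""

    data: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "gene_id", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")
        if self.data.duplicated(["sample_id", "gene_id"]).any():
            dupes = self.data.loc[
                self.data.duplicated(["sample_id", "gene_id"]),
                ["sample_id", "gene_id"]]
            raise ValueError("duplicate (sample, gene) Ct entries: "
                             f"{dupes.values.tolist()[:5]}")
        if not np.isfinite(self.data["ct"].to_numpy(float)).all():
            raise ValueError("non-finite Ct values present")
        samples = set(self.data["sample_id"])
        with_ref = set(self.data.loc[
            self.data["gene_id"] == self.reference_gene, "sample_id"])
        if samples - with_ref:
            raise ValueError("samples missing reference gene "
                             f"{self.reference_gene!r}: "
                             f"{sorted(samples - with_ref)}")

    def genes(self) -> list[str]:
        return sorted(set(self.data["gene_id"]) - {self.reference_gene})


def ddct(table: CtTable, target_gene: str, control_condition: str, *,
         efficiency: float = 2.0) -> tuple[pd.DataFrame, dict]:
    """Per-sample relative quantities for one target gene, plus group summary.

    The ddCt baseline is the arithmetic mean dCt over control samples.
    Returns ``(per_sample, summary)`` where per_sample has columns sample_id,
    condition, delta_ct, delta_delta_ct, rq, and summary holds per-condition
    mean/SEM of RQ plus a Welch t-test of each non-control condition against
    control (when both have >=2 samples).
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    df = table.data
    conditions = set(df["condition"])
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} absent "
                         f"(present: {sorted(conditions)})")
    target = df[df["gene_id"] == target_gene]
    if target.empty:
        raise ValueError(f"target gene {target_gene!r} absent from table")
    ref = (df[df["gene_id"] == table.reference_gene]
           .set_index("sample_id")["ct"])
    missing = set(target["sample_id"]) - set(ref.index)
    if missing:
        raise ValueError(f"samples missing reference Ct: {sorted(missing)}")

    out = target[["sample_id", "condition"]].copy().reset_index(drop=True)
    dct = (target["ct"].to_numpy(float)
           - ref.loc[target["sample_id"]].to_numpy(float))
    out["delta_ct"] = dct
    baseline = out.loc[out["condition"] == control_condition,
                       "delta_ct"].mean()
    out["delta_delta_ct"] = out["delta_ct"] - baseline
    out["rq"] = np.power(efficiency, -out["delta_delta_ct"])

    summary: dict = {"target_gene": target_gene,
                     "reference_gene": table.reference_gene,
                     "control_condition": control_condition,
                     "conditions": {}, "tests": {}}
    for cond, sub in out.groupby("condition"):
        rq = sub["rq"].to_numpy(float)
        entry = {"mean_rq": float(rq.mean()), "n": int(len(rq))}
        if len(rq) >= 2:
            entry["sem_rq"] = sem(rq)
        summary["conditions"][cond] = entry
    ctrl_rq = out.loc[out["condition"] == control_condition, "rq"]
    for cond in sorted(conditions - {control_condition}):
        rq = out.loc[out["condition"] == cond, "rq"]
        if len(rq) >= 2 and len(ctrl_rq) >= 2:
            t, p = two_sample_test(rq, ctrl_rq)
            summary["tests"][cond] = {"t": t, "p_value": p}
    return out, summary


def normalize_density(table: pd.DataFrame, group_a: str | None = None,
                      group_b: str | None = None) -> tuple[pd.DataFrame, dict]:
    """Loading-control normalization of band intensities, with a group test.

    ``table`` needs columns lane_id, group, target_intensity,
    loading_intensity (all intensities > 0). Returns per-lane ratios and a
    summary with group means ± SEM and a Welch t-test between the two named
    (or the only two) groups, including the relative change of group_b vs
    group_a.
    """
    required = {"lane_id", "group", "target_intensity", "loading_intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"densitometry table missing columns "
                         f"{sorted(missing)}")
    loading = table["loading_intensity"].to_numpy(float)
    target = table["target_intensity"].to_numpy(float)
    if (loading <= 0).any():
        bad = table.loc[loading <= 0, "lane_id"].tolist()
        raise ValueError(f"non-positive loading intensity in lanes {bad}")
    if (target <= 0).any():
        bad = table.loc[target <= 0, "lane_id"].tolist()
        raise ValueError(f"non-positive target intensity in lanes {bad}")

    out = table[["lane_id", "group"]].copy().reset_index(drop=True)
    out["ratio"] = target / loading

    groups = list(out["group"].unique())
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise ValueError(f"specify group_a/group_b: table has {groups}")
        group_a, group_b = groups
    a = out.loc[out["group"] == group_a, "ratio"].to_numpy(float)
    b = out.loc[out["group"] == group_b, "ratio"].to_numpy(float)
    summary = {"groups": {}}
    for g, vals in ((group_a, a), (group_b, b)):
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has {len(vals)} lane(s); need >=2")
        summary["groups"][g] = {"mean": float(vals.mean()), "sem": sem(vals),
                                "n": int(len(vals))}
    t, p = two_sample_test(a, b)
    summary["t"] = t
    summary["p_value"] = p
    summary["relative_change"] = float(b.mean() / a.mean())
    return out, summary


def read_ct_csv(path: str | Path, reference_gene: str) -> CtTable:
    return CtTable(pd.read_csv(path), reference_gene=reference_gene)


def read_density_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
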