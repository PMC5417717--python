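"""Mitochondrial stress-test OCR parameter derivation per well.

A run measures oxygen consumption rate (OCR, pmol O2/min) in repeated cycles
through four phases: basal, then injections of oligomycin (blocks ATP
synthase), FCCP (uncoupler, drives maximal respiration) and antimycin A +
rotenone (blocks the electron transport chain, leaving the
non-mitochondrial floor). With

    B6     = 6th basal measurement (acquisition order, 1-based)
    Omin   = lowest oligomycin-phase measurement
    Fmax   = highest FCCP-phase measurement
    AAlast = last antimycin/rotenone measurement

the five derived respiration parameters are

    basal       = B6 - AAlast
    atp_linked  = B6 - Omin          (oligomycin-sensitive respiration)
    proton_leak = Omin - AAlast
    maximal     = Fmax - AAlast
    spare       = Fmax - B6

A well whose atp_linked comes out negative is excluded from group summaries;
no other derived value triggers exclusion (negative leak or spare is only
warned about).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._stats import sem, two_sample_test

logger = logging.getLogger(__name__)

__all__ = [
    "PHASE_ORDER",
    "DEFAULT_SCHEDULE",
    "WellTrace",
    "FluxPlate",
    "RespirationParameters",
    "PARAMETER_NAMES",
    "derive_parameters",
    "derive_plate",
    "apply_exclusions",
    "compare_groups",
    "read_flux_csv",
    "read_schedule",
]

PHASE_ORDER = ("basal", "oligomycin", "fccp", "antimycin_rotenone")
DEFAULT_SCHEDULE: dict[str, int] = {
    "basal": 6, "oligomycin": 3, "fccp": 3, "antimycin_rotenone": 10,
}
PARAMETER_NAMES = ("basal", "atp_linked", "proton_leak", "maximal", "spare")


@dataclass(frozen=True)
class WellTrace:
    """One well's ordered OCR measurements, annotated by injection phase."""

    well_id: str
    phases: tuple[str, ...]
    ocr: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.phases) != len(self.ocr):
            raise ValueError(f"well {self.well_id}: phases and ocr lengths "
                             "differ")
        seen: list[str] = []
        for ph in self.phases:
            if ph not in PHASE_ORDER:
                raise ValueError(f"well {self.well_id}: unknown phase {ph!r}")
            if not seen or seen[-1] != ph:
                seen.append(ph)
        if seen != [p for p in PHASE_ORDER if p in seen]:
            raise ValueError(f"well {self.well_id}: phases out of order "
                             f"{seen}; expected subsequence of {PHASE_ORDER}")
        for ph in PHASE_ORDER[1:]:
            if ph not in seen:
                raise ValueError(f"well {self.well_id}: missing phase {ph!r}")

    def phase_values(self, phase: str) -> np.ndarray:
        return np.array([v for p, v in zip(self.phases, self.ocr)
                         if p == phase], dtype=float)


@dataclass(frozen=True)
class RespirationParameters:
    well_id: str
    basal: float
    atp_linked: float
    proton_leak: float
    maximal: float
    spare: float
    excluded: bool
    exclusion_reason: str | None = None

    def as_dict(self) -> dict:
        return {
            "well_id": self.well_id, "basal": self.basal,
            "atp_linked": self.atp_linked, "proton_leak": self.proton_leak,
            "maximal": self.maximal, "spare": self.spare,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason or "",
        }


@dataclass
class FluxPlate:
    """A set of well traces plus a well -> group assignment."""

    wells: list[WellTrace]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate well ids on plate")
        missing = [i for i in ids if i not in self.groups]
        if missing:
            raise ValueError(f"wells without group assignment: {missing[:5]}")

    @classmethod
    def concat(cls, plates: Iterable["FluxPlate"]) -> "FluxPlate":
        wells: list[WellTrace] = []
        groups: dict[str, str] = {}
        for p in plates:
            wells.extend(p.wells)
            groups.update(p.groups)
        return cls(wells=wells, groups=groups)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.wells:
            for i, (ph, v) in enumerate(zip(w.phases, w.ocr), 1):
                rows.append({"well_id": w.well_id,
                             "group": self.groups[w.well_id],
                             "measurement_index": i, "phase": ph, "ocr": v})
        return pd.DataFrame(rows)


def derive_parameters(trace: WellTrace, *,
                      lenient_basal: bool = False) -> RespirationParameters:
    """Derive the five respiration parameters for one well.

    Strict mode requires >=6 basal measurements (B6 is the 6th in acquisition
    order); ``lenient_basal`` falls back to the last basal measurement when
    fewer cycles were recorded, with a logged warning.
    """
    basal_vals = trace.phase_values("basal")
    if len(basal_vals) >= 6:
        b6 = float(basal_vals[5])
    elif lenient_basal and len(basal_vals) >= 1:
        b6 = float(basal_vals[-1])
        logger.warning("well %s: only %d basal cycles; using last basal "
                       "measurement", trace.well_id, len(basal_vals))
    else:
        raise ValueError(f"well {trace.well_id}: {len(basal_vals)} basal "
                         "measurements (<6); rerun with lenient_basal=True "
                         "to use the last one")
    for ph in ("oligomycin", "fccp", "antimycin_rotenone"):
        if len(trace.phase_values(ph)) == 0:
            raise ValueError(f"well {trace.well_id}: empty {ph} phase")
    o_min = float(trace.phase_values("oligomycin").min())
    f_max = float(trace.phase_values("fccp").max())
    aa_last = float(trace.phase_values("antimycin_rotenone")[-1])

    basal = b6 - aa_last
    atp_linked = b6 - o_min
    proton_leak = o_min - aa_last
    maximal = f_max - aa_last
    spare = f_max - b6

    excluded = atp_linked < 0
    reason = "negative ATP-linked respiration" if excluded else None
    if not excluded and (proton_leak < 0 or spare < 0):
        logger.warning("well %s: negative %s retained (only negative "
                       "ATP-linked excludes)", trace.well_id,
                       "proton leak" if proton_leak < 0 else "spare capacity")
    return RespirationParameters(trace.well_id, basal, atp_linked,
                                 proton_leak, maximal, spare, excluded, reason)


def derive_plate(plate: FluxPlate, *,
                 lenient_basal: bool = False) -> pd.DataFrame:
    """Per-well parameter table for a plate (column ``group`` included)."""
    rows = []
    for w in plate.wells:
        params = derive_parameters(w, lenient_basal=lenient_basal)
        d = params.as_dict()
        d["group"] = plate.groups[w.well_id]
        rows.append(d)
    return pd.DataFrame(rows)


def apply_exclusions(params: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a per-well parameter table into retained wells and exclusion log.

    The log records well_id, group and reason; exclusion counts per group
    are logged. Groups whose every well is excluded trigger a warning.
    """
    excluded = params[params["excluded"]]
    retained = params[~params["excluded"]].reset_index(drop=True)
    log = excluded[["well_id", "group", "exclusion_reason"]].reset_index(
        drop=True)
    for group, n in log.groupby("group").size().items():
        logger.info("group %s: %d well(s) excluded "
                    "(negative ATP-linked respiration)", group, n)
    for group in params["group"].unique():
        if (retained["group"] == group).sum() == 0:
            logger.warning("group %s: all wells excluded; no summary "
                           "possible", group)
    return retained, log


def compare_groups(params: pd.DataFrame, parameter: str,
                   group_a: str | None = None, group_b: str | None = None,
                   ) -> dict:
    """Welch two-sided t-test on per-well values of one derived parameter.

    Excluded wells are dropped first. Returns group means, SEMs, n, the t
    statistic and the two-sided p-value.
    """
    if parameter not in PARAMETER_NAMES:
        raise ValueError(f"unknown parameter {parameter!r}; "
                         f"choose from {PARAMETER_NAMES}")
    retained, _ = apply_exclusions(params)
    groups = list(retained["group"].unique())
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise ValueError("specify group_a/group_b: plate has groups "
                             f"{groups}")
        group_a, group_b = groups
    out = {"parameter": parameter, "groups": {}}
    samples = {}
    for g in (group_a, group_b):
        vals = retained.loc[retained["group"] == g, parameter].to_numpy(float)
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has {len(vals)} retained well(s); "
                             "need >=2")
        samples[g] = vals
        out["groups"][g] = {"mean": float(vals.mean()), "sem": sem(vals),
                            "n": int(len(vals))}
    t, p = two_sample_test(samples[group_a], samples[group_b])
    out["t"] = t
    out["p_value"] = p
    return out


# ---------------------------------------------------------------------------
# I/O

def read_flux_csv(path: str | Path) -> FluxPlate:
    """Load a long-format trace CSV: well_id, group, measurement_index,
    phase, ocr."""
    df = pd.read_csv(path)
    required = {"well_id", "group", "measurement_index", "phase", "ocr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    wells: list[WellTrace] = []
    groups: dict[str, str] = {}
    for well_id, sub in df.groupby("well_id", sort=False):
        sub = sub.sort_values("measurement_index")
        wells.append(WellTrace(well_id=str(well_id),
                               phases=tuple(sub["phase"]),
                               ocr=tuple(float(v) for v in sub["ocr"])))
        group_vals = sub["group"].unique()
        if len(group_vals) != 1:
            raise ValueError(f"well {well_id}: inconsistent group labels")
        groups[str(well_id)] = str(group_vals[0])
    return FluxPlate(wells=wells, groups=groups)


def read_schedule(path: str | Path) -> dict[str, int]:
    """Read an injection-schedule YAML mapping phase -> expected cycle count."""
    sched = yaml.safe_load(Path(path).read_text())
    if not isinstance(sched, Mapping):
        raise ValueError(f"{path}: schedule must map phase -> cycle count")
    unknown = set(sched) - set(PHASE_ORDER)
    if unknown:
        raise ValueError(f"{path}: unknown phases {sorted(unknown)}")
    out = {}
    for ph in PHASE_ORDER:
        n = int(sched.get(ph, 0))
        if n <= 0:
            raise ValueError(f"{path}: phase {ph!r} needs a positive count")
        out[ph] = n
    return out


def check_schedule(plate: FluxPlate, schedule: Mapping[str, int]) -> None:
    """Warn when a well's per-phase cycle counts deviate from the schedule."""
    for w in plate.wells:
        for ph, expected in schedule.items():
            got = len(w.phase_values(ph))
            if got != expected:
                logger.warning("well %s: %d %s cycles, schedule expects %d",
                               w.well_id, got, ph, expected)
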