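"""Categorical neuromuscular phenotype scoring and group comparison.

Two category schemes are supported:

* ``axon`` — zebrafish motor-axon outgrowth classes per embryo
  (normal, branched, severe), 12 axons scored per embryo by default;
* ``endplate`` — mouse neuromuscular-junction occupancy per muscle
  (fully_occupied, partially_occupied, vacant), with at least 80 endplates
  expected per muscle.

The unit of analysis is the embryo or muscle, never the individual axon or
endplate (avoids pseudo-replication); group comparisons are Welch t-tests on
per-unit category percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import sem, two_sample_test

logger = logging.getLogger(__name__)

__all__ = [
    "AXON_CATEGORIES",
    "ENDPLATE_CATEGORIES",
    "PhenotypeTable",
    "GroupComparison",
    "to_percentages",
    "compare_phenotypes",
    "classify_endplate",
    "dose_response_summary",
    "read_phenotype_csv",
]

AXON_CATEGORIES = ("normal", "branched", "severe")
ENDPLATE_CATEGORIES = ("fully_occupied", "partially_occupied", "vacant")
_SCHEMES = {"axon": AXON_CATEGORIES, "endplate": ENDPLATE_CATEGORIES}
ENDPLATE_MIN_COUNT = 80


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-unit category counts.

    ``data`` columns: unit_id, group, optionally dose, one column per
    category. For the axon scheme every unit must sum to ``denominator``
    (12 axons by default); for the endplate scheme the denominator is the
    per-unit total and strict mode warns below 80 endplates.
    """

    data: pd.DataFrame
    scheme: str = "axon"
    denominator: int | None = 12

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; "
                             f"choose from {sorted(_SCHEMES)}")
        cats = self.categories
        missing = set(cats) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing category columns {sorted(missing)}")
        for col in ("unit_id", "group"):
            if col not in self.data.columns:
                raise ValueError(f"missing column {col!r}")
        counts = self.data[list(cats)].to_numpy()
        if (counts < 0).any():
            raise ValueError("negative category counts")
        totals = counts.sum(axis=1)
        if self.scheme == "axon":
            if self.denominator is None or self.denominator <= 0:
                raise ValueError("axon scheme needs a positive denominator")
            bad = self.data.loc[totals != self.denominator, "unit_id"]
            if len(bad):
                raise ValueError(
                    f"units whose counts do not sum to {self.denominator}: "
                    f"{list(bad[:5])}")
        else:
            low = self.data.loc[totals < ENDPLATE_MIN_COUNT, "unit_id"]
            for unit in low:
                logger.warning("unit %s: fewer than %d endplates assessed",
                               unit, ENDPLATE_MIN_COUNT)
            if (totals == 0).any():
                raise ValueError("units with zero scored endplates")

    @property
    def categories(self) -> tuple[str, ...]:
        return _SCHEMES[self.scheme]


@dataclass(frozen=True)
class GroupComparison:
    category: str
    group_a: str
    group_b: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t: float
    p_value: float


def to_percentages(table: PhenotypeTable) -> pd.DataFrame:
    """Per-unit category percentages (each row sums to 100)."""
    cats = list(table.categories)
    counts = table.data[cats].to_numpy(float)
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("unit with denominator 0")
    out = table.data.drop(columns=cats).copy().reset_index(drop=True)
    pct = 100.0 * counts / totals
    for j, c in enumerate(cats):
        out[c] = pct[:, j]
    return out


def compare_phenotypes(table_a: PhenotypeTable, table_b: PhenotypeTable,
                       category: str) -> GroupComparison:
    """Welch two-sided t-test on per-unit percentages of one category.

    Each table must hold one group's units; the group labels are taken from
    the tables (resolved only here, so coded/blinded labels work upstream).
    """
    if table_a.scheme != table_b.scheme:
        raise ValueError("cannot compare tables with different schemes")
    if category not in table_a.categories:
        raise ValueError(f"unknown category {category!r} for scheme "
                         f"{table_a.scheme!r}")
    pct_a = to_percentages(table_a)
    pct_b = to_percentages(table_b)
    ga = _single_group(pct_a, "first table")
    gb = _single_group(pct_b, "second table")
    a = pct_a[category].to_numpy(float)
    b = pct_b[category].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 units per group")
    t, p = two_sample_test(a, b)
    return GroupComparison(category=category, group_a=ga, group_b=gb,
                           mean_a=float(a.mean()), sem_a=sem(a), n_a=len(a),
                           mean_b=float(b.mean()), sem_b=sem(b), n_b=len(b),
                           t=t, p_value=p)


def _single_group(pct: pd.DataFrame, what: str) -> str:
    groups = pct["group"].unique()
    if len(groups) != 1:
        raise ValueError(f"{what} must contain exactly one group, "
                         f"found {list(groups)}")
    return str(groups[0])


def classify_endplate(coverage_fraction: float, *,
                      full_threshold: float = 0.5) -> str:
    """Map presynaptic coverage of an endplate to an occupancy category.

    vacant iff coverage is exactly 0; partially_occupied below
    ``full_threshold`` (default 0.5); fully_occupied at or above it. The
    threshold is configurable because published class definitions leave
    intermediate coverages open.
    """
    f = float(coverage_fraction)
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"coverage fraction must be in [0, 1], got {f}")
    if f == 0.0:
        return "vacant"
    if f < full_threshold:
        return "partially_occupied"
    return "fully_occupied"


def dose_response_summary(tables: Sequence[tuple[float, PhenotypeTable]],
                          category: str) -> tuple[pd.DataFrame, bool]:
    """Mean category percentage per dose, plus a monotonicity flag.

    ``tables`` is a sequence of (dose, table) pairs in strictly increasing
    dose order; the flag is True iff the per-dose means are non-decreasing
    (ties allowed).
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 dose levels")
    doses = [d for d, _ in tables]
    if any(b <= a for a, b in zip(doses, doses[1:])):
        raise ValueError(f"doses must be strictly increasing, got {doses}")
    rows = []
    for dose, table in tables:
        if category not in table.categories:
            raise ValueError(f"unknown category {category!r}")
        pct = to_percentages(table)[category].to_numpy(float)
        rows.append({"dose": dose, "mean_percent": float(pct.mean()),
                     "n_units": int(len(pct))})
    summary = pd.DataFrame(rows)
    means = summary["mean_percent"].to_numpy()
    monotone = bool(np.all(np.diff(means) >= 0))
    return summary, monotone


def read_phenotype_csv(path: str | Path, scheme: str = "axon",
                       denominator: int | None = 12) -> PhenotypeTable:
    """Load a per-unit count CSV: unit_id, group, [dose], category columns."""
    df = pd.read_csv(path)
    if scheme == "endplate":
        denominator = None
    return PhenotypeTable(df, scheme=scheme, denominator=denominator)
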