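"""Two-cut-off vulnerability trending analysis across three ordered groups.

The design has three motor-neuron pools ordered by disease vulnerability
(resistant -> intermediate -> vulnerable; in the mouse study EDL -> GS -> TA).
A transcript is *called* when it passes two filters:

1. significance: a two-sided t-test between the two extreme groups
   (resistant vs vulnerable) on log2 expression, at raw p < alpha (0.05);
2. trend: the intermediate-group mean lies strictly between the extreme
   means, in the direction of the extreme-group difference.

Transcripts passing both are labelled ``protective`` (higher in the resistant
pool) or ``harmful`` (higher in the vulnerable pool); everything else is
``none``. BH q-values are reported for reference but do not gate calls — the
published filter is on raw p.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "TrendingResult",
    "extreme_group_test",
    "trend_filter",
    "run_trending",
    "rank_by_enrichment_ratio",
]

CALL_PROTECTIVE = "protective"
CALL_HARMFUL = "harmful"
CALL_NONE = "none"


@dataclass(frozen=True)
class ExpressionStudy:
    """A processed log2 expression matrix with a three-level vulnerability design.

    Parameters
    ----------
    matrix
        transcripts x samples, log2 scale; index = transcript ids,
        columns = sample ids.
    groups
        mapping sample id -> group label (as a Series indexed by sample id).
    group_order
        exactly three labels ordered resistant, intermediate, vulnerable.
    """

    matrix: pd.DataFrame
    groups: pd.Series
    group_order: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(self.group_order) != 3:
            raise ValueError("group_order must name exactly 3 groups "
                             "(resistant, intermediate, vulnerable)")
        if not self.matrix.index.is_unique:
            dupes = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise ValueError(f"transcript ids not unique: {list(dupes[:5])}")
        if self.matrix.isna().to_numpy().any():
            raise ValueError("expression matrix contains missing values; "
                             "drop or impute at load time")
        missing = set(self.matrix.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group assignment: {sorted(missing)}")
        labels = self.groups.loc[list(self.matrix.columns)]
        unknown = set(labels) - set(self.group_order)
        if unknown:
            raise ValueError(f"sample groups not in group_order: {sorted(unknown)}")
        for g in self.group_order:
            n = int((labels == g).sum())
            if n < 2:
                raise ValueError(f"group {g!r} has {n} sample(s); need >=2 "
                                 "for a t-test")

    # convenience accessors -------------------------------------------------
    @property
    def resistant(self) -> str:
        return self.group_order[0]

    @property
    def intermediate(self) -> str:
        return self.group_order[1]

    @property
    def vulnerable(self) -> str:
        return self.group_order[2]

    def samples_of(self, group: str) -> list[str]:
        labels = self.groups.loc[list(self.matrix.columns)]
        return [s for s, g in labels.items() if g == group]

    def group_values(self, group: str) -> pd.DataFrame:
        return self.matrix[self.samples_of(group)]


@dataclass
class TrendingResult:
    """Output of :func:`run_trending`.

    ``table`` has one row per transcript with columns mean_res, mean_int,
    mean_vul, log2fc_res_vs_vul, p_value, q_value, passes_significance,
    trend_ok, call.
    """

    table: pd.DataFrame
    alpha: float
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def protective(self) -> list[str]:
        return list(self.table.index[self.table["call"] == CALL_PROTECTIVE])

    @property
    def harmful(self) -> list[str]:
        return list(self.table.index[self.table["call"] == CALL_HARMFUL])

    @property
    def called(self) -> list[str]:
        return list(self.table.index[self.table["call"] != CALL_NONE])

    def summary(self) -> dict:
        return {"alpha": self.alpha, **self.counts}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "trending_results.tsv", sep="\t",
                          index_label="transcript_id")
        (outdir / "trending_summary.json").write_text(
            json.dumps(self.summary(), indent=2) + "\n")


def _welch_arrays(res: np.ndarray, vul: np.ndarray,
                  equal_var: bool) -> np.ndarray:
    """Row-wise two-sided t-test p-values with zero-variance conventions."""
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        # constant rows produce NaN plus a precision warning; both are
        # resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(res, vul, axis=1, equal_var=equal_var).pvalue
    p = np.asarray(p, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        diff = res.mean(axis=1) - vul.mean(axis=1)
        p[degenerate & (diff == 0.0)] = 1.0
        p[degenerate & (diff != 0.0)] = 0.0
    return p


def extreme_group_test(study: ExpressionStudy, transcript: str, *,
                       test: Literal["welch", "student"] = "welch",
                       ) -> tuple[float, float]:
    """log2 fold-change and two-sided p between the extreme groups.

    log2fc is mean(resistant) - mean(vulnerable) on the log2 scale. Two
    constant, equal samples give p = 1 by convention.
    """
    res = study.group_values(study.resistant).loc[transcript].to_numpy(float)
    vul = study.group_values(study.vulnerable).loc[transcript].to_numpy(float)
    if res.size < 2 or vul.size < 2:
        raise ValueError("need >=2 samples in each extreme group")
    log2fc = float(res.mean() - vul.mean())
    p = float(_welch_arrays(res[None, :], vul[None, :],
                            equal_var=(test == "student"))[0])
    return log2fc, p


def trend_filter(means: Sequence[float],
                 direction: Literal["protective", "harmful"],
                 *, gap: float = 0.0) -> bool:
    """Strict monotone-trend test on (mean_res, mean_int, mean_vul).

    ``protective`` passes iff mean_res > mean_int > mean_vul, ``harmful`` iff
    the reverse; ties fail (equality is not a trend). ``gap`` > 0 requires
    the intermediate mean to clear each extreme by at least that margin.
    """
    m_res, m_int, m_vul = (float(x) for x in means)
    if not all(np.isfinite([m_res, m_int, m_vul])):
        raise ValueError("group means must be finite")
    if direction == CALL_PROTECTIVE:
        return (m_res - m_int > gap) and (m_int - m_vul > gap)
    if direction == CALL_HARMFUL:
        return (m_int - m_res > gap) and (m_vul - m_int > gap)
    raise ValueError(f"unknown direction {direction!r}")


def run_trending(study: ExpressionStudy, alpha: float = 0.05, *,
                 test: Literal["welch", "student"] = "welch",
                 gap: float = 0.0) -> TrendingResult:
    """Apply the two-cut-off filter to every transcript.

    Cut-off 1 is the extreme-group test at raw p < alpha; cut-off 2 requires
    the intermediate mean to lie strictly between the extremes in the
    direction of the fold-change. Any transcript failing either gets
    call = ``none``.
    """
    if not (0.0 <= alpha < 1.0):
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    res = study.group_values(study.resistant).to_numpy(float)
    inter = study.group_values(study.intermediate).to_numpy(float)
    vul = study.group_values(study.vulnerable).to_numpy(float)

    mean_res = res.mean(axis=1)
    mean_int = inter.mean(axis=1)
    mean_vul = vul.mean(axis=1)
    log2fc = mean_res - mean_vul
    p = _welch_arrays(res, vul, equal_var=(test == "student"))
    q = bh_fdr(p)

    passes_sig = p < alpha
    up = (mean_res - mean_int > gap) & (mean_int - mean_vul > gap)
    down = (mean_int - mean_res > gap) & (mean_vul - mean_int > gap)
    trend_ok = np.where(log2fc > 0, up, np.where(log2fc < 0, down, False))

    call = np.full(len(p), CALL_NONE, dtype=object)
    call[passes_sig & trend_ok & (log2fc > 0)] = CALL_PROTECTIVE
    call[passes_sig & trend_ok & (log2fc < 0)] = CALL_HARMFUL

    table = pd.DataFrame(
        {
            "mean_res": mean_res,
            "mean_int": mean_int,
            "mean_vul": mean_vul,
            "log2fc_res_vs_vul": log2fc,
            "fold_change": np.exp2(log2fc),
            "p_value": p,
            "q_value": q,
            "passes_significance": passes_sig,
            "trend_ok": trend_ok.astype(bool),
            "call": call,
        },
        index=study.matrix.index,
    )
    counts = {
        "n_transcripts": int(len(table)),
        "n_significant": int(passes_sig.sum()),
        "n_protective": int((call == CALL_PROTECTIVE).sum()),
        "n_harmful": int((call == CALL_HARMFUL).sum()),
    }
    return TrendingResult(table=table, alpha=alpha, counts=counts)


def rank_by_enrichment_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """Called transcripts ordered by |log2fc| descending, ties broken by id.

    Deterministic under permutation of the input row order.
    """
    called = table[table["call"] != CALL_NONE].copy()
    if called.empty:
        return called
    called["_abs"] = called["log2fc_res_vs_vul"].abs()
    called = (called.sort_index(kind="mergesort")
              .sort_values("_abs", ascending=False, kind="mergesort"))
    return called.drop(columns="_abs")
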