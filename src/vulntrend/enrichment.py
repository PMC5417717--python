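"""Gene-set over-representation analysis with Benjamini-Hochberg FDR.

One-sided hypergeometric upper-tail test: drawing ``n`` hits from a universe
of ``N`` genes of which ``K`` belong to a set, the p-value is
P(X >= k) where ``k`` is the observed overlap. The universe defaults to the
transcripts actually measured (the testable population), not the union of
the gene-set collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "overrepresentation_test",
    "bh_fdr",
    "run_enrichment",
]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]


@dataclass(frozen=True)
class GeneSetCollection:
    """A named family of gene sets (e.g. GO terms read from a GMT file)."""

    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate set ids: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets that become empty."""
        uni = frozenset(universe)
        kept: list[GeneSet] = []
        for s in self.sets:
            members = s.members & uni
            if members:
                kept.append(GeneSet(s.set_id, s.name, members))
            else:
                logger.warning("dropping gene set %s: no members in universe",
                               s.set_id)
        return GeneSetCollection(tuple(kept))

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        return cls(tuple(GeneSet(k, k, frozenset(v)) for k, v in d.items()))


def read_gmt(path: str | Path, *, uppercase: bool = False) -> GeneSetCollection:
    """Read a GMT file (tab-separated: set_id, description, members...).

    Empty sets are dropped with a warning; ``uppercase`` folds member ids to
    upper case for case-insensitive matching.
    """
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: GMT line needs at least "
                             "set_id and description")
        set_id, name, *members = fields
        members = [m.upper() if uppercase else m for m in members if m.strip()]
        if not members:
            logger.warning("%s:%d: empty gene set %s dropped", path, lineno,
                           set_id)
            continue
        sets.append(GeneSet(set_id, name, frozenset(members)))
    return GeneSetCollection(tuple(sets))


def overrepresentation_test(hits: Iterable[str], gene_set: Iterable[str],
                            universe: Iterable[str]) -> float:
    """Upper-tail hypergeometric p-value for the overlap of hits with a set.

    With N = |universe|, K = |set ∩ universe|, n = |hits| and k = |overlap|,
    returns P(X >= k); k = 0 gives p = 1.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("universe is empty")
    hits = frozenset(hits)
    outside = hits - uni
    if outside:
        raise ValueError("hits not contained in universe: "
                         f"{sorted(outside)[:10]}")
    members = frozenset(gene_set) & uni
    N, K, n = len(uni), len(members), len(hits)
    k = len(hits & members)
    # P(X >= k) = sf(k - 1)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_enrichment(hits: Iterable[str], collection: GeneSetCollection,
                   universe: Iterable[str], *, min_set_size: int = 3,
                   max_set_size: int = 2000) -> pd.DataFrame:
    """ORA over a collection: one row per retained set, sorted by p ascending.

    Sets are restricted to the universe first; sets outside
    [min_set_size, max_set_size] after restriction are excluded and logged.
    An empty hit list yields an empty table (with a warning), not an error.
    """
    uni = frozenset(universe)
    hits = frozenset(hits)
    if not hits:
        logger.warning("empty hit list: enrichment table will be empty")
    restricted = collection.restrict(uni)
    rows = []
    for s in restricted:
        K = len(s.members)
        if not (min_set_size <= K <= max_set_size):
            logger.info("excluding set %s: size %d outside [%d, %d]",
                        s.set_id, K, min_set_size, max_set_size)
            continue
        if not hits:
            continue
        k = len(hits & s.members)
        p = overrepresentation_test(hits, s.members, uni)
        rows.append({"set_id": s.set_id, "name": s.name, "k": k, "K": K,
                     "n": len(hits), "N": len(uni), "p_value": p})
    table = pd.DataFrame(rows, columns=["set_id", "name", "k", "K", "n", "N",
                                        "p_value"])
    if not table.empty:
        table["fdr_q"] = bh_fdr(table["p_value"].to_numpy())
        table = (table.sort_values("set_id", kind="mergesort")
                 .sort_values("p_value", kind="mergesort")
                 .reset_index(drop=True))
    else:
        table["fdr_q"] = pd.Series(dtype=float)
    return table
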