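"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure its downstream stage
assumes, with i.i.d. Gaussian noise on the natural scale (log2 expression,
OCR, Ct) and defaults mirroring the study design this package models:
3 replicate mice per muscle group, the 6/3/3/10 stress-test measurement
schedule with 14 wells per group, and 20 embryos per treatment group with
12 scored axons each. At ``noise_sd = 0`` every generator produces inputs on
which the downstream stage recovers the planted truth exactly, which the
test suite exploits as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .flux import DEFAULT_SCHEDULE, PHASE_ORDER, FluxPlate, WellTrace
from .phenotype import PhenotypeTable
from .quant import CtTable
from .trending import ExpressionStudy

__all__ = [
    "TrendingSimSpec",
    "FluxSimSpec",
    "simulate_expression",
    "simulate_flux",
    "simulate_ct_table",
    "simulate_phenotype_counts",
]

DEFAULT_GROUP_ORDER = ("EDL", "GS", "TA")  # resistant, intermediate, vulnerable


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {msg}")


@dataclass(frozen=True)
class TrendingSimSpec:
    """Design of a synthetic three-group vulnerability study.

    Planted protective transcripts are high in the resistant group and low in
    the vulnerable group; the intermediate mean sits at
    ``intermediate_position`` of the way from vulnerable to resistant
    (0.5 = exact midpoint). Harmful transcripts mirror this; all remaining
    transcripts share a single mean across groups.
    """

    n_transcripts: int
    n_per_group: int = 3
    n_planted_protective: int = 0
    n_planted_harmful: int = 0
    effect_log2fc: float = 2.0
    intermediate_position: float = 0.5
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_transcripts >= 1, "n_transcripts", "must be >= 1")
        _check(self.n_per_group >= 1, "n_per_group", "must be >= 1")
        _check(self.n_planted_protective >= 0, "n_planted_protective",
               "must be >= 0")
        _check(self.n_planted_harmful >= 0, "n_planted_harmful",
               "must be >= 0")
        _check(self.n_planted_protective + self.n_planted_harmful
               <= self.n_transcripts, "n_planted_protective",
               "planted transcripts exceed n_transcripts")
        _check(self.effect_log2fc > 0, "effect_log2fc", "must be > 0")
        _check(0.0 < self.intermediate_position < 1.0,
               "intermediate_position", "must lie in (0, 1)")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")


@dataclass(frozen=True)
class FluxSimSpec:
    """True respiration components of one group of stress-test wells.

    Phase plateaus are built from the components: basal phase =
    nonmito + basal; oligomycin = nonmito + (basal - atp_linked);
    FCCP = nonmito + maximal; antimycin/rotenone = nonmito. OCR units are
    pmol O2/min.
    """

    n_wells_per_group: int = 14
    true_basal: float = 100.0
    true_atp_linked: float = 70.0
    true_maximal: float = 160.0
    true_nonmito: float = 20.0
    noise_sd: float = 2.0
    schedule: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SCHEDULE))
    group: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_wells_per_group >= 1, "n_wells_per_group",
               "must be >= 1")
        _check(self.true_basal > 0, "true_basal", "must be > 0")
        _check(self.true_atp_linked > 0, "true_atp_linked", "must be > 0")
        _check(self.true_maximal > 0, "true_maximal", "must be > 0")
        _check(self.true_nonmito >= 0, "true_nonmito", "must be >= 0")
        _check(self.true_atp_linked <= self.true_basal, "true_atp_linked",
               "must not exceed true_basal")
        _check(self.true_maximal >= self.true_basal, "true_maximal",
               "must be >= true_basal")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        unknown = set(self.schedule) - set(PHASE_ORDER)
        _check(not unknown, "schedule", f"unknown phases {sorted(unknown)}")
        for ph in PHASE_ORDER:
            _check(int(self.schedule.get(ph, 0)) >= 1, "schedule",
                   f"phase {ph!r} needs >= 1 cycle")

    @property
    def true_parameters(self) -> dict[str, float]:
        return {
            "basal": self.true_basal,
            "atp_linked": self.true_atp_linked,
            "proton_leak": self.true_basal - self.true_atp_linked,
            "maximal": self.true_maximal,
            "spare": self.true_maximal - self.true_basal,
        }


def simulate_expression(spec: TrendingSimSpec,
                        group_order: Sequence[str] = DEFAULT_GROUP_ORDER,
                        ) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Simulate a log2 expression matrix with planted trending transcripts.

    Returns the study and a truth table (columns transcript_id, truth_label
    with labels protective / harmful / null). Identical spec -> identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_transcripts
    ids = [f"T{i:05d}" for i in range(n)]
    labels = np.array(
        ["protective"] * spec.n_planted_protective
        + ["harmful"] * spec.n_planted_harmful
        + ["null"] * (n - spec.n_planted_protective - spec.n_planted_harmful),
        dtype=object)

    base = spec.baseline_mean
    eff = spec.effect_log2fc
    pos = spec.intermediate_position
    # group means per transcript, measured from vulnerable toward resistant
    mean_res = np.full(n, base)
    mean_vul = np.full(n, base)
    mean_int = np.full(n, base)
    prot = labels == "protective"
    harm = labels == "harmful"
    mean_res[prot] = base + eff
    mean_int[prot] = base + pos * eff
    mean_vul[harm] = base + eff
    mean_int[harm] = base + (1.0 - pos) * eff

    k = spec.n_per_group
    means = np.column_stack([np.repeat(mean_res[:, None], k, axis=1),
                             np.repeat(mean_int[:, None], k, axis=1),
                             np.repeat(mean_vul[:, None], k, axis=1)])
    noise = rng.normal(0.0, spec.noise_sd, size=means.shape) \
        if spec.noise_sd > 0 else 0.0
    values = means + noise

    res_g, int_g, vul_g = group_order
    samples = ([f"{res_g}_{i+1}" for i in range(k)]
               + [f"{int_g}_{i+1}" for i in range(k)]
               + [f"{vul_g}_{i+1}" for i in range(k)])
    groups = pd.Series([res_g] * k + [int_g] * k + [vul_g] * k,
                       index=samples, name="group")
    matrix = pd.DataFrame(values, index=pd.Index(ids, name="transcript_id"),
                          columns=samples)
    study = ExpressionStudy(matrix=matrix, groups=groups,
                            group_order=tuple(group_order))
    truth = pd.DataFrame({"transcript_id": ids, "truth_label": labels})
    return study, truth


def simulate_flux(spec: FluxSimSpec) -> FluxPlate:
    """Simulate one group of stress-test well traces with known components."""
    rng = np.random.default_rng(spec.seed)
    plateaus = {
        "basal": spec.true_nonmito + spec.true_basal,
        "oligomycin": spec.true_nonmito + spec.true_basal
        - spec.true_atp_linked,
        "fccp": spec.true_nonmito + spec.true_maximal,
        "antimycin_rotenone": spec.true_nonmito,
    }
    wells = []
    groups = {}
    for w in range(spec.n_wells_per_group):
        phases: list[str] = []
        levels: list[float] = []
        for ph in PHASE_ORDER:
            cycles = int(spec.schedule[ph])
            phases.extend([ph] * cycles)
            levels.extend([plateaus[ph]] * cycles)
        ocr = np.asarray(levels, dtype=float)
        if spec.noise_sd > 0:
            ocr = ocr + rng.normal(0.0, spec.noise_sd, size=ocr.shape)
        well_id = f"{spec.group}_w{w+1:02d}"
        wells.append(WellTrace(well_id=well_id, phases=tuple(phases),
                               ocr=tuple(float(v) for v in ocr)))
        groups[well_id] = spec.group
    return FluxPlate(wells=wells, groups=groups)


def simulate_ct_table(fold_changes: Mapping[str, Mapping[str, float]],
                      reference_gene: str = "Actb", *,
                      ct_noise_sd: float = 0.0,
                      n_replicates: int = 3,
                      control_condition: str = "control",
                      base_target_ct: float = 24.0,
                      reference_ct: float = 16.0,
                      seed: int = 0) -> CtTable:
    """Simulate a Ct table implying chosen fold-changes per gene/condition.

    ``fold_changes`` maps gene -> {condition: fold-change vs control}; the
    control condition is implicitly fold 1. A fold-change f lowers the
    target Ct by log2(f) (fewer cycles to threshold = more template), so the
    noise-free ddCt analysis returns exactly f. The reference gene is
    constant across conditions up to noise.
    """
    _check(ct_noise_sd >= 0, "ct_noise_sd", "must be >= 0")
    _check(n_replicates >= 1, "n_replicates", "must be >= 1")
    if not reference_gene:
        raise ValueError("reference gene must be named")
    conditions = {control_condition}
    for gene, per_cond in fold_changes.items():
        for cond, f in per_cond.items():
            _check(f > 0, "fold_changes", f"{gene}/{cond}: must be > 0")
            conditions.add(cond)
    rng = np.random.default_rng(seed)
    rows = []
    for cond in sorted(conditions):
        for r in range(n_replicates):
            sample = f"{cond}_{r+1}"
            rows.append({"sample_id": sample, "condition": cond,
                         "gene_id": reference_gene, "ct": reference_ct})
            for gene, per_cond in fold_changes.items():
                fold = per_cond.get(cond, 1.0) \
                    if cond != control_condition else 1.0
                rows.append({"sample_id": sample, "condition": cond,
                             "gene_id": gene,
                             "ct": base_target_ct - np.log2(fold)})
    df = pd.DataFrame(rows)
    if ct_noise_sd > 0:
        df["ct"] = df["ct"] + rng.normal(0.0, ct_noise_sd, size=len(df))
    return CtTable(df, reference_gene=reference_gene)


def simulate_phenotype_counts(n_embryos: int,
                              category_probs: Sequence[float],
                              *, axons_per_embryo: int = 12,
                              group: str = "control",
                              scheme: str = "axon",
                              seed: int = 0) -> PhenotypeTable:
    """Multinomial per-embryo category counts for one treatment group.

    ``category_probs`` follows the scheme's category order (axon: normal,
    branched, severe) and must sum to 1 within 1e-9.
    """
    _check(n_embryos >= 1, "n_embryos", "must be >= 1")
    _check(axons_per_embryo >= 1, "axons_per_embryo", "must be >= 1")
    probs = np.asarray(category_probs, dtype=float)
    cats = {"axon": ("normal", "branched", "severe"),
            "endplate": ("fully_occupied", "partially_occupied", "vacant")}
    if scheme not in cats:
        raise ValueError(f"unknown scheme {scheme!r}")
    if len(probs) != len(cats[scheme]):
        raise ValueError(f"need {len(cats[scheme])} probabilities for "
                         f"scheme {scheme!r}")
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("category probabilities must be non-negative and "
                         f"sum to 1 (got sum {probs.sum()!r})")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(axons_per_embryo, probs, size=n_embryos)
    df = pd.DataFrame(counts, columns=list(cats[scheme]))
    df.insert(0, "group", group)
    df.insert(0, "unit_id", [f"{group}_e{i+1:02d}" for i in range(n_embryos)])
    return PhenotypeTable(df, scheme=scheme,
                          denominator=axons_per_embryo
                          if scheme == "axon" else None)
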