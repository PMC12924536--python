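"""Synthetic cohort generator with recorded ground truth.

Emulates the statistical structure the downstream analysis assumes: four
histotypes with unbalanced group sizes split into early (FIGO I/II) and
late (III/IV) strata; per-protein log-normal intensities with planted
group fold changes; intensity-dependent (missing-not-at-random)
detection-limit missingness; and survival times from an exponential
proportional-hazards model with planted protein effects plus age and
stage-group covariate effects.

Every draw flows through one ``numpy`` Generator in a documented order
(samples, protein baselines, abundance noise, missingness uniforms,
survival draws); new features must append draws, never reorder them, so a
fixed seed stays bit-reproducible across versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .data_io import (HISTOTYPES, AbundanceMatrix, AnnotationTable, SampleMetadata,
                      ValidationError)

STAGE_GROUPS = ("early", "late")

# Reference cohort shape: histotype totals 122/42/35/45,
# early 92 / late 152 overall, EC half early, early MC n=10, early CCC n=14.
REFERENCE_CELL_COUNTS: dict[tuple[str, str], int] = {
    ("HGSC", "early"): 47, ("HGSC", "late"): 75,
    ("EC", "early"): 21, ("EC", "late"): 21,
    ("MC", "early"): 10, ("MC", "late"): 25,
    ("CCC", "early"): 14, ("CCC", "late"): 31,
}


@dataclass(frozen=True)
class PlantedAbundanceEffect:
    """Additive log2 shift for one protein in one (histotype, stage-group) cell.

    ``stage_group=None`` plants the shift in both stage groups of the
    histotype.
    """

    protein: int
    histotype: str
    stage_group: str | None
    log2_effect: float


@dataclass(frozen=True)
class PlantedHazardEffect:
    """Log hazard ratio per SD of one protein's log2 abundance.

    Applies to samples of the given stratum (``None`` = all histotypes /
    both stage groups).
    """

    protein: int
    log_hr: float
    histotype: str | None = None
    stage_group: str | None = None


@dataclass
class SurvivalConfig:
    """Exponential proportional-hazards truth model.

    ``baseline_rate`` is the daily hazard at covariate zero (default
    1/2000 per day, median survival ~3.8 years at the null — typical of a
    mixed-histotype ovarian carcinoma cohort). ``age_effect`` is the log
    hazard ratio per year of age; ``stage_effect`` the log hazard ratio of
    late vs early stage. ``censoring_rate`` sets the marginal probability
    of loss to follow-up before death; an administrative follow-up cutoff
    is applied on top. Among deaths a fraction ``disease_death_fraction``
    are disease-specific (the rest are deaths from other causes, censored
    for the disease-specific endpoint).
    """

    baseline_rate: float = 1.0 / 2000.0
    planted: list[PlantedHazardEffect] = field(default_factory=list)
    age_effect: float = 0.02
    stage_effect: float = 0.7
    censoring_rate: float = 0.3
    admin_cutoff_days: float = 3650.0
    disease_death_fraction: float = 0.85


@dataclass
class SimulationConfig:
    """Cohort shape and truth model for one simulated dataset."""

    n_per_cell: dict[tuple[str, str], int]
    n_proteins: int = 300
    baseline_log2_mean_range: tuple[float, float] = (18.0, 28.0)
    protein_sd_range: tuple[float, float] = (0.3, 1.2)
    planted_da: list[PlantedAbundanceEffect] = field(default_factory=list)
    detection_quantile: float = 0.05
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    age_mean: float = 60.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (30.0, 90.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for cell, n in self.n_per_cell.items():
            if n < 0:
                raise ValidationError(f"negative cell count for {cell}")
        for eff in self.planted_da:
            if not 0 <= eff.protein < self.n_proteins:
                raise ValidationError(
                    f"planted abundance effect on protein {eff.protein} out of range "
                    f"[0, {self.n_proteins})")
        for eff in self.survival.planted:
            if not 0 <= eff.protein < self.n_proteins:
                raise ValidationError(
                    f"planted hazard effect on protein {eff.protein} out of range "
                    f"[0, {self.n_proteins})")
        if not 0 <= self.survival.censoring_rate < 1:
            raise ValidationError("censoring_rate must be in [0, 1)")
        if not 0 <= self.detection_quantile < 1:
            raise ValidationError("detection_quantile must be in [0, 1)")

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_cell.values())


@dataclass
class TruthSet:
    """Ground truth recorded alongside a generated cohort.

    ``da_effects`` / ``hazard_effects`` tabulate the planted effects with
    protein ids; ``shifts`` holds the realized per-sample log2 shift for
    every planted protein, so the exact expected group difference of any
    two-group contrast can be computed; ``censoring_fraction`` is the
    realized fraction of censored overall-survival records.
    """

    da_effects: pd.DataFrame
    hazard_effects: pd.DataFrame
    shifts: pd.DataFrame  # planted proteins x samples, log2 shift per sample
    censoring_fraction: float

    def expected_log2fc(self, protein_id: str, target_ids: list[str],
                        reference_ids: list[str]) -> float:
        """Exact expected log2 fold change of a contrast under the truth model."""
        if protein_id not in self.shifts.index:
            return 0.0
        row = self.shifts.loc[protein_id]
        return float(row[target_ids].mean() - row[reference_ids].mean())


def generate_cohort(config: SimulationConfig) -> tuple[AbundanceMatrix, SampleMetadata, TruthSet]:
    """Draw one cohort: raw-scale matrix, clinical table, and truth set.

    The log2 quantity of protein p in sample i is
    ``baseline_p + shift_p(i) + sd_p * N(0,1)``; a cell goes missing with
    probability decaying logistically in its log2 intensity around the
    protein's ``detection_quantile`` baseline quantile (MNAR detection
    limit). Survival is exponential with linear predictor = planted
    effects on standardized log2 abundance + age and stage-group terms,
    with independent exponential censoring and an administrative cutoff.
    Identical config and seed give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)

    # --- 1. samples: fixed cell order, stage within group, ages -------------
    rows = []
    for h in HISTOTYPES:
        for sg in STAGE_GROUPS:
            n = config.n_per_cell.get((h, sg), 0)
            if n == 0:
                continue
            # sub-stage mix: early mostly I, late mostly III
            if sg == "early":
                stages = rng.choice(["I", "II"], size=n, p=[0.6, 0.4])
            else:
                stages = rng.choice(["III", "IV"], size=n, p=[0.7, 0.3])
            a, b = config.age_range
            ages = truncnorm.rvs((a - config.age_mean) / config.age_sd,
                                 (b - config.age_mean) / config.age_sd,
                                 loc=config.age_mean, scale=config.age_sd,
                                 size=n, random_state=rng)
            for k in range(n):
                rows.append((h, sg, stages[k], ages[k]))
    if not rows:
        raise ValidationError("empty cohort: all cell counts are zero")
    sample_ids = [f"S{i+1:04d}" for i in range(len(rows))]
    histotype = np.array([r[0] for r in rows])
    stage_grp = np.array([r[1] for r in rows])
    stage = np.array([r[2] for r in rows])
    age = np.array([r[3] for r in rows])
    n_samples = len(rows)

    # --- 2. protein baselines ------------------------------------------------
    P = config.n_proteins
    lo, hi = config.baseline_log2_mean_range
    base_mean = rng.uniform(lo, hi, size=P)
    slo, shi = config.protein_sd_range
    prot_sd = rng.uniform(slo, shi, size=P)
    protein_ids = [f"P{i+1:05d}" for i in range(P)]

    # --- planted shifts (deterministic given config) -------------------------
    shift = np.zeros((P, n_samples))
    for eff in config.planted_da:
        in_cell = histotype == eff.histotype
        if eff.stage_group is not None:
            in_cell &= stage_grp == eff.stage_group
        shift[eff.protein, in_cell] += eff.log2_effect

    # --- 3. abundance noise ---------------------------------------------------
    z = rng.standard_normal((P, n_samples))
    log2x = base_mean[:, None] + shift + prot_sd[:, None] * z

    # --- 4. detection-limit missingness (MNAR) --------------------------------
    u = rng.uniform(size=(P, n_samples))
    q = config.detection_quantile
    if q > 0:
        thresh = base_mean + prot_sd * norm.ppf(q)
        softness = 0.25 * prot_sd
        p_miss = 1.0 / (1.0 + np.exp((log2x - thresh[:, None]) / softness[:, None]))
    else:
        p_miss = np.zeros_like(log2x)
    missing = u < p_miss

    raw = np.power(2.0, log2x)
    raw[missing] = np.nan

    # --- 5. survival ----------------------------------------------------------
    sc = config.survival
    zstd = (log2x - base_mean[:, None]) / prot_sd[:, None]  # pre-missingness
    eta = np.zeros(n_samples)
    for eff in sc.planted:
        mask = np.ones(n_samples, dtype=bool)
        if eff.histotype is not None:
            mask &= histotype == eff.histotype
        if eff.stage_group is not None:
            mask &= stage_grp == eff.stage_group
        eta[mask] += eff.log_hr * zstd[eff.protein, mask]
    eta += sc.age_effect * (age - config.age_mean)
    eta += sc.stage_effect * (stage_grp == "late")

    death_t = rng.exponential(1.0 / (sc.baseline_rate * np.exp(eta)))
    if sc.censoring_rate > 0:
        cens_rate = sc.baseline_rate * sc.censoring_rate / (1.0 - sc.censoring_rate)
        cens_t = rng.exponential(1.0 / cens_rate, size=n_samples)
    else:
        cens_t = np.full(n_samples, np.inf)
    cens_t = np.minimum(cens_t, sc.admin_cutoff_days)
    os_time = np.minimum(death_t, cens_t)
    os_event = (death_t <= cens_t).astype(int)
    disease = rng.uniform(size=n_samples) < sc.disease_death_fraction
    dss_event = (os_event.astype(bool) & disease).astype(int)

    meta = SampleMetadata(pd.DataFrame({
        "histotype": histotype, "stage": stage, "age": np.round(age, 1),
        "os_time": np.round(os_time, 1), "os_event": os_event,
        "dss_time": np.round(os_time, 1), "dss_event": dss_event,
    }, index=pd.Index(sample_ids, name="sample_id")))

    matrix = AbundanceMatrix(
        pd.DataFrame(raw, index=pd.Index(protein_ids, name="protein_id"),
                     columns=sample_ids),
        scale="raw")

    planted_idx = sorted({e.protein for e in config.planted_da})
    truth = TruthSet(
        da_effects=pd.DataFrame(
            [(protein_ids[e.protein], e.histotype, e.stage_group, e.log2_effect)
             for e in config.planted_da],
            columns=["protein_id", "histotype", "stage_group", "log2_effect"]),
        hazard_effects=pd.DataFrame(
            [(protein_ids[e.protein], e.histotype, e.stage_group, e.log_hr)
             for e in sc.planted],
            columns=["protein_id", "histotype", "stage_group", "log_hr"]),
        shifts=pd.DataFrame(shift[planted_idx],
                            index=[protein_ids[i] for i in planted_idx],
                            columns=sample_ids),
        censoring_fraction=float(1.0 - os_event.mean()),
    )
    return matrix, meta, truth


def reference_cohort_shape(n_proteins: int = 300, seed: int = 0,
                        **overrides) -> SimulationConfig:
    """Config whose group sizes reproduce the full 244-patient cohort shape."""
    return SimulationConfig(n_per_cell=dict(REFERENCE_CELL_COUNTS), n_proteins=n_proteins,
                            seed=seed, **overrides)


def desk_shape(n_proteins: int = 200, seed: int = 0, scale: float = 0.25,
               min_cell: int = 6, **overrides) -> SimulationConfig:
    """Reduced variant scaling each (histotype, stage-group) cell down
    proportionally with a floor of ``min_cell`` samples per cell."""
    cells = {cell: max(min_cell, ceil(n * scale))
             for cell, n in REFERENCE_CELL_COUNTS.items()}
    return SimulationConfig(n_per_cell=cells, n_proteins=n_proteins, seed=seed,
                            **overrides)


def standard_planted_effects(n_proteins: int) -> tuple[list[PlantedAbundanceEffect],
                                                       list[PlantedHazardEffect]]:
    """A fixed battery of recoverable effects for demonstration cohorts.

    Three abundance markers per (histotype, stage-group) cell — two up
    (+2.0, +1.5 log2 units), one down (-2.0) — on distinct proteins, plus
    four prognostic proteins (|log HR| = 1 per SD) in the larger strata.
    Requires at least 30 proteins.
    """
    if n_proteins < 30:
        raise ValidationError("standard planted effects need >= 30 proteins")
    da: list[PlantedAbundanceEffect] = []
    i = 0
    for h in HISTOTYPES:
        for sg in STAGE_GROUPS:
            for delta in (2.0, 1.5, -2.0):
                da.append(PlantedAbundanceEffect(i, h, sg, delta))
                i += 1
    hz = [
        PlantedHazardEffect(i, 1.0, "HGSC", "late"),
        PlantedHazardEffect(i + 1, -1.0, "HGSC", "late"),
        PlantedHazardEffect(i + 2, 1.0, "HGSC", "early"),
        PlantedHazardEffect(i + 3, 1.0, "EC", "late"),
    ]
    return da, hz


def synthetic_annotation(protein_ids: list[str], n_terms: int = 25,
                         term_size: tuple[int, int] = (5, 40),
                         enriched_proteins: list[str] | None = None,
                         seed: int = 0) -> AnnotationTable:
    """Random GO-BP-style annotation over the given proteins.

    If ``enriched_proteins`` is given, the first term is loaded with those
    proteins so over-representation is recoverable by construction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_terms):
        go_id = f"GO:{1000000 + t:07d}"
        desc = f"synthetic biological process {t}"
        k = int(rng.integers(term_size[0], term_size[1] + 1))
        members = list(rng.choice(protein_ids, size=min(k, len(protein_ids)),
                                  replace=False))
        if t == 0 and enriched_proteins:
            members = sorted(set(members) | set(enriched_proteins))
        rows.extend((p, go_id, desc) for p in members)
    return AnnotationTable(pd.DataFrame(rows, columns=["protein_id", "go_id",
                                                       "description"]))
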