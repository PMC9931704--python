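"""Virtual pediatric subjects with age-consistent anthropometry and renal function.

The generator emulates what a population PBPK simulator does when asked for a
matched virtual cohort: given a reference subject (age, sex, weight from a
demographic table), it fixes those dose-relevant covariates and resamples the
physiological ones (height, hematocrit, unbound fraction, GFR) with
conventional coefficients of variation.  Healthy GFR follows a two-point
maturation curve — 20 ml/min/1.73 m² at birth rising linearly to the adult
120 ml/min/1.73 m² by age 1 year — and CKD GFRs are drawn uniformly inside
the requested stage band.

Anthropometry uses published pediatric approximations (median weight/height
for age, APLS-style) with log-normal variability; body surface area uses the
Haycock formula by default (DuBois available), which is the BSA that feeds
the under-15 GFR route.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import renal
from .errors import ConfigError, DomainError

__all__ = [
    "Subject",
    "PopulationSpec",
    "compute_bsa",
    "median_weight_for_age",
    "median_height_for_age",
    "gfr_for_age",
    "sample_population",
    "subjects_to_frame",
    "read_demographics_csv",
]

#: Healthy GFR maturation endpoints (ml/min/1.73 m^2).
GFR_BIRTH = 20.0
GFR_ADULT = 120.0

#: Defaults for covariates the source tables do not carry (config-overridable).
HEALTHY_HEMATOCRIT = 0.37
CAPTOPRIL_FU_PLASMA = 0.70


@dataclass(frozen=True)
class Subject:
    """One virtual or observed individual.

    ``bsa`` must equal :func:`compute_bsa` applied to (weight, height) for the
    stated formula, and ``ckd_stage`` must match :func:`renal.stage_from_gfr`;
    both are enforced at construction.  ``imputed`` records which fields were
    filled in rather than observed.
    """

    id: str
    age: float  # years
    sex: str  # "M" | "F"
    weight: float  # kg
    height: float  # cm
    bsa: float  # m^2
    gfr: float  # ml/min/1.73 m^2 (normalized)
    ckd_stage: str
    serum_creatinine: float | None = None  # mg/dl
    hematocrit: float = HEALTHY_HEMATOCRIT
    fu_plasma: float = CAPTOPRIL_FU_PLASMA
    overlay: renal.DiseaseOverlay | None = None
    bsa_formula: str = "haycock"
    imputed: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise DomainError(f"weight must be > 0, got {self.weight}")
        if self.age < 0 or self.age > 80:
            raise DomainError(f"age must be in [0, 80] years, got {self.age}")
        if not 0.0 < self.fu_plasma <= 1.0:
            raise DomainError(f"fu_plasma must be in (0, 1], got {self.fu_plasma}")
        if self.gfr < 0:
            raise DomainError(f"gfr must be >= 0, got {self.gfr}")
        if not 0.0 < self.hematocrit < 1.0:
            raise DomainError(f"hematocrit must be in (0, 1), got {self.hematocrit}")
        expected = compute_bsa(self.weight, self.height, formula=self.bsa_formula)
        if abs(self.bsa - expected) > 1e-9:
            raise DomainError(
                f"bsa {self.bsa} inconsistent with {self.bsa_formula}"
                f"(weight={self.weight}, height={self.height}) = {expected}"
            )
        if self.ckd_stage != renal.stage_from_gfr(self.gfr):
            raise DomainError(
                f"ckd_stage {self.ckd_stage!r} inconsistent with gfr {self.gfr} "
                f"(expected {renal.stage_from_gfr(self.gfr)!r})"
            )


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for a virtual cohort.

    When ``reference_subject`` is set, age, sex and weight (dose-relevant
    covariates) are copied from it for every virtual subject and only the
    physiological covariates are resampled, mirroring how matched virtual
    populations are built around each clinical subject.
    """

    n: int
    age_range: tuple[float, float] = (0.0, 18.0)
    sex_ratio: float = 0.5  # fraction male
    ckd_stage: str = "healthy"
    reference_subject: Subject | None = None
    seed: int = 0
    # Conventional coefficients of variation (log-normal scale).
    weight_cv: float = 0.15
    height_cv: float = 0.04
    hematocrit_cv: float = 0.05
    fu_cv: float = 0.10
    gfr_cv: float = 0.15
    bsa_formula: str = "haycock"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"n must be >= 1, got {self.n}")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 0:
            raise ConfigError(f"invalid age_range {self.age_range}")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigError(f"sex_ratio must be in [0, 1], got {self.sex_ratio}")
        if self.ckd_stage not in renal.STAGES:
            raise ConfigError(f"unknown ckd_stage {self.ckd_stage!r}")


def compute_bsa(weight: float, height: float, formula: str = "haycock") -> float:
    """Body surface area (m²) from weight (kg) and height (cm).

    Haycock (default, validated across pediatric sizes):
    ``0.024265 * W^0.5378 * H^0.3964``; DuBois–DuBois available via
    ``formula="dubois"``.
    """
    if weight <= 0:
        raise DomainError(f"weight must be > 0, got {weight}")
    if height <= 0:
        raise DomainError(f"height must be > 0, got {height}")
    if formula == "haycock":
        return 0.024265 * weight**0.5378 * height**0.3964
    if formula == "dubois":
        return 0.007184 * weight**0.425 * height**0.725
    raise DomainError(f"unknown BSA formula {formula!r}")


def median_weight_for_age(age: float, sex: str = "M") -> float:
    """Median body weight (kg) for age — piecewise APLS-style approximation.

    Continuous by construction: 3.4 kg at birth, 10 kg at 1 y, 22 kg at 6 y,
    43 kg at 13 y, 66 kg at 18 y, plateauing at 70 kg by age 22.  Sex is
    accepted for interface symmetry; the approximation is unisex (the
    reference tables carry measured weights which always override it).
    """
    if age < 0:
        raise DomainError(f"age must be >= 0, got {age}")
    if age < 1:
        return 3.4 + 6.6 * age
    if age < 6:
        return 10.0 + 2.4 * (age - 1.0)
    if age < 13:
        return 22.0 + 3.0 * (age - 6.0)
    if age < 18:
        return 43.0 + 4.6 * (age - 13.0)
    return min(66.0 + 1.0 * (age - 18.0), 70.0)


def median_height_for_age(age: float, sex: str = "M") -> float:
    """Median stature (cm) for age — piecewise linear growth approximation.

    50 cm at birth, 75 cm at 1 y, 89 cm at 2 y, then the common
    ``6*age + 77`` school-age rule to 149 cm at 12 y, reaching 170 cm at 18 y.
    """
    if age < 0:
        raise DomainError(f"age must be >= 0, got {age}")
    if age < 1:
        return 50.0 + 25.0 * age
    if age < 2:
        return 75.0 + 14.0 * (age - 1.0)
    if age < 12:
        return 6.0 * age + 77.0
    if age < 18:
        return 149.0 + (170.0 - 149.0) / 6.0 * (age - 12.0)
    return 170.0


def gfr_for_age(
    age: float, ckd_stage: str = "healthy", rng: np.random.Generator | None = None
) -> float:
    """GFR (ml/min/1.73 m²) for a subject of ``age`` at a CKD stage.

    Healthy kidneys follow the maturation curve (20 at birth, linear to 120 by
    age 1, flat thereafter).  For CKD stages the value is drawn uniformly
    within the stage band, seeded through ``rng``.
    """
    if age < 0:
        raise DomainError(f"age must be >= 0, got {age}")
    if ckd_stage == "healthy":
        return GFR_BIRTH + (GFR_ADULT - GFR_BIRTH) * min(age, 1.0)
    lo, hi = renal.gfr_band(ckd_stage)
    if rng is None:
        rng = np.random.default_rng(0)
    return float(rng.uniform(lo, hi))


def _lognormal(rng: np.random.Generator, median: float, cv: float) -> float:
    """Draw log-normal with the given median and coefficient of variation."""
    if cv <= 0:
        return median
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return float(median * np.exp(rng.normal(0.0, sigma)))


def _sample_gfr(spec: PopulationSpec, age: float, rng: np.random.Generator) -> float:
    ref = spec.reference_subject
    if ref is not None and ref.gfr is not None and renal.stage_from_gfr(ref.gfr) == spec.ckd_stage:
        # Matched cohort: vary around the reference GFR but stay in its band.
        lo, hi = renal.gfr_band(spec.ckd_stage)
        for _ in range(1000):
            g = _lognormal(rng, ref.gfr, spec.gfr_cv)
            if (lo < g <= hi) if spec.ckd_stage == "healthy" else (lo <= g < hi):
                return g
        raise ConfigError(f"could not sample a GFR inside the {spec.ckd_stage} band")
    if spec.ckd_stage == "healthy":
        median = gfr_for_age(age, "healthy")
        for _ in range(1000):
            g = _lognormal(rng, max(median, 91.0), spec.gfr_cv)
            if g > 90.0:
                return g
        raise ConfigError("could not sample a healthy GFR > 90")
    lo, hi = renal.gfr_band(spec.ckd_stage)
    return float(rng.uniform(lo, hi))


def sample_population(spec: PopulationSpec) -> list[Subject]:
    """Sample exactly ``spec.n`` subjects; identical spec+seed reproduce bitwise."""
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference_subject
    subjects: list[Subject] = []
    for i in range(spec.n):
        imputed: list[str] = []
        if ref is not None:
            age, sex, weight = ref.age, ref.sex, ref.weight
        else:
            age = float(rng.uniform(*spec.age_range))
            sex = "M" if rng.uniform() < spec.sex_ratio else "F"
            weight = _lognormal(rng, median_weight_for_age(age, sex), spec.weight_cv)
            imputed.append("weight")
        if ref is not None and "height" not in ref.imputed:
            height = ref.height
        else:
            height = _lognormal(rng, median_height_for_age(age, sex), spec.height_cv)
            imputed.append("height")
        gfr = _sample_gfr(spec, age, rng)
        hct = float(np.clip(_lognormal(rng, HEALTHY_HEMATOCRIT, spec.hematocrit_cv), 0.15, 0.60))
        fu = float(np.clip(_lognormal(rng, CAPTOPRIL_FU_PLASMA, spec.fu_cv), 0.05, 1.0))
        subjects.append(
            Subject(
                id=f"V{i:04d}",
                age=age,
                sex=sex,
                weight=weight,
                height=height,
                bsa=compute_bsa(weight, height, formula=spec.bsa_formula),
                gfr=gfr,
                ckd_stage=renal.stage_from_gfr(gfr),
                serum_creatinine=ref.serum_creatinine if ref is not None else None,
                hematocrit=hct,
                fu_plasma=fu,
                bsa_formula=spec.bsa_formula,
                imputed=tuple(imputed),
            )
        )
    return subjects


def subjects_to_frame(subjects: list[Subject], seed: int | None = None) -> pd.DataFrame:
    """Cohort as a DataFrame mirroring the demographics CSV schema."""
    rows = []
    for s in subjects:
        row = {
            "id": s.id,
            "age_years": s.age,
            "sex": s.sex,
            "weight_kg": s.weight,
            "height_cm": s.height,
            "bsa_m2": s.bsa,
            "serum_creatinine_mg_dl": s.serum_creatinine,
            "gfr": s.gfr,
            "ckd_stage": s.ckd_stage,
            "hematocrit": s.hematocrit,
            "fu_plasma": s.fu_plasma,
            "imputed": ";".join(s.imputed),
        }
        if seed is not None:
            row["seed"] = seed
        rows.append(row)
    return pd.DataFrame(rows)


def subject_from_row(
    row: dict, *, default_stage: str | None = None, bsa_formula: str = "haycock"
) -> tuple[Subject, list[str]]:
    """Build a Subject from a demographics record, imputing what is missing.

    Returns the subject and a human-readable provenance log of imputations.
    Missing height is imputed from age; missing GFR uses the under-15
    BSA/maturation route or, at 15 years and older, the Jelliffe creatinine
    equation.
    """
    log: list[str] = []
    imputed: list[str] = []

    def _missing(key):
        v = row.get(key)
        return v is None or (isinstance(v, float) and np.isnan(v)) or v == ""

    sid = str(row["id"])
    age = float(row["age_years"])
    sex = str(row["sex"]).upper()[:1]
    if _missing("weight_kg"):
        weight = median_weight_for_age(age, sex)
        imputed.append("weight")
        log.append(f"{sid}: weight imputed from age {age} -> {weight:.2f} kg")
    else:
        weight = float(row["weight_kg"])
    if _missing("height_cm"):
        height = median_height_for_age(age, sex)
        imputed.append("height")
        log.append(f"{sid}: height imputed from age {age} -> {height:.1f} cm")
    else:
        height = float(row["height_cm"])
    scr = None if _missing("serum_creatinine_mg_dl") else float(row["serum_creatinine_mg_dl"])
    if not _missing("gfr"):
        gfr = float(row["gfr"])
    elif age >= 15.0 and scr is not None:
        gfr = renal.jelliffe_egfr(age, scr, sex)
        imputed.append("gfr")
        log.append(f"{sid}: gfr from Jelliffe(age={age}, Scr={scr}, {sex}) -> {gfr:.1f}")
    else:
        gfr = gfr_for_age(age, "healthy")
        imputed.append("gfr")
        log.append(f"{sid}: gfr from maturation curve at age {age} -> {gfr:.1f}")
    stage = row.get("ckd_stage") if not _missing("ckd_stage") else None
    if stage is None:
        stage = default_stage or renal.stage_from_gfr(gfr)
    subject = Subject(
        id=sid,
        age=age,
        sex=sex,
        weight=weight,
        height=height,
        bsa=compute_bsa(weight, height, formula=bsa_formula),
        gfr=gfr,
        ckd_stage=stage,
        serum_creatinine=scr,
        bsa_formula=bsa_formula,
        imputed=tuple(imputed),
    )
    return subject, log


def read_demographics_csv(path) -> tuple[list[Subject], list[str]]:
    """Read a demographics CSV (one row per subject); returns subjects + log."""
    frame = pd.read_csv(path)
    required = {"id", "age_years", "sex"}
    missing = required - set(frame.columns)
    if missing:
        from .errors import DataError

        raise DataError(f"demographics CSV missing columns: {sorted(missing)}")
    subjects, log = [], []
    for row in frame.to_dict("records"):
        s, entries = subject_from_row(row)
        subjects.append(s)
        log.extend(entries)
    return subjects, log
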