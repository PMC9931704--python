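"""Renal function equations, CKD staging and disease overlays.

Kidney damage is classified by glomerular filtration rate (GFR, normalized to
1.73 m² body surface area) into the conventional bands: healthy > 90,
mild [60, 90), moderate [30, 60), severe [15, 30) and end-stage renal disease
below 15 ml/min/1.73 m².  A boundary value sits in the band below it
(GFR = 90 is mild, 60 is moderate, 30 is severe, 15 is severe's lower edge),
so the bands partition [0, ∞).

A :class:`DiseaseOverlay` collects the CKD pathophysiology applied on top of a
healthy subject: the fraction of healthy non-renal clearance retained, plasma
protein binding (unbound fraction) scaling, a hematocrit shift, delayed
gastric emptying and a tissue-partition (Kp) multiplier.  The non-renal
clearance fractions for mild and severe disease are 0.8 and 0.6 of the healthy
value; the moderate value (0.7) is a linear interpolation provided for
convenience and overridable in configuration.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, UnsupportedStageError

__all__ = [
    "STAGES",
    "STAGE_BANDS",
    "DiseaseOverlay",
    "DEFAULT_OVERLAYS",
    "jelliffe_egfr",
    "stage_from_gfr",
    "gfr_band",
    "apply_ckd",
    "staging_table",
]

#: CKD stages ordered by increasing severity.
STAGES = ("healthy", "mild", "moderate", "severe", "esrd")

#: Half-open GFR bands [lo, hi) in ml/min/1.73 m^2; ``healthy`` is open above.
#: Note the boundary convention: a GFR exactly on an edge belongs to the band
#: whose *upper* edge it is (90 -> mild), so ``healthy`` is effectively (90, inf).
STAGE_BANDS = {
    "healthy": (90.0, math.inf),
    "mild": (60.0, 90.0),
    "moderate": (30.0, 60.0),
    "severe": (15.0, 30.0),
    "esrd": (0.0, 15.0),
}


@dataclass(frozen=True)
class DiseaseOverlay:
    """CKD pathophysiology applied to a healthy-baseline subject."""

    nonrenal_cl_fraction: float = 1.0
    fu_multiplier: float = 1.0
    hematocrit_delta: float = 0.0
    gastric_emptying_multiplier: float = 1.0
    kp_scalar: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.nonrenal_cl_fraction <= 1.0:
            raise DomainError(
                f"nonrenal_cl_fraction must be in (0, 1], got {self.nonrenal_cl_fraction}"
            )
        for name in ("fu_multiplier", "gastric_emptying_multiplier", "kp_scalar"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def is_identity(self) -> bool:
        return (
            self.nonrenal_cl_fraction == 1.0
            and self.fu_multiplier == 1.0
            and self.hematocrit_delta == 0.0
            and self.gastric_emptying_multiplier == 1.0
            and self.kp_scalar == 1.0
        )


# Stage-specific overlays.  Non-renal CL fractions 0.8 (mild) / 0.6 (severe)
# follow the adult CKD parameterization; 0.7 (moderate) interpolates.  The
# hematocrit, protein-binding and gastric-emptying magnitudes are conventional
# CKD adjustments (renal anemia, reduced albumin binding, delayed emptying)
# and are configuration-overridable.
DEFAULT_OVERLAYS: dict[str, DiseaseOverlay] = {
    "healthy": DiseaseOverlay(),
    "mild": DiseaseOverlay(
        nonrenal_cl_fraction=0.8,
        fu_multiplier=1.05,
        hematocrit_delta=-0.02,
        gastric_emptying_multiplier=1.1,
    ),
    "moderate": DiseaseOverlay(
        nonrenal_cl_fraction=0.7,
        fu_multiplier=1.10,
        hematocrit_delta=-0.04,
        gastric_emptying_multiplier=1.2,
    ),
    "severe": DiseaseOverlay(
        nonrenal_cl_fraction=0.6,
        fu_multiplier=1.15,
        hematocrit_delta=-0.06,
        gastric_emptying_multiplier=1.3,
    ),
}


def jelliffe_egfr(age: float, serum_creatinine: float, sex: str) -> float:
    """Jelliffe creatinine-based eGFR in ml/min/1.73 m².

    ``eGFR = (98 - 0.8 * (age - 20)) / Scr``, multiplied by 0.9 for females,
    clamped at zero.  Intended for subjects 15 years and older; younger
    subjects should use the BSA/maturation route (see :mod:`captoped.population`).

    Parameters
    ----------
    age : years (>= 0)
    serum_creatinine : mg/dl (> 0)
    sex : "M" or "F"
    """
    if serum_creatinine <= 0:
        raise DomainError(f"serum_creatinine must be > 0, got {serum_creatinine}")
    if age < 0:
        raise DomainError(f"age must be >= 0, got {age}")
    value = (98.0 - 0.8 * (age - 20.0)) / serum_creatinine
    if str(sex).upper().startswith("F"):
        value *= 0.9
    return max(value, 0.0)


def stage_from_gfr(gfr: float) -> str:
    """Map a normalized GFR to its CKD stage (see module docstring for bands)."""
    if gfr < 0:
        raise DomainError(f"gfr must be >= 0, got {gfr}")
    if gfr > 90.0:
        return "healthy"
    if gfr > 60.0:
        return "mild"
    if gfr > 30.0:
        return "moderate"
    if gfr >= 15.0:  # severe keeps its printed lower edge (end-stage is GFR < 15)
        return "severe"
    return "esrd"


def gfr_band(stage: str) -> tuple[float, float]:
    """Return the [lo, hi) GFR band for ``stage``."""
    try:
        return STAGE_BANDS[stage]
    except KeyError:
        raise DomainError(f"unknown CKD stage {stage!r}") from None


def apply_ckd(
    subject,
    stage: str,
    *,
    overlays: dict[str, DiseaseOverlay] | None = None,
    rng: np.random.Generator | None = None,
):
    """Return a copy of a healthy-baseline subject moved to a CKD stage.

    The GFR is resampled uniformly within the stage band (seeded via ``rng``;
    for ``healthy`` a GFR already in band is kept), the stage's
    :class:`DiseaseOverlay` is attached, and the unbound fraction / hematocrit
    are adjusted per the overlay.  The input subject is not modified.

    End-stage renal disease has no disease parameterization here (the source
    model covers mild and severe; moderate is interpolated) and raises
    :class:`UnsupportedStageError`.
    """
    if stage == "esrd":
        raise UnsupportedStageError(
            "esrd is not parameterized (only mild/severe are modelled; "
            "moderate is an interpolated convenience)"
        )
    if stage not in STAGES:
        raise DomainError(f"unknown CKD stage {stage!r}")
    table = DEFAULT_OVERLAYS if overlays is None else overlays
    overlay = table[stage]
    if rng is None:
        rng = np.random.default_rng(0)

    lo, hi = STAGE_BANDS[stage]
    if stage == "healthy":
        gfr = subject.gfr if subject.gfr > lo else float(rng.uniform(91.0, 130.0))
    else:
        gfr = float(rng.uniform(lo, hi))

    fu = min(subject.fu_plasma * overlay.fu_multiplier, 1.0)
    hct = subject.hematocrit + overlay.hematocrit_delta
    return dataclasses.replace(
        subject,
        gfr=gfr,
        ckd_stage=stage,
        fu_plasma=fu,
        hematocrit=hct,
        overlay=overlay,
    )


def staging_table() -> dict:
    """Staging bands plus default overlays, JSON-serializable."""
    return {
        stage: {
            "gfr_lo": STAGE_BANDS[stage][0],
            "gfr_hi": None if math.isinf(STAGE_BANDS[stage][1]) else STAGE_BANDS[stage][1],
            "overlay": dataclasses.asdict(DEFAULT_OVERLAYS[stage])
            if stage in DEFAULT_OVERLAYS
            else None,
        }
        for stage in STAGES
    }
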