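"""Packaged reference fixtures and a synthetic-study generator.

Two kinds of test data live here:

* the demographic and PK-parameter tables of the two source pediatric
  captopril studies (six renal-failure subjects dosed in mg/kg, eight
  renal-scarring subjects dosed in mg), shipped verbatim as CSV with a
  quarantine file listing the printed cells that are internally inconsistent;
* a generator of fully synthetic "observed" studies — virtual subjects,
  noise-free model-simulated truth, and multiplicative log-normal residual
  error on concentrations — so the whole pipeline can be exercised and its
  recovery properties tested without any external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import nca as nca_mod
from . import pbpk, renal
from .errors import ConfigError, DataError
from .pbpk import CompoundParams, ConcentrationProfile, DoseRegimen
from .population import PopulationSpec, Subject, sample_population

__all__ = ["SyntheticStudySpec", "load_fixture", "generate_study"]

_FIXTURES = {
    "table1": "table1.csv",
    "table2": "table2.csv",
    "table2_quarantine": "table2_quarantine.json",
}


def load_fixture(name: str):
    """Load a packaged fixture.

    ``table1`` — demographics of the 14 reference subjects (6 renal failure +
    8 renal scarring); ``table2`` — observed/predicted AUC_0-t, C_max, CL/F
    with printed pred/obs ratios (dose units resolved: mg/kg for the
    renal-failure study, mg and L/h for the renal-scarring study);
    ``table2_quarantine`` — printed cells that fail their own internal
    identities, as a list of dicts.
    """
    try:
        fname = _FIXTURES[name]
    except KeyError:
        raise DataError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}") from None
    ref = resources.files("captoped.data").joinpath(fname)
    with resources.as_file(ref) as path:
        if fname.endswith(".json"):
            return json.loads(path.read_text())
        return pd.read_csv(path)


def quarantined_cells() -> set[tuple[str, str]]:
    """(row id, column) pairs excluded from fixture parity assertions."""
    q = load_fixture("table2_quarantine")
    return {(c["id"], c["cell"]) for c in q["cells"]}


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Recipe for a synthetic observed study.

    ``residual_error`` is the standard deviation of the log-normal
    multiplicative error applied to every simulated concentration
    (0 reproduces the noise-free truth exactly).  ``ckd_stages`` maps stage
    names to cohort proportions and must sum to 1.
    """

    n_subjects: int
    age_range: tuple[float, float] = (2.0, 18.0)
    ckd_stages: dict = field(default_factory=lambda: {"healthy": 1.0})
    dose_mg_per_kg: float | None = 1.5
    dose_mg: float | None = None
    sampling_times: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0)
    residual_error: float = 0.2
    true_params: CompoundParams = field(default_factory=CompoundParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.residual_error < 0:
            raise ConfigError("residual_error must be >= 0")
        if abs(sum(self.ckd_stages.values()) - 1.0) > 1e-9:
            raise ConfigError("ckd_stages proportions must sum to 1")
        if (self.dose_mg is None) == (self.dose_mg_per_kg is None):
            raise ConfigError("exactly one of dose_mg / dose_mg_per_kg must be set")


def generate_study(
    spec: SyntheticStudySpec,
) -> tuple[list[Subject], list[ConcentrationProfile], pd.DataFrame]:
    """Generate (subjects, noisy observed profiles, noise-free NCA truth).

    Subjects are sampled per stage proportion, assigned the stage's disease
    overlay, simulated noise-free under ``true_params``, and the observed
    profiles are the truth multiplied by i.i.d. log-normal errors.  The truth
    table carries the noise-free NCA (AUC, C_max, CL/F) plus the model's true
    total clearance for recovery testing.  Fully seeded: identical specs give
    identical output.
    """
    root = np.random.SeedSequence(spec.seed)
    pop_seed, stage_seed, noise_seed = [int(s.generate_state(1)[0] >> 1) for s in root.spawn(3)]
    stage_rng = np.random.default_rng(stage_seed)
    noise_rng = np.random.default_rng(noise_seed)

    stages = list(spec.ckd_stages)
    props = np.array([spec.ckd_stages[s] for s in stages])
    counts = np.floor(props * spec.n_subjects).astype(int)
    while counts.sum() < spec.n_subjects:  # distribute rounding remainder
        counts[int(np.argmax(props * spec.n_subjects - counts))] += 1

    subjects: list[Subject] = []
    offset = 0
    for stage, count in zip(stages, counts):
        if count == 0:
            continue
        pop = sample_population(
            PopulationSpec(
                n=int(count),
                age_range=spec.age_range,
                ckd_stage="healthy",
                seed=pop_seed + offset,
            )
        )
        for s in pop:
            subjects.append(renal.apply_ckd(s, stage, rng=stage_rng))
        offset += int(count)
    # re-label to stable ids across the stage blocks
    subjects = [
        Subject(
            **{
                **{f: getattr(s, f) for f in s.__dataclass_fields__},
                "id": f"SYN{i:04d}",
            }
        )
        for i, s in enumerate(subjects)
    ]

    regimen = DoseRegimen(
        amount_mg=spec.dose_mg,
        amount_mg_per_kg=spec.dose_mg_per_kg,
        sampling_times=spec.sampling_times,
    )
    profiles: list[ConcentrationProfile] = []
    truth_rows = []
    for s in subjects:
        clean = pbpk.simulate_profile(s, spec.true_params, regimen)
        res = nca_mod.nca(clean, weight_kg=s.weight)
        cl_renal, cl_nonrenal = pbpk.scale_clearances(s, spec.true_params)
        truth_rows.append(
            {
                "id": s.id,
                "ckd_stage": s.ckd_stage,
                "weight_kg": s.weight,
                "dose_mg": clean.dose_mg,
                "auc_0_t": res.auc_0_t,
                "auc_0_inf": res.auc_0_inf,
                "cmax": res.cmax,
                "tmax": res.tmax,
                "cl_f": res.cl_f,
                "cl_total_true": cl_renal + cl_nonrenal,
            }
        )
        if spec.residual_error > 0:
            eps = noise_rng.normal(0.0, spec.residual_error, size=len(clean.times))
            noisy = clean.c * np.exp(eps)
        else:
            noisy = clean.c
        profiles.append(
            ConcentrationProfile(
                subject_id=s.id,
                times=clean.times,
                concentrations=tuple(noisy),
                dose_mg=clean.dose_mg,
                is_steady_state=clean.is_steady_state,
            )
        )
    return subjects, profiles, pd.DataFrame(truth_rows)


def profiles_to_frame(profiles: list[ConcentrationProfile]) -> pd.DataFrame:
    """Long-format profile table: subject_id, time_h, conc_ng_ml, dose_mg, steady_state."""
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "time_h": t,
                    "conc_ng_ml": c,
                    "dose_mg": p.dose_mg,
                    "steady_state": p.is_steady_state,
                }
            )
    return pd.DataFrame(rows)


def profiles_from_frame(frame: pd.DataFrame) -> list[ConcentrationProfile]:
    """Inverse of :func:`profiles_to_frame`."""
    needed = {"subject_id", "time_h", "conc_ng_ml"}
    if not needed <= set(frame.columns):
        raise DataError(f"profile table must have columns {sorted(needed)}")
    out = []
    for sid, grp in frame.groupby("subject_id", sort=False):
        grp = grp.sort_values("time_h")
        out.append(
            ConcentrationProfile(
                subject_id=str(sid),
                times=tuple(grp["time_h"].astype(float)),
                concentrations=tuple(grp["conc_ng_ml"].astype(float)),
                dose_mg=float(grp["dose_mg"].iloc[0]) if "dose_mg" in grp else 0.0,
                is_steady_state=bool(grp["steady_state"].iloc[0])
                if "steady_state" in grp
                else False,
            )
        )
    return out
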