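"""Non-compartmental analysis: C_max, T_max, AUC, terminal slope, CL/F.

Conventions match the spreadsheet-style NCA used to derive the reference
PK-parameter tables: linear trapezoidal AUC (log-down available by flag),
CL/F computed on AUC_0-t (so dose/AUC identities in observed tables hold
exactly; a flag switches to AUC_0-inf), and a terminal log-linear fit with
adjusted-R² point selection for lambda_z.

Unit bookkeeping: doses in mg, concentrations in ng/ml, so
``CL/F = dose_mg * 1e6 / AUC`` is in ml/h and is reported divided by 1000 as
L/h.  A dose given per kg yields CL/F per kg by the same identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientDataError
from .pbpk import ConcentrationProfile

__all__ = ["NCAResult", "auc_trapezoid", "cl_f", "lambda_z", "nca"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NCAResult:
    cmax: float  # ng/ml
    tmax: float  # h
    auc_0_t: float  # ng*h/ml
    cl_f: float  # L/h (or L/h/kg when the dose was per kg)
    auc_0_inf: float | None = None  # ng*h/ml
    lambda_z: float | None = None  # 1/h
    cl_f_per_kg: float | None = None  # L/h/kg
    n_lambda_z_points: int | None = None


def auc_trapezoid(
    profile: ConcentrationProfile, t_end: float | None = None, *, method: str = "linear"
) -> float:
    """AUC (ng·h/ml) from the first sample to ``t_end`` (default: last sample).

    ``method="linear"`` is the plain trapezoid; ``"log-down"`` uses the
    log-trapezoid on strictly declining positive segments.  ``t_end`` may fall
    between samples (linear interpolation) but not beyond the last one.
    """
    t, c = profile.t, profile.c
    if t.size < 2:
        raise InsufficientDataError("AUC needs at least 2 points")
    if t_end is None:
        t_end = float(t[-1])
    if t_end > t[-1] + 1e-12:
        raise DomainError(f"t_end {t_end} beyond last sample {t[-1]}")
    if t_end < t[0]:
        raise DomainError(f"t_end {t_end} before first sample {t[0]}")
    mask = t <= t_end + 1e-12
    tt, cc = t[mask], c[mask]
    if tt[-1] < t_end - 1e-12:  # interpolate the cut point
        c_end = float(np.interp(t_end, t, c))
        tt = np.append(tt, t_end)
        cc = np.append(cc, c_end)
    if method == "linear":
        return float(np.trapezoid(cc, tt))
    if method == "log-down":
        total = 0.0
        for i in range(tt.size - 1):
            c1, c2, dt = cc[i], cc[i + 1], tt[i + 1] - tt[i]
            if c1 > c2 > 0:
                total += dt * (c1 - c2) / np.log(c1 / c2)
            else:
                total += dt * (c1 + c2) / 2.0
        return float(total)
    raise DomainError(f"unknown AUC method {method!r}")


def cl_f(dose_mg: float, auc: float) -> float:
    """Apparent oral clearance: ``dose_mg * 1e6 / auc`` ng·h/ml → ml/h → L/h.

    Pass a per-kg dose to obtain L/h/kg by the identical arithmetic.
    """
    if dose_mg <= 0:
        raise DomainError(f"dose must be > 0, got {dose_mg}")
    if auc <= 0:
        raise DomainError(f"auc must be > 0, got {auc}")
    return dose_mg * 1e6 / auc / 1000.0


def lambda_z(
    profile: ConcentrationProfile, *, min_points: int = 3, max_points: int = 8
) -> tuple[float, int, float] | None:
    """Terminal elimination rate (1/h) via log-linear regression.

    Fits unweighted least squares on ln(concentration) over the last
    ``k`` post-peak points, k = ``min_points`` .. ``max_points``, and keeps
    the k maximizing adjusted R².  Returns ``(lambda_z, n_points, c_last_fit)``
    or None when no declining terminal phase exists.
    """
    t, c = profile.t, profile.c
    i_max = int(np.argmax(c))
    tail_t, tail_c = t[i_max:], c[i_max:]
    keep = tail_c > 0
    tail_t, tail_c = tail_t[keep], tail_c[keep]
    if tail_t.size < min_points + 1:  # need points after the peak
        return None
    best = None
    for k in range(min_points, min(max_points, tail_t.size - 1) + 1):
        tt, cc = tail_t[-k:], np.log(tail_c[-k:])
        slope, intercept = np.polyfit(tt, cc, 1)
        if slope >= 0:
            continue
        resid = cc - (slope * tt + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((cc - cc.mean()) ** 2))
        if ss_tot == 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2) if k > 2 else r2
        if best is None or adj > best[0] + 1e-12:
            best = (adj, -slope, k)
    if best is None:
        return None
    _, lam, k = best
    return lam, k, float(tail_c[-1])


def nca(
    profile: ConcentrationProfile,
    dose_mg: float | None = None,
    weight_kg: float | None = None,
    *,
    use_auc_inf: bool = False,
    auc_method: str = "linear",
) -> NCAResult:
    """Full NCA for one profile.

    C_max/T_max come from the observed maximum (earliest time on ties);
    AUC_0-t runs to the last sample; AUC_0-inf adds ``C_last / lambda_z``
    when a declining terminal phase is identifiable (otherwise it is omitted
    with a warning).  CL/F uses the profile's recorded dose unless
    ``dose_mg`` overrides it, and divides by AUC_0-t unless ``use_auc_inf``.
    """
    t, c = profile.t, profile.c
    if t.size < 2:
        raise InsufficientDataError("NCA needs at least 2 samples")
    i_max = int(np.argmax(c))  # argmax returns the earliest tie
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc_t = auc_trapezoid(profile, method=auc_method)
    fit = lambda_z(profile)
    if fit is None:
        lam = auc_inf = n_lam = None
        logger.warning(
            "profile %s: no declining terminal phase; AUC_0-inf omitted", profile.subject_id
        )
    else:
        lam, n_lam, c_last = fit
        auc_inf = auc_t + c_last / lam
    dose = float(dose_mg) if dose_mg is not None else profile.dose_mg
    auc_for_cl = auc_inf if (use_auc_inf and auc_inf is not None) else auc_t
    clearance = cl_f(dose, auc_for_cl)
    return NCAResult(
        cmax=cmax,
        tmax=tmax,
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        lambda_z=lam,
        cl_f=clearance,
        cl_f_per_kg=(clearance / weight_kg if weight_kg else None),
        n_lambda_z_points=n_lam,
    )
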