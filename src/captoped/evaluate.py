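"""Model-evaluation metrics: fold error, AFE, ratio CIs, two-fold counting,
population percentile bands and prediction-interval coverage.

Fold error is *predicted / observed* throughout (``ratio_pred/obs``); the
average fold error (AFE) is its geometric mean, ``10 ** mean(log10 ratio)``,
so AFE = 1 means no net bias, above 1 net over-prediction.  The conventional
acceptance band is two-fold, 0.5 ≤ ratio ≤ 2 (1.5- and 3-fold variants are a
parameter).  Visual-predictive-check coverage counts observed points inside
the per-time 5th–95th percentile band of a simulated virtual population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import AlignmentError, DomainError, InsufficientDataError
from .pbpk import ConcentrationProfile

__all__ = [
    "EvaluationReport",
    "PopulationSummary",
    "fold_error",
    "afe",
    "mean_ratio_ci",
    "twofold_check",
    "population_summary",
    "pi_coverage",
    "evaluate_parameters",
]


def fold_error(observed: float, predicted: float) -> float:
    """Predicted/observed ratio for one PK parameter (both must be > 0)."""
    if observed <= 0:
        raise DomainError(f"observed must be > 0, got {observed}")
    if predicted <= 0:
        raise DomainError(f"predicted must be > 0, got {predicted}")
    return predicted / observed


def afe(ratios) -> float:
    """Average fold error: ``10 ** (sum(log10 r) / N)`` — the geometric mean."""
    r = np.asarray(list(ratios), dtype=float)
    if r.size == 0:
        raise DomainError("afe needs at least one ratio")
    if np.any(r <= 0):
        raise DomainError("all ratios must be > 0")
    return float(10.0 ** np.mean(np.log10(r)))


def mean_ratio_ci(ratios, level: float = 0.95, *, log_scale: bool = False):
    """Arithmetic mean of the ratios with a t-distribution confidence interval.

    ``mean ± t_{(1+level)/2, N-1} * sd / sqrt(N)`` on the raw ratio scale;
    ``log_scale=True`` builds the interval on log10 ratios and back-transforms
    (returning the geometric mean).
    """
    r = np.asarray(list(ratios), dtype=float)
    if r.size < 2:
        raise InsufficientDataError("mean_ratio_ci needs at least 2 ratios")
    if np.any(r <= 0):
        raise DomainError("all ratios must be > 0")
    x = np.log10(r) if log_scale else r
    mean = float(np.mean(x))
    half = float(stats.t.ppf(0.5 + level / 2.0, r.size - 1) * np.std(x, ddof=1) / np.sqrt(r.size))
    lo, hi = mean - half, mean + half
    if log_scale:
        return 10.0**mean, (10.0**lo, 10.0**hi)
    return mean, (lo, hi)


def twofold_check(ratios, lo: float = 0.5, hi: float = 2.0):
    """Per-ratio inclusion flags for ``lo <= r <= hi`` plus the within fraction."""
    r = np.asarray(list(ratios), dtype=float)
    if np.any(r <= 0):
        raise DomainError("all ratios must be > 0")
    flags = (r >= lo) & (r <= hi)
    frac = float(np.mean(flags)) if r.size else 0.0
    return flags, frac


@dataclass(frozen=True)
class PopulationSummary:
    """Per-time summaries of a simulated virtual population."""

    times: tuple[float, ...]
    mean: tuple[float, ...]
    minimum: tuple[float, ...]
    maximum: tuple[float, ...]
    p5: tuple[float, ...]
    p95: tuple[float, ...]
    n: int

    def band(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """5th/95th percentile edges linearly interpolated at times ``t``."""
        t = np.asarray(t, dtype=float)
        grid = np.asarray(self.times)
        if np.any(t < grid[0] - 1e-9) or np.any(t > grid[-1] + 1e-9):
            raise AlignmentError("observation times outside the summary grid")
        return np.interp(t, grid, self.p5), np.interp(t, grid, self.p95)


def population_summary(profiles: list[ConcentrationProfile]) -> PopulationSummary:
    """Mean/min/max and 5th/95th percentiles per time over ≥ 2 profiles.

    Percentiles use linear interpolation between order statistics
    (numpy's default), so small-n bands are reproducible: with two profiles
    the 5th percentile sits 5% of the way up from the lower one.
    """
    if len(profiles) < 2:
        raise InsufficientDataError("population_summary needs at least 2 profiles")
    grid = profiles[0].t
    for p in profiles[1:]:
        if p.t.shape != grid.shape or not np.allclose(p.t, grid):
            raise AlignmentError("profiles are not on a common time grid")
    c = np.vstack([p.c for p in profiles])
    return PopulationSummary(
        times=tuple(grid),
        mean=tuple(c.mean(axis=0)),
        minimum=tuple(c.min(axis=0)),
        maximum=tuple(c.max(axis=0)),
        p5=tuple(np.percentile(c, 5.0, axis=0)),
        p95=tuple(np.percentile(c, 95.0, axis=0)),
        n=len(profiles),
    )


def pi_coverage(observed: ConcentrationProfile, summary: PopulationSummary) -> float:
    """Fraction of observed points inside the 5th–95th percentile band."""
    t, c = observed.t, observed.c
    if t.size == 0:
        raise DomainError("empty observation set")
    lo, hi = summary.band(t)
    return float(np.mean((c >= lo) & (c <= hi)))


@dataclass(frozen=True)
class EvaluationReport:
    """Aggregate evaluation of predicted vs observed PK parameters."""

    per_obs: tuple[tuple, ...]  # (parameter, observed, predicted, ratio)
    mean_ratio: float
    ci95: tuple[float, float]
    afe: float
    n: int
    frac_within_twofold: float
    pi_coverage: float | None = None

    def to_dict(self) -> dict:
        return {
            "mean_ratio": self.mean_ratio,
            "ci95": list(self.ci95),
            "afe": self.afe,
            "n": self.n,
            "frac_within_twofold": self.frac_within_twofold,
            "pi_coverage": self.pi_coverage,
            "per_obs": [
                {"parameter": p, "observed": o, "predicted": pr, "ratio": r}
                for p, o, pr, r in self.per_obs
            ],
        }


def evaluate_parameters(
    records,
    *,
    twofold_lo: float = 0.5,
    twofold_hi: float = 2.0,
    pi_cov: float | None = None,
) -> EvaluationReport:
    """Build an :class:`EvaluationReport` from (parameter, observed, predicted) records."""
    per_obs = []
    for param, obs, pred in records:
        per_obs.append((param, float(obs), float(pred), fold_error(obs, pred)))
    ratios = [r for *_, r in per_obs]
    if len(ratios) >= 2:
        mean, ci = mean_ratio_ci(ratios)
    elif len(ratios) == 1:
        mean, ci = ratios[0], (ratios[0], ratios[0])
    else:
        raise InsufficientDataError("no records to evaluate")
    _, frac = twofold_check(ratios, twofold_lo, twofold_hi)
    return EvaluationReport(
        per_obs=tuple(per_obs),
        mean_ratio=mean,
        ci95=ci,
        afe=afe(ratios),
        n=len(ratios),
        frac_within_twofold=frac,
        pi_coverage=pi_cov,
    )
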