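"""Beat-to-beat blood-pressure-variability metrics.

Five metric families are computed per recording for both the systolic and
diastolic amplitude series:

* **SD** — sample standard deviation of per-beat amplitudes (dispersion).
* **CV** — coefficient of variation, ``100·SD/mean`` (dispersion,
  mean-normalised).
* **VIM** — variability independent of the mean: ``SD / mean^x · M^x``,
  where the exponent ``x`` comes from a nonlinear least-squares fit of the
  power law ``SD = a·mean^x`` across the cohort and ``M`` is the cohort
  grand mean. By construction VIM is uncorrelated with mean BP across the
  sample used for the fit.
* **ΔSBP** — maximum minus minimum systolic amplitude in the analysis
  window (instability).
* **ARV** — average real variability, the mean absolute difference between
  consecutive beat amplitudes (sequence metric; sensitive to temporal
  order). Pairs spanning artifact-masked gaps are excluded, never bridged.

Mean SBP/DBP and interval-based heart rate round out the per-session row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .beats import BeatSeries, compute_hr
from .errors import InsufficientBeatsError, InvalidSeriesError

__all__ = [
    "SessionMetrics",
    "VimFit",
    "METRIC_ORDER",
    "beat_amplitude_series",
    "metric_sd",
    "metric_cv",
    "metric_arv",
    "metric_delta",
    "fit_vim_exponent",
    "metric_vim",
    "compute_session_metrics",
]

#: Canonical report row order for the per-metric tables.
METRIC_ORDER = [
    "hr", "sbp_mean", "sbp_sd", "sbp_cv", "sbp_vim", "sbp_arv", "delta_sbp",
    "dbp_mean", "dbp_sd", "dbp_cv", "dbp_vim", "dbp_arv",
]


@dataclass
class SessionMetrics:
    """All derived cardiovascular parameters for one participant-session."""

    participant_id: str
    session: int
    hr: float
    sbp_mean: float
    dbp_mean: float
    sbp_sd: float
    dbp_sd: float
    sbp_cv: float
    dbp_cv: float
    sbp_vim: float
    dbp_vim: float
    sbp_arv: float
    dbp_arv: float
    delta_sbp: float
    n_beats: int

    def as_dict(self) -> dict:
        return {
            "participant_id": self.participant_id, "session": self.session,
            "hr": self.hr, "sbp_mean": self.sbp_mean, "sbp_sd": self.sbp_sd,
            "sbp_cv": self.sbp_cv, "sbp_vim": self.sbp_vim,
            "sbp_arv": self.sbp_arv, "delta_sbp": self.delta_sbp,
            "dbp_mean": self.dbp_mean, "dbp_sd": self.dbp_sd,
            "dbp_cv": self.dbp_cv, "dbp_vim": self.dbp_vim,
            "dbp_arv": self.dbp_arv, "n_beats": self.n_beats,
        }


@dataclass
class VimFit:
    """Result of the power-law fit ``sd = a·mean^x`` across a cohort."""

    exponent_x: float
    coefficient_a: float
    grand_mean_M: float
    converged: bool
    fit_scope: str = "per-session"  # or "pooled"


def beat_amplitude_series(
    beats: BeatSeries, channel: str
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Ordered per-beat amplitudes plus masked-gap boundary positions.

    ``channel`` is ``"systolic"`` (peak amplitudes) or ``"diastolic"``
    (trough amplitudes). The returned gap positions are indices *i* such
    that elements i and i+1 are not true consecutive beats (an artifact
    span was removed between them); successive-difference metrics skip
    those pairs.
    """
    if channel == "systolic":
        values = np.asarray(beats.sbp_values, dtype=float)
        gaps = beats.gap_boundaries()
    elif channel == "diastolic":
        values = np.asarray(beats.dbp_values, dtype=float)
        gaps = beats.trough_gap_boundaries()
    else:
        raise ValueError(f"unknown channel {channel!r}")
    if len(values) < 2:
        raise InsufficientBeatsError(f"{channel} series has {len(values)} beat(s)")
    return values, gaps


def metric_sd(series: np.ndarray) -> float:
    """Sample standard deviation (n−1 denominator), mmHg."""
    series = np.asarray(series, dtype=float)
    if len(series) < 2:
        raise InsufficientBeatsError("SD needs at least 2 beats")
    return float(np.std(series, ddof=1))


def metric_cv(series: np.ndarray) -> float:
    """Coefficient of variation, percent of the series mean."""
    series = np.asarray(series, dtype=float)
    mean = float(np.mean(series))
    if mean <= 0:
        raise InvalidSeriesError(f"CV undefined for mean {mean} <= 0")
    return 100.0 * metric_sd(series) / mean


def metric_arv(series: np.ndarray, gap_boundaries: tuple[int, ...] = ()) -> float:
    """Average real variability: mean |consecutive difference|, mmHg.

    Pairs whose indices straddle a gap boundary are excluded.
    """
    series = np.asarray(series, dtype=float)
    diffs = np.abs(np.diff(series))
    usable = np.ones(len(diffs), dtype=bool)
    for g in gap_boundaries:
        if 0 <= g < len(diffs):
            usable[g] = False
    if not usable.any():
        raise InsufficientBeatsError("no usable consecutive beat pairs for ARV")
    return float(np.mean(diffs[usable]))


def metric_delta(series: np.ndarray) -> float:
    """Instability metric: max minus min amplitude in the window, mmHg."""
    series = np.asarray(series, dtype=float)
    if len(series) < 1:
        raise InsufficientBeatsError("delta needs at least 1 beat")
    return float(np.max(series) - np.min(series))


def fit_vim_exponent(
    per_unit_sds,
    per_unit_means,
    *,
    fit_scope: str = "per-session",
    x_bounds: tuple[float, float] = (-5.0, 5.0),
    tol: float = 1e-10,
) -> VimFit:
    """Least-squares fit of the power law ``sd = a·mean^x`` across units.

    Initialised at ``a = median(sd)/median(mean)``, ``x = 1`` with the
    exponent bounded to ``x_bounds``; non-convergence is reported through
    ``converged`` rather than raised.
    """
    sds = np.asarray(per_unit_sds, dtype=float)
    means = np.asarray(per_unit_means, dtype=float)
    if sds.shape != means.shape or sds.ndim != 1:
        raise ValueError("sds and means must be 1-D arrays of equal length")
    if len(sds) < 3:
        raise InvalidSeriesError("VIM fit needs at least 3 units")
    if np.any(means <= 0) or np.any(sds < 0):
        raise InvalidSeriesError("VIM fit needs positive means, nonneg sds")
    if np.allclose(means, means[0]):
        raise InvalidSeriesError("VIM fit is degenerate: all means equal")

    a0 = float(np.median(sds) / np.median(means))
    a0 = max(a0, 1e-12)

    def resid(theta):
        a, x = theta
        return a * means ** x - sds

    fit = least_squares(
        resid, x0=[a0, 1.0],
        bounds=([1e-15, x_bounds[0]], [np.inf, x_bounds[1]]),
        xtol=tol, ftol=tol, gtol=tol,
    )
    return VimFit(
        exponent_x=float(fit.x[1]),
        coefficient_a=float(fit.x[0]),
        grand_mean_M=float(np.mean(means)),
        converged=bool(fit.success),
        fit_scope=fit_scope,
    )


def metric_vim(sd: float, mean: float, fit: VimFit) -> float:
    """Variability independent of the mean: ``(sd / mean^x) · M^x``."""
    if mean <= 0:
        raise InvalidSeriesError(f"VIM undefined for mean {mean} <= 0")
    if not fit.converged:
        raise InvalidSeriesError("VIM requires a converged exponent fit")
    x = fit.exponent_x
    return float(sd / mean ** x * fit.grand_mean_M ** x)


def compute_session_metrics(
    beats: BeatSeries,
    sbp_fit: VimFit | None = None,
    dbp_fit: VimFit | None = None,
    *,
    participant_id: str = "",
    session: int = 1,
) -> SessionMetrics:
    """Assemble the full per-session metric row from a delineated recording.

    VIM needs a cohort-level exponent fit; when ``sbp_fit``/``dbp_fit`` are
    absent the corresponding VIM fields are NaN so single-recording use
    still works.
    """
    sbp, sbp_gaps = beat_amplitude_series(beats, "systolic")
    dbp, dbp_gaps = beat_amplitude_series(beats, "diastolic")
    sbp_mean = float(np.mean(sbp))
    dbp_mean = float(np.mean(dbp))
    sbp_sd = metric_sd(sbp)
    dbp_sd = metric_sd(dbp)
    return SessionMetrics(
        participant_id=participant_id,
        session=session,
        hr=compute_hr(beats),
        sbp_mean=sbp_mean,
        dbp_mean=dbp_mean,
        sbp_sd=sbp_sd,
        dbp_sd=dbp_sd,
        sbp_cv=metric_cv(sbp),
        dbp_cv=metric_cv(dbp),
        sbp_vim=metric_vim(sbp_sd, sbp_mean, sbp_fit) if sbp_fit else float("nan"),
        dbp_vim=metric_vim(dbp_sd, dbp_mean, dbp_fit) if dbp_fit else float("nan"),
        sbp_arv=metric_arv(sbp, sbp_gaps),
        dbp_arv=metric_arv(dbp, dbp_gaps),
        delta_sbp=metric_delta(sbp),
        n_beats=beats.n_beats,
    )
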