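"""Synthetic continuous blood-pressure data with known ground truth.

Two levels of simulation are provided:

* **Waveform level** — per-beat systolic/diastolic amplitudes are drawn from
  a generative model (subject offset + low-frequency ~0.1 Hz Mayer-wave
  oscillation + respiratory oscillation + AR(1) beat-to-beat innovation) and
  rendered into a 100 Hz arterial-pressure trace with a stylized pulse
  morphology including a dicrotic notch. Motion artifacts can be injected as
  transient pressure excursions. Ground truth (beat times, amplitudes,
  artifact intervals) is retained so the delineation/metrics pipeline can be
  validated end to end.

* **Metric level** — per-participant, per-session values of each derived
  cardiovascular parameter are drawn directly from a two-session
  variance-components model (subject effect + within-subject noise) with a
  known true intraclass correlation per metric. This mode is exact and fast
  and is used to validate the reliability estimators.

All randomness flows through a single :class:`numpy.random.Generator` derived
from the config seed; nothing touches global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateConfigError, UnsupportedDesignError

__all__ = [
    "BeatTruth",
    "WaveformSimConfig",
    "CohortSimConfig",
    "METRIC_COMPONENT_DEFAULTS",
    "variance_components_from_icc",
    "simulate_beat_sequence",
    "render_waveform",
    "inject_artifacts",
    "simulate_metric_cohort",
    "simulate_waveform_cohort",
    "simulate_cohort",
]


@dataclass(frozen=True)
class BeatTruth:
    """Ground-truth description of a single cardiac cycle."""

    beat_index: int
    peak_time: float  # s, systolic peak
    sbp: float        # mmHg
    trough_time: float  # s, diastolic trough following the peak
    dbp: float        # mmHg


@dataclass
class WaveformSimConfig:
    """Parameters of the waveform-level generative model.

    Defaults emulate a resting older adult measured with a noninvasive
    continuous finger-cuff device: mean SBP/DBP around 133/77 mmHg, heart
    rate near 61 bpm, a ~0.1 Hz low-frequency (Mayer-wave) oscillation that
    dominates beat-to-beat SBP dispersion, a respiratory oscillation near
    0.25 Hz, and an AR(1) innovation for true beat-to-beat changes. With the
    default amplitudes the per-beat SBP standard deviation is ~5 mmHg and the
    successive-difference (ARV) level ~1.7 mmHg.
    """

    duration: float = 420.0       # s; two sequential 7-minute windows per visit
    fs: float = 100.0             # Hz
    hr_mean: float = 60.65        # bpm
    hr_sd: float = 3.0            # bpm, beat-to-beat
    sbp_mean: float = 132.65      # mmHg
    dbp_mean: float = 77.42       # mmHg
    innovation_sd: float = 1.5    # mmHg, AR(1) driving noise
    ar_coefficient: float = 0.4   # unitless, in [0, 1)
    lf_amplitude: float = 6.5     # mmHg, Mayer-wave component
    lf_frequency: float = 0.1     # Hz
    resp_amplitude: float = 1.5   # mmHg
    resp_frequency: float = 0.25  # Hz
    notch_depth: float = 0.25     # fraction of pulse pressure, in [0, 1)
    artifact_rate: float = 0.0    # events / minute
    artifact_magnitude: float = 150.0  # mmHg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise DegenerateConfigError("duration and fs must be positive")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise DegenerateConfigError(
                f"duration*fs = {n} is not a whole number of samples"
            )
        if self.sbp_mean <= self.dbp_mean:
            raise DegenerateConfigError("sbp_mean must exceed dbp_mean")
        if not (0 <= self.ar_coefficient < 1):
            raise DegenerateConfigError("ar_coefficient must lie in [0, 1)")
        if not (0 <= self.notch_depth < 1):
            raise DegenerateConfigError("notch_depth must lie in [0, 1)")
        for name in ("hr_sd", "innovation_sd", "lf_amplitude", "resp_amplitude",
                     "artifact_rate", "artifact_magnitude"):
            if getattr(self, name) < 0:
                raise DegenerateConfigError(f"{name} must be non-negative")

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.fs)


def _ar1_series(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) with innovation sd `sd` and coefficient `phi`."""
    if sd == 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd / math.sqrt(1.0 - phi * phi))
    eps = rng.normal(0.0, sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def simulate_beat_sequence(
    config: WaveformSimConfig,
    subject_offset: float = 0.0,
    *,
    dbp_subject_offset: float | None = None,
    rng: np.random.Generator | None = None,
) -> list[BeatTruth]:
    """Draw per-beat peak/trough times and amplitudes.

    Per-beat SBP is ``sbp_mean + subject_offset + LF sine + respiratory sine
    + AR(1) innovation``; DBP is built the same way around ``dbp_mean`` with
    its own independent AR(1) stream. The oscillatory components get random
    phases so that repeated sessions of the same subject differ through the
    low-frequency phase and the innovations, as repeated recordings do.

    Parameters
    ----------
    subject_offset : mmHg added to every systolic amplitude (subject effect).
    dbp_subject_offset : mmHg added to diastolic amplitudes; defaults to
        ``subject_offset``.
    rng : generator to use; defaults to one seeded from ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if dbp_subject_offset is None:
        dbp_subject_offset = subject_offset

    # Inter-beat intervals: per-beat heart rate ~ N(hr_mean, hr_sd), floored
    # well away from zero so the interval stays finite.
    mean_interval = 60.0 / config.hr_mean
    peak_times: list[float] = []
    t = 0.4 * mean_interval  # first systolic peak shortly after t0
    # Stop early enough that the final pulse decays inside the record and
    # its rendered peak is a proper local maximum.
    while t < config.duration - 0.6 * mean_interval:
        peak_times.append(t)
        hr = config.hr_mean if config.hr_sd == 0 else max(
            20.0, rng.normal(config.hr_mean, config.hr_sd))
        t += 60.0 / hr
    n = len(peak_times)
    if n < 2:
        raise DegenerateConfigError(
            f"duration {config.duration}s at {config.hr_mean} bpm yields {n} beat(s); "
            "need at least 2"
        )
    tp = np.asarray(peak_times)

    lf_phase = rng.uniform(0, 2 * math.pi)
    resp_phase = rng.uniform(0, 2 * math.pi)
    lf = config.lf_amplitude * np.sin(2 * math.pi * config.lf_frequency * tp + lf_phase)
    resp = config.resp_amplitude * np.sin(
        2 * math.pi * config.resp_frequency * tp + resp_phase)

    sbp = (config.sbp_mean + subject_offset + lf + resp
           + _ar1_series(rng, n, config.innovation_sd, config.ar_coefficient))
    dbp = (config.dbp_mean + dbp_subject_offset + lf + resp
           + _ar1_series(rng, n, config.innovation_sd, config.ar_coefficient))
    # Keep a physiological pulse pressure even in noise tails.
    dbp = np.minimum(dbp, sbp - 10.0)

    intervals = np.diff(tp)
    median_interval = float(np.median(intervals))
    beats = []
    for i in range(n):
        gap = intervals[i] if i < n - 1 else median_interval
        trough_time = min(tp[i] + 0.85 * gap, config.duration)
        beats.append(BeatTruth(i, float(tp[i]), float(sbp[i]),
                               trough_time, float(dbp[i])))
    return beats


def _half_cosine(p0: float, p1: float, u: np.ndarray) -> np.ndarray:
    """Ease from p0 (u=0) to p1 (u=1) with zero slope at both ends."""
    return p0 + (p1 - p0) * 0.5 * (1.0 - np.cos(math.pi * u))


def _fill_pulse_segment(
    pressure: np.ndarray,
    t: np.ndarray,
    t_start: float,
    t_end: float,
    sbp0: float,
    dbp0: float,
    sbp1: float,
    trough_time: float,
    notch_depth: float,
) -> None:
    """Render one inter-peak span [t_start, t_end] in place.

    Morphology: fast systolic decay from the peak to a shoulder at
    dbp + 0.25*PP, an optional dicrotic bump of height notch_depth*PP riding
    on the shoulder ~30% of the beat into the cycle, a slow diastolic decay
    to the trough (exactly dbp), then the upstroke of the next beat. Every
    piece has zero slope at its ends so sampled extrema match the analytic
    sbp/dbp to well under 0.5 mmHg at 100 Hz.
    """
    sel = (t >= t_start) & (t < t_end)
    if not sel.any():
        return
    tau = t[sel] - t_start
    T = t_end - t_start
    pp = sbp0 - dbp0
    shoulder = dbp0 + 0.25 * pp
    # The dicrotic notch tracks systolic ejection time (~300 ms), so its
    # timing scales with the cycle only up to ~1 s and saturates beyond.
    T_eff = min(T, 1.0)
    t_notch = 0.24 * T_eff      # start of the dicrotic segment
    notch_w = 0.12 * T_eff      # bump peaks at t_notch + notch_w/2 = 0.30*T_eff
    t_trough = trough_time - t_start
    # Guard pathological geometry (very short beats).
    t_trough = max(t_trough, t_notch + notch_w + 1e-9)

    out = np.empty_like(tau)
    m1 = tau < t_notch
    out[m1] = _half_cosine(sbp0, shoulder, tau[m1] / t_notch)
    m2 = (tau >= t_notch) & (tau < t_notch + notch_w)
    u = (tau[m2] - t_notch) / notch_w
    out[m2] = shoulder + notch_depth * pp * np.sin(math.pi * u) ** 2
    m3 = (tau >= t_notch + notch_w) & (tau < t_trough)
    u = (tau[m3] - t_notch - notch_w) / (t_trough - t_notch - notch_w)
    out[m3] = _half_cosine(shoulder, dbp0, u)
    m4 = tau >= t_trough
    u = (tau[m4] - t_trough) / max(T - t_trough, 1e-9)
    out[m4] = _half_cosine(dbp0, sbp1, u)
    pressure[sel] = out


def render_waveform(beats: list[BeatTruth], config: WaveformSimConfig):
    """Render a beat sequence into a uniformly sampled pressure trace.

    Returns a :class:`pulsevar.beats.BPWaveform` sampled at ``config.fs``
    over ``config.duration``. The rendered maximum of each beat equals its
    true systolic amplitude and the minimum between consecutive peaks equals
    the true diastolic amplitude, both to within 0.5 mmHg.
    """
    from .beats import BPWaveform  # deferred to avoid an import cycle

    if len(beats) < 2:
        raise DegenerateConfigError("need at least 2 beats to render a waveform")
    t = np.arange(config.n_samples) / config.fs
    pressure = np.empty(config.n_samples)

    first = beats[0]
    # Lead-in: rise from the first beat's diastolic level to its peak.
    sel = t < first.peak_time
    if sel.any():
        u = t[sel] / first.peak_time
        pressure[sel] = _half_cosine(first.dbp, first.sbp, u)

    for b, nxt in zip(beats[:-1], beats[1:]):
        _fill_pulse_segment(pressure, t, b.peak_time, nxt.peak_time,
                            b.sbp, b.dbp, nxt.sbp, b.trough_time,
                            config.notch_depth)
    last = beats[-1]
    # Tail: decay from the last peak toward its diastolic level.
    sel = t >= last.peak_time
    if sel.any():
        tail_end = max(config.duration, last.trough_time + 1e-6)
        _fill_pulse_segment(pressure, t, last.peak_time, tail_end,
                            last.sbp, last.dbp, last.dbp,
                            min(last.trough_time, tail_end - 1e-9),
                            config.notch_depth)
    return BPWaveform(samples=pressure, fs=config.fs, t0=0.0)


def inject_artifacts(
    waveform,
    config: WaveformSimConfig,
    *,
    rng: np.random.Generator | None = None,
):
    """Superimpose Poisson-placed motion-artifact excursions.

    Events arrive at ``artifact_rate`` per minute; each lasts 0.5–3 s and
    adds a half-sine-squared pressure excursion of ``artifact_magnitude``
    mmHg. Returns ``(waveform_with_artifacts, intervals)`` where intervals is
    a list of ``(start_s, end_s)`` ground-truth spans (empty for rate 0, in
    which case the input waveform is returned unchanged).

    The spectral/temporal shape of real motion artifacts is not documented
    for this device class; this smooth additive excursion is a deliberately
    simple placeholder whose amplitude, not shape, drives the QC rules.
    """
    if config.artifact_rate == 0:
        return waveform, []
    if rng is None:
        rng = np.random.default_rng(config.seed)
    duration = len(waveform.samples) / waveform.fs
    n_events = rng.poisson(config.artifact_rate * duration / 60.0)
    samples = waveform.samples.copy()
    t = np.arange(len(samples)) / waveform.fs
    intervals: list[tuple[float, float]] = []
    for _ in range(n_events):
        dur = rng.uniform(0.5, 3.0)
        start = rng.uniform(0.0, max(duration - dur, 0.0))
        sel = (t >= start) & (t < start + dur)
        u = (t[sel] - start) / dur
        samples[sel] += config.artifact_magnitude * np.sin(math.pi * u) ** 2
        intervals.append((start, start + dur))
    intervals.sort()
    return type(waveform)(samples=samples, fs=waveform.fs, t0=waveform.t0), intervals


# ---------------------------------------------------------------------------
# Cohort-level simulation
# ---------------------------------------------------------------------------

def variance_components_from_icc(total_sd: float, icc: float) -> tuple[float, float]:
    """Split a total SD into (between_sd, within_sd) for a given true ICC."""
    if not (0.0 <= icc <= 1.0):
        raise ValueError("icc must lie in [0, 1]")
    between = total_sd * math.sqrt(icc)
    within = total_sd * math.sqrt(1.0 - icc)
    return between, within


#: Default per-metric variance structure for the metric-level cohort model:
#: (grand mean, total SD, true ICC). The levels emulate a cohort of
#: community-dwelling older adults measured twice in one session with a
#: noninvasive continuous BP monitor: heart rate ~60 bpm, BP ~132/77 mmHg,
#: beat-to-beat SBP SD ~5 mmHg, high reliability for mean hemodynamics,
#: good reliability for dispersion/sequence BPV metrics, moderate for the
#: max-minus-min instability index.
METRIC_COMPONENT_DEFAULTS: dict[str, tuple[float, float, float]] = {
    "hr":        (60.42, 10.31, 0.98),
    "sbp_mean":  (132.28, 18.83, 0.96),
    "sbp_sd":    (5.36, 2.40, 0.76),
    "sbp_cv":    (4.06, 1.81, 0.76),
    "sbp_vim":   (2.02, 0.40, 0.75),
    "sbp_arv":   (1.73, 1.01, 0.87),
    "delta_sbp": (33.70, 12.19, 0.53),
    "dbp_mean":  (77.49, 10.43, 0.97),
    "dbp_sd":    (3.01, 2.06, 0.77),
    "dbp_cv":    (4.03, 3.14, 0.79),
    "dbp_vim":   (2.30, 1.52, 0.73),
    "dbp_arv":   (1.95, 1.37, 0.82),
}


@dataclass
class CohortSimConfig:
    """Two-session cohort design with known variance components.

    ``metric_components`` maps metric name -> (mean, between_sd, within_sd).
    When omitted it is derived from :data:`METRIC_COMPONENT_DEFAULTS`.
    ``strata_components`` optionally overrides components per antihypertensive
    stratum (keys 0 and 1), e.g. to give medication users a different true
    ICC.
    """

    n_participants: int = 111
    sessions: int = 2
    metric_components: dict[str, tuple[float, float, float]] | None = None
    strata_components: dict[int, dict[str, tuple[float, float, float]]] = field(
        default_factory=dict)
    antihypertensive_fraction: float = 0.351
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sessions != 2:
            raise UnsupportedDesignError(
                f"only the two-session test-retest design is supported "
                f"(got sessions={self.sessions})")
        if self.n_participants < 2:
            raise DegenerateConfigError("n_participants must be >= 2")
        if not (0.0 <= self.antihypertensive_fraction <= 1.0):
            raise DegenerateConfigError(
                "antihypertensive_fraction must lie in [0, 1]")
        if self.metric_components is None:
            self.metric_components = {
                name: (mean, *variance_components_from_icc(sd, icc))
                for name, (mean, sd, icc) in METRIC_COMPONENT_DEFAULTS.items()
            }

    def true_icc(self, metric: str, stratum: int | None = None) -> float:
        comps = self.metric_components
        if stratum is not None and stratum in self.strata_components \
                and metric in self.strata_components[stratum]:
            comps = self.strata_components[stratum]
        _, b, w = comps[metric]
        total = b * b + w * w
        return 0.0 if total == 0 else b * b / total


def _assign_strata(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    n_treated = round(n * fraction)
    strata = np.zeros(n, dtype=int)
    strata[:n_treated] = 1
    rng.shuffle(strata)
    return strata


def simulate_metric_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Draw paired session metric values directly from the variance model.

    Returns a long DataFrame with columns ``participant_id``, ``session``,
    ``antihypertensive`` and one column per metric. Per metric, participant
    *i* has a latent subject value ``mean + N(0, between_sd)`` and each
    session observes it plus independent ``N(0, within_sd)`` noise, giving a
    true ICC of ``between² / (between² + within²)``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    strata = _assign_strata(rng, n, config.antihypertensive_fraction)
    rows: dict[str, np.ndarray] = {}
    for metric, (mean, b_sd, w_sd) in config.metric_components.items():
        means = np.full(n, float(mean))
        b = np.full(n, float(b_sd))
        w = np.full(n, float(w_sd))
        for stratum, overrides in config.strata_components.items():
            if metric in overrides:
                sel = strata == stratum
                m2, b2, w2 = overrides[metric]
                means[sel], b[sel], w[sel] = m2, b2, w2
        subject = means + rng.normal(0.0, 1.0, size=n) * b
        s1 = subject + rng.normal(0.0, 1.0, size=n) * w
        s2 = subject + rng.normal(0.0, 1.0, size=n) * w
        rows[metric] = np.concatenate([s1, s2])

    ids = [f"P{i:03d}" for i in range(1, n + 1)]
    out = pd.DataFrame({
        "participant_id": ids * 2,
        "session": [1] * n + [2] * n,
        "antihypertensive": np.tile(strata, 2),
    })
    for metric, values in rows.items():
        out[metric] = values
    return out


def simulate_waveform_cohort(
    config: CohortSimConfig,
    out_dir: str | Path,
    waveform_config: WaveformSimConfig | None = None,
    *,
    sbp_between_sd: float = 16.9,
    dbp_between_sd: float = 10.4,
) -> pd.DataFrame:
    """Simulate a cohort at the waveform level and write it to disk.

    Each participant gets a latent SBP/DBP offset (between-subject spread
    ``sbp_between_sd``/``dbp_between_sd``); the two sessions share the
    offsets and differ only through innovations and oscillation phases.
    Writes per-session waveform CSVs, per-session beat-truth CSVs, artifact
    interval CSVs (when artifacts are on) and a cohort manifest CSV; returns
    the manifest as a DataFrame.
    """
    from .io import write_waveform_csv

    if waveform_config is None:
        waveform_config = WaveformSimConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    strata = _assign_strata(rng, config.n_participants, config.antihypertensive_fraction)

    records = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        sbp_off = rng.normal(0.0, sbp_between_sd)
        dbp_off = rng.normal(0.0, dbp_between_sd)
        for session in (1, 2):
            beats = simulate_beat_sequence(
                waveform_config, sbp_off, dbp_subject_offset=dbp_off, rng=rng)
            wf = render_waveform(beats, waveform_config)
            wf, artifacts = inject_artifacts(wf, waveform_config, rng=rng)
            wf_path = out_dir / f"{pid}_s{session}_waveform.csv"
            write_waveform_csv(wf, wf_path)
            truth = pd.DataFrame({
                "beat_index": [b.beat_index for b in beats],
                "peak_time_s": [b.peak_time for b in beats],
                "sbp_mmhg": [b.sbp for b in beats],
                "trough_time_s": [b.trough_time for b in beats],
                "dbp_mmhg": [b.dbp for b in beats],
            })
            truth.to_csv(out_dir / f"{pid}_s{session}_truth.csv", index=False)
            if artifacts:
                pd.DataFrame(artifacts, columns=["start_s", "end_s"]).to_csv(
                    out_dir / f"{pid}_s{session}_artifacts.csv", index=False)
            records.append({
                "participant_id": pid,
                "session": session,
                "waveform_path": wf_path.name,
                "antihypertensive": int(strata[i]),
            })
    manifest = pd.DataFrame(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def simulate_cohort(
    config: CohortSimConfig,
    *,
    mode: str = "metric",
    out_dir: str | Path | None = None,
    waveform_config: WaveformSimConfig | None = None,
):
    """Dispatch to metric-level or waveform-level cohort simulation."""
    if mode == "metric":
        return simulate_metric_cohort(config)
    if mode == "waveform":
        if out_dir is None:
            raise ValueError("waveform mode requires out_dir")
        return simulate_waveform_cohort(config, out_dir, waveform_config)
    raise ValueError(f"unknown simulation mode {mode!r}")
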