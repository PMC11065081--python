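"""End-to-end orchestration: waveforms -> beats -> metrics -> reliability.

``run`` takes a cohort manifest (or simulates one), delineates every
session, applies the >10%-exclusion QC rule, fits the VIM exponent across
the cohort, writes the per-session metrics table, and emits three report
tables: session means with paired-t p-values, overall reliability, and
reliability stratified by antihypertensive use — plus QC sidecars and a
run-metadata JSON. Outputs are byte-identical for identical config+seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beats import DetectionParams, delineate
from .errors import EmptyDetectionError, PulsevarError
from .io import read_manifest, read_waveform_csv, write_beat_annotations, write_qc_sidecar
from .metrics import METRIC_ORDER, compute_session_metrics, fit_vim_exponent, metric_vim
from .reliability import reliability_table, results_to_frame

log = logging.getLogger("pulsevar")

__all__ = ["RunConfig", "RunResult", "run", "add_vim_columns", "session_means_table"]


@dataclass
class RunConfig:
    """Pipeline configuration (serialised into the run-metadata JSON)."""

    manifest: str | Path | None = None   # existing cohort; None -> simulate
    output_dir: str | Path = "pulsevar_run"
    detection: DetectionParams = field(default_factory=DetectionParams)
    vim_fit_scope: str = "per-session"   # or "pooled"
    icc_form: str = "2,1"
    srd_factor: str = "sqrt2"
    window: float = 420.0                # s analysed per session
    max_rejected_fraction: float = 0.5   # abort threshold for QC rejections
    simulate_n: int = 20                 # cohort size when simulating
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.vim_fit_scope not in ("per-session", "pooled"):
            raise ValueError("vim_fit_scope must be 'per-session' or 'pooled'")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["manifest"] = None if self.manifest is None else str(self.manifest)
        d["output_dir"] = str(self.output_dir)
        return d


@dataclass
class RunResult:
    metrics_table: pd.DataFrame
    session_means: pd.DataFrame
    reliability_overall: pd.DataFrame
    reliability_stratified: pd.DataFrame
    n_sessions: int
    n_rejected: int
    rejected_sessions: list[str]
    output_dir: Path


def add_vim_columns(df: pd.DataFrame, scope: str = "per-session") -> pd.DataFrame:
    """Fit the VIM power-law exponent across participants and fill
    ``sbp_vim``/``dbp_vim``.

    ``scope="per-session"`` fits each session's sd-vs-mean relation
    separately; ``"pooled"`` fits one relation over all rows.
    """
    df = df.copy()
    for channel in ("sbp", "dbp"):
        sd_col, mean_col, vim_col = f"{channel}_sd", f"{channel}_mean", f"{channel}_vim"
        if scope == "pooled":
            fit = fit_vim_exponent(df[sd_col], df[mean_col], fit_scope="pooled")
            df[vim_col] = [metric_vim(s, m, fit)
                           for s, m in zip(df[sd_col], df[mean_col])]
        else:
            for session, sub in df.groupby("session"):
                fit = fit_vim_exponent(sub[sd_col], sub[mean_col],
                                       fit_scope="per-session")
                df.loc[sub.index, vim_col] = [
                    metric_vim(s, m, fit)
                    for s, m in zip(sub[sd_col], sub[mean_col])]
    return df


def session_means_table(metrics_table: pd.DataFrame) -> pd.DataFrame:
    """Per-metric session means ± SD with the paired-t p-value."""
    from .reliability import PairedMeasurements, paired_t

    rows = []
    for metric in [m for m in METRIC_ORDER if m in metrics_table.columns]:
        wide = metrics_table.pivot_table(index="participant_id", columns="session",
                                         values=metric, aggfunc="first").dropna()
        if len(wide) < 2 or 1 not in wide or 2 not in wide:
            continue
        pairs = PairedMeasurements(metric, wide[1].to_numpy(), wide[2].to_numpy())
        _, p = paired_t(pairs)
        rows.append({
            "metric": metric,
            "session1_mean": wide[1].mean(), "session1_sd": wide[1].std(ddof=1),
            "session2_mean": wide[2].mean(), "session2_sd": wide[2].std(ddof=1),
            "n": len(wide), "p_value": p,
        })
    return pd.DataFrame(rows)


def _simulate_input(config: RunConfig, out_dir: Path) -> Path:
    from .simulate import CohortSimConfig, simulate_waveform_cohort

    sim_dir = out_dir / "simulated"
    cohort = CohortSimConfig(n_participants=config.simulate_n, seed=config.seed)
    simulate_waveform_cohort(cohort, sim_dir)
    return sim_dir / "manifest.csv"


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write the report bundle."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    qc_dir = out_dir / "qc"
    qc_dir.mkdir(exist_ok=True)

    manifest_path = (Path(config.manifest) if config.manifest is not None
                     else _simulate_input(config, out_dir))
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent

    rows = []
    rejected: list[str] = []
    n_sessions = 0
    for rec in manifest.itertuples(index=False):
        n_sessions += 1
        label = f"{rec.participant_id}_s{rec.session}"
        wf_path = Path(rec.waveform_path)
        if not wf_path.is_absolute():
            wf_path = base / wf_path
        try:
            wf = read_waveform_csv(wf_path)
        except (OSError, ValueError) as exc:
            raise PulsevarError(f"unreadable waveform {wf_path}: {exc}") from exc
        n_keep = round(config.window * wf.fs)
        if len(wf.samples) > n_keep:
            wf = type(wf)(wf.samples[:n_keep], wf.fs, wf.t0)
        elif len(wf.samples) < n_keep:
            log.warning("%s: only %.1f s available (< %.0f s window); analysing whole record",
                        label, len(wf.samples) / wf.fs, config.window)
        try:
            beats = delineate(wf, config.detection)
        except EmptyDetectionError as exc:
            log.warning("%s: delineation failed (%s); session rejected", label, exc)
            rejected.append(label)
            continue
        write_beat_annotations(beats, qc_dir / f"{label}_beats.csv")
        write_qc_sidecar(beats, config.detection, qc_dir / f"{label}_qc.json")
        log.info("%s: %d beats, excluded_fraction=%.3f, accepted=%s",
                 label, beats.n_beats, beats.excluded_fraction, beats.accepted)
        if not beats.accepted:
            rejected.append(label)
            continue
        sm = compute_session_metrics(beats, participant_id=rec.participant_id,
                                     session=int(rec.session))
        row = sm.as_dict()
        row["antihypertensive"] = int(rec.antihypertensive)
        rows.append(row)

    if n_sessions == 0:
        raise PulsevarError("manifest contains no sessions")
    if len(rejected) / n_sessions > config.max_rejected_fraction:
        raise PulsevarError(
            f"{len(rejected)}/{n_sessions} sessions rejected by QC "
            f"(> {config.max_rejected_fraction:.0%}); aborting")

    metrics_table = pd.DataFrame(rows)
    # Keep only participants with both sessions surviving QC.
    counts = metrics_table.groupby("participant_id")["session"].nunique()
    complete = counts[counts == 2].index
    dropped = sorted(set(metrics_table["participant_id"]) - set(complete))
    if dropped:
        log.info("dropping %d participant(s) without both sessions: %s",
                 len(dropped), ", ".join(dropped))
    metrics_table = metrics_table[metrics_table["participant_id"].isin(complete)]
    metrics_table = metrics_table.sort_values(["participant_id", "session"])
    metrics_table = add_vim_columns(metrics_table, config.vim_fit_scope)
    metrics_table.to_csv(out_dir / "metrics_table.csv", index=False,
                         float_format="%.6f")

    means = session_means_table(metrics_table)
    means.to_csv(out_dir / "session_means.csv", index=False, float_format="%.6f")

    overall = results_to_frame(reliability_table(
        metrics_table, icc_form=config.icc_form, srd_factor=config.srd_factor))
    overall.to_csv(out_dir / "reliability_overall.csv", index=False,
                   float_format="%.6f")
    stratified = results_to_frame(reliability_table(
        metrics_table, stratify_by="antihypertensive",
        icc_form=config.icc_form, srd_factor=config.srd_factor))
    stratified.to_csv(out_dir / "reliability_stratified.csv", index=False,
                      float_format="%.6f")

    metadata = {
        "pulsevar_version": __version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "n_sessions": n_sessions,
        "n_rejected": len(rejected),
        "rejected_sessions": rejected,
        "n_participants_analysed": int(metrics_table["participant_id"].nunique()),
    }
    (out_dir / "run_metadata.json").write_text(json.dumps(metadata, indent=2))

    return RunResult(
        metrics_table=metrics_table,
        session_means=means,
        reliability_overall=overall,
        reliability_stratified=stratified,
        n_sessions=n_sessions,
        n_rejected=len(rejected),
        rejected_sessions=rejected,
        output_dir=out_dir,
    )
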