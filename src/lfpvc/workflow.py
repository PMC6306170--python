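"""End-to-end pipeline: simulate → score → spectra → coherence → bursts →
lags → SNR curve → theory table, with a JSON report of all scalar results.

A single global seed is expanded deterministically (numpy SeedSequence) into
per-stage child seeds, so a stored config plus seed reproduces every output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

from . import connectivity, events, forward, io, scoring, spectral
from .simulate import (
    DEFAULT_COUNTS,
    SourceParams,
    build_hypnogram,
    build_sources,
    render,
)

__all__ = ["PipelineConfig", "run_all", "REPORT_VERSION"]

log = logging.getLogger("lfpvc")

REPORT_VERSION = 1


@dataclass
class PipelineConfig:
    """Serializable configuration of the full pipeline."""

    counts: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    epoch_length: float = 15.0
    seed: int = 0
    emg_amp: float = 100e-6

    # analysis parameters
    burst_band: Tuple[float, float] = (10.0, 14.0)
    coherence_segment_s: float = 5.0
    lag_max: float = 0.1
    snr_curve_levels: Tuple[float, ...] = (2.0, 5.0, 10.0, 15.0, 20.0, 30.0)
    snr_curve_segments: int = connectivity.PINNED_DEFAULT_SEGMENTS

    # generator parameter overrides (field name -> value)
    generator: Dict = field(default_factory=dict)

    def source_params(self) -> SourceParams:
        return SourceParams(**self.generator) if self.generator else SourceParams()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("burst_band", "snr_curve_levels"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is carried in the message."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tagged with stage context
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %-12s %.2f s", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_all(config: Optional[PipelineConfig] = None, outdir=None) -> Dict:
    """Run the full analysis chain on a generated session.

    Returns the report dictionary (also written to ``report.json`` inside
    ``outdir`` when given, along with the session files and CSV outputs).
    """
    config = config or PipelineConfig()
    params = config.source_params()
    ss = np.random.SeedSequence(config.seed)
    s_hyp, s_src, s_render, s_curve, s_ctrl = ss.spawn(5)

    report: Dict = {
        "version": REPORT_VERSION,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
    }

    # --- simulate ----------------------------------------------------------
    @_stage("simulate")
    def _simulate():
        hyp = build_hypnogram(config.counts, config.epoch_length, seed=s_hyp)
        ens = build_sources(hyp, params, seed=s_src)
        ses = render(ens, params.montage, seed=s_render, emg_amp=config.emg_amp)
        ses.seed = config.seed
        return hyp, ens, ses

    hypnogram, ensemble, session = _simulate()
    report["session"] = {
        "duration_s": session.duration,
        "fs": session.fs,
        "epoch_counts": hypnogram.counts(),
        "n_common_bursts": len(session.common_bursts()),
    }

    if outdir is not None:
        outdir = Path(outdir)
        io.write_session(session, outdir)

    # --- scoring -----------------------------------------------------------
    @_stage("scoring")
    def _score():
        scored, thr = scoring.score_states(
            session.rr("CA1"), session.channel("EMG"), session.fs,
            config.epoch_length,
        )
        return scored, thr

    scored, thresholds = _score()
    report["scoring"] = {
        "agreement": scoring.agreement(scored, hypnogram),
        "thresholds": thresholds,
    }

    # --- spectra -----------------------------------------------------------
    @_stage("spectra")
    def _spectra():
        out = {}
        for state in ("NREM", "REM"):
            for area in ("CA1", "PFC"):
                for mode in ("RR", "DR"):
                    ps = spectral.state_spectrum(session, state, area, mode)
                    out[f"{state}_{area}_{mode}"] = ps
        return out

    spectra = _spectra()
    rem_rr = spectra["REM_CA1_RR"].total_power(0.5, 100.0)
    rem_dr = spectra["REM_CA1_DR"].total_power(0.5, 100.0)
    report["spectra"] = {
        "rem_ca1_rr_total_uv2": rem_rr,
        "rem_ca1_dr_total_uv2": rem_dr,
        "rem_ca1_rr_dr_power_ratio": rem_rr / rem_dr,
        "rem_ca1_dr_peak_hz": spectra["REM_CA1_DR"].peak_frequency(4.0, 20.0),
    }
    if outdir is not None:
        import pandas as pd
        frames = {
            key: pd.DataFrame({"frequency_hz": ps.frequencies, "power": ps.power})
            for key, ps in spectra.items()
        }
        for key, frame in frames.items():
            frame.to_csv(outdir / f"spectrum_{key}.csv", index=False)

    # --- sliding-window coherence ------------------------------------------
    @_stage("coherence")
    def _coherence():
        out = {}
        for state in ("NREM", "REM"):
            for mode in ("RR", "DR"):
                out[f"{state}_{mode}"] = connectivity.state_coherence(
                    session, state, mode, segment_s=config.coherence_segment_s
                )
        out["REM_RR_imag"] = connectivity.state_coherence(
            session, "REM", "RR", variant="imaginary",
            segment_s=config.coherence_segment_s,
        )
        return out

    coh = _coherence()
    lo, hi = config.burst_band
    report["coherence"] = {
        "rem_dr_sigma_band": coh["REM_DR"].band_mean(lo, hi),
        "rem_rr_sigma_band": coh["REM_RR"].band_mean(lo, hi),
        "rem_rr_theta": coh["REM_RR"].at(params.theta_freq),
        "rem_rr_theta_imag": coh["REM_RR_imag"].at(params.theta_freq),
    }

    # --- burst detection ----------------------------------------------------
    @_stage("bursts")
    def _bursts():
        mask = hypnogram.state_mask("REM", session.fs, session.n_samples)
        det = events.detect_bursts(
            session.dr("CA1"), session.fs, band=config.burst_band,
            channel="CA1_DR", mask=mask,
        )
        det_pfc = events.detect_bursts(
            session.dr("PFC"), session.fs, band=config.burst_band,
            channel="PFC_DR", mask=mask,
        )
        return det, det_pfc

    detected, detected_pfc = _bursts()
    truth = session.common_bursts()
    sens, prec, _ = events.match_events(detected, truth)
    report["bursts"] = {
        "n_detected_ca1": len(detected),
        "n_detected_pfc": len(detected_pfc),
        "n_truth": len(truth),
        "sensitivity": sens,
        "precision": prec,
    }

    # --- burst-triggered coherence -----------------------------------------
    @_stage("burst_coherence")
    def _btc():
        btc_ca1 = connectivity.burst_triggered_coherence(
            session, detected, trigger_area="CA1", mode="DR"
        )
        btc_pfc = connectivity.burst_triggered_coherence(
            session, detected_pfc, trigger_area="PFC", mode="DR"
        )
        ctrl = connectivity.burst_triggered_coherence(
            session,
            connectivity.random_windows(session, len(detected), "REM", seed=s_ctrl),
            trigger_area="CA1", mode="DR",
        )
        return btc_ca1, btc_pfc, ctrl

    btc_ca1, btc_pfc, btc_ctrl = _btc()
    report["burst_coherence"] = {
        "dr_sigma_triggered_ca1": btc_ca1.band_mean(lo, hi),
        "dr_sigma_triggered_pfc": btc_pfc.band_mean(lo, hi),
        "dr_sigma_random_windows": btc_ctrl.band_mean(lo, hi),
        "dr_sigma_sliding": coh["REM_DR"].band_mean(lo, hi),
    }

    # --- lag distributions --------------------------------------------------
    @_stage("lags")
    def _lags():
        dr = connectivity.lag_distribution(
            session, detected, mode="DR", max_lag=config.lag_max
        )
        rr = connectivity.lag_distribution(
            session, detected, mode="RR", max_lag=config.lag_max
        )
        return dr, rr

    lag_dr, lag_rr = _lags()
    report["lags"] = {
        "dr_median_ms": lag_dr.median * 1e3,
        "rr_median_ms": lag_rr.median * 1e3,
        "dr_iqr_ms": lag_dr.iqr * 1e3,
        "rr_iqr_ms": lag_rr.iqr * 1e3,
        "n_events": int(len(lag_dr.lags)),
        "dr_mean_peak_corr": float(np.mean(np.abs(lag_dr.correlations))),
    }
    if outdir is not None:
        import pandas as pd
        pd.DataFrame(
            {"lag_s": lag_dr.lags, "corr": lag_dr.correlations}
        ).to_csv(outdir / "lags_dr.csv", index=False)
        pd.DataFrame(
            {"lag_s": lag_rr.lags, "corr": lag_rr.correlations}
        ).to_csv(outdir / "lags_rr.csv", index=False)

    # --- coherence vs noise -------------------------------------------------
    @_stage("snr_curve")
    def _curve():
        curve = connectivity.coherence_vs_noise(
            config.snr_curve_levels, n_segments=config.snr_curve_segments,
            seed=s_curve,
        )
        a, rms = connectivity.fit_sech(curve)
        return curve, a, rms

    curve, sech_a, sech_rms = _curve()
    c10 = float(curve.loc[curve["snr_inv"] == 10.0, "coherence"].iloc[0]) \
        if (curve["snr_inv"] == 10.0).any() else None
    report["snr_curve"] = {
        "levels": list(map(float, curve["snr_inv"])),
        "coherence": list(map(float, curve["coherence"])),
        "coherence_at_10": c10,
        "sech_scale": sech_a,
        "sech_residual_rms": sech_rms,
    }
    if outdir is not None:
        curve.to_csv(outdir / "snr_curve.csv", index=False)

    # --- theory table -------------------------------------------------------
    @_stage("theory")
    def _theory():
        return {
            "gamma_10": float(forward.cmrr(10.0, 1.0)),
            "gamma_100": float(forward.cmrr(100.0, 1.0)),
            "snr_rr_6": float(forward.snr_rr(6.0, 1.0)),
            "snr_dr_6": float(forward.snr_dr(6.0, 1.0)),
            "snr_gain_6": float(forward.snr_gain(6.0, 1.0)),
            "snr_global_6_3d": int(forward.snr_global(6.0, 1.0, dims=3)),
            "gain_unity_ratio": forward.gain_unity_ratio(),
        }

    report["theory"] = _theory()

    if outdir is not None:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report
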