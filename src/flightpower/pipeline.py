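"""End-to-end orchestration: simulate -> kinematics -> aero -> power ->
moments -> partition/sweep -> scaling, in memory or over a run directory.

The directory protocol is plain CSV/YAML for inspectability; a manifest
records seeds, parameter hashes and output hashes so deterministic stages
can be verified bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aero as aero_mod
from . import kinematics as kin_mod
from . import momentum_balance as mom_mod
from . import muscle_tendon as mt_mod
from . import power_balance as pb_mod
from . import scaling as scaling_mod
from . import synthetic_data as syn_mod
from .util import span_average

log = logging.getLogger("flightpower")


# --------------------------------------------------------------------------
# in-memory analysis
# --------------------------------------------------------------------------

@dataclass
class FlightAnalysis:
    """All derived stages for one flight, on the common analysis grid."""

    recording: syn_mod.FlightRecording
    kin: kin_mod.WingbeatKinematics
    force_trace: aero_mod.ForceTrace
    aero_power: aero_mod.AeroPowerTrace
    wing_left: kin_mod.WingPointMassModel
    wing_right: kin_mod.WingPointMassModel
    body: kin_mod.BodyState
    muscle: pb_mod.MuscleState
    power: pb_mod.PowerDecomposition
    moments: mom_mod.MuscleMomentState
    wingbeat_index: int = 0

    @property
    def morphology(self) -> syn_mod.BirdMorphology:
        return self.recording.morphology

    def wingbeat(self, index: int | None = None):
        """(slice, downstroke mask, stroke fraction) for one full wingbeat."""
        if index is None:
            index = self.wingbeat_index
        a, _, b = self.kin.wingbeats[index]
        sl = slice(a, b)
        down = self.kin.phase_labels[sl] == "down"
        return sl, down, self.kin.stroke_fraction[sl]

    def partition(self, scenario: mt_mod.StorageScenario,
                  index: int | None = None) -> mt_mod.MusclePowerPartition:
        sl, down, _ = self.wingbeat(index)
        return mt_mod.partition_power(
            self.kin.time[sl], self.power.p_musc_total[sl], down,
            self._muscle_slice(sl), scenario)

    def _muscle_slice(self, sl: slice) -> pb_mod.MuscleState:
        m = self.muscle
        return pb_mod.MuscleState(
            time=m.time[sl], fiber_length=m.fiber_length[sl],
            rest_length=m.rest_length, strain=m.strain[sl],
            strain_rate=m.strain_rate[sl],
            shortening_velocity=m.shortening_velocity[sl],
            emg_envelope=m.emg_envelope[sl])

    def sweep(self, fractions, timings, profile: str = "flat_force",
              index: int | None = None) -> pd.DataFrame:
        sl, down, _ = self.wingbeat(index)
        return mt_mod.sweep_storage(
            self.kin.time[sl], self.power.p_musc_total[sl], down,
            self._muscle_slice(sl), fractions, timings, profile,
            pect_mass_total=self.power.pect_mass_total)

    def mean_positive_pect_power(self, scenario: mt_mod.StorageScenario,
                                 index: int | None = None) -> float:
        """Stroke-averaged positive pectoralis power, W per kg pectoralis."""
        sl, _, _ = self.wingbeat(index)
        part = self.partition(scenario, index)
        t = self.kin.time[sl]
        w = np.trapezoid(part.p_pect_generate, t) / (t[-1] - t[0])
        return w / self.power.pect_mass_total


def analyze_flight(rec: syn_mod.FlightRecording,
                   smoothing_parameter: float = 1e-3,
                   include_body_potential: bool = True) -> FlightAnalysis:
    """Run the full inverse-dynamics chain on one recording."""
    morph = rec.morphology
    kin = kin_mod.analyze_kinematics(rec.landmarks, morph, smoothing_parameter)
    force_trace, aero_power = aero_mod.analyze_aero(rec.forces, kin, morph)
    t = kin.time
    lm = kin.landmarks
    wing_left = kin_mod.build_point_mass_wing(
        morph, lm["shoulder"], lm["wrist"], lm["XP9"], t)
    mirror = np.array([1.0, -1.0, 1.0])
    wing_right = kin_mod.build_point_mass_wing(
        morph, lm["shoulder"] * mirror, lm["wrist"] * mirror,
        lm["XP9"] * mirror, t)
    body = kin_mod.build_body_state(morph, lm["back"], t)
    p_iner = pb_mod.inertial_power([wing_left, wing_right])
    p_body = pb_mod.body_power(body)
    if not include_body_potential:
        p_body = p_body - body.mass * 9.81 * body.velocity[:, 2]
    power = pb_mod.total_muscle_power(aero_power.p_aero_total, p_iner,
                                      p_body, t, morph)
    muscle = pb_mod.build_muscle_state(rec.muscle, morph, t)
    moments = mom_mod.required_muscle_moment(
        wing_left, force_trace.force_wing, lm["shoulder"], lm["XP9"])
    n_beats = len(kin.wingbeats)
    return FlightAnalysis(recording=rec, kin=kin, force_trace=force_trace,
                          aero_power=aero_power, wing_left=wing_left,
                          wing_right=wing_right, body=body, muscle=muscle,
                          power=power, moments=moments,
                          wingbeat_index=n_beats // 2)


def dove_analysis(seed: int = 0, n_wingbeats: int = 4,
                  params: syn_mod.GenerationParams | None = None
                  ) -> FlightAnalysis:
    """Convenience: generate and analyze the calibrated synthetic dove."""
    morph = syn_mod.make_morphology("dove")
    rec = syn_mod.generate_flight(morph, params, n_wingbeats=n_wingbeats,
                                  seed=seed)
    return analyze_flight(rec)


# --------------------------------------------------------------------------
# directory-based stages (CLI backend)
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    out_dir: str = "run"
    preset: str = "dove"
    seed: int = 0
    n_wingbeats: int = 4
    smoothing_parameter: float = 1e-3
    storage_fraction: float = 0.9
    storage_timing: float = 0.31
    storage_profile: str = "flat_force"
    sweep_fractions: list = field(default_factory=lambda: [0.0, 1.0, 0.05])
    sweep_timings: list = field(default_factory=lambda: [0.0, 0.5, 0.01])
    stages: list = field(default_factory=lambda: [
        "simulate", "kinematics", "aero", "power", "moments",
        "partition", "sweep"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _grid(bounds: list) -> np.ndarray:
    lo, hi, step = bounds
    return np.round(np.arange(lo, hi + step / 2, step), 10)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in dependency order; write a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    manifest = {"config": dataclasses.asdict(config), "outputs": {}}
    try:
        morph = syn_mod.make_morphology(config.preset)
        rec = syn_mod.generate_flight(morph, None, config.n_wingbeats,
                                      config.seed)
        if "simulate" in config.stages:
            log.info("stage simulate -> %s", out)
            syn_mod.write_recording(rec, out)
        analysis = analyze_flight(rec, config.smoothing_parameter)
        if "kinematics" in config.stages:
            log.info("stage kinematics")
            analysis.kin.to_frame().to_csv(out / "kinematics.csv", index=False)
        if "aero" in config.stages:
            log.info("stage aero")
            aero_mod.aero_frame(analysis.force_trace,
                                analysis.aero_power).to_csv(
                out / "aero.csv", index=False)
        if "power" in config.stages:
            log.info("stage power")
            analysis.power.to_frame().to_csv(out / "power.csv", index=False)
        if "moments" in config.stages:
            log.info("stage moments")
            _moments_frame(analysis).to_csv(out / "moments.csv", index=False)
        if "partition" in config.stages:
            log.info("stage partition")
            scenario = mt_mod.StorageScenario(config.storage_fraction,
                                              config.storage_timing,
                                              config.storage_profile)
            analysis.partition(scenario).to_frame().to_csv(
                out / "partition.csv", index=False)
        if "sweep" in config.stages:
            log.info("stage sweep")
            sweep = analysis.sweep(_grid(config.sweep_fractions),
                                   _grid(config.sweep_timings),
                                   config.storage_profile)
            sweep.to_csv(out / "sweep.csv", index=False)
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    for path in sorted(out.glob("*.csv")) + sorted(out.glob("*.yaml")):
        manifest["outputs"][path.name] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out


def _moments_frame(analysis: FlightAnalysis) -> pd.DataFrame:
    mom = analysis.moments
    lm = analysis.kin.landmarks
    hum = mom_mod.humerus_axis(lm["shoulder"], lm["wrist"])
    sl, down, _ = analysis.wingbeat()
    down_full = analysis.kin.phase_labels == "down"
    f_mag, _ = pb_mod.pectoralis_force_from_power(
        0.5 * np.maximum(analysis.power.p_musc_total, 0.0),
        analysis.muscle.shortening_velocity)
    theta_p = mom_mod.pull_angle(mom.muscle_moment, hum, 2.0 * f_mag)
    frame = mom_mod.body_frame(lm["back"], lm["head"])
    pull = mom_mod.pull_direction_and_stress(
        mom.muscle_moment, hum, analysis.morphology.pcsa,
        frame=frame, downstroke=down_full, time=mom.time)
    df = pd.DataFrame({"time": mom.time})
    for i, ax in enumerate("xyz"):
        df[f"M_musc_{ax}"] = mom.muscle_moment[:, i]
        df[f"M_aero_{ax}"] = mom.aero_moment[:, i]
        df[f"M_iner_{ax}"] = mom.inertial_moment_rate[:, i]
        df[f"M_grav_{ax}"] = mom.gravity_moment[:, i]
    df["pull_angle_deg"] = theta_p
    for i, ax in enumerate(("xb", "yb", "zb")):
        df[f"pull_dir_{ax}"] = pull.direction_body[:, i]
    df["stress_Pa"] = pull.stress
    return df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def scale_table(morphologies: pd.DataFrame | list) -> pd.DataFrame:
    """Scaling predictions for a morphology table (CSV row per bird)."""
    if isinstance(morphologies, pd.DataFrame):
        birds = [syn_mod.BirdMorphology(**row._asdict() if hasattr(row, "_asdict")
                                        else dict(row))
                 for _, row in morphologies.iterrows()]
    else:
        birds = list(morphologies)
    return scaling_mod.predictions_frame(birds)


def bodyweight_support(analysis: FlightAnalysis) -> float:
    """Wingbeat-average reconstructed vertical force / bodyweight."""
    sl, _, _ = analysis.wingbeat()
    t = analysis.kin.time
    fz = analysis.force_trace.force_net[:, 2]
    a, _, b = analysis.kin.wingbeats[analysis.wingbeat_index]
    avg = span_average(t[a:b + 1], fz[a:b + 1])
    return avg / analysis.morphology.bodyweight
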