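"""Synthetic deformation traces and cohorts for the stepwise-pressure assay.

Emulates the experiment the analysis pipeline expects: the inlet pressure
rises by 0.1 mbar every 2.5 s; while the applied pressure stays below the
cell's passage threshold Pmax the cell sits at the quasi-static equilibrium
of the shell model, and once the applied pressure first exceeds Pmax the
rear relaxes exponentially into the constriction (passage is a dynamic
event the quasi-static model does not describe; the relaxation tail here is
pure scaffolding so that the rear-entry event exists in every trace).

Cohorts draw cell diameters from a normal law matched to the reported
median and 10th-90th percentile range, and mechanical parameters from
lognormal laws (multiplicative CV, strictly positive).  All randomness
derives from a single seed through named substreams, so cohorts are fully
reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ConstrictionGeometry, ShellParams, KPA_PER_MBAR, MBAR_PER_KPA
from .passage import simulate_passage
from .traces import DeformationTrace, save_trace

__all__ = [
    "Protocol",
    "GroupSpec",
    "CohortSpec",
    "SpindleToy",
    "sample_diameters",
    "population_variation_stat",
    "synthesize_trace",
    "simulate_cohort",
    "make_cohort",
    "MOUSE_D0_MEDIAN_UM",
    "MOUSE_D0_P10_90_UM",
    "HUMAN_D0_MEDIAN_UM",
    "HUMAN_D0_P10_90_UM",
]

# measured oocyte size statistics (median and 10th-90th percentile range, um)
MOUSE_D0_MEDIAN_UM = 73.09
MOUSE_D0_P10_90_UM = 7.5
HUMAN_D0_MEDIAN_UM = 114.7
HUMAN_D0_P10_90_UM = 11.3

# 10th-90th interpercentile width of a standard normal: 2 * z_0.90
_P10_90_WIDTH = 2.5631


@dataclass(frozen=True)
class Protocol:
    """Stepwise pressure protocol: step, dwell, frame interval and cap (mbar, s)."""

    step_mbar: float = 0.1
    dwell_s: float = 2.5
    frame_interval_s: float = 0.25
    cap_mbar: float = 50.0

    def __post_init__(self) -> None:
        if self.step_mbar <= 0 or self.dwell_s <= 0:
            raise ValueError("step and dwell must be positive")
        if self.frame_interval_s > self.dwell_s:
            raise ValueError("frame interval must not exceed the dwell")

    def pressure_at(self, t):
        """Applied inlet pressure (mbar) at time(s) ``t``: a rising staircase."""
        j = np.floor(np.asarray(t, dtype=float) / self.dwell_s + 1e-9)
        return np.minimum(j * self.step_mbar, self.cap_mbar)


@dataclass(frozen=True)
class SpindleToy:
    """Constant-plus-ramp synthetic spindle channel (for exercising metrics only)."""

    len0_um: float = 20.0
    elongation_pct: float = 25.0
    angle0_deg: float = 40.0
    angle_final_deg: float = 10.0


@dataclass(frozen=True)
class GroupSpec:
    """One mechanical group of a synthetic cohort."""

    label: str
    n: int
    tau0: float = 1.0            # nN/um
    E: float = 1.5               # kPa
    tau0_cv: float = 0.10
    E_cv: float = 0.10
    th: float = 24.4             # um
    D0_median: float = MOUSE_D0_MEDIAN_UM
    D0_p10_90: float = MOUSE_D0_P10_90_UM

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label!r}: n must be >= 1")
        if self.tau0_cv < 0 or self.E_cv < 0:
            raise ValueError(f"group {self.label!r}: CVs must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort: groups, geometry, protocol, noise and the seed."""

    groups: tuple[GroupSpec, ...]
    geometry: ConstrictionGeometry = ConstrictionGeometry(d=50.0, alpha_deg=9.0)
    protocol: Protocol = Protocol()
    sigma_pos_um: float = 0.15
    sigma_ar: float = 0.005
    seed: int = 0
    experiment_id: str = "synthetic-01"
    spindle: SpindleToy | None = None


def sample_diameters(n: int, median: float, p10_90_range: float, seed) -> np.ndarray:
    """Cell diameters from a normal law matched to median and 10-90 range.

    ``sigma = range / 2.5631`` (the 10th-90th width of a standard normal),
    truncated at +-3 sigma by resampling.  ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if p10_90_range < 0:
        raise ValueError("p10_90_range must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = p10_90_range / _P10_90_WIDTH
    if sigma == 0.0:
        return np.full(n, float(median))
    out = rng.normal(median, sigma, size=n)
    bad = np.abs(out - median) > 3.0 * sigma
    while bad.any():
        out[bad] = rng.normal(median, sigma, size=int(bad.sum()))
        bad = np.abs(out - median) > 3.0 * sigma
    return out


def population_variation_stat(median: float, p10_90_range: float, ratio: float) -> float:
    """Spread of D0/d induced by size variability, at a given median D0/d ratio.

    With the constriction width chosen so the median diameter maps to
    ``ratio``, the 10th-90th percentile range of D0/d is
    ``p10_90_range * ratio / median`` (reported rounded to 2 decimals).
    """
    if median <= 0 or ratio <= 0:
        raise ValueError("median and ratio must be positive")
    return p10_90_range * ratio / median


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal factors with coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(n)
    s2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2), size=n)


def synthesize_trace(
    params: ShellParams,
    geometry: ConstrictionGeometry,
    protocol: Protocol = Protocol(),
    sigma_pos_um: float = 0.0,
    sigma_ar: float = 0.0,
    seed=0,
    n_steps: int = 300,
    passage_tau_s: float = 2.0,
    spindle: SpindleToy | None = None,
    metadata: dict | None = None,
) -> DeformationTrace:
    """One synthetic trace of a cell driven by the stepwise protocol.

    Below the threshold the cell tracks the first stable equilibrium at the
    applied driving pressure (the increasing envelope of the model's
    pressure curve); once the applied pressure first exceeds Pmax the rear
    relaxes exponentially toward one constriction width past the entry with
    time constant ``passage_tau_s``, guaranteeing the rear-entry crossing.  Gaussian
    noise is added per frame to positions and aspect ratio; the pressure
    series is the exact protocol staircase.
    """
    traj = simulate_passage(params, geometry, n_steps=n_steps)
    # increasing envelope of dP: first stable equilibrium under pressure control
    env = np.maximum.accumulate(traj.dP)
    keep = np.concatenate(([True], np.diff(env) > 0))
    dP_env = env[keep]
    xf_env, xr_env, ar_env = traj.Xf[keep], traj.Xr[keep], traj.AR[keep]
    Pmax_kpa = traj.Pmax

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dwell, dt = protocol.dwell_s, protocol.frame_interval_s
    j_pass = int(math.floor(Pmax_kpa * MBAR_PER_KPA / protocol.step_mbar)) + 1
    t_pass = j_pass * dwell

    # passage tail: rear relaxes from its last equilibrium toward d/2
    xr_star, xf_star, ar_star = xr_env[-1], xf_env[-1], ar_env[-1]
    d = geometry.d
    cross = math.pi * d * d / 4.0 if geometry.mode == "conical" else d * d
    # fully-deformed capsule: two hemispherical caps plus a straight body
    cap_v = math.pi * d**3 / 12.0
    body_full = max((params.V0 - 2.0 * cap_v) / cross, 0.0)
    len_full = body_full + d
    ar_full = len_full / d
    target = d  # rear relaxes toward one constriction width past the entry
    # time (after t_pass) at which the rear crosses the entry
    t_cross = passage_tau_s * math.log(max((target - xr_star) / target, 1.0 + 1e-9))
    t_end = t_pass + t_cross + max(4.0 * dt, 1.0)

    times = np.arange(0.0, t_end + dt / 2.0, dt)
    pressures = protocol.pressure_at(times)
    applied_kpa = pressures * KPA_PER_MBAR

    quasi = times < t_pass
    q = np.clip(applied_kpa, 0.0, dP_env[-1])
    xf = np.interp(q, dP_env, xf_env)
    xr = np.interp(q, dP_env, xr_env)
    ar = np.interp(q, dP_env, ar_env)

    tail = ~quasi
    dtc = times[tail] - t_pass
    xr_tail = target + (xr_star - target) * np.exp(-dtc / passage_tau_s)
    frac = np.clip((xr_tail - xr_star) / (0.0 - xr_star), 0.0, 1.0)
    length_tail = (xf_star - xr_star) + (len_full - (xf_star - xr_star)) * frac
    xf[tail] = xr_tail + length_tail
    xr[tail] = xr_tail
    ar[tail] = ar_star + (ar_full - ar_star) * frac

    if sigma_pos_um > 0:
        xf = xf + rng.normal(0.0, sigma_pos_um, size=len(times))
        xr = xr + rng.normal(0.0, sigma_pos_um, size=len(times))
    if sigma_ar > 0:
        ar = ar + rng.normal(0.0, sigma_ar, size=len(times))

    data = pd.DataFrame(
        {
            "time_s": times,
            "pressure_mbar": pressures,
            "x_front_um": xf,
            "x_rear_um": xr,
            "aspect_ratio": ar,
        }
    )
    if spindle is not None:
        prog = np.clip((ar - 1.0) / max(ar_full - 1.0, 1e-9), 0.0, 1.0)
        data["spindle_len_um"] = spindle.len0_um * (1.0 + spindle.elongation_pct / 100.0 * prog)
        data["spindle_angle_deg"] = (
            spindle.angle0_deg + (spindle.angle_final_deg - spindle.angle0_deg) * prog
        )
    meta = {
        "d_um": geometry.d,
        "alpha_deg": geometry.alpha_deg,
        "mode": geometry.mode,
        "frame_interval_s": dt,
        "tau0_true": params.tau0,
        "E_true": params.E,
        "th_um": params.th,
        "D0_um": params.D0,
        "Pmax_model_mbar": Pmax_kpa * MBAR_PER_KPA,
        "P_Xf_d2_model_mbar": traj.P_Xf_d2 * MBAR_PER_KPA,
        "P_Xf0_model_mbar": traj.P_Xf0 * MBAR_PER_KPA,
    }
    if metadata:
        meta.update(metadata)
    return DeformationTrace(data=data, metadata=meta)


def simulate_cohort(spec: CohortSpec, n_steps: int = 300) -> tuple[list[DeformationTrace], dict]:
    """All traces of a cohort, in memory, plus the ground-truth manifest."""
    root = np.random.SeedSequence(spec.seed)
    traces: list[DeformationTrace] = []
    manifest: dict = {
        "seed": spec.seed,
        "experiment_id": spec.experiment_id,
        "geometry": {"d_um": spec.geometry.d, "alpha_deg": spec.geometry.alpha_deg,
                     "mode": spec.geometry.mode},
        "protocol": asdict(spec.protocol),
        "cells": [],
    }
    for gi, group in enumerate(spec.groups):
        # named substreams per group: 0 = diameters, 1 = mechanics, 2 = noise
        d_rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(gi, 0)))
        p_rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(gi, 1)))
        noise_ss = np.random.SeedSequence(spec.seed, spawn_key=(gi, 2))
        D0s = sample_diameters(group.n, group.D0_median, group.D0_p10_90, d_rng)
        tau0s = group.tau0 * _lognormal_factors(p_rng, group.tau0_cv, group.n)
        Es = group.E * _lognormal_factors(p_rng, group.E_cv, group.n)
        noise_children = noise_ss.spawn(group.n)
        for ci in range(group.n):
            params = ShellParams(tau0=float(tau0s[ci]), E=float(Es[ci]),
                                 th=group.th, D0=float(D0s[ci]))
            oocyte_id = f"{group.label}-{ci:03d}"
            trace = synthesize_trace(
                params, spec.geometry, spec.protocol,
                sigma_pos_um=spec.sigma_pos_um, sigma_ar=spec.sigma_ar,
                seed=np.random.default_rng(noise_children[ci]), n_steps=n_steps,
                spindle=spec.spindle,
                metadata={
                    "oocyte_id": oocyte_id,
                    "group": group.label,
                    "experiment_id": spec.experiment_id,
                },
            )
            traces.append(trace)
            manifest["cells"].append(
                {
                    "oocyte_id": oocyte_id, "group": group.label,
                    "tau0_true": params.tau0, "E_true": params.E,
                    "th_um": params.th, "D0_um": params.D0,
                    "file": f"{oocyte_id}.csv",
                }
            )
    return traces, manifest


def make_cohort(spec: CohortSpec, outdir: str | Path, n_steps: int = 300) -> dict:
    """Write a cohort to ``outdir`` (per-cell CSV + JSON sidecar + manifest.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traces, manifest = simulate_cohort(spec, n_steps=n_steps)
    for trace, cell in zip(traces, manifest["cells"]):
        save_trace(trace, outdir / cell["file"])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
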