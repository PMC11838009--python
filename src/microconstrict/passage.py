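"""Quasi-static passage of a tensile elastic shell through a tapered constriction.

The cell is an incompressible shell with surface stress

    tau = tau0 + E * th * (A / A0 - 1)

(resting tension plus a linear elastic response to areal strain).  At every
imposed front position the rear position follows from volume conservation
(V = V0), and the driving pressure across the cell is Laplace's law applied
to the front and rear spherical caps:

    dP = P_rear - P_front = 2 * tau * (1/Rf - 1/Rr)

The passage is swept in three stages:

1. both caps tangent to the ramp walls, the front cap base advancing to the
   constriction entry X0;
2. front cap base pinned at X0 with base diameter d, cap height hf growing
   to d/2 (front cap becomes a hemisphere), rear cap still wall-tangent;
3. a cylinder (or square prism) of length L grows inside the constriction
   between the entry and the front hemisphere, until the rear cap base
   reaches the entry.

Stage 2 ends at the classical Laplace threshold P(Xf = d/2); with E > 0 the
driving pressure keeps rising into stage 3, so the true threshold Pmax
exceeds it.  With E = 0 stage 3 is monotonically decreasing and Pmax equals
the Laplace threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .geometry import cap_geometry, cap_height_tangent, channel_width, middle_section, straight_section
from .params import (
    CellConfiguration,
    ConstrictionGeometry,
    InvalidGeometryError,
    NoSolutionError,
    ShellParams,
)

__all__ = [
    "surface_stress",
    "equilibrium_dP",
    "solve_rear",
    "simulate_passage",
    "critical_pressure_closed_form",
    "sensitivity_slopes",
    "EquilibriumPoint",
    "PassageTrajectory",
    "SensitivityResult",
    "ShellPassageModel",
]

_VOL_RTOL = 1e-10  # relative volume-closure tolerance of the rear solver


class NoCriticalPointError(NoSolutionError):
    """The critical (front-hemisphere) configuration cannot close the volume."""


def surface_stress(A: float, params: ShellParams):
    """Surface stress tau (nN/um) at shell area ``A`` (um^2).

    ``tau = tau0 + E*th*(A/A0 - 1)``; may drop below tau0 when A < A0.
    Accepts scalars or arrays.
    """
    return params.tau0 + params.E * params.th * (np.asarray(A) / params.A0 - 1.0)


# ---------------------------------------------------------------------------
# volume assembly and the incompressibility solver
# ---------------------------------------------------------------------------


def _rear_volume_area(Xr_cap: float, D_join: float, geometry: ConstrictionGeometry):
    """Rear tangent cap + tapered middle down to base diameter ``D_join``.

    Returns (V, A, hr, Dr, Rr).  ``Xr_cap`` must lie in the ramp (x <= X0).
    """
    Dr = channel_width(Xr_cap, geometry)
    hr, Rr, Vr, Ar = cap_geometry(Dr, alpha=geometry.alpha, end="rear")
    Vm, Am = middle_section(Dr, D_join, geometry.alpha, geometry.mode)
    return Vr + Vm, Ar + Am, hr, Dr, Rr


def solve_rear(
    front_volume: float,
    D_join: float,
    X_join: float,
    params: ShellParams,
    geometry: ConstrictionGeometry,
    x_guess: float | None = None,
) -> float:
    """Rear cap base position closing the cell volume to V0.

    The front part of the cell (everything downstream of the tapered middle
    section's small base, at ``X_join`` with width ``D_join``) contributes a
    fixed volume ``front_volume``; the rear tangent cap plus the middle
    section make up the rest.  Returns the unique ``Xr_cap`` with
    ``|V - V0| / V0 <= 1e-10``.

    Raises
    ------
    NoSolutionError
        If no bracketing interval exists (cell too large for the ramp, or
        too small to reach the join).
    """
    V0 = params.V0

    def resid(x: float) -> float:
        V, *_ = _rear_volume_area(x, D_join, geometry)
        return front_volume + V - V0

    hi = X_join
    f_hi = resid(hi)
    if f_hi > V0 * _VOL_RTOL:
        raise NoSolutionError(
            "front part plus minimal rear cap already exceeds V0 "
            "(cell too small for this configuration)"
        )
    if abs(f_hi) <= V0 * _VOL_RTOL:
        return hi
    # grow the lower bracket geometrically; the volume increases monotonically
    # as the rear cap base moves upstream (wider channel)
    step = 0.25 * params.D0 if x_guess is None else max(hi - x_guess, 1e-3)
    lo = hi - step
    while resid(lo) < 0.0:
        step *= 2.0
        lo = hi - step
        if step > 20.0 * params.D0:
            raise NoSolutionError(
                "no rear position within 20 cell diameters of the entry closes "
                "the volume (cell too large for this ramp)"
            )
    root = brentq(resid, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return float(root)


def equilibrium_dP(config: CellConfiguration, params: ShellParams, geometry: ConstrictionGeometry):
    """Driving pressure (kPa), stress and area for one cell configuration.

    ``dP = 2 tau (1/Rf - 1/Rr)``, positive on the stable branch (the front
    cap is the more curved one).
    """
    if config.Rf <= 0 or config.Rr <= 0:
        raise InvalidGeometryError("cap radii must be positive")
    _, _, Vf, Af = cap_geometry(config.Df, h=config.hf)
    _, _, Vr, Ar = cap_geometry(config.Dr, h=config.hr)
    Vm, Am = middle_section(config.Dr, config.Df, geometry.alpha, geometry.mode)
    Vs, As = straight_section(geometry.d, config.L, geometry.mode)
    A = Af + Am + Ar + As
    V = Vf + Vm + Vr + Vs
    if abs(V - params.V0) / params.V0 > 1e-8:
        raise InvalidGeometryError("configuration violates volume closure")
    tau = float(surface_stress(A, params))
    dP = 2.0 * tau * (1.0 / config.Rf - 1.0 / config.Rr)
    return dP, tau, A


# ---------------------------------------------------------------------------
# geometry backbone: everything about the sweep that does not depend on
# (tau0, E).  dP is affine in those, so sweeps and inverse fits reuse it.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Backbone:
    stage: np.ndarray
    Xf_cap: np.ndarray
    Xr_cap: np.ndarray
    hf: np.ndarray
    hr: np.ndarray
    Df: np.ndarray
    Dr: np.ndarray
    Rf: np.ndarray
    Rr: np.ndarray
    L: np.ndarray
    A: np.ndarray
    Xf: np.ndarray
    Xr: np.ndarray
    AR: np.ndarray


@lru_cache(maxsize=128)
def _backbone(D0: float, d: float, alpha_deg: float, mode: str, n_steps: int) -> _Backbone:
    geometry = ConstrictionGeometry(d=d, alpha_deg=alpha_deg, mode=mode)
    # th/tau0/E are irrelevant to the geometry; any positive placeholders do
    params = ShellParams(tau0=1.0, E=0.0, th=1.0, D0=D0)
    a = geometry.alpha
    t, c = math.tan(a), math.cos(a)
    s = 1.0 / c
    if D0 * c <= d:
        raise NoSolutionError(
            f"undeformed sphere (D0={D0}) cannot rest tangent to both ramp "
            f"walls upstream of a d={d}, alpha={alpha_deg} deg constriction"
        )
    rows: list[tuple] = []

    def push(stage, Xf_cap, Xr_cap, hf, Df, L=0.0):
        Dr = channel_width(Xr_cap, geometry)
        hr, Rr, Vr, Ar = cap_geometry(Dr, alpha=a, end="rear")
        _, Rf, Vf, Af = cap_geometry(Df, h=hf)
        Vm, Am = middle_section(Dr, Df, a, geometry.mode)
        _, As = straight_section(d, L, geometry.mode)
        A = Af + Am + Ar + As
        rows.append((stage, Xf_cap, Xr_cap, hf, hr, Df, Dr, Rf, Rr, L, A))

    # stage 1: front cap base sweeps from the inscribed-sphere start to X0
    X_start = (d - D0 * c) / (2.0 * t)
    guess = X_start
    for Xf_cap in np.linspace(X_start, 0.0, n_steps + 1):
        Df = channel_width(Xf_cap, geometry)
        hf = cap_height_tangent(Df, a, "front")
        _, _, Vf, _ = cap_geometry(Df, h=hf)
        Xr_cap = solve_rear(Vf, Df, Xf_cap, params, geometry, x_guess=guess)
        guess = Xr_cap
        push(1, Xf_cap, Xr_cap, hf, Df)

    # stage 2: front cap base pinned at X0, height grows to d/2
    hf_tan = cap_height_tangent(d, a, "front")
    for hf in np.linspace(hf_tan, d / 2.0, n_steps + 1)[1:]:
        _, _, Vf, _ = cap_geometry(d, h=hf)
        Xr_cap = solve_rear(Vf, d, 0.0, params, geometry, x_guess=guess)
        guess = Xr_cap
        push(2, 0.0, Xr_cap, hf, d)

    # stage 3: front hemisphere + growing cylinder/prism inside the constriction
    _, _, V_hemi, _ = cap_geometry(d, h=d / 2.0)
    _, _, V_rear_at0, _ = cap_geometry(d, alpha=a, end="rear")
    cross = math.pi * d * d / 4.0 if mode == "conical" else d * d
    L_end = (params.V0 - V_hemi - V_rear_at0) / cross
    if L_end > 0.0:
        for L in np.linspace(0.0, L_end, n_steps + 1)[1:]:
            Vs, _ = straight_section(d, L, geometry.mode)
            Xr_cap = solve_rear(V_hemi + Vs, d, 0.0, params, geometry, x_guess=guess)
            guess = Xr_cap
            push(3, L, Xr_cap, d / 2.0, d, L=L)

    arr = np.array(rows, dtype=float)
    stage = arr[:, 0].astype(int)
    Xf_cap, Xr_cap, hf, hr, Df, Dr, Rf, Rr, L, A = (arr[:, i] for i in range(1, 11))
    Xf = Xf_cap + hf
    Xr = Xr_cap - hr
    AR = (Xf - Xr) / (2.0 * Rr)
    return _Backbone(stage, Xf_cap, Xr_cap, hf, hr, Df, Dr, Rf, Rr, L, A, Xf, Xr, AR)


@dataclass(frozen=True)
class EquilibriumPoint:
    """One quasi-static equilibrium: shape, area, stress, driving pressure."""

    config: CellConfiguration
    A: float
    tau: float
    dP: float
    AR: float


@dataclass
class PassageTrajectory:
    """Ordered quasi-static equilibria of one cell passing the constriction.

    Attributes hold parallel numpy arrays (one entry per equilibrium, ordered
    by strictly increasing front-tip position) plus the marker pressures
    ``P_Xf0`` (front tip at the entry), ``P_Xf_d2`` (front tip at d/2, the
    Laplace threshold) and ``Pmax`` (the passage threshold), all in kPa.
    """

    stage: np.ndarray
    Xf: np.ndarray
    Xr: np.ndarray
    AR: np.ndarray
    A: np.ndarray
    tau: np.ndarray
    dP: np.ndarray
    P_Xf0: float
    P_Xf_d2: float
    Pmax: float
    params: ShellParams
    geometry: ConstrictionGeometry
    resolution: int
    _bb: _Backbone | None = None

    @property
    def points(self) -> list[EquilibriumPoint]:
        """Materialize per-point EquilibriumPoint objects (lazy, for inspection)."""
        bb = self._bb
        if bb is None:
            return []
        out = []
        for i in range(len(self.dP)):
            cfg = CellConfiguration(
                stage=int(bb.stage[i]),
                Xf_cap=float(bb.Xf_cap[i] if bb.stage[i] < 3 else bb.L[i]),
                Xr_cap=float(bb.Xr_cap[i]),
                hf=float(bb.hf[i]),
                hr=float(bb.hr[i]),
                Df=float(bb.Df[i]),
                Dr=float(bb.Dr[i]),
                Rf=float(bb.Rf[i]),
                Rr=float(bb.Rr[i]),
                L=float(bb.L[i]),
            )
            out.append(
                EquilibriumPoint(cfg, float(self.A[i]), float(self.tau[i]), float(self.dP[i]), float(self.AR[i]))
            )
        return out

    def to_frame(self):
        """Trajectory as a DataFrame in the trajectory-CSV dialect."""
        import pandas as pd

        return pd.DataFrame(
            {
                "stage": self.stage,
                "x_front_um": self.Xf,
                "x_rear_um": self.Xr,
                "aspect_ratio": self.AR,
                "area_um2": self.A,
                "tau_nN_per_um": self.tau,
                "dP_kPa": self.dP,
                "dP_mbar": self.dP * 10.0,
            }
        )

    def markers(self) -> dict[str, float]:
        return {"P_Xf0": self.P_Xf0, "P_Xf_d2": self.P_Xf_d2, "Pmax": self.Pmax}

    def plot(self, ax=None):
        """Aspect ratio versus driving pressure with the marker pressures."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.dP * 10.0, self.AR, lw=1.5)
        for name, val in self.markers().items():
            ax.axvline(val * 10.0, ls="--", lw=0.8, color="gray")
            ax.annotate(name, (val * 10.0, ax.get_ylim()[1]), fontsize=7, rotation=90)
        ax.set_xlabel("driving pressure (mbar)")
        ax.set_ylabel("aspect ratio")
        return ax


def simulate_passage(
    params: ShellParams, geometry: ConstrictionGeometry, n_steps: int = 500
) -> PassageTrajectory:
    """Sweep the three-stage passage and return the full trajectory.

    ``n_steps`` is the number of discretization steps per stage (uniform in
    each stage's sweep variable).  Marker pressures are linearly interpolated
    in front-tip position.  If ``d >= D0`` the cell passes undeformed and a
    trivial trajectory (dP = 0) is returned with a warning.
    """
    if geometry.d >= params.D0:
        warnings.warn("d >= D0: cell passes undeformed, trajectory is trivial")
        z = np.zeros(1)
        return PassageTrajectory(
            stage=np.array([1]), Xf=z.copy(), Xr=z - params.D0, AR=np.ones(1),
            A=np.full(1, params.A0), tau=np.full(1, params.tau0), dP=z.copy(),
            P_Xf0=0.0, P_Xf_d2=0.0, Pmax=0.0,
            params=params, geometry=geometry, resolution=n_steps,
        )
    bb = _backbone(params.D0, geometry.d, geometry.alpha_deg, geometry.mode, n_steps)
    tau = np.asarray(surface_stress(bb.A, params), dtype=float)
    dP = 2.0 * tau * (1.0 / bb.Rf - 1.0 / bb.Rr)
    P_Xf0 = float(np.interp(0.0, bb.Xf, dP))
    P_Xf_d2 = float(np.interp(geometry.d / 2.0, bb.Xf, dP))
    Pmax = float(np.max(dP))
    return PassageTrajectory(
        stage=bb.stage, Xf=bb.Xf, Xr=bb.Xr, AR=bb.AR, A=bb.A, tau=tau, dP=dP,
        P_Xf0=P_Xf0, P_Xf_d2=P_Xf_d2, Pmax=Pmax,
        params=params, geometry=geometry, resolution=n_steps, _bb=bb,
    )


# ---------------------------------------------------------------------------
# closed-form critical pressure and its parameter sensitivities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensitivityResult:
    """Closed-form Laplace threshold and its linear parameter sensitivities.

    ``Pc = m_tau0 * tau0 + m_E * E`` with ``m_tau0 = 4 (1/d - cos a / Dr_cr)``
    and ``m_E = th (A_cr/A0 - 1) m_tau0``.
    """

    Pc: float
    Dr_cr: float
    A_cr: float
    m_tau0: float
    m_E: float


def _critical_geometry(D0: float, geometry: ConstrictionGeometry) -> tuple[float, float]:
    """(Dr_cr, A_cr) of the critical configuration (front hemisphere at the entry).

    The critical shape is a front hemisphere of diameter d at the entry, the
    tapered middle, and a wall-tangent rear cap; volume closure fixes the rear
    cap base diameter Dr_cr in closed form (the balance is cubic in Dr).
    """
    a = geometry.alpha
    d = geometry.d
    t, c = math.tan(a), math.cos(a)
    V0 = math.pi * D0**3 / 6.0
    _, _, V_hemi, A_hemi = cap_geometry(d, h=d / 2.0)
    c1 = 0.5 * (t + 1.0 / c)  # rear tangent cap: hr = c1 * Dr
    k_rear = math.pi * c1 / 6.0 * (0.75 + c1 * c1)  # V_rear = k_rear * Dr^3
    if geometry.mode == "conical":
        k_mid = math.pi / (24.0 * t)
    else:
        k_mid = 1.0 / (6.0 * t)
    num = V0 - V_hemi + k_mid * d**3
    if num <= 0.0:
        raise NoCriticalPointError("volume balance has no positive root")
    Dr_cr = (num / (k_mid + k_rear)) ** (1.0 / 3.0)
    if Dr_cr <= d:
        raise NoCriticalPointError(
            "critical rear cap base would sit inside the constriction (Dr_cr <= d)"
        )
    _, _, _, A_rear = cap_geometry(Dr_cr, h=c1 * Dr_cr)
    _, A_mid = middle_section(Dr_cr, d, a, geometry.mode)
    A_cr = A_hemi + A_mid + A_rear
    return Dr_cr, A_cr


def sensitivity_slopes(params: ShellParams, geometry: ConstrictionGeometry) -> SensitivityResult:
    """Closed-form critical pressure Pc and slopes dPc/dtau0, dPc/dE.

    Raises :class:`NoCriticalPointError` when the critical configuration
    cannot close the volume (cell too small, or ramp too steep).
    """
    Dr_cr, A_cr = _critical_geometry(params.D0, geometry)
    c = math.cos(geometry.alpha)
    m_tau0 = 4.0 * (1.0 / geometry.d - c / Dr_cr)
    m_E = params.th * (A_cr / params.A0 - 1.0) * m_tau0
    Pc = m_tau0 * params.tau0 + m_E * params.E
    return SensitivityResult(Pc=Pc, Dr_cr=Dr_cr, A_cr=A_cr, m_tau0=m_tau0, m_E=m_E)


def critical_pressure_closed_form(params: ShellParams, geometry: ConstrictionGeometry) -> SensitivityResult:
    """Closed-form critical pressure (the stage-2 terminal Laplace threshold)."""
    return sensitivity_slopes(params, geometry)


class ShellPassageModel:
    """Forward model of one shell in one constriction.

    Thin object-oriented entry point over the functional core: holds a
    (:class:`ShellParams`, :class:`ConstrictionGeometry`) pair and exposes
    simulation, the closed-form threshold, and sensitivities.
    """

    def __init__(self, params: ShellParams, geometry: ConstrictionGeometry):
        self.params = params
        self.geometry = geometry

    def simulate(self, n_steps: int = 500) -> PassageTrajectory:
        return simulate_passage(self.params, self.geometry, n_steps=n_steps)

    def critical_pressure(self) -> SensitivityResult:
        return critical_pressure_closed_form(self.params, self.geometry)

    def sensitivity(self) -> SensitivityResult:
        return sensitivity_slopes(self.params, self.geometry)
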