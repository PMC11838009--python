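"""Parameter sweeps, sensitivity maps and inverse fitting of (tau0, E).

The closed-form threshold is affine in the mechanical parameters,
``Pc = m_tau0 * tau0 + m_E * E``, so sweeps are exactly linear and the
empirical regression slopes recover the analytic sensitivities.  The inverse
problem (recovering tension and elasticity from a measured pressure versus
aspect-ratio curve) exploits the same structure: at fixed geometry the whole
equilibrium pressure curve is affine in (tau0, E), which makes the
least-squares surface quadratic.  We still minimize it the robust way
(coarse grid then Nelder-Mead) so that the machinery survives future model
terms that break the affinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .params import ConstrictionGeometry, NoSolutionError, ShellParams
from .passage import (
    NoCriticalPointError,
    _backbone,
    sensitivity_slopes,
    simulate_passage,
)

__all__ = [
    "sweep",
    "make_grid",
    "empirical_slopes",
    "design_map",
    "invert_fit",
    "SlopeFit",
    "ConstrictionCurveFit",
    "ConstrictionCurveFitResults",
    "InsufficientDeformationError",
]

DEFAULT_BOUNDS = ((0.05, 10.0), (0.0, 20.0))  # tau0 (nN/um), E (kPa)


class InsufficientDeformationError(ValueError):
    """The observed curve never deforms enough (AR <= 1.02) to constrain a fit."""


# ---------------------------------------------------------------------------
# forward sweeps
# ---------------------------------------------------------------------------


def make_grid(
    tau0: Sequence[float],
    E: Sequence[float],
    geometry: ConstrictionGeometry | Sequence[ConstrictionGeometry],
    th: float,
    D0: float | Sequence[float],
) -> list[tuple[ShellParams, ConstrictionGeometry]]:
    """Cartesian product of mechanical parameters and geometries."""
    geoms = [geometry] if isinstance(geometry, ConstrictionGeometry) else list(geometry)
    D0s = [D0] if np.isscalar(D0) else list(D0)
    return [
        (ShellParams(tau0=t, E=e, th=th, D0=dd), g)
        for t, e, g, dd in product(tau0, E, geoms, D0s)
    ]


def sweep(
    grid: Iterable[tuple[ShellParams, ConstrictionGeometry]],
    n_steps: int = 300,
) -> pd.DataFrame:
    """Closed-form Pc plus numerical trajectory markers for every grid point.

    One row per grid point; failed points are kept with a ``status`` code
    rather than dropped, so downstream maps stay rectangular.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty parameter grid")
    rows = []
    for params, geom in grid:
        row = {
            "tau0": params.tau0, "E": params.E, "alpha_deg": geom.alpha_deg,
            "d": geom.d, "D0": params.D0, "th": params.th, "mode": geom.mode,
            "Pc": np.nan, "P_Xf_d2_numeric": np.nan, "Pmax": np.nan,
            "Pmax_minus_Pc": np.nan, "status": "ok",
        }
        try:
            sr = sensitivity_slopes(params, geom)
            traj = simulate_passage(params, geom, n_steps=n_steps)
            row.update(
                Pc=sr.Pc,
                P_Xf_d2_numeric=traj.P_Xf_d2,
                Pmax=traj.Pmax,
                Pmax_minus_Pc=traj.Pmax - sr.Pc,
            )
        except (NoCriticalPointError, NoSolutionError) as exc:
            row["status"] = type(exc).__name__
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SlopeFit:
    """OLS line of the critical pressure against one varied parameter."""

    slope: float
    intercept: float
    r_squared: float


def empirical_slopes(table: pd.DataFrame, varied: str) -> SlopeFit:
    """Regress Pc on ``varied`` ("tau0" or "E") over the rows of a sweep table."""
    if varied not in ("tau0", "E"):
        raise ValueError("varied must be 'tau0' or 'E'")
    ok = table[table["status"] == "ok"] if "status" in table else table
    if len(ok) < 3:
        raise ValueError("need at least 3 rows varying the chosen parameter")
    res = stats.linregress(ok[varied].to_numpy(), ok["Pc"].to_numpy())
    return SlopeFit(slope=float(res.slope), intercept=float(res.intercept),
                    r_squared=float(res.rvalue**2))


def design_map(
    alpha_grid: Sequence[float],
    d_grid: Sequence[float],
    D0_list: Sequence[float],
    params: ShellParams,
    mode: str = "conical",
) -> pd.DataFrame:
    """Sensitivity slopes over a grid of constriction designs.

    Shell thickness is scaled proportionally to D0 (the cortex occupies a
    fixed fraction of the cell radius), so cells of different sizes are
    mechanically self-similar; this is what leaves the elasticity
    sensitivity m_E nearly unchanged when the whole geometry is scaled up at
    fixed D0/d.  Cells with no critical point carry a status code.
    """
    if not len(alpha_grid) or not len(d_grid) or not len(D0_list):
        raise ValueError("empty design grid")
    rows = []
    for alpha_deg, d, D0 in product(alpha_grid, d_grid, D0_list):
        th = params.th * D0 / params.D0
        row = {"alpha_deg": alpha_deg, "d": d, "D0": D0, "th": th,
               "m_tau0": np.nan, "m_E": np.nan, "ratio": np.nan, "status": "ok"}
        try:
            geom = ConstrictionGeometry(d=d, alpha_deg=alpha_deg, mode=mode)
            p = ShellParams(tau0=params.tau0, E=params.E, th=th, D0=D0)
            sr = sensitivity_slopes(p, geom)
            row.update(m_tau0=sr.m_tau0, m_E=sr.m_E, ratio=sr.m_tau0 / sr.m_E)
        except (NoCriticalPointError, NoSolutionError, ValueError) as exc:
            row["status"] = type(exc).__name__
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inverse fit: ConstrictionCurveFit model / results
# ---------------------------------------------------------------------------


class ConstrictionCurveFit:
    """Fit (tau0, E) to an observed pressure versus aspect-ratio curve.

    The endogenous variable is the driving pressure (kPa) because pressure is
    the controlled quantity in the stepwise protocol; residuals are formed
    against the model pressure interpolated at the observed aspect ratios.
    Shell thickness ``th`` and diameter ``D0`` are fixed (not identifiable
    jointly with E from a single curve).

    Parameters
    ----------
    dP : array-like
        Observed driving pressures, kPa.
    ar : array-like
        Observed aspect ratios (dimensionless), same length.
    geometry : ConstrictionGeometry
    th, D0 : float
        Fixed shell thickness and initial diameter, um.
    bounds : ((tau0_lo, tau0_hi), (E_lo, E_hi)), optional
    n_steps : int
        Forward-model discretization per stage used during fitting.
    """

    def __init__(self, dP, ar, geometry: ConstrictionGeometry, th: float, D0: float,
                 bounds=DEFAULT_BOUNDS, n_steps: int = 160):
        dP = np.asarray(dP, dtype=float)
        ar = np.asarray(ar, dtype=float)
        if dP.shape != ar.shape or dP.ndim != 1:
            raise ValueError("dP and ar must be 1-D arrays of equal length")
        self.geometry = geometry
        self.th = float(th)
        self.D0 = float(D0)
        self.bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
        self.n_steps = int(n_steps)

        bb = _backbone(self.D0, geometry.d, geometry.alpha_deg, geometry.mode, self.n_steps)
        geom_factor = 2.0 * (1.0 / bb.Rf - 1.0 / bb.Rr)
        strain = bb.A / (math.pi * self.D0**2) - 1.0
        # keep the strictly increasing AR branch for interpolation
        ar_model = bb.AR
        if np.any(np.diff(ar_model) <= 0):  # pragma: no cover - AR is monotone
            keep = np.concatenate(([True], np.diff(np.maximum.accumulate(ar_model)) > 0))
            ar_model, geom_factor, strain = ar_model[keep], geom_factor[keep], strain[keep]
        usable = (ar > 1.02) & (ar <= ar_model[-1]) & np.isfinite(dP)
        if not np.any(ar > 1.02):
            raise InsufficientDeformationError(
                "curve never exceeds aspect ratio 1.02; cannot constrain (tau0, E)"
            )
        if usable.sum() < 5:
            raise InsufficientDeformationError(
                f"only {int(usable.sum())} usable points with AR in (1.02, model range]"
            )
        self.dP_obs = dP[usable]
        self.ar_obs = ar[usable]
        # dP_model(AR) is affine in (tau0, E): dP = a*tau0 + b*E
        self._a = np.interp(self.ar_obs, ar_model, geom_factor)
        self._b = np.interp(self.ar_obs, ar_model, geom_factor * self.th * strain)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, geometry: ConstrictionGeometry,
                       th: float, D0: float, pressure_col: str = "dP_kPa",
                       ar_col: str = "aspect_ratio", **kwargs) -> "ConstrictionCurveFit":
        return cls(df[pressure_col].to_numpy(), df[ar_col].to_numpy(),
                   geometry, th, D0, **kwargs)

    def loss(self, tau0: float, E: float) -> float:
        """Sum of squared pressure residuals (kPa^2) at (tau0, E)."""
        r = self.dP_obs - self._a * tau0 - self._b * E
        return float(r @ r)

    def fit(self, seed: int = 0, grid_size: int = 20) -> "ConstrictionCurveFitResults":
        """Coarse grid search then Nelder-Mead refinement; deterministic."""
        (t_lo, t_hi), (e_lo, e_hi) = self.bounds
        t_grid = np.linspace(t_lo, t_hi, grid_size)
        e_grid = np.linspace(e_lo, e_hi, grid_size)
        best, best_loss = None, np.inf
        for t in t_grid:
            for e in e_grid:
                l = self.loss(t, e)
                if l < best_loss:
                    best, best_loss = (t, e), l
        res = optimize.minimize(
            lambda x: self.loss(x[0], x[1]), x0=np.asarray(best),
            method="Nelder-Mead",
            bounds=self.bounds,
            options={"fatol": 1e-6 * max(best_loss, 1e-12), "xatol": 1e-8, "maxiter": 2000},
        )
        tau0_hat, E_hat = (float(v) for v in res.x)
        loss = float(res.fun)
        span_t, span_e = t_hi - t_lo, e_hi - e_lo
        at_bounds = (
            min(tau0_hat - t_lo, t_hi - tau0_hat) < 1e-6 * span_t
            or min(E_hat - e_lo, e_hi - E_hat) < 1e-6 * span_e
        )
        converged = bool(res.success) and not at_bounds
        return ConstrictionCurveFitResults(
            model=self, tau0_hat=tau0_hat, E_hat=E_hat, loss=loss,
            converged=converged, n_points=len(self.dP_obs), seed=seed,
        )


@dataclass
class ConstrictionCurveFitResults:
    """Estimates, uncertainties and diagnostics of a curve fit.

    Standard errors come from the local linearization of the model pressure
    in (tau0, E) (exact here, since the equilibrium pressure is affine in
    both at fixed geometry), with residual variance loss/(n-2).
    """

    model: ConstrictionCurveFit
    tau0_hat: float
    E_hat: float
    loss: float
    converged: bool
    n_points: int
    seed: int = 0

    @property
    def params(self) -> dict[str, float]:
        return {"tau0": self.tau0_hat, "E": self.E_hat}

    @property
    def cov_params(self) -> np.ndarray:
        X = np.column_stack([self.model._a, self.model._b])
        dof = max(self.n_points - 2, 1)
        s2 = self.loss / dof
        return s2 * np.linalg.pinv(X.T @ X)

    @property
    def bse(self) -> dict[str, float]:
        cov = self.cov_params
        return {"tau0": float(np.sqrt(cov[0, 0])), "E": float(np.sqrt(cov[1, 1]))}

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        z = stats.t.ppf(1.0 - alpha / 2.0, df=max(self.n_points - 2, 1))
        return {
            name: (est - z * se, est + z * se)
            for (name, est), se in zip(self.params.items(), self.bse.values())
        }

    def predict(self, ar) -> np.ndarray:
        """Model driving pressure (kPa) at the given aspect ratios."""
        m = self.model
        bb = _backbone(m.D0, m.geometry.d, m.geometry.alpha_deg, m.geometry.mode, m.n_steps)
        g = 2.0 * (1.0 / bb.Rf - 1.0 / bb.Rr)
        strain = bb.A / (math.pi * m.D0**2) - 1.0
        dP = g * self.tau0_hat + g * m.th * strain * self.E_hat
        return np.interp(np.asarray(ar, dtype=float), bb.AR, dP)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Constriction curve fit (tensile elastic shell)",
            "=" * 54,
            f"n points used        {self.n_points:>10d}",
            f"loss (kPa^2)         {self.loss:>14.6g}",
            f"converged            {str(self.converged):>10s}",
            "-" * 54,
            f"{'param':<8}{'estimate':>12}{'std err':>12}{'[0.025':>11}{'0.975]':>11}",
        ]
        for name, est in self.params.items():
            se = self.bse[name]
            lo, hi = ci[name]
            lines.append(f"{name:<8}{est:>12.5g}{se:>12.3g}{lo:>11.4g}{hi:>11.4g}")
        lines.append("=" * 54)
        lines.append("tau0 in nN/um, E in kPa; th and D0 held fixed.")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed curve and fitted model pressure versus aspect ratio."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.ar_obs, self.model.dP_obs * 10.0, "o", ms=3, label="observed")
        ar = np.linspace(self.model.ar_obs.min(), self.model.ar_obs.max(), 200)
        ax.plot(ar, self.predict(ar) * 10.0, "-", label="fit")
        ax.set_xlabel("aspect ratio")
        ax.set_ylabel("driving pressure (mbar)")
        ax.legend()
        return ax


def invert_fit(
    curve,
    geometry: ConstrictionGeometry,
    th: float,
    D0: float,
    bounds=DEFAULT_BOUNDS,
    seed: int = 0,
    n_steps: int = 160,
) -> ConstrictionCurveFitResults:
    """Recover (tau0, E) from a list of (dP kPa, aspect ratio) points.

    Convenience wrapper over :class:`ConstrictionCurveFit`.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 2 or len(curve) < 5:
        raise ValueError("curve must be an (n>=5, 2) array of (dP_kPa, AR)")
    model = ConstrictionCurveFit(curve[:, 0], curve[:, 1], geometry, th, D0,
                                 bounds=bounds, n_steps=n_steps)
    return model.fit(seed=seed)
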