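"""Mechanical and geometric parameter containers.

Internal unit system: lengths in um, tensions in nN/um, elastic moduli and
pressures in kPa (1 kPa == 1 nN/um^2), so tau/R is a pressure with no
conversion factor.  Applied pressures in experimental traces are in mbar;
1 kPa = 10 mbar, converted only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

KPA_PER_MBAR = 0.1
MBAR_PER_KPA = 10.0


class InvalidGeometryError(ValueError):
    """A geometric quantity (diameter, height, radius) is non-physical."""


class NoSolutionError(RuntimeError):
    """The volume-conservation equation has no root in the admissible range."""


@dataclass(frozen=True)
class ShellParams:
    """Mechanical identity of one cell modelled as a tensile elastic shell.

    Parameters
    ----------
    tau0 : float
        Resting cortical tension, nN/um (equivalently mN/m).
    E : float
        Elastic modulus of the shell, kPa.
    th : float
        Mean shell thickness, um.
    D0 : float
        Initial (undeformed, spherical) cell diameter, um.
    """

    tau0: float
    E: float
    th: float
    D0: float

    def __post_init__(self) -> None:
        if self.tau0 < 0 or self.E < 0:
            raise ValueError("tau0 and E must be non-negative")
        if self.th <= 0 or self.D0 <= 0:
            raise ValueError("th and D0 must be positive")

    @property
    def V0(self) -> float:
        """Initial volume of the spherical cell, um^3."""
        return math.pi * self.D0**3 / 6.0

    @property
    def A0(self) -> float:
        """Stress-free reference surface area, um^2."""
        return math.pi * self.D0**2


@dataclass(frozen=True)
class ConstrictionGeometry:
    """Tapered constriction: a ramp of half-angle alpha narrowing to width d.

    The axis coordinate x increases in the flow direction; the constriction
    entry sits at ``X0`` (0 by convention) and the ramp occupies x < X0,
    widening upstream with slope 2*tan(alpha).

    Parameters
    ----------
    d : float
        Minimal channel width, um.
    alpha_deg : float
        Ramp inclination in degrees, 0 < alpha < 90.
    mode : str
        ``"conical"`` (axisymmetric) or ``"pyramidal"`` (square cross
        section; spherical caps unchanged).
    """

    d: float
    alpha_deg: float
    mode: str = "conical"
    X0: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_deg < 90.0:
            raise ValueError("alpha must lie strictly between 0 and 90 degrees")
        if self.d <= 0:
            raise ValueError("d must be positive")
        if self.mode not in ("conical", "pyramidal"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def alpha(self) -> float:
        """Ramp inclination in radians."""
        return math.radians(self.alpha_deg)


@dataclass(frozen=True)
class CellConfiguration:
    """One quasi-static shape of the shell in the channel.

    The shell is a rear spherical cap, a tapered middle section, optionally a
    cylinder/prism of length ``L`` inside the constriction (late stage only)
    and a front spherical cap.  Tip positions derive from cap bases as
    ``Xf = Xf_cap + hf`` and ``Xr = Xr_cap - hr``.
    """

    stage: int
    Xf_cap: float
    Xr_cap: float
    hf: float
    hr: float
    Df: float
    Dr: float
    Rf: float
    Rr: float
    L: float = 0.0

    @property
    def Xf(self) -> float:
        return self.Xf_cap + self.hf

    @property
    def Xr(self) -> float:
        return self.Xr_cap - self.hr
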