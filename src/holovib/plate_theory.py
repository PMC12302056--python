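"""Closed-form Kirchhoff thin-plate modal analysis for circular plates.

Implements the classical relation between a circular plate's natural
frequencies and its flexural rigidity,

    lambda^2 = omega * a^2 * sqrt(rho / D),        D = E h^3 / (12 (1 - nu^2)),

where ``lambda`` is the dimensionless eigenvalue of the mode (order ``n`` =
nodal diameters, mode ``m`` = radial index), ``a`` the plate radius, and
``rho`` a density. Two density conventions are supported: the dimensionally
standard *areal* density (kg/m^2, giving omega = (lambda^2/a^2) sqrt(D/mu)),
and a *volume*-density literal form (kg/m^3) kept because published
back-calculations for Transwell-supported skin substitutes use it; the two
differ by a factor sqrt(h) and the convention in force is always explicit.

Also provides an equivalent-single-layer (classical lamination) reduction of
a bonded layer stack to one effective rigidity about the stack's neutral
axis, Bessel mode shapes, exact algebraic inversions of the two relations,
and the taut-string frequency relation used for fibrous constructs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import special

from .fields import DisplacementField, make_field, raster_coords

logger = logging.getLogger("holovib")

__all__ = [
    "LayerSpec", "PlateAssembly", "ModeIdentity", "AnalyticMode", "LaminateRigidity",
    "characteristic_lambda", "flexural_rigidity", "laminate_rigidity",
    "modal_frequency", "invert_rigidity", "invert_modulus", "invert_thickness",
    "mode_shape", "string_frequency",
]

BOUNDARIES = ("clamped", "simply_supported", "free", "tri_arc_clamped")
DENSITY_CONVENTIONS = ("paper_literal_volume", "areal")

# Root bracketing: deterministic sign scan with this step, then bisection.
_SCAN_STEP = 0.05
_BISECT_TOL = 1e-12
_SCAN_MAX = 200.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """One material layer: thickness h (m), Young's modulus E (Pa), Poisson
    ratio nu, volume density rho (kg/m^3)."""

    name: str
    thickness: float
    youngs_modulus: float
    poisson: float
    density: float

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")
        if not 0 < self.poisson < 0.5:
            raise ValueError(f"layer {self.name!r}: Poisson ratio must be in (0, 0.5)")
        if self.youngs_modulus <= 0 or self.density <= 0:
            raise ValueError(f"layer {self.name!r}: modulus and density must be > 0")


@dataclass(frozen=True)
class PlateAssembly:
    """A circular layer stack on a support: radius a, layers bottom-first,
    edge condition, Winkler foundation modulus (Pa/m; 0 = air) and the
    density convention used when evaluating the frequency relation."""

    radius: float
    layers: tuple[LayerSpec, ...]
    boundary: str = "clamped"
    foundation_stiffness: float = 0.0
    density_convention: str = "areal"
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.foundation_stiffness < 0:
            raise ValueError("foundation stiffness must be >= 0")
        if not self.layers:
            raise ValueError("assembly needs at least one layer")
        if self.boundary not in BOUNDARIES:
            raise ValueError(f"unknown boundary {self.boundary!r}; options: {BOUNDARIES}")
        if self.density_convention not in DENSITY_CONVENTIONS:
            raise ValueError(f"unknown density convention {self.density_convention!r}")

    # -- derived bulk quantities ------------------------------------------
    @property
    def total_thickness(self) -> float:
        return sum(l.thickness for l in self.layers)

    @property
    def areal_density(self) -> float:
        """mu = sum rho_i h_i, kg/m^2."""
        return sum(l.density * l.thickness for l in self.layers)

    @property
    def mean_volume_density(self) -> float:
        """Thickness-weighted volume density, used by the literal convention."""
        return self.areal_density / self.total_thickness

    def effective_poisson(self) -> float:
        """Rigidity-share-weighted Poisson ratio of the stack."""
        lam = laminate_rigidity(self.layers)
        return float(sum(s * l.poisson for s, l in zip(lam.per_layer_share, self.layers)))

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "radius_m": self.radius,
            "layers": [
                {"name": l.name, "thickness_m": l.thickness, "E_pa": l.youngs_modulus,
                 "poisson": l.poisson, "density_kg_m3": l.density}
                for l in self.layers
            ],
            "boundary": self.boundary,
            "foundation_pa_per_m": self.foundation_stiffness,
            "density_convention": self.density_convention,
            "notes": self.notes,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PlateAssembly":
        d = json.loads(text)
        layers = tuple(
            LayerSpec(l["name"], l["thickness_m"], l["E_pa"], l["poisson"], l["density_kg_m3"])
            for l in d["layers"]
        )
        return cls(d["radius_m"], layers, d["boundary"], d["foundation_pa_per_m"],
                   d["density_convention"], d.get("notes", {}))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PlateAssembly":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class ModeIdentity:
    """Mode (n, m): n nodal diameters (order), m-th radial mode (mode >= 1)."""

    order: int
    mode: int

    def __post_init__(self) -> None:
        if self.order < 0 or self.mode < 1:
            raise ValueError("need order >= 0 and mode >= 1")


@dataclass(frozen=True)
class AnalyticMode:
    identity: ModeIdentity
    lam: float
    lam_sq: float
    frequency_hz: float
    angular_frequency: float


@dataclass(frozen=True)
class LaminateRigidity:
    """Equivalent single-layer reduction of a bonded stack: effective rigidity
    D (N*m) about the neutral axis, areal density mu (kg/m^2), neutral-axis
    height from the bottom surface (m), and each layer's additive share of D."""

    d_eff: float
    areal_density: float
    neutral_axis: float
    per_layer_share: tuple[float, ...]


# ---------------------------------------------------------------------------
# characteristic equations
# ---------------------------------------------------------------------------

def _clamped_char(lam: np.ndarray | float, n: int) -> np.ndarray | float:
    # J_n(x) I_{n+1}(x) + I_n(x) J_{n+1}(x) = 0, with I terms exp-scaled
    # (ive = iv * exp(-x)) so the scan does not overflow; zeros are unchanged.
    return (special.jv(n, lam) * special.ive(n + 1, lam)
            + special.ive(n, lam) * special.jv(n + 1, lam))


def _ss_char(lam: np.ndarray | float, n: int, nu: float) -> np.ndarray | float:
    # J_{n+1}/J_n + I_{n+1}/I_n = 2 lam / (1 - nu), multiplied through by
    # J_n I_n to remove poles; I_n > 0 for lam > 0 so no roots are added.
    return (special.jv(n + 1, lam) * special.ive(n, lam)
            + special.ive(n + 1, lam) * special.jv(n, lam)
            - 2.0 * lam / (1.0 - nu) * special.jv(n, lam) * special.ive(n, lam))


def _bisect(f, lo: float, hi: float) -> float:
    flo = f(lo)
    if flo == 0.0:
        return lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0.0 or (hi - lo) < _BISECT_TOL:
            return mid
        if (flo < 0) == (fm < 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def characteristic_lambda(identity: ModeIdentity, boundary: str,
                          poisson: float | None = None) -> float:
    """m-th positive root lambda of the edge-condition characteristic equation.

    Supported closed-form edges are ``clamped`` and ``simply_supported``
    (which needs the Poisson ratio); ``free`` and ``tri_arc_clamped`` have no
    closed form here and are handled by the finite-element module.
    """
    n, m = identity.order, identity.mode
    if boundary == "clamped":
        f = lambda x: _clamped_char(x, n)
    elif boundary == "simply_supported":
        if poisson is None:
            raise ValueError("simply_supported edge requires the Poisson ratio")
        if not 0 < poisson < 0.5:
            raise ValueError("Poisson ratio must be in (0, 0.5)")
        f = lambda x: _ss_char(x, n, poisson)
    else:
        raise ValueError(
            f"boundary {boundary!r} has no closed-form eigenvalue; use fe_modal")

    found = 0
    lo = 1e-9
    flo = f(lo)
    x = lo
    while x < _SCAN_MAX:
        x2 = x + _SCAN_STEP
        fx2 = f(x2)
        if np.sign(fx2) != np.sign(flo) and flo != 0.0:
            found += 1
            if found == m:
                return float(_bisect(f, x, x2))
        x, flo = x2, fx2
    raise RuntimeError(
        f"no root #{m} of the {boundary} characteristic equation for order {n} "
        f"in (0, {_SCAN_MAX}] at scan step {_SCAN_STEP}")


# ---------------------------------------------------------------------------
# rigidity
# ---------------------------------------------------------------------------

def flexural_rigidity(E: float, h: float, poisson: float) -> float:
    """D = E h^3 / (12 (1 - nu^2)), N*m."""
    if E <= 0 or h <= 0:
        raise ValueError("modulus and thickness must be positive")
    if not 0 < poisson < 0.5:
        raise ValueError("Poisson ratio must be in (0, 0.5)")
    return E * h ** 3 / (12.0 * (1.0 - poisson ** 2))


def laminate_rigidity(layers) -> LaminateRigidity:
    """Equivalent rigidity of a bonded stack about its neutral axis.

    z_n = sum(E_i h_i zbar_i) / sum(E_i h_i); each layer contributes
    E_i/(1-nu_i^2) * ((z_i - z_n)^3 - (z_{i-1} - z_n)^3) / 3 to D.
    """
    layers = tuple(layers)
    if not layers:
        raise ValueError("laminate needs at least one layer")
    z = np.concatenate([[0.0], np.cumsum([l.thickness for l in layers])])
    weights = np.array([l.youngs_modulus * l.thickness for l in layers])
    midplanes = 0.5 * (z[:-1] + z[1:])
    z_n = float(np.dot(weights, midplanes) / weights.sum())
    contrib = np.array([
        l.youngs_modulus / (1.0 - l.poisson ** 2)
        * ((z[i + 1] - z_n) ** 3 - (z[i] - z_n) ** 3) / 3.0
        for i, l in enumerate(layers)
    ])
    d_eff = float(contrib.sum())
    mu = float(sum(l.density * l.thickness for l in layers))
    return LaminateRigidity(d_eff, mu, z_n, tuple(contrib / d_eff))


# ---------------------------------------------------------------------------
# frequency relation, forward and inverse
# ---------------------------------------------------------------------------

def _density_for(assembly: PlateAssembly) -> float:
    if assembly.density_convention == "areal":
        return assembly.areal_density
    logger.warning(
        "modal_frequency: using the literal volume-density convention "
        "(rho = %.1f kg/m^3); frequencies differ from the areal convention "
        "by sqrt(h).", assembly.mean_volume_density)
    return assembly.mean_volume_density


def modal_frequency(lam_sq: float, assembly: PlateAssembly, D: float | None = None,
                    identity: ModeIdentity | None = None) -> AnalyticMode:
    """omega = (lambda^2 / a^2) sqrt(D / rho) under the assembly's convention."""
    if lam_sq <= 0:
        raise ValueError("lambda^2 must be positive")
    if D is None:
        D = laminate_rigidity(assembly.layers).d_eff
    rho = _density_for(assembly)
    omega = lam_sq / assembly.radius ** 2 * math.sqrt(D / rho)
    lam = math.sqrt(lam_sq)
    return AnalyticMode(identity or ModeIdentity(0, 1), lam, lam_sq,
                        omega / (2.0 * math.pi), omega)


def invert_rigidity(frequency_hz: float, lam_sq: float, radius: float,
                    density: float, convention: str = "paper_literal_volume") -> float:
    """Exact inversion of the frequency relation: D = rho (omega a^2 / lambda^2)^2."""
    if min(frequency_hz, lam_sq, radius, density) <= 0:
        raise ValueError("all inputs must be positive")
    if convention not in DENSITY_CONVENTIONS:
        raise ValueError(f"unknown density convention {convention!r}")
    omega = 2.0 * math.pi * frequency_hz
    return density * (omega * radius ** 2 / lam_sq) ** 2


def invert_modulus(D: float, h: float, poisson: float) -> float:
    """E = 12 (1 - nu^2) D / h^3."""
    if D <= 0 or h <= 0:
        raise ValueError("rigidity and thickness must be positive")
    if not 0 < poisson < 0.5:
        raise ValueError("Poisson ratio must be in (0, 0.5)")
    return 12.0 * (1.0 - poisson ** 2) * D / h ** 3


def invert_thickness(D: float, E: float, poisson: float) -> float:
    """h = (12 (1 - nu^2) D / E)^(1/3)."""
    if D <= 0 or E <= 0:
        raise ValueError("rigidity and modulus must be positive")
    if not 0 < poisson < 0.5:
        raise ValueError("Poisson ratio must be in (0, 0.5)")
    return (12.0 * (1.0 - poisson ** 2) * D / E) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# mode shapes
# ---------------------------------------------------------------------------

def mode_shape(identity: ModeIdentity, boundary: str, assembly: PlateAssembly,
               grid: int = 129) -> DisplacementField:
    """W(r, theta) = [J_n(lam r/a) - C I_n(lam r/a)] cos(n theta), max|W| = 1.

    C = J_n(lam)/I_n(lam) enforces W = 0 on the edge for both supported
    closed-form boundaries.
    """
    nu = assembly.effective_poisson() if boundary == "simply_supported" else None
    lam = characteristic_lambda(identity, boundary, nu)
    n = identity.order
    a = assembly.radius
    x, y, mask, _ = raster_coords(a, grid)
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)
    arg = lam * r / a
    C = special.jv(n, lam) / special.iv(n, lam)
    w = (special.jv(n, arg) - C * special.iv(n, arg)) * np.cos(n * theta)
    w = np.where(mask, w, np.nan)
    return make_field(w, a, unit="1").normalized()


def string_frequency(tension: float, linear_density: float, length: float,
                     harmonic: int = 1) -> float:
    """f_n = (n / 2L) sqrt(T / mu) for a taut string (fibrous constructs)."""
    if min(tension, linear_density, length) <= 0 or harmonic < 1:
        raise ValueError("inputs must be positive and harmonic >= 1")
    return harmonic / (2.0 * length) * math.sqrt(tension / linear_density)
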