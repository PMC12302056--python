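"""Simulated frequency sweep and mode identification.

The forced steady-state response to a uniform acoustic pressure is built by
modal superposition with viscous modal damping zeta:

    w(x; omega) = | sum_j q_j phi_j(x) |,
    q_j = f_j p / (omega_j^2 - omega^2 + 2 i zeta omega_j omega),

with phi_j mass-normalized (integral mu phi_j^2 dA = 1) and f_j the modal
projection of the unit pressure, integral phi_j dA; each |q_j| equals the
familiar 1/sqrt((omega_j^2-omega^2)^2 + (2 zeta omega_j omega)^2) resonance
magnitude, and the complex form keeps the modal phase lags so off-resonance
tails combine physically. A uniform pressure only
projects onto near-axisymmetric modes, which is why a loudspeaker sweep picks
out the order-0 ladder. Resonances are detected as prominent local maxima of
the centre-pixel amplitude over the sweep grid, and measured patterns are
assigned a (nodal diameters, radial mode) identity by correlation against
candidate shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .fields import DisplacementField
from .fe_modal import FEMode
from .phase_analysis import radial_median_profile
from .plate_theory import (AnalyticMode, ModeIdentity, PlateAssembly,
                           characteristic_lambda, laminate_rigidity,
                           modal_frequency, mode_shape)

__all__ = ["SweepResult", "ModeAssignment", "analytic_vibration_modes",
           "forced_response", "frequency_sweep", "classify_mode"]

PEAK_PROMINENCE = 0.05  # fraction of max response; suppresses shoulder artifacts


@dataclass
class SweepResult:
    frequencies: np.ndarray          # Hz grid
    response: np.ndarray             # centre-pixel amplitude, m
    peaks: tuple[tuple[float, float], ...]   # (frequency_hz, prominence)
    damping_ratio: float


@dataclass(frozen=True)
class ModeAssignment:
    identity: ModeIdentity
    correlation: float
    nodal_circles: int
    nodal_diameters: int


def analytic_vibration_modes(assembly: PlateAssembly, identities,
                             boundary: str = "clamped", grid: int = 65
                             ) -> list[FEMode]:
    """Closed-form modes packaged like FE modes (frequency + raster shape)."""
    lam = laminate_rigidity(assembly.layers)
    modes = []
    for ident in identities:
        nu = assembly.effective_poisson() if boundary == "simply_supported" else None
        lam_val = characteristic_lambda(ident, boundary, nu)
        analytic = modal_frequency(lam_val ** 2, assembly, lam.d_eff, ident)
        shape = mode_shape(ident, boundary, assembly, grid=grid)
        modes.append(FEMode(analytic.frequency_hz, shape, math.nan))
    return sorted(modes, key=lambda m: m.frequency_hz)


def _mass_normalized(modes, assembly: PlateAssembly):
    """Scale raster shapes to integral mu phi^2 dA = 1."""
    mu = assembly.areal_density
    out = []
    for m in modes:
        v = m.shape.values
        px = m.shape.pixel_size_m
        norm = math.sqrt(mu * np.nansum(v * v) * px * px)
        if norm == 0:
            raise ValueError("mode shape is identically zero")
        out.append((m, np.where(m.shape.mask, v, 0.0) / norm))
    return out


def forced_response(modes, damping: float, drive_hz: float,
                    drive_pressure: float, assembly: PlateAssembly
                    ) -> DisplacementField:
    """Steady-state amplitude field under uniform pressure drive (linear in p)."""
    modes = list(modes)
    if not modes:
        raise ValueError("need at least one mode")
    if not 0 < damping < 1:
        raise ValueError("damping ratio must be in (0, 1)")
    normalized = _mass_normalized(modes, assembly)
    omega = 2.0 * math.pi * drive_hz
    ref = normalized[0][0].shape
    px = ref.pixel_size_m
    total = np.zeros(ref.values.shape, dtype=complex)
    for mode, phi in normalized:
        omega_j = 2.0 * math.pi * mode.frequency_hz
        f_j = np.sum(phi) * px * px
        # complex FRF keeps each mode's phase lag so modal tails combine
        # physically; |q| matches sqrt((w_j^2-w^2)^2 + (2 zeta w_j w)^2)^-1
        q = f_j * drive_pressure / (omega_j ** 2 - omega ** 2
                                    + 2j * damping * omega_j * omega)
        total = total + q * phi
    amplitude = np.abs(total)
    return DisplacementField(np.where(ref.mask, amplitude, np.nan), ref.mask,
                             px, ref.radius_m, unit="m")


def frequency_sweep(modes, damping: float, assembly: PlateAssembly,
                    range_hz: tuple[float, float] = (70.0, 500.0),
                    step_hz: float = 1.0, drive_pressure: float = 1.0
                    ) -> SweepResult:
    """Centre-pixel response over the drive-frequency grid, with peak picking."""
    if step_hz <= 0:
        raise ValueError("step must be positive")
    freqs = np.arange(range_hz[0], range_hz[1] + 0.5 * step_hz, step_hz)
    normalized = _mass_normalized(list(modes), assembly)
    ref = normalized[0][0].shape
    ci = ref.center_index
    px = ref.pixel_size_m
    centre_phi = np.array([phi[ci] for _, phi in normalized])
    f_j = np.array([np.sum(phi) * px * px for _, phi in normalized])
    omega_j = 2.0 * math.pi * np.array([m.frequency_hz for m, _ in normalized])
    omega = 2.0 * math.pi * freqs[:, None]
    q = f_j * drive_pressure / (omega_j ** 2 - omega ** 2
                                + 2j * damping * omega_j * omega)
    response = np.abs(q @ centre_phi)
    idx, props = signal.find_peaks(response,
                                   prominence=PEAK_PROMINENCE * response.max())
    peaks = tuple((float(freqs[i]), float(p))
                  for i, p in zip(idx, props["prominences"]))
    return SweepResult(freqs, response, peaks, damping)


# ---------------------------------------------------------------------------
# identification
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok] - a[ok].mean(), b[ok] - b[ok].mean()
    denom = math.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom else 0.0


def _nodal_circles(shape: DisplacementField) -> int:
    prof = radial_median_profile(shape.values)
    prof = prof[np.isfinite(prof)]
    # ignore near-zero samples (boundary zero, numerical noise) when counting
    strong = prof[np.abs(prof) > 1e-3 * np.abs(prof).max()]
    return int((np.diff(np.sign(strong)) != 0).sum())


def _nodal_diameters(shape: DisplacementField) -> int:
    angles = np.linspace(0.0, 2.0 * np.pi, 360, endpoint=False)
    r = 0.5 * shape.radius_m
    ring = shape.sample(r * np.cos(angles), r * np.sin(angles))
    ring = ring[np.isfinite(ring)]
    strong = ring[np.abs(ring) > 1e-3 * np.abs(ring).max()]
    crossings = (np.diff(np.sign(np.append(strong, strong[0]))) != 0).sum()
    return int(crossings // 2)


def classify_mode(shape: DisplacementField, candidates) -> ModeAssignment:
    """Assign the candidate identity with maximum |Pearson correlation|.

    Sign-invariant (a mode and its negation classify identically). Nodal
    circles/diameters are counted from the shape itself: interior sign
    changes of the radial median profile, and half the sign changes around a
    mid-radius circle.
    """
    if shape.max_abs() == 0:
        raise ValueError("cannot classify an all-zero shape")
    best = None
    for identity, cand in candidates:
        c = abs(_pearson(shape.values, cand.values))
        if best is None or c > best[1]:
            best = (identity, c)
    if best is None:
        raise ValueError("no candidates given")
    return ModeAssignment(best[0], best[1], _nodal_circles(shape),
                          _nodal_diameters(shape))
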