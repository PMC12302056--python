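"""Forward synthesis of holographic vibrometry observables.

Given a transverse displacement field W (metres), this module produces the
two raw observables of the assay:

* time-average intensity images, I = A0^2 J0(Omega |W|)^2, whose dark rings
  sit at the zeros of J0 — the classic time-average fringe pattern;
* stroboscopic four-step phase-shifted frame sets, I_k = Ar^2 + A0^2 +
  2 Ar A0 cos(phi - delta_k), demodulated downstream via the complex
  combination (I3 - I1) + i (I4 - I2).

Omega = 4 pi / wavelength is the out-of-plane sensitivity for normal
illumination and observation; for a 532 nm laser one radian of optical phase
corresponds to 42.3 nm of displacement. Optional noise: a seeded
multiplicative unit-mean gamma speckle field plus additive Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .fields import DisplacementField
from .phase_analysis import WrappedPhaseMap, wrap

__all__ = ["OpticalConfig", "HologramFrameSet", "TimeAverageImage",
           "time_average_image", "phase_shifted_frames", "complex_image",
           "stroboscopic_series"]

_CANONICAL_STEPS = (0.0, math.pi / 2, math.pi, 3 * math.pi / 2)


@dataclass(frozen=True)
class OpticalConfig:
    """Laser/interferometer description plus the noise model.

    ``object_amplitude`` may be a scalar or an image A0(x, y);
    ``speckle_contrast`` in [0, 1] parameterizes the gamma speckle field
    (0 disables it) and ``additive_sigma`` the Gaussian term, both seeded.
    """

    wavelength: float = 532e-9
    object_amplitude: float | np.ndarray = 1.0
    reference_amplitude: float = 1.0
    phase_steps: tuple[float, ...] = _CANONICAL_STEPS
    strobe_points: int = 12
    speckle_contrast: float = 0.0
    additive_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if len(self.phase_steps) != 4 or not np.allclose(
                np.diff(self.phase_steps), math.pi / 2):
            raise ValueError("phase steps must be four values in pi/2 increments")
        if self.strobe_points < 3:
            raise ValueError("need at least 3 strobe points per cycle")
        if not 0 <= self.speckle_contrast <= 1:
            raise ValueError("speckle contrast must be in [0, 1]")
        if self.additive_sigma < 0:
            raise ValueError("additive noise sigma must be >= 0")

    @property
    def sensitivity(self) -> float:
        """Omega = 4 pi / wavelength, rad per metre of displacement."""
        return 4.0 * math.pi / self.wavelength


@dataclass
class HologramFrameSet:
    """Four phase-stepped intensity frames at one strobe point of the cycle."""

    frames: np.ndarray           # (4, n, n), dimensionless >= 0
    phase_steps: tuple[float, ...]
    strobe_phase: float
    reference_state: bool

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.shape[0] != 4:
            raise ValueError("a frame set holds exactly 4 phase-stepped frames")


@dataclass
class TimeAverageImage:
    intensity: np.ndarray
    mask: np.ndarray


def _check_meters(W: DisplacementField) -> None:
    if W.unit != "m":
        raise ValueError(f"displacement field must be in metres, got unit {W.unit!r}")


def time_average_image(W: DisplacementField, optics: OpticalConfig) -> TimeAverageImage:
    """I(x, y) = A0^2 J0(Omega |W|)^2; invalid pixels stay invalid (NaN).

    The configured speckle/additive noise, if any, is applied on top (so the
    J0^2 ceiling holds exactly only for noise-free synthesis).
    """
    _check_meters(W)
    a0 = np.asarray(optics.object_amplitude, dtype=float)
    intensity = a0 ** 2 * special.j0(optics.sensitivity * np.abs(W.values)) ** 2
    if optics.speckle_contrast > 0 or optics.additive_sigma > 0:
        intensity = _apply_noise(np.where(W.mask, intensity, 0.0), optics,
                                 np.random.default_rng(optics.seed))
    return TimeAverageImage(np.where(W.mask, intensity, np.nan), W.mask)


def _apply_noise(frames: np.ndarray, optics: OpticalConfig,
                 rng: np.random.Generator) -> np.ndarray:
    if optics.speckle_contrast > 0:
        c2 = optics.speckle_contrast ** 2
        frames = frames * rng.gamma(1.0 / c2, c2, size=frames.shape)
    if optics.additive_sigma > 0:
        frames = frames + rng.normal(0.0, optics.additive_sigma, size=frames.shape)
    return np.clip(frames, 0.0, None)


def phase_shifted_frames(W_deformed: DisplacementField, optics: OpticalConfig,
                         strobe_phase: float,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[HologramFrameSet, HologramFrameSet]:
    """Deformed and reference four-step frame sets at one strobe phase.

    The object phase is the instantaneous displacement on the vibration
    cycle, phi = Omega * W * sin(strobe_phase); the reference state is the
    undeformed plate (phi = 0). Noise, if configured, is applied to both sets
    with independent draws from the (seeded) generator.
    """
    _check_meters(W_deformed)
    if rng is None:
        rng = np.random.default_rng(optics.seed)
    ar = float(optics.reference_amplitude)
    a0 = np.asarray(optics.object_amplitude, dtype=float)
    base = ar ** 2 + a0 ** 2
    phi = optics.sensitivity * np.where(W_deformed.mask, W_deformed.values, 0.0) \
        * math.sin(strobe_phase)

    def stack(phase):
        return np.stack([base + 2.0 * ar * a0 * np.cos(phase - dk)
                         for dk in optics.phase_steps])

    deformed = _apply_noise(stack(phi), optics, rng)
    reference = _apply_noise(stack(np.zeros_like(phi)), optics, rng)
    return (HologramFrameSet(deformed, optics.phase_steps, strobe_phase, False),
            HologramFrameSet(reference, optics.phase_steps, strobe_phase, True))


def complex_image(frames: HologramFrameSet) -> np.ndarray:
    """(I3 - I1) + i (I4 - I2).

    For noise-free two-beam frames this equals -4 Ar A0 exp(i phi): the
    modulus is 4 Ar A0 and the argument is phi + pi (mod 2 pi); the constant
    pi offset cancels in every reported phase difference.
    """
    if frames.frames.shape[0] != 4:
        raise ValueError("complex combination needs exactly 4 frames")
    if not np.allclose(np.diff(frames.phase_steps), math.pi / 2):
        raise ValueError("frames are not in the canonical pi/2 step order")
    i1, i2, i3, i4 = frames.frames
    return (i3 - i1) + 1j * (i4 - i2)


def stroboscopic_series(W: DisplacementField, optics: OpticalConfig
                        ) -> list[WrappedPhaseMap]:
    """Wrapped phase-difference maps at the configured strobe points.

    Map k holds wrap(arg(deformed) - arg(reference)) at strobe phase
    2 pi k / strobe_points; with 12 points and no noise, map 0 is identically
    zero and maps k and k+6 are negatives of each other.
    """
    rng = np.random.default_rng(optics.seed)
    maps: list[WrappedPhaseMap] = []
    for k in range(optics.strobe_points):
        strobe = 2.0 * math.pi * k / optics.strobe_points
        deformed, reference = phase_shifted_frames(W, optics, strobe, rng=rng)
        dphi = np.angle(complex_image(deformed)) - np.angle(complex_image(reference))
        maps.append(WrappedPhaseMap(np.where(W.mask, wrap(dphi), np.nan), W.mask))
    return maps
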