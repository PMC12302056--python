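"""Synthetic fixtures and experiment drivers.

Presets for the engineered-skin-on-Transwell assembly (a stiff thin porous
membrane carrying a soft dermis and epidermis, on agar, water or air), the
controlled-drying time course, a spatial epidermis-defect study, and a
reduced-scale simulated-pattern classification harness.

The substrate presets map to (edge pattern, Winkler modulus): the packaging's
three supports give three clamped 30-degree arcs; agar adds an elastic bed;
air removes it; water is represented honestly as a weak bed plus a degraded
data-quality flag — fluid loading is deliberately not modelled because such
measurements were found to carry little usable signal.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fe_modal import BoundaryPattern, fe_modes
from .plate_theory import (LayerSpec, ModeIdentity, PlateAssembly,
                           characteristic_lambda, laminate_rigidity,
                           modal_frequency)

logger = logging.getLogger("holovib")

__all__ = ["DryingSchedule", "PatternDataset", "GridSpec", "apligraf_assembly",
           "drying_schedule", "drying_experiment", "generate_pattern_dataset",
           "evaluate_classifier", "epidermis_defect_experiment",
           "K_AGAR", "K_WATER", "DEFAULT_RADIUS"]

DEFAULT_RADIUS = 0.022          # m; Transwell-scale, exposed in every output
K_AGAR = 1.0e4                  # Pa/m Winkler modulus for the agar bed
K_WATER = 1.0e3                 # weak bed standing in for unusable water data

# membrane / dermis / epidermis defaults: stiff 20 um plastic membrane with
# typical tissue mid-range thicknesses and indentation-measured moduli
_DEFAULTS = {
    "radius": DEFAULT_RADIUS,
    "t_membrane": 20e-6, "e_membrane": 2.3e9, "nu_membrane": 0.33, "rho_membrane": 1000.0,
    "t_dermis": 160e-6, "e_dermis": 25e3, "nu_tissue": 0.48, "rho_tissue": 997.0,
    "t_epidermis": 75e-6, "e_epidermis": 35e3,
}

# soft plausibility bounds; outside them the preset warns but proceeds
_BOUNDS = {
    "radius": (5e-3, 50e-3),
    "t_membrane": (5e-6, 100e-6), "t_dermis": (10e-6, 500e-6),
    "t_epidermis": (0.0, 500e-6),
    "e_membrane": (1e6, 1e10), "e_dermis": (1e2, 1e6), "e_epidermis": (1e2, 1e6),
}


def apligraf_assembly(substrate: str = "agar", params: dict | None = None
                      ) -> PlateAssembly:
    """Three-layer membrane/dermis/epidermis assembly on the chosen substrate.

    ``params`` overrides any default in the preset table (keys such as
    ``t_epidermis``, ``e_dermis``, ``radius``, ``foundation_stiffness``);
    overrides outside the documented physical bounds warn rather than error.
    An epidermis override of 0 drops the layer (a fully dried or debrided
    sample).
    """
    p = dict(_DEFAULTS)
    p.update(params or {})
    for key, (lo, hi) in _BOUNDS.items():
        if key in p and not lo <= p[key] <= hi:
            logger.warning("preset override %s=%g outside plausible bounds [%g, %g]",
                           key, p[key], lo, hi)
    layers = [
        LayerSpec("membrane", p["t_membrane"], p["e_membrane"],
                  p["nu_membrane"], p["rho_membrane"]),
        LayerSpec("dermis", p["t_dermis"], p["e_dermis"],
                  p["nu_tissue"], p["rho_tissue"]),
    ]
    if p["t_epidermis"] > 0:
        layers.append(LayerSpec("epidermis", p["t_epidermis"], p["e_epidermis"],
                                p["nu_tissue"], p["rho_tissue"]))
    substrates = {
        "agar": (K_AGAR, "ok"),
        "air": (0.0, "ok"),
        "water": (K_WATER, "degraded"),
    }
    if substrate not in substrates:
        raise ValueError(f"unknown substrate {substrate!r}; options {tuple(substrates)}")
    k, quality = substrates[substrate]
    k = p.get("foundation_stiffness", k)
    return PlateAssembly(
        radius=p["radius"], layers=tuple(layers), boundary="tri_arc_clamped",
        foundation_stiffness=k, density_convention="areal",
        notes={"substrate": substrate, "data_quality": quality,
               "preset": "apligraf"},
    )


# ---------------------------------------------------------------------------
# drying time course
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DryingSchedule:
    """Layer thicknesses (m) at each oven time point (minutes)."""

    times: tuple[float, ...]
    epidermis_thickness: tuple[float, ...]
    dermis_thickness: tuple[float, ...]

    def __post_init__(self) -> None:
        if not all(b > a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        for seq in (self.epidermis_thickness, self.dermis_thickness):
            if len(seq) != len(self.times):
                raise ValueError("one thickness per time point required")
            if any(b > a for a, b in zip(seq, seq[1:])):
                raise ValueError("drying thicknesses must be non-increasing")


def drying_schedule() -> DryingSchedule:
    """Default oven time course: the epidermis thins linearly from 100 um to
    nothing by the 30 min point, the dermis from 250 um to 150 um over the
    full 90 min."""
    times = (0.0, 3.0, 6.0, 10.0, 15.0, 30.0, 60.0, 90.0)
    epi = tuple(100e-6 * max(0.0, 1.0 - t / 30.0) for t in times)
    derm = tuple(250e-6 - 100e-6 * t / 90.0 for t in times)
    return DryingSchedule(times, epi, derm)


def drying_experiment(schedule: DryingSchedule,
                      assembly_base: PlateAssembly | None = None,
                      solver: str = "analytic_laminate",
                      target_edge: float | None = None) -> pd.DataFrame:
    """Fundamental frequency at each drying time point.

    Per time point the assembly is rebuilt with the scheduled tissue
    thicknesses, everything else held at the preset values; the default is
    the on-air configuration (no foundation). ``solver`` is either the
    clamped-plate closed form on the equivalent laminate, or the tri-arc FE
    model. Solver failures leave a partial table with the error recorded.
    """
    if solver not in ("analytic_laminate", "fe"):
        raise ValueError(f"unknown solver {solver!r}")
    base = assembly_base or apligraf_assembly("air")
    rows = []
    for t, t_epi, t_derm in zip(schedule.times, schedule.epidermis_thickness,
                                schedule.dermis_thickness):
        layers = []
        for layer in base.layers:
            if layer.name == "epidermis":
                if t_epi > 0:
                    layers.append(LayerSpec(layer.name, t_epi, layer.youngs_modulus,
                                            layer.poisson, layer.density))
            elif layer.name == "dermis":
                layers.append(LayerSpec(layer.name, t_derm, layer.youngs_modulus,
                                        layer.poisson, layer.density))
            else:
                layers.append(layer)
        assembly = PlateAssembly(base.radius, tuple(layers), base.boundary,
                                 base.foundation_stiffness, "areal", base.notes)
        try:
            if solver == "analytic_laminate":
                lam2 = characteristic_lambda(ModeIdentity(0, 1), "clamped") ** 2
                f = modal_frequency(lam2, assembly).frequency_hz
            else:
                modes = fe_modes(assembly, BoundaryPattern("tri_arc"),
                                 target_edge=target_edge or base.radius / 10,
                                 n_modes=2, grid=33)
                f = next(m.frequency_hz for m in modes if not m.rigid)
            rows.append({"time_min": t, "fundamental_hz": f, "error": None})
        except Exception as err:  # record and continue: partial table contract
            rows.append({"time_min": t, "fundamental_hz": math.nan,
                         "error": str(err)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# epidermis-defect study
# ---------------------------------------------------------------------------

def epidermis_defect_experiment(substrate: str = "agar",
                                defect_size_m: float = 0.01,
                                target_edge: float | None = None,
                                grid: int = 65) -> dict:
    """Fundamental mode with and without a square epidermis-free region.

    The defect zeroes the epidermis layer over a centred square in the FE
    rigidity/density maps. Only a shape-delta report is promised — observed
    effects of such defects are inconsistent, so no detection claim is made.
    """
    intact = apligraf_assembly(substrate)
    stripped = apligraf_assembly(substrate, {"t_epidermis": 0.0})
    lam_in = laminate_rigidity(intact.layers)
    lam_out = laminate_rigidity(stripped.layers)
    half = defect_size_m / 2.0

    def inhom(xc, yc):
        inside = (np.abs(xc) <= half) & (np.abs(yc) <= half)
        d = np.where(inside, lam_out.d_eff, lam_in.d_eff)
        mu = np.where(inside, lam_out.areal_density, lam_in.areal_density)
        return d, mu

    edge = target_edge or intact.radius / 12
    ref = fe_modes(intact, BoundaryPattern("tri_arc"), edge, n_modes=1, grid=grid)[0]
    defect = fe_modes(intact, BoundaryPattern("tri_arc"), edge, n_modes=1,
                      grid=grid, inhomogeneity=inhom)[0]
    delta = np.nanmax(np.abs(defect.shape.values - ref.shape.values))
    return {
        "intact_hz": ref.frequency_hz,
        "defect_hz": defect.frequency_hz,
        "frequency_shift_hz": defect.frequency_hz - ref.frequency_hz,
        "max_shape_delta": float(delta),
    }


# ---------------------------------------------------------------------------
# classification harness (reduced-scale stand-in)
# ---------------------------------------------------------------------------

PARAM_NAMES = ("t_epidermis", "t_dermis", "e_epidermis", "e_dermis")


@dataclass(frozen=True)
class GridSpec:
    """Factorial grid over the tissue parameter ranges used in the parametric
    modal study (thicknesses 50-200 um, epidermis 20-60 kPa, dermis 3-20 kPa).
    ``jitter`` adds seeded uniform perturbations of +-jitter x grid step."""

    n_t_epi: int = 6
    n_t_derm: int = 6
    n_e_epi: int = 4
    n_e_derm: int = 4
    t_epi_range: tuple[float, float] = (50e-6, 200e-6)
    t_derm_range: tuple[float, float] = (50e-6, 200e-6)
    e_epi_range: tuple[float, float] = (20e3, 60e3)
    e_derm_range: tuple[float, float] = (3e3, 20e3)
    jitter: float = 0.0
    target_edge_fraction: float = 8.0   # mesh edge = radius / fraction
    raster: int = 32


@dataclass
class PatternDataset:
    patterns: np.ndarray            # (N, raster, raster) fundamental shapes
    parameters: pd.DataFrame        # columns PARAM_NAMES
    labels: np.ndarray              # (N, 4) bool, > dataset mean per parameter
    seed: int

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.patterns).tobytes())
        h.update(self.parameters.to_csv(index=False).encode())
        return h.hexdigest()


def generate_pattern_dataset(grid_spec: GridSpec = GridSpec(), seed: int = 0
                             ) -> PatternDataset:
    """Deterministic (seeded) dataset of tri-arc fundamental mode patterns."""
    gs = grid_spec
    axes = [np.linspace(*gs.t_epi_range, gs.n_t_epi),
            np.linspace(*gs.t_derm_range, gs.n_t_derm),
            np.linspace(*gs.e_epi_range, gs.n_e_epi),
            np.linspace(*gs.e_derm_range, gs.n_e_derm)]
    combos = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 4)
    rng = np.random.default_rng(seed)
    if gs.jitter > 0:
        steps = np.array([(ax[-1] - ax[0]) / max(len(ax) - 1, 1) for ax in axes])
        combos = combos + rng.uniform(-gs.jitter, gs.jitter, combos.shape) * steps
    patterns = []
    for t_epi, t_derm, e_epi, e_derm in combos:
        assembly = apligraf_assembly("agar", {
            "t_epidermis": t_epi, "t_dermis": t_derm,
            "e_epidermis": e_epi, "e_dermis": e_derm})
        mode = fe_modes(assembly, BoundaryPattern("tri_arc"),
                        target_edge=assembly.radius / gs.target_edge_fraction,
                        n_modes=1, grid=gs.raster)[0]
        patterns.append(mode.shape.values)
    parameters = pd.DataFrame(combos, columns=PARAM_NAMES)
    labels = (combos > combos.mean(axis=0)).astype(bool)
    return PatternDataset(np.stack(patterns), parameters, labels, seed)


def evaluate_classifier(dataset: PatternDataset, split_fraction: float = 0.75,
                        classifier: str = "nearest_centroid") -> dict:
    """Per-parameter above/below-mean test accuracy of a baseline classifier.

    The split is a seeded permutation; the baseline is nearest centroid on
    flattened patterns. A parameter whose labels are single-valued (degenerate
    grid) reports None.
    """
    if classifier != "nearest_centroid":
        raise ValueError(f"unknown classifier {classifier!r}")
    if not 0 < split_fraction < 1:
        raise ValueError("split fraction must be in (0, 1)")
    n = len(dataset.patterns)
    flat = np.nan_to_num(dataset.patterns.reshape(n, -1))
    rng = np.random.default_rng(dataset.seed)
    order = rng.permutation(n)
    n_train = max(1, int(round(split_fraction * n)))
    train, test = order[:n_train], order[n_train:]
    out = {}
    for j, name in enumerate(PARAM_NAMES):
        y = dataset.labels[:, j]
        if y[train].all() or (~y[train]).all() or len(test) == 0:
            out[name] = None
            continue
        c0 = flat[train][~y[train]].mean(axis=0)
        c1 = flat[train][y[train]].mean(axis=0)
        d0 = ((flat[test] - c0) ** 2).sum(axis=1)
        d1 = ((flat[test] - c1) ** 2).sum(axis=1)
        out[name] = float(((d1 < d0) == y[test]).mean())
    return out
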