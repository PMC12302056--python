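# holovib

Simulation and analysis toolkit for **digital holographic vibrometry (DHV)**
of membrane-supported engineered tissues — the noncontact, nondestructive QC
setting where a circular skin substitute, cultured on a stiff porous Transwell
membrane inside its sterile packaging, is vibrated acoustically and its
nanometre-scale surface motion is read out interferometrically.

It is written for tissue-engineering and biomedical-optics groups who want to
(i) predict what vibration patterns and resonance frequencies such a layered
disc should show under realistic packaging boundary conditions, (ii) render
the raw holographic observables (time-average fringes, phase-stepped
stroboscopic frame sets) for those patterns, and (iii) run the full inverse
chain from fringe images back to displacement fields and structural stiffness.

## The model

A circular plate of radius *a* vibrating transversely obeys classical
(Kirchhoff) thin-plate theory. Each mode — identified by its nodal diameters
*n* and radial mode number *m* — has a dimensionless eigenvalue λ obtained
from the Bessel characteristic equation of the edge condition, and a natural
frequency given by

    λ² = ω a² √(ρ / D),      D = E h³ / 12(1 − ν²),

with *D* the flexural rigidity, *E* Young's modulus, *h* thickness, ν the
Poisson ratio and ρ a density (both the dimensionally standard areal
convention, kg/m², and the volume-density literal form used in published
back-calculations are supported — the convention in force is always explicit).
A bonded layer stack (porous membrane / dermis / epidermis) is reduced to one
effective rigidity about its neutral axis by classical lamination, and a
finite-element Morley-plate model adds what the closed form cannot: three
clamped 30° arcs emulating the packaging supports, free edges, a Winkler
elastic bed for the agar, and spatial defects.

The optical forward model produces time-average intensities
I = A₀² J₀(Ω|W|)², whose dark rings sit at the zeros of J₀, and four-step
phase-shifted frames demodulated via I꜀ = (I₃−I₁) + i(I₄−I₂); Ω = 4π/λ_laser,
i.e. 42.3 nm of displacement per radian of optical phase at 532 nm. The
inverse chain is masked 2D phase unwrapping, phase-to-displacement
conversion, and per-pixel harmonic fitting over the 12-point strobe cycle.

## Worked example

```python
import holovib as hv

asm = hv.apligraf_assembly("air")          # membrane/dermis/epidermis, no bed
lam = hv.laminate_rigidity(asm.layers)
print(lam.d_eff, lam.per_layer_share)

modes = hv.analytic_vibration_modes(
    asm, [hv.ModeIdentity(0, m) for m in range(1, 9)])
sweep = hv.frequency_sweep(modes, damping=0.02, assembly=asm)
print([round(f, 1) for f, _ in sweep.peaks])
```

prints (numbers from this exact run):

```
1.922e-06 (0.895, 0.028, 0.077)
[81.0, 143.0, 223.0]
```

The first line says the equivalent rigidity of the stack is 1.92e-6 N·m and
that the 20 µm plastic membrane alone carries 89.5% of it — the tissue layers
are almost invisible to a bending measurement, which is why single-layer
inversion of a measured resonance returns an absurd ~1200 GPa apparent
modulus. The second line is the simulated loudspeaker sweep: of the order-0
ladder only three resonances couple strongly enough to a uniform acoustic
pressure to be detected in the 70–500 Hz band, matching the handful of modes
such sweeps identify in practice.

The same workflow is scriptable from the shell:

```sh
holovib preset --name apligraf-air --out preset.json
holovib sweep --config preset.json --out sweep.csv
holovib synth --mode 0 1 --boundary clamped --amp-nm 150 --out frames/
holovib unwrap --in frames/ --out displacement/
holovib drying --out drying.csv
```

`holovib drying` reproduces the drying experiment: as the epidermis thins
from 100 µm to nothing and the dermis from 250 µm to 150 µm, the fundamental
frequency rises strictly monotonically (8.5 → 10.8 Hz for the analytic
laminate on air) because the mass loss outweighs the small rigidity loss.

## Layout

| module | contents |
| --- | --- |
| `holovib.plate_theory` | eigenvalue roots, rigidity algebra and inversions, laminate reduction, Bessel mode shapes, string relation |
| `holovib.fe_modal` | symmetric disc meshing, Morley plate elements, boundary patterns, Winkler bed, sparse eigensolution |
| `holovib.holography_sim` | optical configuration, time-average and phase-stepped frame synthesis, noise models |
| `holovib.phase_analysis` | wrapping/unwrapping on masked discs, displacement conversion, harmonic fits, fringe counting |
| `holovib.mode_id` | forced response, frequency sweeps, peak detection, mode classification |
| `holovib.scenarios` | presets (agar/water/air), drying schedule and experiment, defect study, classification harness |
| `holovib.cli` | the `holovib` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
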