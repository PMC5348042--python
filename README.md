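# axonskel

Coarse-grain molecular dynamics of the **axon plasma-membrane skeleton** —
the periodic cytoskeleton of unmyelinated axons in which circumferential
actin rings, spaced ~185 nm, are connected by longitudinal spectrin
tetramers held under entropic tension and anchored to the lipid bilayer
through ankyrin/Naᵥ-channel complexes.

The package is for biophysicists who want to probe how this geometry shapes
the axon's mechanics: it implements the bead-spring model, the NVT
dynamics, and the three in-silico experiments used to interrogate it —
radial-expansion stiffness, thermal motion of the ankyrin-bound sodium
channels, and laceration/re-association of spectrin filaments — plus the
closed-form AFM force-indentation analysis used to interpret indentation
measurements on living neurons.

## The model

Reduced units: length σ = 4.45 nm (so the bead-bead repulsion minimum
2^{1/6}σ equals the 5 nm spectrin repeat), energy ε = k_BT/0.03 ≈ 0.86 eV
at 300 K (the actin-spectrin association energy), mass m = 1 per bead,
time t_s = √(mσ²/ε), timestep dt = 0.01 t_s.

| element | representation | potential |
|---|---|---|
| spectrin tetramer | 41 beads, 40 springs, contour 200 nm | U = ½k₀(r−5 nm)², k₀ = 3.56 ε/σ²; plus shifted repulsive LJ (ε/16, cutoff 5 nm) between all beads |
| actin ring | 39 beads of 35 nm, ring ∅ ≈ 434 nm | springs k_A = 38 ε/σ² (≈0.26 N/m) + FENE bending, k_b = 3500 k_BT, θ₀ = 170.77°, Δθ_max = 0.3 θ₀ |
| actin–spectrin junction | breakable LJ, 4ε[(4σ/r)¹²−(4σ/r)⁶] | breaks past the inflexion (26/7)^{1/6}·4σ ≈ 22.15 nm, re-forms within 2.5·4σ ≈ 44.5 nm |
| microtubule support | FENE on consecutive ring-centre spacings | k_mt = 477 k_BT/σ = 0.3·E_L·πR² (E_L = 10 kPa, R = 217 nm) |
| ankyrin/Naᵥ anchor | 1 bead per filament at the 20th spectrin bead | spring k₀ with 15 nm rest; two-sided radial confinement at 232 nm |
| lipid bilayer | implicit | one-sided (outward) confinement of spectrin at 217 nm, k_c = 0.1 k₀ |

Dynamics: Beeman integration with a Berendsen thermostat at k_BT/ε = 0.03.

## Worked example

```python
from axonskel import ModelConfig, make_preset, make_afm_dataset
from axonskel.afm import fit_modulus, summarize_grid
from axonskel.protocols import channel_density, free_filament_stats, prepare_axon, ankyrin_motion

# geometry: one Nav channel per spectrin tetramer
print(f"channel density: {channel_density(ModelConfig()):.1f} per um^2")

# thermal statistics of a free spectrin tetramer
stats = free_filament_stats(production_steps=200_000, seed=1)
print(f"free spectrin: rms r_ee = {stats.rms_ree_nm:.1f} nm, l_p = {stats.lp_nm:.1f} nm")

# a synthetic 16x16 AFM force map of a 4.6 kPa axon, fitted and summarised
curves = make_afm_dataset(E_true=4.6, n_curves=256, noise_frac=0.10, seed=2)
summary = summarize_grid([fit_modulus(c) for c in curves])
print(f"AFM grid: median E = {summary.median_kPa:.2f} +/- {summary.spread_kPa:.2f} kPa")
```

prints

```
channel density: 154.3 per um^2
free spectrin: rms r_ee = 47.0 nm, l_p = 5.5 nm
AFM grid: median E = 4.60 +/- 0.10 kPa
```

The channel density falls in the physiological 110–300 µm⁻² range of the
axon initial segment; the fitted force-map median recovers the ground-truth
modulus.  A full equilibrated axon is two lines:

```python
sim = prepare_axon(ModelConfig(n_rings=3), seed=0)      # assemble + ramp + thermalise
ank = ankyrin_motion(sim, production_steps=1_000_000)   # channel-lattice statistics
```

A command-line interface mirrors the protocols:
`axonskel run | expand | ankyrin | lacerate | filament | bending | fixtures | afm-fit`.

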