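# Methods

## Model

The axon membrane skeleton is represented by three particle kinds in
reduced units (σ = 4.45 nm, ε = k_BT/0.03 at 300 K, unit bead mass, time
t_s = √(mσ²/ε)):

* **Actin rings.** 39 beads of diameter 35 nm on a circle of ≈ 434 nm
  diameter, one ring every `ring_spacing_nm` (default 185 nm, alternate
  110 nm) along z.  Adjacent beads interact through harmonic springs
  (k_A = 38 ε/σ², rest 35 nm) and a finitely extensible (FENE) bending
  restraint on each consecutive triple,
  U_b = −½ k_b Δθ_max ln[1 − ((θ−θ₀)/Δθ_max)²], with k_b = 3500 k_BT,
  θ₀ = 180°·37/39 = 170.77°, Δθ_max = 0.3 θ₀.  Near equilibrium this is
  harmonic with k_θ = k_b/Δθ_max; Δθ_max only caps the maximum deformation.
* **Spectrin tetramers.** 39 filaments per inter-ring gap, each 41 beads /
  40 springs (k₀ = 3.56 ε/σ², rest 5 nm, contour 200 nm).  All spectrin
  beads repel through the shifted, purely repulsive 12-6 potential with
  well depth ε₁ = ε/16 and cutoff at the 5 nm minimum; ε₁ is chosen so the
  curvature at the minimum equals k₀.
* **Junctions.** Each filament end binds one designated actin bead through
  a breakable LJ potential 4ε[(4σ/r)¹² − (4σ/r)⁶] (minimum ≈ 20 nm, i.e. a
  ~40 nm actin junction).  The attraction is switched off when an intact
  pair crosses the inflexion point (26/7)^{1/6}·4σ ≈ 22.15 nm and restored
  when a broken pair re-enters the capture radius 2.5·4σ ≈ 44.5 nm; the
  repulsive core below the minimum is always active.  Between the two
  thresholds the literal rules alternate the state per step; this is
  transient in practice and the laceration protocol reports a cumulative
  (monotone) reconnected fraction.
* **Ankyrin/Naᵥ anchors.** One bead per filament, bound to the filament's
  20th bead by a k₀ spring of rest length 15 nm (spectrin radius 2.5 nm +
  ankyrin-complex effective radius 12.5 nm) and confined two-sidedly at
  radius 232 nm.  One channel per anchor gives ≈ 150 channels/µm² on the
  434 nm cylinder, inside the 110–300 µm⁻² physiological range.
* **Implicit bilayer and microtubules.**  Spectrin feels a one-sided
  harmonic wall (k_c = 0.1 k₀) beyond radius 217 nm (it may move inward
  freely); consecutive ring-centre spacings (mean z per ring) carry a FENE
  restraint with k_mt = 477 k_BT/σ, the value obtained by matching the
  small-deformation spring constant k_mt/Δd_max to a 10 kPa longitudinal
  Young's modulus over the πR² cross-section (R = 217 nm), with
  Δd_max = 0.3·d_eq.  The axial FENE force on a ring is distributed
  equally over its 39 beads (chain rule through the mean).
* **Steric repulsions** act between all non-bonded pairs (and between
  bonded spectrin neighbours, as above) with additive per-kind radii in σ:
  actin 3.5, spectrin 0.5, ankyrin 2.5.  These close exactly on the
  model's stated pair scales (S-S σ, A-A 7σ ≈ 35 nm, S-K 3σ ≈ 15 nm,
  A-S 4σ ≈ 20 nm); the unstated A-K (6σ) and K-K (5σ) pairs follow the
  same rule.  Pair well depth is ε₁ = ε/16 for S-S and ε otherwise.
  The designated junction pairs are excluded from the generic steric sum
  (their interaction is entirely the breakable LJ).

## Dynamics

Beeman integration (positions third-order accurate; the first step sets
the previous acceleration equal to the current one, making the position
update velocity-Verlet) with dt = 0.01 t_s, and a Berendsen thermostat at
k_BT/ε = 0.03 with coupling time τ_T = 100 dt — weak enough that the
fluctuation statistics the protocols measure are not visibly distorted.
Initial velocities are Maxwell-Boltzmann at the target temperature from
the run seed; a run is bit-reproducible from (config, seed).

Two rigid-body controls are applied, as in mainstream MD engines:

* free filaments have net linear *and* angular momentum removed at
  initialization and every 10³ steps — in vacuum both are conserved, and
  integrator round-off regenerates them slowly, after which velocity
  rescaling amplifies the rigid rotation at the expense of internal motion
  (a free chain otherwise winds up to full extension within ~10⁶ steps);
* the built axon, whose external restraints are axisymmetric, has net z
  translation and rigid rotation about the z axis removed on the same
  schedule.

Ring azimuthal orientation remains a zero mode: nothing in the model pins
an individual ring's rotation about the axis, so on long runs rings
diffuse azimuthally relative to each other.  This inflates the
circumferential component of single-particle trajectory statistics with
observation time (see Limitations).

**Assembly and equilibration.**  Axons are assembled stress-free at ring
spacing 2·junction + contour (240 nm with defaults), where every bond and
steric pair is exactly at rest, and the inter-ring FENE equilibrium is
then ramped linearly (≈200 steps/nm) to the working spacing before
thermalisation (10⁶ steps for production measurements).  Building directly
at the working spacing places 41 beads on a 70–145 nm segment (1.75–3.6 nm
apart against a 5 nm repulsion range) and the resulting force spike breaks
most junctions at 110 nm spacing.  A per-particle force cap of 10³ ε/σ is
available for such artificial starts and is never active during
measurement windows.

Neighbour search: one cell-grid pass with per-kind-pair list radii
(cutoff + 1σ skin), rebuilt when any particle has moved more than half the
skin.  Forces are analytic throughout and verified against central
differences of the total energy at 10⁻⁶ relative tolerance.

## Measurement protocols and desk-scale sizes

All production measurements use a 3-ring axon (3393 particles); stiffness
and per-filament statistics are intensive, which the suite checks directly
(E_between agrees within 15 % between 3- and 5-ring models).

* **Free-filament statistics.** 10⁵ equilibration + 5×10⁵ production
  steps, end-to-end distance sampled every 200 steps; l_p inferred from
  ⟨r_ee²⟩ = 2 l_p L_c.  An independent Metropolis Monte Carlo sampler of
  the same Hamiltonian (pivot + single-bead moves, in the test suite)
  cross-checks the MD sampling.
* **Bending rigidity.** A straight 35 nm-bead filament with ring bond and
  bending parameters, first two beads clamped; κ from the clamped-
  cantilever relation ⟨δu²⟩ = L³k_BT/(3κ) per transverse direction, L
  measured from the last clamped bead.  At the default k_b this yields
  κ ≈ 5×10⁻²⁵ N·m², consistent with the discrete-rod estimate
  κ = (k_b/Δθ_max)·a and several-fold above the ~7×10⁻²⁶ N·m² of bare
  F-actin — the rings are deliberately stiffer than a single filament.
* **Radial expansion.** A cylindrical repulsive wall
  4ε[(σ_w/(r_i−(r_c−r_k)))¹² − …] (σ_w = σ for spectrin, 7σ for actin;
  cutoff at the minimum ≈ r_c + r_k) is activated at r_c = 217 nm, allowed
  to settle 2000 capped steps, and grown 0.5 nm per increment (1000
  transition + 1000 settling steps), 20 increments to 227 nm.  Radial wall
  forces are accumulated every step over a 2000-step window (an 8000-step
  window is the protocol's full size; the window length only sets the
  averaging noise of each increment's mean pressure), summed
  over 80 nm stripes centred on the ring planes and the complementary
  105 nm between-ring stripes, and divided by the lateral stripe area at
  the current wall radius.  Mean stripe pressure vs radius change is fit
  by ordinary least squares and inverted with thin-shell theory
  E = pR²/(δH), R = 217 nm, H = 10 nm.
* **Ankyrin motion.** Positions sampled every 10⁴ steps over 10⁶ steps.
  Per anchor: RMS deviation from its mean position in the local (z,
  circumferential-arc) plane, averaged over anchors; pooled z-deviations
  normalised by the measured mean anchor spacing L_c give the order
  statistic s = std(d(z)/L_c).  Anchors riding on detached filaments (a
  junction broken at the end of the run) are excluded by default: the
  statistic characterises the connected channel lattice, and a single
  free anchor wandering over tens of nanometres swamps it.  The raw
  all-anchor estimator is available (``exclude_detached=False``) and the
  excluded count is reported.
* **Laceration.** 15 angularly contiguous filaments of one gap are
  detached at one end (junction forced broken, recapture suppressed), the
  system evolves 10⁴ steps, recapture at 2.5·4σ is re-enabled, and
  reconnections to the original junctions are recorded for 5×10⁴ steps
  over three velocity seeds.  The severed junctions are placed on the
  gap's interior ring: a ring that keeps tethers on both sides stays
  upright, whereas an end ring that loses over a third of its tethers
  tilts freely (only mean ring plane positions are restrained) and carries
  its junctions away from the severed ends.

## Synthetic data

`make_preset` freezes the documented systems (free filaments, 2/3/11-ring
axons at 185 nm, a 3-ring axon at 110 nm).  `make_afm_dataset` emulates a
16×16 indentation force map: power-law curves F = A(geometry)·E·d^α
(thin-walled cylinder A = 4.41×10⁻³, α = 1.37; cuboid A = 7.95×10⁻³,
α = 1.46; d in nm, E in kPa, F in pN) with independent multiplicative
Gaussian noise per point.  It makes no attempt to emulate adhesion, drift,
or contact-point error of real force curves, so recovery tests demonstrate
the estimator's correctness, not robustness to real AFM artefacts.
Modulus fitting holds the exponent fixed and solves the single linear
coefficient on the first 100 nm of indentation; grids are summarised by
median and robust spread (1.4826·MAD).

## Limitations and known discrepancies

Reference values quoted for this model family in the literature are not
all reproduced by the equations as printed; the implementation follows the
printed equations and reports what they give.

* **Free-spectrin end-to-end distance.**  The 41-bead chain with ε/16
  repulsion at k_BT = 0.03 ε has an equilibrium RMS end-to-end of ≈ 50 nm
  (MD; 54 nm by independent Monte Carlo), i.e. l_p ≈ 6 nm — inside no-
  repulsion (32 nm) and strong-repulsion (56 nm) brackets, but below the
  74.3 nm / 13.8 nm sometimes associated with this chain and below
  spectrin's experimental persistence length of 10–20 nm.  A chain this
  short-ranged cannot reach l_p ≈ 14 nm: tangent correlations would
  require bend exclusion far beyond the 5 nm repulsion range.
* **Expansion stiffness scale.**  At activation the wall minimum for kind
  k sits at r_c + r_k, 2 nm (spectrin) and ~17 nm (actin) outside the
  built skeleton, so the wall immediately loads the network; carrying
  spectrin against the fixed bilayer confinement and inflating k_A-stiff
  rings both cost ~ε/σ² per bead, which makes all three stripe moduli come
  out in the tens of MPa (E_between ≈ 50, E_ring ≈ 27, E_avg ≈ 38 ε/σ³,
  a few % seed variation, r² ≥ 0.99) rather than the kPa scale of AFM
  measurements on axons: the
  measurement as defined probes the restraint fields and ring hoop
  elasticity, not the entropic network alone.  The internal identity —
  whole-axon modulus = 80/105-width-weighted stripe mean — holds exactly,
  and E_between is intensive in ring count.
* **Ankyrin amplitudes.**  The anchor spring's rest length equals the
  built ankyrin-spectrin distance, so its transverse (z, arc) stiffness
  vanishes to first order, and ring azimuthal orientation is a zero mode;
  trajectory radii (~20 nm) and order statistics (s ≈ 0.1 under tension,
  ≈ 0.2–0.5 near equilibrium) are therefore several-fold larger than the
  ~5 nm / 0.027–0.091 scale expected for a tightly coupled anchor, and the
  slow components grow with observation time.  The anchor spacings
  (≈181 nm and ≈110 nm) are robust; the tension/equilibrium ordering of s
  holds in most runs but can invert on desk-scale runs when the slow
  wander at 185 nm happens to dominate the pooled deviations.
* **Laceration re-association.**  Because the chain's equilibrium
  end-to-end (~50 nm) is below the 70 nm junction-to-junction span at
  110 nm spacing, a severed end coils around its remaining anchor 60–110 nm
  from its original junction and re-enters the 44.5 nm capture radius only
  sporadically: desk-scale reconnection is ~10–40 % within 10⁴ steps,
  well below the ~85 % expected when the coil size matches the span.  The
  tension/no-tension contrast (zero reconnections at 185 nm) is robust.
  About 4 % of junctions also break spontaneously while tension develops
  during preparation at 185 nm; the count is then stable for >10⁶ steps.
* The Berendsen thermostat does not sample a strict canonical ensemble;
  fluctuation statistics carry a weak-coupling bias.
* No solvent, hydrodynamics, bilayer particles, or actin turnover; ring
  bead counts are fixed; bond time scales are not mapped to physical time
  (the bead mass is notional), so step counts, not seconds, parameterise
  all kinetics.
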