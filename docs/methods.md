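# Methods

## The model

`nanogelmc` simulates one thermosensitive, positively charged nanogel (and
the nanoparticles it absorbs) in a periodic cubic box, with a
coarse-grained bead model sampled by canonical Metropolis Monte Carlo, and
compares the results with a mean-field Poisson–Boltzmann cell (PBC) model
of the same system.

Monomeric units, cross-linkers, small ions and nanoparticles are spheres in
a continuous dielectric (water).  Four interactions act between beads:

1. **Excluded volume** — a purely repulsive WCA potential,
   `u(r) = ε_WCA [(d/r)^12 − (d/r)^6 + 1/4]` for `r ≤ 2^(1/6) d`, zero
   beyond, with `d = (d_i + d_j)/2`.  The implementation uses the minus
   sign between the two power terms: it is the unique sign choice that is
   continuous (zero) at the stated cutoff and purely repulsive.  No
   conventional factor 4 is applied to the printed ε_WCA.
2. **Bonds** — harmonic springs `u(r) = ½ k_e (r − r_0)²` between
   chain-adjacent beads and chain ends and cross-linkers.
3. **Electrostatics** — Coulomb interactions between all charged beads,
   `u(r)/k_BT = z_i z_j l_B(T)/r`, with the Bjerrum length
   `l_B = e²/(4π ε₀ ε_r(T) k_B T)` and an empirical ε_r(T) polynomial for
   liquid water (ε_r ≈ 78.4 at 25 °C, decreasing with T).  Periodic sums
   are evaluated by Ewald summation under conducting (tinfoil) boundary
   conditions.
4. **Hydrophobicity** — a sigmoidal approximation to a square well,
   `u(r) = −(ε_h/2)(1 − tanh(k_h (r − r_h)))`, acting **only between
   uncharged network beads**.  Its depth switches on with temperature,
   `ε_h(T) = (ε_max/2)(1 + tanh(k_{ε/2}(T − T_{ε/2})))`, which is what
   makes the gel collapse on heating.  The parameter set reproduces the
   swelling behaviour of PNIPAM-based microgels.

Defaults (`ModelParams`): ε_WCA = 4.11e−21 J, k_e = 0.40 N/m,
r₀ = 0.65 nm, k_h = 12.1 nm⁻¹, r_h = 0.90 nm, ε_max = 5.5e−21 J,
T_{ε/2} = 307.5 K, k_{ε/2} = 0.0667 K⁻¹; diameters 0.65 nm
(monomers/cross-linkers), 0.70 nm (ions), 5.0 nm (nanoparticles).

**Units.**  Lengths are nm, temperatures K (the CLI accepts °C), charges
elementary units.  All energies are reduced to k_BT at the run temperature
when a `ThermoState` is constructed; Metropolis acceptance only ever sees
u/k_BT, which avoids underflow and spurious unit conversions in the inner
loop.

## Network construction

Cross-linkers occupy sites of a diamond lattice whose nearest-neighbour
spacing is `(monomers_per_chain + 1)·r₀`, so the straight connecting
chains start exactly at their relaxed bond length (the initial network is
stress-free).  A trimming sphere is centred on a **tetrahedral interstitial
hole** of the lattice and its radius chosen by scanning the sorted site
distances for the value enclosing exactly the requested number of sites
(ties broken lexicographically; an exact count that cannot be reached
raises an error listing the achievable counts).  This centring is the
design choice that makes the reference systems come out exactly: 66
surviving sites induce exactly 100 nearest-neighbour bonds with
cross-linker functionality 4 in the interior and 2–3 at the surface, i.e.
a network of 100 chains of 30 monomers — 3066 network beads.  Charged
monomers (+1e each) are spaced evenly along each chain (indices
`⌊(j+½)m/n⌋`); charging is what removes a bead's hydrophobic eligibility.
Monovalent anions neutralise the network; each −5e nanoparticle brings
five monovalent cations; all mobile species are inserted uniformly at
random, rejecting any overlap (minimum-image centre distance below
contact).  Electroneutrality is exact by integer arithmetic.

## Monte Carlo sampling

Moves:

* **Single-bead displacements**, uniform in a cube of per-species
  half-width; the half-widths adapt multiplicatively (×1.05 / ÷1.05 per
  adaptation window) toward 50 % acceptance during equilibration and are
  frozen in production.  Dilute species in a large box accept nearly every
  move regardless of step size; their step simply grows to its clamp
  (box/4), which is the correct fixed point of the rule.
* **Cluster moves**: a nanoparticle translates rigidly together with the
  cations in a spherical layer of thickness twice the cation diameter
  around it.  A proposed translation is rejected outright if the cluster
  recomputed at the destination differs from the one selected at the
  origin — the standard symmetric-proposal fix that makes detailed balance
  provable rather than argued.
* **Network scaling moves** (equilibration only): the whole network plus
  every particle inside its instantaneous geometric radius scales about
  the network centre of mass by `s = e^δ`, `δ ~ U(−δ_max, δ_max)`; the
  acceptance exponent includes the proposal Jacobian `+3N ln s`.  These
  moves dramatically accelerate the swelling/collapse relaxation.

Energies are tracked incrementally: only terms involving moved beads are
recomputed and the Ewald reciprocal-space structure factors are updated in
place (`S ← S + ΔS`), with a periodic full resynchronisation to keep
accumulated floating-point drift below 1e−8 relative.  The Ewald splitting
is auto-tuned from a target relative accuracy (default 1e−4): real-space
cutoff at half the box, `α = √(−ln δ)/r_cut`, reciprocal cutoff
`⌈√(−ln δ)·αL/π⌉`.  The energy model validates against the rock-salt
Madelung constant (8 digits), brute-force periodic image sums (with the
`2πM²/3V` dipole term that separates tinfoil from vacuum boundary
conditions), and full-recompute checks of every incremental update.

A single seeded `numpy` Generator drives every stochastic choice, so a
(seed, input) pair reproduces a trajectory bit for bit.

## Observables

The gel radius is `R_NG = √(5/3) R_gyr` (the uniform-ball relation), with
`R_gyr` computed from the network beads about their centre of mass; the
network is built and kept contiguous, so no unwrapping is needed, while
mobile species are always referred to the network CM through
minimum-image distances.  A nanoparticle counts as "inside" if its centre
is within `R_NG`.  The shrinkage ratio is `1 − R_NG(64°C)/R_NG(20°C)` and
the desorption ratio `(N_in(20°C) − N_in(64°C))/N_in(20°C)`.  The net
charge `Z_net` is the charge enclosed by the instantaneous `R_NG` sphere
(bead centres decide membership).  The dimensionless potential
`eψ(r)/k_BT` follows from the spherically averaged enclosed charge via
Gauss' law, `E(r) = l_B Q_enc(r)/r²`, integrated inward by trapezoid from
`L/2` where ψ ≡ 0; against a point charge the profile matches
`l_B Q (1/r − 2/L)` to quadrature accuracy.  Radial densities and the
nanoparticle–nanoparticle g(r) use standard shell-volume and ideal-gas
normalisations (default bin widths 0.5 nm and 0.1 nm; the finer g(r) bin
resolves the 5 nm contact peak of close-packed nanoparticles).  Error
bars, where quoted, are standard deviations over ≥3 independent seeds.

## The Poisson–Boltzmann cell model

The gel is a uniformly charged permeable sphere of radius `R_NG` at the
centre of an electroneutral spherical cell whose volume equals the box
volume (radius ≈ 93.1 nm for the 150 nm box).  With ψ the dimensionless
potential,

    ψ'' + (2/r) ψ' = −4π l_B [ ρ_bare(r) + Σ_i z_i n_i0 e^(−z_i ψ) / D(r) ]

where `ρ_bare = 3Z/(4πR_NG³)` inside the gel and zero outside, and the
shared saturation denominator `D = 1 + Σ_j (n_j0/n_j,max) e^(−z_j ψ)` caps
local concentrations at `n_i,max = (1 − φ_NG)/d_i³` inside the gel (with
φ = 0 outside, where only the species' own size limits packing).  Setting
`D ≡ 1` recovers the point-ion equation; the implementation reproduces
that limit node-for-node when the capacities are made huge.  The sign
convention and the factor `z_i` in the mobile-charge term follow the
requirement that the mobile term be the species' contribution *to the
charge density* with Boltzmann weights `e^(−z_i ψ)`; printed forms of this
equation sometimes omit the `z_i` or flip the overall sign, which is
inconsistent with that reading.

Boundary conditions: ψ(R_cell) = 0 (gauge) and ψ'(0) = 0 (regularity);
ψ'(R_cell) = 0 then follows from cell electroneutrality by Gauss' law and
is reported as a residual diagnostic (≲1e−4 on converged solutions).  The
boundary concentrations `n_i0` are unknowns fixed by an outer
multiplicative fixed point (update exponent 0.8, relative tolerance 1e−6)
on the constraint that each species integrates to its prescribed number
per cell.

Numerics: second-order central differences on a uniform radial mesh
(default 4000 nodes) with damped Newton iteration (step halving on
residual increase) and a 4-stage charge ramp as continuation for strongly
charged gels.  The bare-charge step at `R_NG` is volume-averaged onto the
grid cell containing it; sampling it pointwise would degrade ψ(R_NG) to
first order in the mesh spacing (observed as ~1e−3 oscillation with node
placement), while the smeared source converges to <1e−6 under mesh
halving.  The solver validates against an independently discretised
linearised (Debye–Hückel) solve at weak charge to <1 %.

φ_NG is an input, estimated as the total network bead volume over
`(4/3)πR_NG³` with the radius measured from the particle simulation (and
capped at 0.74, the close-packing bound, for deeply collapsed states); the
solver does not determine `R_NG` self-consistently, because the intended
use is to feed particle-simulation geometry into the mean-field
prediction.

When comparing net charges, the cell model counts the entire bare charge
inside `R_NG` while the particle simulation always finds some charged
monomers outside that sphere; subtracting this *external bare charge*
(measured from the trajectory) from the PBC prediction is exposed as an
optional correction.

## The miniature study systems

Full-size runs (3066-bead networks, 3×10⁸ + 2×10⁸ moves) are
multi-day computations, so the package's tests and the acceptance script
exercise the complete pipeline on proportionally scaled systems: 10
cross-linkers trimmed from the same diamond construction (the smallest
connected trimmed network, functionality 2–3), 12 chains of 3 monomers,
box four times the network diameter, 0–4 nanoparticles of −5e with a 2 nm
diameter — chosen so the nanoparticle-to-gel size ratio roughly matches
the full system while the nanoparticle stays distinctly larger than the
0.7 nm ions.  Default schedules are 4×10⁴ equilibration and 2×10⁴
production moves, which a single CPU completes in tens of seconds.

These miniatures reproduce the study's *qualitative* physics — collapse on
heating, shrinkage decreasing with bare charge, nanoparticle expulsion
from weakly charged gels, rising surface potential, the mean-field model
overestimating absorption once a weakly charged gel has collapsed — and
those trends are what the tests assert.  They do not reproduce the
full-scale magnitudes: a 46-bead network has far fewer hydrophobic
contacts per bead and a much larger surface-to-volume ratio than the
3066-bead system, so, e.g., its shrinkage ratio is ~0.2 where the
full-size weakly charged gel reaches 0.67.  The corresponding quantitative
test is expected to fail until run at full scale.  What passing miniature
tests show is that the machinery (builder, energies, sampling, analysis,
mean-field solver) is correct and that the physics has the right sign and
ordering; they say nothing about quantitative agreement with experiments.

## Known limitations

* No dielectric heterogeneity or image charges: ε_r is uniform, also
  inside the collapsed polymer, where real systems develop low-permittivity
  regions.
* No forces or dynamics: Monte Carlo only; no pressure/virial.
* The open-boundary emulation (`strip-external-nps`) deletes a
  nanoparticle's five nearest cations along with it to keep the box
  neutral, which is a modelling choice the underlying question (does
  surface crowding suppress desorption?) does not fix uniquely.
* The PBC comparison inherits every mean-field limitation: no steric or
  electrostatic correlations between nanoparticles, strict spherical
  symmetry, structureless gel interior.
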