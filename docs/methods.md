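# Methods

`idrslab` implements the biophysical classification pipeline for
intrinsically disordered regions (IDRs) of YTHDF-family m⁶A reader
proteins: sequence-level charge and stickiness analytics, residue-level
coarse-grained slab simulations with coexistence analysis, and
Equal-Input evolutionary distances.  This note records the models, their
assumptions, the defaults, and the choices made where the design was
genuinely open.

## The coarse-grained energy model

Each amino acid is a single bead.  Within a chain, consecutive beads are
joined by harmonic bonds

    E_bond(r) = ½ k (r − r₀)²,   r₀ = 0.38 nm,  k = 8033 kJ mol⁻¹ nm⁻²

Nonbonded interactions have two terms.

**Stickiness (hydropathy).** An Ashbaugh–Hatch split of a 12-6 pair
potential, scaled by a per-residue stickiness λ ∈ [0, 1]:

    E_AH(r) = LJ(r) + (1 − λᵢⱼ) ε          for r ≤ 2^{1/6} σᵢⱼ
            = λᵢⱼ LJ(r)                     for 2^{1/6} σᵢⱼ < r < 2 nm
    LJ(r)   = 4 ε [(σᵢⱼ/r)¹² − (σᵢⱼ/r)⁶]

with arithmetic-mean combining rules for σᵢⱼ and λᵢⱼ and ε = 0.2 kcal/mol
(0.8368 kJ/mol).  The default λ/σ/mass table is the CALVADOS 2 hydropathy
scale (`src/idrslab/data/calvados2.tsv`, external provenance noted in the
file); it is an editable TSV, and the test suite uses synthetic tables so
correctness never depends on those constants.  The term is truncated at
2 nm **with a shift to zero at the cutoff**: whether the original slab
protocol shifted this term is not specified anywhere we could check, and
continuity of energies and forces is worth the ≤ 1e−3 kJ/mol offset it
introduces at σ ≤ 0.7 nm.

**Electrostatics.** A truncated-and-shifted Debye–Hückel potential with
cutoff 4 nm:

    E_DH(r) = (C q_i q_j / ε_r) [exp(−r/λ_D)/r − exp(−r_c/λ_D)/r_c]

Charges follow the convention of the charge-patterning analysis: Arg and
Lys +1, Asp and Glu −1, all other residues — including His — 0.  Termini
carry no extra charge by default (a flag restores ±1 terminal charges).
Ionic strength defaults to 0.15 mol/L and the relative permittivity of
water is taken from an empirical ε_r(T) fit (≈ 80.3 at 293 K, giving
λ_D ≈ 0.79 nm); neither value is prescribed by the protocol this package
follows, so both are configuration options.

Energies are in kJ/mol, distances in nm, masses in Da, times in ps.
Minimum-image periodicity applies in all three dimensions, including the
long z axis.  Pair distances below 10⁻⁴ nm abort the calculation rather
than overflow.

## Langevin slab simulations

Dynamics use a BAOAB-splitting Langevin integrator with dt = 0.01 ps,
friction γ = 0.01 ps⁻¹, and T = 293 K.  BAOAB was chosen because it gives
accurate configurational sampling at this time step; only "a Langevin
integrator" is prescribed.  Velocities are initialized from the
Maxwell–Boltzmann distribution.  One sequential PCG64 stream per run,
keyed by the seed, supplies both the velocity draw and the thermostat
noise; the engine is single-threaded, so trajectories are bitwise
reproducible per seed.

Initial configurations place each chain as a fixed-step random walk
inside the central 20% of the z axis so a condensate nucleus exists at
t = 0, then (i) a geometric relaxation pushes all nonbonded bead pairs to
≥ 0.4 nm (≈ 0.7 σ) while holding bonds near r₀, and (ii) a
capped-displacement steepest-descent minimization drains the remaining
packing energy.  Without step (ii) the first ~50 ps of the run heat the
system by several hundred Kelvin; with it the thermostat holds the set
point within 2% after the equilibration cut.  A 0.2 nm hard floor on
pair distances is verified before the run starts.

Forces are evaluated through Verlet pair lists (a short-range list at
2 nm + 0.4 nm skin over all beads, an electrostatic list at 4 nm + skin
over charged beads only), rebuilt on a half-skin displacement criterion.
The kernel path is contract-tested against a plain all-pairs numpy
reference to better than 1e−10 relative on energies and forces.

### Protocol presets

| preset | copies | box (nm) | steps | sampled time |
|--------|--------|----------|-------|--------------|
| ci     | 6      | 9×9×30   | 5×10³ | 50 ps |
| desk   | 10     | 10×10×26 | 2×10⁵ | 2 ns |
| full   | 100    | 25×25×300| 7.5×10⁸ | 7500 ns |

The `full` preset reproduces the original slab protocol (100 copies, 7500 ns,
first 2000 ns discarded, frames every 1 ns) and is cluster-scale; it is
configured but not exercised by the test suite.  The `desk` preset is the
package's own scaled-down mirror used by the tests and the acceptance
script: 10 copies of 50-mers, 2 ns with the first 25% of frames
discarded and frames every 10 ps.  The sizing rationale: at γ = 0.01 ps⁻¹
dynamics are heavily underdamped and chain diffusion is fast
(D ≈ kT/(N m γ) ≈ 0.04 nm² ps⁻¹ for a 50-mer), so ~2 ns lets a
sub-critical sequence actually evaporate out of the initial nucleus
while a condensing one retains it — shorter windows leave both systems
in a transient condensed state and the contrast becomes fit-noise; at
these sizes the full desk analysis (two sequences × ten seeds) completes
on a single CPU core in minutes.  Desk-scale ΔG_trans values are *not*
converged equilibrium coexistence values — dilute-phase sampling is
limited and the interface is only a few σ wide — and are used for
ordering and trend statements only.

## Coexistence analysis

Frames are re-centered per frame along z using the phase of the first
Fourier mode of the bead z-density (ties resolve to zero shift), so a
condensate wrapped across the periodic boundary is made whole.  The
default concentration histogram counts **chain centers of mass** (bonds
reconstructed by minimum image before the center is taken) in 1-nm bins
and converts to chain molarity in mM; a bead-based profile is available.
Chain molarity is the default because ΔG_trans depends only on the
dilute/dense concentration *ratio*, which is species-independent as long
as the species choice is consistent.

The averaged profile is fitted by least squares to the symmetric
interface form

    c(z) = (c_dense + c_dilute)/2 − (c_dense − c_dilute)/2 · tanh((|z| − z₀)/w)

with bounds c ≥ 0, 0 ≤ z₀ ≤ L_z/2, w > 0.  A profile is declared *not*
phase separated — reported as c_dense = c_dilute = mean concentration and
ΔG_trans = 0 with a flag — when the fit fails, the fitted step is smaller
than three times the fit RMS, or the fitted dense plateau does not exceed
the profile mean by at least 20%.  When the fitted dilute concentration
falls below one chain per dilute-region volume, it is reported at that
occupancy bound and flagged: finite sampling cannot resolve anything
lower, so the corresponding ΔG_trans is a bound, not an estimate.

The excess transfer free energy is

    ΔG_trans = R T ln(c_dilute / c_dense)

with R = 8.314 J mol⁻¹ K⁻¹; more negative means stronger partitioning
into the condensate.

## Sequence analytics

`cumulative_charge` accumulates the per-residue charges N→C; plots are
offered on an absolute residue axis and on a length-normalized 0..1 axis
for cross-length comparison.  `mean_stickiness` is the arithmetic mean of
λ over the sequence (identically the composition–λ dot product).  The
scalar `dipole_index` — net charge of the N-terminal half minus the
C-terminal half — is an extension of this package, added so the
qualitative "acidic N-terminus, near-neutral C-terminus" dipole pattern
has a testable one-number summary; negative values indicate an acidic-N
dipole.

## Equal-Input distances

Alignment columns containing '-' (gap) or 'X'/'?' (missing data) are
removed before any distance is computed (complete deletion).  For a pair
of filtered rows with mismatch fraction p,

    d = −b ln(1 − p/b),    b = 1 − Σᵢ gᵢ²

where g are amino-acid frequencies — by default pooled over all retained
columns of the whole alignment (matching how frequencies are estimated in
standard Equal-Input implementations); a uniform-1/20 mode exists for
analytic checks, and whole-alignment vs per-pair pooling is switchable.
p ≥ b is a saturated distance and raises by default (a sentinel-∞ mode is
available).  d ≥ p always, and d → p as p → 0.

## Synthetic data

The generators exist so every stage is testable without downloads; they
are pure functions of (spec, seed).

* **Sequences**: a residue multiset realizing a target length, net charge
  (K/R vs D/E counts) and mean stickiness (greedy fill over neutral
  residues, realized λ̄ within 0.02 of target or an error), arranged
  uniformly or as a charge dipole (acidic residues shuffled into the
  N-terminal 40%, basic into the C-terminal 40%).  Dipole, reverse-dipole
  and uniform variants of one spec share one multiset, so arrangement is
  the *only* variable — the control the dipole analysis requires.  What
  these sequences do not emulate: the full residue diversity, SLiM
  content, or length distribution of real YTHDF IDRs; conclusions from
  passing tests are about the pipeline's behavior, not about plant
  biology.
* **Profiles**: the tanh coexistence form on a bin grid with optional
  multiplicative Gaussian noise, for exercising the fit in isolation.
* **Alignments**: mutated copies of a random ancestor (per-site
  substitution probability 0.2, below distance saturation) with a known
  gap-column mask, so the complete-deletion survivor count is predictable
  exactly.

## Numerical and degenerate-case choices

* Stickiness and electrostatic terms are continuous at their cutoffs
  (shift construction); branch continuity at 2^{1/6}σ is exact by
  construction and asserted to 1e−12.
* The uniform z-density has no defined center; the Fourier centering
  returns shift 0 when the mode resultant is below 1e−9.
* Saturated Equal-Input distances (p ≥ b) raise rather than return ∞.
* Flat profiles fit degenerately; the no-phase-separation flag (above)
  is the supported outcome, not an exception.
* `X` is accepted in sequence input but rejected explicitly wherever λ
  parameters are required.

## Known limitations

* Desk-scale ΔG_trans values are ordering-grade, not equilibrium
  coexistence measurements (finite size, short sampling, dilute-phase
  occupancy floor).
* One IDR species per slab; no folded domains, no explicit solvent, no
  pH titration of histidine.
* The bundled λ scale is transcribed from the literature; any error in
  transcription would shift absolute λ̄ and ΔG values but not the
  package's internal consistency (tests run on synthetic tables).
* Equal-Input distances assume site-independence and stationary
  frequencies; no rate heterogeneity or tree inference is provided.
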