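# idrslab

Sequence analytics and coarse-grained slab simulations for intrinsically
disordered regions (IDRs) of YTHDF-family m⁶A reader proteins.

Plant YTHDF proteins ("ECTs" in *Arabidopsis*) pair a conserved
C-terminal YTH domain with a long N-terminal IDR, and functional classes
of these proteins differ in the biophysics of that IDR: how readily it
partitions into biomolecular condensates, how sticky its residue
composition is, and how charge is patterned along the chain.  `idrslab`
packages the quantitative side of that comparison for anyone studying
disordered regions:

* **Sequence metrics** — per-residue and cumulative charge profiles
  (R/K = +1, D/E = −1, all others including His = 0), amino-acid
  composition, mean stickiness λ̄, and a scalar charge-dipole index.
* **A residue-level implicit-solvent model** — one bead per residue,
  harmonic bonds (r₀ = 0.38 nm, k = 8033 kJ mol⁻¹ nm⁻²), an
  Ashbaugh–Hatch hydropathy ("stickiness") pair term truncated at 2 nm
  using the CALVADOS 2 λ scale, and truncated-and-shifted Debye–Hückel
  electrostatics (r_c = 4 nm).
* **A Langevin slab engine** — BAOAB integration (dt = 0.01 ps,
  γ = 0.01 ps⁻¹, T = 293 K), many chain copies in an elongated periodic
  box so a dense condensate coexists with a dilute phase along z.
* **Coexistence analysis** — per-frame condensate centering,
  time-averaged concentration profiles, a tanh interface fit for
  c_dense and c_dilute, and the excess transfer free energy
  ΔG_trans = RT ln(c_dilute / c_dense).
* **Evolutionary distances** — complete-deletion filtering of clustal
  alignments and Equal-Input pairwise distances
  d = −b ln(1 − p/b), b = 1 − Σ gᵢ².
* **Synthetic generators** — IDR-like sequences with controlled length,
  λ̄, net charge and charge arrangement; noisy tanh profiles with known
  coexistence densities; alignments with known gap masks.

See `docs/methods.md` for models, assumptions and parameter rationale.

## Worked example

Simulate two synthetic 50-mer IDRs that share length, net charge (0) and
composition class but differ in mean stickiness, then compare their
transfer free energies (desk preset: 10 chain copies, 10×10×26 nm box,
2 ns, first 25% discarded):

```python
from idrslab import (SimulationConfig, build_system, density_profile,
                     fit_coexistence, initialize_slab, run)
from idrslab.forcefield import ResidueParameterTable
from idrslab.synthetic import SequenceSpec, generate_idr

table = ResidueParameterTable.default()
for lam_bar in (0.65, 0.35):
    spec = SequenceSpec(length=50, lambda_bar=lam_bar, net_charge=0,
                        charged_fraction=0.0, seed=11)
    idr = generate_idr(spec, table)
    system = build_system(idr, copies=10, box=[10, 10, 26], table=table)
    traj = run(system, SimulationConfig(n_steps=200_000, save_interval_ps=10.0,
                                        seed=11),
               initialize_slab(system, seed=11))
    fit = fit_coexistence(density_profile(traj, system), temperature=293.0)
    print(f"lambda_bar={lam_bar}: c_dense={fit.c_dense:.1f} mM, "
          f"c_dilute={fit.c_dilute:.2f} mM, dG_trans={fit.delta_g_trans:.2f} kJ/mol")
```

Output:

```
lambda_bar=0.65: c_dense=28.2 mM, c_dilute=1.34 mM, dG_trans=-7.42 kJ/mol
lambda_bar=0.35: c_dense=6.4 mM, c_dilute=6.39 mM, dG_trans=0.00 kJ/mol
```

The sticky sequence keeps its condensate (ΔG_trans = −7.4 kJ/mol for
transfer out of the dilute phase) while the non-sticky one disperses —
its profile goes flat and the fit flags no phase separation, reported as
ΔG_trans = 0.  At desk scale these numbers rank phase-separation
propensity; they are not converged equilibrium coexistence values (see
the methods note).

The same pipeline is available from a shell:

```bash
idrslab features idrs.fasta --annotations yth_starts.tsv   # charge/λ̄ table
idrslab slab idrs.fasta --id ECT2_IDR --preset desk --seed 1
idrslab phase slab_ECT2_IDR.xyz --fasta idrs.fasta --id ECT2_IDR
idrslab distances alignment.aln                            # Equal-Input matrix
```

For real proteins, supply the IDR boundary (first YTH-domain residue,
1-based) in a TSV with columns `id` and `yth_start`; the IDR is
everything upstream of it.

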