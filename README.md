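# filadyn

Coarse-grained dynamics and structural analysis of **enzyme filamentation
allostery** — how cross-linking of enzyme oligomers into head-to-tail
filaments perturbs active-site dynamics and inhibits catalysis.

The motivating system is the *E. coli* methionine *S*-adenosyltransferase
(MAT) homotetramer, which the bacteriophage T3 SAM lyase (SAMase) assembles
into linear filaments in which adjacent MAT tetramers are joined by two
SAMase dimers.  The filament barely changes MAT's structure, so the loss of
activity must be dynamic: junction restraints redistribute the enzyme's
soft modes and deform the active-site pockets.  `filadyn` implements the
computational toolchain for testing that hypothesis on any structure pair
(a free oligomer and a filament repeating unit), plus a synthetic-fixture
generator so the entire pipeline is testable without any downloads.

## What it computes

**Pocket deformation from Gō-model DMD.**  Each residue is a Cα bead;
residue pairs within 7.5 Å in the native structure interact through
attractive square wells, all other pairs by hardcore repulsion; bonds are
hard windows.  Event-driven (discrete) molecular dynamics with an
Andersen-style thermostat samples the equilibrium ensemble, and pocket
deformation is scored per frame as

    d_rms = sqrt( (1/N) Σ_{i<j} (d_ij − d⁰_ij)² ),   N = n(n−1)/2,

over all residue pairs of the active-site pocket (d⁰ from the native
state).

**Per-mode correlations from an elastic network (GNM).**  The Kirchhoff
matrix of the Cα contact network is diagonalised; mode k has frequency λ_k
and amplitude 1/λ_k.  Within one mode, residues i, j are correlated as
c_ij = u_i u_j / √(u_i u_i · u_j u_j) = sign(u_i)·sign(u_j), and the mean
of c_ij over a residue set gives the per-mode deformation scores
*C_pocket* and *C_interface* (1 = the set moves as a block; low/negative =
the mode deforms the set).

**Buried interface areas (PISA convention).**  Shrake–Rupley SASA on a
deterministic Fibonacci lattice; interface area
= (SASA(A) + SASA(B) − SASA(A∪B)) / 2, with per-residue buried areas and an
interface-residue census.

**Filament reconstruction.**  The rigid transform mapping one repeating
unit onto the next is recovered by Kabsch superposition and decomposed as a
screw motion (twist, rise, axis, handedness, repeats per turn = 360/twist);
iterating it reconstructs the filament, and the kink angle between
consecutive units' principal axes measures filament curvature.

**Selections.**  Native contacts (7.5 Å), active-site pockets (6 Å
expansion around bound ligand atoms), junction interfaces (residues within
0.75 nm of a partner group).

**Synthetic fixtures.**  Compact self-avoiding Cα chains, a D2
dimer-of-dimers "tetramer", an "octamer" of two tetramers joined by two
linker chains with a *planted* allosteric signature, and helical stacks
with known screw parameters — every generator returns brute-force ground
truth for testing.

## Worked example

```python
import numpy as np
from filadyn import (synthetic, build_kirchhoff, mode_decomposition,
                     mode_correlation, ResidueSet, extract_ca, ca_array,
                     unit_transform, screw_decompose)

# helical fixture with known geometry, recovered from coordinates alone
helix, truth = synthetic.make_helical_fixture(twist=40.0, rise=50.0, n=3, seed=2)
t, rmsd = unit_transform(helix, truth.unit_chain_sets[0], truth.unit_chain_sets[1])
s = screw_decompose(t)
print(f"twist {s.twist_deg:.2f} deg, rise {s.rise:.2f} A, "
      f"{s.repeats_per_turn:.2f} repeats/turn, "
      f"{'right' if s.handedness > 0 else 'left'}-handed")

# free tetramer vs linker-joined octamer: low-mode pocket correlation
tet, tt = synthetic.make_tetramer_analog(seed=1)
octo, ot = synthetic.make_octamer_analog(seed=1)
for name, st, truthx in [("tetramer", tet, tt), ("octamer", octo, ot)]:
    trace = extract_ca(st)
    spec = mode_decomposition(build_kirchhoff(ca_array(trace), 7.5))
    c = np.mean([mode_correlation(spec, k, ResidueSet(m, "pocket").indices_in(trace)).mean
                 for m in truthx.pockets.values() for k in (1, 2, 3)])
    print(f"{name}: low-mode C_pocket = {c:.3f}")
```

prints

```
twist 40.00 deg, rise 50.00 A, 9.00 repeats/turn, right-handed
tetramer: low-mode C_pocket = 1.000
octamer: low-mode C_pocket = 0.876
```

A 40° twist closes a full helical turn every nine repeating units.  The
free tetramer's pockets ride rigidly on the three softest modes
(C_pocket = 1, no deformation), while junction formation in the octamer
reroutes soft modes through the junction-adjacent pockets (C_pocket < 1 —
low-frequency pocket deformation, the allosteric-inhibition signature).

The same comparison is available end-to-end from the shell:

```
filadyn run --seed 1 --out-dir filadyn_out
```

which writes per-stage TSV/JSON artifacts and a master `report.json`
(selections, GNM profiles, d_rms distributions, interface areas, screw
parameters).  `filadyn --help` lists the stage-level subcommands
(`select`, `gnm`, `dmd`, `interface`, `filament`, `synth`).

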