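# Methods

This note documents the models implemented in `filadyn`, the parameter
choices behind them, what the synthetic fixtures do and do not emulate,
and the numerical conventions that matter for reproducing results.

## Coarse-grained Gō model and event-driven dynamics

Each residue is a single Cα bead of unit mass (reduced units throughout:
ε = 1 for the native-contact well depth, k_B = 1, m = 1; lengths in Å).
The pair potential partition is defined entirely by the native structure:

* **Bonds** — consecutive beads of a chain are held in a hard window
  `[0.98, 1.02] × b⁰` around the native bond length b⁰.
* **Native contacts** — bead pairs within 7.5 Å in the native structure
  (excluding intra-chain pairs closer than 2 in sequence) get a single
  square well: an infinite wall at `0.85·d⁰`, depth −ε out to `1.15·d⁰`,
  zero beyond, centred on the native distance d⁰.
* **All other pairs** — hardcore repulsion at 3.6 Å.

The upstream literature on discrete molecular dynamics (DMD) for Gō models
does not fix a unique parameterisation; the values above are minimal,
standard choices and are all exposed on `GoParams`.  Model construction
rejects native contacts shorter than the hardcore diameter and bonded
pairs appearing in the contact list, so the three classes partition all
pairs exactly.

Dynamics are event-driven: beads move ballistically between events; at
each event (hardcore collision, well-boundary crossing or capture/escape,
bond-window wall) the two velocities change analytically under energy and
momentum conservation, with the well depth added or removed from the
radial kinetic energy on well crossings.  One **step = one processed
event**.  An Andersen-style thermostat redraws single-bead velocities from
the Maxwell–Boltzmann distribution at Poisson times (default rate 0.1 per
bead per reduced time unit — weak coupling that minimally perturbs the
dynamics; the thermostat-accuracy checks use rate 1.0 for tight
statistics, and temperature averages are time-weighted because per-event
averages are biased towards hot, collision-rich periods).  With the
thermostat off the integrator conserves total energy to ~10⁻¹³ per 10⁵
events (the test bound is 10⁻⁹ per event).
Velocities are initialised from the Maxwell–Boltzmann distribution at the
target temperature with net momentum removed.  Runs are bit-reproducible
for a fixed seed.

Default temperature is T = 0.5 ε/k_B — well below unfolding for these
parameters (compact fixtures retain > 90 % of native contacts over 10⁵
events) — and the tetramer/octamer comparison is about relative
deformation, which is preserved across moderate T.

**Production scale.**  The reference protocol for this analysis is 39
replicas × 6·10⁶ events per system with the last 4·10⁶ analysed.  Package
defaults are scaled down to 8 replicas × 2·10⁵ events with the same
burn-in fraction (first 1/3 discarded) so a full tetramer + octamer
comparison completes in minutes on one CPU; the full protocol is reachable
via `--paper-scale` / `AnalysisConfig.paper_scale`.

**d_rms.**  Pocket deformation of a frame is
`sqrt((1/N) Σ_{i<j} (d_ij − d⁰_ij)²)` over all N = n(n−1)/2 distinct pairs
of the pocket's n residues — not only native-contact pairs.  Reference
distances d⁰ are taken from each system's own native coordinates (the free
oligomer uses its native state, the filament unit its own), so d_rms
measures deformation relative to each system's starting conformation.

## Elastic network (GNM) and per-mode correlations

The Kirchhoff matrix Γ has Γ_ij = −1 for Cα pairs within the cutoff and
node degree on the diagonal.  The cutoff defaults to 7.5 Å for internal
consistency with the DMD contact definition (a common alternative in the
GNM literature is 10 Å; it is a parameter).  Eigenmodes are sorted by
eigenvalue; zero modes (λ < 10⁻¹⁰) are flagged — exactly one per connected
component — and excluded from analysis, so "mode 1" is the lowest internal
mode.  Mode amplitude is 1/λ.

Within a single mode the inter-residue correlation reduces to the sign
product `sign(u_i)·sign(u_j)`; components with |u_i| below 10⁻⁹ of the
mode's largest component are excluded from the pair average as numerical
zeros.  C_pocket / C_interface is the mean over distinct pairs (i < j) of
the residue set, averaged over pockets where a system has several.  Note
that this sign-based statistic is deliberately coarse: a residue set that
straddles a nodal surface of a smooth global mode scores low C even for
tiny motions.  On real, well-packed active sites this is rare in the
lowest modes; on small random-blob fixtures it is the main source of
variability (see below).

## Buried interface areas

Solvent-accessible surface areas use the Shrake–Rupley method with probe
radius 1.4 Å and 960 quadrature points per atom on a deterministic
Fibonacci (golden-spiral) lattice, so results carry no RNG state.  Van der
Waals radii: C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å (others in
`interfaces.VDW_RADII`).  The buried interface area between chain groups
follows the PISA convention, `(SASA(A) + SASA(B) − SASA(A∪B)) / 2`, and
interface residues are those burying more than a 0.1 Å² noise floor.
Since PISA's exact radii set is not published, areas computed here should
be compared with PISA values with a ±15 % allowance.  Waters and HETATM
ligands are excluded from interface SASA by default.

## Superposition, screw decomposition, kink

Superposition is least-squares Kabsch (SVD with the reflection corrected
by flipping the smallest singular vector), with degenerate (collinear or
coincident) point sets rejected.  For the free-tetramer-onto-filament
check, the superposition uses Cα atoms of residues matched by author
number after chain pairing; since the deposited filament's chain naming is
model-specific, the implementation scores all chain pairings of a
tetramer and reports the best.

A rigid motion x ↦ Rx + d is decomposed into a screw: twist = rotation
angle (in (0°, 180°]), axis = invariant direction of R oriented so the
rise d·axis is non-negative, axis point from solving (I − R)p = d⊥ in the
plane normal to the axis, repeats-per-turn = 360/twist.  Handedness is the
sense of rotation about the direction of advance (+1 = right-handed); with
zero rise the reported handedness follows the original rotation vector.
Decompose-then-recompose round-trips to < 10⁻⁶ over random transforms.

The kink angle between consecutive filament units is the angle (folded to
[0°, 90°]) between the units' principal inertia axes of smallest moment;
a best-fit-plane-normal rule is available as an alternative, since the
choice of molecular axis is a convention.

## Synthetic fixtures and the planted allosteric signature

The generator builds: self-avoiding compact Cα chains (3.8 Å bonds,
≥ 4.0 Å excluded volume, density tuned to ~4 native contacts per residue);
a D2 dimer-of-dimers tetramer docked so dimer and dimer–dimer interfaces
just touch (~4.8 Å), with a small deterministic jitter (σ = 0.35 Å)
breaking the exact symmetry — without it the spectrum contains degenerate
mode pairs whose arbitrary eigenvector mixtures contaminate sign-based
correlations; four pockets, one per chain, planted as 6 Å neighbourhoods
of pseudo-ligand atoms at a well-embedded surface anchor residue; and an
octamer of two such tetramers bridged by two 14-residue linker chains.

The octamer plants the allosteric signature **by construction**: the
junction-facing pocket segment of each tetramer is pulled toward the
junction (capped so backbone bonds stay within the elastic-network cutoff
and no pair violates the hardcore), the linkers grab the two segments, and
the junction pseudo-ligands are re-planted at the segments' closest
approach, so the two junction pockets straddle the inter-tetramer hinge.
Because the hinge is always among the assembly's softest modes and carries
opposite phases on its two sides, the junction pockets lose low-mode
correlation (C_pocket < 1 in modes 1–3) while the free tetramer's pockets
ride rigidly (C_pocket = 1); in the dynamics, the loosely tethered
junction cluster enlarges the junction pockets' d_rms (typically 2–3× the
other pockets').  This is a geometric surrogate for the biological
mechanism — in the real enzyme the pockets are remote from the junction
and the coupling is genuinely allosteric — so passing fixtures demonstrates
that the pipeline detects the signature when present, not that the
biological coupling exists.

Limitations of the fixtures: no secondary structure, side chains or
realistic packing; pockets are small surface clusters, so mid-frequency
modes occasionally cross them (C dips in modes ≳ 4 of the free tetramer
are fixture noise, which is why the planted contrast is evaluated on the
three softest modes); a small fraction of random seeds produce marginally
folded chains for which the free tetramer is itself floppy at T = 0.5, or
geometries where linker placement fails its bounded retries (the
generators then raise; the acceptance script advances to the next fixture
seed deterministically).

## Numerical conventions

* Distances are Euclidean with inclusive (≤) cutoffs; coordinates in Å.
* Residue identity is (chain id, author residue number, insertion code);
  author numbering is preserved from input files.
* Alternate locations collapse to the highest-occupancy conformer.
* 0.75 nm (interface cutoff) is the same number as the 7.5 Å contact
  cutoff but is kept as an independent parameter.
* Pocket expansion is measured all-atom against ligand atoms; on Cα-only
  models this degenerates naturally to Cα–ligand distances with the same
  6 Å cutoff.
* Problem sizes in the default tests and the acceptance script: 40-residue
  chains (160-bead tetramer, ~350-bead octamer), 8 replicas × 2·10⁵ DMD
  events per system, 960-point SASA quadrature, 10 reported GNM modes.
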