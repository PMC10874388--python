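# Methods

This note documents the models and procedures implemented in `pepgroove`,
their assumptions, the parameters that matter, and the numerical choices
made where the design was open.

## Atomic model and structure input

Structures are read from PDB coordinate text (MODEL 1 only; the complexes
this package targets are single-model crystal structures).  Alternate
locations are resolved to the highest-occupancy copy, ties broken by file
order.  HETATM records are retained because ADT-cyclised peptides are
deposited as ATOM/HETATM hybrids; waters are flagged and kept at parse time
and excluded by the receptor-side analyses by default.  Coordinates stay in
Å with the file's 1-based residue numbering — no renumbering, insertion
codes carried but not interpreted.  Records missing the occupancy,
B-factor or element columns are accepted: occupancy defaults to 1.00 and
the element is derived from the atom name.  Non-standard ligand residues
need no template; every detector works from element, atom name and
geometry alone.

## Interface geometry

**Contacts.**  A receptor residue is a contact if any of its heavy atoms
lies within the cutoff (default 5.0 Å) of any ligand heavy atom; the
per-residue minimum distance is reported.  Distances are exact (k-d tree
nearest-neighbour queries, no grid approximation).

**Hydrogen bonds.**  Crystal structures at ~2 Å resolution carry no
hydrogens, so the criterion is the standard heavy-atom one: N/O donor with
a covalently bonded heavy antecedent (bond detection at ≤ 1.8 Å), N/O
acceptor, donor–acceptor distance ≤ 3.5 Å and antecedent–donor–acceptor
angle ≥ 120° (best antecedent).  Both cutoffs are configurable.

**Salt bridges.**  Barlow–Thornton convention: any Arg guanidinium / Lys
NZ / His imidazole nitrogen within 4.0 Å of an Asp/Glu carboxylate or
C-terminal oxygen.  One bridge is reported per residue pair at the minimum
N–O distance.  A salt bridge at these distances usually also satisfies the
hydrogen-bond criterion; the two detectors are intentionally independent.

**Conservation.**  Contact sets of two homologous complexes are compared
through an explicit residue pairing map (two-column text, or built from a
biotite global sequence alignment by `pairing_from_sequences`; the explicit
map remains the source of truth because the BCL-2 ↔ BCL-X_L numbering
offset is not uniform).  A pair is non-conserved iff the residue names
differ; unpaired residues are flagged, never errored.

**SASA.**  Shrake–Rupley with deterministic golden-spiral sphere points,
default 960 points and probe 1.4 Å.  Element radii (Å): C 1.70, N 1.55,
O 1.52, S 1.80, H 1.20, P 1.80; unknown elements are an error naming the
atom.  Subset SASA is always computed against occlusion by the *whole*
structure.  With 960 points the discretisation error on small clusters is
well under the 2 % band verified against a 10⁶-sample Monte-Carlo surface
oracle in the tests.

**Buried interface.**  Reported as the half-sum convention
½·[SASA(receptor) + SASA(ligand) − SASA(complex)], with per-side ΔSASA also
emitted so either convention can be checked.  For a ~10-residue macrocycle
the half-sum is the per-side magnitude (hundreds of Å²).

**Superposition.**  Kabsch least squares on paired Cα atoms (SVD with the
determinant correction, so reflections are never returned).  At least three
pairs are required; the paired-atom count is reported with the RMSD because
published cross-protein RMSDs depend on the residue subset used.

## Rotamer states and the correlation network

Dihedrals use the right-handed atan2 convention (cis = 0, trans = π) on
(−π, π].  χ1 is N–CA–CB–XG and χ2 is CA–CB–XG–XD per the standard
side-chain definitions; Gly/Ala have no χ and raise a typed error (this
asymmetry is exactly what makes an Asp→Ala contrast structurally
informative).  Asp χ2 runs over a chemically symmetric carboxylate
(OD1/OD2 interchangeable) and is folded to (−π/2, π/2].

States are assigned to the nearest peak center under circular distance,
default centers {−1.5, +3.0} rad (the two χ1 modes of the groove
phenylalanines); exact ties go to the lower-index center.  Identity-coded
residues — a mutation site whose "state" is the amino-acid type, 0/1,
constant within a trajectory — pass through unchanged, which lets a
mutation enter the network on the same footing as a rotamer state.

The network's association measure is Cramér's V on the pooled contingency
table (default), chosen because it treats the binary identity state and
k-state rotamer series uniformly and is invariant to relabelling of state
codes; normalised mutual information is available behind a flag.  Frames
from all trajectories are pooled with equal weight.  Residues whose pooled
series is constant get association 0 and are flagged.  No attempt is made
to reproduce any published network figure numerically: the measure and
threshold behind such figures are generally unstated, so both are exposed
as configuration.

The wrapped kernel density (von Mises kernels, concentration by
leave-one-out likelihood over a coarse grid) exists for diagnostic plots
only; every quantitative statement runs on discrete state frequencies.

## Hamiltonian replica exchange with torsion scaling

The protocol softens *selected* side-chain torsion terms by
`U'_torsion = scale_n · U_torsion = (T0/Tn) · U_torsion`, so replica n
samples torsion barriers reduced as if at temperature Tn while running at
T0.  The ladder has scale 1.0 at the bottom; the default 8-replica ladder
from 300 K to 430 K ends at scale 300/430 ≈ 0.6977.  Spacing is geometric
in effective temperature (constant neighbour ratio — the standard choice
giving near-uniform exchange acceptance); linear spacing is available.

The sampler is Metropolis Monte Carlo over torsion coordinates of toy
systems: periodic terms k·(1 + cos(mφ − phase)) (a multiplicity-2 term *is*
the double well used throughout the tests) plus optional unscaled couplings
J·cos(φi − φj).  Energies are in kT units at T0, so β is absorbed and the
Metropolis tests use energies directly.  Single-angle Gaussian proposals
(default width 0.6 rad) against the scale-weighted energy satisfy detailed
balance at T0.

Exchanges use the standard Hamiltonian-exchange criterion at common
temperature: accept with min(1, e^−Δ),
Δ = U_i(x_j) + U_j(x_i) − U_i(x_i) − U_j(x_j) with U_k the scale_k-scaled
potential — the unique criterion preserving each replica's Boltzmann
distribution.  Scheduling alternates even/odd neighbour pairs every
`exchange_interval` sweeps (the analogue of a fixed attempt time).  The
scale-1.0 replica is the analysis trajectory.  Each replica draws from its
own stream spawned from the master seed, so a run is a pure function of
(system, ladder, schedule, seed) independent of execution order.

Validation is against quadrature: the analysis-replica marginal of a
one-coordinate system must match the normalised Boltzmann density within a
total-variation distance of 0.03 (binned circularly — the well minimum of a
multiplicity-2 term sits at ±π, exactly on the wrap seam).  Desk-scale runs
use 10² – 10⁴ sweeps of 10–20 moves on 1–3 coordinates; production-scale
all-atom replica exchange is out of scope by design, and published
exchange-probability figures for all-atom systems are not comparison
targets for the toy engine.

## Fluorescence polarization

Direct binding uses the exact single-site isotherm with ligand depletion
(required because the labelled-peptide concentration c = 20 nM is not
negligible against nanomolar–micromolar K_D).  It is evaluated in the
conjugate form bound = 2x / (s + √(s² − 4xc)), s = x + c + K_D, avoiding
the subtractive cancellation of the printed radical at large s.  The
competition model defaults to the internally consistent one-site sigmoid
y = A0 + (Amax − A0)/(1 + 10^(x − logEC50)); a strict-as-printed mode with
the leading Amax is kept for auditability — its low-concentration plateau
is 2·Amax − A0, which the tests demonstrate.  K_i follows from
EC50/(L50/K_D + P0/K_D + 1); L50 and P0 are inputs, not derived.

Fitting is trust-region least squares in (log10 K_D, A0, Amax) with eight
data-driven starts (plateaus from the y extremes, K_D/EC50 brackets around
the half-response point).  Uncertainty comes from seeded residual
resampling (x is a designed variable, so pairs resampling would distort
the design), 1000 bootstrap refits by default, percentile intervals.
A flat response is flagged as unidentifiable and its K_D interval widened
to the admissible box (10⁻³ – 10⁶ nM) rather than reporting a collapsed
interval from zero residuals.

## Synthetic data: what it emulates and what it does not

**Toy complexes** place residues on a stretched helical spiral (7 Å rise,
2.3 Å Cα radius, 100°/residue twist).  The exaggerated rise keeps every
non-planted residue > 8 Å from the ligand while planted features are
realised exactly at construction distances: contacts 4.0 Å, hydrogen bonds
2.9 Å at 165°, salt bridges 3.2 Å (forcing the receptor residue to an Arg
stub).  The generator *verifies* these clearances numerically after
construction and errors on infeasible requests.  This geometry exercises
everything the detectors measure — distances, angles, occlusion — but is
not a physical protein: no packing, no secondary-structure realism, no
electron-density artefacts.  Passing construction-oracle tests therefore
demonstrates detector correctness, not robustness to crystallographic
noise.

**χ-angle trajectories** draw wrapped Gaussians (default width 0.3 rad)
around the active peak of a persistent two-state chain whose stationary
distribution equals the requested occupancies (per-frame redraw probability
`switch_prob`, default 0.1).  A coupled pair (i, j, c) rebuilds j frame-wise
as a copy of i with probability c, otherwise from j's own independent
chain, so c = 1 gives identical series, c = 0 independence, and marginals
are honoured when occupancies match.  At width 0.3 the per-frame
misassignment probability against peaks 1.78 rad apart is ≈ 3·10⁻³
(0.89 rad ≈ 3σ) — small but not negligible over 10⁴ frames, which the
state-frequency tests account for.  Real trajectories additionally contain
autocorrelated noise, multi-modal minor states and frame-dropping, which
this generator does not model.

**FP titrations** follow the assay design: 20 nM labelled peptide, protein
titrated 60–1000 nM for direct binding (12 concentrations in duplicate —
the usual plate layout; a Cramér–Rao computation shows 12 single wells at
2 % noise cannot determine K_D = 200 nM to better than ~12 % median error,
so duplicates are the realistic default), and 1 nM – 30 µM for
competition.  Noise is Gaussian with σ expressed as a fraction of the
dynamic range.

## Reproducibility and numerics

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; generators and pipeline runs are pure
functions of their spec.  Pipeline tables use fixed formatting (areas to
0.1 Å², distances and RMSD to 0.001 Å), so a rerun with the same
configuration is byte-identical.  Angles live on (−π, π] with −π mapped to
+π; circular distances are computed by wrapping differences, never by
naive subtraction.  Collinear dihedral quadruples, empty selections used
as ligands, sub-minimal superposition pairs, unknown elements and
non-converging fits all raise typed errors rather than returning
placeholder values.

## Known limitations

* The HREX engine samples toy torsion potentials; force-field terms,
  solvent and barostats are out of scope, so its validation says nothing
  about all-atom convergence rates.
* Hydrogen-bond detection is purely geometric; no energy or chemistry
  scoring beyond element/antecedent rules.
* The buried-interface convention (half-sum) must be matched to whatever a
  published number used; per-side values are emitted for that reason.
* Bootstrap intervals are percentile intervals; they slightly undercover
  at small n (the tests bound coverage at ≥ 90 % for nominal 95 %).
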