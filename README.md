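# pepgroove

Structural and biophysical analysis of cyclic peptides that bind the BH3
surface groove of pro-survival BCL-2-family proteins (BCL-2, BCL-X_L).
Unlike BH3-mimetic small molecules, these macrocycles sit on the flat groove
surface without opening the deep P2/P4 pockets, so their recognition is
governed by a handful of surface residues — most prominently the single
non-conserved position BCL-2 D111 / BCL-X_L A104.  The package provides the
computational toolchain for studying that binding mode:

* **`structio`** — PDB reading/writing into a uniform atomic model
  (biotite-backed), altloc resolution, and a small selection language.
* **`geometry`** — contact residues within a cutoff, conservation comparison
  between homologous complexes, geometric hydrogen-bond and salt-bridge
  detection, exact minimum distances, Shrake–Rupley SASA (golden-spiral
  sphere points), buried interface area, and Kabsch Cα superposition/RMSD.
* **`rotamers`** — side-chain χ1/χ2 dihedrals, rotamer-state assignment to
  the two groove-residue peaks (Peak1 ≈ −1.5 rad, Peak2 ≈ +3 rad), and
  cross-residue state-correlation networks (Cramér's V or normalised mutual
  information), including identity-coded mutation sites (0 = Gly, 1 = Val).
* **`hrex`** — the tailored Hamiltonian replica-exchange protocol that
  accelerates side-chain transitions: selected torsion terms are scaled by
  `scale_n = T0/Tn` (8 replicas, scales 1.0 → 0.7 ≙ 300 → 430 K), with
  neighbour exchanges at a fixed interval and the scale-1.0 replica as the
  analysis trajectory.  The sampler runs Metropolis Monte Carlo on toy
  torsion-chain systems behind a pluggable potential interface.
* **`fpfit`** — fluorescence-polarization quantification: the exact
  quadratic direct-binding isotherm

  `y = A0 + (Amax − A0)·[(x+c+K_D) − √((x+c+K_D)² − 4xc)]/(2c)`,

  the one-site competition sigmoid over log10 molar concentration, and the
  inhibition constant `K_i = EC50 / (L50/K_D + P0/K_D + 1)`, fitted by
  multi-start trust-region least squares with seeded residual-resampling
  bootstrap intervals.
* **`synth`** — synthetic inputs with machine-readable truth manifests:
  toy helical receptor/cyclic-peptide complexes with planted contacts,
  hydrogen bonds and salt bridges; multi-residue χ-angle trajectories with
  planted occupancies and Markov couplings; noisy FP titrations.
* **`pipeline` / `pepgroove` CLI** — reproducible end-to-end runs with a
  single master seed and fixed-format tab-separated outputs.

## Worked example

```python
import pepgroove as pg

spec = pg.ToyComplexSpec(n_receptor=14, n_ligand=8, contacts=(2, 6, 11),
                         hbonds=(9,), salt_bridges=(4,), seed=11)
structure, manifest = pg.make_toy_complex(spec)
ligand = pg.select(structure, "chain B")

report = pg.contact_residues(structure, ligand, cutoff=5.0)
print([(r.chain, r.resnum, r.resname, round(r.min_distance, 2))
       for r in report.residues])
print(str(pg.detect_salt_bridges(structure, ligand, ligand.complement())[0]))
print(f"buried interface: {pg.buried_interface(structure, ligand).buried:.1f} A^2")

t = pg.simulate_fp_titration(pg.FPSpec(kd=200.0, sigma=0.02, seed=3))
print(pg.fit_binding(t, n_boot=500, seed=0).summary())
```

prints

```
[('A', 2, 'ALA', 4.0), ('A', 4, 'ARG', 3.2), ('A', 6, 'ALA', 4.0), ('A', 9, 'ALA', 2.9), ('A', 11, 'ALA', 4.0)]
A:ARG4 <-> B:ASP5 (3.20 A)
buried interface: 142.3 A^2
Direct-binding FP fit (quadratic isotherm)
  n = 24 points, c = 20 nM
  KD    =      209.6 nM   95% CI [157.1, 276.3]
  A0    =    0.04992      95% CI [0.03605, 0.06195]
  Amax  =     0.2534      95% CI [0.2428, 0.2669]
  RSS   =  0.0005199   (bootstrap n = 500)
```

The five contact residues are exactly the planted ones (the hydrogen-bond
residue 9 at 2.9 Å and the Arg4–Asp salt bridge at 3.2 Å are contacts too),
and the fitted K_D of 209.6 nM recovers the simulated 200 nM truth within
the 2 %-noise confidence interval.

The same operations are available from the shell:

```sh
pepgroove simulate complex --spec spec.yaml --seed 3 --out sim/
pepgroove analyze-interface --complex sim/complex.pdb --ligand-chain B --cutoff 5.0
pepgroove hrex-run --config sys.yaml --replicas 8 --t0 300 --tmax 430 --seed 7
pepgroove fp-fit binding data.tsv
```

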