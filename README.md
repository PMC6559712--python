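# mptraj

Trajectory analysis for metal-ion/peptide conformational ensembles, built
around the kind of question asked of intrinsically disordered peptides such
as amyloid-beta with a bound Al(III)-like ion: when has each simulation run
equilibrated, which oxygens coordinate the ion and how many on average,
what secondary structure does the peptide adopt, which hydrogen bonds and
salt bridges form and how often, and which conformational clusters dominate
the ensemble.

The package reads multi-model PDB trajectories (one `MODEL` per frame) of a
single peptide chain plus an optional single-atom ion, and provides:

- **Equilibration** — RMSD time series after optimal (Kabsch) superposition,
  an explicit windowed-stability detector for the equilibration point
  `t_eq`, and pooled post-equilibration statistics across runs, including
  the pooled equilibrated time `sum(T_run - t_eq)` in microseconds.
- **Geometry** — RMSD/RMSF, radius of gyration
  `Rg = sqrt(sum_i m_i |x_i - x̄|^2 / sum_i m_i)`, IUPAC torsions, and
  Ramachandran (phi, psi) histograms.
- **Ion coordination** — per-oxygen distance statistics, mono/bi-dentate
  classification of carboxylate binding, a radial distribution function
  g(r) with its directly counted cumulative coordination number n(r), and
  the coordination number at a chosen inner-shell cutoff.
- **Secondary structure** — a Kabsch–Sander (DSSP) implementation: H-bond
  energy `E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)` kcal/mol
  with bonds below -0.5, n-turns, helices (G/H/I), bridges and ladders
  (B/E), turns and bends, plus per-residue occupancies and the
  Helix/Sheet/Other totals.
- **Interactions** — geometric hydrogen-bond detection (heavy-atom
  distance + D-H-A angle), per-pair incidence percentages, i+3/i+4/i+5
  backbone bond tallies, and salt bridges: all acidic x basic side-chain
  pairs with an O–N contact strictly below 3.2 Å.
- **Tertiary structure** — mean C-alpha contact maps, pairwise backbone-RMSD
  matrices, DBSCAN clustering with deterministic border assignment, cluster
  populations and medoid representatives.
- **Synthetic ensembles** — a generator that builds peptides from
  per-residue backbone torsions with known ground truth (planted secondary
  structure, drift phase with a true equilibration onset, an ion tethered
  to chosen side-chain oxygens), so every analysis is testable without
  running molecular dynamics.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

The bundled demo generates two 50 ns runs (500 frames each) of a
16-residue amyloid-beta-like peptide — coil N-terminus, 3-10 segment over
residues 6–10, alpha helix over 11–16, a drift phase ending at 10 ns, and
an ion tethered to the Glu3/Asp7/Glu11 side-chain oxygens — then runs the
full analysis battery on the pooled post-equilibration frames:

```sh
mptraj demo --seed 1 --out demo_out
```

prints

```
demo report written to demo_out
pooled equilibrated time: 0.1 us
ion coordination number at 2.6 A: 3.00
```

The equilibration table recovers the generator's 10 ns drift onset in both
runs (`equilibration_points.csv`):

```
run,t_eq_ns,equilibrated,run_length_ns
A,10.000000,True,49.900000
B,10.000000,True,49.900000
```

so 2 x 39.9 ns ≈ 0.1 us of pooled equilibrated data remain.  The ion
contact statistics (`ion_contact_stats.csv`) show the three tethered
oxygens at 1.90 ± 0.03 Å and the unused carboxylate partners in the outer
sphere near 3.8 Å, which is why integrating the RDF to the 2.6 Å
inner-shell cutoff gives a coordination number of 3.00:

```
label,atom_name,mean_A,sd_A,min_A
Glu3 sidechain O (OE1),OE1,1.898857,0.029342,1.807660
Asp7 sidechain O (OD1),OD1,1.899438,0.030285,1.794142
Glu11 sidechain O (OE1),OE1,1.900744,0.029582,1.811843
Asp7 sidechain O (OD2),OD2,3.795729,0.199465,3.164532
...
```

The secondary-structure totals (`ss_totals.csv`) reflect the planted
helical and 3-10 segments (Helix = H + G + I states over all
residue-frames; the three columns close to 100):

```
system,Helix,Sheet,Other,sheet_parallel_pct,sheet_antiparallel_pct
Ab16-demo,66.093750,0.046875,33.859375,0.000000,100.000000
```

and clustering the pairwise backbone-RMSD matrix (DBSCAN, eps 2.0 Å,
min_pts 5, stride 4) finds one dominant conformational cluster holding
32.5% of frames with the remainder diffuse (`cluster_summary.csv`), whose
medoid structure is written as `cluster_0_medoid.pdb`.  Hydrogen-bond
statistics (`hbond_stats.csv`) report 8.2 ± 1.5 bonds per frame across 66
distinct donor–acceptor pairs, and `salt_bridge_incidence.csv` lists all
8 possible acidic–basic pairs of this sequence with the percentage of
frames each is formed.

The same battery runs on your own trajectories via a YAML configuration:

```sh
mptraj analyze --config analysis.yaml
mptraj generate --config ensemble.yaml --out traj.pdb --seed 7   # synthetic input
```

Every report is CSV with units in the headers; rerunning with the same
configuration and seed reproduces the bundle byte for byte.

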