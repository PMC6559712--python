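# Methods

`mptraj` analyses conformational ensembles of a single short peptide chain
(amyloid-beta fragments are the motivating system) with at most one bound
metal ion, stored as multi-model PDB trajectories.  This note documents the
models, conventions, and numerical choices; everything stated here is what
the code computes, nothing more.

## Data model and conventions

Residues are numbered from 1 (Asp1 ... Lys16/Ala42 for amyloid-beta
fragments) and reported with labels like "Glu11".  Coordinates are
angstroms, times nanoseconds.  The ensembles are implicit-solvent: there is
no periodic box and no distance is ever imaged.  Charge classes follow the
side-chain convention acidic = {Asp, Glu}, basic = {Arg, Lys}; histidine is
neutral and chain termini carry no salt-bridge partners.  Under this
convention a 16-residue amyloid-beta fragment (4 acidic x 2 basic) has 8
possible salt bridges and the 40/42-residue peptides (6 x 3) have 18.

Hydrogens are optional in input.  Amide hydrogens, when needed (DSSP,
hydrogen bonds), are reconstructed at 1.0 A from N along the inverted
direction of the preceding carbonyl, the classic DSSP construction;
residue 1, prolines and chain-break starts (C(i-1)-N(i) > 2.5 A) get none.

## Synthetic ensemble generator

The generator replaces trajectory production.  It builds peptides from
per-residue backbone torsions by internal-coordinate (NeRF) chain
extension with standard stereochemistry: N-CA 1.458, CA-C 1.525, C-N
1.329, C=O 1.231, CA-CB 1.530 A; angles C-N-CA 121.7, N-CA-C 111.2,
CA-C-N 116.6 degrees; omega fixed trans.  Side chains are reduced to
C-beta plus the charged-group atoms of Asp/Glu/Lys/Arg placed at idealised
all-trans geometry — every analysis in scope needs only backbone atoms,
carboxylate oxygens and Lys/Arg nitrogens, and the reduction keeps the
generator verifiable and fast.

Each frame samples per-residue torsions independently as segment target +
N(0, sigma_t^2).  Segment classes and their targets (degrees): alpha
(-57, -47), 3-10 (-49, -26), strand (-139, +135), polyproline-II
(-75, +145).  Coil residues draw a basin per frame from the three broad
allowed regions (alpha (-63,-43), beta (-120,130), left-handed alpha
(60,45)) with weights 0.5/0.4/0.1 and 15-degree intra-basin spread; exact
weights are a free choice with no experimental target, and in the exact
noise-free limit coil pins to the dominant alpha basin so that sigma = 0
reproduces bit-identical frames.  An optional drift phase adds extra noise
amplitude_deg * max(0, 1 - t/t0) that decays linearly to zero at t0,
producing an RMSD-versus-time curve that settles at a controllable true
onset.  Because frames are independent draws and the frame-0 reference is
itself noisy, the synthetic RMSD series *falls* toward its plateau rather
than rising as a real relaxing trajectory does; equilibration detection is
agnostic to the sign of the approach.

All randomness flows through one `numpy` generator seeded from the
ensemble specification; the same (specification, seed) pair reproduces
coordinates bit for bit.

### Ion tethering

`attach_ion` places one ion per frame, relaxed by 50 sweeps of distance
restraints toward per-anchor targets tether_length + N(0, tether_sigma^2)
(defaults 1.9 A and 0.03 A, a first-shell metal--carboxylate contact).
In the default mode only the ion moves, and frames whose residual exceeds
0.05 A are reported as infeasible — anchors further apart than the tethers
can reconcile stay infeasible by design.

The anchor-pulling mode (used by the generator and demo) instead emulates
the ion gathering its ligating side chains: the ion takes 20% of each
correction and the anchor residue's side-chain tail the remaining 80%; the
ion is initialised outside the peptide envelope (displaced from the anchor
centroid away from the centre of mass); an exclusion restraint keeps all
non-anchor oxygens beyond ~3.5 A (released for the final sweeps so the
tethers settle exactly); with three anchors the mirror position across the
anchor plane — which satisfies the same tethers — is chosen to maximise
clearance from non-anchor oxygens; and the unused sibling oxygen of a
mono-dentate carboxylate is oriented away from the ion at outer_length
(default 3.8 +/- 0.2 A), creating an outer coordination sphere.  The
result realises the generator's stated ground truth: three oxygens at
1.9 +/- 0.03 A, everything else outside the inner shell, giving a
coordination number of 3.0 at a 2.6 A cutoff.  The construction is a
geometric idealisation, not physics: side-chain pseudo-bond lengths
stretch to meet the tethers and the outer-sphere distance is imposed, not
emergent.

## Geometry

Superposition is Kabsch via SVD with the reflection corrected to a proper
rotation; (near-)collinear selections raise rather than return an
ill-defined rotation.  Tests cross-check against an independent
quaternion-eigenvalue oracle at 1e-8 A.  "Backbone" means N, CA, C (O
excluded) for RMSD selections.  RMSF superposes all frames to the
iterated mean structure (two align/re-average rounds) to remove global
drift; alignment to frame 0 or no alignment are options.  Radius of
gyration is mass-weighted over the selection (heavy atoms in the
pipeline).  Torsions follow the IUPAC convention (cis = 0, trans = +180,
result in (-180, 180]); note that reversing the atom order is a symmetry
of the torsion, not a sign flip.  Ramachandran histograms cover interior
residues only, so the grid total is exactly (n_res - 2) x n_frames;
default bin 10 degrees.  Summary statistics (Ave/SD/Min/Max) use the
population SD, matching large-n trajectory statistics.

## Equilibration

Published trajectory studies typically pick equilibration points by eye;
here the criterion is explicit.  The RMSD series is cut into
non-overlapping windows (default 25 ns, tolerance 0.5 A); the
equilibration time is the earliest window boundary from which every later
window mean stays within the tolerance of the final window mean and no
window-to-window rise exceeds it.  A stable tail of at least two windows
is required, so a series that never settles reports "not equilibrated"
(distinct from equilibrating at the end).  Larger tolerances can only move
the detected point earlier.  Reference equilibration points quoted from
the literature are treated as human-chosen inputs, not ground truth this
detector must reproduce.

The recovery experiment (tests and acceptance script) uses 20 drifted
ensembles with onsets 10-50 ns, drift amplitude 60 degrees, window 5 ns
and tolerance 0.2 A.  The tolerance is ~4x the window-mean standard error
at 50 frames/window; with a linearly decaying drift the detector fires
when the remaining drift falls below the tolerance, so the tolerance must
be small against the drift-induced RMSD drop for the onset to be
localisable to one window.  Median onset error: one window.

Pooled equilibrated time is sum(run length - t_eq)/1000, reported in
microseconds to one decimal, the convention for quoting pooled trajectory
lengths.

## Ion coordination

Distances are monitored for every peptide oxygen (backbone plus side
chain).  Denticity per carboxylate: bi if both oxygens are inside the
inner-shell cutoff, mono if one, outer otherwise.  These are finite,
non-periodic systems, so the bulk-density normalisation of a liquid-state
RDF does not exist; g(r) is normalised by the mean density of the
candidate-oxygen set within r_max (default 6 A, bin 0.05 A).  All
quantitative statements use the cumulative count n_cum(r), obtained by
direct counting (never by integrating g); the two counting paths agree to
1e-10 by construction and are cross-checked in tests.  The default
inner-shell cutoff is 2.6 A, between the 1.9 A first-shell peak and the
~3.8 A outer feature; a helper locates the first minimum of (lightly
smoothed) g(r) after the first peak as a suggested cutoff.

## Secondary structure

Kabsch-Sander throughout: hydrogen-bond energy E = 0.084 * 332 * (1/r_ON +
1/r_CH - 1/r_OH - 1/r_CN) kcal/mol, bonded below -0.5, clamped at -9.9
for contacts under 0.5 A.  n-turns (n = 3, 4, 5) from i+n -> i bonds; two
consecutive n-turns make G/H/I helices; parallel/antiparallel bridges
(|i-j| >= 3) make B, ladders of consecutive bridges make E; turn T, bend
S (C-alpha kink > 70 degrees); priority H > E > B > G > I > T > S, else
coil.  Chains under 5 residues are all-coil with a warning.  Occupancy
aggregates Helix = H+G+I, Sheet = E+B, Other = remainder, which closes to
100 by construction; the parallel/antiparallel composition of sheet states
is tallied separately.  The assignment is cross-checked against an
independent DSSP implementation (mdtraj) on an ideal helix in the test
suite.

## Hydrogen bonds and salt bridges

Geometric hydrogen-bond criterion: heavy-atom donor--acceptor distance
<= 3.5 A and D-H-A angle >= 135 degrees, both configurable.  The 3.5 A
default is the common heavy-atom convention; a 3.0 A cutoff would miss
textbook helical bonds (the ideal alpha helix at (-57,-47) under standard
stereochemistry has N(i+4)-O(i) = 3.11 A) that the Kabsch-Sander energy
criterion accepts.  Backbone donors use the reconstructed amide H for the
angle; side-chain donors (Lys, Arg, His, Ser/Thr/Tyr, Asn/Gln — the
amides are included by default, excludable by flag) carry rotatable or
symmetric hydrogens, so their angle test is an antecedent-D-A
plausibility check (>= 90 degrees) rather than an explicit H position.
Intra-residue backbone-to-side-chain bonds are allowed (they genuinely
occur for Glu/Asp); same-moiety pairs within a residue and the covalent
N(i)...O(i-1) peptide pair are excluded.  Incidence is reported at
residue+moiety granularity ("His14 sidechain -> Glu11 backbone"), merging
equivalent atom pairs such as the two carboxylate oxygens; atom-level
granularity is a flag.  Per-frame counts are raw detections.  Distinct
backbone-backbone bonds with donor-acceptor separation 3/4/5 are tallied
as i+3/i+4/i+5 (3-10, alpha, pi helical signatures) together with the
subset present in at least 5% of frames.

Salt bridges: all acidic x basic residue pairs are enumerated from the
sequence; a pair is bridged in a frame iff the minimum side-chain
oxygen--nitrogen distance is strictly less than 3.2 A.

## Tertiary structure

Contact maps are mean C-alpha--C-alpha distances over frames.  Clustering
runs DBSCAN on a pairwise backbone-RMSD matrix: core points have >=
min_pts neighbours within eps (self included), clusters are connected
components of cores plus border points, the rest is noise; border points
adjacent to several clusters deterministically join their lowest-index
core neighbour's cluster.  Defaults eps = 2.0 A, min_pts = 5, chosen as
unambiguous reproducible stand-ins (no literature values exist for this
choice) and recorded in run metadata.  A frame sieve (stride) bounds the
O(n^2) matrix; sieved-out frames are assigned post hoc to the nearest
medoid within eps, else noise.  Representatives are medoids (member
minimising summed intra-cluster distance); populations are percentages of
all frames and close to 100 with the noise fraction.

## Pipeline

`run_pipeline` detects equilibration per run from the backbone RMSD
series against frame 0, pools post-equilibration frames of all
equilibrated runs (non-equilibrated runs are excluded with a warning, an
error under `--strict`), and feeds the pooled ensemble to every analysis.
All outputs are CSV with units in the headers, plus single-model PDB
files for cluster medoids and a JSON metadata record (package version,
seed, full parameter set, per-frame provenance).  No timestamps are
written, so identical configuration and seed reproduce the bundle byte
for byte.

The demo builds a two-run, 500-frames-per-run 16-residue system (50 ns at
0.1 ns/frame per run): coil residues 1-5, a 3-10 turn-like segment 6-10,
a helical C-terminal segment 11-16, dihedral noise 8 degrees, drift onset
10 ns with amplitude 25 degrees, and an ion tethered to the Glu3/Asp7/
Glu11 side-chain oxygens in the anchor-pulling mode.  These sizes keep
the full battery at roughly a minute on one CPU while leaving every
stage's statistics well resolved.

## What the synthetic data does and does not show

The generator realises known secondary structure, a known equilibration
onset, a known inner coordination shell, and reproducible contacts — so
passing tests demonstrate that the analyses recover planted ground truth.
It does not model a force field, solvent, temperature, kinetics, or
correlated frame-to-frame motion (frames are independent draws), and the
ion geometry is constructed rather than emergent.  Agreement with the
analyses here therefore validates the measurement machinery, not any
physical prediction about real metal-peptide systems; quantities that
depend on genuine dynamics (e.g. literature occupancy percentages from
microsecond simulations) are out of reach by design.

## Known limitations

- Single chain, single ion; no PDBx/mmCIF or binary trajectory formats.
- Reduced side chains in the generator mean His/Ser/Thr/Tyr side-chain
  donors exist only when full-atom input supplies them.
- The windowed equilibration criterion compares to the final window's
  mean; for very short noisy runs that reference is itself noisy, so
  windows should contain >= 20 frames in practice.
- DBSCAN border-point assignment is deterministic but convention-bound;
  cluster *membership* of border points can differ from other DBSCAN
  implementations (core structure and noise agree).
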