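# Methods

This note records the modelling choices, default parameters, numerical
conventions and known limitations of the package. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`;
nothing is quoted from external runs.

## Structures and geometry

Structures are heavy-atom, standard-residue views of PDB files (biotite
parser; highest-occupancy alternate locations; MSE and a few other common
nonstandard residues mapped to their parents, others dropped with a warning).
Residues are addressed by `(chain, author number, insertion code)`.

* **Solvent accessibility** — Shrake–Rupley with 960 sphere points, probe
  1.4 Å, element-based van der Waals radii. Relative ASA divides by the
  residue type's theoretical maximum (Tien et al. 2013 values) and is clipped
  to [0, 1]. Because the sphere grid is fixed in the laboratory frame, total
  ASA is invariant under rigid motion only to ~10⁻³ relative — the resolution
  of the discretisation, not an implementation artifact.
* **Superposition** — Kabsch/SVD with the determinant correction, so the
  returned rotation is always proper. Collinear point sets are flagged with a
  warning (the in-line rotation component is then arbitrary). The test suite
  cross-checks against the quaternion solver in
  `scipy.spatial.transform.Rotation.align_vectors`.
* **Contacts** — residue pairs with any heavy-atom pair within the cutoff
  (5 Å for binding, 10 Å for interface membership, 2.5 Å for clashes, all
  configurable). KD-tree implementation, brute-force-verified in tests.
* **IRMSD** — backbone (N, CA, C, O) RMSD over the antibody interface
  residues with the antigen frame fixed and **no re-superposition**. The
  interface residue set is the reference complex's (10 Å rule), fixed per
  query, so all poses of a query are measured on the same atoms. Missing
  backbone atoms are skipped with a warning.

## Residue features

Feature blocks are concatenated over a ±5 window (11 positions, zero-padded
across chain ends). Each window position carries its own per-residue block;
the physico-chemical histogram at a position is computed over that position's
own ±5 sequence neighbourhood (nine overlapping Taylor classes plus the
isoelectric point by pKa-table bisection, EMBOSS pKa set). The five
Laplacian-norm radii default to 4, 6, 8, 10, 12 Å; the value at radius r is
the distance between a residue's Cα and the Gaussian-weighted (bandwidth r)
mean of neighbour Cαs within 3r, which is rigid-motion invariant by
construction. Conservation rows come from an external PSSM when supplied;
otherwise the fallback uses the residue's own BLOSUM62 column standardised
per row — a deliberately database-free stand-in that preserves the block
shape but carries no alignment information (flagged `source="fallback"`).

Column counts: paratope 11×56 = 616, initial epitope 11×46 = 506, final
epitope 11×36 = 396.

## Site predictors

The binding-site networks are feed-forward classifiers (ReLU, batch
normalisation after each hidden layer starting from the second and before
the activation, per-layer dropout, Adam, weighted binary cross-entropy,
early stopping with restore-best-weights) implemented directly on numpy so
the class-weighting scheme and batch-norm placement are exactly as specified.
Depths are fixed at 7 (paratope), 11 (initial epitope) and 7 (final epitope)
hidden layers. Width and dropout schedules are per-layer hyperparameters;
the package default is a geometric 256→32 ramp with dropout 0.2. Inputs are
column-standardised with training statistics. Class weights are
`0.5 · length / class size` per class. Early stopping holds out 10% of
*complexes* (grouped split), never splitting one complex's residues across
train and validation. All stochastic steps flow from a single integer seed;
identical seeds give bitwise-identical predictions.

The desk-scale experiments use narrower nets (widths 64→32 for the site
models; uniform width 16, weight decay 0.07, fixed 150 epochs for the final
epitope model) because their training tables hold only a few hundred rows;
at that size the full-width default only slows training without changing
outcomes. The final epitope predictor is a 5-member seed-averaged ensemble:
single small-data trainings of a 7-layer net vary noticeably with
initialisation, and averaging removes that variance without touching the
architecture.

## Pose handling

Poses are rigid transforms of the antibody with the antigen fixed; the
identity pose reproduces the reference complex. The reference is built by
superposing the antibody model onto the native via paratope Cαs and the
antigen model via epitope Cαs (native binding sets at 5 Å); references whose
site RMSD exceeds 6 Å are flagged excluded. True poses satisfy IRMSD < 15 Å
and contact precision > 0.5 on both sides, where precision is the fraction
of the pose's own binding residues that are reference binding residues —
a pose with no contacts scores 0 and is False.

The 47-term pose feature vector uses expected contacts proportional to each
amino-acid type's share of the molecule's solvent-accessible surface area,
and drops the dominant noncontact∧nonsite joint term on each side. The
per-engine classifiers are XGBoost with `scale_pos_weight` set to the
False/True count ratio and training capped at 10 000 poses (seeded
subsample). The cluster-level regressor targets `1/IRMSD²` with IRMSD floored
at 0.5 Å so the target is bounded by 4. Greedy coclustering breaks neighbour
count ties toward the lower pose index; final ranking breaks score ties
toward larger clusters, then lower pose index.

## Synthetic fixtures

The generator emulates exactly what downstream code consumes — geometry with
a controlled interface and decoy sets with controlled IRMSD structure — and
nothing else. Chains are idealised poly-helices (or persistent-random-walk
coils) with N/CA/C/O and a pseudo-Cβ per residue and random sequences. The
antibody heavy chain is slid toward the antigen until the planted interface
reaches the requested size (default 10 antigen residues) without steric
overlap, at a uniformly random offset along the antigen axis so no antigen
position is a-priori epitope-like; the light chain packs alongside without
touching. Models are jittered (0.2 Å), rigidly displaced copies of the
native chains, giving site RMSDs far below the 6 Å exclusion threshold.

Decoy sets plant a target fraction of near-native poses: perturbations about
the interface centroid rejection-sampled so the measured IRMSD lands in
[1, 12] Å **and** both contact precisions stay above 0.5 — with toy-sized
binding sets an IRMSD-only calibration would shed most reference contacts
and the planted fraction would not survive labeling. Far poses are uniform
random orientations slid into surface contact (gap 3.5–4.3 Å) from random
directions, accepted when IRMSD lands in [15, 80] Å; the slide solves the
first-contact distance analytically over the antibody's convex-hull atoms.
Raw energy is IRMSD plus Gaussian noise (σ = 75), which places the
raw-energy ROC AUC against True labels near 0.6 — weakly informative, like
raw docking scores. Engine tags follow a 0.9 global-engine fraction.

What the fixtures do **not** model: real side-chain packing, energetics,
antibody-specific loop geometry, correlated sequence composition, or
realistic decoy clustering structure. Passing tests therefore demonstrate
correctness of the pipeline's bookkeeping and the learnability of planted
signals at desk scale, not performance on crystallographic data.

## Experiments and problem sizes

Two integration experiments drive the acceptance checks, both fully seeded:

* **Pose ranking** — 4 training complexes × 500 decoys train the site
  models, per-engine classifiers and the cluster regressor; a held-out query
  with 2000 decoys at 5% planted True fraction is selected (fPiper = 0.9,
  budget 10 000), coclustered at 10 Å and rescored. Reported: True Rank under
  the learned final score and under raw energy, coverage, pose-level ROC
  AUCs.
* **Epitope re-prediction gain** — the same stack plus profile decoy sets of
  150 poses per complex; the enriched condition plants 50% near-native poses
  (contacts concentrate on the epitope), the uniform condition 0%. The final
  model trains on 4 complexes' profiles and is evaluated on 4 held-out
  queries (AUCs averaged); the control comparison is the initial epitope
  model. At desk scale the initial model is essentially uninformative
  (toy antigens carry no intrinsic epitope signal), so the measured gain is
  attributable to the docking-derived profile.

These sizes were chosen so a full 10-replicate run of both experiments
completes in roughly a quarter of an hour on one CPU while leaving the
planted signals clearly detectable.

## Known limitations

* The learned pose score's pose-level ROC AUC only modestly exceeds the
  raw-energy baseline at these training sizes (the amino-acid contact-ratio
  features are composition-specific and need many complexes to generalise);
  the decisive advantage appears at the ranking stage, where cluster size
  and engine score concentrate near-native poses at the top.
* The conservation fallback carries no evolutionary signal; supply a real
  PSSM for meaningful conservation features.
* The coclustering is a single-cutoff greedy pass; a decreasing-cutoff
  schedule is a possible alternative reading of "progressive" clustering and
  would slot into the same interface.
* mmCIF input, homology modelling and the docking engines themselves are out
  of scope by design.
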