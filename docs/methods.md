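# Methods

This note records the models, conventions and deliberate simplifications
behind the package, in the spirit of a methods appendix.

## Analysis definitions

**Hydrogen bond.** Two waters are hydrogen-bonded when their oxygens are
within 3.5 Å. No angle criterion is applied — the distance-only definition
is the one the cluster statistic is built on, and adding an angle term
would change the statistic, not refine it. The same 3.5 Å cutoff defines
iron ligation (O–Fe distance).

**Cluster and bulk classification.** The binding-site water cluster of a
frame is the union of connected components, under the O–O adjacency over
*all* waters in the system, that contain any iron-ligated water. When a
periodic box is present the adjacency uses minimum-image distances; bulk
water spans the periodic cell, and without imaging the bulk component
would fragment at the box faces. (Whether imaging is used upstream of the
numbers we emulate is not documented anywhere we could rely on; periodic
adjacency is this package's choice, and a non-periodic mode exists for
fixtures.) Observed cluster sizes are strongly bimodal — tens of waters
for sealed sites versus many thousands for solvent-connected ones — so the
bulk flag is simply `size ≥ threshold` with a default threshold of 1000,
chosen inside that gap; raw sizes are always emitted so users can
re-threshold. Frames with no ligated water (rare, but they occur in
restrained early frames) get cluster size 0, count as not bulk-connected,
and are logged.

If several waters ligate the iron simultaneously, all are seeds and the
cluster is the union of their components; the single-seed case is the
common one.

**Pocket membership and volume.** A water is in the pocket iff its oxygen
is within the radius of any alpha sphere; the boundary is inclusive (a
measure-zero convention fixed for determinism). Pocket–water distances are
non-periodic by default since binding-site pockets sit deep inside the
protein; a periodic override exists for synthetic edge cases. Volume is a
Monte Carlo estimate of the union of spheres: uniform samples in the
spheres' bounding box, inside-fraction × box volume, standard error from
the binomial formula. Default 1e5 samples (≈1% relative error for compact
pockets); per-frame seeds are derived from (global seed, frame index) so
whole-trajectory runs are reproducible and order-independent. The modal
("most probable") volume of a distribution is the center of the
highest-count histogram bin, bins centered on multiples of the bin width
(default 100 ų, the granularity at which modal pocket volumes are
conventionally quoted), count ties breaking toward the lower bin.

The parser for pocket files reads the fpocket `*_pockets.pqr` dialect
(sphere center in the coordinate fields, radius in the final field, pocket
index in the residue-number field). Pocket *detection* is out of scope;
this package consumes detector output or generates synthetic spheres, and
its volume estimator is an independent union-of-spheres computation, not a
re-implementation of any detector's internal volume algorithm.

**Residence correlation.** C(Δt) averages n_persistent/(n_persistent +
n_transient) over all time origins within a stage; stages are analysed
separately because restraint conditions change at stage boundaries. Pairs
where both occupancy sets are empty are dropped from the average (the
ratio is 0/0 and such pairs carry no residence information); frames with
empty occupancy still participate in pairs whose other frame is occupied.
The default lag grid is every frame interval up to half the stage span;
the maximal lag is configurable and must stay below the span.

**Exchange-rate fit.** Under independent per-frame replacement with
survival fraction q(Δt), the expected correlation is C = q/(2−q). The fit
inverts this (q = 2C/(1+C)) and regresses log q on Δt through the origin,
using lags with C above a floor of 0.02 — below it the transform is
dominated by sampling noise. This rate is an extension beyond the
correlation curves themselves and is labelled model-derived in the fit
report.

**Two-pass RMSF.** Pass 1 superposes every frame onto the reference on all
Cα atoms (Kabsch/SVD with determinant correction; at least three
non-collinear pairs required) and computes per-Cα RMSF about the ensemble
mean. Pass 2 repeats the alignment using only Cα atoms with pass-1 RMSF
strictly below the mask threshold (default 2 Å) and recomputes Cα and
sidechain RMSF. Two conventions in this procedure are genuinely open and
are fixed as follows: (i) displacements are measured from the
ensemble-mean position, not the reference — the standard RMSF definition;
the reference only anchors the alignment, and a reference-based mode is
available in `rmsf()`; (ii) sidechain atoms are non-backbone heavy atoms
(N, Cα, C, O, OXT and hydrogens excluded); hydrogen inclusion is a flag,
default off. Per-residue sidechain RMSF is the root-mean-square of the
per-atom values; residues with no sidechain atoms yield an absent value,
not zero. Aggregation across ensembles is the residue-wise mean and sample
standard deviation.

## Synthetic gated-cavity generator

The generator is geometric and stochastic, not physical: no forces,
energies or diffusion. It plants exactly the structures the analyses
measure.

Geometry (defaults): a spherical shell of pseudo-residues (150 atoms
before cap removal, radius 14 Å, one CA + one CB per residue) inside a
40 Å periodic cube; a polar cap of half-angle 25° is left open as the
channel mouth. The heme iron sits at the shell center with the nearest
cavity-water lattice site 2.1 Å away, so an iron-ligated seed water exists
by construction. Cavity waters occupy a 2.8 Å cubic lattice ball
(connected under the 3.5 Å criterion); bulk waters fill a box-commensurate
lattice (~3 Å spacing, jittered 0.15 Å) outside the shell, connected and
percolating across the periodic boundary; an axial corridor of waters at
3.0 Å spacing joins the cavity to the bulk lattice and is present only
when the gate is open. The solvation protocols are emulated by deleting
waters whose oxygen starts within 2 or 3 Å of any *shell* atom; the iron
is exempt from this rule because deleting the axial water would remove the
seed the whole cluster statistic is defined on.

Dynamics: per frame, the gate state is fixed or Bernoulli-drawn; while the
gate is open each cavity occupant is exchanged for a fresh identity with a
fixed probability; all coordinates receive iid Gaussian jitter about their
base positions (so per-atom RMSF is σ√3 exactly in expectation).
Exchanged-in waters take over the lattice site of the water they replace:
identity exchange at a fixed site keeps the geometry — and therefore iron
ligation and the planted connectivity class — exactly invariant, which is
what makes the generator a trustworthy oracle for identity-based
statistics. A model in which incoming waters materialise at random cavity
positions was considered and rejected because it can silently unseat the
seed water. Water identities are never reused.

Defaults mirror the emulated study bookkeeping: 250 ps frame interval,
1000 frames per stage, five stages (`Stage 1` … `Stage 4.2`), triplicate
replicates, two solvation protocols. Tests and the shipped examples run
reduced problem sizes (tens to a few hundred frames per stage, a reduced
world for unit tests) — a deliberate scaling choice; every statistical
tolerance in the tests is computed for the sizes actually run.

What the generator does *not* emulate: real protein geometry and
chemistry, water structure beyond lattice packing, diffusive (rather than
teleporting) exchange pathways, correlated motions, barostat volume
fluctuations, and pocket-shape change over time (pocket spheres translate
rigidly with the iron, so synthetic volume distributions have Monte Carlo
and rigid-motion width only). Passing tests therefore demonstrate
correctness of the *analyses* under known ground truth, not fidelity of
any simulation.

Preset phenomenology: `1A2-like` keeps the gate closed in stages 1–2,
intermittent (p = 0.3) in stage 3 and open in stages 4.x, with exchange
probability rising across stages — a sealed site that only connects and
exchanges once flexible. `2D6-like`/`3A4-like` keep the gate open
throughout with mild exchange early, and a fluctuating gate (p = 0.85–0.9
open) plus faster exchange in stages 4.x — an open site whose bulk ratio
dips slightly once fully flexible. Stages 1 and 2 of `1A2-like` have
identical (zero) exchange by construction; ordering diagnostics treat ties
as compatible, and `compare_stages` accepts a tolerance for comparing
stages whose true kinetics coincide.

## Numerical and interface choices

- Coordinates are Å, internal times ps, correlation lags reported in ns.
- Orthorhombic boxes only; triclinic input raises an explicit
  unsupported-feature error.
- Persistent water identity is the file-given id (PDB residue number,
  fixture-file id, or generator id); nothing ever renumbers waters.
- Pair search uses a k-d tree (periodic when boxed); results are
  verified in tests against all-pairs connected components.
- The fixture trajectory format writes floats with six decimals, making
  write → read → write byte-identical; duplicate water ids within a frame
  and non-monotone times are format errors.
- PDB reading goes through Bio.PDB in strict mode; water residue names
  default to {HOH, TIP3, WAT, SPC} and are configurable. Which fpocket
  artifact (sphere file vs. info file) should feed per-snapshot volumes is
  ambiguous in the emulated workflow; the parser reads the sphere file and
  the volume is always recomputed independently.
- Pocket occupancy for the figures-equivalent tables uses all alpha
  spheres of the matched pocket (a residue-filtered subset would also be
  defensible; the pocket object makes such filtering easy downstream).
- Pipeline outputs are deterministic functions of (config, seed); the
  summary carries a hash of the scientific parameters, the seed and the
  package version.

## Known limitations

- The exchange-rate fit assumes memoryless, independent replacement;
  correlated or intermittent exchange would bias λ (the fit report's
  residual norm is the first diagnostic).
- The bulk threshold is meaningful only when the system is large enough to
  show the bimodal gap; tiny test systems must lower it accordingly.
- `C(Δt)` averages a ratio, whose expectation differs from the ratio of
  expectations at small pocket sizes; the closed form q/(2−q) used in
  recovery tests is exact only in the large-pocket limit, and test
  tolerances account for this.
- Sidechain RMSF with hydrogens included will differ from the heavy-atom
  default; comparisons across tools must match this convention.
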