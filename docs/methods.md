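# Methods

This note documents the models, conventions and numerical choices behind
`mdcompare`, and what the synthetic-data verification does and does not
establish about real trajectories.

## Superposition and fluctuation metrics

Superposition minimizes the (optionally weighted) coordinate RMSD over
proper rotations and translations. The rotation comes from the SVD-based
closed-form solution (`scipy.spatial.transform.Rotation.align_vectors`);
the residual RMSD is then recomputed directly from the transformed
coordinates, because the solver's own residual loses precision to
cancellation near zero. References with fewer than three atoms or a
collinear atom arrangement are rejected: the optimal rotation is not
unique there.

Conventions, declared because MD engine tools differ:

- **RMSD** is measured against the *starting structure* after fitting each
  frame on the fit selection. Self-fitting sets fit = measure = one
  monomer's Cα atoms; non-self-fitting fits on the partner monomer, so the
  measured RMSD additionally contains the inter-monomer displacement.
  On a rigid hinge-opening ensemble this makes non-self RMSD strictly
  larger than self RMSD at every opened frame, which is the property the
  test suite checks.
- **RMSF** is the root-mean-square deviation of each atom about its
  *time-average position*, after fitting every frame to the reference.
  For an isotropic Gaussian ensemble with per-coordinate σ, per-atom RMSF
  converges to σ√3; at 200 atoms × 5000 frames the fitting correction is
  below the 3% verification tolerance.
- The RMSF profile for a dimer is computed after fitting on **all dimer
  Cα atoms** by default; per-monomer fitting is available through
  `FitSpec.monomer`.
- **Region statistics** use the arithmetic mean and the *population* (n)
  standard deviation over member residues, reported separately per
  monomer. Region definitions list residues of the owning monomer and
  residues contributed by the partner across the interface; the shipped
  set describes the SHMT active site (floor 197–204 + 213–242; inner wall
  97–110 with 258–264 from the partner; outer wall 174–182; roof 118–133)
  and the PLP and folate cofactor sites.
- **Radius of gyration** is mass-weighted about the center of mass, in Å.

## Geometric interaction criteria

All cutoffs are *strict* inequalities, matching their definitions:

| parameter | criterion | default |
|---|---|---|
| SASA probe radius | — | 1.4 Å |
| close contact | d < cutoff | 6 Å |
| hydrogen bond, distance | donor–acceptor d < cutoff | 3.5 Å |
| hydrogen bond, angle | D–H–A angle > cutoff | 120° |

SASA uses Shrake–Rupley sphere sampling with a fixed deterministic
golden-spiral point set (960 points/atom), so results are bit-reproducible;
van der Waals radii are the Bondi (1964) values shipped in
`geometry_interactions.VDW_RADII`. The implementation works directly on
coordinate frames and is cross-checked in the test suite against the
independent Shrake–Rupley implementation in Bio.PDB and against analytic
one- and two-sphere areas.

Contacts are defined purely by distance — no bonded or same-residue
exclusions — because the criterion says nothing else; consequently
absolute intra-protein contact counts are not comparable to engine tools
that exclude bonded pairs, and only differences/trends should be compared
across conventions.

Donor/acceptor typing is rule-based: acceptors are all N/O atoms; donors
are N/O heavy atoms with a hydrogen within 1.25 Å in the topology
(hydrogens attach to their nearest N/O). A donor-capable atom without
hydrogens (e.g. a structure solved without protons) is skipped and logged,
not an error. Water oxygen is both donor parent and acceptor; the
protein–solvent mode counts both directions.

## Essential dynamics

The Cα covariance is built about the ensemble mean with a two-pass fit:
frames are fitted to the starting structure, their mean is formed, and all
frames are re-fitted to that mean. The covariance is the population
(divide-by-F) second moment; `numpy.linalg.eigh` diagonalizes it, eigenpairs
are sorted by decreasing eigenvalue (stable sort, so exact ties keep the
solver's order), and each eigenvector's sign is fixed so its
largest-magnitude component is positive — removing the sign ambiguity from
projections and porcupine output. Cα covariance is unweighted: equal
masses make mass-weighting a constant factor.

Rigid-body fitting removes six degrees of freedom, so at least six
eigenvalues of a fitted ensemble vanish (to numerical precision). TMSF is
the trace and equals the eigenvalue sum; projection series have mean ~0
and variance equal to their eigenvalue by construction, and both identities
are asserted numerically rather than assumed.

`FitSpec(superpose=False)` bypasses fitting entirely. That path exists for
verification: sampled ensembles with *prescribed* covariance can then be
compared against the raw sample covariance and against the generator's
ground truth without the fit redistributing variance. Top-3 eigenvalue
recovery within 5% at 10⁴ frames is the tested bound.

**Cosine content** of projection *p*(*t*) for harmonic *i* is

c_i = (2/T) (∫₀ᵀ cos(iπt/T) p(t) dt)² / ∫₀ᵀ p(t)² dt,

with trapezoid integration on the actual frame-time grid. It is invariant
to amplitude and time-axis scaling. Values near 1 mean the mode resembles
free diffusion (unconverged sampling); near 0, converged sampling. After
concatenating replica segments the time axis is re-indexed to a continuous
grid (each segment keeps its spacing and starts one median step after the
previous one) precisely so these integrals see one uninterrupted axis.
Cosine contents are computed on the equilibrated window.

**Porcupine extraction** returns the conformations at the minimum and
maximum of a projection series and per-atom displacement vectors
((max − min) × eigenvector components) for arrow rendering, plus a
two-model PDB export.

## Free-energy landscapes

Projections onto eigenvectors 1 and 2 are histogrammed on a 32×32 grid by
default (configurable; the choice is a compromise between resolution and
per-bin counts) spanning [min, max] per axis with numpy's half-open bins
(last bin closed, so extreme frames count). Boltzmann inversion
F_i = −k_B T ln(N_i/N_max), with k_B = 0.0083144621 kJ·mol⁻¹·K⁻¹ and
T = 300 K by default, fixes F = 0 at the most populated bin; all finite
values are ≥ 0 and empty bins are +∞. Published landscapes often carry an
engine-specific negative offset; since basin structure is invariant under
a constant shift (asserted as a test property), basin counts at level L on
this scale correspond to counts at L + c on any shifted scale.

Basins at level L are connected components of {bins: F < L} under
8-neighbour connectivity (diagonally touching contour cells count as one
basin — the convention that matches visual counting on smooth contour
plots). The flood fill is `scipy.ndimage.label`; the test suite compares it
against an exhaustive depth-first labelling oracle on random grids up to
64×64. Two-state mixtures with populations (p, 1−p) must reproduce
ΔF = −k_B T ln((1−p)/p) within 0.3 kJ/mol at 10⁵ frames.

## Replica statistics

Each replica's RMSD series over the equilibration window (default
10–100 ns, the window applied per replica before concatenation) yields a
per-replica mean and SD. The two systems' SD sets are compared with a
one-sided Welch (unequal-variance) t-test, Welch–Satterthwaite degrees of
freedom; a pooled-variance variant is available by flag. The phrase "SDs
of the RMSD means" is read as the per-replica SDs of the RMSD series (ten
replicas giving ten SDs per system); this reading is the one that produces
"two sets of SDs" of the right size. Degenerate input — both groups
constant and equal — carries no directional information and returns
p = 0.5 by convention, logged.

## Synthetic generators: what they emulate and what they do not

The generators produce ensembles whose *statistical* ground truth is known
exactly: prescribed (diagonal or low-rank-plus-isotropic) covariance,
linear-in-time diffusion variance, exact two-state labels, exact hinge
angles, and a dimer interface with hydrogen bonds and contacts present by
construction. All draw from `numpy.random.default_rng(seed)`; identical
arguments give bit-identical output and no global random state is touched.

They do **not** emulate: bonded geometry and excluded volume, solvent
structure beyond isolated point waters, force-field energetics,
autocorrelated dynamics (Gaussian ensembles are i.i.d. in time), or
anharmonic mode coupling. Passing tests therefore establish that the
*estimators* are correct — superposition, covariance spectra, Boltzmann
inversion, counting criteria, test statistics — not that any physical
conclusion about a real protein follows; that depends on the quality of
the input trajectories.

Default generator conditions used in verification (chosen once, as
realistic magnitudes for Cα fluctuations in nm): noise σ = 0.05 nm;
isotropic RMSF check at 200 atoms × 5000 frames; eigen-recovery at 20
atoms × 10⁴ frames with mode variances 0.06/0.03/0.015 nm² over a
0.004 nm isotropic floor; diffusion walks of 200 steps × 50 seeds;
two-state mixtures of 10⁵ frames at p = 0.75 with 0.03 nm jitter; hinge
openings of 0–25°. These sizes keep the whole verification suite under a
minute on one CPU while leaving Monte-Carlo error well inside each stated
tolerance.

## Numerical and degenerate-input choices

- PDB coordinates round-trip at the format's 0.001 Å precision; a second
  round trip is exact.
- Alternate locations resolve to the highest-occupancy conformer, ties to
  the altloc appearing first. Residue numbering is author numbering and is
  never rewritten. HETATM groups (cofactors, waters) are parsed but
  excluded from Cα analytics. Missing residues are reported
  (`numbering_gaps`), never rebuilt.
- Pairwise alignment: global, BLOSUM62, gap open 10 / extend 0.5.
  Percent identity = identical pairs / aligned columns carrying a residue
  on both sides (gap columns excluded from the denominator — a documented
  convention, since a bare identity figure does not define one).
- A static trajectory yields a zero covariance (TMSF 0) rather than an
  error; an all-zero projection series makes cosine content undefined and
  raises; a constant projection series has no extremes and raises.
- Zero-frame landscapes, empty selections, empty regions, single-frame
  RMSF, and sub-minimal replica counts are errors, not silent zeros.

## Known limitations

- Absolute contact counts (no exclusions) and absolute free-energy offsets
  are convention-dependent; compare trends, not raw magnitudes, across
  tools.
- The SASA implementation is O(N·k) per frame with k neighbours per atom;
  it is meant for analysis-scale selections, not millions of atoms.
- Binary trajectory formats are out of scope; multi-model PDB (plus time
  sidecar) is the interchange dialect. Adapters can be layered on without
  touching the analysis modules.
- Force-field energy decompositions (e.g. inter-monomer van der Waals or
  electrostatic energies) are deliberately absent: they are engine- and
  parameter-set-dependent and cannot be reproduced from coordinates alone.
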