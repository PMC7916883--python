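# mdcompare

Comparative analysis of molecular-dynamics trajectories of homologous
proteins — built for the kind of question asked about temperature
adaptation in enzymes: *does the cold-adapted homologue really fluctuate
more than the warm-adapted one, and where?*

The package implements the full trajectory-analysis side of such a study
for a homodimeric enzyme (the shipped region definitions describe serine
hydroxymethyltransferase, a PLP-dependent dimer whose active site straddles
the monomer interface), while the analysis machinery itself is generic:

- **Superposition metrics** — Kabsch least-squares fitting; Cα RMSD time
  series against the starting structure, including *self-fitting*
  (fit and measure the same monomer) and *non-self-fitting* (fit one
  monomer, measure the other) to separate internal fluctuation from
  inter-monomer displacement; per-residue RMSF; per-region RMSF means ± SD;
  radius of gyration.
- **Geometric interaction statistics** — Shrake–Rupley SASA (1.4 Å probe),
  close inter-atomic contacts (< 6 Å, strict), geometric hydrogen bonds
  (donor–acceptor < 3.5 Å *and* donor–hydrogen–acceptor angle > 120°,
  both strict), summarized as trajectory means ± SDs.
- **Essential dynamics** — the 3N×3N Cα positional covariance matrix of
  the fitted ensemble, its eigenvectors (collective motion modes) and
  eigenvalues (mean-square amplitudes, nm²); total mean square fluctuation
  TMSF = tr(C); cumulative eigenvalue contributions; trajectory
  projections; cosine-content sampling-convergence diagnostics; porcupine
  (extreme-conformation) extraction.
- **Free-energy landscapes** — 2-D Boltzmann inversion over the first two
  eigenvector projections, *F*(*s*) = −*k*<sub>B</sub>*T* ln(*N<sub>i</sub>*/*N*<sub>max</sub>),
  with basin counting at energy levels by 8-connected flood fill.
- **Replica statistics** — per-replica RMSD means/SDs over the
  equilibration window (default 10–100 ns) and a one-sided Welch *t*-test
  on the two systems' replica SDs.
- **Synthetic generators** — seeded ensembles with prescribed covariance,
  random-diffusion walks, two-state mixtures with known populations, rigid
  hinge motions of a dimer, and a toy hydrogen-bonded dimer, each emitting
  a ground-truth record, so every stage is verifiable without real MD data.

Trajectories are interchanged as multi-model PDB (plus a TSV time sidecar);
structures as standard PDB. Internal units are nm; Å appears only at the
PDB boundary and in SASA/Rg reports.

## Worked example

Generate a known-ground-truth ensemble and run essential dynamics on it:

```sh
mdcompare simulate --kind gaussian --n-frames 400 --n-atoms 12 \
    --sigma 0.05 --seed 5 --outdir sim
mdcompare ed sim/trajectory.pdb --outdir ed
head -4 ed/eigenvalues.tsv && cat ed/tmsf.json
```

```
eigenvector	eigenvalue_nm2	cumulative_pct
1	0.00381268	5.08156122
2	0.00372393	10.04483507
3	0.00358746	14.82622687
{
  "tmsf_nm2": 0.07502967267583026
}
```

The input was isotropic noise with per-coordinate σ = 0.05 nm on 12 atoms,
so the spectrum is nearly flat (no dominant collective mode — the
cumulative contribution climbs almost linearly) and the TMSF sits near
σ²·(3·12 − 6) = 0.075 nm²: the total variance of the 36 coordinate
dimensions minus the six rigid-body degrees of freedom removed by the
least-squares fit. `ed/cosine_content.json` reports cosine contents ~0.002
for the leading modes: i.i.d. sampling is maximally converged, in contrast
to the values near 1 produced by a random-walk ensemble
(`--kind diffusion`).

The `compare` subcommand runs the whole two-system pipeline (RMSD, RMSF,
regions, geometry, essential dynamics, landscape, replica SD test) from a
small INI config listing the replica trajectories of both systems.

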