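# Methods

## Elastic network models

Both models place springs of uniform force constant γ between every node
pair within a cutoff r_c of the native structure.

The **GNM** uses the Kirchhoff matrix Γ: Γ_ij = −1 for a contact,
0 otherwise, and diagonal elements equal to the node degree. Square
fluctuations are the diagonal of the Moore–Penrose pseudo-inverse scaled
by 3kT/γ, computed here as the eigen-sum Σ_k λ_k⁻¹ u_k[i]² over non-zero
modes (the two routes agree to 1e-8 and both are implemented; the
pseudo-inverse serves as the independent oracle in the tests).

The **ANM** Hessian assembles, for each contact, the 3×3 super-element
−γ (R⁰⊗R⁰)/|R⁰|² with diagonal blocks closing the row sums to zero.
Row sums of both matrices are exactly zero by construction (assembled,
not accumulated).

Zero modes are flagged by a relative threshold (λ < 1e-8 · λ_max), which
is robust across system sizes; a connected network must yield exactly 1
(GNM) or 6 (ANM) of them, and any other count raises a warning carrying
the connected-component count. "Mode 1" always means the first non-zero
mode. Within degenerate eigenvalue clusters (the symmetric cage has
many) the individual eigenvectors are solver-dependent, but fluctuations
and correlation maps sum over modes and are invariant to rotations
inside a degenerate subspace; overlap maps against individual modes are
the one place where degeneracy matters and should be read alongside the
eigenvalue spectrum.

Cutoffs default per representation level — GNM 20/15/10 Å and ANM
30/20/15 Å for the one-, two- and three-node models — and are
overridable. γ defaults to 1 and kT_scale (the 3kT/γ prefactor) to 1:
every comparison in the package is a correlation or a rescaled profile,
so absolute units never matter; scaling γ by c divides all fluctuations
by c and leaves every correlation unchanged (tested).

The eigensolver is a full dense symmetric decomposition; the largest
problem in the study, the 4968×4968 three-node ANM of the cage, takes
~25 s on one core. A Lanczos path (`diagonalize_partial`) is provided
and verified against the dense route on the first modes for cases where
only the slow end of a larger spectrum is needed.

## The surrogate cage

No coordinates for the analysed octahedron are publicly deposited, so
the package builds an idealized stand-in. Design values that are fixed
by the cage architecture: octahedron skeleton (6 vertices, 12 edges,
vertex degree 4), 18 bp per edge, 5 nt per single-strand linker, 24
linkers, 552 nucleotides total, threading into 8 covalently closed
strands (the threading follows a fixed cyclic rule at each vertex:
the outgoing 3′ strand of each incident duplex connects to the incoming
5′ strand of the next duplex around the vertex axis, which closes into
exactly 8 loops).

Free geometric choices, fixed once and documented:

- B-DNA fiber constants: rise 3.38 Å, twist 36°, track radii P 8.9 Å,
  O4* 7.9 Å, C4* 7.0 Å, C2 3.5 Å, second-backbone phase 154°. All of a
  residue's pseudo-atoms sit at the same azimuth (concentric tracks);
  optional per-track angular offsets exist but default to zero.
- The O4* track is emitted only on request (`include_O4`); the default
  three-track residue is P/C4*/C2, which the two-node P/O4* analysis
  supplements.
- Vertex stand-off (distance from a vertex to the nearest helix
  terminus): 2.8 Å per linker nucleotide, i.e. 14 Å for the default
  cage. This keeps the truncation gap wider than the three-node GNM
  cutoff, so vertex coupling flows through the linkers rather than
  through direct duplex–duplex contacts, and leaves room for
  single-strand backbone spacing along the linker arc.
- Linkers are circular arcs of length (n+1)·6 Å bowing outward from
  their own chord (the four arcs around a vertex run along the separate
  sides of the truncation square); consecutive linker phosphates end up
  5.9–6.5 Å apart, the spacing of an extended single strand. Each
  linker nucleotide is a compact near-collinear cluster (O4* +0.8 Å,
  C4* +1.5 Å, C2 +3.0 Å along the arc normal).
- Edge scale is derived, not set: centre-to-vertex distance is chosen so
  an edge exactly spans the 17 × 3.38 Å helix plus two stand-offs.
- The builder is bitwise deterministic; an optional Gaussian coordinate
  jitter (seeded) exists for robustness experiments and defaults to 0.

Sequence is cosmetic (alternating C/G in duplexes, T in linkers): the
models see only coordinates.

### What the surrogate reproduces, and what it does not

The idealized cage reproduces the topology-driven observables well:
hinge nucleotides from the two slowest GNM modes cluster at the vertex
linkers (73% within 2 residues of a linker), duplex edges move as
internally correlated blocks, the 20-mode cross-correlation extrema land
near −0.42 for both models, the slowest-GNM-mode variance share is
≈ 0.07–0.08, and the one-node ANM–GNM profile correlation is ≈ 0.95.

Two families of observables are sensitive to the difference between an
ideal lattice and a relaxed, thermally disordered structure, and the
surrogate is known to overshoot them. First, its perfect octahedral
symmetry makes the ANM and GNM fluctuation profiles nearly congruent at
every representation level (r ≈ 0.88–0.95), whereas a relaxed structure
decorrelates them level-dependently; in the two-node model this is
compounded by the concentric-track simplification, which places P and
O4* only 1 Å apart and makes the two-node network essentially a doubled
one-node network. Second, the symmetric cage spreads variance across
many near-degenerate slow modes, so the first 20 modes carry ~0.40–0.43
of the total variance rather than a majority. Coordinate-level jitter
does not close either gap (tested up to 1.5 Å), so the difference is
conformational — bent duplexes, collapsed linkers — not noise.
Conclusions drawn from the surrogate should therefore be limited to
topology-driven quantities.

## Ensembles and PCA

The generator draws frame f = R⁰ + Σ_l a_{f,l} ν_l + η_f with
a_{f,l} ~ N(0, σ_l²) along chosen ANM modes and i.i.d. coordinate noise
η ~ N(0, ε²). One seeded generator with a fixed draw order (modes in
ascending index, frames within a mode, noise last) pins ensembles
bitwise. This emulates the statistical shape of an equilibrated
trajectory — a few dominant collective directions over a
high-dimensional noise floor — with known ground truth, so every
PCA-versus-ANM comparison doubles as a parameter-recovery check. It does
not emulate anharmonicity, drift, or conformational substates; a real
trajectory's PCA can disagree with ANM in ways the generator cannot
produce by construction. Demonstration amplitudes (σ = 3, 2, 1.5 Å on
the three slowest modes, ε = 0.05 Å, 100 frames) put the top two PC
variance fractions near one third and one seventh, the regime reported
for stable nanocage trajectories.

Superposition iterates least-squares rigid fits (proper rotations only)
of every frame to the running mean until the mean moves < 1e-10 Å,
seeding from the raw mean so the procedure is idempotent. The converged
orientation is arbitrary; an optional reference structure fixes it,
which matters whenever frame projections are compared against mode
vectors expressed in the reference frame. All nodes carry equal fit
weights. PCA uses covariance divisor F (population); directions and
variance fractions — the only quantities consumed — are invariant to
the F vs F−1 choice. The decomposition runs as a thin SVD of the F×3N
displacement matrix, which yields the same non-null eigenpairs as the
explicit 3N×3N covariance (cross-checked in a test) at a fraction of
the cost.

## Mode comparison conventions

- Overlap uses the absolute dot product: eigenvector sign is arbitrary.
- Cross-level profile comparisons reduce per-node profiles to
  per-residue means first, so 1/2/3-node models share an axis.
- Map correlations exclude the diagonal (2N entries identically 1 would
  inflate r).
- Fraction of variance for GNM/ANM uses inverse eigenvalues over the
  non-zero spectrum; for PCA, the eigenvalues themselves.
- Collectivity is the information-entropy form
  κ = exp(−Σ p_i ln p_i)/N with p_i the normalised per-node squared
  amplitude (3N vectors reduce per node by the 3-component norm);
  uniform modes give 1, single-node modes 1/N.
- Hinge detection: per-residue single-mode square-fluctuation profile;
  a hinge is a strict local minimum within ±5 residues along its strand
  that also lies below the 25th percentile of the profile. Both
  parameters are exposed; strands are treated as closed loops by
  default because the cage oligonucleotides are covalently closed. The
  percentile gate suppresses the shallow minima that pure
  local-minimum rules produce on flat profile stretches; detection is
  invariant to profile rescaling.

## Numerical conventions and degenerate inputs

Duplicate nodes (zero distance) are rejected rather than silently
merged. Residues missing a required role atom are skipped and logged,
never substituted, since substitution would rewire the network.
Collinear node sets make the rigid fit degenerate and raise an error.
Cutoff monotonicity (more contacts at larger cutoff), rigid-motion
invariance of GNM/ANM outputs, and CO ≤ 1 with equality on a complete
basis are enforced by property tests. PDB output uses the prime dialect
(O4′); input accepts both dialects and normalises to `*`. Files with
insertion codes are rejected explicitly.

## Problem sizes

The package's standard analyses run the full spectra: level-1 models
diagonalize 552 (GNM) and 1656 (ANM) dimensional matrices, level 2
1104/3312, level 3 1656/4968. The complete representation sweep,
including all six eigenproblems, finishes in roughly forty seconds on a
single core; synthetic-ensemble PCA on the level-3 cage (100 frames)
adds a few seconds more.
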