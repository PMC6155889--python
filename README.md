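# nacage

Elastic-network analysis of DNA polyhedral nanocages.

DNA nanocages — polyhedra whose edges are short B-DNA duplexes joined at
the vertices by single-stranded linkers — are rigid enough to carry cargo
yet flexible enough to breathe, and their slow collective motions decide
how they deform, open and close. All-atom molecular dynamics of a
500-nucleotide cage is expensive; elastic network models (ENMs) predict
the same slow dynamics from nothing but the native contact topology, in
seconds. This package provides the full ENM toolbox for nucleic-acid
cages, aimed at structural DNA-nanotechnology groups who want
intrinsic-dynamics estimates (flexibility profiles, hinge nucleotides,
correlated motions, global modes) without running a trajectory.

## What it computes

A nucleotide is coarse-grained to one (P), two (P, O4\*) or three
(P, C4\*, C2) pseudo-atom nodes. Nodes closer than a cutoff r_c are
joined by identical springs (force constant γ).

**GNM** — the N×N Kirchhoff matrix Γ (graph Laplacian of the contact
network) gives isotropic square fluctuations and cross-correlations from
its pseudo-inverse:

    ⟨ΔR_i²⟩ = (3kT/γ) [Γ⁺]_ii ,   C_ij = ⟨ΔR_i·ΔR_j⟩ / (⟨ΔR_i²⟩⟨ΔR_j²⟩)^½

**ANM** — the 3N×3N Hessian of V = (γ/2) Σ_ij (|R_ij| − |R_ij⁰|)²
yields directional normal modes ν_l with variances ∝ 1/λ_l.

**PCA** — conformational ensembles (multi-model PDB, or synthesized as
mode-directed Gaussian deformations) are iteratively superposed and the
displacement covariance ⟨(R_i−⟨R_i⟩)(R_j−⟨R_j⟩)⟩ diagonalized into PC
modes u_k ranked by variance.

Modes are compared through the overlap O(u,ν) = |u·ν|, the cumulative
overlap CO(m) = (Σ_{l≤m} O²)^½, per-mode fraction of variance p, the
entropy collectivity κ ∈ (1/N, 1], and Pearson correlations of
fluctuation profiles and correlation maps. Hinge nucleotides are strict
local minima of the slowest GNM-mode profiles below a percentile gate.

Because no coordinate set for the cage studied here is deposited, the
package includes a deterministic builder for an idealized truncated
octahedron: 12 edges of 18-bp B-DNA, 6 vertices each bridged by four
5-nucleotide single-strand linkers — 552 nucleotides threading into 8
covalently closed strands.

## Worked example

```
$ python analysis/01_build_cage.py
  residues_total: 552
  residues_helix: 432
 residues_linker: 120
         strands: 8
```

The builder reproduces the design arithmetic exactly: 2×18×12 duplex
nucleotides plus 5×24 linker nucleotides, in 8 closed oligonucleotides.

```
$ python analysis/03_hinges_maps_global_motions.py
hinges from GNM modes 1-2: 44; 73% within 2 residues of a linker
GNM 20-mode map range: [-0.4230, 1.0000]
ANM 20-mode map range: [-0.4153, 1.0000]
GNM-ANM map correlation (upper triangle): 0.841
```

The two slowest GNM modes place almost three quarters of the predicted
hinge nucleotides at or next to the single-strand vertex bridges — the
cage's mechanics are set by its polyhedral geometry, with the vertices
acting as pivots. The strongest anti-correlations in the 20-mode maps
(≈ −0.42 for both models) couple opposite regions of the cage.

```
$ python analysis/04_ensemble_vs_anm.py
PC variance fractions: 0.323 0.148 0.083 0.006 0.006
max overlap 0.991 at (PC1, ANM1)
cumulative overlap over 20 ANM modes: PC1 0.993, PC2 0.985
projection correlation |r|(PC1, ANM1) = 1.000
projection correlation |r|(PC2, ANM2) = 0.997
```

With a synthetic ensemble whose ground truth is known (Gaussian
amplitudes along three slow ANM modes plus a small noise floor), PCA
recovers the generating modes nearly perfectly — the parameter-recovery
check that validates the whole PCA-versus-ANM comparison chain.

A command-line interface wraps the same stages:

```
nacage build --edge-bp 18 --linker-nt 5 -o cage.pdb
nacage enm -i cage.pdb --level 3 -o enm_out/
nacage compare -i cage.pdb --generate 1:3.0,2:2.0 --noise 0.05 -o cmp_out/
```

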