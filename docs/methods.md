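# Methods

This note records the model, the numerical choices, and the places
where the design was genuinely open, in enough detail to reimplement
the package.

## Scalar fluctuations and the covariance convention

An ensemble of m conformers of an N-residue protein is reduced to its
Cα trace. External (rigid-body) degrees of freedom are removed by
iterative mean-structure superposition: every model is least-squares
fitted (Kabsch SVD, proper-rotation corrected) onto the current mean,
the mean is recomputed, and the loop repeats until the mean moves by
less than 10⁻⁶ Å RMS. Iterating against the mean, rather than
progressive pairwise fitting, makes the internal reference frame
independent of model order; the first model only seeds the iteration.
Cα atoms carry uniform weight; backbone N/C/O atoms ride along with
their model's Cα-derived transform.

The scalar covariance is defined with the isotropic-GNM convention

    C_ij = (1/3)·(1/m) Σ_k ΔR_i^(k)·ΔR_j^(k),

where ΔR_i^(k) is the vector displacement of residue i in model k from
its mean position. The 1/3 makes C_ii the per-axis mean-square
fluctuation, which is the unique convention under which interaction
matrices fitted to C convert to physical force constants by the single
factor 3·k_B·T (k_B = 1.9872×10⁻³ kcal/mol/K). Division is by m, not
m−1: C enters the estimation problem as a constrained expectation, not
as an unbiased estimator (`ddof=1` is available). C is symmetrized and
is nonnegative definite up to round-off by construction.

Residues are intersected across models (a residue missing its Cα in
any model is dropped with a warning); alternate locations resolve to
highest occupancy, first-listed on ties. Indices are 0-based
internally and 1-based in every user-facing table.

## The maximum-entropy fit

Given a constraint set π of residue pairs (the network topology; the
diagonal MSFs are constrained by default), the maximum-entropy
distribution reproducing the constrained covariances is a Gaussian
whose precision matrix K is exactly zero on off-diagonal entries
outside π. K minimizes

    f(K, C) = tr(K·C) − log det K,

whose unique stationary point on the free entries satisfies
(K⁻¹)_e = C_e. This is the standard Gaussian maximum-entropy /
graphical-model duality: constrain covariances, obtain sparse
precision. Off-diagonal elements are negative spring constants,
K_ij = −γ_ij.

**Solver.** The stationarity system is solved by damped Newton
iteration on the free entries. With p free parameters (q pairs plus N
diagonal entries), the Jacobian J_ab = ∂(K⁻¹)_{e_a}/∂x_{e_b} is
assembled in closed form from K⁻¹ (Jacobi's formula), and the step
solves J·Δx = −R for the scaled residual vector
R_e = ((K⁻¹)_e − C_e)/s_e. Backtracking halves the step until K stays
positive definite (Cholesky succeeds and the smallest eigenvalue
exceeds 10⁻¹²·tr(K)/N) and the residual norm decreases. A
scaled-gradient fallback covers a singular Jacobian. Newton converges
quadratically here (typically 5–10 steps for N = 30) and is exactly
equivariant under C → c·C, K → K/c, so the covariance scaling law
holds to round-off. The initial iterate is the diagonal matrix
K_ii = 1/C_ii — a feasible positive-definite start; because the
minimum is unique, initialization affects only the step count. (A
Kirchhoff-based start scaled to match tr(C) is attempted first but the
Kirchhoff matrix of any topology is singular, so the diagonal start is
the effective one.)

**Convergence criterion.** The per-entry residual scale is
s_e = max(|C_e|, 10⁻²·tr(C)/N), guarding the relative residual against
constrained covariances near zero. Iteration stops when both

1. |(K⁻¹)_e − C_e| ≤ tolerance·s_e for every constrained entry, and
2. the last Newton step moved every free parameter by at most
   `tolerance` in relative terms (|Δx_e| / max(|x_e|, 10⁻²·mean|x_off|)).

The default tolerance is 0.01 with a 10⁵-step budget. The second
condition exists because condition 1 alone leaves the stopping point
quantized by the solver's step sizes: two runs at tolerances 0.01 and
0.005 can stop one step apart, and near-zero springs then show large
*relative* differences even though both iterates satisfy their
covariance tolerance. Requiring the interactions themselves to have
stopped moving makes the fit insensitive to halving the convergence
constant (the measured mean relative spring change is ≈ 0, comfortably
under the ~1% the criterion is designed to guarantee). With quadratic
convergence the extra condition typically costs one additional step.

**Degenerate inputs.** If C is rank-deficient by the package-wide
pseudoinverse rule (eigenvalue < 10⁻⁸ × largest), a ridge
ε·tr(C)/N·I with ε = 10⁻⁶ is added and recorded in the result
metadata; this covers the m−1 < N regime and the rigid-mode null space
of superposed ensembles. A constrained diagonal entry C_ii ≤ 0 is a
hard error. Non-convergence raises an error carrying the best iterate
and its residual.

**Derived operations.** Model covariances are recomputed as the
pseudoinverse K⁺ under the same eigenvalue rule. Normalization divides
all γ by the mean |γ| over nonzero off-diagonal constrained pairs
(making force constants comparable across proteins, since covariance
scale trades off inversely with interaction scale). Pruning removes
the weakest fraction of pairs by |γ| (ties broken by pair index) from
both K and π; the pruned network's covariance again comes from the
pseudoinverse.

## GNM and the modified GNM

The contact topology connects all Cα pairs within `R_c` (default 10 Å,
deliberately longer than the 7–8 Å that optimizes B-factor
reproduction, so that weak long-range interactions are representable)
in one declared structure — by default the mean structure, which is
the reference for fluctuations. Classical GNM assigns γ = 1 to every
edge; the covariance is Γ⁺/γ with null modes (and any negative
eigenvalues of a frustrated network) excluded and reported.

The modified GNM weights each edge as
base × contact-order factor × H-bond factor, composed multiplicatively
in that fixed order:

| ingredient | factor |
|---|---|
| base | 1 (uniform, "U") or 1/d² ("D") |
| bonded, |i−j| = 1 | ×10 |
| second neighbor, |i−j| = 2 | ×(−1) on U base, ×(−5) on D base |
| backbone H-bonded pair | ×10 |

The ten named variants (U … D+g1+g2+HB = mGNM) set factors of 1 where
an ingredient is absent. Whether the bonded factor should *replace*
rather than multiply the 1/d² base is not decidable from the variant
definitions; multiplication is used because the ingredients are
defined as independent modifiers, and the choice is flagged here.
Negative second-neighbor springs can in principle push Γ indefinite;
the covariance then uses only positive eigenmodes and the negative
eigenvalues are reported in metadata rather than silently repaired.

## Annotation

Secondary structure and backbone hydrogen bonds are assigned on the
representative model — the model with lowest RMSD to the mean (ties to
the lowest index) — since these are single-structure algorithms.
Two sources are supported:

- **Classic DSSP files**: structure code column mapped H→helix, E and
  B→strand, everything else→other; H-bond partners taken from the four
  N-H→O / O→H-N fields with energy < −0.5 kcal/mol. Only the classic
  fixed-width layout is parsed.
- **Internal assignment**: amide hydrogens are reconstructed 1.01 Å
  from N, trans to the preceding carbonyl (prolines excluded as
  donors), and donor–acceptor pairs are scored with the Kabsch–Sander
  electrostatic energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH −
  1/r_CN) kcal/mol, bonded when E < −0.5. Helices are residues covered
  by two consecutive i→i+4 turns; strands come from the standard
  parallel/antiparallel bridge patterns. This is a deliberately coarse
  three-class assignment (H / E / other), not a DSSP reimplementation;
  on ideal-geometry fixtures it reproduces the canonical helical
  H-bond ladder exactly.

## Analysis statistics

Stratification groups table rows by contact order, secondary-structure
pair, H-bond flag or amino-acid pair and reports exact group means,
population SDs, counts and histograms (default bin width 0.25 in
normalized units; the bin width is a free choice and configurable).
The distance-decay fits maximize the Pearson correlation between the
binned ⟨|γ|⟩(d) curve and A·exp(−d²/r₀²) or A/d^α over the shape
parameter (coarse grid + bounded scalar refinement — correlation is
amplitude-free), then set the amplitude by least squares; fits are
reported with the achieved correlation and are exactly
scale-equivariant.

The inter-order correlation between orders k > n correlates γ_{i,i+k}
with the arithmetic mean of the k−n+1 order-n constants nested in the
span, γ̄ = mean(γ_{j,j+n}, j = i..i+k−n), over positions where the full
nested set is present; scoping to helix or strand requires every
residue of every participating pair to carry the code. Fewer than 3
valid positions is an error, not a number.

Covariance agreement splits matrix elements into diagonal (MSF),
interacting (edge in the declared topology), non-interacting, and all
off-diagonal classes, reporting a Pearson correlation per class; the
top-m-modes variant first replaces both matrices by their rank-m
reconstruction from the largest-variance eigenmodes. Node weight is
Σ_j |γ_ij| for a fitted network and the degree for a GNM; its inverse
is correlated against the MSF, with NaN for degenerate (constant)
inputs.

## Mode-space comparison

"Slowest" modes of a stiffness-type matrix (K, Γ) are the smallest
nonzero eigenvalues; for a covariance matrix they are the largest
eigenvalues — the orderings correspond under inversion. Null modes
(|λ| < 10⁻⁸ × largest) are excluded from mode counting. Mobilities
from m modes are Σ v_i²/λ (stiffness) or Σ λ·v_i² (covariance), so the
all-modes profile is the diagonal of the pseudoinverse (respectively,
of the matrix). The subspace overlap is

    Q_m = (1/m) Σ_{k,p ≤ m} (u^(k)·v^(p))²,

the only normalization for which identical m-subspaces give exactly 1;
it is symmetric, bounded in [0, 1], and invariant to rotations of
either basis inside its leading-m subspace. Overlap curves evaluate
mobility correlation and Q_m on a 2%-step fraction grid by default.

## Synthetic fixtures

The generator emulates the statistical signature of fitted force
constants in real ensembles: bonded springs |N(2.9, 1.0)| (matching
the observed mean ± SD of normalized bonded constants), second
neighbors N(−0.2, 0.5) with a configurable negative fraction
(frustration), and sparse long-range contacts (rate 0.1, springs
|N(0.4, 0.4)|). The diagonal starts from the Laplacian convention and
is lifted uniformly so the smallest eigenvalue equals 5% of the mean
diagonal — strictly positive definite, hence a valid Gaussian
precision matrix with no null modes.

Scalar ensembles are exact draws from N(0, K⁺) in the range space of
K. The 3-D embedding places residues on an ideal α-helix (or extended
chain) built from standard internal coordinates (φ = −57°, ψ = −47°;
N-Cα 1.458 Å, Cα-C 1.525 Å, C-N 1.329 Å) and draws each Cartesian
component of the displacement field independently from N(0, K⁺), so
the embedded ensemble's scalar covariance equals K⁺ exactly in
expectation under the 1/3 convention — including the cross terms. (An
embedding that multiplies a scalar draw by an independent random unit
vector per residue would preserve only the diagonal: independent
directions average cross-covariances to zero.)

What the generator does *not* emulate: superposing a 3-D ensemble
removes its six rigid-body degrees of freedom, so the recovered scalar
covariance is the rigid-mode-projected P(C⊗I₃)P reduction rather than
K⁺ itself — the package provides that closed form as the test oracle —
and at large displacement amplitudes the superposition becomes
nonlinear, as it does for real NMR ensembles. Synthetic ensembles also
carry no sequence variety, side chains, NOE-style noise structure, or
strand topology beyond what the ideal backbones provide. Passing tests
therefore demonstrate the estimator and fit machinery, not the
field-level claims about real protein datasets, which require the
original multi-protein NMR sets.

## Problem sizes and defaults

Fits and pipelines in the tests and the acceptance script use N = 30
residues, 500-model ensembles for exactness checks and 10⁴-sample
draws for recovery checks — sizes at which the Newton fit takes
well under a second and results are statistically stable. Key defaults:
cutoff 10 Å; tolerance 0.01; max steps 10⁵; ridge ε 10⁻⁶; pseudoinverse
cut 10⁻⁸ × largest eigenvalue; temperature 300 K for physical units.

## Known limitations

- Isotropic (scalar) model only; no 3N×3N anisotropic generalization,
  per-edge rest lengths, or MD-covariance fitting.
- The maximum-entropy fit requires a (ridge-repaired) positive
  definite covariance; heavily rank-deficient input (m ≪ N) yields a
  fit dominated by the ridge.
- mmCIF input, NMR restraint files and multi-crystal ensembles are out
  of scope; PDB multi-MODEL files only.
- The internal secondary-structure assignment distinguishes only
  helix/strand/other and is validated on ideal geometry, not
  benchmarked against DSSP on real proteins.
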