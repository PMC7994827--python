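# Methods

This note documents the models implemented in `hingeshift`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions that a maintainer would otherwise
have to reverse-engineer from the code.

## Elastic network and linear response

Residues are beads at their Cα positions. In ANM form, every pair within a
distance cutoff is connected by a Hookean spring; the off-diagonal 3×3
Hessian block of a contact (i, j) is −γ·d dᵀ/|d|², with d the equilibrium
displacement vector, and the diagonal blocks enforce zero block-row sums
(translation invariance). The equilibrium covariance is the Moore–Penrose
pseudo-inverse of the Hessian over its nonzero modes.

* **Cutoff, default 13 Å.** The conventional Cα-ANM operating point: large
  enough that globular folds are rigid (exactly six zero modes), small
  enough to retain contact topology. Exposed everywhere as a parameter.
* **Spring constant γ, default 1 (arbitrary units).** DFI and DCI are
  ratios of responses, so a uniform γ cancels exactly; a property test
  asserts invariance under γ-rescaling. Only *relative* spring scalings
  (the mutation proxy below) matter.
* **Zero-mode tolerance.** Eigenvalues below 1e-10·λ_max are treated as
  rigid-body modes. Exactly six must appear; more indicate a disconnected
  or mechanically floppy network and raise an error rather than silently
  producing a meaningless covariance. Connectivity is additionally checked
  on the contact graph at Hessian build time, with an error message
  advising a larger cutoff.

Covariances can equally come from a coordinate ensemble (see "Windowed
covariance") or be supplied as a plain-text 3N×3N matrix; everything
downstream is agnostic to the provenance, which is carried as metadata.

## Perturbation response scanning, DFI, DCI

The response entry A_ij is the root-mean-square displacement magnitude of
residue i under a unit force at j, averaged over force directions. For a
force uniform on the sphere, E[ffᵀ] = I/3, so the exact average is

    A_ij = sqrt(‖B_ij‖_F² / 3),   B_ij = 3×3 block of G.

This closed form is the default (deterministic, and symmetric whenever G
is). A Monte-Carlo mode draws M seeded unit forces per perturbed site and
averages the squared responses; it exists as the stochastic reference for
the closed form (the acceptance suite checks 1% agreement at M = 10⁵) and
for fidelity to the random-kick picture of the scanning procedure. The
square root is taken of the *mean squared* response; the alternative
convention (mean of |ΔR|) differs by a direction-dependent factor and is
deliberately not implemented.

DFI_i is the row sum of A normalized by the grand total, so profiles sum
to one by construction. DCI uses mean response to a functional subset over
mean response to all sites; when the subset is the whole chain the
numerator and denominator are computed from the identical array so the
profile is exactly 1, not merely within rounding. The pairwise form
divides each entry by its row mean (every row of the pairwise DCI matrix
has mean exactly 1).

**Percentile ranks.** %DFI and %DCI are fractional ranks in (0, 1]:
rank = (# values ≤ own value)/N, ties sharing the maximal rank. The
maximal-tie rule makes hinge calls (rank strictly below a threshold)
conservative — a tied block never straddles the threshold. For selection
thresholds on the pairwise DCI matrix, ranking is done per perturbed site
(within each column: for a fixed perturbed residue, responders are ranked
against each other); a global ranking over all matrix entries is available
as an option.

## Windowed covariance and convergence

Ensembles are cut into windows of length W starting at burn-in, burn-in +
lag, … while a full window fits: the window count is
floor((T − burn-in − W)/lag) + 1. Defaults follow the method's standard
operating point for simulation-derived dynamics: window sizes 25/50/75/100
ns for the convergence scan, lag 25 ns, burn-in 100 ns, with 50 ns windows
feeding production DFI/DCI profiles. Times are configured in ns and
converted through the frame spacing; a non-integral frame count is an
error, never a silent round.

Within a window every frame is Kabsch-superposed onto the window's *first*
frame, using backbone heavy atoms when the ensemble carries them and Cα
otherwise. The covariance is then taken about the window *mean* with the
population (1/n) denominator: the fit frame only fixes the rotational
gauge, while fluctuations are defined about equilibrium, matching the
harmonic formalism.

Convergence: per window size, DFI is computed for every window and
averaged (renormalized to sum 1); the trajectory is declared converged iff
all pairwise Pearson correlations between the per-size mean profiles reach
a threshold, default 0.9. The underlying idea — profiles independent of
window size iff all frames sample one harmonic basin — needs a numeric
cut-off to be executable; 0.9 is exposed in the API and CLI. A constant
profile has no defined correlation and is reported as *not converged* with
a diagnostic.

## Hinge classification and mutation sets

Hinges are residues with %DFI strictly below 0.2. On a pairwise alignment
(Needleman–Wunsch, BLOSUM62, gap open 10 / extend 0.5 — or a user-supplied
mapping table, since alignment details should never silently decide a
design), aligned positions fall into common hinge / non-common (A or B) /
non-hinge, and "conserved" means identical amino acids.

Selection rules, all with the coupling threshold ≥ 0.8 on percentile
pairwise DCI ("greater than about 0.8" is hardened to ≥ 0.8 and exposed):

* **Set X** — candidates: non-conserved hinges unique to protein A;
  qualifying partners: hinges unique to protein B; coupling judged in
  *B's* matrix (the target dynamics the design should reach).
* **Set Y** — candidates: non-conserved common hinges; partners:
  non-conserved non-common hinges of either protein; coupling judged in
  *A's* matrix, since these compensating substitutions act in the protein
  being redesigned. The choice of matrix per set is recorded in each set's
  metadata because it is a genuine design decision, not a forced one. A
  manual-include list lets the user force specific common-hinge positions
  into set Y (the analogue of including a known key position that couples
  to fewer partners); forced members are flagged in their evidence and
  rejected with a diagnostic if they are not non-conserved common hinges.
* **Set Z (DARC spots)** — candidates: residues of A with 0.3 < %DFI < 0.5
  (open band, boundaries excluded), minimum Cα–Cα distance to any
  active-site residue strictly greater than 8 Å, coupled ≥ 0.8 to at least
  one *sequentially conserved* non-common hinge. Distance is Cα–Cα
  because the model is Cα-coarse-grained; an all-atom distance would claim
  precision the representation does not have. Only aligned positions are
  eligible, because the substitution target is read from protein B at the
  aligned position.

Every selected member carries evidence: the qualifying partners with their
%DCI scores, and for set Z the distance to the active site. The design
report enforces that X, Y, Z are disjoint by position and fails loudly,
naming the collision, if they are not. By construction set Z members are
never hinges of A (the band (0.3, 0.5) cannot intersect %DFI < 0.2).

## Profile clustering

Percentile-ranked DFI profiles of m proteins are stacked column-wise over
the positions aligned across *all* of them. The truncated SVD X = U Σ Vᵀ
gives protein coordinates V*Σ* on the r leading components; r defaults
to 2 (a biplot). `center=True` (default) subtracts each position's mean
across proteins first — ordinary PCA, which is what biplots of profile
similarity usually show; `center=False` applies the decomposition to the
raw matrix. Both are exposed because the two conventions genuinely differ
and neither is canonical for this use. Signs are fixed so each component's
largest-magnitude position loading is positive, making embeddings
bit-for-bit reproducible. If centering annihilates the matrix (identical
profiles), all proteins are placed at the origin rather than raising.
Hierarchical clustering uses average linkage (an unweighted, scale-robust
default) on Euclidean biplot distances; trees are exported as Newick text.

## Synthetic generator: what it emulates, and what it does not

`synthetic_fixtures` exists so that every stage is testable without
external data:

* **Topologies.** `helix` — ideal α-helix (rise 1.5 Å, 100°/residue,
  radius 2.3 Å; consecutive Cα distances ≈ 3.8 Å); `chain` — beads along
  an axis with ±1 Å seeded transverse jitter; `two-domain` — an
  antiparallel helix hairpin (axes 8 Å apart, joined by a short arcing
  loop). The hairpin, rather than two helices on a straight linker, is
  deliberate: springs crossing a straight linker are nearly parallel, so
  each domain can twist about the linker axis at zero elastic cost and the
  network acquires spurious zero modes. The same physics limits the
  `chain` topology to short fixtures — the bending mode of a long,
  nearly straight elastic rod approaches the rigid-body null space — so
  larger fixtures use `helix` or `two-domain`.
* **Mutations** are emulated by scaling the spring constants of contacts
  touching chosen residues (stiffen: factor 10; soften: factor 0.1, the
  same defaults used by the hinge-shift re-enactment). This is the
  minimal perturbation with an exactly known ground-truth covariance —
  the property recovery tests need — and makes no claim to side-chain
  chemistry, packing or electrostatics. Sequence divergence is emulated
  by substituting letters at perturbed positions (plus optional
  dynamics-neutral substitutions), so conservation flags behave
  realistically.
* **Ensembles** are exact Gaussian draws through the symmetric square
  root of G over its nonzero modes, optionally composed with random
  rigid rotations/translations per frame to exercise superposition.
  Real simulation data differ in every anharmonic respect: multiple
  basins, correlated sampling in time, solvent coupling. Passing the
  recovery tests therefore demonstrates the *estimator* chain
  (superposition → windowing → covariance → DFI) is correct and
  self-consistent, not that an elastic network reproduces the dynamics a
  long atomistic simulation would give for a specific protein.

### Canonical hinge-shift pair

The re-enactment scenario used by tests and the acceptance script is the
30-residue two-domain fixture (seed 5) with contacts of positions 3 and 20
stiffened ×10, hinges 19 and 4 softened ×0.1, and a dynamics-neutral
substitution at position 26. Stiffening targets *mid-flexibility*
positions because that is how rigidification works mechanically: a
residue that is already maximally flexible sits in a soft neighborhood
and a ×10 scaling of its few contacts does not pull it below the hinge
percentile, whereas mid-band residues cross it cleanly. On this pair the
stiffened positions classify as hinges unique to the perturbed protein,
the softened ones as hinges lost, and set X selection agrees with a
brute-force enumeration of its rule.

### Convergence contrast scenario

The non-converged reference is the same 20-residue fixture whose second
domain jumps 10 Å at the trajectory midpoint (a two-basin trajectory with
displaced means). A covariance-only switch with a common mean is *not*
used: window-averaged DFI profiles wash it out at these system sizes,
because the mean profile over short pure windows and the profile of the
mixed covariance are too similar. A mean jump is also the realistic
signature of unconverged sampling — a conformational transition mid-run —
and reliably separates the window sizes (stationary pairwise correlations
≥ 0.96, switching ≤ 0.88 across seeds, against the 0.9 threshold).

## Problem sizes

Fixtures are 6–30 residues; ensemble statistics use 10⁴ frames for
recovery (observed L1 error ≈ 1.4% against the 3% acceptance band) and
300 frames for the convergence scenarios; Monte-Carlo force averages use
10⁵ samples. These sizes give the statistical headroom the assertions
need while keeping the full suite and the acceptance script each well
under a minute of compute on one core.

## Known limitations

* ENM-derived covariances capture global harmonic dynamics only; the
  chemistry-dependent effects of substitutions require ensemble input
  (the covariance/ensemble modes exist precisely so externally computed
  dynamics can be analyzed).
* Percentile granularity is 1/N; on very small proteins the 0.2/0.8
  thresholds quantize coarsely, and selections should be read
  accordingly.
* The Gaussian (isotropic) network variant, mass weighting, mmCIF input
  and binary trajectory formats are out of scope; multi-model PDB is the
  canonical ensemble format.
* B-factor annotated output writes Cα (plus backbone when present) atoms
  only; it is a visualization vehicle, not a full-fidelity structure
  copy.
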