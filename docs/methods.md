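# Methods

`defold` predicts a protein's backbone fold from three sequence-level
inputs — a family alignment, per-residue feature scores, and the query
sequence itself — by converting statistical signals into restraint
potentials and sampling a coarse-grained backbone model under them.  This
note records the models, the parameter choices, and the limits of what the
synthetic tests demonstrate.

## Coupling inference

The family alignment is modelled as independent draws from a pairwise
maximum-entropy (Potts) distribution over q = 21 states (20 amino acids +
gap),

    P(A_1..A_L) = Z^-1 exp( Σ_{i<j} e_ij(A_i, A_j) + Σ_i h_i(A_i) ).

Before fitting, the alignment is trimmed: columns whose gap count strictly
exceeds 50% of the sequences are removed, then sequences with strictly more
than 30% gaps over the remaining columns are deleted (the query row is always
kept).  Both thresholds use strictly-greater semantics, so boundary cases
survive; the order of the two filters is configurable.  Because coupling
estimates degrade badly on redundant alignments, sequences are down-weighted
by the size of their 80%-identity neighborhood (weight = 1/neighborhood
size, m_eff = Σ weights); the threshold is configurable and reweighting can
be switched off.

Fields and couplings are estimated by L2-regularized pseudo-likelihood
maximization (the plmDCA estimator): the product over sites of the exact
conditionals P(A_i | A_-i) is maximized with L-BFGS from a zero
initialization, making the fit deterministic.  The negative
pseudo-log-likelihood is normalized by m_eff so the default regularization
strengths — λ_h = 0.01 on fields, λ_e = 0.01·(L−1) on couplings — act
consistently across alignment depths.  Unregularized pseudo-likelihood
diverges on finite alignments (complete-separation directions), which is why
a nonzero λ_e is not optional.  The fitted model is reported in the zero-sum
gauge (all state-means of h_i and of every e_ij row/column are zero), the
standard representative of the gauge orbit.

Pairs are ranked by **direct information**: for each pair the
coupling-only two-site distribution P^dir_ij(a,b) ∝ exp(e_ij(a,b) + h̃_i(a)
+ h̃_j(b)) is built, with auxiliary fields h̃ fixed by iterative
proportional fitting so that P^dir's marginals reproduce the empirical
(pseudocount-mixed, default λ = 0.1) single-site frequencies; DI_ij is the
Kullback–Leibler divergence of P^dir from the factorized background.  DI is
gauge-invariant and zero exactly when the pair carries no direct coupling.
An APC-corrected Frobenius norm of the zero-sum couplings is available as
the usual alternative ranking; DI is the default.  The folding stage
consumes the top 2L pairs at a minimum sequence separation of 5 (the
separation is not dictated by the protocol; without it, trivially coupled
near-diagonal pairs crowd out tertiary contacts).

## Torsion prediction

Each residue carries 24 features normalized to [0, 1]: 20 position-specific
scores, 3 secondary-structure probabilities, and 1 solvent-accessibility
value.  These are produced by external predictors and enter as a plain
numeric table.  A context window of 17 residues on each side yields a
35 × 24 input map per residue; off-chain rows are zero-padded, matching the
normalization floor.

The predictor is a small convolutional network: conv(16 filters, width 5) →
max-pool(2) → conv(32, width 3) → max-pool(2) → conv(64, width 3) → two
dense layers (64 hidden units → 4 outputs), ReLU activations.  The channel
counts and pooling of the later layers are this package's choice and are
exposed in the architecture config.  The four outputs are (sin φ, cos φ,
sin ψ, cos ψ): encoding angles on the circle removes the ±180° wrap, and
predictions decode through the quadrant-aware arctangent after renormalizing
each (sin, cos) pair to the unit circle.  Training minimizes the MSE of the
sin/cos 4-vector with Adam; angles are decoded only for evaluation.  Weights
initialize from a zero-centered Gaussian with σ = 5/N (N = layer fan-in),
implemented literally, with √(5/N) available as a config option; both are
seeded, and training is deterministic given the seed.  The network is small
enough that plain numpy forward/backward passes train it in seconds, so no
deep-learning framework is required.

Prediction error is measured as mean absolute error in degrees over
non-terminal residues.  The default convention is the minimal circular
difference (170° vs −170° differ by 20°); the literal absolute difference is
available with `periodic=False`.

## Restraints

Predicted torsions become flat-bottom windows [pred − 20°, pred + 20°],
handled on the circle, with a harmonic wall V = ½ k_tor·(excess°)² outside
(k_tor = 0.05 energy/deg² by default).  The harmonic convention means a
window of zero width is an ordinary harmonic well with Boltzmann variance
T/k_tor, which is how the sampler's statistics are validated.

Ranked contacts become attractive sigmoid wells on CB–CB distances,
V(r) = −depth / (1 + exp((r − 7.5 Å)/width)), with depth 2.0 and width
0.5 Å by default: −depth/2 exactly at the 7.5 Å contact cutoff, saturating
below, vanishing above.

The general pair interaction is a sum of two sigmoids,
V(r) = e_in/(1+exp((r−r_in)/w_in)) + e_out/(1+exp((r−r_out)/w_out)).  Two
named profiles carry the published constants: side-chain pairs (e_in = 3,
w_in = 0.2, r_out = 6.5, w_out = 0.2, e_out from a statistical contact
energy table) and backbone hydrogen bonds (e_in = 6, r_in = 1.4, w_in = 0.1,
e_out = −4, r_out = 2.5, w_out = 0.125).  The side-chain inner radius r_in
defaults to a uniform 6.0 Å; a per-pair table can be supplied.  The
attractive depth table is built from the published Miyazawa per-residue
contact-energy scale (shipped with Biopython) under the additive
approximation e(a,b) = −s·(m_a + m_b)/2, which captures the dominant
hydrophobicity mode of statistical pair potentials; any user 20 × 20 table
(e.g. the full Miyazawa–Jernigan pair table) can be passed instead.

## Coarse-grained sampling

Each residue carries dynamic N, CA, C atoms; O, H and CB are derived from
ideal trans-peptide geometry, so the state is fully parameterized by the
(φ, ψ) torsions and bond lengths/angles are ideal by construction.  The
energy is

    V = V_torsion + Σ V_pair + Σ_i w_env(aa_i)·N_i + V_contact,

with V_pair the two-sigmoid potential over CB–CB (side-chain profile) and
H···O (hydrogen-bond profile) distances, and N_i a smooth burial count: over
partners j with |i−j| > 2, a distance switch S(d_ij − 8 Å, 1 Å) times an
angular switch S(−cos θ + 0.1, 1) selecting the hemisphere above CB_i along
the CA→CB axis (S(x, w) = 1/(1+exp(x/w))).  The burial term is linear in
N_i with per-residue weights ±0.1 signed by Kyte–Doolittle hydropathy
(burial favorable for hydrophobics); the linear form and the collapse of the
side-chain rotamer average onto the single ideal CB direction are this
package's simplifications, both switchable.

**The central simplification**: conformation space is sampled by Metropolis
Monte Carlo in torsion space — single-torsion Gaussian proposals (σ = 5°),
acceptance min(1, exp(−ΔV/T)) — rather than by a molecular-dynamics
integrator.  This preserves the Boltzmann ensemble exp(−V/T) that the
restraints define, at the cost of kinetic realism; "time" is measured in MC
steps (default 50,000 per trajectory at desk scale) and the temperature is
a dimensionless unit (default 1.0).  Runs are bit-reproducible for a fixed
seed.  The production protocol launches many independent trajectories
(default 500) from the same extended chain (φ = ψ = 180°).

Excluded volume is handled softly by the e_in sigmoid core of the pair
potential; there is no hard-sphere clash check.

## Model selection

The last 50 captured frames of every trajectory are pooled (500 × 50 =
25,000 at production scale), the pool is clustered on pairwise CA-RMSD
(Kabsch superposition) with the Daura greedy neighbor-count algorithm at a
3.5 Å cutoff, and the centroids of the top five clusters — ordered by size,
ties broken by lower centroid energy — are the predicted models, the
largest cluster's centroid being the blind prediction.  Cluster tightness is
reported as mean intra-cluster pairwise RMSD.  The pairwise matrix is O(N²);
a stride option subsamples large pools.  When a reference structure is
given, models are scored by CA-RMSD and by TM-score (d0 = 1.24·(L−15)^⅓ −
1.8, floored at 0.5 for chains of ≤15 residues, maximized over iteratively
refined superpositions seeded from chain fragments).

## Synthetic data and what the tests show

The synthetic module generates every input class: alignments sampled from
Potts models with planted couplings (exact enumeration below ~2 million
states — the brute-force oracle — and seeded Gibbs sampling with burn-in
and thinning above), idealized hairpin/helix-bundle folds whose native
contacts are recomputed from their own coordinates, feature tables that
either are noise or deterministically encode their target torsions, and
mock trajectories as torsion-noise perturbations of a base fold.

Validated properties include: recovery of six planted coupled pairs (q = 4,
L = 12, 2,000 sequences) as the top six DI pairs; agreement of the
pseudo-likelihood fit with an independent derivative-free minimization on an
exhaustively checkable 2-site system; a single harmonic torsion sampling its
Boltzmann variance T/k within 5% over 10⁶ steps; and refolding of a
16-residue hairpin to < 2 Å CA-RMSD from the extended chain in at least half
of 20 seeded 50,000-step runs under native torsion windows and contact
wells.  The refolding control runs with the restraint terms only: the
generic pair/burial statistics describe real proteins, which the idealized
toy does not obey (its strands are not H-bond registered), so leaving them
on tests the wrong thing — the control isolates restraint-guided folding.
"Reaches" is evaluated as the minimum RMSD over captured frames; at T = 1
the equilibrium ensemble inside ±20° windows fluctuates by 1–3 Å around the
target, so the final frame alone is a noisier statistic of the same basin.

These synthetic conditions omit much of real data: alignments have no gaps,
no phylogenetic correlation and no alignment error; feature tables are not
real PSSM/SS/SA predictions; toy folds have ideal geometry and no side-chain
packing constraints.  Passing tests therefore demonstrate correctness of the
machinery (estimators, samplers, metrics) under known ground truth, not
prediction accuracy on natural proteins, which additionally depends on
alignment depth, feature quality, and simulation scale.

## Numerical choices

- Potts fit: zero initialization, L-BFGS, ftol 1e-9; convergence failure
  raises with the final gradient norm.  DI fixed point: tolerance 1e-6,
  500 iterations max.
- Contact ranking ties break by ascending (i, j); clustering center ties by
  lowest index — all stages are deterministic given their inputs.
- Sigmoid arguments are clamped at ±500 before exponentiation.
- Degenerate inputs: empty alignments, all-gap columns, zero-length
  windows, (0,0) sin/cos pairs, non-finite starting torsions and mismatched
  restraint lengths all raise typed errors rather than propagating NaNs.
- Backbone kernels (chain building, energy terms) are numba-compiled; the
  first call in a session pays a one-time compilation cost.

## Known limitations

- The sampler explores torsion space only; bond geometry never relaxes, and
  omega is fixed trans (no cis-proline).
- The burial term's rotamer sum is collapsed to the CB direction with
  probability 1.
- The hydrophobicity-additive pair-energy table ignores the specific
  (non-additive) structure of statistical contact potentials; supply the
  full published pair table for production use.
- TM-score uses a fragment-seeded iterative refinement that matches the
  standard optimization on well-superposable models but is not guaranteed
  to find the global maximum on pathological pairs.
- Production-scale accuracy on natural proteins (deep alignments, real
  feature predictors, 500 long trajectories) is outside the test envelope.
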