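# Methods

## Sequence descriptors

Features are computed over the unmasked part of a sequence; the standard
expression overhangs (GSGSC prefix, CTLGPR suffix, which also contain the
labeling cysteines) are masked when present.  Charge assignment is D,E = −1
and K,R = +1; histidine and the termini are treated as neutral, the common
convention in the charge-patterning literature.

* Normalized hydrophobicity: H = (1/N) Σ (KD_i + 4.5)/9 with the
  Kyte–Doolittle index KD ∈ [−4.5, 4.5], so H ∈ [0, 1].
* FCR = f₊ + f₋, NCPR = f₊ − f₋.
* κ (Das–Pappu): blob-averaged squared deviation of the local charge
  asymmetry σ = (f₊−f₋)²/(f₊+f₋) from its global value, averaged over blob
  sizes 5 and 6.  Blob windows slide one residue at a time and are fully
  contained in the sequence (no partial end blobs).  The normalization is
  the maximum of the same quantity over charge-preserving rearrangements;
  we scan two analytic candidate families exhaustively — (a) contiguous
  all-positive and all-negative blocks placed independently among the
  neutrals, and (b) the +/− double block split at any point by the full
  neutral block — and additionally include the observed arrangement itself,
  which guarantees κ ≤ 1 by construction.  Family (a) attains the optimum
  for long polyampholytes; (b) matters only for nearly charge-saturated
  chains.  κ is reported as NaN below two charged residues.
* SCD = (1/N) Σ_{i<j} q_i q_j (j−i)^{1/2} (signed; more negative for
  charge-segregated polyampholytes).

## Photon-level smFRET analysis

Photons carry 16 ps clock ticks, a detection channel and an excitation
period (pulsed interleaved excitation).  Bursts are maximal runs of
interphoton gaps < 150 µs retained at ≥ 50 photons.  The dual-channel
criterion re-applies a run criterion to each excitation period inside a
burst (defaults: gap < 300 µs, ≥ 10 photons, qualifying run spanning at
least half of the burst); this removes single-labeled molecules and
mid-burst bleaching/blinking.  Both per-period thresholds are configuration
parameters since they are instrument-dependent.

Corrections are applied in the standard order background → spectral
crosstalk and direct acceptor excitation → detection/quantum-yield ratio γ:

    DD' = DD − b_DD·T,  DA' = DA − b_DA·T − ct·DD' − de·AA',  n_D = γ·DD'

then S = n_tot,Dex/(n_tot,Dex + n_tot,Aex) and E = n_A/(n_A + n_D).  Bursts
with corrected denominators ≤ 0 are flagged invalid rather than dropped;
the stoichiometry gate 0.2 < S < 0.8 uses strict inequalities.  Efficiency
histograms use fixed 0.02-wide bins on [−0.1, 1.1]; Gaussian mixtures are
least-squares fit with peaks seeded at the highest well-separated histogram
modes.

## SAW-ν polymer model

The end-to-end distance density in reduced units x = r/R is

    P(x) = A x^{2+g} exp(−α x^δ),  g = (γ−1)/ν,  δ = 1/(1−ν),  γ = 1.1615.

A and α follow in closed form from ∫P = 1 and ⟨x²⟩ = 1 via gamma-function
moments, making R the root-mean-squared end-to-end distance.  ν is limited
to [1/3, 0.95]; δ diverges as ν → 1.

The scaling law R = b·N_eff^ν couples size and exponent.  Defaults:
b = 0.55 nm; N_eff = 59 backbone segments between the two labeling
cysteines of the standard construct (positions 5 and 64 of the
overhang-flanked 68-mer) plus 9 equivalent residues for the two dye
linkers, giving N_eff = 68.  Both are configuration parameters and recorded
in outputs.  The linker offset convention is not uniquely fixed by
experiment; sensitivity is modest (changing the offset from 9 to 18 shifts
the inverted ν by about 0.01 and R by well under 1%).

Inversion solves mean_efficiency(P_ν(R = b·N_eff^ν), R0) = ⟨E⟩ by Brent
bracketing on ν; the forward map is strictly decreasing in ν so the root is
unique.  The residual in E is verified against a 10⁻⁶ tolerance.
Efficiencies outside the achievable range raise an error that reports the
range.

## Coarse-grained (HPS) model

One bead per residue; harmonic bonds (r0 = 0.38 nm,
k = 481.4 kJ nm⁻² mol⁻¹).  Nonbonded interactions are the Ashbaugh–Hatch
modification of Lennard-Jones — U = Φ_LJ + (1−λ_ij)ε inside the WCA
minimum, λ_ij·Φ_LJ outside, λ_ij the arithmetic mean of the per-type
stickiness — plus Debye–Hückel electrostatics with the Debye length from
the ionic strength (165 mM default, ε_r = 80).  Numerical settings:
ε = 0.8368 kJ/mol (0.2 kcal/mol), short-range cutoff 2.0 nm, electrostatic
cutoff 3.5 nm, bonded 1–2 pairs excluded from nonbonded terms.  Per-residue
λ defaults come from the Kapcha–Rossky-derived scale of the HPS lineage and
σ from average residue volumes; both are configurable, and the λ vector is
the object of force-balance optimization.

Dyes are small bead subgraphs (negative, neutral, positive and linker bead
types; 100 amu per bead) attached at the labeling cysteines.  Net charges:
Alexa 488 and Alexa 594 −2, Cy3B 0, CF660R −1.  Harmonic angle terms
(k = 48.14 kJ rad⁻² mol⁻¹, θ0 = π/2 at branch points, π elsewhere) act
only on the colored dye beads, never on linker beads.  The shipped dye
geometries are synthetic approximations that preserve bead counts,
connectivity, branch structure and net charge; the bead graph, charges and
the designated dye-center bead are user-editable through the dye-spec
mapping.

Dynamics: BAOAB-discretized Langevin at 300 K, 10 fs time step, friction
1 ps⁻¹.  Seeds are mandatory and logged; identical seeds give bit-identical
trajectories.  The first 1/6 of frames is marked as equilibration by
default (mirroring a 100 ns discard of a 600 ns production run).  Initial
configurations are clash-avoiding random walks along the bond graph.
Validation oracles: single-bead equipartition, the exact harmonic-dimer
bond-length distribution (r²-weighted Boltzmann), continuity of the pair
potential at the WCA crossover, an independent O(N²) energy double-loop,
and the self-avoiding-walk internal-scaling exponent of the athermal chain.

## Force-balance optimization

Loss = Σ_c (⟨E⟩_c − E_c^exp)² + α‖λ−λ₀‖², α = 10⁻⁴ (L2 starting-point
regularization).  Gradients use linear response on stored equilibrium
frames, ∂⟨E⟩/∂λ_k = −β(⟨E·u_k⟩ − ⟨E⟩⟨u_k⟩) with u_k the per-frame sum of
∂U_pair/∂λ_k over pairs involving type k (−ε inside the WCA minimum,
Φ_LJ(r) outside, weight 1/2 per participating bead).  The estimator is
finite-difference validated against exponential reweighting of the same
frames.  Updates are plain gradient descent at learning rate η = 5.0; after
two consecutive loss increases η is halved and the step retried from the
best λ; optimization stops on a loss plateau (relative span < 10⁻³ over a
3-iteration window), a floor on η, or the iteration cap.  Freezing masks
zero the update of selected types (e.g. optimize dye beads only).  Initial
dye/linker λ can be set by a coarse grid search over (dye, linker) values
minimizing the initial loss.

The learning rate must be matched to the sampling noise of the
per-iteration ⟨E⟩ estimates: the stationary λ fluctuation of stochastic
gradient descent scales as η·σ_⟨E⟩·|∂E/∂λ|, so η = 5.0 presumes long
production runs (hundreds of ns across many constructs).  The
self-consistency recovery test therefore runs one 20-residue construct at
50 ns per iteration with η = 3 and friction 0.3 ps⁻¹ — lower friction
roughly halves σ_⟨E⟩ at fixed wall time by speeding conformational
diffusion without changing the sampled ensemble.  A Jacobian/noise scan
over chain length and friction (recorded here as the package's test
design) showed ∂⟨E⟩/∂λ ≈ 0.26 and σ_⟨E⟩ ≈ 0.013 per 50 ns estimate in
this configuration, giving a λ resolution of about ±0.05 at test scale.

## Maximum-entropy reweighting

Per construct, posterior weights w_i ∝ w⁰_i e^{−θE_i} with θ solved so the
posterior mean equals the target (Brent after geometric bracket expansion;
the exponential-family mean is strictly monotone in θ).  The experimental
error enters as an inequality relaxation: θ = 0 if the prior already
matches within tolerance, otherwise the constraint is solved to the nearer
band edge.  Frames are treated jointly (one concatenated ensemble per
construct).  Weights below 10⁻¹² are floored to zero and renormalized.
D_KL = Σ w ln(w/w⁰) in nats with 0·ln 0 = 0; absolute-continuity violations
raise.  Ensembles with D_KL > 0.1 are flagged as requiring substantial
reweighting.

## Dye attachment (rotamer mapping)

Rotamers are rigid coordinate sets in the attachment frame (origin at the
γ-sulfur, +z along Cβ→Sγ, ideal bond geometry by construction) with a
declared dye-center atom.  Per frame and site, 50 rotamers are drawn with
replacement; a trial fails if any dye atom is within 5 Å of a protein atom
(attachment residue excluded).  Frames where either site collects fewer
than 20 successes are rejected.  Distinct successful rotamers are combined
across the two sites; mutually clashing dye pairs are removed with the
same 5 Å radius — the pair stage reuses the single printed radius.  The
per-frame efficiency is the mean Förster efficiency over surviving
center–center distances (R0 = 6 nm default).  The shipped library is
synthetic (jittered arcs with controlled reach), adequate for steric logic
and convergence tests; a chemically derived library can be supplied in the
same structure.

## Ensemble analytics

Distances follow the RMS-then-average convention: the inner average is the
weighted mean squared distance over frames, the outer average runs over
residue pairs at equal separation.  Homopolymer fits ⟨R⟩(s) = A0·s^ν use
nonlinear least squares over a configurable window (default s ∈ [5, N−5]).
Scaled distance maps divide each pairwise RMS distance by the fitted
homopolymer prediction and mask |i−j| < 10.  Contact maps are weighted
frame fractions below a 10 Å threshold (bead mode, or closest-heavy with
an atom→residue mapping); contact networks take node sizes from mean
contact probabilities excluding |i−j| ≤ 2 and draw edges at ≥ 35% of the
per-chain maximum probability, with residue-class color metadata.  Shape
metrics come from gyration-tensor eigenvalues (asphericity
δ = 1 − 3(λ1λ2+λ2λ3+λ3λ1)/(λ1+λ2+λ3)²).  SAXS uses the Debye formula with
unit form factors (only I(q)/I(0) is compared; per-bead factors can be
supplied).  The regression suite fits ordinary least squares over all 1–3
feature combinations, reports ρ², Lin's concordance
ρ_c = 2cov/(var x + var y + (Δmean)²), and leave-one-out ρ² distributions.

## Synthetic data

Generators are deterministic under a mandatory seed and return truth
sidecars.  Sequences: composition-constrained 57-mers (plus overhangs)
with FCR/NCPR fixed by counts and κ annealed into a requested band by
accept/reject charge swaps, verified through the descriptor module.
Ensembles: Gaussian chains (i.i.d. bond vectors, variance b²/3 per axis,
b = 0.38 nm to match the simulator bond length) with exact
⟨R²⟩ = (N−1)b², and rigid rods.  Photon streams: sequential bursts with a
guaranteed minimum separation (so the planted burst count is exactly
recoverable), Poisson photon counts, binomial acceptor selection at E_true,
optional donor→acceptor leakage and uniform background.  The generative
leakage convention maps to the analysis corrections as α = ct/(1−ct),
γ = 1/(1−ct).

What the generators do not emulate: real photophysics (lifetimes,
quenching, dye blinking statistics), heteropolymer ensembles beyond the
coarse-grained model, and atomistic side-chain packing.  Passing tests
therefore establish the correctness of the algorithms and their
self-consistency, not force-field accuracy on real proteins.

## Problem sizes used in the test suite

Simulation-based checks run at reduced scale chosen for statistical
sufficiency: the athermal-chain scaling test pools four independent 30 ns
trajectories of a 60-mer (the internal-scaling exponent estimator has a
seed-to-seed spread of ±0.03–0.05 on single 25 ns runs, which pooling
brings below ±0.02); force-balance recovery uses two 20-residue constructs
with 30 ns target generation and 15 ns per iteration.  Longer runs
(hundreds of ns per construct) are appropriate for production use and are
what the defaults of `run_langevin` metadata document.

## Known limitations

* The dye-bead geometries are structural placeholders; only bead count,
  connectivity, charge and branch topology are meaningful.
* κ normalization is exact over the scanned arrangement families (plus the
  identity), not over all permutations; for realistic polyampholytes the
  family optimum is the global one.
* The smFRET model omits lifetime information, so γ must be supplied, not
  inferred.
* Internal-scaling exponents on short chains carry finite-size bias (a
  40-mer athermal chain fits ν ≈ 0.62 where a 60-mer gives ≈ 0.59).
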