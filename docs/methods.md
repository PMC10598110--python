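# Methods

This note records the model conventions, algorithms, parameter choices and
known limitations of `phenospace`.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## GMA representation and the clock fixture

A model is an ordered list of equations whose rates are sums of power-law
terms `c·∏ x_v^e_v`; exponent maps may reference dependent variables,
algebraic auxiliaries and parameter symbols uniformly, so every term's
logarithm is affine in log-variables and log-parameters.  Term order
within an equation is part of the model definition: the position of the
dominant positive/negative term is the digit pair of the phenotype
signature, and phenotype numbers are the 1-based index of the signature in
the lexicographic enumeration of all candidate signatures.

The clock fixture (`data/clock.yaml`, equal to `build_clock_model(2, 2)`)
implements the two-transcription-factor negative-feedback loop with
hyperbolic regulation recast through denominator auxiliaries
`DP = 1 + (N/K_N)^n` and `DN = 1 + (P/K_P)^p`:

* mP synthesis: maximal term `α_mPmax·DP⁻¹` first, then the leak term
  `α_mPmin·(N/K_N)^n·DP⁻¹`; degradation `β_mP·mP`;
* mN synthesis: basal term `α_mNmin·DN⁻¹` first, then the activated term
  `α_mNmax·(P/K_P)^p·DN⁻¹`;
* translation/turnover of P and N are single-term;
* auxiliary equations list the constant term first, then the binding term.

This canonical ordering is pinned down by three independent checks
(enforced in the tests): the signature `11 11 21 11 21 11` reduces exactly
to the oscillator S-system `dmP/dt = α_mPmax(N/K_N)⁻ⁿ − β_mP·mP`, …;
exactly nine signatures are feasible with the published numbering
{1,3,5,6,7,8,11,15,16}; and the #5/#7 boundary reduces to the design
principle `K_N·K_P² = 10⁵ (≈ 316²)`.

The scaled parameter table (K_N = 0.316, K_P = 1.78, α_mPmax = 10⁴,
α_mNmax = 10, α_P = 0.01, remaining rate constants 1) is dimensionless;
all scale factors cancel in log-space differences, so none of the
downstream geometry depends on the unit system.

## Design space construction

For each candidate signature the algebraic auxiliaries are replaced by
their dominant positive term (exact power-law closure) and the resulting
S-system steady state is solved **symbolically as an affine function of
the free log-parameters** (one 4×4 linear solve with multiple right-hand
sides).  Substituting that steady state into every dominance condition
(log dominant − log sibling ≥ 0) yields linear inequalities in
(log₁₀K_P, log₁₀K_N).  Feasible regions are built by half-plane
intersection with the Π-box (shapely); genuinely empty regions are
distinguished from measure-zero ones by an LP feasibility check, and
zero-area regions would be retained flagged (none occur for the clock).
All logarithms are base 10 — distances are in decades.

Conventions:

* the Π-box (default Π = 6) is centered on the log₁₀ of the published
  K_P, K_N table values, which coincide with the oscillatory phenotype's
  centroid;
* the centroid is the midpoint of the per-parameter tolerances (bounding
  box), matching the published approximation; the exact polygon
  barycenter is available as an alternative mode (`centroid_mode`);
* areas use the exact polygon (shoelace via shapely);
* points on boundaries classify to the lowest phenotype number
  (measure-zero tie break);
* eigenvalues are classified with a 1e-9 tolerance on real/imaginary
  parts.  At n = p = 2 the oscillatory phenotype sits exactly at its
  instability threshold — the characteristic polynomial with equal decay
  rates is `(λ/β + 1)⁴ = −n·p`, marginal at loop cooperativity n·p = 4 —
  so its leading pair has numerically zero real part; it is reported as
  "complex pair present, maximal real part ≈ 0" and is the unique
  phenotype whose spectrum reaches the axis.

## Mutation kernel

Per the transition-probability model, a recipient is *reachable* from a
donor via parameter q iff some axis-parallel q-line through the donor
polygon intersects the recipient inside the Π-box (projections onto the
other parameter overlap with positive length).  The kernel entry sums one
exponential factor per reachable parameter path, with the centroid
separation `s` along the mutated parameter and branch scales `λδ`
(entropy-increasing; increasing either binding constant) and `λ/δ`
(entropy-decreasing).  A path of zero separation contributes exp(0) = 1.

Two deliberate conventions:

* **Self term.** A mutation can fail to leave the donor region
  (robustness).  The self entry contributes one unit per mutable
  parameter and is included in the row normalization
  `k_ij = K_ij V_j / Σ_j K_ij V_j` (the diagonal is excluded from the
  dynamics, which sum over j ≠ i).  This choice makes the strictly
  neutral, no-size-scale equilibrium equal the normalized phenotype
  volumes `V_i/ΣV_j` exactly, as the analytic idealization requires.
* **Pure-volume limit.** At `λ = ∞, δ = 1` the kernel degenerates to the
  volume factor over the *whole* repertoire (`k_ij = V_j/ΣV`), the
  idealization in which a mutation can land anywhere.

## Population dynamics

Time is measured in generations of the reference phenotype (τ = γ_k·t);
growth rates are relative (μ_k = 1 non-selecting, μ_k* selecting).  The
replicator–mutator equations conserve ΣR ≡ 1 identically.

Two structural facts make the numerics exact rather than iterative:

* **Equilibrium = Perron eigenvector.**  With constant growth rates the
  stationary distribution is the dominant eigenvector of
  `A = m·kᵀ·diag(γ) + diag(γ(1 − m·c))`, `c_i = Σ_{j≠i} k_ij`, whose
  column sums equal γ — the Perron value is the equilibrium mean fitness.
  The eigenvector is polished by shifted power iteration and Newton
  steps; residuals reach ~1e-17 even when frequencies span 12 decades.
  The strictly neutral case is solved as a null space and is independent
  of m (m only rescales time).
* **Trajectories are projectively linear.**  `R(τ)` is the normalized
  matrix exponential `expm(Aτ)R₀`; one eigendecomposition gives the whole
  trajectory on any log-spaced grid with no stiffness.  The spectrum is
  shifted by its largest real part so nothing overflows over 1e10
  generations.  Rank-change events are bracketed on a 400-point-per-decade
  log grid and refined by bisection on the exact propagator to 3
  significant figures.

Absolute counts during exponential growth use the same propagator on
`dN/dτ = A·N` from a single founder cell (default: the oscillatory
phenotype), stopping when the total reaches the target (a scalar
root-find in log-total; mutation terms conserve the total, so growth to
10¹³ cells takes ln 10¹³ ≈ 29.9 reference generations).

The Eq.-style rate decomposition (mutation, mutation×selection,
selection) is returned for the selected phenotype and sums to its net
rate exactly; in the weak-selection regimes examined the cross term is
orders of magnitude below the other two.

## Fitness characteristics and aggregate classes

Protein burden is the total steady-state protein N + P at each phenotype
centroid (oscillatory phenotype: 3.16 + 1.0 = 4.16).  Three fitness
modes exist: `neutral`; `burden_printed` — the nine published relative
growth rates, which are *inputs* of the framework
(`data/mu_printed.yaml`) and anticorrelate perfectly in rank with the
computed burden; and `burden_model` — `μ_i = 1 − c(B_i − B_k)/B_k` with c
scaled so the largest cost is ≤ 1e-5 (the published construction is
under-determined, so the printed list is the default).

Aggregate classes map the repertoire onto what an expression assay can
distinguish: constitutive {6, 8}, super-repressed {3, 11}, oscillatory
{7}; fractions renormalize over the classified five (the published
triples sum to 100% over these).

## Time-zero mutant classes and the (λ, δ) calibration

For single mutations of one parameter from a donor phenotype, the
escape probabilities use the donor region's **full tolerance width** `w`
along that parameter (on the axis line through its centroid) as the
barrier:

    P(convert, entropy-increasing side) = exp(−w/(λδ))
    P(convert, entropy-decreasing side) = exp(−w·δ/λ)
    P(tolerant) = 1 − the two conversions

Landing classes are those of the neighboring regions beyond each
boundary (for the clock's oscillatory donor along K_N: constitutive
above, super-repressed below; a boundary on the Π-box edge cannot be
escaped).  This survival form was chosen over a truncated two-sided
density from the centroid because it is the unique simple construction
consistent with *both* published calibration facts — the forward
prediction ≈ (67, 31, 2)% at (λ, δ) = (0.6, 1.85) and the inverse fit of
(0.67, 0.31, 0.02) returning ≈ (0.6, 1.85).  With w = 1.25 decades the
package computes (65.5, 32.4, 2.1)% forward and fits (0.584, 1.828),
which round to the published grid values.  The fit is closed-form
invertible (`λδ = w/−ln p_up`, `λ/δ = w/−ln p_down`) and polished by 2-D
root finding; symmetric data give δ = 1 exactly, and round-trips recover
(λ, δ) to 1e-6.

Back-calculation of selection strength bisects μ_k* against the
equilibrium oscillatory class fraction, which is monotone in μ_k*
(asserted); the 60% target requires a selection coefficient ≈ 4.8×
larger under the burden spectrum than under neutral fitness.

## Reconstruction fidelity and known limitations

The geometry, steady states, eigenstructure, reachability sets,
calibration and stability threshold reproduce the published case-study
values closely.  The population-level equilibrium shapes are
qualitatively right (entropy gradient toward high-entropy phenotypes;
burden equilibrium concentrated on the super-repressed class; rank
changes after imposing selection complete before 3.5e5 generations;
removal relaxes ~3700× more slowly) but differ quantitatively from some
published figures: the neutral-with-bias gradient computes to ~5.2
decades (published ~4), its constitutive class fraction to ~85%
(published 93%), and the rarest chemostat phenotypes to ~1e3 cells
(published ~10).  These quantities are sensitive to the exact per-path
transition table, which the main-text kernel description does not fully
determine; an extensive scan of alternative conventions (pair-averaged
kernels, L1 distances, centroid-line gating, scale-factor variants)
found none that matches all published population-level numbers
simultaneously, so the package implements the literal kernel definition
above and reports what it yields.

Other limitations: volumes are computed for the 2-D slice the analysis
uses (the module boundary admits an n-dimensional backend); only
single-parameter mutations are modeled; dynamics are deterministic
expectations for asexual haploids in exponential steady state — no
drift, so low-frequency phenotype counts are expectations, not
realizations; and recasting is supported for sums of power laws plus
hyperbolic/Hill denominators (which covers the clock), not arbitrary
rational kinetics.
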