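# Methods

## Model class

A model is a finite set of binding sites, each in exactly one configuration
(always including `empty`), with three kinds of structure:

- **Ligand species** map (site, configuration) assignments to bound-molecule
  counts; a microstate's stoichiometry n_s is the number of satisfied
  assignments of species s.
- **Exclusion rules** are pairwise: two assignments on distinct sites that
  may not co-occur.  "RNAP at this promoter blocks that operator site" is
  expressed as one rule per non-empty configuration of the blocked site.
- **Energy terms** are strictly additive in kcal/mol: a term contributes its
  ΔG iff all assignments in its condition hold, and matches at most once per
  microstate.  Singleton conditions are intrinsic binding energies,
  two-assignment conditions pairwise cooperativities, larger conditions
  multi-site effects such as DNA looping.

Microstates are enumerated lexicographically (sites in declaration order,
configurations in declared order, 0-based indices), so enumeration is a pure
function of the model description.  A configurable cap (default 2·10⁵ raw
combinations) guards combinatorial blow-up.

## Thermodynamics

Equilibrium occupancies are grand-canonical Boltzmann weights

K_i = (1/Z) exp(−ΔG_i/RT) · Π_s [s]^{n_{i,s}},

with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and T defaulting to 310 K.
Concentrations are those of the binding species themselves (dimers for
dimeric transcription factors); monomer–dimer equilibria are not modeled.
Weights are accumulated in log space with max-subtraction; a zero
concentration sends the affected states to weight zero exactly, and a model
in which *every* state has zero weight is an error.  Normalization is
checked to 10⁻¹².  Entropies and mutual information are reported in bits
(log base 2), with 0·log 0 ≡ 0 and tiny negative MI from rounding clamped
to zero.

## Kinetics

Transitions connect microstates that differ at exactly one site, one of the
two configurations being `empty`: a single binding or unbinding event.
Ligand substitution at a site is two transitions.  All binding transitions
share one rate D (diffusion-limited binding); unbinding rates follow from
detailed balance, q_ij = D·K_j/K_i.  Consequences used throughout:

- the stationary law of the chain *is* the thermodynamic distribution
  (K Q = 0 structurally, checked to 10⁻¹⁰ scaled by D);
- rescaling D rescales time only — occupancies, MI, and CA are invariant;
- D defaults to 1 inverse time unit, making all reported times
  "per mean binding attempt".

The generator is stored dense up to 5000 states (the lambda model has
1200).  The rate matrix is always built from the same equilibrium object
used elsewhere, so thermodynamic/kinetic consistency is structural rather
than re-derived.

## Conditional activity, empirically

For site a with transition times T(a,t) in a window of duration τ,
W(a,T) is the time from T to a's next transition strictly after T.

- τ_p[a] = (1/2τ) Σ W(a,T(a,t))², summing over events with a defined next
  event.  The nominal sum would include the record's final event, whose
  forward waiting time is undefined; we end the sum one event earlier,
  which is the convention under which τ_p converges to the stationary mean
  residual life E[W²]/2E[W].
- τ_x[a←b] = (1/τ) Σ_{t=1}^{N(b)−1} W(a,T(b,t+1))·W(b,T(b,t)).  Terms whose
  next a-event lies beyond the window are dropped and counted; a warning
  fires if more than 1% of terms are dropped.  One common window duration τ
  normalizes both sums (identical to per-site record lengths in the
  long-record limit, where the empirical and analytic normalizations meet).
- CA[a←b] = −log₁₀(τ_x/τ_p); an estimate is flagged undefined (NA in
  exports, reported to 4 decimals otherwise) when either series has fewer
  than 2 events, and flagged infinite when τ_x = 0 with τ_p > 0.

Standard errors use a joint non-overlapping time-block bootstrap (default
50 blocks, 200 replicates): both sums are decomposed into per-block partial
sums, blocks are resampled with replacement, and CA is recomputed — this
respects the serial correlation of terms and the covariance between τ_p and
τ_x, which a term-wise bootstrap would miss.

Event files are plain TSV (time, site, new_configuration) with a window and
seed header.  Duplicate timestamps are rejected on read: coincident events
have measure zero in continuous time, so duplicates signal truncated or
merged records; jitter or re-export instead.

## Conditional activity, analytically

For site a, the generator splits as off-diagonal(Q) = Q^a + R^a, where Q^a
keeps transitions preserving a's configuration (diagonal retains the *full*
exit rates) and R^a holds the a-changing rates.  Q^a is block diagonal over
the connected components of the a-preserving transition graph; every block
is strictly substochastic whenever the site can transition somewhere in
that subspace.  With the fundamental matrix N^a = −(Q^a)⁻¹:

- (N^a)_ij is the expected time spent in j before a next changes, from i;
- B^a = N^a R^a is row-stochastic: row i is the distribution over the first
  microstate in which a has changed;
- K^a_i ∝ Σ_j K_j (R^a)_ji is the flux-weighted distribution over states
  entered just after an a-transition;
- τ^a = K^a N^a 1 is a's mean transition interval (checked: its reciprocal
  equals a's total stationary flux).

Then, using E[T] = N 1 and E[T²]/2 = N² 1 for absorption times and the
occupation-time identity E_i[time in j; absorbed at k] = (N^b)_ij (B^b)_jk:

τ_p[a] = (1/τ^a) K^a N^a N^a 1
τ_x[a←b] = (1/τ^b) K^b N^b B^b (N^a 1)

The exchange contraction deserves a note: an alternative form interposes an
extra post-transition weight K^a between B^b and N^a.  That variant breaks
the exact identity τ_x[a←b] = τ_p[a] for independent subsystems (which the
implemented form satisfies to machine precision, via the factorization of
the product chain and the renewal residual-life identity) and disagrees
with the simulation estimator; it remains available behind
`analytic_exchange(..., printed_variant=True)` for comparison only.

### Numerics

- All N-applications are per-block dense LU solves against the needed
  right-hand sides (ones vector, R columns, transposed solves for the K^b
  contractions); no global inverse is ever formed.  For the lambda model
  the largest blocks are a few hundred states.
- A block whose condition number exceeds 10¹² is refused with an error
  naming the site and block (extreme rate spreads make the fundamental
  matrix meaningless at double precision).
- A block with no a-changing exit means the site is frozen in that
  subspace: its sub-generator is an honest generator (singular), and the
  error says so rather than returning garbage.
- Sites with zero transition flux at a condition become NA rows/columns of
  the CA table (with recorded reasons), not exceptions.
- |CA| below 10⁻⁹ is reported as exactly 0.

## Simulation

Exact SSA over the microstate chain: exponential holding time at rate
−q_ii, next state proportional to q_ij.  The jump loop is numba-compiled
and consumes pre-drawn uniforms in chunks, so 10⁷ events take seconds; the
stopping rule is whichever of t_max / n_events is reached first.  By
default the initial state is drawn from the equilibrium distribution
(stationary start — estimators need no burn-in); fixed starts are
supported.  Trajectories record their seed, and equal seeds give identical
paths.

## The lambda switch instance

Nine sites: operators O_R1–3, O_L1–3 (configurations empty/CI₂/Cro₂) and
promoters P_R, P_RM, P_L (empty/RNAP).  Steric overlap follows the
classical right-operator geometry: P_R overlaps O_R1 and O_R2, P_RM
overlaps O_R3, P_L overlaps O_L1 and O_L2; simultaneous RNAP at P_R and
P_RM is allowed.  This yields 40 right-operator joint configurations × 30
left = 1200 microstates.  Note that with zero energies and unit
concentrations the uniform law on this *constrained* space still carries
MI between sites of the same overlap cluster — exclusion alone
anticorrelates them — so "no interactions" means zero MI only across
clusters.

Energy parameters are an explicit input schema (intrinsic energies per
site/species, pairwise cooperativities, multi-site looping terms with
free-text provenance per value).  The shipped parameter and condition files
are deliberately value-empty: the quantitative lambda literature values
must be transcribed by the user, and the loader marks untranscribed files
as placeholders, which `pathway_report` refuses without an explicit
override.  A clearly-labeled synthetic parameter set (plausible magnitudes
only) exists for exercising the machinery.  Lysogeny and lysis are two
fixed concentration conditions; switching tendency is reported through the
stationary RNAP occupancy and transition statistics of P_R.

## Fixtures and what the tests show

The toy generators (`single_site`, `independent_pair`, `cooperative_pair`,
`blocker_pair`, `chain_n`) define the test conditions:

- single_site with bind/unbind rates (3,1): τ_p = 5/6, τ_x = 1/2,
  CA[a←a] = −log₁₀ 0.6 ≈ 0.2218, all closed form, validated against a
  10⁶-event simulation;
- independent_pair (unbinding rates 1/3 and 2.5 via concentrations 3 and
  0.4): MI = 0 and cross-CA = 0 exactly;
- cooperative_pair (default ΔG_coop = −1.5 kcal/mol ≈ 11-fold weight at
  310 K): hand-computable 4-state Boltzmann weights;
- chain_n with n = 4, nearest-neighbor ΔG_coop = −1.5 and an end-to-end
  exclusion (12 states): the analytic-vs-simulated CA comparison at
  10⁷ events, every cell agreeing within 3 bootstrap SE.

These fixtures emulate the *structure* of regulatory binding modules —
competition, cooperativity, steric overlap — under idealized conditions:
exact detailed balance, a single global binding rate, fixed concentrations,
no protein production or degradation, no measurement noise or missed
events.  Passing tests therefore certify the estimators and the
absorbing-chain algebra, not the biological accuracy of any particular
parameterization; real single-molecule records additionally face detection
gaps and timestamp discretization that the duplicate-timestamp guard only
partially addresses.

## Known limitations

- Dense generator storage caps models at ~5000 microstates.
- The equal-binding-rate assumption is a modeling choice inherited with the
  detailed-balance construction; site-specific binding rates would require
  measured kinetics.
- CA of a two-state site with unequal rates is positive even though the
  site's own dynamics are Markov conditional on the full state — "zero CA"
  characterizes Poisson transition processes, not all Markov ones.  The
  estimator is deliberately not forced to zero in that case.
- Transient (non-stationary) conditional activities and inference of
  events from raw traces are out of scope.
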