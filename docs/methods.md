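# Methods

## Model

The cell is a closed autocatalytic network of eleven (base) or thirteen
(extended) fluxes over twelve species.  Enzymatic reactions (fluxes `v`):
carbon import (IC), amino-acid synthesis (EAA: n_AA·C → AA), nucleotide
synthesis (ENT: n_NT·C + AA → NT), rRNA transcription (RNAP:
n_rRNA·NT → rRNA), ribosome assembly (AF: rRNA + rP → R) and, in the
extended model, rRNA degradation (RNase: rRNA → n_rRNA·NT).  Protein
synthesis reactions (fluxes `w`): the ribosome translates each protein i
from n_i amino acids.  At steady state with growth rate μ,
N·(v,w) = μ·c ≥ 0 and the dry-mass normalization ω᷀c = 1 makes μ equal the
mass-weighted exchange flux; carbon import is the only exchange reaction,
so ω_C·v_IC = μ.

Catalyst concentrations are eliminated through c_i = w_i/μ and c_R = v_AF/μ,
turning each capacity constraint into a row of the form
(−μ·demand, +k·supply) ≥ 0.  The resulting growth-rate-parameterized table
has rows C, AA, NT, rRNA, rP (stoichiometry), cap IC/EAA/ENT/RNAP/(RNase)/
AF/R (capacities), (min deg), and mass — 12×11 in the base model, 14×13
extended.  The rRNA, cap R and min deg rows may be switched from
inequalities to equalities (`accumulation_mode="forbid"`) to select the
branch in which neither free rRNA nor idle ribosomes accumulate.

Assumptions inherited from the model class: fixed ribosome mass ω_R with a
continuously divisible rRNA/protein split; constant kinetic parameters per
condition (a user-supplied k̄el_R(μ) hook is deliberately out of scope);
no mRNA/tRNA species, no energy metabolism, protein degradation neglected
(protein turnover is slow compared with rRNA turnover); RNAP fully
allocated to rRNA (φ_rRNA_RNAP = 1 by default, adjustable as a scalar).

## rRNA degradation

RNases are always present, so the extended model imposes a minimum
degradation flux v_RNase ≥ k_deg(x_rP)·(1−x_rP)·c_R, proportional to the
rRNA content of the ribosome pool (free rRNA is negligible in vivo).  Three
scenarios for the rate constant: `none` (base model), `constant`
(k_deg ≡ k_deg,max), and `hill`
(k_deg = k_deg,max·(1 − xⁿ/(Kⁿ + xⁿ))), which models cooperative protection
of rRNA by ribosomal proteins — below the half-saturation K ribosomal
protein barely protects, above it degradation shuts off with
cooperativity n.  Degradation carries a double cost: re-transcription of
the lost rRNA and synthesis of the RNase itself (capacity
n_rRNA·v_RNase ≤ k_deg,RNase·c_RNase).

## Parameters and fixtures

Internal units: hour, mmol, gram.  The file loader accepts per-second rates
with unit tags (`{"value": 21, "unit": "AA/s"}`) and converts on load.
Mass consistency (ω_AA = n_AA·ω_C, ω_NT = n_NT·ω_C + ω_AA) is enforced by
the validator so that every internal reaction conserves mass exactly
(ω᷀N = 0 off the exchange columns); this is what makes the dry-mass
identity ω᷀c = 1 hold to machine precision for every solution.

The six packaged *E. coli*-like conditions are synthetic fixtures anchored
to well-established numbers: translation elongation 21 AA/s; RNase R
turnover 88 NT/s; a 55-protein ribosomal complex of ≈7400 amino acids at
the observed x_rP = 0.36, which fixes ω_R = 7400·ω_AA/0.36 ≈ 2220 g/mmol
(≈2.2 MDa); 15–20% inactive ribosomes (f_act_R 0.80–0.85); Hill parameters
K = 0.2 with n ∈ {2, 6}.  Fixture choices: a 27 g/mol carbon-equivalent
unit with n_AA = 4 and n_NT = 8 (ω_AA = 108, ω_NT = 324 g/mol); lumped
protein lengths (RNAP 3407 AA, RNase 813 AA as for RNase R, transporter
650 AA, pathways 900/1200 AA, assembly factors 600 AA); transcription
85 NT/s with 30% of RNAP active.  Nutrient quality is encoded as
per-condition kcat_EAA = kcat values chosen by inverting the closed-form
quadratic so that base-model μ_max at x_rP = 0.36 lands at
{0.45, 0.70, 1.00, 1.40, 1.75, 2.05} h⁻¹ — the experimentally observed
span — and increases monotonically from poor to rich media.  Every
non-anchored value is flagged `fixture_derived` in the metadata, and the
JSON loader is the injection point for users holding measured parameter
tables.  The identities of the three minimal media are not fixed by any
printed value, so they carry neutral labels (min1, min2, glc).

What the fixtures do *not* emulate: growth-rate-dependent elongation rates,
RNAP allocation shifts between RNA classes, non-growth-associated
maintenance.  Consequently the model reproduces the linear RNA/protein
ratio versus μ but with a near-zero intercept, and degraded-rRNA fractions
are only qualitatively comparable to measurements; passing tests certify
the model's internal laws, not quantitative agreement with any organism.

The carbon-source molar mass appearing in the closed-form coefficients is
taken to be ω_C (the model has a single carbon species); this is recorded
in the coefficient object's notes.

## Growth maximization

Feasibility at fixed μ is decided by a max-min-slack linear program
(HiGHS): maximize t subject to every inequality row having normalized slack
at least t.  Rows are normalized to unit max-abs coefficient first — the
raw table mixes counts of order 10⁴ with fractions of order 1.  The
bisection on μ brackets from the autocatalytic ceiling
k̄el_R·ω_AA/ω_R (doubling until infeasible) and accepts μ when the optimal
slack is nonnegative; the slack value crosses zero linearly in μ, so a
zero cut-off keeps the bisection error at the LP's own accuracy rather
than tolerance/slope.  Default tolerance 1e-6 h⁻¹.

Because the LP can declare feasibility a hair beyond the true optimum
(objective accuracy ~1e-12, worth up to ~1e-8·μ), the final witness is
snapped onto an exact vertex: near-active rows and near-zero fluxes are
assembled into a square system (surplus rows dropped, or near-zero fluxes
pinned, in all few combinations), solved with iterative refinement, and
accepted under a backward-error criterion that compares each row residual
to the magnitude of the terms it sums.  If no exact vertex exists at the
bisection point, μ is backed off in steps of max(tol/2, 1e-8·μ).  The
result: dry mass, allocation sums and nonnegativity hold to machine
precision, and bisection agrees with the closed-form root to ~1e-9
relative on randomized parameter sets (tested at 1e-6).

Degenerate compositions are kept with zero coefficients rather than
dropped rows, so system shapes are constant across a sweep; at x_rP = 0 or
1 the flux polytope acquires a free direction and vertex enumeration
reports it as an error instead of returning rays.

## Vertex enumeration

Extreme solutions at fixed μ (the elementary growth vectors of the
polytope) are enumerated exactly: equality rows are eliminated by a
particular solution plus null-space basis, and every choice of dim
inequalities (rows or nonnegativity bounds) is solved as a batched linear
system, keeping feasible solutions and deduplicating coincident vertices.
Boundedness is certified first by checking that the recession cone is
trivial (2·dim small LPs).  At 19–23 inequalities and dimension 7–9 the
exhaustive search is exact and takes well under a second (base model); an
independent full-space brute-force oracle in the test suite reproduces the
same vertex set.  Branches are classified by the activity of the rRNA and
cap R rows: excess-rRNA, excess-ribosome, or no-accumulation; all vertices
are reported, with per-branch spreads, rather than pruned.

## Calibration and sweeps

Composition sweeps use a 0.01 grid on [0, 1]; n_rRNA and n_rP are kept
real-valued across the sweep (rounding would create grid artifacts).
The interior-optimum flag requires the grid argmax to beat both endpoints
by more than the solver tolerance.  k_deg,max is calibrated by bisection
on log k_deg,max — the grid argmax is non-decreasing in k_deg,max — until
the optimum matches the target composition (0.36) within grid resolution;
the inner argmax uses a two-stage grid (step 0.04, then 0.01 around the
coarse optimum).  With the glucose fixture this yields k_deg,max ≈ 29.7 h⁻¹
(constant), 52.3 h⁻¹ (Hill n = 2) and 162.5 h⁻¹ (Hill n = 6); these values
are recomputed at run time, not stored.

Problem sizes used in the shipped analyses — 101-point sweeps across six
conditions and three degradation scenarios, 50 randomized parameter sets
for the oracle cross-checks, ten-point μ grids for branch enumeration —
were chosen so the full analysis reruns in minutes on a laptop while still
exercising every code path.

## Variant scenarios

*Archaea*: harsher environments are modeled as a factor (default 2×) on
k_deg,max; the optimal protein fraction increases, more weakly the higher
the cooperativity.  *Mitochondria*: a fraction f of ribosomal protein is
imported free of synthesis cost; the AA balance and the ribosome-time
charge of w_rP are discounted to (1−f)·n_rP, and the imported residues
enter the dry mass as an exchange contribution on the mass row (otherwise
ω᷀c = 1 would fail).  The closed form is restricted to f = 0; variant
optima come from the numeric solver.

## Known limitations

- The optimum of the base model is provably at an endpoint; interior optima
  exist only with degradation costs.  Near-flat profiles (constant-k_deg)
  make the argmax location sensitive at the grid-resolution level — the
  calibration therefore reports the verifying sweep alongside the rate.
- LP-based μ_max carries a relative accuracy floor of ~1e-8 set by the
  solver tolerances; the closed form should be preferred for the base
  model when available.
- The degraded-rRNA fraction at low cooperativity is much higher than
  measured values; only its qualitative decrease with growth rate is a
  robust model prediction.
- Concentrations of non-catalyst metabolites are identically zero in this
  steady-state formulation, so degradation of nascent rRNA during
  transcription/assembly is represented only through the lumped minimum-
  degradation constraint.
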