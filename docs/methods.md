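# Methods

## Model

Two populations, A and B, differ by a single gene allele that affects only
their reproduction rates. They reproduce (r_A, r_B, per unit time), compete
within and between populations (rates a_ij, per individual per unit time,
all positive in the raw ecological model), and exchange the allele by HGT.
A transfer event converts the recipient's type, so only the *balance* of
the two directions enters the deterministic dynamics: γ > 0 means B → A
conversions dominate. Mutational inactivation, spatial structure, more than
two types and more than one transferred locus are outside the model.

The count-space equations (see README) are equivalent, for N > 0, to a
replicator system for (p_A, N) in which the fitness of each population is
the expected payoff of a 2×2 matrix game whose entries depend linearly on
N; γ enters the off-diagonal (between-population) entries with opposite
signs. The package keeps both representations and the test suite holds
them to agree to 1e-10 under the change of variables; the fraction view is
undefined at N = 0, which the state type reports as an explicit extinct
marker rather than NaN.

## Equilibria and stability

Rest points are closed-form: extinction (always unstable for positive
reproduction rates), two monocultures (1, r_A/a_AA) and (0, r_B/a_BB), and
at most one interior point (see `hgtgames.equilibria`). Stability verdicts
come from the analytic count-space Jacobian; for the monocultures the
dominant eigenvalue reproduces the classical threshold inequalities
((a_BA+γ)/a_AA · r_A/r_B > 1 for the A-monoculture, and its mirror), which
`stability_boundary` also evaluates directly as an independent route. When
the interior denominator a_AA a_BB − (a_AB−γ)(a_BA+γ) vanishes the
nullclines are parallel; if they moreover coincide (equal reproduction
rates, equal competition, balanced transfer) every composition at N = r/a
is neutrally stationary and the result is reported as a degenerate line,
never silently binned.

A subtlety worth recording: the compact published expression for the
coexistence composition, p_A* = (a/|κ|)(1 − r_B/r_A), is exact only on the
ξ = 0 line. The package always uses the general interior closed form
p_A* = (a(r_A−r_B) + r_B ξ)/(r_B ξ − r_A κ), which is a root of the
dynamics for all admissible (ξ, κ) — e.g. 5/7, not 5/9, for
(ξ, κ) = (0.08, −0.08) — and which direct integration of the forced system
confirms.

## Oscillating environments and averaging

Oscillatory parts are zero-mean 2π-periodic signals in the fast time
τ = ωt, ω > 1, represented either as finite harmonic series (no k = 0
term, enforced at construction) or as tabulated samples on a uniform
period grid (mean-centered at construction). The emergent payoffs are the
period-averaged overlaps of the competitor's reproduction-rate primitive
with the transfer oscillation, divided by ω. Only the first-order averaged
terms (ξ, κ) are retained; they reproduce every printed scenario value
exactly, and the comparison metrics quantify what the truncation costs
(see below).

Numerical choices:

* Harmonic × harmonic overlaps are evaluated by exact coefficient algebra
  (⟨cos k cos k⟩ = ⟨sin k sin k⟩ = 1/2, cross terms vanish).
* Tabulated signals use a 4096-point uniform grid per period. The primitive
  is computed spectrally — FFT coefficients divided by ik, mean zeroed, an
  unpaired Nyquist mode dropped — because a cumulative-quadrature primitive
  has O(h²) error (~1e-6 at this grid), far above the 1e-10 agreement the
  harmonic oracle check demands; spectral integration is exact for
  band-limited signals. The product average is the plain grid mean, which
  for periodic data is the trapezoid rule and spectrally accurate.
* The primitive's additive constant is fixed by mean-centering. It is
  mathematically irrelevant (the averaging partner has zero mean); centering
  just makes intermediate arrays reproducible, and a test shifts the
  primitive by a random constant to prove the payoffs do not move.

The effective-rate substitution a_AB − ξ, a_BA + κ may legitimately produce
negative between-population "competition" rates (mutualism); such rate sets
are flagged `effective` and exempted from the positivity invariant.

## Phase-map classification

Region labels (convention r_A > r_B; other inputs are relabeled, mapping
(ξ, κ) → (−κ, −ξ), and the swap recorded): coexistence requires
κ < a(r_B/r_A − 1), ξ > a(1 − r_A/r_B) and a(ξ−κ) + ξκ > 0, and splits
into I (ξ < 0), II (0 < ξ < a, κ > −a) and III (otherwise). Failing only
the κ condition gives IV (A wins); failing only the ξ condition gives VI
(B wins); failing both is resolved through the general stability machinery
on the effective rates — both monocultures stable ⇒ bistability (V) —
rather than by transcribing the verbal "conditions violated" phrasing,
whose sub-inequality assignment is ambiguous. Existence without stability
is the N/A zone, sub-coded `divergent` (on the a(ξ−κ)+ξκ = 0 curve, where
N_c* → ∞) or `negative_abundance` (below it). All boundary comparisons use
a relative tolerance of 1e-9 and boundary hits are labeled `boundary`,
because the regions are open sets. The point (ξ, κ) = (0, 0) is strictly
interior to region IV — the fixed-environment limit, where exclusion holds.

Symbiosis is classified from the signs of the cross-derivatives of total
fitness (N-independent), and synergy is always computed by comparing
N_c* with N_f* = max(r_A, r_B)/a, never inferred from region membership.

## Integration and comparison metrics

Both integrators use SciPy's LSODA with rtol 1e-8, atol 1e-10 (N spans
orders of magnitude near divergence and the forcing is fast). The full
integrator caps the step at a twentieth of the environmental period and
samples 40 points per period; blow-up past a configurable ceiling
(default 1e6) terminates the run and marks the trajectory divergent — a
first-class result, since unbounded averaged growth is a documented model
behaviour, not an error. The RHS clamps the state to the physical domain
to absorb solver overshoot of order the tolerance; samples beyond 1e-6
outside the domain are treated as errors.

Period averages are trapezoid means over an integer number of periods
aligned to the end of the trajectory; the default window is the last 25 %
rounded down to whole periods, never fewer than 10 (the averaging window
is not prescribed anywhere authoritative, so it is explicit and
configurable). The comparison metrics are the Euclidean distance of the
time-averaged fraction vectors and the relative error of time-averaged
abundances, on matched windows.

One refinement subtlety: the scenario presets fix the oscillation
*amplitudes*, so (ξ, κ) ∝ 1/ω and a scenario that coexists at ω = 5 exits
the coexistence region as ω grows; both descriptions then agree on
exclusion and the fraction distance collapses to the solver noise floor
(~1e-14). The ω-refinement test therefore requires strict decrease only
until the distance is numerically zero (below 1e-12). Holding (ξ, κ) fixed
by scaling amplitudes with ω is not a valid alternative: the neglected
second-order averaging terms then stay O(1) and the error plateaus near
1e-3 instead of vanishing.

Problem sizes used by the shipped tests: comparison runs integrate to
t = 250 (≈200 environmental periods at ω = 5), exclusion sweeps use 1000
random parameter draws with 100 long integrations to t = 900, and the
ω sweep covers ω ∈ {5, 10, 20, 40} for the three presets.

## Stochastic simulation

The event system is the minimal one whose large-system limit is the
deterministic model: birth of each type (r_i n_i), death by competition
((a_iA n_A + a_iB n_B) n_i / Ω), and directional transfer
(γ_AB n_A n_B / Ω converting B → A, γ_BA the reverse). Competition and
transfer propensities carry 1/Ω so concentrations x = n/Ω obey the ODEs —
the standard system-size scaling. Only γ_AB − γ_BA is constrained by the
deterministic balance; the symmetric baseline γ₀ adds conversion noise
without moving the mean field, which a test verifies across
γ₀ ∈ {0, 1}. Transfer events conserve n_A + n_B exactly; (0, 0) is
absorbing. Sampling is exact (direct-method SSA), compiled with numba, with
one master seed and per-replicate streams derived deterministically, so a
given seed reproduces the event sequence bit-for-bit. Time-varying rates
are not supported in the SSA; it exists to validate the fixed-environment
mean-field limit and to explore demographic noise.

## What the synthetic scenarios do and do not show

The presets encode the published phase-map base parameterisation
(r_A = 1.8, r_B = 1, a = 0.1, γ = 0) and the three oscillating scenarios
(γ̃ = 0.5 sin τ, cosine reproduction oscillations with amplitudes
(−1.6, −0.2), (−1.6, 1.6), (−2.2, 2.2), ω = 5). They exercise every regime
the theory predicts, but they are single-harmonic, perfectly periodic,
noiseless forcings of a two-type, well-mixed model: passing tests say the
implementation realises the model faithfully, not that real microbiomes —
with many strains, multi-gene transfer, stochastic environments and
spatial structure — behave quantitatively like it.

## Known limitations

* Averaging is first-order only; near the N/A curve the averaged abundance
  error grows without bound even though the exact forced dynamics stays
  bounded.
* The classifier's region V verdict relies on the effective-rate stability
  machinery; exactly on region boundaries it reports `boundary` and leaves
  interpretation to the caller.
* The SSA treats within-population competition propensity as a n_i²/Ω
  (not n_i(n_i−1)/Ω); the O(1/Ω) difference is invisible at the validated
  system sizes.
* Tabulated signals are evaluated off-grid by linear interpolation;
  spectral accuracy holds only for the period-average quadratures.
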