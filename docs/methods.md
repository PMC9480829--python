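# Methods

## Models

Both models share the core cascade BCAR → CISB → CTNL → CL.  BCAR enters at
a constant rate k₀ (mM s⁻¹); every enzymatic step is an irreversible
Michaelis–Menten flux v = V_max·[S]/(K_M+[S]) with V_max = k_cat·[E]; the
D27 isomerase acts in both directions, forward (BCAR→CISB, k_catD27A) and
reverse (CISB→BCAR, k_catD27B), both with the same K_MD27.  Model AB (6
state variables) splits the MAX1 flux out of CL into ORO (fraction ω) and
STR (fraction 1−ω).  Model AC (8 state variables) routes CL → CLA → DO → ORO
through three independent MAX1-catalysed steps — each using the full
V_maxMAX1 and K_MMAX1, i.e. no competition for enzyme capacity is modelled —
and splits the parallel ABA8HD flux out of CLA into ORO (ϕ) and STR (1−ϕ).
ORO and STR leave the system with first-order constant k (s⁻¹); "diffusion"
here means removal from the production site, not spatial transport.

Units are mM, s, and mM s⁻¹ throughout.  The bundled `*_adjusted` parameter
fixtures are the stabilized sets (k₀ = 10⁻⁸ mM s⁻¹, D27 = 1.06·10⁻⁷ mM,
K_MD27 = 0.26 mM, CCD8 = 1.06·10⁻⁶ mM, …); the `*_literature` fixtures keep
the unadjusted database values for those four constants (k₀ = 3.7·10⁻¹⁴,
D27 = 1.06·10⁻⁸, K_MD27 = 2.6·10⁻⁴, CCD8 = 1.06·10⁻⁷).  Two K_M values near
0.009 mM appear in the sources with ambiguous labels; 0.0087 mM is assigned
to CCD7 and 0.0092 mM to CCD8.  ϕ has no tabulated value; the fixtures use
ϕ = 0.5, the symmetric split, mirroring ω = 0.5.  Model AC's influx is
given in concentration units in one source; it is treated as the same
mM s⁻¹ influx as in Model AB.

Feedback regulation uses the power-law (biochemical-systems-theory) form:
a regulated flux is multiplied by [X]^f per regulator X, with f ∈ [−1, 0]
(no cooperativity; f = 0 is no regulation and restores the unregulated
equations exactly).  Concentrations enter the multiplier raw, in mM, with no
normalization; since all concentrations here are far below 1 mM, negative
exponents produce large multipliers — that is the modelled mechanism, not an
artifact.  Below a floor of 10⁻³⁰ mM a negative-exponent multiplier raises a
singular-multiplier error; regulated systems are therefore always solved
from strictly positive seeds (default: the unregulated steady state).

The network is stored once as a reaction table (stoichiometry matrix ×
rate vector), from which the ODE right-hand side and an analytic Jacobian
are both derived; this guarantees the two stay consistent and yields the
exact telescoping identity Σᵢ dxᵢ/dt = k₀ − k([ORO]+[STR]) for any state,
parameters, and feedback.

## Steady states

Unregulated, the cascade is feed-forward: at stationarity every net flux
equals k₀, so the state is solved sequentially by inverting each
Michaelis–Menten law, S = K_M·f/(V_max−f).  CISB comes first (CCD7 carries
k₀), which fixes the D27 reverse flux and hence BCAR (D27 forward carries
k₀ + reverse); the CLA level in Model AC is the root of a scalar equation
(MAX1 + ABA8HD consumption = k₀), solved by Brent bracketing to relative
tolerance 10⁻¹⁵.  This closed form exists iff k₀ is below the capacity
(effective V_max) of every consuming step — k_catD27A·[D27], V_maxCCD7,
V_maxCCD8, V_maxMAX1, and in Model AC also V_maxMAX1+V_maxABA8HD for CLA
and V_maxMAX1 for DO.  At the adjusted values the bottleneck is CCD8
(1.908·10⁻⁷ mM s⁻¹).  Beyond the bound the substrate of the saturated step
grows without limit; the solver reports `no_steady_state` with the limiting
step rather than a pseudo-state.  Operationally this capacity loss is what
"instability at large k₀" means for this cascade: as k₀ approaches the
bound the substrate's relaxation eigenvalue approaches 0⁻, and past it no
steady state exists at all — wherever a steady state does exist the
unregulated cascade is stable (verified over random ensembles).

With feedback (or rescaled rate constants) the state solves a genuine
nonlinear system: a damped Newton iteration on log-concentrations (positivity
is automatic; steps clipped to ±5 natural-log units, step halving up to 50
times), seeded from the unregulated solution, with a long-time stiff
integration (LSODA, analytic Jacobian, rtol 10⁻¹⁰ / atol 10⁻¹⁶ mM) as
fallback and Newton polish.  Any returned state must satisfy
‖dx/dt‖∞ ≤ 10⁻¹⁸ mM s⁻¹ (≈10⁻¹⁰·k₀); otherwise the solver raises rather
than returning a non-stationary state.

Stability is classified from the eigenvalues of the analytic Jacobian:
stable iff the largest real part is below −10⁻¹² times the spectral scale;
eigenvalues within that tolerance of zero are reported `marginal` (counted
as not stable in verdicts).  A central finite-difference Jacobian (relative
step 10⁻⁵, the round-off/truncation crossover here) is provided as a
cross-check and agrees with the analytic one to 10⁻⁶ relative on nonzero
entries at both adjusted steady states.

## Sensitivity and scans

Local sensitivities S(X,p) = ∂ln X/∂ln p are central log-differences with
step h = 0.01, falling back to one-sided h = 0.001 beside an existence
boundary, and raising (never NaN) if the steady state is lost on both
sides.  Global behaviour is probed by one-at-a-time log-spaced scans (default
10 points per decade; 4-decade spans for sensitivity checks, 6 for capacity
scans) recording every grid point including those without a steady state,
and by branch-fraction × removal-rate scans on linear fraction grids
(branch fractions live on [0,1] and are excluded from log scans).  Useful
closed forms in Model AB: ORO = ω·k₀/k and STR = (1−ω)·k₀/k, hence
S(ORO,k₀) = 1 and S(ORO,k) = −1 exactly; in Model AC flux conservation pins
ϕ·k₀/k ≤ ORO ≤ k₀/k regardless of the MAX1/ABA8HD kinetics — with ϕ = 0.5
and k = 1 that is the 10⁻⁸·³–10⁻⁸ mM confinement window.

## Feedback screen

The tested combinations are fixed lists (8 for AB, 9 for AC) of elementary
loops: end products and the branch-point metabolite inhibiting the first
(D27) reaction; each end product inhibiting its own branch share; ORO
inhibiting the CLA→DO step in AC.  The label→exponent mapping (AB1=foro1,
AB2=fstr1, AB3=fcl, AB4=foro2, AB5=fstr2; AC1=foro1, AC2=fstr1, AC3=fcla,
AC4=foro3, AC5=fstr3, AC6=foro4) is one configuration table and can be
permuted without code changes; in paired schemes both exponents share the
single scanned strength.  Strengths run −1.00…0.00 in steps of 0.01 (101
points); the solver walks the grid from 0 downward, seeding each point from
the previous solution (continuation), and records per-point status, BCAR,
leading eigenvalue, and whether BCAR ∈ [10⁻⁴, 10⁻¹] mM (inclusive).

A scheme's verdict is `viable` only if every negative strength keeps a
stable steady state with BCAR in the window — i.e. the feedback could be
present at any strength without contradicting observation.  This is
deliberately a per-scheme criterion: very weak inhibition (|f| ≲ 0.06)
deflates BCAR only mildly and remains stable, so isolated viable points
exist at the weak end of every first-reaction scheme; what fails is
sustaining the feedback across its admissible range.  The summary report
exposes those weak-strength points (`weak_feedback_points`) rather than
hiding them.  Failure precedence when not viable: window loss, then
destabilization, then loss of a steady state.

The flux-constrained variant multiplies each regulated reaction's rate
constant by Π_r [X_r*]^(−f) at the unregulated reference concentrations, so
the reference state stays exactly stationary, then recomputes the spectrum
there.  Stability degradation is then a pure eigenvalue statement: the
leading eigenvalue creeps from −1.86·10⁻⁵ s⁻¹ (no feedback) toward
−9.3·10⁻⁶ s⁻¹ (f = −1) for first-reaction schemes, monotonically in
strength.

## Synthetic data

No deposited concentration measurements exist for this pathway, so test
inputs are generated from the models: parameter ensembles drawn log-uniform
within ±w decades of a base set (branch fractions uniform on [0,1]; k fixed
unless requested; default w = 1 decade, a generous spread for kinetic-
constant uncertainty), and observations with multiplicative log-normal
noise, value = prediction·exp(ε), ε ~ N(0, σ_log²) iid — chosen because the
concentrations span nine decades, making additive noise meaningless.
Default σ_log = 0.1; recovery experiments use σ_log = 0.05 with 3
replicates of steady-state (BCAR, CL, ORO, STR) observations.  All
randomness derives from one integer seed via independent substreams.

Recovery is bounded multi-start least squares on log-concentrations
(positive parameters fitted in log space, fractions linearly; bounds default
to ±2 decades around truth).  What passing these tests shows is internal
consistency — the estimation machinery inverts the generative model it was
given; it does not show that real tissue measurements (with their sampling,
matrix-effect, and model-misspecification errors) would identify the same
parameters.

## Problem sizes and limitations

Default experiment sizes keep the full suite light: 101-point strength
grids over 17 schemes, 40–50-member ensembles per model with integration
horizons set to 40 relaxation times of the slowest mode, 10 points per
decade in scans.  Known limitations: no mechanistic inhibition kinetics, no
thermodynamic coupling of the D27 directions, one-at-a-time (not
variance-based) global sensitivity, no bifurcation continuation or
limit-cycle search (none was ever observed), and no spatial transport —
`k` lumps all removal processes.
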