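# Methods

## Model and assumptions

The simulator integrates a deterministic 15-compartment ODE system
coupling tumor subpopulations, two immune compartments, microenvironment
variables and a two-compartment drug model. The key structural
assumptions:

* **Shared logistic crowding.** All six tumor compartments compete for
  one carrying capacity `K = 1000`; the growth factor
  `max(0, 1 − T/K)·(1 + 0.2·M)` is divided by an acidosis penalty
  `1 + 0.01·M·T/K`, so metabolic shift (`M`) both fuels growth and sours
  the microenvironment.
* **Saturating, hypoxia-impaired immune killing.** Cytotoxic kills scale
  with `β1·I1·pop/(1 + 0.01·T)` and are multiplied by
  `1/(1 + 0.5·h)` where `h` is the normalized excess of `T/K` over the
  hypoxia threshold 0.3. Partially resistant cells are killed at half
  rate; resistant clones at 10 % / 5 % of baseline.
* **Therapy pressure drives both kill and resistance.** The linear
  combination `η_E·u_E + η_H·u_H + η_C·u_C` (η = 0.01 each) removes
  sensitive cells, induces senescence, and feeds resistance development
  `ω_R·pressure·N1·(2 − G)`, clipped at zero. Protocol-specific
  multipliers scale ω: ×2.0 under continuous dosing (sustained selection
  pressure), ×1.2 under adaptive dosing.
* **Memory surrogate.** The entire right-hand side is multiplied by
  `γ(t, α) = 0.01·(1 + (1 − α)·min(t^−α, 100))` for `t > 0` (1.0 at
  `t ≤ 0`). This emulates the power-law kernel of a fractional derivative
  of order α with a single time-dependent scale; it is *not* a
  history-integral solver, and the package deliberately does not include
  one. The factor's jump at `t = 0` is kept as specified; integration
  starts at `t = 1e−9` so the solver never evaluates on the jump, and the
  `t = 0` sample reports the initial state.
* **Nonnegativity by flooring inside the RHS.** Every derivative
  evaluation clamps the incoming state copy to `1e−6` (and `G` to 1,
  since `G` is a 0–1 stability index whose recovery term targets 1)
  before any flux is computed. This keeps the ODE well defined when the
  integrator probes slightly negative states, and is preferred over
  post-hoc trajectory clipping.

Two printed-system fidelity choices are worth flagging: the
`hypoxia_effect` intermediate (`1 + h·A/(1+A)`) is computed and logged
but feeds no flux, because no equation of the complete system references
it; and six tabled parameters (`epigenetic_silencing`, `age_factor`,
`performance_status`, `bmi_factor`, `prior_treatment_factor`,
`microenv_stress_factor`) are stored and validated but inert, because
they appear in no printed flux either. Their sensitivity coefficients are
consequently exactly zero. The metastasis drive divides by
`1 + 0.5·h` (hypoxia suppresses the drive, mirroring the quiescence
reactivation structure); a `metastasis_hypoxia_mode="multiply"` switch
exposes the opposite reading.

## Dosing, PK and controls

Scheduled doses convert to an absorption flux
`absorption_rate·dose·intensity·bioavailability/V_d` into one
concentration compartment per drug; clearance uses the organ-adjusted
rate `elimination_rate·liver·kidney` for both the loss from `D` and the
gain of `Dm`, so drug mass `D + Dm` is conserved exactly under zero
input. (For the average patient the adjusted and nominal rates
coincide.)

The drug-to-control mapping is the package's most consequential open
choice. Two modes are provided:

* `control_mode="raw_dose"` (default): `u_X` equals the currently
  scheduled dose × `treatment_intensity`. Chosen as default because the
  resulting outcome magnitudes and protocol ordering reproduce published
  comparative results for this model family to within ~1 %.
* `control_mode="hill"`: `u_X` is the Hill transform
  `c^1.5/(0.3^1.5 + c^1.5)` of the on-board concentration. With the
  bundled PK parameters the steady-state concentration under continuous
  dosing is ≈ 0.049, far below EC50 = 0.3, so therapy pressure is ~13×
  weaker and all protocols compress toward the untreated outcome. The
  mode remains available for studying concentration-mediated coupling.

Immunotherapy enters separately: `u_I` stimulates `I1` (+0.1·u_I·I1),
suppresses `I2`, and multiplies the immune kill terms through
`immuno_boost = 1 + 0.5·u_I` (the boost coefficient is the tabled
`immuno_resist_boost`; the precise semantics are a package decision and
configurable). Hyperthermia sessions multiply therapy pressure by
`1 + θ_T·(T − 37 °C)` with default `θ_T = 0.1/°C` — an explicit artifact
decision, as no thermal-effect equation is published for this protocol.

The adaptive controller re-evaluates every 21 days: if the burden ratio
over the elapsed period exceeds the target ratio (1.0) the dose steps up
by 0.1, if it falls below its reciprocal the dose steps down, always
confined to [0.6, 0.9] and starting from the band midpoint 0.75. The
monitoring period, step and initial dose are package defaults (only the
band is tabled) and are configurable on `DoseSchedule`.

## Numerics

`safe_solve` wraps `scipy.integrate.solve_ivp` with a method chain (RK45,
BDF, Radau, DOP853), each method attempted at the configured tolerances
(`rtol = 1e−4`, `atol = 1e−7`) and then at two ×10 relaxations before
falling through to the next; a run that defeats the whole ladder returns
a flagged constant dummy trajectory instead of raising. Adaptive
protocols integrate piecewise between controller events, so dose changes
occur exactly at monitoring boundaries.

A `max_step` of 0.25 days is imposed. The circadian modulation has a
1-day period, and without the cap the adaptive integrator happily takes
multi-day steps through it, aliasing the oscillation into a
tolerance-dependent jitter of order ±1 efficacy point; with the cap,
halving the tolerances moves the 500-day final burden by far less than
0.1 %. This has a substantive consequence: the *converged* efficacy
varies only ≈ 0.24 points across the α sweep (monotone in α), because
the deterministic α-effect of the memory surrogate — its 500-day
integral differs from the α = 1 case by ~1 % of total effective time —
is intrinsically small. Published spreads of ~2 points across α for this
model family are consistent with the unresolved-oscillation jitter, and
are not reproducible by a tolerance-stable integrator.

`reference_integrate` is an independent fixed-step classical RK4 stepper
over the identical right-hand side, used in tests to cross-validate
`safe_solve` (agreement < 1e−3 relative over 10 days at `dt = 0.005`)
and validated itself against closed forms on injected linear systems.

## Sensitivity analysis

One-at-a-time multiplicative perturbations (±10 %, ±20 %) of each of the
58 parameters in each of the 20 profile × protocol contexts, at α = 1.0
(the memory order is a study dimension, never a perturbed parameter):
4,640 runs. Perturbations apply to the *context-effective* value (after
profile application), otherwise profile contexts would overwrite
perturbations of e.g. `mutation_rate`. Coefficients are normalized,
`S = (ΔO/O_base)/(Δp/p_base)`, computed per outcome metric;
per-parameter ranking takes `max |S|` over levels and contexts on the
efficacy score, with bands critical (≥ 1.0), important (≥ 0.5),
non-critical (< 0.5) — boundaries classify upward. Non-converged runs
are excluded and counted, with > 95 % retention required. The engine is
validated by injecting closed-form responses (`O = c·p` must give
`S = 1` exactly; `O = a + b·p` gives `S = b·p/(a + b·p)`).

Aggregate statistics (grid and comparison tables) use the sample
standard deviation (ddof = 1); this is switchable where it appears.

## Default study conditions

500-day horizon, 501 daily samples, initial state
`N1 = 190, N2 = 10, I1 = 40, I2 = 10, P = 0.1, A = 1, Q = 0.1,
R1 = R2 = 1, S = 0.1, D = Dm = 0, G = 1, M = 1, H = 0` (initial burden
202.2), circadian effects enabled, α sweep
{0.75, 0.80, 0.85, 0.90, 0.93, 0.95, 1.00}. `R1`/`R2` are clamped up to
`resistance_floor = 0.01` at initialization only (pre-existing resistant
subclones); the printed ODEs contain no floor term, so none is applied
during integration. These are the conditions under which all bundled
experiment engines and the acceptance script run; tests use shorter
horizons (2–120 days) for speed except where an invariant is explicitly
about the full course.

## What the tests do and do not show

The test suite validates the implementation against independent oracles
(a monolithic transcription of the right-hand side, closed-form
solutions, a fixed-step integrator, closed-form sensitivity responses)
and checks structural invariants (mass balance, flooring, dose bounds,
determinism across worker counts). Passing them shows the machinery
faithfully implements the stated model under the stated conditions; it
shows nothing about real tumors, and the absolute outcome values depend
on calibrated coefficients (notably η ≈ 0.01, chosen so course-level
reductions land in the 30–40 % clinical response range) rather than
measurement.

## Known limitations

* The memory surrogate is a scaling factor, not a fractional-order
  integrator; α-effects are correspondingly mild and monotone.
* Single effective drug compartment per drug type; no PBPK, no
  drug–drug interactions.
* Patient heterogeneity is four discrete profiles, not a covariate
  model; several demographic factors are documented as inert.
* The immuno-combination protocol's boost semantics and the thermal
  modifier are package decisions where no published equation exists;
  both are configurable and flagged.
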