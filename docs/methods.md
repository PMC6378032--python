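# Methods

## Model

`adcascade` simulates the dynamic biomarker cascade of Alzheimer's disease
as a mechanistic (cause-effect) system of five coupled nonlinear
first-order ODEs over age t in years, t = 0 at birth, horizon 100 years.
All state variables are normalized, dimensionless levels with nominal
range [0, 1]:

| symbol | state | meaning |
|---|---|---|
| A  | `a_beta` | amyloid-beta pathology |
| Tp | `tau_p`  | amyloid-related phospho-tau |
| To | `tau_o`  | aging/SNAP-related tauopathy |
| N  | `n_deg`  | neuronal dysfunction / loss |
| C  | `cog`    | cognitive impairment |

with total tau T = Tp + To derived, not integrated. The equations are

    dA/dt  = λ_Aβ A (K_Aβ − A) + λ_AβAo · Ao − δ_Aβ · A_Rx(t)
    dTp/dt = λ_τρAβ A + λ_τρ Tp (K_τρ − Tp)
    dTo/dt = λ_τoAS · AS
    dN/dt  = λ_Nτo To + λ_Nτρ Tp + λ_N N (K_N − N) + λ_NAS · AS
    dC/dt  = λ_CN N R + λ_C C (K_C − C) + λ_CAS · AS + λ_Cε ε

Each of the amyloid, p-tau, neurodegeneration, and cognition cascades is a
logistic growth law (rate λ, carrying capacity K) with additive linear
forcing from upstream cascades and from constant host factors:
amyloidopathy Ao, aging/SNAP burden AS, ApoE genetic risk ε, and cognitive
reserve R. SNAP-tau grows linearly from AS and has no capacity; summing
the Tp and To equations reproduces the total-tau rate expression exactly
(asserted at machine precision in the tests). Anti-amyloid therapy enters
through A_Rx(t) = H(t − t_onset), a Heaviside step with the half-maximum
convention H(0) = 1/2, maintained for life once started.

### Design choices where the formulation was open

- **Total tau is derived, not integrated.** The total-tau equation is
  algebraically the sum of the Tp and To equations; integrating all three
  would be redundant and invite drift.
- **Cognitive reserve is multiplicative**: the neurodegeneration-to-
  cognition coupling is λ_CN · N · R. The published parameterization sets
  R = 1 for the low-risk and R = 25 for the high-risk group, and the
  high-risk group declines earlier — which a multiplicative R produces and
  a divisive R would invert.
- **The therapy clearance term is literal**, −δ_Aβ · A_Rx(t), i.e. a
  state-independent sink, because that is the printed form and it
  produces the substantial fall of amyloid from its peak seen in the
  intervention scenario. A state-proportional alternative
  −δ_Aβ · A · A_Rx(t) is available via the config switch
  `degradation_form: proportional`; it instead relaxes amyloid to the
  equilibrium K − δ/λ and gives a much smaller fall from peak.
- **H(0) = 1/2 is implemented and unit-tested** but never influences a
  trajectory: the integration interval is split at the onset age, so the
  step value at the single onset point is never evaluated by the solver.

## Numerics

The system is small and non-stiff. `scipy.integrate.solve_ivp` (adaptive
RK45) integrates it with rtol 1e-8 / atol 1e-10 and dense output sampled
on the caller's age grid (default 0–100 years, 0.1-year spacing);
decoupled cascades agree with the closed-form logistic solution to better
than 1e-6 at every grid point. The span is split at the therapy onset so
the adaptive stepper never meets the discontinuity. Nonnegativity is
enforced three ways: the derivative of a state that is non-positive and
falling is projected to 0 (a depleted level cannot be driven further down
by the state-independent sink — without this the unfloored ODE escapes to
−∞ under strong clearance), output levels are clamped at 0, and the
integration restarts from the clamped state if a level still falls below
−1e-9. States may transiently exceed their carrying capacity because of
the additive forcing terms; no upper clamp is applied.

## Scenarios

Four presets reproduce the published parameter columns exactly
(table-driven test): `early_onset` (A0 = 0.05, λ_Aβ = 0.08, AS = 0),
`late_amyloid_first` (A0 = 0.01, To0 = 0.05, λ_Aβ = 0.12, AS = 1),
`late_tau_first` (λ_Aβ = 0.1, AS = 2), and `late_amyloid_first_rx`
(amyloid-first plus δ_Aβ = 0.04 from age 65). Shared values: λ_τρAβ =
0.025, λ_τρ = 0.05, λ_τoAS = 0.002, λ_N = 0.05, λ_Nτρ = 0.025, λ_Nτo =
0.0075, λ_C = 0.05, λ_CN = 0.001, λ_Cε = 0.001, all K = 1, Ao = ε = 0,
R = 1 / 25. Config files are YAML with a required `schema_version`;
unknown keys are rejected by name.

## Calibration

Carrying capacities are published as K = 1, and the presets ship that
literal value; calibration is an explicit, separate step. It fits
(K_Aβ, K_τρ, K_N, K_C) by bounded trust-region least squares
(`scipy.optimize.least_squares`, bounds [0.1, 10], start = current caps)
so that amyloid, total tau, neurodegeneration, and *high-risk* cognition
(the cognition curve that saturates within the horizon) each reach level 1
at age 100, giving every curve a sigmoidal shape that saturates at the end
of the modeled lifespan. SNAP-tau is calibrated implicitly through total
tau (it has no capacity). One objective evaluation is one simulation run
at the high-risk reserve on a 200-interval grid — accuracy comes from the
integrator tolerances, not the output spacing. Therapy scenarios are
calibrated with the clearance rate set to zero (natural history) and the
capacities then frozen, so the pre-therapy course is untouched by the
later intervention. On the early-onset preset the calibration residual is
~1e-15 and all four targets land within 3e-8 of 1.

## Onset analysis

A biomarker's onset age is the first upward crossing of the detection
level (default 0.15) located by linear interpolation between bracketing
grid points; with the 0.1-year grid the interpolation error is negligible.
Ties (equal onsets to 1e-9) are broken by the hypothesized cascade order
amyloid → tau → neurodegeneration → cognition. A level already above
threshold at the start of the grid is assigned onset at the start age.
Therapy contrasts report the cognitive onset difference, the difference in
least-squares cognitive slope over a 10-year post-onset window
(configurable; the original description of "slope of cognitive decline" is
unquantified), the fractional fall of treated amyloid from its peak, and
the untreated-minus-treated total tau at the end age. The 0.05 minimal
graphed level is a display floor applied only in `plotting`, never in the
dynamics or analysis.

## Synthetic observations and parameter recovery

`fitting.generate_observations` samples the model's own trajectories on a
stated age design and adds independent Gaussian noise truncated at zero
(levels are nonnegative) — the simplest noise model consistent with
normalized biomarker scales, chosen in the absence of any published noise
model. Defaults used in the recovery studies: 21 timepoints (ages 0, 5,
…, 100) and noise sd 0.02 on the level scale, a plausible assay/imaging
reproducibility for normalized biomarkers. The generator emulates clean
dense longitudinal sampling of a single deterministic subject; it does not
model between-subject parameter variation, irregular visit schedules,
missingness, or measurement floors/ceilings, so passing recovery tests
show identifiability of the stated parameter subsets under this design,
not performance on real cohort data.

`fitting.fit_parameters` recovers named free parameters (rates, initial
values, capacities, host factors) by bounded trust-region nonlinear least
squares against the forward model, default bounds (0, 10), start = base
config values. This is a deliberately simple stand-in for full Bayesian
inversion, which is out of scope. Only small subsets are identifiable
from single-cascade data; {λ_Aβ, A0} from amyloid observations alone is
the canonical identifiable pair (noiseless recovery is exact to ~1e-3;
at sd 0.02 both are recovered within 20%). Fitting many rates at once is
permitted but typically ill-conditioned.

## Known limitations

- The original report states no integrator or tolerances, so agreement
  with its figures is property-level (orderings, shapes, saturation), not
  pointwise numeric.
- One quantitative expectation is not met by the model as parameterized:
  the treated-minus-untreated total-tau gap at age 100 in the therapy
  scenario is ≈ 0.13 (literal K = 1; ≈ 0.15 with calibrated capacities),
  not below 0.1. The amyloid forcing term λ_τρAβ · A integrates a ~0.5
  amyloid difference over 35 post-onset years into a tau difference of
  that size; the proportional clearance variant shrinks it but then
  amyloid no longer falls below half its peak. The corresponding
  acceptance test is left failing rather than weakened.
- Comorbidity drivers are constants; there is no molecular/cellular
  mechanism, no spatial or network structure, and no stochastic dynamics.
- Cognition feeds back into nothing, so risk-group pairs share all
  non-cognitive curves exactly (and the test suite relies on this).
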