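# Methods

## Model structure

The package implements a deterministic cohort decision tree for postpartum
hemorrhage (PPH) treatment in sub-Saharan Africa. Every delivery follows a
fixed-order cascade — uterotonic drugs, then uterine balloon tamponade
(UBT), then last-resort surgery — with no re-treatment loops: a case that
fails a step moves down the cascade and never revisits it. The single
exception is deliberate and structural: bleeding *successfully controlled*
by the balloon below the 1000 mL threshold may still cross it later
("rebleed"), and the device already in place is then used at severe-stratum
efficacy. Cases whose balloon *failed* are not re-treated.

The full tree is materialised as a branch table
(`ubt_impact.cascade.branch_table`): a list of terminal paths, each with a
probability (conditional on a delivery in its setting), outcome flags
(severe, resolved-by route, surgery) and a terminal death probability. The
cohort model integrates expected case mass over this table; the
microsimulation oracle draws individual deliveries through the *same*
table. Both engines consuming one table makes structural drift between
them impossible, which is what allows the oracle to serve as an independent
check on the arithmetic (a test asserts the shared table directly).

Counts are real-valued throughout ("fractional people"); rounding to
integers — and, for scenario deltas, to the nearest hundred — happens only
in the reporting layer, mirroring the precision of the published figures.

## Key assumptions

* **Settings.** Home, clinic, hospital, with fixed birth shares
  (50/35/15 %) and PPH rates (12/10/8 %); 90 % of PPH is atonic. The
  balloon is never available at home; uterotonic coverage at home defaults
  to 0 and is overridable in config.
* **Coverage.** Balloon coverage per setting is penetration × utilization
  (0.51 clinic, 0.68 hospital). Uterotonic coverage is matched to the
  balloon's penetration assumption (0.60 clinic, 0.80 hospital), reading
  "availability matched to existing uterotonic use" as equality of
  coverage; uterotonic efficacy stays a calibrated unknown.
* **Severity.** A calibrated fraction π of uterotonic failures is already
  severe at second line. Uncontrolled nonsevere bleeding progresses with
  probability p; controlled bleeding rebleeds with probability q ≤ p. The
  constraint q ≤ p is what makes lives saved monotone in balloon coverage
  and efficacy, and it is enforced in validation, in synthetic sampling
  (rejection) and during optimisation (smooth penalty plus clamping).
* **Surgery.** Last-resort surgery reaches *any* unresolved case — severe
  or persistently bleeding nonsevere — with per-setting access. Restricting
  surgery to the severe stratum is arithmetically incompatible with the
  published outputs: in the nonsevere-only scenario more surgeries are
  averted (10,823) than severe cases (5,287), which is impossible if every
  averted surgery corresponds to an averted severe case. A single surgery
  category is modelled (no hysterectomy/other taxonomy).
* **Mortality.** Unresolved severe cases face the no-surgery or surgical
  case-fatality rate; every other pathway faces a small background rate.
  Deaths from non-atonic PPH (retained placenta, lacerations) enter as one
  additive load converted to a per-case rate; they are identical across
  scenarios and matter only for the percent-reduction denominator, which is
  total baseline PPH mortality.
* **Anemia.** 12 % of severe hemorrhage develops severe anemia. Anemia
  *averted* applies the fraction to severe cases averted (the published
  arithmetic: 5287 × 0.12 ≈ 634); the cascade result separately reports
  anemia among severe survivors.
* **Nonsevere-only scenario.** The balloon is withheld once blood loss
  passes 1000 mL: severe-stratum efficacy is set to zero, the nonsevere
  pathway is untouched, and rebleeding controlled cases consequently lose
  their in-place rescue. This choice preserves baseline behaviour for
  already-severe cases.

## Why the rebleed parameter exists

Without it, the two severity strata are independent and total lives saved
is affine in each efficacy with no interaction. The published outputs then
over-determine the model: lives saved in the base scenario (6547), in the
nonsevere-only scenario (1148), and the ~10 % gain from raising nonsevere
efficacy to 95 % cannot hold together, because independence forces that
gain to 100 × (0.10/0.85) × 1148/6547 ≈ 2 %. The rebleed pathway gives
nonsevere efficacy leverage over severe-stratum deaths *only when
severe-stratum use is permitted*, creating the positive
e_ns × e_sv interaction the numbers require. It is also clinically
plausible: tamponade can control bleeding that later resumes as the balloon
is deflated or displaced. With it, one parameter vector reproduces all
eight published outputs at their printed precision (the joint-feasibility
test).

## Calibration

Eight published outputs constrain eleven hidden scalars, so the inverse
problem is under-determined by design. The objective is the weighted
squared relative error Σ wᵢ((modelᵢ − obsᵢ)/obsᵢ)², minimised by
multi-start bounded least squares (scipy's trust-region reflective solver;
starts are the placeholder defaults, the shipped reference fit, and seeded
uniform draws within bounds; best final objective wins, ties to the
earliest start — bit-identical reruns at a fixed seed).

Weights are 1 except two targets that would otherwise double-count or
over-constrain:

* the ≈800 optimistic/pessimistic delta (weight 10⁻³): printed only to the
  nearest hundred, and structurally tied to the other mortality targets —
  in this cascade it equals (base − nonsevere-only lives)/7, ≈771, already
  inside the ±50 band;
* the 634 anemia count (weight 10⁻²): deterministically 0.12 × the severe
  cases averted target (634.44), so full weight would pull severe cases
  averted off its own ±0.5 band to chase 0.06 of an anemia case.

Target tolerances encode printing precision: 0.5 on integer counts and on
percents, 50 on the nearest-hundred delta. `converged` means every
residual is within its tolerance.

The shipped reference fit (`configs/fitted_params.yaml`) is *a* compatible
point, not a unique solution: uterotonic efficacy ≈ 0.50, π ≈ 0.012,
p ≈ 0.075, q ≈ 0.064, surgical access ≈ 0.018 (clinic) / 0.044 (hospital),
CFR ≈ 0.22 for unresolved severe hemorrhage without surgery and 0.05 with,
non-atonic death load ≈ 1712. Several directions are flat:
`identifiability_scan` re-optimises the remaining parameters along a grid
and flags profiles whose objective range is under 10 % of its minimum
(with a 10⁻¹⁰ absolute floor for numerically-zero optima). Home surgical
access is exactly inert for counterfactual deltas (the balloon never
reaches home births) and is profiled as such in `analysis/02_calibrate.py`.
The holdout check refits the severity/mortality parameters
(π, p, q, CFR, non-atonic load) to the four mortality targets alone from
placeholder starting values — surgical access, uterotonic efficacy and the
surgical CFR stay at the reference — and requires the surgeries-averted
count and the optimistic delta to be predicted within 15 %.

## Synthetic data and the oracle

`sample_params` draws hidden parameters uniformly from the placeholder
defaults ±50 % (clipped to [0, 1]; the ordering constraints enforced by
rejection), wide enough to exercise calibration while staying in
clinically sane territory. `make_problem` records the exact target vector
a draw implies, giving parameter-recovery problems with known answers.

The microsimulation draws each delivery's setting, terminal branch
(categorical over branch probabilities — distribution-identical to the
underlying sequence of binary decisions) and survival, scales counts by
live births / n, and reports binomial standard errors per field.
Total-level standard errors add per-setting variances and are therefore
slightly conservative (multinomial setting counts are negatively
correlated), which only loosens the 3-SE agreement band. Validation runs
use n = 2 × 10⁶ individuals, where key aggregates carry relative standard
errors around 1–2 %; recovery and agreement tests across random parameter
sets use n = 5 × 10⁵ to keep the suite fast. The generator emulates
complete parameter sets and aggregate flows only; it does not emulate
country-level heterogeneity, time trends, measurement error in blood-loss
assessment, or correlations between access parameters — so passing tests
certify the arithmetic and the inverse problem, not the realism of any
single parameter value.

## Numerical choices and degenerate inputs

Probabilities are validated to [0, 1]; setting maps must cover exactly
{home, clinic, hospital}; shares must sum to 1 within 10⁻⁹. A zero-birth
cohort yields all-zero flows. A deathless parameter set yields zero
mortality targets with the percent reduction defined as 0. The non-atonic
death load must not exceed the cohort's non-atonic case count. Flow
conservation (branch probabilities summing to 1 and atonic inflow equalling
terminal outflow) holds to 10⁻⁹ and is asserted property-style over random
parameter sets.

## Known limitations

* The calibrated internals are a compatible set for the published
  aggregates, not estimates of the source framework's actual values; no
  uncertainty is propagated (the published analysis is scenario-based, not
  probabilistic, and the package deliberately mirrors that).
* Surgery is a single category with a single access probability per
  setting; transfer logistics are not modelled.
* Home births never receive the balloon (a conservative published
  assumption); other balloon indications (cesarean, placenta previa or
  accreta, post-abortion care) and costs are out of scope.
* The percent-swap asymmetry of `compare` (the percent is always relative
  to the first argument's deaths) is intentional; all absolute deltas are
  antisymmetric.
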