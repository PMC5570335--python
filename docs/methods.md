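# Methods

This note documents the model, its calibration, the numerical choices,
and the limits of what the test suite demonstrates.

## Model structure

The tibial circulation is a three-segment lumped circuit: popliteal
artery (R_p, C_p), arteriolar bed (R_a(r_a), C_a(r_a)), veins (R_v, C_v),
fed by a constant arterial input pressure P_ai and draining at the
venous output pressure P_vo. Each segment's resistance is split in half
around its mid-pressure node, so the tissue-level (ASL) flow is
Q_v = (P_a − P_v)/((R_a + R_v)/2). The dynamic state has 11 components:
three circuit pressures/radius (P_p, r_a, P_v), four regulatory states
(myogenic, shear, ATP, adenosine), two oxygen tensions (capillary,
tissue) and two metabolite concentrations (intravascular ATP,
interstitial adenosine).

Internal units are mmHg / s / mL / cm / µM throughout; µm, minutes and
litres are converted once at the configuration boundary. Perfusion is
reported in mL/100g/min with muscle density taken as 1 g/mL.

## Baseline calibration

All derived constants are fixed so the resting state is an *exact* fixed
point of the dynamics (verified to ≤1e−10 in every state derivative):

* **Popliteal**: R_p = 8η_b·l_p/(π·r_p⁴) = 0.013 mmHg·min/mL (times a
  stenosis multiple R_p_scale for patients); C_p = τ_p/R_p(standard), so
  stenosis scales the arterial time constant, not the compliance.
* **Veins**: R_v from the 1 mmHg venous drop at the reference flow
  Q_r = 144 mL/min; C_v from R_v·C_v = 10 s.
* **Arterioles**: the power laws R_a = K_R/r_a⁴, V_a = K_V·r_a² are
  anchored at the *group-average resting radius* r_ref — the radius that
  balances the wall tension at the assumed resting mid-arteriolar
  pressure of 50 mmHg with activation A = σ(2·0.45), giving
  r_ref = 64.0 µm — where R_a = ΔP_a/Q_r (ΔP_a = 70 mmHg) and
  R_a·C_a = 1 s. The constant table's 75 µm radius is the *unstressed*
  wall geometry entering the thickness and elastic-tension laws; at
  physiological pressure and partial activation the operating radius
  sits well below it, and anchoring the power laws at the operating
  point is what makes the printed resting values (x_init = 0.45,
  P_a = 50 mmHg, the full pressure ledger) mutually consistent.
* **Arterial input**: P_ai = P_vo + 1 + 70 + Q_r·R_p = 86.88 mmHg, held
  constant; not a printed constant, derived from the resting pressure
  ledger.
* **Subject tone**: the subject's resting flow f_r·V_m is imposed on the
  circuit; this determines the resting radius and pressures, the
  activation A_base follows from the tension balance, and
  x_init = ½·ln(A_base/(1−A_base)). At the group-average resting
  perfusion (4.8 mL/100g/min) this returns x_init = 0.449. The mapping
  is monotone: high-flow subjects have low resting tone. Resting
  perfusions below ≈3 mL/100g/min would require A > 1 (more tension than
  the smooth muscle can generate at that radius) and raise a calibration
  error rather than being clamped.
* **Oxygen/metabolites**: arterial PO₂ = 95 mmHg, resting capillary
  PO₂ = 40 mmHg and resting tissue PO₂ = 30 mmHg (standard resting-muscle
  values; configurable) jointly fix the O₂ extraction, the diffusion
  capacity D and the maximal metabolic rate V_max,m from the subject's
  own baseline perfusion. The myoglobin P50 is 2.39 mmHg (standard human
  value). Baseline ATP is the fixed point of its balance (0.14 µM at
  group-average flow); baseline adenosine is the exact fixed point of
  formation/clearance, 0.10005 µM rather than the nominal 0.1 µM, so the
  calibrated state has zero drift.

The steady circuit is 1 mmHg over-determined as printed (R_a = ΔP_a/Q_r,
P_a = 50 and the half-resistance flow laws cannot all hold exactly); we
resolve it by imposing the flow, which puts the resting mid-arteriolar
pressure at 50.25 mmHg and the resting radius 0.2% above the anchor.

## Cuff convention

Inflating the cuff opens both end switches (Q_ai = Q_vo = 0). The
compliant segments still exchange volume internally — the arteriole
dilates during ischemia by drawing on the stored arterial volume — but
all *transported* quantities see zero flow: oxygen convection, plasma
ATP wash-in/out, and the shear drive (y_sh = −1 exactly). Physically the
cuff collapses the feeding vessels, so no fresh arterial blood reaches
the capillary bed; without this the model's large popliteal compliance
would keep delivering oxygenated blood for minutes (discharge time
constant ≈ C_p·R_a ≈ 150 s) and the smooth muscle would not deactivate
on the observed time scale.

## Regulation sign convention

The activation sigmoid rises with z; the myogenic state enters with
positive sign (tension above baseline → constriction) and shear, ATP and
adenosine with negative sign (accumulation → dilation). This is the only
assignment under which flow interruption causes shear-mediated
*constriction* drive while metabolite accumulation de-activates the
muscle, as required by the ischemic phenomenology the model encodes.

## Numerics

* Integration: LSODA (scipy `solve_ivp`), rtol 1e−7 (1e−6 inside the
  fitting loop), per-state absolute tolerances (1e−11 for the radius,
  which is O(6e−3) in cm). Cuff transitions are integration restarts,
  never discontinuities inside a solver step. The right-hand side is a
  compiled scalar closure (≈5 µs/call) because a fit evaluates it
  ~10⁵–10⁶ times; its agreement with the per-module reference functions
  and with a fixed-step 1 ms RK4 integration (max perfusion difference
  < 0.01 mL/100g/min over a full 2-min-cuff run) is asserted in the
  suite.
* The adenosine formation switch at PO₂ = 10 mmHg is kept discontinuous
  (the "≥" branch as printed); an optional logistic blend of width
  0.1 mmHg exists for solver robustness experiments, off by default.
* The inverse tension solve (radius from pressure) is bracketed Brent on
  [10, 400] µm and raises a calibration error when no root exists. At
  high activation the balance is bistable for r ≈ 127–150 µm (the
  active-tension bump); the inverse solve is only used at calibration,
  where the operating branch is unique.
* Oxygen partial pressures are clamped at zero inside the rate laws so
  fractional Hill powers never see negative arguments; concentrations
  remain non-negative dynamically (rates vanish at zero).

## Fitting

Trust-region-reflective bounded least squares (`scipy.optimize.
least_squares`) on the residuals between simulated and measured
perfusion at the sample times, with multi-start: bound-centre plus
Latin-hypercube points (seeded; best final cost wins). σ² for the
reduced chi-square is the variance of the pre-cuff baseline samples,
pooled across traces for joint fits.

*Healthy schedule* (two steps): step 1 frees [f_r, g_ado, τ_ado, τ_p]
with g_ATP, τ_ATP fixed at the group means (15.66, 15.86 s) against the
3- and 5-min traces; step 2 frees [f_r, g_ATP, τ_ATP] with step-1 values
fixed against the 1- and 2-min traces. *Patient schedule*: one step,
[f_r, g_ATP, τ_ATP, R_p_scale, τ_p] on a single 2-min trace with the
adenosine parameters at the group means. Responses with fewer than four
post-release samples two baseline SDs above the baseline mean are
flagged insufficient (and still fitted).

Identifiability: at the healthy-mean point the ATP influence at release
from a long cuff is ≈ −11, deep in the saturated region of the
activation sigmoid, so g_ATP and τ_ATP act on long-cuff responses almost
solely through the timing of the recovery flank and compensate each
other along a ridge (sensitivity-column cosine ≈ 0.85). This is why the
two-step schedule holds them fixed on long-cuff data instead of
estimating them there; their individual flank sensitivities are *not*
small, so freeing them in step 1 would trade them off against each other
rather than fail loudly. The healthy-recovery harness generates its
truth at the schedule's fixed ATP values (the schedule's consistency
condition); with deliberately mismatched fixed values the mismatch is
absorbed into the adenosine parameters.

At the default noise level, single patient fits move along a
(R_p_scale, τ_p, τ_ATP) likelihood ridge: replicate fits reach
χ²_red ≈ 1 (as good as the noise allows) while individual R_p_scale
estimates scatter by up to ~25%. The recovery checks therefore assert
the replicate median against the truth; χ²_red, itself a ratio of two
noisy estimates (SD ≈ 0.26 at these sample counts), is asserted on the
median and on the bulk of the replicate distribution rather than on
every replicate.

## Synthetic data

`generate_trace` emulates the measured recordings: sampling every
3.35 s, a pre-cuff baseline segment (default 120 s — a typical
pre-inflation acquisition), absent frames during the cuff, 300 s of
recovery, and additive i.i.d. Gaussian noise with default
σ = 0.5 mL/100g/min — representative of whole-calf ROI FAIR ASL at 3 T,
where heavy spatial averaging over the muscle cross-section suppresses
voxel-level noise. An optional linear drift reproduces one of the slow
artefacts seen in real recordings; sudden jumps, motion artefacts and
flow oscillations are *not* modelled. Passing tests on synthetic data
therefore demonstrate correctness of the pipeline under the model's own
noise assumptions (homoscedastic, independent), not robustness to the
full artefact spectrum of measured ASL.

## Known limitations

* Exercise (active) hyperemia is out of scope: capillary recruitment
  changes the diffusion capacity, which is constant here.
* Lactate/H⁺ and other late-ischemia metabolites are not modelled; the
  adenosine two-mode formation law is a deliberate coarse surrogate, and
  long (≫5 min) occlusions are outside the validated regime.
* The simulated hyperemic peaks under healthy-mean parameters are at the
  high end of measured responses, and simulated TTPs are shorter than
  typical measured ones; orderings across durations and lesions — what
  the scenario analyses rely on — are robust to this.
* Single constant P_ai: systemic pressure changes, pulsatility and
  venous valve mechanics are not represented.
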