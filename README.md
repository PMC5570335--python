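# aslrh

Physiological modelling and subject-specific fitting of **arterial spin
labeling (ASL) reactive hyperemia** in calf skeletal muscle.

Post-occlusive reactive hyperemia — the transient overshoot of muscle
perfusion after release of a thigh cuff — is used to probe the
microcirculation in peripheral arterial disease (PAD). Raw peak and
time-to-peak (TTP) readings of the ASL response conflate two very
different lesions: conduit-artery stenosis and microvascular
(endothelial) dysfunction. `aslrh` implements a lumped-parameter
physiological model of the tibial circulation that separates them, plus
the fitting machinery to estimate each subject's parameters from
measured perfusion–time curves.

Intended users: researchers analysing dynamic ASL perfusion of the leg,
and modellers studying ischemia–reperfusion flow regulation.

## The model

Three vascular segments in series (popliteal artery R_p·C_p, arteriolar
bed R_a(r_a)·C_a(r_a), veins R_v·C_v) with the ASL perfusion

    f_ASL = Q_v / V_m = (P_a − P_v) / ((R_a + R_v)/2) / V_m .

Only the arteriolar segment is regulated: R_a = K_R/r_a⁴, V_a = K_V·r_a²,
and the radius obeys Laplace's law

    T = P_a·r_a − P_im·(r_a + h_a) = T_e(r_a) + A·T_m(r_a)

with passive elastic tension T_e, maximal smooth-muscle tension T_m, and
activation A = 1/(1+e^(−2z)). The total regulatory influence

    z = x_init + g_myo·x_myo − g_sh·x_sh − g_ATP·x_ATP − g_ado·x_ado

sums four first-order regulatory states (dx_i/dt = (y_i − x_i)/τ_i)
driven by wall tension (myogenic), wall shear (∝ Q_v/r_a³), intravascular
ATP released by red blood cells at low hemoglobin saturation, and
interstitial adenosine formed when the tissue oxygen tension falls below
the 10 mmHg anaerobic threshold. Oxygen is tracked in two compartments
(capillary, Hill-bound to hemoglobin; tissue, bound to myoglobin) with
Michaelis–Menten muscle consumption. Cuff occlusion opens the circuit's
end switches; the 11-state ODE system is integrated through
baseline → cuff → release and sampled at the ASL repetition time
(3.35 s).

Subject-specific free parameters: resting perfusion f_r, metabolic gains
and time constants (g_ATP, τ_ATP, g_ado, τ_ado), popliteal time constant
τ_p, and (for patients) the popliteal resistance as a multiple of the
Poiseuille standard value (R_p_scale). Fitting is bounded nonlinear
least squares with Latin-hypercube multi-start; goodness of fit is the
reduced chi-square against the baseline-sample variance.

## Worked example

```python
from aslrh import SubjectParams, CuffProtocol, calibrate, simulate, characterize

subject = SubjectParams()            # healthy-group mean parameters
calib = calibrate(subject)
print(f"x_init={calib.x_init:.3f}  A_base={calib.A_base:.3f}  "
      f"r_base={calib.r_base*1e4:.1f} um")

sim = simulate(subject, CuffProtocol(t_cuff=120.0))   # 2-min cuff
peak, ttp = characterize(sim.trace)
print(f"peak={peak:.1f}  ttp={ttp:.1f}")
```

prints

```
x_init=0.411  A_base=0.695  r_base=64.6 um
peak=48.1  ttp=11.2
```

i.e. at this subject's resting perfusion the calibrated arteriolar tone
is x_init = 0.41 (the smooth muscle ~70% activated, resting radius
64.6 µm), and a 2-minute occlusion produces a hyperemic peak of
48 mL/100g/min (about ten-fold baseline) 11 s after release.

The lesion scenarios (`aslrh scenarios --out table.csv` or
`run_scenarios(default_scenarios())`) tabulate peak/TTP for
normal / stenosis (R_p ×2) / dysfunction (g_ATP at 40%) / combined
across 1–5-min cuffs; stenosis lowers the peak and delays it at every
duration, while microvascular dysfunction causes early attenuation that
is far more visible with 2-min than 5-min cuffing (peak deficit 37% vs
3% in the default table) — the model's case for short-occlusion
protocols when the microvasculature is the target.

Synthetic recordings (`generate_trace`, or `aslrh synth`) emulate the
measured data structure — baseline segment, gap during the cuff,
recovery segment at 3.35 s sampling with Gaussian noise — and the
fitting engines (`fit_healthy`, `fit_patient`, or `aslrh fit`) recover
the generating parameters from them.

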