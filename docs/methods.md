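# Methods

## Scope and state representation

The package models plasma lipoprotein metabolism at the level needed to
reason about reverse cholesterol transport (RCT): the dynamics of ApoA-I and
cholesteryl ester (CE), with everything else implicit.  Two HDL species are
distinguished — small lipid-poor ApoA-I and mature spherical α-HDL — plus CE
pools in LDL and VLDL.  Per-particle triglyceride rides along with CE at a
fixed TG/CE volume ratio of 0.13; surface free cholesterol (FC) and
phospholipid are implicit functions of particle size; ApoA-I is assumed to be
60% by weight of the HDL proteome, with the other apolipoproteins co-varying.
CE mass is measured throughout as the equivalent mass of free cholesterol
(molecular weight 386 g/mol), the convention of clinical lipid panels.
IDL is pooled into VLDL.  There is no β-LCAT activity: in consequence the
model under-predicts LDL-CE/VLDL-CE when CETP activity is very low, a known
structural limitation rather than a bug, and those cells are deliberately
absent from the calibration data.

All rate laws are first order in their source pools; the two synthesis terms
(ApoA-I, VLDL-CE) are zero order.  Units: concentrations mg/dL (particles
mmol/dL), rate constants pool/day, fluxes mg/dL/day; whole-body quantities
use a plasma volume of 3.15 L (70 kg adult).

## Geometric submodel

A spherical α-HDL particle of given CE content has core volume
$n_{CE}(v_{CE} + 0.13\,v_{TG})$ ($v_{CE}=1068$ Å³, $v_{TG}=1556$ Å³), core
radius $r$ from the sphere volume, and diameter $d = 2(r + t)$ with surface
thickness $t = 20.2$ Å.  The surface bookkeeping is:

* FC occupies a fixed fraction $f_{FC}$ of the core surface area
  ($n_{FC} = f_{FC}\,4\pi r^2 / a_{FC}$);
* phospholipid covers the rest of the core surface
  ($n_{PL} = (1-f_{FC})\,4\pi r^2 / a_{PL}$, clamped at zero if FC coverage
  would exceed the core area);
* protein covers the hydrophobic annulus by which the outer sphere exceeds
  the covered area, $n_{AA} = (4\pi (r+t)^2 - n_{PL}a_{PL} - n_{FC}a_{FC})
  / a_{AA}$ amino acids, hence
  $n_{ApoA\text{-}I}^{shen} = 0.60\, n_{AA} / 243$.

The difference between the ApoA-I actually on the pool
($A_\alpha / (m_A P)$ per particle) and this requirement, expressed as a
concentration, is the signed excess $X$; with the fast dissociation constant
$k_{diss}$ it forms the remodeling flux that returns excess ApoA-I to the
lipid-poor pool (or, in deficit, recruits it).  Clamping the deficit side to
zero is available as an option (`ModelOptions.clamp_excess`) but is off by
default; with $k_{diss} \approx 170$/day the excess is quasi-equilibrated
either way.

**Surface constants are provisional configuration, not measurements.**  The
defaults $a_{FC} = 38$ Å², $a_{PL} = 62$ Å² are classical lipoprotein
surface cross sections; $a_{AA} = 14.0$ Å² and $f_{FC} = 0.13$ were fixed
once so that (i) particles carry 2–5 ApoA-I over the physiological 7.5–13 nm
range, with the count increasing in size, (ii) the surface FC/PL molar ratio
is ~0.25, and (iii) the nominal-subject steady state reproduces the pooled
calibration observables (HDL-C ≈ 50, ApoA-I ≈ 143, LDL-CE ≈ 77,
VLDL-CE ≈ 5.7 mg/dL).  Tests of the geometric layer are property tests
(monotonicity, scaling, the 2–5 range) rather than point assertions, so
substituting better-sourced constants does not invalidate the suite.
Absolute particle concentrations are roughly half of NMR HDL-P values, a
known scale offset of surface-coverage particle models.

## Particle number balance: fusion

Nascent particles are produced at $k_{ABCA1}A_{lp}/(2 m_A)$ (two ApoA-I per
nascent particle) and removed by holo-uptake $u(d)P$.  A nascent particle
traverses two stages — disc, then sphere — and at each stage it either fuses
with an existing α-HDL particle or escapes; with an encounter-limited
survival probability $1/(1 + k_{fus}P)$ per stage, the fused fraction is
$\varphi = 1 - (1 + k_{fus}P)^{-2}$.  Fusion destroys prospective particles
but conserves ApoA-I and CE mass (they enter the α-pool regardless).  A
single-stage saturating form $k_{fus}P/(1+k_{fus}P)$ was tried first and
rejected: with the shipped $k_{fus} = 5000$ (mmol/dL)⁻¹ it cannot balance
particle production against uptake anywhere near the observed state (it
forces ~3-fold too many, ~25% too small particles and HDL-C ≈ 26 mg/dL).
The two-stage form closes the balance at the same $k_{fus}$.

## Holo-uptake reference size

The uptake law is $u = k_{u0} + k_{u1}(d/10 - d_{ref})$ with
$d_{ref} = 7.5$ nm (the nascent-sphere diameter) and a floor at 0.  With the
shipped estimates ($k_{u0}=0.13$, $k_{u1}=-0.016$) the unshifted form
($d_{ref}=0$) would be negative at physiological sizes; the reference shift
restores positivity while preserving the size sensitivity.  $d_{ref}$ and
the floor are `ModelOptions` fields; set `d_ref_nm=0` for the literal form.

## Steady states

`RctModel.steady_state` integrates 2000 days from a physiological initial
state (LSODA, rtol = atol = 1e-9) and polishes with a Newton root search,
accepting only residuals below 1e-10 relative.  A `fast=True` path starts
the root search directly from a supplied nearby state (used across virtual
populations and warm-started calibration, ~50× faster) and falls back to the
integration path on failure.  Degenerate pools (ABCA1-null, ApoA-I-null)
drive $P \to 0$; below $P = 10^{-12}$ mmol/dL the excess flux is set to 0
and uptake to $k_{u0}$ (the $P\to0$ limit), and the relaxed state is
accepted when its residual is already below 1e-8 relative, since the Newton
polish cannot act on the empty-pool manifold.

## Calibration

The MAP objective is the standard Gaussian form
$J(k) = (g(k)-d)^T C_D^{-1}(g(k)-d) + (k-k_0)^T C_M^{-1}(k-k_0)$ with
diagonal covariances (squared SEMs; squared prior SDs).  The two parameters
without prior information ($k_{u1}$, $k_{fus}$) contribute zero precision —
implemented as an exact zero row, not a large-variance surrogate.  The 15
data residuals comprise 6 HDL cells (HDL-C, ApoA-I × normal / 50% CETP /
0% CETP), 3 ApoB-particle CE pools, 3 CE fluxes, and 3 FCR terms whose
target is the piecewise-linear FCR-versus-(HDL-C/ApoA-I) relation evaluated
at the *predicted* ratio, floored at 0.135 pool/day and weighted by its
±0.065 pool/day band.  The line's slope and intercept are derived from two
anchors: FCR = 1/4.8 pool/day at the normal pooled ratio (the measured
4.8-day residence time) and the floor at the CETP-homozygote pooled ratio;
both are configuration and refittable.

Fitting runs an optional seeded differential-evolution stage inside
prior-derived bounds followed by a trust-region least-squares polish; the
default is the local stage only — the objective is smooth and the priors
informative, so a large global budget buys nothing here (the refit improves
the shipped nominal estimates' objective from 103 to ~34 on the shipped
dataset while staying close to them in parameter space).  Posterior SDs come
from the Fisher information $J^TJ$ of the weighted residual Jacobian
(central differences, relative step 1e-5); confidence sets keep sampled
parameters with $J(k) - J(k_{MAP}) \le \chi^2_{0.95}(\mathrm{df})$,
df = 29 (15 data + 14 informative priors), threshold ≈ 42.56 computed at
run time.

## Tracer kinetics: two conventions

The tracer module simulates a labelled-ApoA-I study by adding a trace dose
to the lipid-poor pool at steady state and following the dose fraction in
the two ApoA-I pools.  Two quantities are exposed because they genuinely
differ in this nonlinear model:

* **sensitivity mode** (default): the complex-step construction — an
  imaginary dose $\varepsilon i$, with the imaginary solution component
  extracted.  Numerically the imaginary part is propagated alongside the
  real trajectory (the derivative callback evaluates the complex-extended
  right-hand side), so the integrator's error control acts on the tracer
  signal; naively integrating with $\varepsilon = 10^{-20}$ leaves the
  imaginary components far below the absolute tolerance and produces
  garbage.  A central finite-difference dose (default 0.5% of the lipid-poor
  pool, ~0.02% of total ApoA-I) reproduces this curve to better than 1e-6
  relative.
* **label mode**: classical radiolabel kinetics — labelled molecules carried
  through the frozen steady-state fluxes (a linear two-pool system: out via
  kidney and holo-uptake, exchange via lipidation and the remodeling flux).
  Its MRT equals total ApoA-I / synthesis rate exactly (turnover identity).

The sensitivity is the derivative of *total* plasma ApoA-I with respect to
the dose, and the model's geometry immediately declares an added increment
of α-ApoA-I "excess", shunting it through the rapidly cleared lipid-poor
pool; size feedback on uptake partly offsets this.  At the nominal estimates
the sensitivity MRT is 4.16 days against a turnover time of 5.04 days, and
the sensitivity decay is strongly biphasic (first-day log-slope ≈ 2.6× the
terminal slope) like measured tracer curves.  Both modes are tested: the
sensitivity against the ~4.2-day observed residence time, the label mode
against the turnover identity.

MRT is computed as the trapezoidal integral over the 28-day default horizon
plus an analytic exponential tail from the terminal log-slope (fitted on the
last fifth of the samples); non-decaying tails are an error.

## Virtual populations and interventions

Subjects are drawn with each of the 16 parameters i.i.d. normal around the
nominal estimate, relative SD 15%, uncorrelated, n = 2000 — the reference
study conditions.  Draws crossing zero are redrawn to preserve sign (at 15%
SD the redraw probability is ~0, so the distribution stays effectively
normal); correlations are Pearson on untransformed values.  Steady-state
failures are recorded, not dropped silently, and a failure rate above 1%
raises.  Interventions multiply the linked parameters (CETP: the three
transfer constants; ABCA1: the lipidation constant; ApoA-I: the synthesis
rate); treatment simulations select on baseline HDL-C and report paired
baseline/treated outputs, with LDL-C responses summarized as mean percent
change across treated subjects.

At these conditions the population reproduces the model's characteristic
correlation structure (RCT–HDL-C strongly positive, ~0.91 here; clearance
weakly negative; HDL-P and size positively correlated with HDL-C), and the
treatment contrast: 80% CETP inhibition raises HDL-C without changing RCT
(and lowers LDL-C ~14%), while ABCA1 doubling raises both along the baseline
RCT–HDL-C relation.  Because the population varies only these 16 parameters
log-symmetrically and independently, it does not emulate real-cohort
features such as correlated lipid phenotypes, assay noise, or non-normal
parameter spread — passing tests show internal consistency of the model
mechanism, not population realism.

## Known limitations

* No β-LCAT, ApoA-II, triglyceride or phospholipid dynamics; no IDL.
* Shen-surface constants are provisional (see above); absolute HDL-P is
  ~2× below NMR scales.
* The RCT–HDL-C population correlation is ~0.91, somewhat below the 0.95
  reported for this class of model; the gap traces to the residual HDL-C
  variance contributed by the CETP-transfer draws and is insensitive to the
  surface-constant choices within their plausible ranges.
* The MAP refit is supported by informative priors; with flat priors the
  16-parameter problem is not fully identifiable from 15 pooled observables
  (the Fisher information's weakest directions are then near-singular).
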