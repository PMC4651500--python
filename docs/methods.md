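# Methods

## The biochemical demand function

Net C3 assimilation follows the FvCB model:
An = Am − Rd, where Am smoothly combines the Rubisco-limited rate
Ac = Vcmax (Cc − Γ*)/(Cc + Km) and the RuBP-regeneration-limited rate
Aj = (J/4)(Cc − Γ*)/(Cc + 2Γ*), with Km = Kc (1 + Oi/Ko). Instead of the
hard minimum, the hyperbolic minimum

    Am = (Ac + Aj − sqrt((Ac+Aj)² − 4 θ Ac Aj)) / (2 θ),   θ = 0.9999

is used, which is continuous in Ci and therefore well behaved inside a
least-squares loop; at θ → 1 it reduces to min(Ac, Aj) exactly. The
discriminant is clamped at zero as a guard against rounding for nearly
equal rates.

Electron transport J responds to PAR through the non-rectangular
hyperbola: J is the smaller root of θJ J² − (αQ + Jmax) J + αQ Jmax = 0
with quantum yield α = 0.24 mol mol⁻¹ and curvature θJ = 0.85. This is
the conventional light-response closure; the choice matters only when
curves are measured at sub-saturating PAR.

### Temperature responses

Every kinetic parameter is defined at 25 °C and scaled with an
Arrhenius-type response. Kc, Ko, Γ* and Rd use the plain form
exp(Ea (Tk − 298.15)/(298.15 R Tk)); Vcmax and Jmax use the peaked
(deactivated) form with deactivation energy Hd and entropy term ΔS, so
both capacities decline at high temperature. Defaults (J mol⁻¹ unless
noted): Ea,Kc 79430; Ea,Ko 36380; Ea,Γ* 37830; Ea,Rd 46390;
Vcmax: Ea 82620.87, Hd 200000, ΔS 645.1013 J mol⁻¹ K⁻¹ (optimum ≈ 36 °C);
Jmax: Ea 39676.89, Hd 200000, ΔS 641.3615 (optimum ≈ 33 °C).
Kinetic constants at 25 °C: Kc 404.9 µmol mol⁻¹, Ko 278.4 mmol mol⁻¹,
Γ* 42.75 µmol mol⁻¹, Oi 210 mmol mol⁻¹. All are overridable per
`BiochemParams`; evaluation at exactly 25 °C returns the reference value
in either form.

### Mesophyll conductance

With finite gm, chloroplastic CO₂ is Cc = Ci − An/gm. Each limitation is
then a quadratic in An (substituting the linear Cc(An) into the
limitation hyperbola), solved in closed form with the physically valid
root (the one with Cc ≤ Ci); the hyperbolic minimum is taken afterwards.
This is exact per limitation and branch-stable, with no iteration. The
smooth minimum introduces a small inconsistency if the combined An is
substituted back (the two limb quadratics each assumed their own rate
drew down Cc); the effect is below ~10⁻³ µmol m⁻² s⁻¹ away from the
transition and bounded by the θ-blending depth (~1%) at it. gm is a
constant per leaf: no dynamic mesophyll-conductance model is attempted.
A large finite gm (10⁶) reproduces the gm-absent path to < 10⁻⁶.

## A-Ci curve fitting

`fit_aci` minimises Σ(An,obs − An,model)² over (Vcmax25, Jmax25, Rd25)
with `scipy.optimize.least_squares`, box-constrained to ≥ 0. By default
the estimates are 25 °C-normalised and the model applies each row's
Tleaf; with `tcorrect=False` the capacity temperature responses are
disabled and the estimates apply at measurement temperature (kinetic
constants still use the row Tleaf). Missing Tleaf defaults to 25 °C and
missing PAR to a saturating 1800 µmol m⁻² s⁻¹.

Starting values are inverted from the data: Vcmax from single-point
inversion of the Rubisco limb on the lowest-Ci points, Jmax from
inversion of the RuBP limb (and the light response) on the highest-Ci
points, Rd from a small positive default (1.5) or the supplied known
value. A multi-start grid scales each starting value by {0.5, 1, 2} (up
to 27 starts), keeps the best SSR and exits early once two further
starts fail to improve the best SSR by more than 1e-10; the data-driven
start is tried first and almost always wins.

Standard errors come from the linearised covariance
s² (JᵀJ)⁻¹ at the optimum (s² = SSR/(n − p)); confidence intervals are
95% t-based on the residual degrees of freedom. Simulation shows the
empirical spread of estimates matches these SEs within a few percent at
realistic noise (SD 0.5 µmol m⁻² s⁻¹). R² is reported as the squared
Pearson correlation of measured versus fitted. Observations are
unweighted. A free-Rd fit requires at least 5 observations (3 parameters
plus 2 residual df).

The Ci transition is found afterwards by Brent root-finding on
Ac(Ci) = Aj(Ci) at the curve-mean Tleaf and PAR; if a limb holds no
observations at the estimates, the corresponding parameter is flagged
unreliable rather than silently dropped. With `citransition` fixed, rows
below the transition fit the Rubisco limb only and rows above the RuBP
limb only (Rd shared), each limb needing ≥ 2 points. Because the free
fit blends the limbs smoothly near the transition while the fixed fit
splits them hard, the two agree to ~1% on Vcmax/Jmax but the small Rd
term absorbs the blending difference (up to ~0.1–0.2 µmol m⁻² s⁻¹).

`fit_acis_batch` fits one curve per group label; a failing group is
reported as its error and never aborts the others.

## Stomatal conductance models

Three variants of gs = g0 + g1 f(env) An/Ca (gs to H₂O, mol m⁻² s⁻¹):

| variant        | form                                   | g1 units |
|----------------|----------------------------------------|----------|
| ball_berry_rh  | g0 + g1 An (RH/100) / Ca               | –        |
| leuning_d0     | g0 + g1 An / (Ca (1 + D/D0))           | –        |
| medlyn_opti    | g0 + 1.6 (1 + g1/√D) An / Ca           | kPa^0.5  |

The 1.6 diffusivity ratio is explicit only in the optimality-based
variant (where the theory fixes it); for the other two any such factor
is conventionally absorbed into the dimensionless g1. The original
Ball-Berry humidity term uses leaf-surface RH approximated by air RH
(boundary-layer-free assumption). Given a fixed D0 every variant is
linear in (g0, g1), so fitting is ordinary least squares (statsmodels),
which directly supplies SEs and t-based 95% CIs; with g0 fixed the
regression runs through the (offset-corrected) origin.

The instantaneous transpiration efficiency of the optimality-based model
with g0 = 0 and perfectly coupled transpiration E = gs D/Pa has the
closed form ITE = Ca Pa / (1.6 (g1 √D + D)) / 1000 in µmol CO₂ per mmol
H₂O (Ca in µmol mol⁻¹; D, Pa in kPa; the 1000 converts mol → mmol). The
coupled solver reproduces this identity to < 10⁻⁶ relative, which pins
down the unit conventions end to end.

## Coupled leaf gas exchange

The operating point solves demand = supply with gs from the stomatal
model, a single root-find in Ci with Brent's method on
[10⁻⁶, Ca] (relative tolerance 10⁻¹²); uniqueness follows from demand
non-decreasing and supply strictly decreasing in Ci. D is floored at
0.05 kPa with a warning (the 1/√D term diverges). Predicted gs is
floored at g0 (and 0). When demand is negative everywhere (e.g. PAR = 0)
the night-time rule applies: gs = g0 and Ci solves supply = demand at
that conductance (Ci then exceeds Ca, the respiring leaf); with g0 = 0
no steady state exists and a flagged `NoSolutionError` is raised.
In non-energy-balance modes transpiration assumes perfect coupling,
E = gs D/Pa, reported in mmol m⁻² s⁻¹.

### Energy balance

`photosyn_eb` computes Tleaf from Rnet = λE + H. E comes from the
Penman–Monteith combination equation
λE = (s Rnet + ρ cp D ga)/(s + γ (1 + ga/gv)), with the esat slope s
evaluated numerically at Tair, γ = cp P/(λ Mw/Ma), and conductances
converted from molar to velocity units at Tair; in the well-coupled
limit (ga → ∞, no radiative term) this reduces exactly to E = gs D/Pa.
Boundary-layer conductances use the forced-convection flat-plate forms
gbH = 0.135 √(u/w), gbW = 0.147 √(u/w) mol m⁻² s⁻¹ (wind u in m s⁻¹,
leaf width w in m), single-sided; sensible heat is H = ρ cp gbH (Tleaf −
Tair). The fixed-point iteration (damping 0.7) stops at |ΔTleaf| < 0.01
°C (max 50, non-convergence flagged on the result); the reported closure
residual is < 0.1 W m⁻² in practice. The stomatal model sees air-based
D throughout (leaf-surface humidity is not iterated). Exact parity with
any particular micrometeorological coefficient set is not claimed — the
energy-closure contract is.

## Stomatal optimality

The objective is An(Ci) − λE(Ci) with gs = 1.6 An/(Ca − Ci) (rearranged
supply) and E = gs D/Pa in mol m⁻² s⁻¹; λ is in mol C mol⁻¹ H₂O, so the
water-cost term is λ E × 10⁶ on the µmol scale of An. Default λ = 0.002
(within the range implied by typical g1 values); the search interval is
[0.01 Ca, 0.999 Ca] (the upper bound excludes the gs singularity at
Ci → Ca), scanned on a 500-point grid and refined by bounded
minimisation between the best point's neighbours (xatol 10⁻⁴ µmol
mol⁻¹). Concavity is never assumed — the grid-first strategy resolves
multi-modal cases — and a maximum on a search bound is flagged
non-interior (λ = 0 makes the objective monotone, so the maximum sits at
the upper bound by construction). At interior optima the first-order
condition dAn/dCi = λ dE/dCi holds to < 0.01%. In energy-balance mode
each candidate Ci closes the leaf energy balance (Penman–Monteith E,
Tleaf iteration); candidates that fail to converge are marked invalid
rather than aborting the search, and with a strong boundary layer the
optimum can legitimately sit on a bound (flagged, run completes).

Over D ∈ [0.5, 3] kPa the implied VPD response of the optimal gs follows
f(D) ≈ 1/√D: at a low marginal water cost (λ = 0.0005, where the
optimum sits high on the demand curve, the regime in which the
optimality–Ball-Berry correspondence is derived) the log-log slope of
the implied (gs Ca/(1.6 An) − 1) against D is ≈ −0.57, checked as a soft
property with a ±0.15 band around −0.5.

## C4 photosynthesis

`aci_c4` implements the enzyme-limited and light-limited quadratics of
the standard C4 model with bundle-sheath leakage conductance gbs:
mesophyll PEP carboxylation Vp = min(Cm Vpmax/(Cm + Kp), Vpr) feeds the
bundle sheath, and the realised rate is the smaller root of a quadratic
coupling Vp, the bundle-sheath Rubisco (or electron-transport) capacity
and leakage. The bundle-sheath O₂-evolution fraction is fixed at zero,
which keeps both quadratics monic. Defaults: Vcmax 60, Vpmax 120,
Vpr 80, Jmax 400 µmol m⁻² s⁻¹, Kp 80 µmol mol⁻¹, Kc 650 µmol mol⁻¹,
Ko 450 mmol mol⁻¹, gbs 0.003 mol m⁻² s⁻¹, x = 0.4, Rm = 0.5 Rd,
γ* = 1.93 × 10⁻⁴; capacities scale with Q10 = 2 from 25 °C. Mesophyll
CO₂ is taken equal to Ci. Simulation only — no C4 fitting is offered.

## Meteorological conversions

Saturation vapour pressure uses the Magnus form
esat = 0.61078 exp(17.269 T/(237.3 + T)) kPa over [−40, 60] °C; RH, VPD
and dewpoint conversions are exact round trips built on it (tested to
10⁻⁹). The empirical field relation D = 0.000605 Tair^2.39 kPa captures
the strong covariance of VPD and temperature and drives the coupled
model's temperature-response demonstration. Conversions ignore the
leaf-to-air temperature difference; leaf-surface humidity belongs to the
energy-balance module.

## Synthetic data

The generators produce the two data shapes the fitters consume, with the
generating truth stored alongside. A-Ci curves: 12 Ci points spanning
40–1500 µmol mol⁻¹ (the usual chamber protocol), An from the demand
function plus additive Gaussian noise on the response only — matching
the NLS error model; Ci itself is treated as error-free, which real
analysers only approximate. Spot gas exchange: a 64-row driver table
spanning PAR 400–1800 µmol m⁻² s⁻¹, Tleaf 15–35 °C, D 0.6–2.4 kPa at
Ca = 400; An from the coupled model under the chosen gs-model truth,
noise added to gs. Default truth magnitudes (Vcmax 47, Jmax 105, Rd 1.3
µmol m⁻² s⁻¹) are typical C3 broadleaf values. What passing round-trip
tests show is that the fitters invert the package's own forward models
correctly at these noise levels; they do not certify against instrument
artefacts (leaks, matching offsets), autocorrelated noise, or Ci
measurement error, none of which are simulated.

## Problem sizes

The verification suite uses desk-scale designs chosen to make each check
statistically meaningful: 50 random truths for noiseless recovery, 200
replicates for SE calibration and CI coverage, 100 random draws for the
coupled-solver contract, a 10⁴-point brute-force grid for the optimality
oracle, and 1 µmol mol⁻¹ resolution for the demand-monotonicity scan.

## Known limitations

- No triose-phosphate-utilisation limitation; the demand function has
  exactly two limbs.
- C4 support is simulation-only and untested against field data.
- Soil water stress, canopy scaling and sun/shade partitioning are out
  of scope; λ and g1 are constants, not functions of soil moisture.
- The energy balance uses single-sided flat-plate conductances and
  air-based D in the stomatal model; radiative feedback on Rnet is not
  modelled (Rnet is an input).
- Profile-likelihood intervals are not offered; all intervals are
  linearised t-based.
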