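# Methods

## Scope and model

`hkafsim` estimates interindividual toxicokinetic variability for
continuous inhalation exposure to volatile organic chemicals by Monte
Carlo simulation of a closed-form steady-state model. It deliberately
omits time-course (dynamic PBPK) behaviour: for lifetime continuous
exposure the steady-state arterial concentration

    CAss = Qp·Ci / (Ql·E_hep + Qp/P_b),   E_hep = Clint/(Clint + Ql)

and the liver-normalized metabolism rate `RAM = CAss·Ql·E_hep/Vl` capture
the dose metrics of interest. The hepatic term is the well-stirred liver
model; the pulmonary term `Qp/P_b` treats exhalation as a clearance
pathway governed by the blood:air partition coefficient. Metabolism is
first-order (`Clint = Vmax/Km`): at the low exposure concentrations
simulated (fractions of a mg/L in blood against Km ≥ 0.1 mg/L) saturable
kinetics would deviate negligibly, and linearity of both dose metrics in
the exposure concentration is an exercised model property.

Interindividual variability enters through five sampled quantities per
person — body weight, hepatic CYP2E1 content, and three dimensionless
variability terms multiplying the allometric equations

    Qp [L/h] = 60·((0.2519·BW^0.7609 + 0.2508·BW^0.7815)/2)·u_qp
    Vl [L]   = 0.05012·BW^0.78·u_vl
    Ql [L/h] = 60·0.92·Vl·u_ql

The allometric expressions evaluate to L/min and are converted to L/h;
this unit reading is locked by the central-adult cross-checks below.
Individual metabolic capacity scales a reference adult's:

    Vmax_ind = Vmax_c·BW_ref^0.75/([CYP2E1]_ref·Vl_ref)·[CYP2E1]_ind·Vl_ind

with constant hepatic microsomal protein concentration across ages.

## Parameters

Chemical constants (per chemical, YAML): `vmax_c` (mg/h/kg^0.75), `km`
(mg/L), `pb` (–), `exposure_conc` (mg/m³). Built-ins: benzene
(2.11, 0.1, 7.4, 0.3) and 1,4-dioxane (0.27, 3.0, 3650, 3); the dioxane
exposure is ten times benzene's, mirroring its roughly tenfold larger
reference dose. Exposure is converted mg/m³ → mg/L at the model boundary;
CAss is reported in µg/L and RAM in µg/h per L liver.

Subpopulation distributions (YAML): body weight and CYP2E1 content are
truncated lognormals; the three variability terms are truncated normals
(1 ± 0.10 on 0.8–1.2 for ventilation, 1 ± 0.14 on 0.66–1.34 for liver
volume, 1 ± 0.13 on 0.67–1.33 for liver blood flow), shared by all seven
subgroups and sampled independently of each other and of body weight (no
correlation structure is imposed, none being reported for these terms).
Adult CYP2E1 is specified geometrically (GM 49, GSD 2, bounds 11–130
pmol/mg microsomal protein); elderly and pregnant women reuse it; the
child groups use arithmetic mean ± SD lognormals reflecting CYP2E1
ontogeny (neonates 18 ± 14 on 1–56, rising through infancy and childhood
toward adult levels).

Pregnant women: the body-weight distribution is that of non-pregnant
women (70 ± 18 kg, 36–152); gestational gain (truncated normal 5 ± 4.4 kg
on 0–14.1) is added per individual. Liver volume and liver blood flow use
the **non-pregnant** weight, while ventilation uses the pregnant weight
**and** a fixed multiplier `qp_scale = 1.25`, the gestation-averaged rise
in alveolar ventilation (tidal volume increases of 20–40% over pregnancy
are standard respiratory physiology). The multiplier is required to
reproduce the elevated pregnant-women dose metrics that make them the
critical subgroup for metabolism-rate-based factors; weight gain alone
raises ventilation only ~5%.

Reference adult: BW_ref = 76 kg (adult arithmetic mean), Vl_ref the
allometric volume at that weight with unit variability (≈1.47 L), and
[CYP2E1]_ref the **arithmetic** mean of the untruncated adult lognormal
(GM·exp(ln²GSD/2) ≈ 62.3 pmol/mg). The arithmetic reading is the one
consistent with the intended flow-limited/enzyme-limited contrast — it
places the central intrinsic clearance near 400 L/h (benzene) and 1.7 L/h
(1,4-dioxane) and the central adult blood benzene level near 1 µg/L; the
geometric reading does not, and is rejected by the interpretation-lock
tests.

Demography: the Canadian-census profile fixes subgroup counts per 100,000
(adults 63,923; neonates 93; infants 1,015; toddlers 3,322;
children/adolescents 15,866; elderly 13,662; pregnant women 2,119).
Other totals are apportioned by largest-remainder rounding (deterministic,
sum-preserving, minimum one individual per subgroup). The "younger
population" variant triples every under-18 subgroup and pregnant women,
keeps the elderly, and lets adults absorb the difference, bringing the
under-18 share above 60%.

## Sampling and numerical choices

- Arithmetic mean/SD lognormals are converted by exact moment matching
  (σ² = ln(1+(SD/m)²), µ = ln m − σ²/2); conversion precedes truncation.
- Truncation bounds are enforced by rejection sampling, not clipping —
  clipping would deposit probability atoms on the bounds. Intervals
  holding < 1e-4 of the distribution's mass raise an error (checked
  analytically via the normal CDF) rather than looping.
- Draw order within a cohort is fixed (weight, CYP2E1, gain, three
  variability terms), and each subpopulation draws from a stream
  sub-seeded by `(master seed, CRC32(subpopulation name))`, so one
  subgroup's draws are invariant to the presence, order or size of other
  subgroups, and any stratum of a merged population is bit-identical to
  the directly simulated subgroup.
- Percentiles use linear interpolation between closest order statistics
  (`numpy` "linear"); the original software's estimator is unknown, and
  the comparison tolerances absorb the difference.
- Coverage counts strictly-below ("lower than") values; ties are not
  covered.
- Mass balance (`RAM·Vl = CAss·Ql·E_hep`) holds to 1e-10 relative
  tolerance for every simulated individual, and `E_hep ∈ [0, 1)` always.

## What the generator emulates — and what it does not

The virtual population reproduces the *marginal* physiological
distributions and census weights of the target demography. It does not
model parameter correlations (beyond allometry in body weight), gender,
ethnicity, CYP2E1 polymorphism, disease states, within-lifetime aging, or
microsomal-protein variability. Passing tests therefore demonstrate
faithful propagation of the stated population variability through the
steady-state model — not that real populations have these marginals.

## Known limitations

- Summary statistics dominated by distribution *tails* are sensitive to
  parameterization conventions the source tables do not fix (truncation
  handling, moment conventions, percentile estimators). In this
  implementation the poorly cleared chemical's blood-level upper tail
  runs somewhat wide and its metabolism-rate spread somewhat thin
  relative to the published tables, which shifts tail-based factors and
  neonate coverage by roughly 5–15% while central tendencies and the
  flow-/enzyme-limited contrast are reproduced. The acceptance suite
  quantifies this at study scale.
- The pregnancy ventilation multiplier is a fixed gestation-average; no
  gestational-age profile is modelled.
- Steady state only: peak-to-trough dynamics under intermittent exposure
  are out of scope, as are toxicodynamics, reference-concentration
  derivation and any chemical-specific regulatory conclusion.
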