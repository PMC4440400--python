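# Methods

## The model

Chemolithoautotrophic sulfur-oxidizing bacteria (SOB) oxidize a reduced
sulfur substrate (here sulfide or thiosulfate) and spend the electrons on two
sinks: reduction of a terminal electron acceptor (TEA — O2, or nitrate via
denitrification or DNRA), which generates energy, and reduction of CO2 to
biomass. Two parameters fully determine the overall stoichiometry:

* **x** — the fraction of oxidized sulfur atoms ending as zero-valent sulfur
  (S0) rather than sulfate. `x < 0` describes net co-oxidation of previously
  stored S0 (as observed in tubeworm symbionts); the implementation allows
  `x >= -10` with a warning below −2, values beyond which have no chemical
  reading.
* **y** — the fraction of the reduced-sulfur electron pool routed to the
  TEA; `1 - y` reduces CO2.

The electron yield per mole of substrate is `e(x) = 8 - 6x` for sulfide and
`e(x) = 8 - 12x` for thiosulfate (with x defined per sulfur atom, admissible
`0 <= x < 2/3`; the thiosulfate and DNRA generalizations are our own
re-derivations by element/charge/electron balance, since only the sulfide
forms are published in full). The TEA coefficient is `y·e(x)/n_e` with
`n_e = 4 (O2), 5 (NO3→N2), 8 (NO3→NH4)`, and the CO2 coefficient is
`(1-y)·e(x)/4` (four electrons per CO2 reduced to the CH2O level). All
reaction builders close the hydrogen/oxygen balance with H2O and H+ and are
verified to balance every element and the charge to 1e-9.

Given two measured rate ratios (TEA:substrate and CO2:substrate), (x, y)
follow in closed form: `e(x) = n_e·r_TEA + 4·r_CO2` is linear in x and
`y = n_e·r_TEA / e(x)`. For symbiotic systems the whole-animal rates are
first corrected for host respiration (symbiont O2 = (1−f)·whole O2; symbiont
CO2 = whole CO2 + RQ·f·whole O2).

## Thermodynamics

Reaction free energies are Σ ν_i ΔGf°′_i + RT ln Q per mole of substrate.
The formation energies (data/thermo_table.tsv) are pH-7 biochemical standard
values after Thauer et al. (1977), with three deliberate choices:

* **O2, CO2 and N2 are priced as dissolved species** (+16.4, −386.02,
  +18.18 kJ/mol). The dissolved-O2 choice is what makes the complete sulfide
  oxidation come out at −829 rather than −796 kJ/mol.
* **Biomass carbon (CH2O) is one sixth of glucose** (−152.87 kJ/mol); this
  reproduces the net CO2-reduction requirement of ~145 kJ/mol, which
  formaldehyde does not.
* **Thiosulfate is calibrated, not tabulated.** Thauer's −513.4 kJ/mol
  yields a traditional efficiency of 0.0266 for the reference aerobic
  thiosulfate oxidizer (*T. versutus*, y = 0.844) where 0.0290 is the
  published value. We therefore calibrate ΔGf°′(S2O3²⁻) = −523.2 kJ/mol
  against that single row; with this one entry *all* thiosulfate rows of the
  compilation (aerobic and denitrifying, Calvin and rTCA) are reproduced to
  better than 0.4 percentage points. The calibration is visible in the data
  file and can be overridden with any user-supplied table.

H+ is priced at its pH-7 value (−39.87 kJ/mol), so the reaction quotient
uses the proton activity *relative to 1e-7*, i.e. `10^-(pH-7)`. Taking the
quotient's [H+] literally would double-count the pH-7 convention already
embedded in the formation energies; with our convention ΔG_r = ΔG°'_r holds
exactly at 1 M / pH 7 / 298.15 K. Activities equal concentrations (no ionic
strength model); S0 (solid), H2O (solvent) and CH2O (biomass) carry activity
1. Temperature enters only through RT ln Q — the formation energies are not
van-'t-Hoff corrected, so temperature sweeps far from 25 °C are indicative
only. Redox carriers are priced by the reduced-minus-oxidized increments
(NADH 60.99, FADH2 42.65, Fd_red 38.88 kJ/mol) and only the pool *ratios*
matter in quotients.

## Efficiencies

* Traditional: `eps_I = (1-y)·ΔGr(CO2 red) / (−y·ΔGr(TEA red))`, using the
  net assimilation reaction.
* Carrier-resolved: `eps_II = (1-y)·[ΔGr(RET) + ΔGr(CO2 fix)] /
  (−y·ΔGr(TEA red))`. The reverse-electron-transport (RET) reaction reduces
  the carbon pathway's carrier mix (Calvin: all electrons via NADH; rTCA:
  6/12 NADH, 4/12 Fd, 2/12 FADH2), and ΔGr(CO2 fix) is the pathway's
  requirement per CO2 (Calvin 69.7, rTCA 64.3 kJ/mol) scaled by `e(x)/4`
  CO2 per substrate. eps_II > eps_I always, because the two-step route
  carries a larger theoretical requirement than the net reaction.
* Factorization: with ATP at 41 kJ/mol the pathway ATP costs (3 ATP/CO2
  Calvin → 123 kJ; 5/3 ATP/CO2 rTCA → 68.33 kJ) give the known constants
  eps_CO2 = 0.57 and 0.94. The identifiable minima are
  `eps_SO,min = eps_t,min = (1-y)·[ΔGr(RET) + ΔEr(CO2 fix)] /
  (−y·ΔGr(TEA red))` — equivalently `eps_II·(α/eps_CO2 + 1 − α)` with
  `α = ΔGr(CO2 fix)/[ΔGr(RET)+ΔGr(CO2 fix)]` — and eps_RET,min solves the
  factorized product with the other partials at 1. The individual eps_SO,
  eps_RET, eps_t are *not* resolvable and are not reported.
* The CO2:TEA yield is `(1-y)/y · n_e/4`. For denitrification this carries
  the factor 5/4; the published compilation's CO2:TEA column confirms this
  scaling on every denitrifying row.

## Inverse problems

`solve_constrained` recovers (x, y) from a single TEA:substrate ratio plus a
constraint: constant eps_II, constant CO2:TEA, or eps_II linear in x.
y is eliminated analytically (`y(x) = ratio·n_e/e(x)`); the residual in x is
pre-scanned on 64 subintervals of the admissible domain and each sign change
refined by Brent's method to 1e-10. Multiple roots return the smallest x
with a warning; the constant-yield constraint is solved in closed form.
`co2_tea_curve` exploits that `(1-y)/y = eps·|ΔG_energy|/ΔG_demand` to
evaluate constant- or linear-efficiency yield curves without root finding.
The "environmental" conditions preset (all dissolved reactants 1 mM, pH 7)
flattens these curves relative to standard conditions.

For the yield-curve robustness check we evaluate four strain
configurations — two aerobic sulfide oxidizers with the Calvin cycle
(y = 0.808, 0.859) and two denitrifiers with the rTCA cycle (y = 0.852,
0.902). The x ∈ [0, 1] domain of the check only exists for sulfide, so the
denitrifying pair is evaluated as sulfide oxidation coupled to nitrate
reduction; under a constant-eps_II assumption the CO2:TEA curves then vary
by 17.7 % (aerobic/Calvin) and 19.6 % (denitrifying/rTCA) over the full
range of x — under the "less than ~20 %" bound that motivates using either
constraint interchangeably.

## Sensitivity

`scan` sweeps one concentration (or pH, or temperature) with (x, y) held
fixed; responses are monotone because each species enters RT ln Q with a
fixed-sign coefficient. "Changes by ~N %" is defined as
|eps(10⁻³·standard) − eps(standard)|/eps(standard); which endpoint of a
three-order range is meant is ambiguous in the source material, so the
dilution side is used and documented here. pH sweeps move [H+] in all
quotients simultaneously; carrier scans move one pool (only ratios enter Q).
`equalizing_shift` root-finds (to 1e-6 in log10 space, after a 121-point
pre-scan that skips thermodynamically undefined regions) the fold-change in
one concentration that levels two strains' efficiencies. For the aerobic
sulfide pair (y = 0.808 vs 0.859) our table gives ~10⁻⁷ in [SO4²⁻] (or
pH ≈ 10.5) for eps_I and ~10⁻¹⁹ for eps_SO,II,min; the published summary
quotes ~10⁶-fold and ~10²⁰-fold read off a figure, the same order-of-
magnitude contrast that motivates the robustness claim. Tests assert the
order-of-magnitude bands and the invariant that the eps_SO,min shift is
vastly larger than the eps_I shift.

## Flux interpretation

For steady-state mats (x = 0 by premise; non-steady systems belong to the
inverse module), the SOB consume 2y O2 per sulfide, so the heterotrophic O2
share of an observed O2:ΣH2S ratio is `observed − 2y` and the recycled
fraction of SOB biomass is `(observed − 2y)/(2(1−y))`: 1 at an observed
ratio of exactly 2 (independently of y), below 1 organic-carbon export,
above 1 import of external reductant.

## Synthetic rates

`generate_synthetic_rates` emits the overall-equation coefficients scaled by
a substrate consumption rate, each multiplied by mean-one lognormal noise
(σ² = ln(1+cv²)) — emulating multiplicative measurement error of
microsensor/bottle incubation rate estimates. It does not emulate correlated
errors, instrument drift, or transport limitation, so round-trip tests show
estimator correctness under idealized noise, not field accuracy. Default
validation uses cv = 5 % and 200 replicates under a fixed seed, checking
that the recovered x is unbiased within two standard errors (the ratio-of-
lognormals bias is quadratic in cv and negligible at this level).

## Numerical choices and limitations

* Balance residual tolerance 1e-9; round-trip identity to 1e-12; inverse
  solver tolerance 1e-10 in x.
* Display rounding is two decimals (percent) for the regenerated strain
  table; all internal math is full precision. Recomputed efficiencies agree
  with the published compilation to ≤ 0.15 pp on every sulfide row and
  ≤ 0.4 pp on thiosulfate rows (after the thermo calibration above).
* y = 1 returns efficiency 0 (well-defined limit); y = 0 raises.
* Efficiencies are only defined where the energy reaction is exergonic and
  the demand side endergonic at the evaluated conditions; violations raise
  with both ΔG values in the message.
* No kinetics, transport or intermediate sulfur chemistry (polysulfides,
  tetrathionate); the framework is purely stoichiometric/thermodynamic.
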