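# sulfurox

Stoichiometry and energy-conservation efficiency of chemolithoautotrophic
sulfur oxidation coupled to CO2 fixation.

Sulfur-oxidizing bacteria (SOB) — mat-forming *Beggiatoa*, vent symbionts,
*Sulfurimonas* and their relatives — gain energy by oxidizing sulfide or
thiosulfate with O2 or nitrate and spend part of it fixing CO2. Their
overall activity is captured by two parameters: **x**, the fraction of
oxidized sulfur ending as zero-valent sulfur instead of sulfate (negative
when stored S⁰ is co-oxidized), and **y**, the fraction of the
reduced-sulfur electron pool routed to the terminal electron acceptor (TEA)
rather than to CO2. `sulfurox` is written for microbial ecologists and
biogeochemists who want to turn a handful of rate measurements into a full
balanced reaction, a growth yield, and a thermodynamic efficiency — and back.

The package builds the generalized balanced equations for any substrate
(sulfide, thiosulfate) × TEA process (aerobic, denitrification, DNRA) ×
CO2-fixation pathway (Calvin, rTCA), evaluates their Gibbs free energies
(ΔG_r = ΔG°′_r + RT ln Q, per mole substrate) and computes two efficiencies:

* the traditional ε_I = (1−y)·ΔG_r(CO2 red) / (−y·ΔG_r(TEA red)), and
* the carrier-resolved ε_II = (1−y)·[ΔG_r(RET) + ΔG_r(CO2 fix)] /
  (−y·ΔG_r(TEA red)), which separates reverse electron transport (RET) from
  the fixation pathway's own requirement and factorizes into partial
  efficiencies with identifiable minima (ε_SO,II,min in particular).

It also solves the inverse problems: (x, y) from two rate ratios; (x, y)
from *one* ratio plus a constant-efficiency or constant-yield assumption;
efficiency bands implied by fluctuating environmental O2:ΣH2S supply
ratios; sensitivity of all of the above to concentrations and pH; and the
interpretation of community-level O2:ΣH2S flux ratios in terms of internal
carbon recycling.

## Worked example

The classic chemostat experiment on a marine *Beggiatoa* strain measured an
O2:ΣH2S consumption ratio of 1.65 and a CO2:ΣH2S ratio of 0.35:

```python
import sulfurox as sx

x, y, eq = sx.solve_xy(sx.RateSet(ratios={"O2:H2S": 1.65, "CO2:H2S": 0.35}),
                       "sulfide", "aerobic")
print(x, y)
print(eq.to_text())
b = sx.factorize(x, y, "sulfide", "aerobic", "calvin")
print(f"eps_I = {b.epsilon_I:.4f}  eps_II = {100*b.epsilon_II:.2f}%  "
      f"eps_SO,min = {100*b.epsilon_so_min:.2f}%")
```

prints

```
0.0 0.825
H2S + 1.65 O2 + 0.35 CO2 + 0.35 H2O -> SO4^2- + 2 H+ + 0.35 CH2O
eps_I = 0.0369  eps_II = 9.62%  eps_SO,min = 12.35%
```

i.e. the strain oxidized sulfide completely to sulfate (x = 0), used 82.5 %
of it for energy generation, conserved 3.7 % of the released free energy by
the traditional measure, and its sulfur-oxidation pathway converts at least
12.3 % of that energy into ATP once the Calvin cycle's own requirements are
accounted for.

Suppose a later experiment on the same strain finds O2:ΣH2S = 0.5. Assuming
its ε_II is a property of the organism (independent of x):

```python
eps = sx.efficiency_new(0.0, 0.825, "sulfide", "aerobic", "calvin")
x, y, eq = sx.solve_constrained("O2:H2S", 0.5,
                                sx.Constraint("constant_efficiency", eps),
                                "sulfide", "aerobic", "calvin")
print(f"x = {x:.3f}, y = {y:.3f}")
print(eq.to_text())
```

```
x = 0.920, y = 0.807
H2S + 0.5 O2 + 0.119548 CO2 -> 0.920301 S0 + 0.079699 SO4^2- + 0.800753 H2O + 0.159398 H+ + 0.119548 CH2O
```

— the strain must now be producing almost exclusively S⁰. The same CLI:

```sh
sulfurox solve-xy --ratio O2:H2S=1.65 --ratio CO2:H2S=0.35
sulfurox efficiency -x 0 -y 0.825 --pathway calvin
sulfurox table1          # regenerate the full strain compilation
sulfurox interpret --y 0.825 --ratio 2.0
```

All thermodynamic constants live in a plain-text table
(`src/sulfurox/data/thermo_table.tsv`, overridable via `--thermo-table`);
see `docs/methods.md` for the conventions (dissolved gases, pH-7 proton
pricing, biomass as glucose/6, the calibrated thiosulfate entry) and the
model's limitations.

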