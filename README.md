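# nephroflux

Steady-state, sex- and species-specific models of water and solute
transport along rat and mouse nephrons.

Renal transporters — NHE3 in the proximal tubule, NKCC2 in the thick
ascending limb, NCC in the distal convoluted tubule, ENaC in the
collecting system, with the basolateral Na⁺-K⁺-ATPase driving them all —
are expressed in markedly different patterns in male and female rats and
mice. `nephroflux` is a computational tool for asking what those
differences *do*: it solves epithelial-cell-based transport models of
whole kidneys for the four sex/species combinations and compares their
segmental deliveries, urinary excretions and responses to perturbations
such as an acute saline load. Its audience is renal physiologists and
modellers who want a mechanistic bridge between transporter-abundance
data (immunoblots, micropuncture) and kidney-level function.

## The model

Each nephron segment is a tubule lined by epithelial cells. At every
axial station a cross-section couples the lumen, one or two cell types,
the lateral interspace and the peritubular bath. Transmembrane water
flow follows osmotic and hydrostatic driving,

$$J_{v,ab} = A_{ab} L_{p,ab}\,(\sigma_{ab}\,\Delta\pi_{ab} + \Delta P_{ab}),
\qquad \Delta\pi_{ab} = RT\sum_k \Delta C_{k,ab},$$

and the flux of each of the 15 solutes (Na⁺, K⁺, Cl⁻, the CO₂/HCO₃⁻
system, NH₃/NH₄⁺, phosphate, formate, H⁺, urea, glucose) is the sum of
convection, electrodiffusion, coupled transport and primary active
transport,

$$J_{k,ab} = (1-\sigma_{k,ab})\,\bar C_{k,ab} J_{v,ab}
 + J^{\mathrm{ED}}_{k,ab} + J^{\mathrm{coupled}}_{k,ab}
 + J^{\mathrm{ATP}}_{k,ab},$$

with ion electrodiffusion given by the Goldman–Hodgkin–Katz equation
$J = h\zeta\,(C_a - C_b e^{-\zeta})/(1-e^{-\zeta})$, $\zeta = zF\Delta V/RT$.
Steady state enforces volume and solute conservation in each interior
compartment, buffer mass action (CO₂ hydration finite-rate in cells),
electroneutrality, and open-circuit (zero net current) conditions that
set the membrane and luminal potentials.

Along the lumen, volume and solute flows obey
$d(\omega_i Q_i)/dx = -\,\omega_i\, 2\pi r_i \hat J_{v,L}$ (and the
analogue for solutes) with Poiseuille pressure
$dP/dx = -8\mu Q/(\pi r^4)$. Proximal tubules are compliant, and their
transport is scaled by the microvillous-torque factor
$S_{\mathrm{torq}} = 1 + s(\tau/\tau_0 - 1)$ — flow-activated transport
that produces glomerulotubular balance. Connecting tubules and
inner-medullary collecting ducts coalesce: the remaining tubule
fraction is $\omega_{CNT}(x) = 2 - 2.32^{x/L}$ and
$\omega_{IMCD}(x) = 0.1\,(1 - 0.95 (x/L)^2)\,e^{-2.75 x/L}$.

A kidney is six nephron classes — one superficial, five juxtamedullary
with loops reaching 1–5 mm into the inner medulla — whose connecting
tubules merge into a shared collecting duct; per-kidney totals scale by
36,000 nephrons (rat) or 12,000 (mouse). The female-rat, male-mouse and
female-mouse parameter sets are derived from the packaged male-rat base
by a table of relative differences (SNGFR, tubule dimensions,
transporter activities, water and paracellular permeabilities), applied
multiplicatively by a delta engine that records provenance.

## Worked example

```python
import nephroflux as nf

toy = nf.build_toy_fixture()          # miniature kidney for fast runs
base = nf.run_baseline(toy)
print(base.fractional.round(1))

sal = nf.run_saline_load(toy, base)
print("saline urine flow / baseline:",
      round(sal.solution.urine_flow / base.solution.urine_flow, 2))
print("omega_imcd(0):", nf.omega_imcd(0.0, 0.5))
print("invert_delta(-0.32):", round(nf.invert_delta(-0.32), 4))
print("excretion_ratio(47, 54, 'rat'):",
      round(nf.excretion_ratio(47, 54, "rat"), 2))
```

prints

```
       volume    Na+     K+    Cl-  HCO3-   NH4+
PT      100.0  100.0  100.0  100.0  100.0  100.0
DL       62.0   74.6   90.3   88.0   13.0  239.3
mTAL     56.0   74.3   90.2   87.7   12.8  239.5
DCT      56.5   63.2   13.5   70.7   13.6    1.0
CNT      56.6   61.5   21.0   69.1   13.6   12.0
CCD      57.4   60.7   21.8   68.1   13.5   22.6
urine    37.5   58.8   30.6   66.6   12.2   60.9

saline urine flow / baseline: 1.85
omega_imcd(0): 0.1
invert_delta(-0.32): 0.4706
excretion_ratio(47, 54, 'rat'): 1.74
```

Each row is the delivery of fluid and key solutes to a segment inlet as
a percent of the filtered load (PT proximal tubule, DL descending limb,
mTAL medullary thick ascending limb, DCT distal convoluted tubule, CNT
connecting tubule, CCD cortical collecting duct; the last row is urine).
Reading down a column shows where each species is reabsorbed or, for
K⁺ in the connecting tubule and NH₄⁺ in the proximal tubule, secreted.
The toy fixture is deliberately small (short tubules, three nephron
classes), so its fractional excretions are far larger than a real
kidney's; the full models (`nf.build_model("rat", "male")` etc.) excrete
about 1–3% of filtered Na⁺ and water. The saline-load ratio shows the
expected diuresis; the last three lines are the coalescence fraction at
the inner-medulla entrance, the activity increase that undoes a 32%
reduction, and the weight-normalised female-to-male Na⁺ excretion ratio
for rats.

A CLI wraps the same protocols:

```sh
nephroflux simulate --species mouse --sex female --protocol baseline --toy --out out/
```

## Layout

- `src/nephroflux/solutes.py` — 15-solute chemistry, buffers, speciation
- `src/nephroflux/fluxes.py` — flux laws and transporter kinetics
- `src/nephroflux/epithelium.py` — cross-section steady-state solver
- `src/nephroflux/network.py` — axial integration, coalescence, kidney assembly
- `src/nephroflux/parameters.py` — parameter sets, delta engine, toy fixture
- `src/nephroflux/experiments.py` — baseline / saline / swap protocols
- `src/nephroflux/data/` — base male-rat set and the three delta tables
- `docs/methods.md` — model description, assumptions and numerical choices
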