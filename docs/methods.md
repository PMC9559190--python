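# Methods

## Scope and structure

`nephroflux` computes steady-state water and solute transport along the
nephrons of rat and mouse kidneys, separately for males and females. A
kidney is represented by six nephron classes — a superficial nephron
(SF) whose loop turns at the outer–inner medullary boundary, and five
juxtamedullary classes (JM-1…JM-5) with long loops reaching 1–5 mm into
the inner medulla — in population ratios 2/3 : 0.4/3 : 0.3/3 : 0.15/3 :
0.1/3 : 0.05/3 for the rat. For the mouse the superficial share is 0.82
and the juxtamedullary sub-fractions are read as fractions of the
remaining pool, so the weights sum to one. Juxtamedullary single-nephron
GFR exceeds superficial SNGFR by 45% in the rat (midpoint of the
reported 40–50% range) and by 20% in the mouse. Per-kidney totals scale
by 36,000 (rat) or 12,000 (mouse) nephrons. The connecting tubules
coalesce into a cortical collecting duct chain (CCD → OMCD → IMCD)
shared by all classes; the IMCD outlet is urine.

Segments in flow order: PCT, S3, SDL, (LDL, LAL for juxtamedullary
classes), mTAL, cTAL, early and late DCT, CNT, then the collecting-duct
chain. The proximal tubule is compliant and torque-modulated; CNT and
IMCD coalesce; CNT, CCD and OMCD cross-sections carry principal and
intercalated cells in parallel (area fractions ~0.7/0.3, configuration).

## Cross-section model

Unknowns per interior compartment: 15 log-concentrations, electrical
potential, and a closure variable; plus the luminal potential. The
equations are

* solute conservation per reaction-conserved group (Na, K, Cl, urea,
  glucose, total phosphate, total ammonia, total formate, CO2 and total
  bicarbonate);
* buffer mass action (phosphate pK 6.80, ammonium 9.15, formate 3.76,
  carbonic acid 3.57); CO2 hydration is finite-rate inside cells
  (kh = 0.145 s⁻¹, kd = 49.6 s⁻¹, multiplied by a configurable carbonic
  anhydrase factor) and at equilibrium in the interspace;
* electroneutrality, which closes the free-proton balance (H⁺ is
  carried as a free concentration; pH is derived);
* zero net ionic current into each interior compartment and out of the
  lumen (open-circuit conditions fixing the potentials);
* volume conservation.

The volume closure deserves a note. Cell volume and pressure are held at
reference and each cell carries an osmoregulated pool of neutral
impermeant osmolytes; because every membrane water flux is linear in
that pool, the pool that balances the cell's water throughput has a
closed form and is substituted analytically, making cell volume
conservation hold identically at every solver iterate. Dynamic-volume
closures (cell volume or pressure as the Newton unknown) were found to
produce a soft, nearly singular direction coupling volume, potential and
osmolyte content that is numerically hostile at full pump activity; the
analytic elimination removes it without changing the steady state. The
interspace closure is its hydrostatic pressure. A compartment with no
pathway for some solute group, for water, or for charge has the
corresponding balance replaced by a pin to the bath value (structural
degeneracy detection), and every cell membrane carries a small
phosphate leak (2×10⁻⁷ cm/s) so that a pool served only by a reversible
cotransporter cannot drift along its equilibrium manifold.

Transporter kinetics: cotransporters and exchangers default to the
linear nonequilibrium-thermodynamic form (turnover = activity ×
stoichiometry-weighted electrochemical gradient, with optional
Michaelis factors); NHE3 uses a saturable alternating-access carrier
form whose turnover is bounded by its activity, with NH₄⁺ substituting
for H⁺ in a parallel mode (weight 0.15). NKCC2 runs a parallel mode
with NH₄⁺ substituting for K⁺ (weight 0.2). The carrier form matters:
with purely linear kinetics a model with reduced NHE3 activity
compensates through gradient growth, and the characteristic sex/species
separation of proximal deliveries is largely erased. ATPases use Hill
kinetics — Na⁺-K⁺-ATPase: activity × (C_Na/(C_Na+K_Na))³ ×
(C_K/(C_K+K_K))², 3 Na⁺ out : 2 K⁺ in, with K_Na raised by external K⁺
(scale 8.33 mM); H⁺-K⁺-ATPase: 1 H⁺ for 1 K⁺ driven by luminal K⁺.
Channels (ENaC, apical K⁺) add to the passive GHK permeability. The
proximal tubule additionally carries the Cl⁻/formate exchanger with
formic-acid recycling (high apical H₂CO₂ permeability), the canonical
route by which apical Na⁺/H⁺ exchange drives net NaCl uptake.

## Axial integration

The marched variables are the conserved luminal flows: ω-scaled volume
flow and the ten conserved group flows, plus pressure. Stations advance
with an implicit scheme — backward Euler on the first interval, BDF2
afterwards — in which the luminal state (15 log-concentrations, log
flow, pressure) and the full epithelial cross-section are solved as one
coupled nonlinear system per station. Implicitness is essential: with
physiological permeabilities the luminal relaxation lengths of CO₂, NH₃
and water are far below any practical grid spacing, and explicit
schemes are violently unstable. Luminal CO₂/H₂CO₃/HCO₃⁻ is held at
hydration equilibrium (a single carbonate pool): with carbonic
anhydrase the luminal reaction length is of order micrometres, four
orders below the grid, so only the pool total is dynamically
meaningful. Electroneutral speciation (a 1-D root in pH) resolves the
pool and all buffer pairs at each station; luminal electroneutrality is
preserved exactly because the cross-section enforces zero net current
out of the lumen. Mass conservation of the assembled kidney is exact by
construction (segment reabsorption is defined as inlet minus outlet of
the marched flows, and merges are linear), independent of solver
tolerance.

The nonlinear solver is a damped Newton iteration on a residual scaled
per equation by its transport capacity, with: finite-difference
Jacobians (forward, escalating to central differences when polish
stalls) reused across warm-started stations; per-component step limits
with a runaway clip; a 2-norm line-search merit (for which a fresh
Newton step provably descends); Levenberg–Marquardt fallback steps near
singular Jacobians; adaptive activity-ramp and lumen-morphing
continuation for cold starts; and interval subdivision with a salvage
acceptance (scaled residual < 10⁻³) for rare extreme deep-inner-medulla
stations of the full models. Target tolerance is 10⁻¹² (scaled,
max-norm), stall acceptance 10⁻⁵. Solves are deterministic: identical
inputs yield bitwise-identical results.

Torque modulation: the compliant radius is r = r₀(1 + μ_PT(P − P₀))
with μ_PT = 0.02 mmHg⁻¹ and P₀ = 13 mmHg (the inlet pressure); the
microvillous torque τ = 8μQl/r²·(1 + (l+δ)/r + l²/2r²) uses l = 2.5 µm
and δ = 0.15 µm, and luminal-membrane fluxes scale by
S = max(0, 1 + s(τ/τ₀ − 1)). τ₀ is fixed per nephron class from its
baseline SNGFR and reference radius — and stays at the baseline value
during a saline load, which is what makes proximal reabsorption rise
with filtered load (glomerulotubular balance). The scaling factor
s = 1.35 is a calibration choice of the packaged transcription: s
controls how strongly flow feedback damps inter-model differences, and
this value lets the four models separate as the difference tables
dictate while preserving a robust saline-load response.

## Parameters

Absolute baseline values (geometry, permeabilities, activities) are a
best-effort transcription of this model family for the male rat,
calibrated so the male-rat model reproduces textbook segmental
function: two-thirds of filtered Na⁺ and water reabsorbed proximally,
TAL dilution to ~50 mM Na⁺ with a lumen-positive potential, distal K⁺
secretion in the CNT at a lumen-negative potential, and urinary
fractional excretions of a few percent for Na⁺, Cl⁻ and water. They are
configuration, not measurements; the tests treat them as such. The
female-rat, male-mouse and female-mouse sets are produced by the delta
engine from layered relative-difference files
(`deltas_rat_f`, `deltas_mouse_m`, `deltas_mouse_f`), applied as
value × (1 + change) in the documented order (male rat → {female rat,
male mouse}; male mouse → female mouse). Single-valued length/diameter
rows scale both; diameter changes rescale radius and membrane areas so
transport area ∝ length × diameter. Every value carries a provenance
tag (`transcribed`, `delta-derived` or `fixture`) and building a model
can emit a provenance report.

The interstitial composition is prescribed (no nephron-to-interstitium
feedback): cortex equals plasma; Na⁺, K⁺ and urea rise
piecewise-exponentially to 200/10/60 mM at the outer–inner medullary
boundary and 280/20/450 mM at the papillary tip, with Cl⁻ adjusted for
electroneutrality at pH 7.4. Bath pressure is 4 mmHg, luminal fluid
viscosity 7.2×10⁻³ g cm⁻¹ s⁻¹.

## Protocols

* Baseline: solve and tabulate absolute and fractional deliveries of
  volume, Na⁺, K⁺, Cl⁻, HCO₃⁻ and NH₄⁺ to each segment inlet.
* Saline load: SNGFR × 1.50 (males) or × 1.65 (females), everything
  else unchanged. The weight-normalised female-to-male excretion ratio
  divides by 0.5 for rats (a female weighs about half a male) and
  multiplies by 1.3 for mice (a male weighs about 30% more).
* Segment swap: one mouse segment group (PT, TAL, DCT, CNT, CCD+OMCD,
  IMCD) gets the sex-matched rat transporter and channel activities by
  inverting the rat-to-mouse activity rows for that group — for the PT
  that is a single +47.06% NHE3 change; geometry and SNGFR stay mouse.
* Sex swap: one female-mouse sex difference made rat-like — proximal
  apical water permeability set to 0.64 × male (instead of 1.4 ×),
  Na⁺-K⁺-ATPase along TAL/DCT/CNT set to 2 × male, or ENaC set to
  1.30/1.50/1.20 × male along CNT/CCD/OMCD.

## The toy fixture

`build_toy_fixture` shrinks the packaged sets for fast, exhaustive
testing: every segment at 0.3 × length, 4 axial intervals per segment
(16 for the coalescing IMCD, whose population fraction decays
exponentially), and three nephron classes (SF, JM-1, JM-3 with
renormalised weights). It keeps every code path live — compliant
proximal tubule, short and long loops, coalescing CNT and IMCD,
principal and intercalated cells, every transporter kind — and accepts
the same delta chains and protocols as the full sets. Because its
tubules are short relative to its flows, it excretes tens of percent of
its filtered load; passing conservation and ordering tests on the toy
therefore demonstrates correctness of the machinery, not physiological
realism, which is the province of the full sets. Problem sizes: a toy
kidney solves in a few seconds, a full kidney in ~15–30 s on one CPU.

## Numerical choices and degenerate inputs

* GHK uses a second-order series for |ζ| < 10⁻⁴ (removable
  singularity); the log-mean concentration switches to its limit within
  relative 10⁻⁹ of equal concentrations.
* Zero-length segments return inlet unchanged; zero-permeability
  pathways give exactly zero flux (structural, not round-off).
* The ω_CNT formula crosses zero before the segment end; it is clamped
  below at 0.182 (about 2/11, six tubules merging toward one collecting
  duct), configurable, with the pre-clamp value available for testing.
* Clamped-potential solves (a testing aid) pin all potentials and
  replace electroneutrality by a pH pin — with fixed potentials every
  permeant ion is determined by its own balance and electroneutrality
  would overdetermine the system.
* The early/late DCT split is 50/50 by length (configuration).

## Known limitations

The interstitium is static: medullary gradients do not respond to
nephron transport, so urine-concentrating behaviour is imposed rather
than emergent. SNGFR is prescribed per experiment (no tubuloglomerular
feedback). Transporter kinetic constants are standard forms with
approximate packaged constants, not fits; quantitative agreement with
measured absolute deliveries is limited by the transcription, and the
package's quantitative claims are therefore orderings, thresholds and
conservation properties rather than exact delivery percentages. Urinary
K⁺ handling is the least constrained part of the distal model: the
female-rat set, with its doubled distal Na⁺-K⁺-ATPase and elevated
ENaC, secretes K⁺ more avidly than is realistic. The salvage acceptance
(see above) can leave isolated deep-IMCD stations of the full models
self-consistent only to ~10⁻³ in scaled units; network conservation is
unaffected.
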