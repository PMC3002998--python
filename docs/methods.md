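# Methods

## Model overview

The simulator couples three deterministic subsystems on an exponentially
growing cylindrical cell, `L(t) = L0·exp(α t)` with constant radius
(growth is purely lengthwise, so the surface-to-volume ratio of the
lateral membrane is constant and interfacial normalization factors can be
absorbed into the membrane on/off rate constants). Units throughout:
minutes, micrometres, nanomolar; copy numbers convert via
1 nM·µm³ = 0.6022 copies. Defaults: L0 = 7 µm, radius 1.5 µm, doubling
time 100 min (α = ln 2/100).

### Microtubule subsystem (non-spatial ODEs)

Tubulin exists as a GDP-bound pool `T_D` and a polymerization-competent
GTP-bound pool `T_T`; exchange is irreversible and first order
(`k_ex·T_D`, consuming GTP from a large reservoir). Polymers are
discretized into subunits of Δd = 0.07 µm (Ns·Δd = 1625·0.07 = 113.75
monomers each). Reactions:

| reaction | rate law | tubulin weight |
|---|---|---|
| production | `feed_T` (into T_D) | — |
| exchange | `k_ex·T_D` | 1:1, consumes GTP |
| nucleation | `k_nuc1·T_T − k_nuc2·MT_1^g` | Ns·Δd per event |
| elongation `MT_i^g + T_T → MT_{i+1}^g` | `k_el·MT_i^g·T_T` | Ns·Δd |
| catastrophe `MT_i^g → MT_i^s` | `k_cat(i)·MT_i^g` | — |
| depolymerization `MT_i^s → MT_{i−1}^s + T_D` | `k_dep·MT_i^s` | Ns·Δd |

plus `−α·u` dilution on every species. The `T_T` dependence of elongation
is first order rather than raised to the subunit stoichiometry — a
polymer's elongation speed is length-independent — and nucleation carries
the same Ns·Δd mass weight as elongation so that total monomer-equivalent
mass obeys `d(mass)/dt = feed_T − α·mass` exactly (this identity is a unit
test). The top class cannot elongate (it has reached the cell tip); class
1 shrinking polymers dissolve entirely.

Rate constants from measured velocities: equating the per-polymer subunit
addition rate `v_el/Δd` with the mass-action law at the reference
concentration gives `k_el = v_el/(Δd·T_T_ref)` — the Avogadro/cell-volume
factors cancel between the one-molecule concentration and the per-cell
event rate. Analogously `k_dep = v_dp/Δd`. Defaults `v_el` = 2 µm/min,
`v_dp` = 8 µm/min, `T_T_ref` = 7.5 µM (typical interphase values; the
back-substitution speed tests integrate a single seeded polymer through
the actual ODE and recover the configured velocities to < 5 %).

The catastrophe rate is `k_cat(i) = kcat_a·exp(kcat_b·i/N)`: an
exponential function of polymer extent relative to cell length, rising
toward the tips. As the cell grows, a new zero-concentration class is
appended whenever `floor((L/2)/Δd)` increments (polymers span at most half
the cell; N runs 50 → 100 over one doubling). The stiff system is
integrated with LSODA piecewise between these extension events at
rtol 1e-8, atol 1e-12 nM.

**Tip-touching count.** A class touches the tip when its ceiling-normalized
extent `ni = ⌈i·Δd/(L/100)⌉` reaches the 50-interval half-mesh. The
reported count sums `(MT_i^g + MT_i^s)` over tip-touching classes and
converts to copies per cell at the current volume; at t = 0 this is
exactly the top class. Using the placement rule (rather than the top class
alone) keeps the observable continuous across extension events, whose
freshly appended classes are empty for a fraction of a second.

**Calibration.** `k_nuc1`, `kcat_a`, `kcat_b`, `k_ex` and `feed_T` are not
measurable directly and were calibrated jointly, once, against two
constraints: a time-averaged tip-touching count of 3.6 microtubules over
t ∈ [10, 100] min, and as fast and flat an approach to quasi-steady state
as the system allows. The survival of a nucleated polymer to the tip is
`exp(−kcat_a·f(kcat_b)·(L/2)/v)` with `f(b) = (e^b−1)/b`, so the count
scales as `L·exp(−L/L*)` with `L* = 2v/(kcat_a·f)`; choosing L* ≈ 10 µm
(the geometric mean of newborn and dividing lengths) makes the count flat
to ±3 % across the cycle, and `k_nuc1` then scales the level (the polymer
sector is nearly linear in it — `calibrate_nucleation` exploits this).
Frozen defaults: `kcat_a` = 0.1385 min⁻¹, `kcat_b` = 1.5,
`k_nuc1` = 2.062e-5 min⁻¹, `k_nuc2` = 1 min⁻¹, `k_ex` = 5 min⁻¹,
`feed_T` = 70.6 nM/min.

A limitation worth stating: starting from polymer-free initial pools
(`T_T` = 7.5 µM, `T_D` = 0.5 µM, GTP = 340 µM), building the standing
polymer population borrows ≈1.4 µM tubulin-equivalent mass from the free
pools within the first ~4 min. The resulting few-percent dip in `T_T` is
amplified ~2.5-fold into the tip count (through nucleation flux and
survival), and the pool turnover time bounds its recovery, so the count
enters its 5 % quasi-steady band at ≈11.6 min rather than within 10. Wide
exploration of the calibration space (production, exchange, nucleation,
catastrophe, velocities) did not push this below ~11.5 min while holding
the other constraints; the acceptance script reports the measured value.

### Spatial placement and convection velocity

All microtubules are nucleated between the two central mesh nodes and grow
antiparallel toward the tips; each length class is converted to expected
copies, split equally between the half-cells, anchored at the centre over
`ni` mesh intervals, and mirrored. Cytosolic Pom1 (with the Tea1/Tea2
machinery lumped in) is advected tip-ward at

`v(x̄) = v_el·f(m_g(x̄)) + v_walk·f(m_tot(x̄))`, `f(m) = m/(m + K_occ)`,

where `m_g` and `m_tot` are the expected numbers of growing and of all
microtubules covering the point. The occupancy factor saturates with track
number, so cargo speed is bounded by the carrier speeds (`v_walk` = 3
µm/min). `K_occ` = 0.05 microtubules: with the wild-type complement of
3–4 tip-touching polymers per cell the conveyor runs essentially at
capacity, and modest growth-rate-dependent differences in MT numbers do
not perturb the Pom1 gradient — which is what makes the trigger volume
invariant across growth rates (measured: 0.4 % between 100-min and 120-min
doubling). Large losses of coverage, as under catastrophe-promoting drugs,
still collapse transport. The velocity field is refreshed every 0.1 min
(MT dynamics are slow relative to the PDE step); zero microtubules
anywhere gives v ≡ 0 and no gradient can form.

### Pom1:Cdr2 reaction–diffusion–convection system

Species on the fixed 100-point midpoint mesh: `P_c`, `P_m`, `C_c` and
membrane Cdr2 phosphoforms `C_m^(0..n)`, n = 10. Reactions: constant
feeds into the cytosolic forms; reversible first-order Pom1 partitioning
(`k_P_on` = 1, `k_P_off` = 2 min⁻¹); first-order Cdr2 insertion
(`k_C_on` = 1 min⁻¹); the ordered distributive phosphorylation chain
(`k_phos·P_m` per site up, `k_dephos` = 1 min⁻¹ per site down); expulsion
of the top form (`k_expel` = 5 min⁻¹) returning fully dephosphorylated
Cdr2 to the cytosol. Total Cdr2 reaction flux telescopes to `feed_C` — a
unit test. Diffusion `D_c` = 6, `D_m` = 0.06 µm²/min (membrane diffusion
is orders of magnitude slower).

The chain places a threshold at local kinase/phosphatase ratio
`r(x̄) = k_phos·P_m/k_dephos = 1`: for n = 10 the steady phosphoform
distribution is geometric in r, so membrane residence collapses where
r ≫ 1 (tips) and is long where r ≪ 1 (midcell). `k_phos` = 4.5
nM⁻¹min⁻¹ positions the midcell crossing inside the midcell-Pom1 dynamic
range of a cycle, deep enough in the suppressed regime that the trigger
fires while Pom1 inhibition is still being relieved — this both steepens
the size signal and balances the opposing effects of the Pom1 and Cdr2
production surpluses a slower-growing cell accumulates at equal length.
With n = 0 the model degenerates to single-step Pom1-catalysed expulsion
(`k_expel_single` = 0.4 nM⁻¹min⁻¹, chosen to match the multisite variant's
midcell membrane level); its linear — rather than ultrasensitive —
response to the Pom1 gradient yields a visibly broader midcell Cdr2 peak
(FWHM 0.21 vs 0.185 in normalized units), which is the argument for
multisite phosphorylation.

**Feeds.** For a spatially uniform concentration feed f into a conserved
pool, copies added over [0, T] are `f·N_A·V0·(e^{αT}−1)/α`; inverting this
closed form for the target increases (+62 % Pom1, +38.6 % of that pace for
Cdr2's +20 %) over the 100-min wild-type doubling gives
`feed_P` = 0.2884 and `feed_C` = 0.0863 nM/min. All scenarios share these
wild-type constants. Full simulations reproduce 2000 → 3240 and
1855 → 2226 copies to < 0.1 %.

### Numerics

Each step (dt = 0.01 min) is a Strang-like split: a half-step of
reactions + dilution by classical RK4 (automatically substepped so the
fastest local first-order rate, e.g. `k_phos·P_m` at the tips, stays
within the stability region), one implicit transport step, and a second
reaction half-step. Transport is finite-volume: Crank–Nicolson diffusion
with `D/L(t)²` scaling and no-flux faces, and first-order upwind
convection in flux form `∂(v u)/∂x̄ / L`, folded fully implicitly into the
same tridiagonal solve (applied to `P_c` only). Flux form makes transport
conserve total copies to machine precision — with feeds off, spatially
integrated Pom1 and Cdr2 copies are constant over a full run to ≈1e-9
relative, and symmetric initial data stay symmetric to < 1e-8. Against
closed forms: the cosine diffusion eigenmode decays to 0.1 % accuracy at
default resolution, pure dilution is exact to integrator precision, and
halving dt while doubling the mesh moves final profiles by < 1 %.
Instabilities (NaN or concentrations below −0.1 nM) abort with the
offending species named. Membrane species experience the same −α dilution
as cytosolic ones (the lateral membrane area of a lengthening cylinder
grows at the same exponential rate as the volume).

### Trigger

Midcell membrane Cdr2 — the mean of Σ_j C_m^(j) over x̄ ∈ [0.4, 0.6]
("midcell" is not quantified experimentally; the central 20 % is
config-exposed) — drives the standard Goldbeter–Koshland closed form with
J1 = J2 = 0.01 (zeroth-order regime), constant inactivation rate
v_inact = 1 and gain 0.01722 nM⁻¹, calibrated once so the wild-type run
crosses activity 0.5 at L = 14.000 µm. The switch is memoryless (an
instantaneous function of the current input); commitment is the first
upward crossing of 0.5, linearly interpolated on the 0.1-min grid.

## Synthetic initial profiles

The published initial distributions are digitized fluorescence data that
are not machine-readable, so a generator emulates their described shape:
Pom1 ∝ `exp(−x̄/λ) + exp(−(1−x̄)/λ)` with λ = 0.12 (tip-peaked,
symmetric), Cdr2 membrane pool Gaussian at midcell with σ = 0.10, both
normalized to exact copy totals (2000 and 1855 in the newborn cell; the
Pom1-overexpression scenario multiplies the Pom1 total). Pom1 starts 80 %
membrane-bound; Cdr2 starts 20 % membrane-bound with the cytosolic 80 %
uniform (cytosolic diffusion is fast). The membrane Cdr2 pool is
distributed across phosphoforms at the local steady ratio `r(x̄)^j` so
that Pom1-driven expulsion is active from t = 0 — an empty chain would
produce a spurious burst of midcell membrane Cdr2 while filling. The
asymmetric "newborn" variant weights Pom1 3:1 toward the new end and
shifts the Cdr2 peak to x̄ = 0.65; by t = 100 min its profiles agree with
the symmetric run to well under 1 % of peak, demonstrating that the
steady-state spatial pattern is set by the dynamics, not the initial data.

What the generator does not emulate: the measured profiles' fine structure
(cortical-node granularity, tip asymmetries of real fluorescence data),
photobleaching or background corrections, or cell-to-cell variability. Passing tests
therefore show that the mechanism reproduces the qualitative spatial
program and the quantitative copy-number bookkeeping, not that it fits any
particular fluorescence trace.

## Scenarios and their single modifiers

| scenario | modifier | everything else |
|---|---|---|
| `wt` | — | defaults |
| `lat_a` | doubling time 120 min | wild-type parameters |
| `mbc` | catastrophe ×5 | wild-type parameters |
| `pom1_oe` | initial Pom1 ×2 (or ×k) | wild-type parameters |

Horizons: 120 min (wt), 150 (lat_a), 180 (mbc, pom1_oe), so the trigger
crossing falls inside the simulated window; the feed calibration horizon
stays the 100-min wild-type doubling. The four canonical runs complete in
about two minutes on one CPU at default resolution (0.01-min PDE steps,
100 mesh points, 0.1-min velocity refresh).

## Known limitations

- The microtubule quasi-steady settling time is ≈11.6 min from the stated
  polymer-free initial pools (see the calibration note above).
- Total polymer *concentration* summed over all length classes stays
  roughly constant as the cell grows (the class count doubles while
  per-class concentrations fall); the cleaner size-scaling statement, and
  the one tested, is that the tip-class concentration dilutes ≈ with 1/V
  while tip-touching *copies* stay constant.
- Tea1/Tea2 are lumped into Pom1's convection; there are no explicit
  cortical nodes, no sterol microdomains, no stochasticity, and the
  Wee1/Cdr1/Cdc25 cascade is collapsed into one memoryless switch.
- The trigger-volume invariance (0.4 % across growth rates) degrades if
  the velocity field is taken out of its saturated regime (large `K_occ`)
  or if Pom1 membrane retention is made much stronger (small `k_P_off`),
  both of which lengthen the slow global Pom1 redistribution mode.
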