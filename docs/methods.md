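# Methods

This note documents the models implemented in `twistpore`, the
conventions chosen where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## The system

The artificial potassium channel is a bilayer graphene nanopore whose
two stacked sub-nanometre pores are each lined by four carbonyl (C=O)
groups, oxygens pointing to the pore axis — a graphene mimic of the
carbonyl rings in the KcsA selectivity filter.  Rotating ("twisting")
the four functionalized positions of one layer relative to the other by
an integral number of edge steps generates the family of pore
configurations AmAn.  Ion transport through such a pore proceeds by a
dual-ion, water-bridged soft knock-on mechanism; permselective K⁺
transport across a membrane of such pores converts the mixing free
energy of KCl/NaCl solutions into electrical power.

## Pore geometry (`pore_builder`)

* Graphene C–C bond length 1.42 Å; the pore is carved by deleting the 16
  lattice atoms nearest a bond midpoint.  Bond-centring makes the
  16-atom vacancy unique (the 16th and 17th nearest atoms are at 3.55
  and 3.95 Å).  The rim-to-rim opening is 9.94 Å along the long axis.
  No 16-atom vacancy of a honeycomb lattice has a ~9.9 Å rim box along
  *both* axes, so the transverse dimension is a property of this carve
  (7.38 Å).
* Eight candidate carbonyl sites sit on the rim, indexed 0..7
  counterclockwise from +x.  The site ring is **unevenly spaced**
  (sites 4–7 form a dense 30° arc; the remaining gaps are 54°), and two
  sites closer than 2.6 Å — i.e. within the same dense-arc step — cannot
  both carry a carbonyl.  Under this adjacency rule exactly the five
  clockwise twists t = 0..4 of the base motif {0, 2, 5, 7} are
  admissible and t = 5..7 are dismissed; the five single-layer elements
  A0–A4 are therefore *derived* from the clash rule rather than
  postulated.  Clockwise twist means +1 modulo 8 on the site indices
  viewed down +z.
* Carbonyl C=O bond length 1.23 Å; each oxygen is displaced from its rim
  carbon toward the pore axis, in the layer plane.
* Default interlayer distance d = 3.35 Å (pristine graphite).  The layer
  pair is coaxial; a bilayer is labelled "AmAn".
* 25 ordered AmAn combinations exist; 15 survive layer-swap
  deduplication.  The further reduction to 13 investigated pores
  reported for this design space is not derivable from layer swap alone
  and is deliberately **not** hard-coded; `enumerate_configs` accepts a
  custom equivalence predicate instead.
* **Effective pore area** is measured on a grid in each layer plane: a
  point is open if it clears every atom's covalent radius (C 0.76 Å,
  O 0.66 Å) plus a probe radius, and connected to the pore centre; the
  bilayer area is the smaller of the two layers.  With the calibrated
  probe of 0.3 Å the functionalized pore measures ≈32.8 Å², matching the
  ~32 Å² effective cross-section of the carbonyl-lined pore.  Van der
  Waals radii cannot reproduce that number for any non-negative probe
  (they give ≈16 Å²), which is why the covalent-surface convention is
  used; the probe also seals sub-Å necks between rim atoms against
  flood-fill leakage.

## TST kinetics (`tst_kinetics`)

Permeation rate k = τ⁻¹·exp(−ΔG/k_BT) with k_B = 0.0019872 kcal/(mol·K)
and T = 300 K by default.

* The rate-determining barrier is the ion hop between the L1 and L2
  binding sites: ΔG = (highest free energy between the two layer-interval
  minima) − (L1 minimum).  It is referenced to the preceding minimum,
  not to bulk, and is invariant under constant shifts of the PMF.
* PMF profiles are normalized to a zero mean over a bulk reference
  region.  Extremum location uses a centred moving average (default
  window 3 points — biasing-force profiles are noisy and no smoothing
  prescription exists for them) plus an optional prominence filter that
  drops extrema whose value gap to both neighbours (or to the profile
  ends) is below a threshold.
* The attempt period τ is the second zero of the normalized velocity
  autocorrelation function, located by sign change with linear
  interpolation.  A series whose VACF never dips below −0.2 before that
  zero is rejected as non-oscillatory: a white-noise VACF hovers near
  zero and produces spurious crossings, so zero-counting alone cannot
  distinguish vibration from noise.
* The K⁺/Na⁺ selectivity ratio is the ratio of the two rates.  With
  equal attempt periods, the 3.5 vs 8.9 kcal/mol hop barriers give
  exp(5.4/k_BT) ≈ 8.6×10³ at 300 K.  The headline MD selectivity of
  ~1295 also folds in the two ions' different attempt periods, which are
  not printed anywhere and therefore cannot be recomputed here; the
  formula pathway is validated against a high-precision oracle instead.

## Barrier decomposition (`decomposition`)

ΔG = a·ΔN_water + b·ΔN_carbonyl + c, fitted by ordinary least squares
(statsmodels) on ≥4 samples with a full-rank design.  The intercept c
(the ion–membrane term) is *fitted*, not fixed, because its value is not
published; per-ion fits are separate.  The generator draws ΔN_water ∈
U(−6, −1) and ΔN_carbonyl ∈ U(0, 4) — partial dehydration against up to
four carbonyl contacts — with Gaussian noise on ΔG.  The recovery
contract is parameter recovery (exact when noise-free, within standard
errors otherwise) and the sign contract b(K⁺) < 0 < b(Na⁺) for
generators parameterized at −2.55 and +4.92 kcal/mol per carbonyl.

## Primitive-model electrolyte (`electrolyte`)

Ions are charged hard spheres in a dielectric continuum: hydrated
diameters K⁺ 5.6, Na⁺ 4.7, Cl⁻ 6.4 Å; relative permittivity 78.4 (bulk
water; the Bjerrum length at 300 K is 7.11 Å); temperature 300 K.

Chemical potential terms, all in kcal/mol:

* **Ideal**: k_BT ln(c/c°), c° = 1 mol/L.
* **Hard sphere**: the BMCSL mixture equation of state, differentiated
  analytically through the moments ξ₀..ξ₃.  It reduces to the
  Carnahan–Starling excess chemical potential for equal diameters (a
  test oracle).
* **Electrostatics**: the non-restricted MSA, energy route.  The
  screening parameter Γ solves 2Γ = √(4πλ_B Σᵢ ρᵢXᵢ²), Xᵢ =
  (zᵢ − ησᵢ²)/(1+Γσᵢ), by damped fixed-point iteration from the Debye
  value κ/2 to 10⁻¹² relative tolerance; η couples unequal diameters
  and vanishes in the restricted (equal-σ) limit, where Γ =
  (√(1+2κσ)−1)/(2σ) exactly.  The free-energy density is
  βa = βE + Γ³/3π with βE = −λ_B Σ ρᵢzᵢ(Γzᵢ+ησᵢ)/(1+Γσᵢ); μᵢ is
  obtained as a central-difference composition derivative of a with Γ
  re-solved at the displaced compositions, avoiding any commitment to a
  closed-form μ expression for the unequal-diameter theory.  Oracles:
  the restricted closed form, the Debye–Hückel limiting law at
  10⁻⁴–10⁻⁶ M, and Maxwell symmetry ∂μᵢ/∂ρⱼ = ∂μⱼ/∂ρᵢ.
* The direct mean-field Coulomb term between reservoirs is zero: each
  reservoir is homogeneous and electroneutral.

**Reservoir free energy** uses the Euler form G = Σ nᵢμᵢ.  For solutions
at effectively constant pressure this is the standard Gibbs-energy
bookkeeping (μ_ex = k_BT ln γ); the alternative of summing the
Helmholtz free-energy density directly was implemented and compared
during design and moves the mixing minimum from 0.141 to 0.200 M — the
Euler convention is the package's choice and the one closer to the
reference behaviour of this system.

**Mixing scenarios** (1 L reservoirs, initially 1 M KCl left / 1 M NaCl
right; neutral-salt bookkeeping, i.e. the left reservoir loses δC mol of
KCl and the right gains it even though only K⁺ physically permeates —
electroneutral accounting with external charge compensation):

* free mix: left (1−δC) M KCl + δC M NaCl, right mirrored;
* KPM: left (1−δC) M KCl; right 1 M NaCl + δC M KCl.

ΔG_m(δC) = G(δC) − G(0), reported in kJ per mole of initial salt per
reservoir (the normalization is a knob; the efficiency η is a ratio of
two ΔG_m values and is normalization-independent).  The spontaneous
terminus δC₀ is the grid argmin refined by a local quadratic; the
default grid is 0–0.45 M in 2.5–5 mM steps.  ON = |ΔG_m,KPM(δC)|,
OP = |ΔG_m,free(δC)|, η = ON/OP, defined on the spontaneous branch
(δC ≤ δC₀; a flag relaxes the branch check for evaluating the ratio at
a prescribed δC).

Computed values under these conventions: ideal-only argmins are exactly
1/3 (KPM) and 1/2 (free mix); the full model gives δC₀ = 0.141 M and
η = 39.3% at δC = 0.16 M (43.1% at δC₀).  The reference values for this
system are ~0.16 M and 37.5%; the residual offset is attributed to the
unpublished details of the original thermodynamic implementation (MSA
variant, free-energy route, axis normalization), which the alternative
conventions explored here bracket but do not pin down.

## Power generation (`power`)

* I–V lines are least-squares fits; I_diff is the current at V = 0 and
  U_diff = −I_diff/G.  Positive current is cation flux from the KCl to
  the NaCl reservoir.
* Single-pore power defaults to the maximum-power-transfer value
  |I_diff·U_diff|/4 of a linear source (≈0.13 pW for ~7 pA and 73 mV);
  a caller-specified operating point is also accepted, since the
  definition behind the reported per-pore figure is not stated.
* GHK reversal potential: the standard monovalent Goldman–Hodgkin–Katz
  form with caller-supplied permeabilities.  The "modified" GHK used for
  the reference U_diff = 73.1 mV is supplementary-only and is *not*
  reproduced; concentrations are used directly, with activity
  corrections possible via `electrolyte` upstream.
* Coulomb energy 332.0637·z₁z₂/(ε_r·r) kcal/mol; two +1 charges at
  3.9 Å in vacuum give 85.1 kcal/mol.
* Pore density 1/pitch² (10 nm pitch → 10¹⁶ m⁻²); areal power density is
  the product with per-pore power (0.13 pW → 1300 W/m²); porosity is
  pore area × density (32 Å² × 10¹⁶ m⁻² = 0.32%).

## Trajectory statistics (`trajectory`, `trajectory_analysis`)

The pore axis is stored as z; layer planes at z₁, z₂.  Trajectories are
multi-frame XYZ plus a JSON sidecar (timestep, box, periodicity, layer
planes, role map).

* **Site occupancy**: an ion is bound to P1/P2 if within 1.0 Å axially
  of the plane and 3.0 Å radially of the axis (defaults; both exposed).
  The axially nearest ion wins a contested site.
* **Permeation events**: the ion's axial coordinate is unwrapped along
  the periodic axis; thresholds at z₁−entry_margin and z₂+exit_margin
  (2 Å defaults) form a hysteresis ladder replicated every box length.
  An event is below(k)→above(k) (or reverse) on the same pore image;
  above(k)→below(k+1) is bulk traversal and never counts.  Margins
  debounce re-crossings; shuttling into P1 and retreating counts
  nothing.
* **Hydration numbers**: water oxygens within the species cutoff
  (K⁺ 3.5 Å, Na⁺ 3.2 Å — first RDF minima of common water models; the
  source states no cutoff), minimum-image distances.
* **Triplets**: a K–nH₂O–K episode is a maximal run of dual occupancy by
  the same ion pair, labelled by the modal bridging-water count — waters
  strictly between the layer planes and within the radial cutoff of the
  inter-ion axis.  Zero-water episodes are excluded and flagged.
  Lifetime = episode duration.
* **Dipole orientation**: θ is the angle between the water dipole
  (O through the H–H midpoint) and the P1→P2 ion axis.  For angle
  computation the bridging waters are re-selected by a frame-internal
  criterion (projection inside the inter-ion segment), which makes the
  series exactly invariant under rigid rotation/translation of frames.
  Histogram peaks are detected on a 5°-binned, lightly smoothed
  histogram.
* **Switching frequency**: frames classify as state A (θ < 90°−15°) or
  B (θ > 90°+15°) with hysteresis (ambiguous frames keep the previous
  state) and a 2-frame debounce; f = transitions/(2·duration), i.e. one
  full switching cycle is two transitions, converted to GHz
  (1 ps⁻¹ = 10³ GHz).  Whether the reported switching rates count
  half- or full cycles is not stated; this convention is fixed here and
  shared by the generator, and at the 578/89.3 GHz scale it corresponds
  to ~0.9/5.6 ps mean holding times, which are physically sensible for
  librating confined water.

## Synthetic data (`synthetic`)

All generators are seeded (`numpy.random.default_rng`) and bit-identical
under identical specs.  They emulate the *statistical structure* the
analyses assume — not water structure, forces, or real MD dynamics:

* `gen_pmf`: sum of Gaussians whose amplitudes are iteratively refined
  until every requested well/saddle value is met to 0.01 kcal/mol;
  baseline decays to bulk zero.  Presets: K⁺-like (wells −6.0/−6.4,
  saddle −2.5 → 3.5 kcal/mol hop, 6.4 exit) and Na⁺-like (well −6.9,
  saddle +2.0 → 8.9 hop, retreat 2 kcal/mol cheaper than the hop).
* `gen_oscillator_velocities`: damped cosine + optional noise; errors on
  undersampling (dt ≥ T/10).
* `gen_triplet_trajectory`: dual-occupancy episodes, Bernoulli(0.513)
  single- vs two-water, exponential lifetimes (300/2074 ps means),
  orientation telegraph simulated in continuous time (holding rate 2f so
  the transitions/(2T) estimator recovers f) and sampled at the frame
  spacing; two-water episodes swap the two waters' state angles
  (defaults 40°/120°) anticorrelated.  Ion positional jitter (0.15 Å) is
  configurable; episode ground truth is embedded in the trajectory
  metadata.  Estimator bias from sampling and debounce is below ~2% when
  the mean holding time spans ≥ 10 frames.
* `gen_permeation_trajectory`: scripted capture → dual occupancy →
  knock-on → release; stage dwell fractions configurable (stage IV
  defaults to 70% of the event); with `wrap`, successive events traverse
  successive periodic images.  Event counts are exact ground truth.
* `gen_hydration_trajectory`: Poisson-perturbed first shell around a
  fixed ion plus bulk waters, constant atom count.
* `gen_iv`, `gen_decomposition_samples`: linear models with Gaussian
  noise and prescribed intercepts/coefficients.

Because the generators realize exactly the structure the estimators
assume, passing tests demonstrate estimator correctness and internal
consistency — not agreement with real MD data, whose trajectories are
not distributed.

## Problem sizes and numerical choices

Test and analysis problem sizes are chosen so the whole suite runs in a
few minutes on one core: mixing curves use 2.5–5 mM grids (the δC₀
quadratic refinement makes the result grid-insensitive at this
resolution), triplet-statistics runs use 150–400 episodes, flip-rate
runs use single long episodes (1.5–6 ns at 10–50 fs sampling) sized so
that 3σ recovery bounds are a few percent.  Γ fixed-point tolerance
10⁻¹² relative; MSA μ finite-difference step 10⁻⁵ relative (floor
10⁻⁷ M); degenerate inputs (zero concentrations, empty episodes,
monotone curves, all-ambiguous orientation series) raise typed errors
rather than returning silently.

## Known limitations

* Headline MD-derived numbers (K⁺ rate 3.5×10⁷ ions/s, SR 1295, U_diff
  73.1 mV, 0.13 pW) require undeposited trajectories or unpublished
  parameters; they appear here only as generator parameters and formula
  inputs.
* The 25→13 configuration reduction and the exact modified-GHK equation
  are unrecoverable from the available text.
* δC₀ and η carry a model-convention uncertainty of order 0.02 M / 2
  percentage points (see the electrolyte section).
* The uneven carbonyl-site ring is a reconstruction that makes the
  twist/adjacency system self-consistent; the true lattice assignment
  of the eight sites is not published.
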