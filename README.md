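# twistpore

Analysis toolkit for an artificial potassium channel built from a
**bilayer graphene nanopore with twisted carbonyl functionalization**,
and for the potassium-permselectivity-enabled osmotic power generation
(PoPee-OPG) it enables.

Biological K⁺ channels discriminate K⁺ from Na⁺ by >1000-fold using
stacked rings of carbonyl oxygens whose adjacent rings are rotated
against each other.  The graphene mimic reproduces this: each layer
carries a sub-nanometre pore (16 carbons removed, ~32 Å² effective
cross-section) lined by four C=O groups, and the functionalized
positions of the second layer are twisted by an integral number of edge
steps, giving the pore family AmAn (m, n ∈ 0..4).  This package
implements the computational analyses around that design:

* **`pore_builder`** — atomic models of the A0–A4 layers and AmAn
  bilayers, configuration enumeration, effective-area measurement,
  XYZ/PDB export.
* **`tst_kinetics`** — PMF handling and transition-state-theory rates,
  k = τ⁻¹·e^(−ΔG/k_BT), with the attempt period τ read from the second
  zero of a velocity autocorrelation function; K⁺/Na⁺ selectivity
  ratios.
* **`decomposition`** — the linear barrier decomposition
  ΔG = ΔG_ion–water + ΔG_carbonyl + ΔG_ion–membrane
  (= a·ΔN_water + b·ΔN_carbonyl + c), fitted by OLS.
* **`electrolyte`** — primitive-model electrolyte thermodynamics
  (ideal + BMCSL hard-sphere mixture + non-restricted MSA), the
  KPM/free-mix salinity-mixing curves ΔG_m(δC), the spontaneous
  terminus δC₀ and the conversion efficiency η = ON/OP.
* **`power`** — I–V intercept fitting (I_diff, U_diff), GHK reversal
  potentials, the dual-ion Coulomb energy, and pore-density → areal
  power-density scaling.
* **`trajectory` / `trajectory_analysis`** — site occupancy, permeation
  events, hydration numbers, K–nH₂O–K triplet fractions and lifetimes,
  water-dipole orientations and switching frequencies.
* **`synthetic`** — seeded generators for every input (multi-well PMFs,
  damped-oscillator velocities, dual-ion trajectories with telegraph
  water orientations, I–V samples, decomposition samples), standing in
  for the MD engine so every stage is testable.

The scientific conventions and their rationale are documented in
[docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
inputs and write tables under `results/`.  For instance the mixing
thermodynamics:

```sh
$ python analysis/05_mixing_thermodynamics.py
ideal-only argmins: KPM 0.3333 (exact 1/3), free mix 0.5000 (exact 1/2)

full model: spontaneous terminus dC0 = 0.1413 M
at dC0:   ON = 0.8897, OP = 2.0647 kJ/mol-salt, eta = 43.09%
at 0.16 M: ON = 0.8773, OP = 2.2296 kJ/mol-salt, eta = 39.35%
(the KPM curve lies above the free-mix curve everywhere: True)
```

Reading: transferring K⁺ from a 1 M KCl reservoir into a 1 M NaCl
reservoir through a potassium-permselective membrane is spontaneous up
to δC₀ ≈ 0.14 M of transferred salt; at δC = 0.16 M the extractable
work ON is ≈39% of the free-energy loss OP that uncontrolled mixing
would dissipate.  And the power side:

```sh
$ python analysis/06_power_output.py
I-V fit: G = 0.0966 nS, I_diff = -7.05 pA, U_diff = 73.0 mV
single-pore power (max transfer |IU|/4): 0.129 pW
pore density 1e+16 /m^2 -> power density 1287 W/m^2
porosity at 32 A^2/pore: 0.0032 (<1%)
dual-ion Coulomb energy at 3.9 A in vacuum: 85.1 kcal/mol
GHK single-cation Nernst check, 10:1 ratio: -59.5 mV
```

A ~0.13 pW pore at one pore per 10 nm × 10 nm patch (10¹⁶ pores/m²,
0.32% porosity) yields a theoretical areal power density around
1300 W/m².

There is also a CLI mirroring the stages:

```sh
twistpore build-pore --m 0 --n 1 --d 3.35 --format xyz --out A0A1.xyz
twistpore synth pmf --seed 1 --out data/
twistpore tst --pmf data/pmf_K.tsv --tau 0.3
twistpore mix --dc-step 0.005 --eval-dc 0.16
twistpore run --seed 1 --out-dir results/
```

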