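# Methods

## Scope and modelling stance

The package reimplements a computational design study of a plasmonic
organic-photovoltaic retinal pixel at desk scale. The original study leans
on three heavy solvers — full-wave FEM for the cathode-array optics, a
drift-diffusion semiconductor solve for the device curves, and a
proprietary tissue/neuron engine for activation thresholds. Each is
replaced here by the lightest model that preserves the quantities the
chain actually consumes, and every place where a constant is *fitted to a
published anchor* rather than predicted is declared below and echoed in
`src/plasmopv/data/calibration.json`.

## Optical constants

**Silver** is generated from a Drude–Lorentz parameterization of bulk
silver (one Drude term, five Lorentz oscillators) sampled on a 1-nm grid
over 250–810 nm and shipped as a static CSV; it is treated as a physical
constant. At the 453-nm design point it gives ε ≈ −5.53 + 0.64i.

**Water** is n = 1.33, k = 0 across the band.

**The PCPDTBT:PCBM blend** is a calibrated fixture, not a literature
digitization (its cited optical-constant source is not packaged with the
study, and the study's own printed transmittances and photocurrents are
mutually inconsistent — see "Known inconsistencies"). Its parameters:

* real index: a Cauchy curve `n(λ) = A + B/λ²` (B = 2×10⁴ nm²) whose level
  A is solved so the single-particle absorption peak of a 10-nm silver
  sphere lands exactly at 453 nm (n ≈ 1.66 at 453 nm);
* extinction index: a smooth monotone shape through seven control points,
  scaled so that (a) the peak normalized absorption cross-section of the
  10-nm sphere equals 2.4 and (b) k(250)/k(453) = 19/7.5, which fixes the
  bare-photocurrent ratio between the two study wavelengths exactly
  (J ∝ αλ = 4πk at fixed intensity).

Interpolation is linear in n and k (never in ε), with hard errors instead
of extrapolation: metal dispersion outside the table is not guessable.

## Single-particle optics

Pure quasi-static dipole response, no radiative or size-damping
corrections, evaluated with the **vacuum** wavelength in the 2π/λ
prefactors. The vacuum convention is forced by the published numbers
themselves: the printed peak ratio Q_scat/Q_abs = 0.019/2.4 ≈ 7.9×10⁻³ for
r = 10 nm matches the vacuum-λ prediction (≈7.7×10⁻³), while an in-medium
convention multiplies it by n_s³ ≈ 4.5. The in-medium alternative remains a
one-flag change (`in_medium_wavelength=True`).

With Q_abs anchored at 2.4 for r = 10 nm, linearity of Q_abs in r makes the
5- and 7.5-nm values (1.2, 1.8) predictions, and the r⁴ scaling of Q_scat
puts 0.0015/0.006/0.019 within their published tolerances with no further
freedom. Peak finding is on a fixed 1-nm grid with ties broken toward
shorter wavelengths, so results are deterministic.

## Cathode-array optics

Two sources for the array absorptance A_b:

* **Reference table** (pipeline default): the published feature values —
  peak absorptances 68/65/58/50% for gaps 1/1.5/2.5/5 nm, reflectance
  minima, transmittance peaks, and the 1500 nm² per-particle cross-section
  of the design array at 453 nm. Published spectra are not available, so
  anchor wavelengths for the non-design gaps are model-derived (collective
  resonance shifts from the coupled-dipole model) and their 453-nm
  absorptances are synthetic: a Lorentzian with the model's resonance
  halfwidth scaled to the printed peak. Queries off the tabulated anchors
  raise instead of interpolating.
* **Coupled-dipole model**: radiatively corrected point dipoles on a
  staggered (hexagonal) lattice with pitch 2R + gap, normal incidence,
  polarization-averaged. The conditionally convergent in-plane dipole sum
  is evaluated with a smooth quartic taper (truncation 60 pitches, with a
  two-radius convergence check); the collective imaginary part
  `Im G = 2πk/A − (2/3)k³` is imposed analytically, which cancels the
  isolated-particle radiative term and makes A + R + T = 1 hold to machine
  precision. Diffractive pitches (pitch ≥ λ/n) are rejected.

A dipole model cannot reproduce the published absolute absorptances at
nanometre gaps: it lacks the multipolar gap hot-spots, so the dense array
is strongly undercoupled (reflection-dominated, A ≈ 0.14 at the design
point vs the published 0.65). What it does reproduce, and what the tests
assert, are the orderings: the collective resonance (reflectance peak)
blue-shifts as the gap widens (506 → 466 nm for 1.5 → 5 nm), band-peak
absorptance decreases with gap, the dilute limit converges to the
single-particle cross-section (checked at 700–800 nm, away from both the
particle resonance and the interband edge, where the dilute comparison is
meaningful), and a vanishing-density array transmits everything. This is
why the photocurrent stage defaults to the reference table.

## Beer–Lambert attenuation

Nanoparticle channel (decadic): ε = N_Aσ/(2.3×10³) with σ = C_abs/N per
silver atom, N from the bulk atomic density (58.6 atoms/nm³), and the
concentration taken as the **atom** molarity (f_s/V_NP particles × N atoms
each / N_A). The particle count cancels, so the optical depth scales with
f_s alone and is radius-independent — the only convention consistent with a
per-atom σ and with the published radius-independent transmittances. The
path length is calibrated to the published design-point value
(T = 94.6% at f_s = 10%), giving ~3 nm; the geometric 70-nm thickness would
transmit only ~28%.

Layer channel (natural): `T = exp(−α·x_eff·(1−f_s))`, with the (1−f_s)
volume displacement of blend by silver and an effective optical path x_eff
calibrated to the published mid-loading transmittance (57% at f_s = 7.5%),
giving x_eff ≈ 117 nm (≈1.7× the physical thickness — consistent with a
folded path in a cathode-mirrored film, but held as a calibration, not a
claim).

## Composite photocurrent

Bare device: `J_sc = G·q·L·η` with `G = αλI₀P/(hc)`, P = 0.7, and a single
collection efficiency η ≈ 0.309 calibrated once to the published bare
current (7.5 A/m² at 453 nm, 0.26 mW/mm²). η absorbs everything between
optical generation and collected charge (exciton transport, recombination);
with the fixture's k-ratio anchoring, the 250-nm bare values (19 and
24 A/m²) follow with no further freedom.

Composite device: the three-term balance quoted in the README. Specifics:

* `v₁ = Q_abs^{3/2}` — the near-field influence region is the sphere whose
  cross-sectional area equals C_abs; this convention uniquely reproduces
  the published radius scaling of the J_sc-vs-f_s slopes (1 : 1.8 : 2.8).
* `v₂` = (areal density of cathode particles) × 1500 nm² × influence depth
  (default: the 25-nm particle radius; any rescaling is absorbed by κ_K)
  / layer thickness ≈ 0.233.
* α₂ = 4πk_silver/λ from the silver fixture.
* κ_A ≈ 0.801 is fitted **only** at (r = 5 nm, f_s = 5%, with cathode,
  15 A/m²); κ_K ≈ 0.435 **only** at the (r = 7.5 nm, f_s = 5%,
  0.33 mW/mm²) with/without-cathode difference of 3 A/m². Both are frozen
  in calibration.json; runs never refit. The remaining 19 published grid
  values are predictions and land within ±1.7 A/m² (tolerance ±2); the
  residual grows toward large v₁f_s because the model is exactly linear in
  the influence volume while the published grid is slightly sublinear.
* The 70%/85% dissociation probabilities appear once, as the P factors of
  the generation integral moved outside — never double-counted.
* The bare-absorber fraction (1 − f_s − v₁f_s − v₂) is used exactly as
  written and raises if negative rather than clipping silently.

## Device electrics

A single ideal diode `J(V) = J_sc − J₀(exp(V/nV_T) − 1)` is calibrated
**per configuration**: the ideality n is bisected so the curve's fill
factor matches the published one (J₀ pinned by V_oc). A fixed-parameter
diode cannot reproduce the published table — V_oc moves only 20 mV across a
5× J_sc range — so per-configuration fitting is the honest lumped
substitute for the original device solver. Series/shunt resistances exist
as fields (0 and ∞ by default). Voltage grid 1 mV from 0 to 1.1 V_oc;
maximum power refined by bounded scalar optimization; all sign conventions
photovoltaic-quadrant magnitudes, with cathodic polarity applied only at
the neuron boundary.

The electrode–electrolyte interface is the pure resistive load line
J = V/Z through the origin, Z = |−0.11 V|/25.1 A/m² = 4.38×10⁻³ Ω·m²
(printed rounded as 4.3 kΩ·mm²); the operating point is the bisected
intersection with the device curve, and threshold light intensity is
bisected over intensity using the linearity of J_sc in I₀ (default
resolution 0.005 mW/mm²).

## Neural stimulation

The plate electrode (100×100 µm², tissue conductivity 0.027 S/m) is solved
by a method of moments on an n×n patch grid (default 30, hard floor 20):
the equipotential-plate current distribution is edge-peaked, and the
extracellular potential and normal current density are sampled along the
axon line at the 5-µm standoff. The published 177×177 µm² effective area
enters only as the ±88.5 µm averaging footprint; its derivation from
sphere packing is not reconstructible, so it is carried as a constant. At
the −0.11 V design voltage the footprint-mean current density computes to
~27 A/m², the order of the 25.1 A/m² activation value.

The axon is an unmyelinated 1-µm fibre, 400 µm long, discretized at ≤5 µm,
with classical Hodgkin–Huxley membrane kinetics and axial resistivity
35.4 Ω·cm, driven by the extracellular potential (activating-function
coupling). Integration is Crank–Nicolson on the cable term with
Rush–Larsen gate updates, fixed step 5 µs; thresholds are bisected to
1 mV. The membrane model is declared a **qualitative substitute**: the
published channel set is unspecified, so tests assert existence and
finiteness of the threshold, all-or-none firing, bidirectional
propagation, strength–duration and standoff monotonicities, and <5%
refinement stability — not the −0.11 V value itself (the classical squid
membrane at its default temperature is substantially more excitable; the
computed 1-ms threshold is ≈ −0.026 V).

## Known inconsistencies in the published values

* **Transmittance trio vs Beer–Lambert.** The published A-AgNP
  transmittances 99/97/94.6% at f_s = 5/7.5/10% have absorbance decrements
  1 : 3 : 5.4, which no decadic channel with depth ∝ f_s can reproduce (the
  feasible bands for f_s = 5% and 10% within ±1 point are disjoint; the
  best single calibration misses by ~1.2 points). The path calibration
  anchors the design point (94.6%) exactly; the model then gives 97.3% and
  95.9% at the lighter loadings. The corresponding acceptance-level test
  states the published trio and is left failing by design.
* **Layer transmittance vs bare photocurrent.** The published 56–58% layer
  transmittance at 453 nm implies αL ≈ 0.56 over the 70-nm thickness,
  while the published bare J_sc implies an ~16× smaller absorbed fraction
  if collection is perfect. The package resolves this with two exposed
  constants (x_eff for the optics, η for the electronics) rather than one
  silently merged number.
* **38 vs 39 A/m² and 35 vs 36 A/m²** for the f_s = 10% devices: the
  performance table and the current-density figures disagree; tests use
  the figure values and both sit within the ±2 A/m² tolerance of the
  model's 40.1 and 37.2.
* **Q_sc = 0.007 vs 0.019/2.419 = 0.0079** for r = 10 nm: the package
  reports its computed 0.0077, consistent with the ratio, not the 1-sig-fig
  print.

## What the synthetic fixtures do and do not emulate

The blend fixture reproduces the published resonance position, peak
cross-section efficiencies, transmittance scale and photocurrent scale. It
does not claim the true PCPDTBT:PCBM dispersion (in particular the real
low-bandgap NIR absorption band is not modelled, and n ≈ 1.66 at 453 nm is
at the low end for such blends). Passing tests therefore demonstrate the
pipeline's internal consistency and its agreement with the published
design-study numbers — not transferability to measured optical data, which
a user can supply as drop-in CSVs.

## Problem sizes

Defaults were chosen so the full chain runs in seconds: 1-nm optical
grids (≈500–560 points), 60-pitch lattice sums (≈12,000 sites), 30×30
MoM patches, 80-compartment/5-µs cable integrations. All are parameters,
and the refinement tests double them to show the answers do not move.
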