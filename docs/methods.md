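# Methods

This note documents the physics model behind `nanodose`, the choices made
where the design was genuinely open, and what the package's results do and
do not establish.

## Problem and observable

Orthovoltage skin therapy delivers dose with 100–300 kVp photon beams, a
regime where the photoelectric cross section (∝ Z⁴⁻⁵/E³⁻³·⁵ per atom)
dominates in high-Z media. Loading tissue with heavy-metal nanoparticles
therefore multiplies the local energy absorption. The package's primary
observable is the dose enhancement ratio DER(d): central-axis dose at depth
d in a nanoparticle-loaded water phantom divided by the dose at the same
depth in plain water, per source photon. Two competing effects shape it:
photoelectric enhancement (raises DER, strongest for soft spectra and high
concentration) and self-absorption of the beam by the loaded medium
upstream (lowers DER with depth, eventually below 1).

## Source model

The tube output is a Kramers photon-number continuum N(E) ∝ Z·(E_max−E)/E on
1 keV bins from the 1 keV transport cutoff to the tube potential, with a
tungsten anode (Z = 74; the anode metal cancels under normalization).
Beam quality is then set entirely by the stated added filtration — 2.4 mm
Al at 105 kVp, 1 mm Al + 1.2 mm Cu at 220 kVp — applied as
exp(−Σ (μ/ρ)ᵢ ρᵢ tᵢ) per bin with renormalization. The filtered beams have
mean energies 46.7 keV (105 kVp) and 110.2 keV (220 kVp); the 220 kVp HVL
of 2.03 mm Cu is typical of clinical beams of this quality.

**This spectrum model is the dominant systematic of the package.** The
clinical machine it emulates publishes neither anode angle, inherent
filtration, nor HVL, so no treatment-head simulation is possible.
Consequences are concentrated at 105 kVp, where the Kramers continuum
retains more 20–40 keV fluence than a real inherently-filtered tube:
enhancement driven by that soft component (low concentrations, mid-Z
materials, the 105 kVp band generally) comes out 10–25% high relative to
the reference treatment-head results, while the heavily Cu-filtered
220 kVp beam — whose shape is pinned by the filter, not the anode — agrees
to a few percent. Tungsten K lines (59.3/67.2 keV doublets) can be
superimposed via `k_lines=True` but are off by default: their intensity
depends on the unknown head geometry and cannot be grounded.

## Materials and data provenance

Mixtures follow the added-mass convention: C mg of nanoparticle per mL of
water gives mass fraction C/(1000+C) at density (1000+C)/1000 g/cm³. At
≤ 40 mg/mL, alternative displacement conventions differ by < 0.5%. Iron
oxide is magnetite Fe₃O₄ by default (the MRI-contrast standard; Fe₂O₃
available), expanded into Fe and O by stoichiometric mass fractions.
Nanoparticle size and shape are ignored (macroscopic mixture model):
coefficients combine by Bragg additivity with log-log interpolation,
edge-aware because every absorption edge is stored as a doublet of grid
points.

The shipped per-element tables (H, O, Al, Fe, Cu, Ag, I, Pt, Au; 1–300 keV)
are generated by `scripts/build_element_tables.py`:

* **H, O, Al, Fe, Cu, water** — totals and mass energy-absorption anchored
  on the standard published tabulations; O is recovered from the water and
  H tables through the mixture rule (this reproduces the published O table
  to three digits and makes water closure exact). The incoherent channel is
  the exact Klein–Nishina cross section (numerically integrated
  differential) with an empirical screening factor; coherent scattering is
  a screened-Thomson model; photoelectric is the remainder, so tabulated
  totals are preserved exactly.
* **Ag, I, Pt, Au** — the photoelectric coefficient is a piecewise log-log
  power law between edges with standard edge energies and jump ratios,
  anchored above the K edge on published high-Z values (Pt/Au by Z-scaling
  from the lead chain; Ag/I from their K-edge magnitudes). Mass
  energy-absorption is built as photoelectric minus the expected
  K-fluorescence loss (yield ω_K, mean K-line energy) plus the
  Klein–Nishina energy-transfer term.

Estimated data accuracy: water and the low/mid-Z elements reproduce the
reference tabulations within ~1–2% at 10–200 keV (tested); Pt/Au within
~5%; Ag/I carry the largest uncertainty (~10–20%) and feed no headline
number. Channel *splits* (used only for interaction sampling) are model-
derived and less accurate than the totals; this perturbs dose far less than
the spectrum model does.

## Transport

Analog photon Monte Carlo, vectorized over photon arrays:

* point source on the axis at SSD 20 cm, directions sampled uniformly over
  the 5 cm diameter entry disk (beam divergence included);
* exponential free paths from the mixture's total linear attenuation;
* channel selection ∝ partial coefficients at the photon energy;
* Compton: polar angle by rejection from the exact Klein–Nishina
  differential (envelope at the forward maximum), scattered energy from the
  Compton relation, azimuth uniform; the electron share E−E′ deposits in
  the interaction voxel;
* Rayleigh: Thomson angular form (1+cos²θ), no energy transfer. Atomic form
  factors are omitted — coherent scattering contributes little to absorbed
  dose and the simplification is testable (forward-peaking would slightly
  reduce the effective attenuation of the coherent channel);
* photoelectric: full local deposit, except that photoabsorption in Ag, I,
  Pt or Au above the K edge emits a K x-ray with probability
  ω_K·(1−1/jump_K), carrying a single mean K-line energy, re-emitted
  isotropically and transported like any photon. L- and low-Z K
  fluorescence (≲ 10 keV, sub-millimetre range in water) deposits locally;
* photons below 1 keV deposit locally and terminate; photons leaving the
  10 × 10 × 12 cm³ box are tallied as escaped. Per batch,
  emitted = deposited + escaped exactly (tested to 1e-6 relative).

**Kerma approximation.** Secondary electrons are not transported: at
≤ 220 kVp the CSDA range of any secondary electron is ≲ 0.7 mm in water,
far below the 1 cm depth bins, so depositing transferred energy at the
interaction site is accurate at the scoring resolution. This replaces the
reference implementation's condensed-history electron transport with a
~10 keV effective cutoff.

**K-fluorescence transport is on by default.** A magnitude analysis made
this non-optional: for gold under the 220 kVp beam, ω_K ≈ 0.96 and the
~69.5 keV mean K photon (5 cm mean free path in water) remove roughly half
of the locally transferred energy from the interaction voxel; suppressing
the mechanism inflates the first-bin DER by tens of percent. The single
mean-line approximation (Kα/Kβ intensity-weighted) is adequate because the
line energies span only a few keV. The flag `k_fluorescence=False`
recovers pure local deposition.

**Randomness and reproducibility.** One master seed per run; batches use
`SeedSequence`-spawned substreams, so results are bit-reproducible for a
fixed configuration, and the batch count only affects variance estimation,
not the expectation. Study sweeps derive per-run seeds from a master seed
by spawn keys recorded in the manifest.

## Scoring and statistics

Voxels are 0.5 × 0.5 × 1.0 cm (lateral × lateral × depth); depth bins are
centred at 0.5, 1.5, … 11.5 cm, chosen to match the depths at which the
reference results are quoted (0.5 and 5.5 cm). Central-axis dose sums the
four voxels whose lateral centres lie within 0.5 cm of the axis. Dose is
keV per gram per source photon; uncertainties come from the spread of
(default) 10 independent batches, and DER uncertainties add the two
relative errors in quadrature. Bins where the water dose vanishes are
flagged undefined rather than reported as 0 or ∞. Both percent-contrast
conventions are provided: `ratio_percent` (new/old × 100, the convention
under which a rise from 1.10 to 3.77 prints as ~343%) and
`increase_percent` ((new−old)/old × 100, ~243% for the same pair).

## Problem sizes

Default runs use 2 × 10⁶ histories (the package's desk-scale choice,
~1% first-bin relative error; the reference study used 2 × 10⁸ for ±1%
everywhere). The deep-bin (5.5 cm) gold value uses 10⁷ histories because
the deep mixture dose is ~50× smaller than at the surface. The engine
transports ~0.5–1 × 10⁶ histories per second per core, so the full
52-run sweep at default statistics completes in under two minutes.

## Deterministic cross-check

`surface_der_estimate` computes the kerma ratio
Σ w(E)·E·(μ_en/ρ)_mix / Σ w(E)·E·(μ_en/ρ)_water over the unhardened
incident spectrum — a closed-form first-bin DER that ignores attenuation
and scatter. It links the Monte Carlo to the tabulated data through an
independent path: at C ≤ 7 mg/mL the two agree within 10% (tested); at
40 mg/mL the estimate exceeds the simulation by ~50% because the soft
spectral component self-screens within the first centimetre — physics the
estimate cannot see, which is why the Monte Carlo is the method of record.

## What the tests do and do not show

The oracle suite (energy conservation, Beer–Lambert recovery of the
attenuation coefficient in a photoelectric-only medium, chi-square
agreement of the Klein–Nishina sampler with the analytic density,
inverse-square emission geometry, water-vs-water DER ≡ 1, reference-table
agreement of water coefficients) validates the engine's physics
independently of any reproduction target. The reproduction band for
printed DER values is ±15%, reflecting the spectrum-model dependence
above; values driven by the soft 105 kVp component (gold at 3 mg/mL, iron
oxide at 105 kVp, the 105-vs-220 contrast, the 5.5 cm deep bin) exceed
that band with this spectrum model and are reported as computed. The
synthetic source term emulates beam *quality* (kVp + filtration), not any
specific machine; agreement on ordering and scaling behaviour (material Z,
concentration, energy, depth) is therefore the robust scientific content,
while absolute DER values inherit the spectrum uncertainty.

## Known limitations

* No electron transport (kerma approximation) — fine at 1 cm depth bins,
  wrong for sub-millimetre or nanoscale dosimetry questions.
* No bound-Compton (Doppler) effects; incoherent screening is an empirical
  factor on the exact free-electron Klein–Nishina cross section.
* Rayleigh without form factors.
* Single mean K line per element; no L-fluorescence transport.
* Homogeneous phantom only; no CT-based heterogeneity.
* Ag/I cross-section data are semi-empirical (~10–20%); treat silver and
  iodine DER values as indicative.
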