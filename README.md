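# nanodose

A desk-scale kilovoltage photon Monte Carlo dose engine for studying
nanoparticle radiosensitization in orthovoltage (skin) radiotherapy.

Heavy-metal nanoparticles (gold, platinum, iodine, silver, iron oxide)
loaded into tissue strongly absorb kilovoltage photons through the
photoelectric effect, whose cross section rises steeply with atomic number
and falls steeply with photon energy. `nanodose` quantifies the resulting
dose enhancement in a water phantom: it builds filtered x-ray tube spectra,
transports photons through water/nanoparticle mixtures with analog Monte
Carlo, scores voxel energy deposition under the kerma approximation, and
reduces everything to the **dose enhancement ratio**

```
DER(d) = D_np(d) / D_water(d)
```

— the central-axis dose at depth *d* with nanoparticles present divided by
the dose at the same depth in plain water, per source photon.

## What is modelled

* **Beams** — Kramers bremsstrahlung continua, N(E) ∝ Z·(E_max − E)/E on
  1 keV bins, hardened through the stated added filtration: 105 kVp with
  2.4 mm Al, and 220 kVp with 1 mm Al + 1.2 mm Cu (HVL ≈ 2.0 mm Cu).
  Optional tungsten K lines; half-value-layer diagnostics.
* **Materials** — water plus water+nanoparticle mixtures at 3–40 mg per mL
  of water (added-mass convention: mass fraction C/(1000+C), density
  (1000+C)/1000 g/cm³). Photon coefficients come from shipped per-element
  tables (photoelectric/incoherent/coherent and mass energy-absorption,
  1–300 keV, edge-resolved) combined by Bragg additivity with log-log
  interpolation.
* **Transport** — analog photon Monte Carlo in a 10 × 10 × 12 cm³ phantom
  (point source, SSD 20 cm, 5 cm diameter field): exponential free paths,
  channel selection from partial coefficients, exact Klein–Nishina Compton
  sampling, Thomson-form Rayleigh scattering, 1 keV photon cutoff, and
  K-fluorescence x-rays of Ag/I/Pt/Au re-emitted and transported. Energy
  transferred to electrons is deposited at the interaction voxel (kerma
  approximation). Energy is conserved exactly per batch.
* **Scoring** — 0.5 × 0.5 × 1.0 cm voxels; central-axis depth dose within a
  0.5 cm scoring radius in 1 cm depth bins (centers 0.5, 1.5, … cm); batch
  statistics for uncertainties; DER with propagated errors.

## Worked example

```python
import nanodose as nd
from nanodose.transport import TransportConfig, run_simulation
from nanodose.scoring import compute_der, depth_dose

beam = nd.beam_105()
print(f"mean energy: {beam.mean_energy:.1f} keV")

water_grid = run_simulation(beam, nd.water(),
                            config=TransportConfig(n_histories=1_000_000, rng_seed=1))
gold_grid = run_simulation(beam, nd.nanoparticle_mixture("gold", 40),
                           config=TransportConfig(n_histories=1_000_000, rng_seed=2))
der = compute_der(depth_dose(gold_grid), depth_dose(water_grid))
for d, v, u in list(zip(der.depth_cm, der.der, der.rel_unc))[:6]:
    print(f"depth {d:4.1f} cm   DER {v:5.2f} +- {v*u:.2f}")
```

prints (about a minute on one core):

```
mean energy: 46.7 keV
depth  0.5 cm   DER  4.12 +- 0.04
depth  1.5 cm   DER  2.35 +- 0.03
depth  2.5 cm   DER  1.66 +- 0.03
depth  3.5 cm   DER  1.30 +- 0.03
depth  4.5 cm   DER  1.04 +- 0.04
depth  5.5 cm   DER  0.88 +- 0.04
```

Gold at 40 mg/mL roughly quadruples the first-centimetre dose under the
105 kVp beam, and the enhancement decays with depth — the nanoparticle-
loaded medium also *shields* the beam, so by ~5 cm the mixture receives
less dose than plain water (DER < 1). The deterministic kerma-ratio
estimate `nd.surface_der_estimate(beam, mixture)` gives 6.40 for this
configuration: an upper bound that ignores the strong in-bin
self-attenuation the Monte Carlo resolves; at dilute concentrations
(≤ 7 mg/mL) estimate and simulation agree within 10%.

The full 5-material × 5-concentration × 2-beam sweep (52 simulations,
shared water baselines, CSV + figures + manifest):

```bash
nanodose study --config configs/study.yaml --out study_out
```

## Layout

| module | contents |
|---|---|
| `nanodose.spectra` | Kramers spectra, filtration, sampling, HVL |
| `nanodose.materials` | elements, mixtures, mass attenuation / energy absorption |
| `nanodose.transport` | analog photon Monte Carlo engine |
| `nanodose.scoring` | dose grids, depth dose, DER, summary tables |
| `nanodose.study` | full sweep orchestration, kerma-ratio estimate |
| `nanodose.cli` | `nanodose spectrum / simulate / study / summarize / plot` |
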