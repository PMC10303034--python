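# Full dose-enhancement study configuration: five nanoparticle materials at
# five concentrations under the two filtered clinical beams, each against a
# shared plain-water baseline (52 simulations in total).
materials: [gold, platinum, iodine, silver, iron_oxide]
concentrations_mg_per_ml: [3, 7, 18, 30, 40]
beams:
  - kvp: 105
    filters:
      - {material: Al, thickness_mm: 2.4}
  - kvp: 220
    filters:
      - {material: Al, thickness_mm: 1.0}
      - {material: Cu, thickness_mm: 1.2}
run:
  n_histories: 2000000   # desk-scale; the reference study used 2e8
  n_batches: 10
  photon_cutoff_keV: 1.0
  k_fluorescence: true
  seed: 0
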