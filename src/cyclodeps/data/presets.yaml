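# Simulation manifest presets (desk-scale).
# "demo" exercises every pipeline stage with planted truth; "null" has no
# planted group effect or microbe-metabolite coupling; "strong-signal"
# pushes the group effect to the permutation floor.
demo:
  seed: 0
  peptides:
    - [Phe, Lxx, Hba, Phe, Lxx, Hda]
    - [Phe, Lxx, Lac, Phe, Lxx, Hda]
    - [Phe, Lxx, Lac, Phe, Lxx, Hdda]
    - [Phe, Lxx, Hba, Phe, Lxx, Hdda]
  adducts: [M+Na]
  ppm_sd: 5.0
  n_noise: 20
  n_stations: 9
  station_exposures: [exposed, submerged, exposed, submerged, submerged,
                      submerged, submerged, exposed, exposed]
  n_samples_per_station: 12
  n_blanks: 3
  n_features: 500
  n_washout: 30
  n_blank_contaminated: 20
  n_enriched: 30
  effect_size: 4.0
  dropout: 0.05
  n_otus: 300
  depth: 50000
  n_planted_pairs: 10
  coupling_noise: 0.1

"null":
  seed: 0
  peptides:
    - [Phe, Lxx, Hba, Phe, Lxx, Hda]
  adducts: [M+Na]
  ppm_sd: 5.0
  n_noise: 20
  n_stations: 9
  station_exposures: [exposed, submerged, exposed, submerged, submerged,
                      submerged, submerged, exposed, exposed]
  n_samples_per_station: 12
  n_blanks: 3
  n_features: 500
  n_washout: 30
  n_blank_contaminated: 20
  n_enriched: 0
  effect_size: 1.0
  dropout: 0.05
  n_otus: 300
  depth: 50000
  n_planted_pairs: 0
  coupling_noise: 0.1

strong-signal:
  seed: 0
  peptides:
    - [Phe, Lxx, Hba, Phe, Lxx, Hda]
  adducts: [M+Na]
  ppm_sd: 5.0
  n_noise: 20
  n_stations: 9
  station_exposures: [exposed, submerged, exposed, submerged, submerged,
                      submerged, submerged, exposed, exposed]
  n_samples_per_station: 12
  n_blanks: 3
  n_features: 500
  n_washout: 30
  n_blank_contaminated: 20
  n_enriched: 30
  effect_size: 8.0
  dropout: 0.05
  n_otus: 300
  depth: 50000
  n_planted_pairs: 10
  coupling_noise: 0.1
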