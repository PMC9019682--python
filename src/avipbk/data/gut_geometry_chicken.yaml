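# Small-intestine geometry template for the chicken, used by the
# synthetic-data generator and the gut-area calculators.
#
# Provenance notes:
#   - lengths, villus height/width, microvillus geometry: printed table values
#   - villus density_per_um2 is null -> reconstructed at load time from the
#     tabulated villus amplification factor via D' = (VAF-1)/(pi*H*W)
#     (the underlying densities were never published)
#   - lumen_diameter_cm is RECONSTRUCTED (not printed): a uniform 0.7107 cm
#     makes the total absorptive area computed from this template (nominal
#     cylinder x VAF x MAF per segment) equal the tabulated 7.78 m^2
#     (4.86 m^2/kg at 1.6 kg body weight)
schema_version: 1
species: chicken
body_weight_kg: 1.6
segments:
  duodenum:
    length_cm: 26.6
    lumen_diameter_cm: 0.7107
    lumen_diameter_reconstructed: true
    villus:
      height_um: 1357.0
      width_um: 276.8
      density_per_um2: null
      vaf_tabulated: 11.62
    microvillus:
      length_um: 1.463
      diameter_um: 0.0705
      density_per_um2: 113.0
  jejunum:
    length_cm: 59.3
    lumen_diameter_cm: 0.7107
    lumen_diameter_reconstructed: true
    villus:
      height_um: 960.0
      width_um: 148.1
      density_per_um2: null
      vaf_tabulated: 9.04
    microvillus:
      length_um: 1.467
      diameter_um: 0.0705
      density_per_um2: 76.8
  ileum:
    length_cm: 42.7
    lumen_diameter_cm: 0.7107
    lumen_diameter_reconstructed: true
    villus:
      height_um: 721.0
      width_um: 216.2
      density_per_um2: null
      vaf_tabulated: 7.93
    microvillus:
      length_um: 1.029
      diameter_um: 0.0787
      density_per_um2: 104.1
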