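# Class-typical surface-reflectance signatures (band order BLUE, GREEN, RED,
# NIR, SWIR1, SWIR2) used by the synthetic-scene generator.  Values are
# dimensionless reflectances chosen to reproduce the spectral contrasts the
# indicators rely on: water high GREEN / very low NIR-SWIR, vegetation high
# NIR / low RED, built-up and bare surfaces bright in SWIR, aquaculture ponds
# water-like but slightly more turbid.  thermal_dn emulates a single-channel
# thermal band in digital numbers (hotter over sealed and bare surfaces).
version: 1
noise_sd: 0.012
thermal_dn_sd: 2.0
classes:
  cultivated land:
    reflectance: [0.06, 0.09, 0.10, 0.35, 0.22, 0.14]
    thermal_dn: 142.0
  forest:
    reflectance: [0.04, 0.07, 0.05, 0.45, 0.18, 0.08]
    thermal_dn: 128.0
  water:
    reflectance: [0.06, 0.08, 0.05, 0.02, 0.01, 0.01]
    thermal_dn: 118.0
  grassland:
    reflectance: [0.06, 0.10, 0.09, 0.38, 0.23, 0.12]
    thermal_dn: 138.0
  shrubland:
    reflectance: [0.05, 0.08, 0.07, 0.30, 0.20, 0.11]
    thermal_dn: 134.0
  bare land:
    reflectance: [0.14, 0.18, 0.22, 0.28, 0.35, 0.30]
    thermal_dn: 158.0
  aquaculture pond:
    reflectance: [0.07, 0.10, 0.08, 0.06, 0.04, 0.03]
    thermal_dn: 122.0
  artificial surface:
    reflectance: [0.18, 0.20, 0.23, 0.26, 0.32, 0.34]
    thermal_dn: 162.0
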