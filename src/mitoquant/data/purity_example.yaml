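# Example 8-plex reporter purity matrix for the six channels used in the
# C1/C2/LOF1/LOF2/HOF1/HOF2 design.  The values are of vendor-certificate
# STYLE only (a few percent of -1/+1 Da bleed); they are NOT a real reagent
# lot certificate.  Supply your own lot's matrix for real data.
# matrix[i][j] = fraction of channel j reagent observed in channel i.
channels: [113, 115, 116, 117, 118, 119]
matrix:
  - [0.930, 0.000, 0.000, 0.000, 0.000, 0.000]
  - [0.000, 0.931, 0.020, 0.000, 0.000, 0.000]
  - [0.000, 0.030, 0.924, 0.021, 0.001, 0.000]
  - [0.000, 0.001, 0.029, 0.926, 0.022, 0.001]
  - [0.000, 0.000, 0.001, 0.028, 0.925, 0.023]
  - [0.000, 0.000, 0.000, 0.001, 0.027, 0.924]
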