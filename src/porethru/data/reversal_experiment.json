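{
  "comment": "Reversal-potential experiment: 0.1 mM K2SO4 background on both sides; 0.25 mM protamine sulfate added to cis; 11 mobile sulfate counterions per Ptm(21+). Voltage convention: V_m = V_trans - V_cis, cis grounded. null P marks the permeability to be inferred.",
  "temperature_K": 298.15,
  "species": [
    {"name": "K", "z": 1, "P": 1.0, "c_cis_M": 2.0e-4, "c_trans_M": 2.0e-4},
    {"name": "Ptm", "z": 21, "P": 1.0, "c_cis_M": 2.5e-4, "c_trans_M": 0.0},
    {"name": "SO4", "z": -2, "P": null, "c_cis_M": 2.85e-3, "c_trans_M": 1.0e-4}
  ]
}
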