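# porethru

Quantitative analysis of passive peptide translocation through the ΔCymA
nanopore — the wide (~15 Å), cation-selective channel obtained by deleting
the N-terminal loop of CymA, the cyclodextrin-uptake porin of *Klebsiella
oxytoca*. The analyte is protamine (Ptm), a 32-residue, 21-arginine
polycation with effective charge +21 e. The package is for membrane
biophysicists who want the three standard experimental readouts of peptide
permeation analysed in one tested pipeline:

1. **Reversal-potential electrodiffusion** (`porethru.electrodiffusion`) —
   multivalent Goldman–Hodgkin–Katz charge flux
   `Φ_i = P_i z_i² u (c_cis − c_trans e^{z_i u})/(e^{z_i u} − 1)`,
   `u = F V_m/RT`; zero-current potentials by root finding; inference of an
   unknown permeability ratio from a measured V_rev by exact linear solve.
2. **Single-channel blockage statistics** (`porethru.event_analysis`, with
   the `porethru.trace_synth` generator) — hysteresis-threshold event
   detection, event rate f_e with exact Poisson CIs, left-truncated
   exponential dwell-time (τ_d) fits, and log-linear extrapolation of both
   to zero voltage.
3. **Liposome tandem-assay kinetics** (`porethru.liposome_assay`) —
   competitive CX4/LCG/peptide binding equilibrium, saturable per-channel
   transport `j(C) = k_exit k_entry C/(k_entry C + k_exit)`, fluorescence
   time-course simulation, and the inverse estimator from initial
   fluorescence rate to molecules·s⁻¹·channel⁻¹.

`porethru.peptide` handles sequence parsing and the charge bookkeeping
(net charge, arginine count, sulfate counterion stoichiometry) that the
electrodiffusion model assumes.

## Worked example

The reversal-potential experiment: 0.1 mM K₂SO₄ on both sides of the
bilayer, 0.25 mM protamine sulfate added to the cis (grounded) side, a
reversal potential of −20 mV measured at the trans side. Running

```
python analysis/01_peptide_charge.py
python analysis/02_reversal_potential.py
```

prints

```
Ptm: 32 residues, 21 Arg, net charge +21 e, 11 sulfate counterions (free-base mass 4249.93 Da)
11 sulfates/peptide: inferred P_SO4/P_K = 43.5 at -20 mV; forward V_rev at 1:1:48 = -20.86 mV
10.5 sulfates/peptide: inferred P_SO4/P_K = 45.9 at -20 mV; forward V_rev at 1:1:48 = -20.38 mV
```

Reading: treating the peptide as a +21 point charge accompanied by 11
mobile divalent sulfates, and tying the peptide permeability to that of
K⁺, the measured −20 mV implies sulfate permeates ~44–48× faster than
either cation — i.e. each translocating peptide is accompanied by tens of
counterions. The forward solve at the nominal 1:1:48 ratio lands within a
millivolt of the measurement, so the pair (−20 mV, 48) is self-consistent.

The synthetic pipelines (`analysis/03_electrophysiology_recovery.py`,
`analysis/04_assay_kinetics.py`) close the loop on the stochastic stages:

```
V (mV)  events  f_e (/s)  tau_d (ms)
    -20     325      1.62       66.6
   -100    3168     15.84       13.5
zero-voltage event rate: recovered 0.95 /s (true 1.00)
...
rate spread over 10x concentration range: 1.8% (exit-limited transport)
recovered k_exit = 1.87 /s (true 2.0 /s, error 6.5%)
```

Event rates rise and dwell times shrink with voltage; extrapolating the
fitted rates to 0 V recovers the spontaneous ~1 event/s entry rate at 1 µM.
In the liposome assay the initial fluorescence slope is independent of the
outside concentration — the signature that exit from the channel, not
entry, limits transport — and inverting the fluorescence mapping recovers
the per-channel flux of ~2 molecules/s.

A `porethru` CLI exposes the same operations
(`porethru peptide`, `porethru ghk rev|infer|flux`, `porethru simulate`,
`porethru detect`, `porethru dwell`, `porethru vtrend`,
`porethru assay simulate|flux`, `porethru worked-example`,
`porethru recovery-suite`); every subcommand emits a JSON report with a
metadata block.

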