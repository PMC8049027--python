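# Methods

`porethru` quantifies passive translocation of the polycationic peptide
protamine (Ptm, 32 residues, 21 Arg, effective charge +21 e) through the
ΔCymA nanopore, combining three independent lines of analysis: multivalent
reversal-potential electrodiffusion, single-channel blockage-event
statistics, and liposome indicator-displacement influx kinetics. Every
stochastic stage has a synthetic-data generator, so the full chain is
validated by parameter recovery rather than against withheld experimental
files.

## Peptide charge model

The net charge is the count of charged side chains at neutral pH: +1 per
Arg/Lys, −1 per Asp/Glu. His and the termini are excluded by default (the
termini can be switched on, contributing +1 and −1, net zero for a free
peptide). For protamine this gives +21 e — equal to the arginine count —
which is the valence the electrodiffusion analysis uses. Counterion
stoichiometry is `ceil(|q|/|z_c|)`: 11 divalent sulfates for +21. The
free-base sequence mass (≈4.25 kDa by residue-mass summation) is a
convenience only; the commonly quoted ~5.1 kDa refers to the sulfate salt,
so no analysis depends on the mass.

The packaged FASTA carries the canonical salmine A1 protamine sequence; its
transcription is validated by the three counts above (32 residues, 21 Arg,
+21 e).

## Electrodiffusion (GHK)

Per species of valence `z`, relative permeability `P` and bath
concentrations `c_cis`, `c_trans`, the constant-field charge flux is

    Φ(V) = P z² u (c_cis − c_trans e^{zu}) / (e^{zu} − 1),   u = F V_m / R T,

with `V_m = V_trans − V_cis` (cis grounded) and positive Φ meaning
cation-equivalent charge moving cis → trans. The form is fixed by two
requirements: Φ → P z (c_cis − c_trans) as V → 0 (Fick), and Φ = 0 exactly
at the Nernst potential. Numerically, the series branch is taken for
|z u| < 1e−6 and the exponential is rewritten for |z u| > 30 so that a +21
valence at ±300 mV cannot overflow. The total flux is strictly monotone
(decreasing) in V for nonnegative permeabilities, so the reversal potential
is the unique root, found by Brent on [−300, 300] mV to 1e−10 mV.

Because Φ is linear in each `P_i`, one unknown permeability is inferred from
a measured reversal potential by an exact linear solve. One measured V_rev
cannot determine two ratios, so the three-species protamine problem is
closed by tying P_Ptm = P_K — an assumption of the analysis, not a result.

The experiment's ionic bookkeeping: 0.1 mM K₂SO₄ both sides (0.2 mM K⁺,
0.1 mM SO₄²⁻ per side); 0.25 mM protamine sulfate added to cis, counted as
0.25 mM Ptm²¹⁺ plus 11 × 0.25 mM sulfate. The alternative exact-balance
stoichiometry (10.5 sulfates per peptide) is a config switch; the inferred
ratio moves from 43.5 to 45.9 and the forward reversal potential from
−20.86 to −20.38 mV, so nothing rests on the choice. Temperature is
298.15 K.

Zero-voltage molar fluxes are reported as the relative quantity
`P (c_cis − c_trans)`; an absolute molecules/s scale must be supplied by the
caller. Note that under the 1:1:48 ratio and the 11× sulfate bookkeeping the
P·ΔC sulfate-to-peptide flux ratio is 528:1 — the free-solution GHK flux
does not capture the saturable per-channel transport that actually limits
the peptide rate (see the assay model below), which is why absolute fluxes
are derived from the assay and the single-channel statistics instead.

## Synthetic gating traces

A two-state alternating renewal process is the minimal generative model
consistent with discrete complete-closure blockages and single-exponential
dwell fits: open sojourns Exp(k_on), blocked sojourns Exp(1/τ_d), with

    k_on(V, C) = k_on0 · C_µM · exp(α_on |V|),
    τ_d(V) = τ0 · exp(−α_off |V|).

The exponential voltage dependence makes log-linear extrapolation to V = 0
exact on synthetic data, so extrapolation accuracy is attributable to the
estimation chain, not model mismatch. Defaults (k_on0 = 1 /s/µM,
α_on = 0.03 /mV, τ0 = 0.1 s, α_off = 0.02 /mV at 1 µM) put the event rate at
1.6–16 /s and dwells at 67–13 ms over −20…−100 mV — millisecond-range
blockages at a few per second, the regime of the protamine recordings — and
an extrapolated zero-voltage rate in the 1–2 events/s range.

The ideal two-level trace (open 50 pA, blocked 0 pA by default) is sampled
at 50 kHz (the acquisition rate is an implementation choice; only the
2.5 kHz analysis filter is prescribed by the recordings), corrupted with
i.i.d. Gaussian noise, and low-pass filtered with a Gaussian FIR kernel
whose −3 dB point is the configured cutoff. A Gaussian kernel stands in for
the recording chain's 4-pole Bessel filter: both are monotone-step,
non-ringing low-pass responses, and the Gaussian has a closed-form σ for a
given cutoff. Blockages shorter than the filter rise time remain in the
ground-truth ledger; detector attrition is measured, not hidden. A blockage
still in progress at the end of the recording is truncated at the boundary.

What the generator does not emulate: open-channel flicker and substates
(the wild-type channel's N-terminal-loop noise), 1/f noise, baseline drift,
and multi-channel recordings. Passing recovery tests therefore demonstrate
the correctness of the estimation chain under the two-state model, not
robustness to every artefact of real recordings.

## Event statistics

Detection is hysteresis thresholding: the open level is the trace median,
the blocked level the median of samples more than 4 noise-SDs below it
(noise scale = 1.4826 × MAD), the entry threshold sits at 50% of the
amplitude, and exit requires recovery past an additional 10% hysteresis
band. Traces whose two levels are not separated by at least 6 noise-SDs are
declared event-free rather than thresholded inside the noise. Events
shorter than `min_dwell` (default three samples) and events touching either
boundary are discarded; the boundary-discard bias is O(τ/duration).

The event rate is `n/T` with an exact Poisson 95% CI (χ² quantiles; the
zero-count upper bound is 3.689/T). The dwell fit is the left-truncated
exponential MLE: for exponential data observed above a known bound t_min,
mean(dwell − t_min) is unbiased by memorylessness, so detector attrition at
short dwells does not bias τ_d provided t_min is at or above the effective
detection limit. The 95% CI is a 1000-resample nonparametric bootstrap with
a fixed seed. Zero-voltage extrapolation is OLS of ln(value) on |V| with
the intercept exponentiated back; both the rate and the dwell series use
the same form.

The end-to-end recovery benchmark (five voltages −20…−100 mV, 200 s each,
seeded) recovers k_on0·C and τ0 within 15% and both voltage sensitivities
within 20%; observed errors are ≤6%.

## Liposome tandem assay

The lumen holds the reporter pair: 700 µM calixarene (CX4) and 500 µM
lucigenin (LCG). Competitive 1:1 binding (CX4·LCG with K_CL, CX4·Ptm with
K_CP) reduces to a single monotone equation in free CX4, solved by Brent to
machine precision; conservation of all three totals then holds to better
than 1e−12 relative. Relative fluorescence is linear in the free-LCG
fraction between `f_floor` and `f_ceiling`. The binding constants are not
fixed by the translocation experiments themselves (they belong to the
reporter-pair literature); the package defaults K_CL = 1e5 L/mol,
K_CP = 1e7 L/mol are fixtures chosen to make displacement thermodynamically
favourable, and every check on this module is a round-trip or property
test, never a comparison against a printed fluorescence value.

Transport through one channel is the two-step saturable law
`j(C) = k_exit k_entry C / (k_entry C + k_exit)`, bounded by the
rate-limiting exit step. Influx into a liposome of diameter d (default
100 nm, one channel — both standing in for an unavailable independent size
estimate, both configurable) integrates

    dC_in/dt = n_ch (j(c_out) − j(c_free_in)) / (N_A V_lip),  V_lip = (π/6) d³,

with LSODA at rtol 1e−8; efflux uses the same law on the CX4-unbound
internal peptide (symmetric channel, consistent with permeation being
observed from both sides). Internal CX4 buffers the free peptide, so efflux
is negligible early in the time course; the initial-rate window (default
0.1 s on synthetic curves) must stay inside that early regime. One molecule
in a 100 nm lumen is ≈3.2 µM, so a 2 /s flux moves the lumen concentration
at ≈6 µM/s.

The initial rate is the least-squares slope of f_rel over a window starting
at the first point above baseline + 3σ (σ from the pre-addition segment; on
noiseless synthetic curves the rise starts at the first sample). The
inverse estimator divides the rate by the baseline fluorescence gain
df_rel/dC_in (one-sided second-order finite difference at C_in = 0, step =
one molecule's worth of concentration) and converts to molecules/s/channel
via N_A V_lip / n_ch. In the exit-limited regime (k_entry c_out ≫ k_exit)
initial rates across a 10-fold concentration range agree within 2% and the
round trip recovers k_exit within 7% — the concentration-independence
signature that identifies channel exit as the rate-limiting step, with
per-channel fluxes of order 1–3 molecules/s at µM gradients.

## Degenerate inputs and tie-breaks

Zero analyte concentration produces a valid open trace with an empty
ledger; an event-free or level-unresolvable trace yields an empty event
table; dwell fits require ≥50 events and reject degenerate (all-equal)
dwells; extrapolation requires ≥3 strictly positive points; the equilibrium
solver accepts zero totals; `flux_per_channel` refuses a saturated assay
(zero gain) and zero channels.

## Known limitations

- The 1:1 permeability tie and the 11× sulfate bookkeeping are modelling
  choices; the reversal-potential data alone cannot resolve them.
- Absolute fluxes require either the assay-side calibration (liposome size
  and channel count per liposome) or a conductance calibration; the package
  reports relative GHK fluxes and assay-derived per-channel fluxes, and
  makes no claim of absolute calibration beyond the round-trip validated
  estimator.
- Multivalent Ptm–CX4 binding (one peptide engaging several calixarenes) is
  not modelled; stoichiometry is 1:1.
- The dwell model is a single exponential; mixtures (e.g. translocation vs
  retraction populations) are out of scope, as is discriminating the two
  from current traces alone.
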