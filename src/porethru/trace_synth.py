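"""Synthetic single-channel current traces with a ground-truth event ledger.

The generative model is a two-state alternating renewal process: the channel
is open until a peptide enters (rate ``k_on``, proportional to analyte
concentration and exponentially voltage-sensitive) and blocked for an
exponentially distributed dwell of mean ``tau_d`` (exponentially shortened by
voltage).  The ideal two-level trace is corrupted with per-sample Gaussian
noise and low-pass filtered with a Gaussian FIR kernel whose -3 dB point
matches the recording filter (2.5 kHz by default).  Every blockage, including
those shorter than the filter rise time, is recorded in the ground-truth
ledger so that detector attrition can be measured rather than hidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d


@dataclass(frozen=True)
class GatingModel:
    """Voltage-dependent two-state gating kinetics.

    k_on(V, C) = k_on0 * C_uM * exp(alpha_on * |V|)   [events/s]
    tau_d(V)   = tau0 * exp(-alpha_off * |V|)         [s]

    k_on0 is the zero-voltage entry rate per uM of analyte; tau0 the
    zero-voltage mean dwell.  The exponential |V| dependence makes log-linear
    extrapolation of fitted rates back to V = 0 exact for synthetic data.
    """

    k_on0: float = 1.0       # events / s / uM at V = 0
    alpha_on: float = 0.03   # 1/mV
    tau0: float = 0.1        # s
    alpha_off: float = 0.02  # 1/mV

    def __post_init__(self) -> None:
        if self.k_on0 <= 0 or self.tau0 <= 0:
            raise ValueError("k_on0 and tau0 must be positive")
        if self.alpha_on < 0 or self.alpha_off < 0:
            raise ValueError("voltage sensitivities must be nonnegative")

    def k_on(self, V_mV: float, concentration_uM: float) -> float:
        return self.k_on0 * concentration_uM * math.exp(self.alpha_on * abs(V_mV))

    def tau_d(self, V_mV: float) -> float:
        return self.tau0 * math.exp(-self.alpha_off * abs(V_mV))


@dataclass(frozen=True)
class TraceConfig:
    """Sampling, current levels, noise and filtering of a synthetic recording."""

    duration: float                  # s
    sampling_rate: float = 50_000.0  # Hz
    i_open: float = 50.0             # pA
    i_blocked: float = 0.0           # pA (complete closure)
    noise_sd: float = 0.0            # pA, per raw sample before filtering
    filter_cutoff: float | None = 2500.0  # Hz (-3 dB); None disables
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.i_open == self.i_blocked:
            raise ValueError("open and blocked levels must differ")
        if self.filter_cutoff is not None and (
            self.sampling_rate <= 2 * self.filter_cutoff
        ):
            raise ValueError("sampling_rate must exceed twice the filter cutoff")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.sampling_rate)


@dataclass(frozen=True)
class CurrentTrace:
    sampling_rate: float
    samples: np.ndarray  # pA

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class EventLedger:
    """Ground-truth blockages as (onset_s, dwell_s), non-overlapping, sorted."""

    onsets: np.ndarray
    dwells: np.ndarray

    def __post_init__(self) -> None:
        if len(self.onsets) != len(self.dwells):
            raise ValueError("onsets and dwells must have equal length")
        if len(self.onsets) and (
            np.any(np.diff(self.onsets) <= 0) or np.any(self.dwells <= 0)
        ):
            raise ValueError("onsets must be strictly increasing, dwells positive")

    def __len__(self) -> int:
        return len(self.onsets)


def _gaussian_sigma_samples(cutoff_hz: float, fs: float) -> float:
    """Std-dev (in samples) of the Gaussian kernel with -3 dB point at cutoff.

    |H(f)| = exp(-2 pi^2 sigma_t^2 f^2) = 1/sqrt(2) at f = cutoff.
    """
    sigma_t = math.sqrt(math.log(2.0)) / (2.0 * math.pi * cutoff_hz)
    return sigma_t * fs


def simulate_trace(
    gating: GatingModel,
    config: TraceConfig,
    concentration_uM: float,
    V_mV: float,
) -> tuple[CurrentTrace, EventLedger]:
    """Simulate one recording at fixed voltage and analyte concentration.

    Open sojourns are Exp(k_on(V, C)); blocked sojourns Exp(1/tau_d(V)).  The
    same seed gives bit-identical output.  Zero concentration yields an open
    trace with an empty ledger.  A blockage still in progress at the end of
    the recording is truncated at the trace boundary.
    """
    if concentration_uM < 0:
        raise ValueError("concentration must be nonnegative")
    rng = np.random.default_rng(config.seed)
    k_on = gating.k_on(V_mV, concentration_uM)
    tau = gating.tau_d(V_mV)

    onsets: list[float] = []
    dwells: list[float] = []
    t = 0.0
    if k_on > 0:
        while True:
            t += rng.exponential(1.0 / k_on)
            if t >= config.duration:
                break
            dwell = rng.exponential(tau)
            onsets.append(t)
            dwells.append(min(dwell, config.duration - t))
            t += dwell
            if t >= config.duration:
                break

    n = config.n_samples
    ideal = np.full(n, config.i_open, dtype=float)
    fs = config.sampling_rate
    for onset, dwell in zip(onsets, dwells):
        i0 = int(math.ceil(onset * fs))
        i1 = int(math.ceil((onset + dwell) * fs))
        ideal[i0 : min(i1, n)] = config.i_blocked

    samples = ideal
    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd, size=n)
    if config.filter_cutoff is not None:
        sigma = _gaussian_sigma_samples(config.filter_cutoff, fs)
        samples = gaussian_filter1d(samples, sigma, mode="nearest")

    trace = CurrentTrace(sampling_rate=fs, samples=samples)
    ledger = EventLedger(onsets=np.asarray(onsets), dwells=np.asarray(dwells))
    return trace, ledger


def simulate_voltage_series(
    gating: GatingModel,
    config: TraceConfig,
    concentration_uM: float,
    voltages_mV: list[float],
) -> list[tuple[float, CurrentTrace, EventLedger]]:
    """One independent simulation per voltage, seeded ``config.seed + index``."""
    if not voltages_mV:
        raise ValueError("voltage list must be nonempty")
    out = []
    for i, v in enumerate(voltages_mV):
        cfg = TraceConfig(
            duration=config.duration,
            sampling_rate=config.sampling_rate,
            i_open=config.i_open,
            i_blocked=config.i_blocked,
            noise_sd=config.noise_sd,
            filter_cutoff=config.filter_cutoff,
            seed=config.seed + i,
        )
        trace, ledger = simulate_trace(gating, cfg, concentration_uM, v)
        out.append((v, trace, ledger))
    return out


def trace_to_csv(trace: CurrentTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "current_pA": trace.samples}
    ).to_csv(path, index=False)


def trace_from_csv(path: str | Path) -> CurrentTrace:
    df = pd.read_csv(path)
    dt = np.diff(df["time_s"].to_numpy())
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("trace CSV must be uniformly sampled")
    return CurrentTrace(
        sampling_rate=1.0 / dt[0], samples=df["current_pA"].to_numpy(dtype=float)
    )


def ledger_to_tsv(ledger: EventLedger, path: str | Path) -> None:
    pd.DataFrame({"onset_s": ledger.onsets, "dwell_s": ledger.dwells}).to_csv(
        path, sep="\t", index=False
    )
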