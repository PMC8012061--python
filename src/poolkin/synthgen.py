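"""Synthetic data with the statistical structure the analysis assumes.

Generators for (i) capacitance flash responses from either kinetic model
plus additive Gaussian noise, (ii) paired-flash recovery experiments under
the free-pool or release-site priming model, with the forward priming rate
switched at the first stimulus, (iii) amperometric spike trains with foot
signals, and (iv) perturbed stereology measurement sets.  Everything is
driven by a seeded generator: identical seed and parameters reproduce
identical outputs bit for bit.

The default conditions mirror the experimental ones: capacitance sampled at
1 kHz on t in [-0.5, 5] s around the flash with 2 fF noise; amperometry at
25 kHz with 1 pA RMS noise; spikes placed as a Poisson process thinned by a
50 ms refractory gap so single spikes stay resolvable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .kinetics import CapacitanceTrace, DelayedSRPKinetics, FlashKinetics, SingleExpKinetics
from .pool_models import Model1Params, Model2Params, RecoveryCurve, _pool, steady_state
from .spikes import AmperometryTrace
from .stereology import StereologyInput

__all__ = [
    "NoiseSpec",
    "TimeGrid",
    "SpikeShapeSpec",
    "generate_flash_trace",
    "generate_recovery_experiment",
    "generate_spike_train",
    "generate_stereology_sample",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive i.i.d. Gaussian measurement noise and the random seed."""

    sigma_cm: float = 2.0  # fF, capacitance noise SD
    sigma_amp: float = 1.0  # pA, current noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_cm < 0 or self.sigma_amp < 0:
            raise ValueError("noise SDs must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid around the flash at t = 0."""

    t_start: float = -0.5  # s, pre-flash
    t_end: float = 5.0  # s
    dt: float = 1e-3  # s

    def __post_init__(self) -> None:
        if not (self.t_start < 0 < self.t_end):
            raise ValueError("grid must span the flash: t_start < 0 < t_end")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def times(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.dt)) + 1
        return self.t_start + self.dt * np.arange(n)


@dataclass(frozen=True)
class SpikeShapeSpec:
    """Template for one amperometric spike.

    A flat foot plateau (``foot_amplitude`` for ``foot_duration``) precedes
    a linear rise to ``i_max`` over ``rise_time``, followed by exponential
    decay with time constant ``decay_tau``.
    """

    i_max: float = 40.0  # pA
    rise_time: float = 1e-3  # s
    decay_tau: float = 3e-3  # s
    foot_amplitude: float = 0.0  # pA; 0 disables the foot
    foot_duration: float = 0.0  # s

    def __post_init__(self) -> None:
        if self.i_max <= 0 or self.rise_time <= 0 or self.decay_tau <= 0:
            raise ValueError("spike template parameters must be positive")
        if self.foot_amplitude < 0 or self.foot_duration < 0:
            raise ValueError("foot parameters must be non-negative")

    def render(self, fs: float) -> np.ndarray:
        """Sampled template starting at the foot onset."""
        dt = 1.0 / fs
        t_total = self.foot_duration + self.rise_time + 8.0 * self.decay_tau
        t = np.arange(0.0, t_total, dt)
        y = np.zeros_like(t)
        foot = t < self.foot_duration
        y[foot] = self.foot_amplitude
        rising = (~foot) & (t < self.foot_duration + self.rise_time)
        frac = (t[rising] - self.foot_duration) / self.rise_time
        y[rising] = self.foot_amplitude + (self.i_max - self.foot_amplitude) * frac
        tail = t >= self.foot_duration + self.rise_time
        y[tail] = self.i_max * np.exp(-(t[tail] - self.foot_duration - self.rise_time)
                                      / self.decay_tau)
        return y


def generate_flash_trace(
    kin: FlashKinetics | DelayedSRPKinetics | SingleExpKinetics,
    grid: TimeGrid = TimeGrid(),
    noise: NoiseSpec = NoiseSpec(),
) -> CapacitanceTrace:
    """Capacitance flash response: 0 before the flash, the model function
    after, plus i.i.d. Gaussian noise of SD ``sigma_cm``."""
    t = grid.times()
    cm = kin.evaluate(t)
    if noise.sigma_cm > 0:
        cm = cm + noise.rng().normal(0.0, noise.sigma_cm, size=t.shape)
    meta = {"truth": kin, "seed": noise.seed, "sigma_cm": noise.sigma_cm}
    return CapacitanceTrace(t=t, cm=cm, meta=meta)


def generate_recovery_experiment(
    params: Model1Params | Model2Params,
    intervals: Iterable[float],
    k1dp_after: float | None = None,
    n_cells_per_interval: int = 1,
    noise: NoiseSpec = NoiseSpec(),
    readout: float = 0.06,
) -> RecoveryCurve:
    """Simulated paired-flash recovery cohort.

    For each cell, Stim1 measures the pre-stimulation steady-state pool and
    Stim2 the pool recovered after the interval, with the forward priming
    rate switched to ``k1dp_after`` at the first flash (default: unchanged).
    Gaussian noise of SD sigma_cm is added to both pool estimates before
    forming the per-cell ratio Stim2/Stim1; noiseless output equals the
    model's closed form exactly.
    """
    intervals = np.asarray(list(intervals), dtype=float)
    if np.any(intervals <= 0):
        raise ValueError("intervals must be positive")
    if n_cells_per_interval < 1:
        raise ValueError("n_cells_per_interval must be >= 1")
    if k1dp_after is None:
        k1dp_after = params.k1dp
    rng = noise.rng()
    stim1_true = steady_state(params)
    p_after = replace(params, k1dp=k1dp_after)
    all_iv = np.repeat(intervals, n_cells_per_interval)
    stim2_true = _pool(all_iv, p_after, 0.0)
    if noise.sigma_cm > 0:
        stim1 = stim1_true + rng.normal(0.0, noise.sigma_cm, size=all_iv.shape)
        stim2 = stim2_true + rng.normal(0.0, noise.sigma_cm, size=all_iv.shape)
    else:
        stim1 = np.full_like(all_iv, stim1_true)
        stim2 = np.asarray(stim2_true)
    ratios = np.clip(stim2 / stim1, 0.0, None)
    return RecoveryCurve(intervals=all_iv, ratios=ratios, readout=readout)


def generate_spike_train(
    rate: float,
    shape: SpikeShapeSpec = SpikeShapeSpec(),
    duration: float = 10.0,
    noise: NoiseSpec = NoiseSpec(),
    fs: float = 25_000.0,
    refractory: float = 0.050,
) -> tuple[AmperometryTrace, np.ndarray]:
    """Poisson spike train rendered from the template plus Gaussian noise.

    Candidate event times are a Poisson process of the given rate; events
    closer than ``refractory`` to the previously kept event are dropped so
    single spikes stay resolvable.  Returns the trace and the kept event
    (foot-onset) times.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = noise.rng()
    n_samples = int(round(duration * fs)) + 1
    t = np.arange(n_samples) / fs
    i = np.zeros(n_samples)

    kept: list[float] = []
    if rate > 0:
        n_events = rng.poisson(rate * duration)
        times = np.sort(rng.uniform(0.0, duration, size=n_events))
        last = -np.inf
        for ev in times:
            if ev - last >= refractory:
                kept.append(float(ev))
                last = ev
        template = shape.render(fs)
        for ev in kept:
            start = int(round(ev * fs))
            end = min(start + template.size, n_samples)
            i[start:end] += template[: end - start]
    if noise.sigma_amp > 0:
        i = i + rng.normal(0.0, noise.sigma_amp, size=n_samples)
    return AmperometryTrace(t=t, i=i, fs=fs), np.asarray(kept)


def generate_stereology_sample(
    truth: StereologyInput,
    noise: NoiseSpec = NoiseSpec(),
    rel_sd: float = 0.05,
) -> StereologyInput:
    """Perturbed copy of a stereology measurement set for robustness tests.

    Gaussian jitter of relative SD ``rel_sd`` is applied to the measured
    quantities (density, diameter, linear density); jittered values are
    clipped to stay positive.  ``rel_sd = 0`` returns the input unchanged.
    """
    if rel_sd < 0:
        raise ValueError("rel_sd must be non-negative")
    if rel_sd == 0:
        return truth
    rng = noise.rng()

    def jitter(x: float) -> float:
        if x == 0:
            return 0.0
        return float(max(x * (1.0 + rng.normal(0.0, rel_sd)), 1e-6 * x))

    return replace(
        truth,
        delta_v=jitter(truth.delta_v),
        d_v=jitter(truth.d_v),
        n_l=jitter(truth.n_l),
    )
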