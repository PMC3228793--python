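"""Input event streams: presynaptic spike trains and astrocytic Ca2+ signals.

Everything downstream of the astrocyte consumes only the *times* of
gliotransmitter release events (GREs), so the Ca2+ trace generators are
deliberately generic parametric oscillators: an amplitude- and/or
frequency-modulated sinusoid standing in for the stereotypical limit-cycle
shapes of IP3-driven Ca2+ dynamics.  A GRE is emitted whenever the trace
crosses the exocytosis threshold ``C_thr`` from below.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrain",
    "CaSignal",
    "GRESchedule",
    "gen_poisson_train",
    "gen_periodic_train",
    "gen_paired_pulses",
    "gen_ca_signal",
    "detect_gres",
    "gen_gre_schedule",
    "read_times",
    "write_times",
]

CA_MODES = ("AM", "FM", "AFM", "flat")


def _check_event_times(times: np.ndarray, duration: float | None = None) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("event times must be a 1-D sequence")
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("event times must be strictly increasing")
    if times.size and duration is not None:
        if times[0] < 0 or times[-1] > duration:
            raise ValueError("event times must lie in [0, duration]")
    return times


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted presynaptic spike times (seconds) on [0, duration]."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        object.__setattr__(self, "times", _check_event_times(self.times, self.duration))

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class GRESchedule:
    """Sorted gliotransmitter-release-event times (seconds).

    ``f_c`` records the nominal GRE frequency when the schedule is periodic;
    it is informational only.
    """

    times: np.ndarray
    f_c: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", _check_event_times(self.times))

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class CaSignal:
    """Sampled intracellular Ca2+ trace in normalized units.

    ``mode`` is one of AM / FM / AFM / flat; ``params`` stores the generator
    parameters so a signal is self-describing.
    """

    mode: str
    t: np.ndarray
    c: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in CA_MODES:
            raise ValueError(f"unknown Ca signal mode {self.mode!r}")
        t = np.asarray(self.t, dtype=float)
        c = np.asarray(self.c, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("time grid and trace must be 1-D of equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "c", c)


def gen_poisson_train(rate: float, duration: float, seed: int) -> SpikeTrain:
    """Homogeneous Poisson spike train at ``rate`` Hz on [0, duration].

    Sampling is by exponential inter-arrival times; the seed is mandatory so
    every stochastic trial is reproducible from a single integer.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate == 0:
        return SpikeTrain(np.empty(0), duration)
    rng = np.random.default_rng(seed)
    # draw in blocks until the cumulative sum passes `duration`
    times: list[np.ndarray] = []
    t = 0.0
    block = max(16, int(rate * duration * 1.2))
    while t <= duration:
        isi = rng.exponential(1.0 / rate, size=block)
        chunk = t + np.cumsum(isi)
        times.append(chunk)
        t = chunk[-1]
    all_times = np.concatenate(times)
    return SpikeTrain(all_times[all_times <= duration], duration)


def gen_periodic_train(freq: float, n_spikes: int, t0: float = 0.0) -> SpikeTrain:
    """Regular train: spikes at t0 + k/freq for k = 0..n_spikes-1."""
    if freq <= 0:
        raise ValueError("freq must be positive")
    if n_spikes < 1:
        raise ValueError("n_spikes must be at least 1")
    times = t0 + np.arange(n_spikes) / freq
    return SpikeTrain(times, float(times[-1]) + 1.0 / freq)


def gen_paired_pulses(isi: float, pair_rate: float, n_pairs: int) -> SpikeTrain:
    """Spike pairs (t_k, t_k + isi) with pair onsets at t_k = k / pair_rate."""
    if pair_rate <= 0:
        raise ValueError("pair_rate must be positive")
    if not 0 < isi < 1.0 / pair_rate:
        raise ValueError("isi must be positive and shorter than the pair period")
    if n_pairs < 1:
        raise ValueError("n_pairs must be at least 1")
    onsets = np.arange(n_pairs) / pair_rate
    times = np.sort(np.concatenate([onsets, onsets + isi]))
    return SpikeTrain(times, float(times[-1]) + 1.0 / pair_rate)


def gen_ca_signal(mode: str, params: dict, duration: float, dt: float) -> CaSignal:
    """Stereotypical Ca2+ oscillation trace.

    The trace oscillates between the baseline ``C_0`` and at most ``C_max``:

        C(t) = C_0 + a * (C_max - C_0) * (1 - cos(2*pi*f_eff*t)) / 2

    where the amplitude fraction ``a`` (AM, AFM) and the frequency ``f_eff``
    (FM, AFM) are set by the modulation law ``m_0 + k * I_b`` applied to the
    stimulus bias ``I_b``.  ``flat`` returns the constant baseline.  The exact
    functional form is an implementation detail: downstream code consumes
    only the threshold-crossing times.

    params keys (all optional, with defaults): C_0=0, C_max=1, f_C=0.1 Hz,
    m_0=1.0, k=0.0, I_b=0.0.
    """
    if mode not in CA_MODES:
        raise ValueError(f"unknown Ca signal mode {mode!r}")
    if dt <= 0 or duration <= 0:
        raise ValueError("duration and dt must be positive")
    p = {"C_0": 0.0, "C_max": 1.0, "f_C": 0.1, "m_0": 1.0, "k": 0.0, "I_b": 0.0}
    unknown = set(params) - set(p)
    if unknown:
        raise ValueError(f"unknown Ca signal parameters: {sorted(unknown)}")
    p.update(params)
    if not 0 <= p["C_0"] <= p["C_max"]:
        raise ValueError("need 0 <= C_0 <= C_max")
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    drive = np.clip(p["m_0"] + p["k"] * p["I_b"], 0.0, 1.0)
    if mode == "flat":
        c = np.full_like(t, p["C_0"])
    else:
        amp_frac = drive if mode in ("AM", "AFM") else 1.0
        f_eff = p["f_C"] * (drive if mode in ("FM", "AFM") else 1.0)
        c = p["C_0"] + amp_frac * (p["C_max"] - p["C_0"]) * 0.5 * (
            1.0 - np.cos(2.0 * np.pi * f_eff * t)
        )
    return CaSignal(mode, t, c, dict(p))


def detect_gres(
    signal: CaSignal, c_thr: float, *, trigger_if_initial_above: bool = False
) -> GRESchedule:
    """One GRE per upward crossing of ``c_thr`` (rising-edge semantics).

    Crossing times are linearly interpolated between grid points.  A trace
    that *starts* at or above threshold emits an event at t[0] only when
    ``trigger_if_initial_above`` is set: a sustained suprathreshold plateau
    must fall below threshold before it can trigger again.
    """
    t, c = signal.t, signal.c
    times = []
    if c.size and c[0] >= c_thr and trigger_if_initial_above:
        times.append(t[0])
    below = c[:-1] < c_thr
    above = c[1:] >= c_thr
    idx = np.nonzero(below & above)[0]
    for i in idx:
        frac = (c_thr - c[i]) / (c[i + 1] - c[i])
        times.append(t[i] + frac * (t[i + 1] - t[i]))
    return GRESchedule(np.asarray(times, dtype=float))


def gen_gre_schedule(f_c: float, duration: float, onset: float = 0.0) -> GRESchedule:
    """Periodic GREs at 1/f_c spacing starting at ``onset`` (default 0)."""
    if f_c < 0:
        raise ValueError("f_c must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if f_c == 0:
        return GRESchedule(np.empty(0), f_c=0.0)
    times = onset + np.arange(int(np.floor((duration - onset) * f_c)) + 1) / f_c
    return GRESchedule(times[times < duration], f_c=f_c)


def write_times(times: np.ndarray, path: str | os.PathLike) -> None:
    """Write event times as plain text, one per line; CSV gets a `time_s` header."""
    times = np.asarray(times, dtype=float)
    header = "time_s" if str(path).endswith(".csv") else ""
    np.savetxt(path, times, fmt="%.9f", header=header, comments="")


def read_times(path: str | os.PathLike) -> np.ndarray:
    """Read event times written by :func:`write_times`."""
    skip = 1 if str(path).endswith(".csv") else 0
    times = np.loadtxt(path, skiprows=skip, ndmin=1)
    return np.asarray(times, dtype=float)
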