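"""Retinal spike-train generation and injected currents.

Retinal ganglion cells (ON-center Y type) are modeled as renewal processes
with gamma-distributed interspike intervals: rate 30 Hz (mean ISI 33.33 ms)
and shape k = 3 by default, giving ISI CV = 1/sqrt(3). Synchronization
across N retinal lines is imposed by letting M = 1 + round(S*(N-1)) lines
replay one common train, so S = (M-1)/(N-1). Spike-time jitter delays each
spike by an independent exponential draw of mean J.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain", "RetinalGenSpec", "CurrentSpec", "gamma_spike_train",
    "synchronize_lines", "jitter_spikes", "injected_current",
    "save_spike_trains", "load_spike_trains",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike event times (ms) over [0, duration]."""

    times: np.ndarray
    duration: float
    source: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and (np.any(~np.isfinite(t)) or np.any(np.diff(t) <= 0)):
            raise ValueError("spike times must be finite and strictly increasing")
        if t.size and (t[0] < 0 or t[-1] > self.duration):
            raise ValueError("spike times outside [0, duration]")

    def __len__(self) -> int:
        return self.times.size

    @property
    def rate(self) -> float:
        """Mean firing rate in Hz."""
        return 1000.0 * self.times.size / self.duration

    def isi(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass(frozen=True)
class RetinalGenSpec:
    """Gamma renewal-process parameters for one retinal line."""

    mean_isi: float = 1000.0 / 30.0   # ms (30 Hz)
    shape: float = 3.0                # gamma shape k
    duration: float = 100_000.0       # ms

    def __post_init__(self):
        if self.mean_isi <= 0 or self.duration <= 0:
            raise ValueError("mean_isi and duration must be positive")
        if self.shape < 1:
            raise ValueError("gamma shape must be >= 1")

    @property
    def scale(self) -> float:
        """Gamma scale theta = mean_isi / k (ms)."""
        return self.mean_isi / self.shape


@dataclass(frozen=True)
class CurrentSpec:
    """Constant plus zero-offset sine current (nA, Hz, rad)."""

    i_const: float = 0.0
    sine_amp: float = 0.0
    sine_freq: float = 0.0
    phase: float = 0.0

    def __post_init__(self):
        if self.sine_amp < 0:
            raise ValueError("sine amplitude must be nonnegative")


def gamma_spike_train(spec: RetinalGenSpec, rng: np.random.Generator,
                      source: str = "retina") -> SpikeTrain:
    """Draw one gamma-renewal spike train truncated at spec.duration."""
    # draw in blocks until past the duration
    n_guess = int(spec.duration / spec.mean_isi * 1.5) + 32
    times = np.cumsum(rng.gamma(spec.shape, spec.scale, size=n_guess))
    while times.size and times[-1] < spec.duration:
        extra = np.cumsum(rng.gamma(spec.shape, spec.scale, size=n_guess))
        times = np.concatenate([times, times[-1] + extra])
    return SpikeTrain(times[times < spec.duration], spec.duration, source)


def synchronize_lines(n_lines: int, s_ret: float, spec: RetinalGenSpec,
                      rng: np.random.Generator) -> list[SpikeTrain]:
    """N retinal lines of which M = 1 + round(S*(N-1)) replay a common train.

    The common lines come first in the returned list; the reference line
    (index 0) is always one of them.
    """
    if not 0.0 <= s_ret <= 1.0:
        raise ValueError("retinal synchronization must be in [0, 1]")
    if n_lines < 1:
        raise ValueError("need at least one retinal line")
    if n_lines == 1:
        return [gamma_spike_train(spec, rng)]
    m = 1 + int(np.floor(s_ret * (n_lines - 1) + 0.5))
    common = gamma_spike_train(spec, rng)
    out = [common] * m
    for _ in range(n_lines - m):
        out.append(gamma_spike_train(spec, rng))
    return out


def jitter_spikes(train: SpikeTrain, j_mean: float,
                  rng: np.random.Generator) -> SpikeTrain:
    """Delay each spike by an independent Exponential(mean j_mean) draw.

    Jitter is one-sided (pure delay); the output is re-sorted, which may
    reorder spikes. Spike count is preserved; the duration is extended by
    whatever tail the delays produce.
    """
    if j_mean < 0:
        raise ValueError("mean jitter must be nonnegative")
    if j_mean == 0 or len(train) == 0:
        return train
    t = train.times + rng.exponential(j_mean, size=train.times.size)
    t = np.sort(t)
    t = _strictify(t)
    return SpikeTrain(t, max(train.duration, float(t[-1]) + 1e-9), train.source)


def _strictify(t: np.ndarray) -> np.ndarray:
    """Break exact ties by an epsilon so times are strictly increasing."""
    for i in range(1, t.size):
        if t[i] <= t[i - 1]:
            t[i] = np.nextafter(t[i - 1], np.inf)
    return t


def injected_current(spec: CurrentSpec, t) -> np.ndarray | float:
    """I(t) = I_const + A*sin(2*pi*f*t/1000 + phi), t in ms, I in nA."""
    return spec.i_const + spec.sine_amp * np.sin(
        2.0 * np.pi * spec.sine_freq * np.asarray(t) / 1000.0 + spec.phase)


# ---------------------------------------------------------------------------
# persistence: two-column CSV (time_ms, unit_id)
# ---------------------------------------------------------------------------

def save_spike_trains(trains: list[SpikeTrain], path) -> None:
    rows = [(t, i) for i, tr in enumerate(trains) for t in tr.times]
    pd.DataFrame(rows, columns=["time_ms", "unit_id"]).to_csv(path, index=False)


def load_spike_trains(path, duration: float | None = None) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    if duration is None:
        duration = float(df["time_ms"].max()) + 1.0 if len(df) else 1.0
    out = []
    for uid in sorted(df["unit_id"].unique()):
        t = np.sort(df.loc[df["unit_id"] == uid, "time_ms"].to_numpy(float))
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"unit {uid}: times not strictly increasing")
        out.append(SpikeTrain(t, duration, f"unit{uid}"))
    return out
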