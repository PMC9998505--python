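"""Core time-series containers.

A :class:`TimeCourse` is the universal unit of analysis: one uniformly
sampled fMRI signal (a region sum or a single voxel) together with its
sampling interval ``dt`` (the TR after any resampling) and the time ``t0``
of its first retained sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["TimeCourse", "StimulusParadigm"]


@dataclass(frozen=True)
class TimeCourse:
    """A uniformly sampled signal.

    Parameters
    ----------
    values : ndarray
        Signal samples, arbitrary (scanner) units.
    dt : float
        Sampling interval in seconds.
    t0 : float
        Acquisition time of the first sample, seconds.
    label : str
        Free-form name (region, voxel index, ...).
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if values.ndim != 1 or values.size < 2:
            raise ValueError("values must be a 1-D vector of length >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")

    # -- convenience -----------------------------------------------------
    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Total covered time in seconds (n * dt)."""
        return self.values.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) * self.dt

    def with_values(self, values: np.ndarray, **kwargs) -> "TimeCourse":
        return replace(self, values=np.asarray(values, dtype=float), **kwargs)

    # -- IO ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, label: str = "") -> "TimeCourse":
        df = pd.read_csv(path)
        if not {"time_s", "value"} <= set(df.columns):
            raise ValueError("time-course CSV needs columns time_s,value")
        t = df["time_s"].to_numpy(float)
        dts = np.diff(t)
        if t.size < 2 or not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform")
        return cls(df["value"].to_numpy(float), dt=float(dts[0]), t0=float(t[0]),
                   label=label)


@dataclass(frozen=True)
class StimulusParadigm:
    """Block stimulation paradigm: onset/duration pairs in seconds."""

    onsets: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        if onsets.size != durations.size:
            raise ValueError("onsets and durations must have equal length")
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(durations <= 0):
            raise ValueError("durations must be positive")

    def __len__(self) -> int:
        return self.onsets.size

    @classmethod
    def block(cls, n_blocks: int = 20, stim_s: float = 5.0, rest_s: float = 25.0,
              start_s: float = 0.0) -> "StimulusParadigm":
        """Regular block design; defaults: 5 s stimulation, 25 s rest, 20 blocks."""
        onsets = start_s + np.arange(n_blocks) * (stim_s + rest_s)
        return cls(onsets, np.full(n_blocks, float(stim_s)))

    def boxcar(self, n: int, dt: float, t0: float = 0.0) -> np.ndarray:
        """Sample the on/off indicator on a uniform grid of ``n`` points."""
        t = t0 + np.arange(n) * dt
        box = np.zeros(n)
        for on, dur in zip(self.onsets, self.durations):
            box[(t >= on) & (t < on + dur)] = 1.0
        return box

    def to_csv(self, path) -> None:
        pd.DataFrame({"onset_s": self.onsets, "duration_s": self.durations}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "StimulusParadigm":
        df = pd.read_csv(path)
        return cls(df["onset_s"].to_numpy(float), df["duration_s"].to_numpy(float))
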