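"""Region time-course preprocessing.

Mirrors the standard rodent-fMRI reduction: discard the first seconds of
each scan (pre-steady-state), sum voxel signals per atlas region,
downsample to 1-s resolution by bin averaging, and normalize each course to
its mean.  Frequency characterization (module :mod:`hdotools.spectral`)
works on the un-downsampled course, which is why ``resample_to_1s`` is a
separate, optional step.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .timecourse import TimeCourse

__all__ = [
    "trim_presteady",
    "extract_region_time_courses",
    "resample_to_1s",
    "normalize_mean",
    "read_region_table",
]


def trim_presteady(tc: TimeCourse, trim_s: float = 5.0) -> TimeCourse:
    """Drop samples acquired before ``t0 + trim_s`` (default first 5 s)."""
    if trim_s < 0:
        raise ValueError("trim_s must be >= 0")
    n_drop = int(round(trim_s / tc.dt))
    if n_drop >= len(tc):
        raise ValueError(
            f"trim of {trim_s} s would remove the whole {tc.duration} s course")
    if n_drop == 0:
        return tc
    return tc.with_values(tc.values[n_drop:], t0=tc.t0 + n_drop * tc.dt)


def read_region_table(path) -> pd.DataFrame:
    """Two-column region table CSV (id,name); ids unique positive integers."""
    df = pd.read_csv(path)
    if not {"id", "name"} <= set(df.columns):
        raise ValueError("region table needs columns id,name")
    _validate_region_table(df)
    return df[["id", "name"]]


def _validate_region_table(table: pd.DataFrame) -> None:
    ids = table["id"].to_numpy()
    if ids.size != np.unique(ids).size:
        raise ValueError("region ids must be unique")
    if np.any(ids <= 0):
        raise ValueError("region ids must be positive (0 is background)")


def extract_region_time_courses(volume: np.ndarray, labels: np.ndarray,
                                table: pd.DataFrame, dt: float,
                                t0: float = 0.0) -> list[TimeCourse]:
    """Sum voxel signals per labelled region.

    ``volume`` is (x, y, z, t), ``labels`` an integer volume of the same
    spatial shape; ``table`` maps label ids to region names.  Regions with
    no voxels are omitted with a warning.
    """
    volume = np.asarray(volume, dtype=float)
    labels = np.asarray(labels)
    if volume.ndim != 4:
        raise ValueError("volume must be 4-D (x, y, z, t)")
    if labels.shape != volume.shape[:3]:
        raise ValueError(
            f"label shape {labels.shape} does not match volume {volume.shape[:3]}")
    _validate_region_table(table)
    out = []
    for rid, name in zip(table["id"], table["name"]):
        mask = labels == rid
        if not mask.any():
            warnings.warn(f"region {name!r} (id {rid}) has no voxels; omitted",
                          stacklevel=2)
            continue
        summed = volume[mask].sum(axis=0)
        out.append(TimeCourse(summed, dt=dt, t0=t0, label=str(name)))
    return out


def resample_to_1s(tc: TimeCourse, bin_s: float = 1.0) -> TimeCourse:
    """Downsample by averaging the samples falling into each 1-s bin.

    Bin averaging (rather than decimation) acts as an anti-aliasing filter
    by construction and preserves the overall signal mean exactly when the
    course length is a whole number of bins.  An incomplete trailing bin is
    dropped.
    """
    if tc.dt > bin_s:
        raise ValueError(f"cannot upsample: dt={tc.dt} s exceeds the {bin_s}-s bin")
    ratio = bin_s / tc.dt
    if abs(ratio - round(ratio)) > 1e-6:
        raise ValueError(
            f"bin of {bin_s} s is not an integer multiple of dt={tc.dt} s")
    ratio = int(round(ratio))
    if ratio == 1:
        return tc
    n_bins = len(tc) // ratio
    binned = tc.values[:n_bins * ratio].reshape(n_bins, ratio).mean(axis=1)
    return tc.with_values(binned, dt=bin_s)


def normalize_mean(tc: TimeCourse) -> TimeCourse:
    """Divide by the mean so the returned course has mean exactly 1."""
    m = tc.values.mean()
    scale = np.max(np.abs(tc.values))
    if scale == 0 or abs(m) < 1e-12 * scale:
        raise ValueError("cannot normalize a zero-mean time course")
    return tc.with_values(tc.values / m)
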