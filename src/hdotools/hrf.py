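"""Rodent hemodynamic response function.

Double-gamma impulse response with a fast positive lobe (peak near 2.8 s in
rat under medetomidine-type sedation) and a late undershoot.  The peak time,
undershoot time and undershoot ratio are configuration, not fixed truth:
rodent HRFs vary with strain, anesthesia and stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["HRFParams", "hrf", "hrf_basis"]


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma parameters.

    peak_delay : seconds to the positive-lobe maximum (rat default 2.8 s).
    undershoot_delay : seconds to the undershoot minimum.
    dispersion : gamma scale of the positive lobe, seconds.  Larger values
        widen the response.
    undershoot_ratio : undershoot amplitude relative to the peak (0.35).
    """

    peak_delay: float = 2.8
    undershoot_delay: float = 7.0
    dispersion: float = 0.6
    undershoot_dispersion: float = 1.2
    undershoot_ratio: float = 0.35


def _gamma_lobe(t: np.ndarray, delay: float, disp: float) -> np.ndarray:
    # shape chosen so the gamma mode sits at `delay`: mode = (k - 1) * scale
    k = delay / disp + 1.0
    y = stats.gamma.pdf(t, k, scale=disp)
    peak = stats.gamma.pdf(delay, k, scale=disp)
    return y / peak


def hrf(t: np.ndarray, params: HRFParams | None = None) -> np.ndarray:
    """Evaluate the HRF at times ``t`` (seconds); peak normalized to 1."""
    p = params or HRFParams()
    t = np.asarray(t, dtype=float)
    pos = _gamma_lobe(t, p.peak_delay, p.dispersion)
    neg = _gamma_lobe(t, p.undershoot_delay, p.undershoot_dispersion)
    return pos - p.undershoot_ratio * neg


def hrf_basis(dt: float, duration: float = 32.0,
              params: HRFParams | None = None) -> np.ndarray:
    """3rd-order canonical basis sampled at ``dt``.

    Columns: HRF, its temporal derivative and its dispersion derivative
    (finite differences in time shift and in the dispersion parameter).
    """
    p = params or HRFParams()
    t = np.arange(0.0, duration, dt)
    h = hrf(t, p)
    # temporal derivative: d/dt via a 0.1-s shift
    dshift = 0.1
    dtemp = (hrf(t, p) - hrf(t - dshift, p)) / dshift
    # dispersion derivative: central difference on the positive-lobe scale
    ddisp_step = 0.01
    p_hi = HRFParams(p.peak_delay, p.undershoot_delay, p.dispersion + ddisp_step,
                     p.undershoot_dispersion, p.undershoot_ratio)
    p_lo = HRFParams(p.peak_delay, p.undershoot_delay, p.dispersion - ddisp_step,
                     p.undershoot_dispersion, p.undershoot_ratio)
    ddisp = (hrf(t, p_hi) - hrf(t, p_lo)) / (2 * ddisp_step)
    return np.column_stack([h, dtemp, ddisp])
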